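"""Counter-propagation network for two-reaction mixture classification.

A counter-propagation network couples a Kohonen input layer with an output
layer of the same grid geometry that acts as a look-up table.  Training is
semi-supervised: winners are selected *exclusively* on the input layer
(identically to an unsupervised map, so with the same seed the input layer is
bitwise equal to a plain SOM), while the output weights of the winner and its
neighborhood are moved toward the object's target vector with the same
learning rate and triangular kernel.

Targets encode the mixture composition as a binary vector over the reaction
types: exactly two components are 1 (the two types present in the mixture).
A prediction reads the winning neuron's output weights; the mixture class is
assigned only when *exactly two* output values exceed the decision threshold
(0.5 by default) — otherwise the object is left undecided.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .registry import TypeRegistry, default_registry
from .som import UNDECIDED, _find_winners, _train_grid, majority_vote

__all__ = ["encode_target", "decide_mixture", "CPNNClassifier", "CPNNEnsemble"]


def encode_target(mclass: str, registry: TypeRegistry | None = None) -> np.ndarray:
    """Binary type-indicator target of a mixture class (two ones, rest zeros)."""
    registry = registry or default_registry()
    return registry.target_vector(mclass)


def decide_mixture(
    output: np.ndarray,
    threshold: float = 0.5,
    registry: TypeRegistry | None = None,
) -> str:
    """Class of the two types whose outputs exceed ``threshold``, else undecided.

    Values exactly equal to the threshold do not count ("higher than").
    """
    registry = registry or default_registry()
    output = np.asarray(output, dtype=float)
    if output.shape != (registry.n_types,):
        raise ValueError(
            f"output must have length {registry.n_types}, got shape {output.shape}"
        )
    above = np.flatnonzero(output > threshold)
    if len(above) != 2:
        return UNDECIDED
    return registry.mixture_class(registry.types[above[0]], registry.types[above[1]])


class CPNNClassifier(BaseEstimator, ClassifierMixin):
    """Counter-propagation network over the toroidal Kohonen grid.

    Shares all training hyperparameters with
    :class:`~rxnmix.som.SOMClassifier`; adds the decision ``threshold`` of
    the exactly-two-above rule.  Output weights start at the uninformative
    midpoint 0.5 and, being convex combinations of values in [0, 1], remain
    in [0, 1] throughout training.
    """

    def __init__(
        self,
        rows: int = 49,
        cols: int = 49,
        epochs: int = 75,
        lr0: float = 0.1,
        span0: int | None = None,
        threshold: float = 0.5,
        random_state: int | None = None,
    ):
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.lr0 = lr0
        self.span0 = span0
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y, registry: TypeRegistry | None = None):
        """Train on descriptor rows ``X`` with mixture-class labels ``y``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        self.registry_ = registry or default_registry()
        targets = np.stack([encode_target(str(lab), self.registry_) for lab in y])
        span0 = self.span0 if self.span0 is not None else min(self.rows, self.cols) // 2
        rng = np.random.default_rng(self.random_state)
        self.weights_, self.output_weights_ = _train_grid(
            X,
            self.rows,
            self.cols,
            self.epochs,
            self.lr0,
            int(span0),
            rng,
            targets=targets,
        )
        self.classes_ = np.unique(y.astype(str)).astype(object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_types(self, X) -> np.ndarray:
        """Six-value output vectors: the winning neurons' output weights."""
        check_is_fitted(self, "output_weights_")
        X = np.asarray(X, dtype=float)
        winners = _find_winners(self.weights_, X)
        return self.output_weights_[winners]

    def predict(self, X):
        """Mixture class per row, or ``UNDECIDED`` under the two-above rule."""
        outputs = self.predict_types(X)
        return np.array(
            [decide_mixture(o, self.threshold, self.registry_) for o in outputs],
            dtype=object,
        )


class CPNNEnsemble(BaseEstimator, ClassifierMixin):
    """Majority vote over independently trained counter-propagation nets."""

    def __init__(
        self,
        n_members: int = 5,
        rows: int = 49,
        cols: int = 49,
        epochs: int = 75,
        lr0: float = 0.1,
        span0: int | None = None,
        threshold: float = 0.5,
        random_state: int | None = None,
    ):
        self.n_members = n_members
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.lr0 = lr0
        self.span0 = span0
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y, registry: TypeRegistry | None = None):
        if self.n_members < 1:
            raise ValueError("ensemble needs at least one member")
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_members)
        self.members_ = []
        for ss in seeds:
            net = CPNNClassifier(
                rows=self.rows,
                cols=self.cols,
                epochs=self.epochs,
                lr0=self.lr0,
                span0=self.span0,
                threshold=self.threshold,
                random_state=int(ss.generate_state(1)[0] % (2**31)),
            )
            self.members_.append(net.fit(X, y, registry=registry))
        self.classes_ = self.members_[0].classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "members_")
        votes = np.stack([m.predict(X) for m in self.members_])
        return majority_vote(votes)
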