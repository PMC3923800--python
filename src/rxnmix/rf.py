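"""Random-forest mixture classification with vote-fraction reliability.

The 15-way mixture-class problem is handled by a bagged ensemble of unpruned
classification trees (bootstrap samples, random sqrt(p) feature subsets per
split), delegated to scikit-learn's ``RandomForestClassifier``.  On top of
the delegated forest this module provides

* hard-vote prediction probabilities: the fraction of trees voting for the
  winning class, used as a per-prediction reliability score;
* probability-threshold reliability tables (predictions retained at
  increasing vote-fraction cutoffs, with per-class counts and true-positive
  percentages);
* y-randomization: retraining on label-scrambled data as a sanity check that
  the model's accuracy reflects genuine structure.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MixtureForest",
    "y_randomization",
    "threshold_filter",
]

DEFAULT_THRESHOLDS = (0.0, 0.5, 0.6, 0.8)


class MixtureForest(BaseEstimator, ClassifierMixin):
    """Random forest over mixture descriptors with vote-fraction probabilities.

    Parameters
    ----------
    n_trees : int, default 1000
        Number of trees in the forest.
    vars_per_split : int or None
        Variables tested at each split; ``None`` uses floor(sqrt(p)).
    random_state : int or None
        Seed for bootstrap sampling and feature subsets.

    Attributes
    ----------
    forest_ : the fitted delegated ensemble.
    oob_accuracy_ : float
        Out-of-bag accuracy estimate (fraction in [0, 1]).
    classes_ : sorted class labels.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        vars_per_split: int | None = None,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.vars_per_split = vars_per_split
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes to train a classifier")
        p = X.shape[1]
        max_features = self.vars_per_split
        if max_features is None:
            max_features = max(1, math.floor(math.sqrt(p)))
        if not (1 <= max_features <= p):
            raise ValueError(f"vars_per_split must be in [1, {p}]")
        with warnings.catch_warnings():
            # tiny fixtures can leave a few rows never out-of-bag; harmless here
            warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
            self.forest_ = RandomForestClassifier(
                n_estimators=self.n_trees,
                max_features=max_features,
                bootstrap=True,
                oob_score=True,
                n_jobs=1,
                random_state=self.random_state,
            ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.oob_accuracy_ = float(self.forest_.oob_score_)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.predict_with_probability(X)["predicted"].to_numpy()

    def vote_fractions(self, X) -> np.ndarray:
        """Per-class fraction of trees voting for each row of ``X``."""
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was trained with {self.n_features_in_}"
            )
        counts = np.zeros((len(X), len(self.classes_)))
        for tree in self.forest_.estimators_:
            # trees store the forest's label encoding: predictions are class indices
            leaf_class = np.argmax(tree.predict_proba(X), axis=1)
            counts[np.arange(len(X)), leaf_class] += 1.0
        return counts / len(self.forest_.estimators_)

    def predict_with_probability(self, X, ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Majority-vote class and its vote fraction per row.

        Exact vote ties are broken by class-label order and flagged in the
        ``tie`` column.
        """
        fracs = self.vote_fractions(X)
        best = np.argmax(fracs, axis=1)  # argmax takes the first = class order
        prob = fracs[np.arange(len(fracs)), best]
        tie = (fracs == prob[:, None]).sum(axis=1) > 1
        df = pd.DataFrame(
            {
                "predicted": self.classes_[best],
                "probability": prob,
                "tie": tie,
            }
        )
        if ids is not None:
            df.insert(0, "mixture_id", list(ids))
        return df


def y_randomization(
    X,
    y,
    X_test,
    y_test,
    n_repeats: int = 5,
    n_trees: int = 1000,
    vars_per_split: int | None = None,
    random_state: int | None = None,
) -> list[float]:
    """Test accuracies of models retrained on label-scrambled training data.

    The descriptor matrix is kept unchanged; only the label column is
    permuted (freshly per repeat).  A trustworthy model's true accuracy
    should sit far above every scrambled accuracy, which should hover near
    the no-information rate.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    y_test = np.asarray(y_test)
    rng = np.random.default_rng(random_state)
    accs: list[float] = []
    for k in range(n_repeats):
        y_scrambled = y[rng.permutation(len(y))]
        model = MixtureForest(
            n_trees=n_trees,
            vars_per_split=vars_per_split,
            random_state=int(rng.integers(2**31)),
        ).fit(X, y_scrambled)
        pred = model.predict(X_test)
        accs.append(float(np.mean(pred == y_test)))
    return accs


def threshold_filter(
    predictions: pd.DataFrame,
    truths: Sequence,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Reliability table: per class and vote-fraction cutoff, the number of
    mixtures predicted for that class and the true-positive percentage among
    them, plus a ``Total`` row per cutoff.

    ``predictions`` must carry ``predicted`` and ``probability`` columns (as
    produced by :meth:`MixtureForest.predict_with_probability`).  Threshold 0
    reproduces the unfiltered counts.
    """
    truths = np.asarray(truths)
    pred = predictions["predicted"].to_numpy()
    prob = predictions["probability"].to_numpy()
    if len(pred) != len(truths):
        raise ValueError("predictions and truths must be aligned")
    if classes is None:
        classes = sorted(set(map(str, np.concatenate([pred.astype(str), truths.astype(str)]))))

    rows = []
    for thr in thresholds:
        keep = prob >= thr
        for cls in classes:
            sel = keep & (pred == cls)
            n_pred = int(sel.sum())
            n_correct = int((truths[sel] == cls).sum())
            rows.append(
                {
                    "class": cls,
                    "threshold": thr,
                    "n_predicted": n_pred,
                    "n_correct": n_correct,
                    "pct_correct": 100.0 * n_correct / n_pred if n_pred else np.nan,
                }
            )
        n_pred = int(keep.sum())
        n_correct = int((pred[keep] == truths[keep]).sum())
        rows.append(
            {
                "class": "Total",
                "threshold": thr,
                "n_predicted": n_pred,
                "n_correct": n_correct,
                "pct_correct": 100.0 * n_correct / n_pred if n_pred else np.nan,
            }
        )
    return pd.DataFrame(rows)


def stratified_cv_accuracy(
    X, y, n_folds: int = 10, n_trees: int = 1000, random_state: int | None = None
) -> float:
    """Stratified k-fold cross-validation accuracy of the forest (fraction)."""
    model = MixtureForest(n_trees=n_trees, random_state=random_state)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    scores = cross_val_score(model, np.asarray(X, dtype=float), np.asarray(y), cv=cv)
    return float(scores.mean())
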