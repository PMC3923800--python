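"""Toroidal Kohonen self-organizing map with neuron labeling and ensembles.

The map is a rows x cols grid of neurons living on a torus: both axes wrap,
every neuron has 8 neighbors, and topological distance is the Chebyshev
metric with per-axis wraparound.  Training is the classic competitive scheme:
each input is assigned to the neuron with the nearest weight vector
(Euclidean distance), and the winner plus its topological neighborhood are
pulled toward the input with a triangular (linearly decaying) kernel.  Both
the learning rate and the neighborhood span decrease linearly to zero over
the training cycles:

    lr(t)   = lr0  * (1 - t / epochs)
    span(t) = round(span0 * (1 - t / epochs))
    w      += lr(t) * (1 - d / (span(t) + 1)) * (x - w)   for d <= span(t)

Weights are initialized per variable from Normal(mean_j, sd_j) of the
training data.  After unsupervised training each neuron is labeled by the
classes of the training objects mapped onto it: a single class, ``None``
(empty), or a conflict (several classes; the plurality class is retained for
classification).  New objects take the label of their winning neuron; an
empty winner falls back to the nearest labeled neuron on the torus.

Because single maps fluctuate with the random initialization and the
presentation order, ensembles of independently trained maps vote by
plurality (:class:`SOMEnsemble`).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "UNDECIDED",
    "toroidal_distance",
    "SOMClassifier",
    "SOMEnsemble",
    "majority_vote",
    "save_som",
    "load_som",
]

#: Sentinel label returned when no class can be assigned.
UNDECIDED = "undecided"

#: Neuron status markers used in label maps.
EMPTY = "empty"
CONFLICT = "conflict"


def toroidal_distance(
    p1: tuple[int, int], p2: tuple[int, int], rows: int, cols: int
) -> int:
    """Chebyshev distance between two grid cells with per-axis wraparound."""
    (r1, c1), (r2, c2) = p1, p2
    for r, c in ((r1, c1), (r2, c2)):
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"coordinate ({r}, {c}) outside {rows}x{cols} grid")
    dr = abs(r1 - r2)
    dc = abs(c1 - c2)
    return int(max(min(dr, rows - dr), min(dc, cols - dc)))


def _torus_distance_matrix(rows: int, cols: int) -> np.ndarray:
    """All-pairs toroidal Chebyshev distances between flat neuron indices."""
    r = np.arange(rows)
    c = np.arange(cols)
    dr = np.abs(r[:, None] - r[None, :])
    dr = np.minimum(dr, rows - dr)
    dc = np.abs(c[:, None] - c[None, :])
    dc = np.minimum(dc, cols - dc)
    # broadcast to (rows, cols, rows, cols) then flatten pairs
    d = np.maximum(dr[:, None, :, None], dc[None, :, None, :])
    return d.reshape(rows * cols, rows * cols)


def _neighborhood_offsets(span: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row/col offsets and Chebyshev distances of all cells within ``span``."""
    rng = np.arange(-span, span + 1)
    di, dj = np.meshgrid(rng, rng, indexing="ij")
    dist = np.maximum(np.abs(di), np.abs(dj)).ravel()
    return di.ravel(), dj.ravel(), dist


def _init_weights(
    X: np.ndarray, n_neurons: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-variable Normal(mean_j, sd_j) initialization from the data."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # sd 0 -> constant init for that variable
    return rng.normal(mu, sd, size=(n_neurons, X.shape[1]))


def _train_grid(
    X: np.ndarray,
    rows: int,
    cols: int,
    epochs: int,
    lr0: float,
    span0: int,
    rng: np.random.Generator,
    targets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Shared competitive-training loop for SOM and counter-propagation nets.

    Returns the trained input-layer weights and, when ``targets`` is given,
    an output layer of the same grid shape updated with the identical
    learning rate and neighborhood kernel (winners are always selected on the
    input layer alone, so the presence of targets never changes the input
    layer's trajectory or random stream).
    """
    n, p = X.shape
    n_neurons = rows * cols
    W = _init_weights(X, n_neurons, rng)
    O = None
    if targets is not None:
        O = np.full((n_neurons, targets.shape[1]), 0.5)

    max_span = (min(rows, cols) - 1) // 2  # keeps wrapped neighborhoods duplicate-free
    spans = [
        min(max_span, int(round(span0 * (1.0 - t / epochs)))) for t in range(epochs)
    ]
    neigh = {s: _neighborhood_offsets(s) for s in set(spans)}
    w_norms = np.einsum("ij,ij->i", W, W)

    for t in range(epochs):
        lr = lr0 * (1.0 - t / epochs)
        if lr <= 0.0:
            break
        span = spans[t]
        di, dj, dist = neigh[span]
        kernel = lr * (1.0 - dist / (span + 1.0))
        order = rng.permutation(n)
        for i in order:
            x = X[i]
            winner = int(np.argmin(w_norms - 2.0 * (W @ x)))
            wi, wj = divmod(winner, cols)
            idx = ((wi + di) % rows) * cols + (wj + dj) % cols
            Wn = W[idx]
            Wn += kernel[:, None] * (x - Wn)
            W[idx] = Wn
            w_norms[idx] = np.einsum("ij,ij->i", Wn, Wn)
            if O is not None:
                On = O[idx]
                On += kernel[:, None] * (targets[i] - On)
                O[idx] = On
    return W, O


def _find_winners(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Flat index of the closest neuron for each row of ``X`` (ties: lowest)."""
    d = cdist(X, W, metric="sqeuclidean")
    return np.argmin(d, axis=1)


class SOMClassifier(BaseEstimator, ClassifierMixin):
    """Toroidal self-organizing map used as a classifier via neuron labels.

    Parameters
    ----------
    rows, cols : int, default 49
        Grid dimensions; the map is toroidal, so every neuron has 8 neighbors.
    epochs : int, default 75
        Training cycles (full passes over the data, shuffled each cycle).
    lr0 : float, default 0.1
        Initial learning rate; decays linearly to zero over the cycles.
    span0 : int or None
        Initial neighborhood span in topological (Chebyshev) units; ``None``
        means half the smaller grid dimension.
    random_state : int or None
        Seed for weight initialization and presentation order.

    Attributes
    ----------
    weights_ : ndarray of shape (rows*cols, n_features)
    label_map_ : ndarray of objects, shape (rows*cols,)
        Per neuron: a class label, ``"conflict"`` or ``"empty"``.
    effective_label_ : ndarray of objects, shape (rows*cols,)
        The label used for classification: the class, the plurality class of
        a conflict neuron (``None`` on an exact tie), or ``None`` if empty.
    classes_ : ndarray of seen class labels.
    """

    def __init__(
        self,
        rows: int = 49,
        cols: int = 49,
        epochs: int = 75,
        lr0: float = 0.1,
        span0: int | None = None,
        random_state: int | None = None,
    ):
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.lr0 = lr0
        self.span0 = span0
        self.random_state = random_state

    def _validate_config(self, n_samples: int) -> int:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2x2")
        if not (0.0 <= self.lr0 <= 1.0):
            raise ValueError("lr0 must be in [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        span0 = self.span0 if self.span0 is not None else min(self.rows, self.cols) // 2
        if n_samples < 2 * self.rows * self.cols:
            warnings.warn(
                f"{n_samples} objects for {self.rows * self.cols} neurons: fewer than "
                "two objects per neuron; consider a smaller map",
                stacklevel=2,
            )
        return int(span0)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        span0 = self._validate_config(len(X))
        rng = np.random.default_rng(self.random_state)
        self.weights_, _ = _train_grid(
            X, self.rows, self.cols, self.epochs, self.lr0, span0, rng
        )
        self.classes_ = np.unique(y.astype(str)).astype(object)
        self._label_from_winners(_find_winners(self.weights_, X), y)
        self.n_features_in_ = X.shape[1]
        return self

    def _label_from_winners(self, winners: np.ndarray, y: np.ndarray) -> None:
        n_neurons = self.rows * self.cols
        label_map = np.full(n_neurons, EMPTY, dtype=object)
        effective = np.full(n_neurons, None, dtype=object)
        counts: dict[int, dict[str, int]] = {}
        for w, lab in zip(winners, y):
            counts.setdefault(int(w), {}).setdefault(str(lab), 0)
            counts[int(w)][str(lab)] += 1
        for w, cc in counts.items():
            if len(cc) == 1:
                lab = next(iter(cc))
                label_map[w] = lab
                effective[w] = lab
            else:
                label_map[w] = CONFLICT
                best = max(cc.values())
                top = sorted(lab for lab, c in cc.items() if c == best)
                effective[w] = top[0] if len(top) == 1 else None
        self.label_map_ = label_map
        self.effective_label_ = effective
        self.neuron_counts_ = counts

    def _fallback_map(self) -> np.ndarray:
        """For every neuron, the effective label of the nearest decided neuron."""
        decided = np.array(
            [i for i, lab in enumerate(self.effective_label_) if lab is not None]
        )
        if len(decided) == 0:
            raise ValueError("model has no labeled neurons; cannot classify")
        dmat = _torus_distance_matrix(self.rows, self.cols)
        out = np.array(self.effective_label_, dtype=object)
        for i in range(len(out)):
            if out[i] is None:
                # argmin over decided neurons; ties resolved by row-major order
                j = decided[np.argmin(dmat[i, decided])]
                out[i] = self.effective_label_[j]
        return out

    def predict(self, X):
        """Class of the winning neuron; ``UNDECIDED`` on unresolvable ties."""
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        winners = _find_winners(self.weights_, X)
        resolved = self._fallback_map()
        labels = np.empty(len(X), dtype=object)
        for k, w in enumerate(winners):
            lab = self.effective_label_[w]
            if lab is None:
                if self.label_map_[w] == CONFLICT:
                    lab = UNDECIDED  # exact plurality tie on the winner itself
                else:
                    lab = resolved[w]  # empty winner: nearest labeled neuron
                    if lab is None:
                        lab = UNDECIDED
            labels[k] = lab
        return labels

    def label_summary(self) -> dict[str, float]:
        """Fractions of labeled / empty / conflict neurons over the grid."""
        check_is_fitted(self, "label_map_")
        n = len(self.label_map_)
        empty = float(np.sum(self.label_map_ == EMPTY)) / n
        conflict = float(np.sum(self.label_map_ == CONFLICT)) / n
        return {"labeled": 1.0 - empty - conflict, "empty": empty, "conflict": conflict}

    def label_map_frame(self):
        """Label map as a (row, col, status, label) table for map exports."""
        import pandas as pd

        check_is_fitted(self, "label_map_")
        rows_, cols_, status, label = [], [], [], []
        for i in range(self.rows * self.cols):
            r, c = divmod(i, self.cols)
            s = self.label_map_[i]
            rows_.append(r)
            cols_.append(c)
            status.append(s if s in (EMPTY, CONFLICT) else "labeled")
            label.append(self.effective_label_[i])
        return pd.DataFrame(
            {"row": rows_, "col": cols_, "status": status, "label": label}
        )


def majority_vote(votes: np.ndarray) -> np.ndarray:
    """Plurality vote per column of a (n_members, n_objects) label array.

    ``UNDECIDED`` votes are excluded; an exact tie among the remaining votes,
    or all members undecided, yields ``UNDECIDED``.
    """
    votes = np.asarray(votes, dtype=object)
    out = np.empty(votes.shape[1], dtype=object)
    for k in range(votes.shape[1]):
        counts: dict[str, int] = {}
        for v in votes[:, k]:
            if v != UNDECIDED:
                counts[v] = counts.get(v, 0) + 1
        if not counts:
            out[k] = UNDECIDED
            continue
        best = max(counts.values())
        top = [lab for lab, c in counts.items() if c == best]
        out[k] = top[0] if len(top) == 1 else UNDECIDED
    return out


class SOMEnsemble(BaseEstimator, ClassifierMixin):
    """Majority vote over independently trained self-organizing maps."""

    def __init__(
        self,
        n_members: int = 5,
        rows: int = 49,
        cols: int = 49,
        epochs: int = 75,
        lr0: float = 0.1,
        span0: int | None = None,
        random_state: int | None = None,
    ):
        self.n_members = n_members
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.lr0 = lr0
        self.span0 = span0
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_members < 1:
            raise ValueError("ensemble needs at least one member")
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_members)
        self.members_ = []
        for ss in seeds:
            som = SOMClassifier(
                rows=self.rows,
                cols=self.cols,
                epochs=self.epochs,
                lr0=self.lr0,
                span0=self.span0,
                random_state=int(ss.generate_state(1)[0] % (2**31)),
            )
            self.members_.append(som.fit(X, y))
        self.classes_ = self.members_[0].classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "members_")
        votes = np.stack([m.predict(X) for m in self.members_])
        return majority_vote(votes)


# ---------------------------------------------------------------------------
# Persistence: weight archive + JSON sidecar

def save_som(model: SOMClassifier, path: str | Path) -> None:
    """Persist a fitted map as ``<path>.npz`` (weights) + ``<path>.json``."""
    check_is_fitted(model, "weights_")
    path = Path(path)
    np.savez(path.with_suffix(".npz"), weights=model.weights_)
    sidecar = {
        "params": model.get_params(),
        "label_map": list(model.label_map_),
        "effective_label": list(model.effective_label_),
        "classes": list(model.classes_),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_som(path: str | Path) -> SOMClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = SOMClassifier(**sidecar["params"])
    model.weights_ = np.load(path.with_suffix(".npz"))["weights"]
    model.label_map_ = np.array(sidecar["label_map"], dtype=object)
    model.effective_label_ = np.array(sidecar["effective_label"], dtype=object)
    model.classes_ = np.array(sidecar["classes"], dtype=object)
    model.n_features_in_ = model.weights_.shape[1]
    return model
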