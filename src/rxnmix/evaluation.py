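"""Accuracy metrics, confusion tables and the robustness experiment battery.

Two accuracy conventions are reported throughout, because the map- and
network-based classifiers can leave objects undecided: ``as_error`` counts
undecided predictions as wrong (correct / total), ``exclude`` scores only the
assigned objects (correct / assigned).  Confusion matrices are oriented with
true classes as rows and predicted classes as columns, with an explicit extra
column for undecided predictions rather than dropping them silently.

The experiment battery re-scores a model trained on unperturbed mixtures
against test sets rebuilt with partial conversions, unequal molar ratios and
integration-normalization changes, reproducing the robustness protocol of
the mixture formula ``norm * (ratio * A + B)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mixtures import MixtureRecord, mixture_matrix, perturbation_battery
from .registry import TypeRegistry, default_registry
from .som import UNDECIDED

__all__ = [
    "accuracy",
    "confusion_table",
    "EvaluationReport",
    "evaluate_predictions",
    "run_experiment_battery",
]


def accuracy(predictions, truths, undecided_policy: str = "as_error") -> float:
    """Percentage of correct predictions under an undecided-handling policy.

    ``as_error``: correct / total.  ``exclude``: correct / assigned (raises
    on a batch with no assigned predictions at all).
    """
    predictions = np.asarray(predictions, dtype=object)
    truths = np.asarray(truths, dtype=object)
    if len(predictions) == 0:
        raise ValueError("empty prediction list")
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must be aligned")
    assigned = predictions != UNDECIDED
    correct = int(np.sum(assigned & (predictions == truths)))
    if undecided_policy == "as_error":
        return 100.0 * correct / len(predictions)
    if undecided_policy == "exclude":
        n_assigned = int(assigned.sum())
        if n_assigned == 0:
            raise ValueError("no assigned predictions to score under 'exclude'")
        return 100.0 * correct / n_assigned
    raise ValueError(f"unknown undecided_policy {undecided_policy!r}")


def confusion_table(
    predictions,
    truths,
    classes: Sequence[str] | None = None,
    include_undecided: bool = True,
) -> pd.DataFrame:
    """Confusion matrix: rows true class, columns predicted, plus recall.

    The last column ``pct_correct`` is the per-class recall in percent; an
    ``undecided`` column is appended when requested (and always counted in
    the row totals, so row sums equal per-class truth counts).
    """
    predictions = np.asarray(predictions, dtype=object)
    truths = np.asarray(truths, dtype=object)
    registry = default_registry()
    if classes is None:
        classes = [c for c in registry.class_labels if c in set(truths) | set(predictions)]
        if not classes:
            classes = sorted(set(map(str, truths)))
    cols = list(classes) + ([UNDECIDED] if include_undecided else [])
    mat = pd.DataFrame(0, index=list(classes), columns=cols, dtype=int)
    for p, t in zip(predictions, truths):
        if t not in mat.index:
            continue
        col = p if p in mat.columns else (UNDECIDED if include_undecided else None)
        if col is not None:
            mat.loc[t, col] += 1
    totals = mat.sum(axis=1)
    diag = pd.Series([mat.loc[c, c] for c in classes], index=list(classes))
    with np.errstate(invalid="ignore"):
        mat["pct_correct"] = (100.0 * diag / totals.replace(0, np.nan)).round(1)
    return mat


@dataclass(frozen=True)
class EvaluationReport:
    """Summary of one prediction batch."""

    overall_accuracy: float
    assigned_only_accuracy: float
    n_undecided: int
    n_total: int
    confusion: pd.DataFrame
    per_class_recall: pd.Series


def evaluate_predictions(
    predictions, truths, classes: Sequence[str] | None = None
) -> EvaluationReport:
    predictions = np.asarray(predictions, dtype=object)
    truths = np.asarray(truths, dtype=object)
    n_undecided = int(np.sum(predictions == UNDECIDED))
    overall = accuracy(predictions, truths, "as_error")
    assigned_only = (
        accuracy(predictions, truths, "exclude")
        if n_undecided < len(predictions)
        else float("nan")
    )
    conf = confusion_table(predictions, truths, classes)
    return EvaluationReport(
        overall_accuracy=overall,
        assigned_only_accuracy=assigned_only,
        n_undecided=n_undecided,
        n_total=len(predictions),
        confusion=conf,
        per_class_recall=conf["pct_correct"],
    )


def run_experiment_battery(
    model,
    test_mixtures: Sequence[MixtureRecord],
    descriptors: dict[str, np.ndarray],
    yields: Sequence[float] = (0.9, 0.8, 0.7),
    ratio_values: Sequence[float] = (2.0, 5.0),
    norm_range: tuple[float, float] = (0.2, 1.0),
    seed: int = 0,
    registry: TypeRegistry | None = None,
) -> pd.DataFrame:
    """Robustness battery of a trained classifier on a perturbed test set.

    Cells, one row each in the returned table:

    * ``yield=<y>`` — both reactions at conversion ``y`` (ratio/norm 1);
    * ``ratio=<r>, norm=1`` — molar ratio ``r`` of the first reaction;
    * ``ratio=<r>, norm~U`` — same ratio with a random normalization factor;
    * ``identity`` — the unperturbed test set, for reference.

    Accuracies use the as-error policy.  All sampling is seeded.
    """
    truths = np.asarray([m.mclass for m in test_mixtures], dtype=object)
    rows = []

    def score(mixtures, cell):
        X = mixture_matrix(mixtures, descriptors)
        pred = np.asarray(model.predict(X), dtype=object)
        rows.append(
            {
                "cell": cell,
                "n": len(mixtures),
                "accuracy_pct": accuracy(pred, truths, "as_error"),
            }
        )

    score(list(test_mixtures), "identity")
    for y in yields:
        perturbed = perturbation_battery(
            test_mixtures, yield_range=(y, y), replicates=1, seed=seed
        )
        score(perturbed, f"yield={y:g}")
    for r in ratio_values:
        fixed = perturbation_battery(test_mixtures, ratio_values=[r], seed=seed)
        score(fixed, f"ratio={r:g}, norm=1")
        randomized = perturbation_battery(
            test_mixtures, ratio_values=[r], norm_range=norm_range, seed=seed + 1
        )
        score(randomized, f"ratio={r:g}, norm~U{norm_range}")
    return pd.DataFrame(rows)
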