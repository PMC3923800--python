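"""End-to-end synthetic benchmark of the mixture-classification method.

Drives the whole pipeline on the default synthetic dataset: generate the
181-reaction dataset, encode reaction spectra, enumerate the 12421 two-
reaction mixtures, build the mixture-level and reaction-level partitions,
train the random forest and the self-organizing-map / counter-propagation
ensembles, and run the validation protocol (y-randomization, vote-fraction
reliability filtering, and the yield / ratio / normalization robustness
battery).

Problem sizes default to a single-CPU desk scale: a 25x25 map ensemble
trained on a subsample of the training mixtures and a 300-tree forest.  The
combinatorial quantities are scale-independent; the accuracy comparisons are
relative (forest vs. map ensemble, mixture-level vs. reaction-level split,
true vs. label-scrambled) and do not hinge on these sizes.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .encoding import descriptor_matrix
from .evaluation import accuracy, run_experiment_battery
from .mixtures import (
    enumerate_mixtures,
    mixture_matrix,
    partition_mixture_level,
    partition_reaction_level,
    perturbation_battery,
)
from .registry import default_registry
from .rf import MixtureForest, threshold_filter, y_randomization
from .som import SOMEnsemble
from .cpnn import CPNNEnsemble
from .synthetic import DEFAULT_PER_TYPE_COUNTS, GeneratorConfig, generate_dataset

__all__ = ["run_benchmark"]

logger = logging.getLogger(__name__)

#: Reaction-level split: held-out reactions per type (totals 41 of 181).
DEFAULT_PER_TYPE_TEST_COUNTS = (4, 8, 4, 17, 2, 6)


def _derive_seeds(seed: int, n: int = 16) -> list[int]:
    """Independent 31-bit sub-seeds for the pipeline stages."""
    return [
        int(child.generate_state(1)[0] % (2**31))
        for child in np.random.SeedSequence(seed).spawn(n)
    ]


def run_benchmark(
    seed: int = 42,
    per_type_counts: Sequence[int] = DEFAULT_PER_TYPE_COUNTS,
    train_fraction: float = 2.0 / 3.0,
    som_shape: tuple[int, int] = (25, 25),
    som_epochs: int = 30,
    som_members: int = 5,
    som_train_subsample: int = 2500,
    som_test_subsample: int = 1500,
    n_trees: int = 300,
    yrand_trees: int = 100,
    yrand_repeats: int = 5,
    include_cpnn: bool = True,
) -> dict[str, dict[str, float]]:
    """Run the full benchmark; returns ``{quantity: {"value", "n"}}``.

    ``train_fraction`` of the mixture set goes to the mixture-level training
    split (2/3 by default, e.g. 8280 of 12421 at the default counts).
    Accuracy values are percentages; counts are plain integers.
    """
    registry = default_registry()
    subseed = _derive_seeds(seed)
    results: dict[str, dict[str, float]] = {}

    def put(name: str, value: float, n: int) -> None:
        results[name] = {"value": float(value), "n": int(n)}
        logger.info("%s = %s (n=%d)", name, value, n)

    # ------------------------------------------------------------------ data
    reactions = generate_dataset(
        GeneratorConfig(per_type_counts=tuple(per_type_counts), seed=subseed[0])
    )
    n_reactions = len(reactions)
    ids, desc = descriptor_matrix(reactions)
    descriptors = dict(zip(ids, desc))

    mixtures = enumerate_mixtures(reactions, registry)
    by_class: dict[str, int] = {}
    for m in mixtures:
        by_class[m.mclass] = by_class.get(m.mclass, 0) + 1

    put("n_mixtures_total", len(mixtures), n_reactions)
    put("n_mixtures_class_a", by_class.get("A", 0), per_type_counts[0] + per_type_counts[1])
    put("n_mixtures_class_b", by_class.get("B", 0), per_type_counts[0] + per_type_counts[2])
    put("n_descriptor_bins", desc.shape[1], n_reactions)
    put("n_mixture_classes", registry.n_classes, registry.n_types)

    # ------------------------------------------------- mixture-level split
    n_train = int(round(train_fraction * len(mixtures)))
    train_mix, test_mix = partition_mixture_level(mixtures, n_train, subseed[1])
    X_train = mixture_matrix(train_mix, descriptors)
    y_train = np.asarray([m.mclass for m in train_mix], dtype=object)
    X_test = mixture_matrix(test_mix, descriptors)
    y_test = np.asarray([m.mclass for m in test_mix], dtype=object)

    forest = MixtureForest(n_trees=n_trees, random_state=subseed[2]).fit(
        X_train, y_train
    )
    put("rf_oob_accuracy_pct", 100.0 * forest.oob_accuracy_, len(train_mix))
    pred_test = forest.predict(X_test)
    rf_test_acc = accuracy(pred_test, y_test, "as_error")
    put("rf_test_accuracy_mixture_level_pct", rf_test_acc, len(test_mix))

    # ------------------------------------------------ reaction-level split
    test_counts = dict(zip(registry.types, DEFAULT_PER_TYPE_TEST_COUNTS))
    split = partition_reaction_level(reactions, test_counts, subseed[3], registry)
    cls_train: dict[str, int] = {}
    for m in split.train_mixtures:
        cls_train[m.mclass] = cls_train.get(m.mclass, 0) + 1
    n_tr_a = sum(1 for r in split.train_reactions if r.rtype in registry.class_pair("A"))
    n_tr_b = sum(1 for r in split.train_reactions if r.rtype in registry.class_pair("B"))
    put("n_train_mixtures_class_a_reaction_level", cls_train.get("A", 0), n_tr_a)
    put("n_train_mixtures_class_b_reaction_level", cls_train.get("B", 0), n_tr_b)

    X_tr2 = mixture_matrix(split.train_mixtures, descriptors)
    y_tr2 = np.asarray([m.mclass for m in split.train_mixtures], dtype=object)
    X_te2 = mixture_matrix(split.test_mixtures, descriptors)
    y_te2 = np.asarray([m.mclass for m in split.test_mixtures], dtype=object)
    forest2 = MixtureForest(n_trees=n_trees, random_state=subseed[4]).fit(X_tr2, y_tr2)
    pred2 = forest2.predict(X_te2)
    put(
        "rf_test_accuracy_reaction_level_pct",
        accuracy(pred2, y_te2, "as_error"),
        len(split.test_mixtures),
    )

    # -------------------------------------------------- SOM / CPNN ensembles
    rng = np.random.default_rng(subseed[5])
    tr_idx = rng.permutation(len(train_mix))[: min(som_train_subsample, len(train_mix))]
    te_idx = rng.permutation(len(test_mix))[: min(som_test_subsample, len(test_mix))]
    rows, cols = som_shape
    som = SOMEnsemble(
        n_members=som_members,
        rows=rows,
        cols=cols,
        epochs=som_epochs,
        lr0=0.1,
        random_state=subseed[6],
    ).fit(X_train[tr_idx], y_train[tr_idx])
    som_pred = som.predict(X_test[te_idx])
    som_acc = accuracy(som_pred, y_test[te_idx], "as_error")
    put("som_ensemble_test_accuracy_pct", som_acc, len(te_idx))

    if include_cpnn:
        cpnn = CPNNEnsemble(
            n_members=som_members,
            rows=rows,
            cols=cols,
            epochs=som_epochs,
            lr0=0.1,
            random_state=subseed[7],
        ).fit(X_train[tr_idx], y_train[tr_idx], registry=registry)
        cpnn_pred = cpnn.predict(X_test[te_idx])
        put(
            "cpnn_ensemble_test_accuracy_pct",
            accuracy(cpnn_pred, y_test[te_idx], "as_error"),
            len(te_idx),
        )

    # -------------------------------------------------------- y-randomization
    yr = y_randomization(
        X_train,
        y_train,
        X_test,
        y_test,
        n_repeats=yrand_repeats,
        n_trees=yrand_trees,
        random_state=subseed[8],
    )
    put("y_randomization_max_accuracy_pct", 100.0 * max(yr), len(test_mix))

    # ------------------------------------------------------ robustness battery
    battery = run_experiment_battery(
        forest,
        test_mix,
        descriptors,
        yields=(0.9, 0.8, 0.7),
        ratio_values=(2.0, 5.0),
        seed=subseed[9],
        registry=registry,
    )
    cells = dict(zip(battery["cell"], battery["accuracy_pct"]))
    put("accuracy_yield_90_pct", cells["yield=0.9"], len(test_mix))
    put("accuracy_yield_80_pct", cells["yield=0.8"], len(test_mix))
    put("accuracy_yield_70_pct", cells["yield=0.7"], len(test_mix))
    put("accuracy_ratio_2_pct", cells["ratio=2, norm=1"], len(test_mix))
    put("accuracy_ratio_5_pct", cells["ratio=5, norm=1"], len(test_mix))

    # ---------------------------------- reliability filtering (hard battery)
    combined = perturbation_battery(
        test_mix,
        yield_range=(0.5, 1.0),
        norm_range=(0.2, 1.0),
        ratio_range=(1.0, 4.0),
        replicates=2,
        seed=subseed[10],
    )
    Xc = mixture_matrix(combined, descriptors)
    yc = np.asarray([m.mclass for m in combined], dtype=object)
    preds = forest.predict_with_probability(Xc)
    table = threshold_filter(preds, yc, thresholds=(0.0, 0.5, 0.6, 0.8))
    totals = table[table["class"] == "Total"].set_index("threshold")
    put("n_combined_battery_mixtures", len(combined), len(test_mix))
    for thr, key in ((0.0, "0"), (0.5, "50"), (0.6, "60"), (0.8, "80")):
        put(
            f"filtered_accuracy_pct_threshold_{key}",
            totals.loc[thr, "pct_correct"],
            int(totals.loc[thr, "n_predicted"]),
        )

    return results
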