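"""Two-reaction mixture enumeration, descriptors, partitions and perturbations.

All cross-type reaction pairs form the mixture dataset; each mixture carries a
class label (one of the 15 unordered type pairs, A..O) and a descriptor built
from the two reaction spectra:

    mixture = norm * (ratio * yield_a * A + yield_b * B)

where ``A`` and ``B`` are the full-conversion reaction spectra of the two
reactions, ``ratio`` is the molar ratio of the first reaction to the second,
``norm`` a global integration-normalization factor, and the yields the
conversions of each reaction.  Defaults (ratio = norm = yields = 1) give the
plain sum of the two reaction spectra.

Two partition schemes are provided: *mixture-level* (random split of the
mixture set; the same reaction may appear, in different pairings, on both
sides) and the stricter *reaction-level* scheme in which the reactions
themselves are split first and mixtures are enumerated only within each side,
so no reaction is shared between training and test mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .encoding import ReactionRecord
from .registry import TypeRegistry, default_registry

__all__ = [
    "MixtureRecord",
    "ReactionLevelSplit",
    "mixture_class",
    "enumerate_mixtures",
    "mixture_descriptor",
    "mixture_matrix",
    "partition_mixture_level",
    "partition_reaction_level",
    "perturbation_battery",
    "mixtures_to_manifest",
]


@dataclass(frozen=True)
class MixtureRecord:
    """A simulated two-reaction mixture and its perturbation parameters."""

    id: str
    rxn_a: str
    rxn_b: str
    mclass: str
    ratio: float = 1.0
    norm: float = 1.0
    yield_a: float = 1.0
    yield_b: float = 1.0

    def __post_init__(self) -> None:
        if self.ratio <= 0 or self.norm <= 0:
            raise ValueError("ratio and norm must be positive")
        for y in (self.yield_a, self.yield_b):
            if not (0.0 < y <= 1.0):
                raise ValueError(f"yields must be in (0, 1], got {y!r}")


def mixture_class(type_i: str, type_j: str, registry: TypeRegistry | None = None) -> str:
    """Class label (A..O) of a mixture of two distinct reaction types."""
    registry = registry or default_registry()
    return registry.mixture_class(type_i, type_j)


def enumerate_mixtures(
    reactions: Sequence[ReactionRecord], registry: TypeRegistry | None = None
) -> list[MixtureRecord]:
    """All unordered cross-type reaction pairs, one mixture record each.

    The first reaction of each pair is the one whose type comes first in the
    registry order; the total count is sum over type pairs i<j of n_i * n_j.
    """
    registry = registry or default_registry()
    by_type: dict[str, list[ReactionRecord]] = {t: [] for t in registry.types}
    for r in reactions:
        if r.rtype not in by_type:
            raise KeyError(f"reaction {r.id!r} has unregistered type {r.rtype!r}")
        by_type[r.rtype].append(r)
    out: list[MixtureRecord] = []
    types = registry.types
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            label = registry.mixture_class(types[i], types[j])
            for ra in by_type[types[i]]:
                for rb in by_type[types[j]]:
                    out.append(
                        MixtureRecord(
                            id=f"{ra.id}+{rb.id}",
                            rxn_a=ra.id,
                            rxn_b=rb.id,
                            mclass=label,
                        )
                    )
    return out


def mixture_descriptor(
    a: np.ndarray, b: np.ndarray, ratio: float = 1.0, norm: float = 1.0
) -> np.ndarray:
    """``norm * (ratio * a + b)`` for two reaction-spectrum vectors.

    Yields are assumed already folded into ``a`` and ``b`` (a reaction
    spectrum scales linearly with conversion).
    """
    if ratio <= 0 or norm <= 0:
        raise ValueError("ratio and norm must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("incompatible descriptor grids")
    return norm * (ratio * a + b)


def mixture_matrix(
    mixtures: Sequence[MixtureRecord], descriptors: dict[str, np.ndarray]
) -> np.ndarray:
    """Stack mixture descriptor vectors, applying each record's parameters.

    ``descriptors`` maps reaction id -> full-conversion reaction spectrum.
    """
    rows = []
    for m in mixtures:
        a = m.yield_a * descriptors[m.rxn_a]
        b = m.yield_b * descriptors[m.rxn_b]
        rows.append(mixture_descriptor(a, b, ratio=m.ratio, norm=m.norm))
    return np.asarray(rows)


def partition_mixture_level(
    mixtures: Sequence[MixtureRecord], train_size: int, seed: int
) -> tuple[list[MixtureRecord], list[MixtureRecord]]:
    """Random disjoint train/test split of the mixture set itself."""
    n = len(mixtures)
    if not (0 < train_size < n):
        raise ValueError(f"train_size must be in (0, {n}), got {train_size}")
    order = np.random.default_rng(seed).permutation(n)
    train = [mixtures[k] for k in sorted(order[:train_size])]
    test = [mixtures[k] for k in sorted(order[train_size:])]
    return train, test


class ReactionLevelSplit(NamedTuple):
    train_mixtures: list[MixtureRecord]
    test_mixtures: list[MixtureRecord]
    train_reactions: list[ReactionRecord]
    test_reactions: list[ReactionRecord]


def partition_reaction_level(
    reactions: Sequence[ReactionRecord],
    per_type_test_counts: dict[str, int],
    seed: int,
    registry: TypeRegistry | None = None,
) -> ReactionLevelSplit:
    """Split the *reactions* per type, then enumerate mixtures within each side.

    No reaction id appears in both training and test mixtures, making the
    resulting test set a genuine generalization test to unseen reactions.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[ReactionRecord]] = {}
    for r in reactions:
        by_type.setdefault(r.rtype, []).append(r)

    train_rxns: list[ReactionRecord] = []
    test_rxns: list[ReactionRecord] = []
    for rtype, members in by_type.items():
        k = int(per_type_test_counts.get(rtype, 0))
        if not (0 <= k <= len(members)):
            raise ValueError(
                f"test count {k} infeasible for type {rtype!r} with {len(members)} reactions"
            )
        pick = rng.permutation(len(members))
        test_idx = set(pick[:k].tolist())
        for i, r in enumerate(members):
            (test_rxns if i in test_idx else train_rxns).append(r)

    train_mix = enumerate_mixtures(train_rxns, registry) if train_rxns else []
    test_mix = enumerate_mixtures(test_rxns, registry) if test_rxns else []
    return ReactionLevelSplit(train_mix, test_mix, train_rxns, test_rxns)


def perturbation_battery(
    mixtures: Sequence[MixtureRecord],
    yield_range: tuple[float, float] | None = None,
    norm_range: tuple[float, float] | None = None,
    ratio_values: Sequence[float] | None = None,
    ratio_range: tuple[float, float] | None = None,
    replicates: int = 1,
    seed: int = 0,
) -> list[MixtureRecord]:
    """Perturbed copies of a mixture set for robustness experiments.

    With ``ratio_values`` given, one record is produced per (mixture, ratio
    value); otherwise ``replicates`` records per mixture.  Ranges (yield,
    norm, ratio) are sampled uniformly per record with the given seed; a
    range left ``None`` keeps the parameter at its current value.  Yields are
    sampled independently for the two reactions of each mixture.
    """
    if len(mixtures) == 0:
        raise ValueError("empty mixture battery")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if ratio_values is not None and ratio_range is not None:
        raise ValueError("give ratio_values or ratio_range, not both")

    rng = np.random.default_rng(seed)

    def _sample(rec: MixtureRecord, k: int, ratio: float | None) -> MixtureRecord:
        ya, yb = rec.yield_a, rec.yield_b
        if yield_range is not None:
            ya = float(rng.uniform(*yield_range))
            yb = float(rng.uniform(*yield_range))
        norm = rec.norm
        if norm_range is not None:
            norm = float(rng.uniform(*norm_range))
        if ratio is None:
            ratio = rec.ratio
            if ratio_range is not None:
                ratio = float(rng.uniform(*ratio_range))
        return replace(
            rec,
            id=f"{rec.id}#r{ratio:g}k{k}",
            ratio=float(ratio),
            norm=norm,
            yield_a=ya,
            yield_b=yb,
        )

    out: list[MixtureRecord] = []
    if ratio_values is not None:
        for ratio in ratio_values:
            for rec in mixtures:
                out.append(_sample(rec, 0, float(ratio)))
    else:
        for k in range(replicates):
            for rec in mixtures:
                out.append(_sample(rec, k, None))
    return out


def mixtures_to_manifest(
    mixtures: Sequence[MixtureRecord], split: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tabular manifest of a mixture set (one row per mixture)."""
    df = pd.DataFrame(
        {
            "mixture_id": [m.id for m in mixtures],
            "rxn_a": [m.rxn_a for m in mixtures],
            "rxn_b": [m.rxn_b for m in mixtures],
            "class": [m.mclass for m in mixtures],
            "ratio": [m.ratio for m in mixtures],
            "norm": [m.norm for m in mixtures],
            "yield_a": [m.yield_a for m in mixtures],
            "yield_b": [m.yield_b for m in mixtures],
        }
    )
    if split is not None:
        df["split"] = list(split)
    return df
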