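"""Synthetic photocycloaddition reaction generator.

Real reaction datasets with predicted proton shifts for every reactant and
product are not redistributable, so this module generates stick-spectrum
reaction records that emulate their statistical structure.  Each of the six
reaction types carries a fixed *signature*: protons that move from a
type-characteristic "lost" shift region (e.g. olefinic hydrogens around
5.3-6.3 ppm for a [2+2] olefin cycloaddition) to a "gained" region (e.g. the
cyclobutane envelope at 2.3-3.3 ppm).  On top of the signature each reaction
has spectator protons that appear in both the reactant and product spectra,
displaced by a small normal drift that mimics the shift-prediction error of
an empirical NMR predictor — in the difference spectrum the spectators nearly
cancel, leaving structured residual noise.

Hydrogen counts are conserved by construction (each signature element loses
and gains the same number of protons; spectators keep theirs), so every
generated reaction spectrum integrates to zero.  Signature *positions* are
sampled per reaction within the template regions, giving intra-type
variability comparable to a family of related real reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import ReactionRecord
from .spectra import ShiftList

__all__ = [
    "SignatureMove",
    "ReactionTypeTemplate",
    "GeneratorConfig",
    "default_templates",
    "sample_reaction",
    "generate_dataset",
]

#: Per-type reaction counts of the default study dataset (6 types, 181 total).
DEFAULT_PER_TYPE_COUNTS = (20, 31, 20, 73, 10, 27)

#: Default spectator drift between reactant and product spectra, in ppm.
DEFAULT_DRIFT_SD = 0.15


@dataclass(frozen=True)
class SignatureMove:
    """Protons moving from a lost shift region to a gained one."""

    lost: tuple[float, float]
    gained: tuple[float, float]
    protons: float

    def __post_init__(self) -> None:
        for lo, hi in (self.lost, self.gained):
            if not (0.0 < lo < hi < 12.0):
                raise ValueError(f"region ({lo}, {hi}) must lie inside (0, 12) ppm")
        if self.protons <= 0:
            raise ValueError("protons must be positive")


@dataclass(frozen=True)
class ReactionTypeTemplate:
    """Generative template of one reaction type."""

    label: str
    signature: tuple[SignatureMove, ...]
    spectator_count: tuple[int, int] = (3, 10)
    spectator_region: tuple[float, float] = (0.5, 9.5)
    drift_sd: float = DEFAULT_DRIFT_SD

    @property
    def protons_moved(self) -> float:
        return float(sum(m.protons for m in self.signature))


@dataclass(frozen=True)
class GeneratorConfig:
    """Dataset-level generation settings."""

    per_type_counts: tuple[int, ...] = DEFAULT_PER_TYPE_COUNTS
    seed: int | None = None
    drift_sd: float = DEFAULT_DRIFT_SD
    spectator_count: tuple[int, int] = (3, 10)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.per_type_counts):
            raise ValueError("per-type counts must be non-negative")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be non-negative")


def default_templates(
    drift_sd: float = DEFAULT_DRIFT_SD, spectator_count: tuple[int, int] = (3, 10)
) -> tuple[ReactionTypeTemplate, ...]:
    """Templates of the six photocycloaddition types.

    The lost/gained regions follow the chemistry of each motif: cycloadditions
    consume unsaturation (olefinic 5-7 ppm, aromatic 7-8 ppm, aldehydic
    9.4-10 ppm, azomethine/heteroaromatic 8-9 ppm hydrogens) and create
    saturated ring hydrogens (2-5.5 ppm).  Regions overlap between types —
    most types lose olefinic protons — so the classes are distinguishable but
    not trivially separable, as in real reaction families.
    """
    from .registry import DEFAULT_TYPES

    def mk(label, moves):
        return ReactionTypeTemplate(
            label=label,
            signature=tuple(SignatureMove(*m) for m in moves),
            spectator_count=spectator_count,
            drift_sd=drift_sd,
        )

    return (
        # azirine + C=C [3+2]: azomethine CH and olefinic H into pyrroline ring CH
        mk(DEFAULT_TYPES[0], [((8.0, 9.0), (4.4, 5.4), 1), ((5.6, 6.6), (3.2, 4.2), 2)]),
        # C=C + C=O [2+2] (oxetane formation): aldehydic H and olefinic H to O-CH
        mk(DEFAULT_TYPES[1], [((9.4, 10.0), (4.6, 5.6), 1), ((5.8, 6.8), (3.4, 4.4), 2)]),
        # arene + olefin [4+2]/[4+4]: aromatic and olefinic H to bridgehead/aliphatic
        mk(DEFAULT_TYPES[2], [((7.0, 7.8), (2.8, 3.8), 2), ((5.4, 6.2), (2.0, 2.8), 2)]),
        # C=C + C=C [2+2]: olefinic H to cyclobutane envelope
        mk(DEFAULT_TYPES[3], [((5.3, 6.3), (2.3, 3.3), 4)]),
        # s-triazolo[4,3-b]pyridazine + C=C [3+2]: heteroaromatic + olefinic H down
        mk(DEFAULT_TYPES[4], [((7.8, 8.8), (4.8, 5.8), 2), ((5.4, 6.2), (3.6, 4.4), 2)]),
        # C=C + C=S [2+2] (thietane formation): olefinic H to S-CH / ring CH
        mk(DEFAULT_TYPES[5], [((5.9, 6.9), (3.0, 3.6), 2), ((6.9, 7.5), (3.6, 4.2), 2)]),
    )


def sample_reaction(
    template: ReactionTypeTemplate, rng: np.random.Generator, rxn_id: str = "r0"
) -> ReactionRecord:
    """Draw one reaction record from a type template.

    Signature lost-peaks and spectators are distributed over two reactant
    spectra; the product carries the gained peaks plus the same spectators
    displaced by Normal(0, drift_sd) (clipped to stay inside the usual
    binning range, fuzzification support included).
    """
    reactant_peaks: tuple[list, list] = ([], [])
    product_peaks: list = []

    for k, move in enumerate(template.signature):
        lost_shift = float(rng.uniform(*move.lost))
        gained_shift = float(rng.uniform(*move.gained))
        reactant_peaks[k % 2].append((lost_shift, move.protons))
        product_peaks.append((gained_shift, move.protons))

    lo_c, hi_c = template.spectator_count
    n_spect = int(rng.integers(lo_c, hi_c + 1))
    for k in range(n_spect):
        shift = float(rng.uniform(*template.spectator_region))
        protons = int(rng.integers(1, 4))
        # first two spectators pin one to each reactant so neither is empty
        side = k % 2 if k < 2 else int(rng.integers(0, 2))
        reactant_peaks[side].append((shift, protons))
        drifted = shift + float(rng.normal(0.0, template.drift_sd))
        drifted = float(np.clip(drifted, 0.15, 11.85))
        product_peaks.append((drifted, protons))

    reactants = tuple(
        ShiftList.from_pairs(pks) for pks in reactant_peaks if pks
    )
    return ReactionRecord(
        id=rxn_id,
        rtype=template.label,
        reactants=reactants,
        product=ShiftList.from_pairs(product_peaks),
    )


def generate_dataset(config: GeneratorConfig | None = None) -> list[ReactionRecord]:
    """Generate the full synthetic reaction dataset (default: 181 reactions)."""
    config = config or GeneratorConfig()
    templates = default_templates(
        drift_sd=config.drift_sd, spectator_count=config.spectator_count
    )
    if len(config.per_type_counts) != len(templates):
        raise ValueError(
            f"expected {len(templates)} per-type counts, got {len(config.per_type_counts)}"
        )
    rng = np.random.default_rng(config.seed)
    out: list[ReactionRecord] = []
    for t_idx, (tmpl, count) in enumerate(zip(templates, config.per_type_counts), start=1):
        for k in range(count):
            out.append(sample_reaction(tmpl, rng, rxn_id=f"t{t_idx}_{k:03d}"))
    return out
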