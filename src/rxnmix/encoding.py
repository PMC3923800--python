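"""Reaction records and the difference-spectrum ("reaction spectrum") descriptor.

A reaction is described by the difference between the binned spectrum of its
product and the binned spectrum of all its reactants pooled together — the
spectrum after the reaction minus the spectrum before it, assuming a given
conversion.  Signals of unreacted material cancel in the subtraction, so at
conversion (yield) ``y`` the descriptor is exactly ``y`` times the
full-conversion descriptor:

    after  = (1 - y) * reactants + y * product
    before = reactants
    after - before = y * (product - reactants)

Hydrogen conservation (reactant protons == product protons) makes the
descriptor integrate to zero whenever all fuzzified mass lies inside the
binning range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_HALF_WIDTH,
    DEFAULT_HI,
    DEFAULT_LO,
    BinnedSpectrum,
    ShiftList,
    bin_spectrum,
    combine,
    fuzzify,
)

__all__ = [
    "ReactionRecord",
    "ReactionDescriptor",
    "reaction_spectrum",
    "descriptor_matrix",
    "reactions_to_json",
    "reactions_from_json",
    "shift_lists_to_csv",
    "shift_lists_from_csv",
]


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: reactant stick spectra, a product stick spectrum, a type."""

    id: str
    rtype: str
    reactants: tuple[ShiftList, ...]
    product: ShiftList

    def __post_init__(self) -> None:
        if len(self.reactants) < 1:
            raise ValueError(f"reaction {self.id!r}: needs at least one reactant")
        if len(self.product) == 0:
            raise ValueError(
                f"reaction {self.id!r}: product spectrum is empty "
                "(at least one C-bonded hydrogen is required)"
            )

    @property
    def pooled_reactants(self) -> ShiftList:
        """All reactant signals taken together (1:1 stoichiometry)."""
        pooled = ShiftList()
        for r in self.reactants:
            pooled = pooled + r
        return pooled


@dataclass(frozen=True)
class ReactionDescriptor:
    """A reaction spectrum: signed binned difference vector at a given yield."""

    vector: BinnedSpectrum
    yield_: float = 1.0


def reaction_spectrum(
    rxn: ReactionRecord,
    yield_: float = 1.0,
    half_width: float = DEFAULT_HALF_WIDTH,
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> ReactionDescriptor:
    """Binned product spectrum minus binned pooled-reactant spectrum, times yield."""
    if not (0.0 < yield_ <= 1.0):
        raise ValueError(f"yield_ must be in (0, 1], got {yield_!r}")
    prod = bin_spectrum(fuzzify(rxn.product, half_width), lo, hi, bin_width)
    reac = bin_spectrum(fuzzify(rxn.pooled_reactants, half_width), lo, hi, bin_width)
    vec = combine([prod, reac], [yield_, -yield_])
    return ReactionDescriptor(vector=vec, yield_=float(yield_))


def descriptor_matrix(
    reactions: Sequence[ReactionRecord], **binning
) -> tuple[list[str], np.ndarray]:
    """Full-conversion descriptor vectors for a reaction list, as (ids, matrix)."""
    ids = [r.id for r in reactions]
    rows = [reaction_spectrum(r, 1.0, **binning).vector.values for r in reactions]
    return ids, np.asarray(rows)


# ---------------------------------------------------------------------------
# I/O: reaction JSON and stick-spectrum CSV

def reactions_to_json(reactions: Iterable[ReactionRecord], path: str | Path) -> None:
    payload = [
        {
            "id": r.id,
            "type": r.rtype,
            "reactants": [s.to_pairs() for s in r.reactants],
            "product": r.product.to_pairs(),
        }
        for r in reactions
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def reactions_from_json(path: str | Path) -> list[ReactionRecord]:
    payload = json.loads(Path(path).read_text())
    return [
        ReactionRecord(
            id=str(rec["id"]),
            rtype=str(rec["type"]),
            reactants=tuple(ShiftList.from_pairs(s) for s in rec["reactants"]),
            product=ShiftList.from_pairs(rec["product"]),
        )
        for rec in payload
    ]


def shift_lists_to_csv(spectra: dict[str, ShiftList], path: str | Path) -> None:
    """Write stick spectra as rows of (compound_id, shift_ppm, protons)."""
    rows = [
        {"compound_id": cid, "shift_ppm": pk.shift, "protons": pk.protons}
        for cid, sl in spectra.items()
        for pk in sl.peaks
    ]
    pd.DataFrame(rows, columns=["compound_id", "shift_ppm", "protons"]).to_csv(
        path, index=False
    )


def shift_lists_from_csv(path: str | Path) -> dict[str, ShiftList]:
    df = pd.read_csv(path)
    out: dict[str, ShiftList] = {}
    for cid, grp in df.groupby("compound_id", sort=False):
        out[str(cid)] = ShiftList.from_pairs(grp[["shift_ppm", "protons"]].to_numpy())
    return out
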