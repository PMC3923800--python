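"""Stick spectra, triangular fuzzification and analytic binning.

A compound's predicted proton NMR spectrum is handled as a *stick spectrum*:
a list of (chemical shift in ppm, number of protons) peaks.  To tolerate small
shift-prediction errors each stick is fuzzified into a triangle of fixed
half-width whose *area* equals the proton count, so that integration over any
interval remains proportional to the number of protons it covers.  The
fuzzified spectrum is then integrated over a fixed grid of bins (by default
0-12 ppm in 0.1 ppm steps, i.e. 120 variables) to give a fixed-length vector.

Binning is exact: the cumulative integral of a unit triangle is piecewise
quadratic and is evaluated analytically at the bin edges, so no sampling grid
is involved.  Difference spectra are plain vector arithmetic on the binned
representation (see :func:`combine`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ShiftPeak",
    "ShiftList",
    "FuzzySpectrum",
    "BinnedSpectrum",
    "fuzzify",
    "bin_spectrum",
    "combine",
]

#: default triangle half-width in ppm
DEFAULT_HALF_WIDTH = 0.1
#: default binning range and width in ppm (120 bins)
DEFAULT_LO = 0.0
DEFAULT_HI = 12.0
DEFAULT_BIN_WIDTH = 0.1


@dataclass(frozen=True)
class ShiftPeak:
    """One stick: a chemical shift (ppm) carrying an integrating weight.

    The weight is the number of protons resonating at this shift; fractional
    values are allowed (e.g. for averaged or partially weighted signals).
    """

    shift: float
    protons: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.shift):
            raise ValueError(f"shift must be finite, got {self.shift!r}")
        if not (np.isfinite(self.protons) and self.protons > 0):
            raise ValueError(f"protons must be a positive finite number, got {self.protons!r}")


@dataclass(frozen=True)
class ShiftList:
    """A stick spectrum: an ordered collection of :class:`ShiftPeak`.

    May be empty (a compound with no observable protons contributes nothing).
    """

    peaks: tuple[ShiftPeak, ...] = ()

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[float]]) -> "ShiftList":
        """Build from an iterable of ``(shift_ppm, protons)`` pairs."""
        return cls(tuple(ShiftPeak(float(s), float(p)) for s, p in pairs))

    def to_pairs(self) -> list[list[float]]:
        return [[pk.shift, pk.protons] for pk in self.peaks]

    @property
    def total_protons(self) -> float:
        return float(sum(pk.protons for pk in self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    def __add__(self, other: "ShiftList") -> "ShiftList":
        """Pool two stick spectra (signal union, 1:1 stoichiometry)."""
        return ShiftList(self.peaks + other.peaks)


@dataclass(frozen=True)
class FuzzySpectrum:
    """A sum of triangles: tuples of (center ppm, half-width ppm, area).

    Each triangle has support ``[center - half_width, center + half_width]``
    and integrates to ``area`` (apex height ``area / half_width``).
    """

    triangles: tuple[tuple[float, float, float], ...] = ()

    @property
    def total_area(self) -> float:
        return float(sum(a for _, _, a in self.triangles))

    def intensity(self, x: np.ndarray) -> np.ndarray:
        """Pointwise intensity of the piecewise-linear spectrum (test aid)."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c, h, a in self.triangles:
            out += (a / h) * np.clip(1.0 - np.abs(x - c) / h, 0.0, None)
        return out


@dataclass(frozen=True)
class BinnedSpectrum:
    """A fixed-grid integrated spectrum; signed values for difference spectra."""

    values: np.ndarray
    lo: float = DEFAULT_LO
    hi: float = DEFAULT_HI
    bin_width: float = DEFAULT_BIN_WIDTH
    #: integrated mass that fell outside [lo, hi] and was dropped
    clipped_mass: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(values) != self.n_bins_expected:
            raise ValueError(
                f"expected {self.n_bins_expected} bins for range "
                f"[{self.lo}, {self.hi}] at width {self.bin_width}, got {len(values)}"
            )

    @property
    def n_bins_expected(self) -> int:
        return int(round((self.hi - self.lo) / self.bin_width))

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def same_grid(self, other: "BinnedSpectrum") -> bool:
        return (
            self.lo == other.lo
            and self.hi == other.hi
            and self.bin_width == other.bin_width
        )

    @property
    def edges(self) -> np.ndarray:
        return self.lo + self.bin_width * np.arange(self.n_bins + 1)


def fuzzify(peaks: ShiftList, half_width: float = DEFAULT_HALF_WIDTH) -> FuzzySpectrum:
    """Replace each stick by a triangle of the given half-width.

    The triangle is centered at the peak shift with support
    ``[shift - half_width, shift + half_width]`` and area equal to the proton
    count, so the fuzzified spectrum integrates to the same total as the
    sticks.

    Parameters
    ----------
    peaks : ShiftList
        Stick spectrum.
    half_width : float, default 0.1
        Half-width of the triangle in ppm ("width at each side").
    """
    if not (np.isfinite(half_width) and half_width > 0):
        raise ValueError(f"half_width must be positive, got {half_width!r}")
    return FuzzySpectrum(tuple((pk.shift, float(half_width), pk.protons) for pk in peaks.peaks))


def _triangle_cdf(edges: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Cumulative integral of a *unit-area* triangle evaluated at ``edges``."""
    u = np.clip((edges - center) / half_width, -1.0, 1.0)
    left = 0.5 * (u + 1.0) ** 2
    right = 1.0 - 0.5 * (1.0 - u) ** 2
    return np.where(u < 0.0, left, right)


def bin_spectrum(
    spec: FuzzySpectrum,
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BinnedSpectrum:
    """Integrate a fuzzified spectrum over a regular bin grid, exactly.

    Each output value is the analytic integral of the piecewise-linear
    spectrum over the half-open interval ``[lo + k*w, lo + (k+1)*w)``.  Mass
    lying outside ``[lo, hi]`` is dropped; its total is recorded on the result
    (``clipped_mass``) and a warning is emitted when it is non-negligible.
    """
    if not hi > lo:
        raise ValueError("hi must exceed lo")
    n_bins = (hi - lo) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("(hi - lo) must be an integral number of bin widths")
    n_bins = int(round(n_bins))

    edges = lo + bin_width * np.arange(n_bins + 1)
    values = np.zeros(n_bins)
    total_area = 0.0
    in_range = 0.0
    for center, half_width, area in spec.triangles:
        cdf = _triangle_cdf(edges, center, half_width)
        values += area * np.diff(cdf)
        total_area += area
        in_range += area * (cdf[-1] - cdf[0])
    clipped = total_area - in_range
    if clipped > 1e-12:
        warnings.warn(
            f"{clipped:.6g} proton-units of spectral mass fall outside "
            f"[{lo}, {hi}] ppm and were dropped",
            stacklevel=2,
        )
    return BinnedSpectrum(values, lo=lo, hi=hi, bin_width=bin_width, clipped_mass=float(clipped))


def combine(
    vectors: Sequence[BinnedSpectrum], coefficients: Sequence[float]
) -> BinnedSpectrum:
    """Elementwise linear combination of binned spectra on a shared grid."""
    if len(vectors) == 0:
        raise ValueError("need at least one spectrum")
    if len(vectors) != len(coefficients):
        raise ValueError("vectors and coefficients must have equal length")
    ref = vectors[0]
    for v in vectors[1:]:
        if not ref.same_grid(v):
            raise ValueError("incompatible bin grids: lo/hi/bin_width must all match")
    out = np.zeros_like(ref.values)
    for v, c in zip(vectors, coefficients):
        out += float(c) * v.values
    return BinnedSpectrum(out, lo=ref.lo, hi=ref.hi, bin_width=ref.bin_width)
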