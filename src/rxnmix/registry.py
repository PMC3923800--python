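"""Registry of reaction types and the derived two-reaction mixture classes.

Six photochemical cycloaddition types are tracked in a fixed order; the 15
unordered cross-type pairs are labeled A..O lexicographically over that order:
(type 1, type 2) -> A, (type 1, type 3) -> B, ..., (type 5, type 6) -> O.
Class labels are therefore meaningful only relative to the registry's type
order, which callers must not reorder after mixtures have been labeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["DEFAULT_TYPES", "TypeRegistry", "default_registry"]

#: Default type labels, in the canonical order used everywhere downstream.
DEFAULT_TYPES: tuple[str, ...] = (
    "azirine+C=C [3+2]",
    "C=C+C=O [2+2]",
    "arene+olefin [4+2]/[4+4]",
    "C=C+C=C [2+2]",
    "triazolopyridazine+C=C [3+2]",
    "C=C+C=S [2+2]",
)

_CLASS_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class TypeRegistry:
    """Ordered reaction-type labels plus the pair -> class-label mapping."""

    types: tuple[str, ...] = DEFAULT_TYPES
    _pair_to_class: dict = field(init=False, repr=False, compare=False)
    _class_to_pair: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.types) < 2:
            raise ValueError("registry needs at least two reaction types")
        if len(set(self.types)) != len(self.types):
            raise ValueError("duplicate type labels")
        pairs = list(combinations(range(len(self.types)), 2))
        if len(pairs) > len(_CLASS_ALPHABET):
            raise ValueError("too many types for single-letter class labels")
        p2c = {pair: _CLASS_ALPHABET[k] for k, pair in enumerate(pairs)}
        object.__setattr__(self, "_pair_to_class", p2c)
        object.__setattr__(self, "_class_to_pair", {c: p for p, c in p2c.items()})

    @property
    def n_types(self) -> int:
        return len(self.types)

    @property
    def n_classes(self) -> int:
        return len(self._pair_to_class)

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(self._class_to_pair)

    def index(self, rtype: str) -> int:
        try:
            return self.types.index(rtype)
        except ValueError:
            raise KeyError(f"unknown reaction type {rtype!r}") from None

    def mixture_class(self, type_i: str, type_j: str) -> str:
        """Class label of the unordered pair of two *distinct* types."""
        i, j = self.index(type_i), self.index(type_j)
        if i == j:
            raise ValueError(f"mixture requires two distinct types, got {type_i!r} twice")
        return self._pair_to_class[(min(i, j), max(i, j))]

    def class_pair(self, label: str) -> tuple[str, str]:
        """The two type labels making up a mixture class."""
        try:
            i, j = self._class_to_pair[label]
        except KeyError:
            raise KeyError(f"unknown mixture class {label!r}") from None
        return self.types[i], self.types[j]

    def target_vector(self, label: str) -> np.ndarray:
        """Binary type-indicator vector of a mixture class (two ones)."""
        i, j = self._class_to_pair[label] if label in self._class_to_pair else (None, None)
        if i is None:
            raise KeyError(f"unknown mixture class {label!r}")
        v = np.zeros(self.n_types)
        v[i] = v[j] = 1.0
        return v


def default_registry() -> TypeRegistry:
    """The registry of the six default photocycloaddition types."""
    return TypeRegistry()
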