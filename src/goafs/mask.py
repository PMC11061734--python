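"""Binary feature masks — the unit of the wrapper feature-selection search."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["FeatureMask"]


@dataclass(frozen=True)
class FeatureMask:
    """A non-empty bit vector over the predictors.

    Bit ``i`` set means predictor ``i + 1`` (1-based reporting
    convention) is selected.  Immutable and hashable, so masks can key
    fitness caches directly.
    """

    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", tuple(bool(b) for b in self.bits))
        if len(self.bits) < 1:
            raise ValueError("mask must cover at least one predictor")
        if not any(self.bits):
            raise ValueError("mask must select at least one feature")

    @classmethod
    def from_indices(cls, indices_1based: Iterable[int], d: int) -> "FeatureMask":
        bits = [False] * d
        for i in indices_1based:
            if not 1 <= i <= d:
                raise ValueError(f"feature index {i} outside 1..{d}")
            bits[i - 1] = True
        return cls(tuple(bits))

    @classmethod
    def from_array(cls, arr: Sequence[bool] | np.ndarray) -> "FeatureMask":
        return cls(tuple(bool(b) for b in np.asarray(arr, dtype=bool)))

    @classmethod
    def full(cls, d: int) -> "FeatureMask":
        return cls(tuple([True] * d))

    @property
    def d(self) -> int:
        return len(self.bits)

    @property
    def size(self) -> int:
        """Number of selected features (popcount)."""
        return sum(self.bits)

    @property
    def indices(self) -> tuple[int, ...]:
        """Selected feature indices, 1-based."""
        return tuple(i + 1 for i, b in enumerate(self.bits) if b)

    @property
    def bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def asarray(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=bool)

    def columns(self) -> np.ndarray:
        """0-based column indices of the selected features."""
        return np.flatnonzero(self.asarray())

    def overlap(self, other: "FeatureMask") -> int:
        """Number of features selected by both masks."""
        return int((self.asarray() & other.asarray()).sum())

    def __str__(self) -> str:  # pragma: no cover - convenience
        return "{" + ",".join(map(str, self.indices)) + "}"
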