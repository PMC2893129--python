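"""Sparse binary descriptor vectors (GO-term and functional-domain modes)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BinaryVector:
    """A {0,1} vector of fixed dimension stored as its support set."""

    support: frozenset[int]
    dim: int
    mode: str = "binary"

    def __post_init__(self) -> None:
        if self.support and (min(self.support) < 0 or max(self.support) >= self.dim):
            raise ValueError("support positions out of range for dimension")

    @property
    def is_zero(self) -> bool:
        return not self.support

    def to_array(self, dtype=np.float64) -> np.ndarray:
        arr = np.zeros(self.dim, dtype=dtype)
        if self.support:
            arr[sorted(self.support)] = 1
        return arr

    def overlaps(self, other: "BinaryVector") -> bool:
        return bool(self.support & other.support)

    @classmethod
    def from_array(cls, arr: np.ndarray, mode: str = "binary") -> "BinaryVector":
        arr = np.asarray(arr)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("array entries must be 0 or 1")
        return cls(frozenset(int(i) for i in np.flatnonzero(arr)), int(arr.size), mode)


class GOVector(BinaryVector):
    """Binary GO-term descriptor; the zero vector marks a non-productive query."""

    def __init__(self, support: frozenset[int], dim: int):
        super().__init__(frozenset(support), dim, "go")


class FunDVector(BinaryVector):
    """Binary functional-domain hit descriptor."""

    def __init__(self, support: frozenset[int], dim: int):
        super().__init__(frozenset(support), dim, "fund")
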