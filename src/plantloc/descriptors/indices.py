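"""Ordered identifier indices mapping term/domain ids to vector positions."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator


class IdentifierIndex:
    """Bijection between an ordered list of identifiers and 0-based positions.

    Used both for GO term catalogues (reference dimension 60,020) and for
    conserved-domain catalogues (reference dimension 17,402); the synthetic
    fixtures use much smaller indices of the same shape.
    """

    def __init__(self, identifiers: Iterable[str]):
        self._ids: tuple[str, ...] = tuple(identifiers)
        self._pos: dict[str, int] = {t: i for i, t in enumerate(self._ids)}
        if len(self._pos) != len(self._ids):
            raise ValueError("duplicate identifiers in index")

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._pos

    def __iter__(self) -> Iterator[str]:
        return iter(self._ids)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IdentifierIndex) and self._ids == other._ids

    def position(self, identifier: str) -> int:
        try:
            return self._pos[identifier]
        except KeyError:
            raise KeyError(f"identifier {identifier!r} not in index") from None

    def identifier(self, position: int) -> str:
        return self._ids[position]

    @property
    def identifiers(self) -> tuple[str, ...]:
        return self._ids

    @classmethod
    def from_file(cls, path: str | Path) -> "IdentifierIndex":
        """Read one identifier per line; order defines vector positions."""
        lines = Path(path).read_text().splitlines()
        return cls(line.strip() for line in lines if line.strip())

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self._ids) + "\n")
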