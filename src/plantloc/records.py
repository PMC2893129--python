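"""Core record types shared across the package.

A *locative* entry is one (protein, location) pair: a protein annotated with
two locations contributes two locative entries even though it is a single
sequence.  All dataset accounting downstream builds on this distinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

#: The twelve plant subcellular location sites, in their canonical order.
DEFAULT_LOCATIONS: tuple[str, ...] = (
    "cell membrane",
    "cell wall",
    "chloroplast",
    "cytoplasm",
    "endoplasmic reticulum",
    "extracellular",
    "golgi apparatus",
    "mitochondrion",
    "nucleus",
    "peroxisome",
    "plastid",
    "vacuole",
)

#: Canonical 20-letter amino acid alphabet, alphabetical single-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Letters tolerated in input sequences beyond the canonical twenty.
EXTRA_LETTERS: str = "XBZUJO*"

_VALID_LETTERS = frozenset(AMINO_ACIDS) | frozenset(EXTRA_LETTERS)

#: Query sequences shorter than this are treated as fragments (warning only).
FRAGMENT_LENGTH: int = 50


class SequenceError(ValueError):
    """Raised for an empty or non-amino-acid protein sequence."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an optional set of true location labels.

    Parameters
    ----------
    id : str
        Accession or user-supplied identifier.
    sequence : str
        Amino acid sequence over the 20-letter alphabet; ``X`` and the other
        common ambiguity codes are tolerated.
    labels : frozenset of str
        True subcellular locations; empty for query proteins.
    """

    id: str
    sequence: str
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise SequenceError(f"protein {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_LETTERS
        if bad:
            raise SequenceError(
                f"protein {self.id!r}: invalid sequence letters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)
        if not isinstance(self.labels, frozenset):
            object.__setattr__(self, "labels", frozenset(self.labels))

    @property
    def is_fragment(self) -> bool:
        return len(self.sequence) < FRAGMENT_LENGTH

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LocativeDataset:
    """A labeled multi-location benchmark.

    ``locations`` is the frame of candidate location sites; every protein's
    label set must be a subset of it.
    """

    proteins: list[ProteinRecord]
    locations: tuple[str, ...] = DEFAULT_LOCATIONS

    def __post_init__(self) -> None:
        if len(set(self.locations)) != len(self.locations):
            raise ValueError("duplicate location names in frame")
        known = set(self.locations)
        for rec in self.proteins:
            extra = rec.labels - known
            if extra:
                raise ValueError(
                    f"protein {rec.id!r} labeled with unknown locations {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.proteins)

    def locative_entries(self) -> list[tuple[str, str]]:
        """Flatten to (protein id, location) pairs, one per locative entry."""
        out: list[tuple[str, str]] = []
        for rec in self.proteins:
            for loc in sorted(rec.labels):
                out.append((rec.id, loc))
        return out

    def label_counts(self) -> dict[int, int]:
        """Map k -> number of proteins with exactly k locations (k >= 1)."""
        counts: dict[int, int] = {}
        for rec in self.proteins:
            k = len(rec.labels)
            counts[k] = counts.get(k, 0) + 1
        return counts

    def truth_sets(self) -> dict[str, set[str]]:
        return {rec.id: set(rec.labels) for rec in self.proteins}
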