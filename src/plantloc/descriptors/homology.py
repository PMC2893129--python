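"""GO-term descriptors transferred from database homologs.

The query itself carries no annotation: its homology set — the significant
database matches above an identity floor — stands in for it, and the union of
the homologs' GO annotations becomes a binary vector over the term catalogue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .binary import BinaryVector, GOVector
from .indices import IdentifierIndex

logger = logging.getLogger(__name__)

#: Default homology-search expect-value cutoff.
DEFAULT_E_CUTOFF = 1e-3
#: Default percent-identity floor for homology-set membership.
DEFAULT_IDENTITY_CUTOFF = 25.0


@dataclass(frozen=True)
class HomologyMember:
    accession: str
    identity_pct: float
    evalue: float


@dataclass(frozen=True)
class HomologySet:
    """The significant database matches of one query; may be empty."""

    query_id: str
    members: tuple[HomologyMember, ...]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(m.accession for m in self.members)


def build_homology_set(
    query_id: str,
    homology_table: Mapping[str, Sequence[tuple[str, float, float]]],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
) -> HomologySet:
    """Filter a pre-computed homology table down to one query's homology set.

    Rows are (accession, percent identity, e-value).  Members must pass both
    ``evalue <= e_cutoff`` and ``identity >= identity_cutoff`` and are returned
    sorted by ascending e-value (accession breaks ties, for determinism).
    A query with no table rows yields an empty set — not an error.
    """
    rows = homology_table.get(query_id, ())
    members = [
        HomologyMember(acc, float(ident), float(ev))
        for acc, ident, ev in rows
        if float(ev) <= e_cutoff and float(ident) >= identity_cutoff
    ]
    members.sort(key=lambda m: (m.evalue, m.accession))
    return HomologySet(query_id, tuple(members))


def go_vector(
    homology_set: HomologySet,
    annotation_index: Mapping[str, Iterable[str]],
    go_term_index: IdentifierIndex,
) -> GOVector:
    """Union the homologs' GO annotations into a binary term vector.

    Position i is 1 iff at least one member of the homology set is annotated
    with term i.  Members absent from the annotation index are skipped with a
    logged warning; annotated terms absent from the term catalogue likewise.
    An empty homology set yields the zero vector.
    """
    support: set[int] = set()
    for member in homology_set.members:
        try:
            terms = annotation_index[member.accession]
        except KeyError:
            logger.warning(
                "homology member %r of query %r has no annotation entry; skipped",
                member.accession,
                homology_set.query_id,
            )
            continue
        for term in terms:
            if term in go_term_index:
                support.add(go_term_index.position(term))
            else:
                logger.warning("GO term %r not in term index; skipped", term)
    return GOVector(frozenset(support), len(go_term_index))


def is_productive(
    vector: BinaryVector, training_vectors: Iterable[BinaryVector]
) -> bool:
    """Whether a GO vector carries usable evidence for nearest-neighbor search.

    True iff the vector is nonzero *and* shares at least one nonzero position
    with some training vector — otherwise no training protein provides any
    evidence under the angular distance and the query must be rerouted.
    """
    if vector.is_zero:
        return False
    return any(vector.overlaps(tv) for tv in training_vectors)
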