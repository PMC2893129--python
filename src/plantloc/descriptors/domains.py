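"""Functional-domain hit descriptors.

A protein is projected onto a conserved-domain catalogue: position j is 1 iff
a pre-computed alignment hit to domain j reaches the significance cutoff.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .binary import FunDVector
from .indices import IdentifierIndex

#: Default significance (expect-value) threshold for a domain hit.
DEFAULT_E_CUTOFF = 1e-3


class UnknownDomainError(KeyError):
    """A hit references a domain id absent from the domain catalogue."""


def fund_vector(
    protein_id: str,
    domain_hit_table: Mapping[str, Sequence[tuple[str, float]]],
    domain_index: IdentifierIndex,
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> FunDVector:
    """Threshold a protein's domain hits into a binary indicator vector.

    Rows are (domain id, e-value); position j is set iff some hit to domain j
    has ``evalue <= e_cutoff``.  A protein with no table rows yields the zero
    vector.  A hit naming a domain outside the catalogue is an error.
    """
    support: set[int] = set()
    for domain_id, evalue in domain_hit_table.get(protein_id, ()):
        if domain_id not in domain_index:
            raise UnknownDomainError(
                f"protein {protein_id!r}: domain id {domain_id!r} not in domain index"
            )
        if float(evalue) <= e_cutoff:
            support.add(domain_index.position(domain_id))
    return FunDVector(frozenset(support), len(domain_index))
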