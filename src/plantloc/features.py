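"""Assemble per-protein descriptor feature sets from pre-computed tables."""

from __future__ import annotations

from typing import Callable, Iterable, Mapping

import numpy as np

from .descriptors import (
    IdentifierIndex,
    build_homology_set,
    fund_vector,
    go_vector,
    standardize_pssm,
)
from .ensemble import FeatureSet

PSSMProvider = Callable[[str], "np.ndarray | None"]


def build_features(
    protein_ids: Iterable[str],
    homology_table: Mapping[str, list[tuple[str, float, float]]],
    annotation_index: Mapping[str, set[str]],
    go_index: IdentifierIndex,
    domain_hits: Mapping[str, list[tuple[str, float]]],
    domain_index: IdentifierIndex,
    pssm_provider: PSSMProvider | Mapping[str, np.ndarray] | None = None,
    homology_e_cutoff: float = 1e-3,
    identity_cutoff: float = 25.0,
    domain_e_cutoff: float = 1e-3,
) -> dict[str, FeatureSet]:
    """Run the full descriptor pipeline for each protein id.

    Produces a GO vector via the homology set, a domain vector via hit
    thresholding, and a standardized scoring matrix when the provider has one
    for the id (a missing matrix simply leaves that mode absent, triggering
    the GO/domain-only routing downstream).
    """
    if pssm_provider is None:
        provider: PSSMProvider = lambda pid: None
    elif isinstance(pssm_provider, Mapping):
        provider = pssm_provider.get
    else:
        provider = pssm_provider

    out: dict[str, FeatureSet] = {}
    for pid in protein_ids:
        hs = build_homology_set(pid, homology_table, homology_e_cutoff, identity_cutoff)
        go = go_vector(hs, annotation_index, go_index)
        fund = fund_vector(pid, domain_hits, domain_index, domain_e_cutoff)
        raw = provider(pid)
        pssm = standardize_pssm(raw) if raw is not None else None
        out[pid] = FeatureSet(go=go, fund=fund, pssm=pssm)
    return out
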