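"""Statistically controlled synthetic benchmarks.

Each location owns a disjoint GO-term signature, domain signature, and
scoring-matrix column profile.  A protein samples from its location's
signatures; the class-separation knob ``s`` blends toward a shared background
(at s = 1 with zero noise, all proteins of a location have identical
descriptors), and multi-location proteins blend two locations' profiles and
carry both labels.  Every file dialect the descriptor layer reads can be
emitted, and all randomness flows from one seed.

Random draws are consumed identically regardless of the separation, noise,
and informativeness rates (decisions are thresholded against pre-drawn
uniforms), so benchmarks generated at the same seed but different rates share
their underlying random structure — separation ladders are monotone by
construction, not by luck.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import formats
from .descriptors import IdentifierIndex, format_pssm_ascii
from .ensemble import FeatureSet
from .features import build_features
from .records import AMINO_ACIDS, DEFAULT_LOCATIONS, LocativeDataset, ProteinRecord


class InfeasibleConfigError(ValueError):
    """A simulation config whose signature demands exceed its index sizes."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs for benchmark generation.

    ``proteins_per_location`` counts single-location proteins; multi-location
    proteins are generated on top, in same-pair groups of at least two so that
    leave-one-out always retains a same-pair exemplar.
    """

    n_locations: int = 4
    proteins_per_location: int = 20
    length_range: tuple[int, int] = (60, 400)
    separation: float = 0.9
    multi_location_fraction: float = 0.08
    annotation_informativeness: float = 1.0
    noise: float = 0.0
    go_terms_per_location: int = 8
    background_go_terms: int = 40
    domains_per_location: int = 5
    background_domains: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "separation",
            "multi_location_fraction",
            "annotation_informativeness",
            "noise",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InfeasibleConfigError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.length_range
        if lo < 50 or hi < lo:
            raise InfeasibleConfigError(
                f"length range {self.length_range} invalid: lengths must be >= 50 "
                "(shorter chains are fragments)"
            )
        if self.n_locations < 2:
            raise InfeasibleConfigError("need at least 2 locations")
        if self.proteins_per_location < 2:
            raise InfeasibleConfigError("need at least 2 proteins per location")
        if self.go_terms_per_location < 1 or self.domains_per_location < 1:
            raise InfeasibleConfigError("signature sizes must be positive")

    @property
    def locations(self) -> tuple[str, ...]:
        if self.n_locations <= len(DEFAULT_LOCATIONS):
            return DEFAULT_LOCATIONS[: self.n_locations]
        extra = tuple(
            f"site {i}" for i in range(len(DEFAULT_LOCATIONS) + 1, self.n_locations + 1)
        )
        return DEFAULT_LOCATIONS + extra


@dataclass
class SyntheticBenchmark:
    """A generated benchmark plus every table the descriptor layer consumes."""

    config: SimConfig
    dataset: LocativeDataset
    go_index: IdentifierIndex
    domain_index: IdentifierIndex
    homology_table: dict[str, list[tuple[str, float, float]]]
    annotation_index: dict[str, set[str]]
    domain_hits: dict[str, list[tuple[str, float]]]
    pssms: dict[str, np.ndarray]

    def features(self) -> dict[str, FeatureSet]:
        """Run the real descriptor pipeline over the generated tables."""
        return build_features(
            [rec.id for rec in self.dataset],
            self.homology_table,
            self.annotation_index,
            self.go_index,
            self.domain_hits,
            self.domain_index,
            self.pssms,
        )

    def write(self, out_dir: str | Path) -> Path:
        """Emit the full fixture tree (plain text only) and a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        formats.write_benchmark(self.dataset, out / "benchmark.tsv")
        formats.write_fasta(self.dataset.proteins, out / "sequences.fasta")
        formats.write_homology_table(self.homology_table, out / "homology.tsv")
        formats.write_annotation_index(self.annotation_index, out / "annotations.tsv")
        formats.write_domain_hits(self.domain_hits, out / "domain_hits.tsv")
        self.go_index.to_file(out / "go_terms.txt")
        self.domain_index.to_file(out / "domains.txt")
        pssm_dir = out / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        seq_by_id = {rec.id: rec.sequence for rec in self.dataset}
        for pid, matrix in self.pssms.items():
            (pssm_dir / f"{pid}.pssm").write_text(
                format_pssm_ascii(matrix, seq_by_id[pid])
            )
        manifest = {"config": asdict(self.config), "seed": self.config.seed}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return out / "manifest.json"


def generate_pssm(
    profile: np.ndarray,
    length: int,
    noise: float,
    seed: int,
    sequence: str | None = None,
) -> tuple[np.ndarray, str]:
    """Raw integer score matrix around a 20-component profile, plus its ASCII form.

    Every row is the profile plus integer-rounded Gaussian noise; at zero
    noise all rows equal the rounded profile exactly.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.shape != (20,):
        raise ValueError("profile must have 20 components")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, 1.0, size=(length, 20))
    raw = np.rint(profile + 3.0 * noise * eps).astype(np.int64)
    if sequence is None:
        sequence = "A" * length
    return raw, format_pssm_ascii(raw, sequence)


def _multi_plan(config: SimConfig) -> list[tuple[int, int]]:
    """Disjoint location pairs for multi-location proteins, each used >= 2 times."""
    pairs = [(2 * i, 2 * i + 1) for i in range(config.n_locations // 2)]
    f = config.multi_location_fraction
    if f == 0.0 or not pairs:
        return []
    n_singles = config.n_locations * config.proteins_per_location
    target = f / (1.0 - f) * n_singles if f < 1.0 else n_singles
    per_pair = max(2, round(target / len(pairs)))
    plan = []
    for pair in pairs:
        plan.extend([pair] * per_pair)
    return plan


def generate_benchmark(config: SimConfig) -> SyntheticBenchmark:
    """Generate a fully seeded benchmark with all descriptor input tables."""
    rng = np.random.default_rng(config.seed)
    M = config.n_locations
    locations = config.locations
    g = config.go_terms_per_location
    dsig = config.domains_per_location

    n_go = M * g + config.background_go_terms
    go_ids = [f"GO:{i + 1:07d}" for i in range(n_go)]
    go_index = IdentifierIndex(go_ids)
    go_sig = {c: [go_ids[c * g + j] for j in range(g)] for c in range(M)}
    go_background = go_ids[M * g :]

    n_dom = M * dsig + config.background_domains
    dom_ids = [f"CDD{i + 1:05d}" for i in range(n_dom)]
    domain_index = IdentifierIndex(dom_ids)
    dom_sig = {c: [dom_ids[c * dsig + j] for j in range(dsig)] for c in range(M)}
    dom_background = dom_ids[M * dsig :]

    class_profiles = rng.normal(0.0, 4.0, size=(M, 20))
    background_profile = rng.normal(0.0, 4.0, size=20)

    memberships: list[tuple[int, ...]] = []
    for c in range(M):
        memberships.extend([(c,)] * config.proteins_per_location)
    memberships.extend(_multi_plan(config))

    s = config.separation
    noise = config.noise
    proteins: list[ProteinRecord] = []
    homology: dict[str, list[tuple[str, float, float]]] = {}
    annotations: dict[str, set[str]] = {}
    domain_hits: dict[str, list[tuple[str, float]]] = {}
    pssms: dict[str, np.ndarray] = {}
    lo, hi = config.length_range

    for n, classes in enumerate(memberships, start=1):
        pid = f"P{n:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
        labels = frozenset(locations[c] for c in classes)
        proteins.append(ProteinRecord(pid, seq, labels))

        # GO terms: one slot per signature term of each contributing class;
        # each slot independently degrades toward background / arbitrary terms.
        # All uniforms are drawn regardless of the rates (common random numbers).
        terms: list[str] = []
        slots = [t for c in classes for t in go_sig[c]]
        for term in slots:
            u_sig = rng.random()
            u_noise = rng.random()
            bg = go_background[int(rng.integers(len(go_background)))]
            anyterm = go_ids[int(rng.integers(n_go))]
            chosen = term if u_sig < s or s == 1.0 else bg
            if u_noise < noise:
                chosen = anyterm
            terms.append(chosen)
        u_inf = rng.random()
        informative = (
            u_inf < config.annotation_informativeness
            or config.annotation_informativeness == 1.0
        )
        if informative:
            ref_a, ref_b = f"R{pid}a", f"R{pid}b"
            annotations[ref_a] = set(terms[0::2]) or set(terms)
            annotations[ref_b] = set(terms[1::2]) or set(terms)
            homology[pid] = [(ref_a, 90.0, 1e-60), (ref_b, 80.0, 1e-40)]

        hits: list[tuple[str, float]] = []
        for dom in [d for c in classes for d in dom_sig[c]]:
            u_sig = rng.random()
            u_noise = rng.random()
            bg = dom_background[int(rng.integers(len(dom_background)))]
            anydom = dom_ids[int(rng.integers(n_dom))]
            chosen = dom if u_sig < s or s == 1.0 else bg
            if u_noise < noise:
                chosen = anydom
            hits.append((chosen, 1e-8))
        u_fail = rng.random()
        fail_dom = dom_ids[int(rng.integers(n_dom))]
        if u_fail < noise:
            hits.append((fail_dom, 0.5))  # insignificant hit, must be filtered
        domain_hits[pid] = hits

        class_profile = class_profiles[list(classes)].mean(axis=0)
        profile = s * class_profile + (1.0 - s) * background_profile
        child_seed = int(rng.integers(2**31))
        raw, _ = generate_pssm(profile, length, noise, child_seed, seq)
        pssms[pid] = raw

    dataset = LocativeDataset(proteins, locations)
    return SyntheticBenchmark(
        config=config,
        dataset=dataset,
        go_index=go_index,
        domain_index=domain_index,
        homology_table=homology,
        annotation_index=annotations,
        domain_hits=domain_hits,
        pssms=pssms,
    )
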