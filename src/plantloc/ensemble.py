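"""Ensembles of evidence-theoretic KNN members with GO-first routing.

A trained model holds one training set per descriptor mode (GO, functional
domain, and one evolution-descriptor set per correlation tier lambda).  A
query is routed to the GO engine alone when its GO vector is productive;
otherwise the domain and evolution engines are fused.  Members — one per
(mode, K[, lambda]) grid point — vote, votes are tallied into normalized
per-location scores, and every location scoring at least ``tau`` times the
maximum is reported, so single- and multi-location proteins share one
decision rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import etknn
from .descriptors import (
    FunDVector,
    GOVector,
    PSSMatrix,
    is_productive,
    psepssm_vector,
)
from .etknn import ETKNNParams, Frame, MassFunction, TrainingSet
from .records import LocativeDataset, ProteinRecord

logger = logging.getLogger(__name__)

GO_MODE = "go"
FUND_MODE = "fund"
PSE_MODE = "psepssm"


class UnroutableQueryError(ValueError):
    """A query with no usable descriptor representation at all."""


@dataclass(frozen=True)
class EnsembleConfig:
    """Grids and decision parameters for the fused classifier."""

    k_grid: tuple[int, ...] = tuple(range(1, 11))
    lambda_grid: tuple[int, ...] = tuple(range(0, 11))
    tau: float = 0.7
    mode_weights: Mapping[str, float] = field(
        default_factory=lambda: {GO_MODE: 1.0, FUND_MODE: 1.0, PSE_MODE: 1.0}
    )
    alpha: float = 0.95
    fit_gammas: bool = False
    fit_max_iter: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.k_grid or not self.lambda_grid:
            raise ValueError("K and lambda grids must be non-empty")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must lie in (0, 1]")


@dataclass(frozen=True)
class FeatureSet:
    """Per-protein descriptor inputs; any subset may be present."""

    go: GOVector | None = None
    fund: FunDVector | None = None
    pssm: PSSMatrix | None = None


@dataclass(frozen=True)
class MemberVote:
    """One grid member's prediction; exact belief ties keep all tied classes."""

    mode: str
    k: int
    lambda_: int | None
    classes: tuple[str, ...]


@dataclass
class FusedScores:
    """Normalized per-location support with member provenance."""

    scores: dict[str, float]
    votes: list[MemberVote]

    @property
    def max_score(self) -> float:
        return max(self.scores.values())

    def top(self) -> str:
        return max(sorted(self.scores), key=lambda c: self.scores[c])


@dataclass
class TrainedModel:
    """Training sets, fitted parameters, and bookkeeping for all modes."""

    frame: Frame
    config: EnsembleConfig
    go_training: TrainingSet | None = None
    go_gamma: np.ndarray | None = None
    fund_training: TrainingSet | None = None
    fund_gamma: np.ndarray | None = None
    pse_training: dict[int, TrainingSet] = field(default_factory=dict)
    pse_gamma: dict[int, np.ndarray] = field(default_factory=dict)
    go_vectors: list[GOVector] = field(default_factory=list)

    def max_k(self) -> int:
        sizes = [
            len(ts)
            for ts in [self.go_training, self.fund_training, *self.pse_training.values()]
            if ts is not None
        ]
        return min(sizes) if sizes else 0


def _fit_mode(
    X: np.ndarray,
    y: np.ndarray,
    frame: Frame,
    config: EnsembleConfig,
    distance: etknn.DistanceFn,
) -> tuple[TrainingSet, np.ndarray]:
    training = TrainingSet(X, y, frame)
    gamma = etknn.initial_gammas(training, distance)
    if config.fit_gammas and len(np.unique(y)) >= 2 and len(training) >= 3:
        k = min(max(config.k_grid), len(training) - 1)
        params = ETKNNParams(k=k, alpha=config.alpha, gamma=gamma)
        fitted = etknn.optimize_gammas(
            training,
            params,
            max_iter=config.fit_max_iter,
            seed=config.seed,
            distance=distance,
        )
        gamma = np.asarray(fitted.gamma)
    return training, gamma


def train_model(
    dataset: LocativeDataset,
    features: Mapping[str, FeatureSet],
    config: EnsembleConfig,
) -> TrainedModel:
    """Assemble per-mode training sets from locative entries and fit rates.

    Each (protein, location) pair contributes one row per mode the protein has
    features for; a 2-location protein appears twice with identical rows.
    Evolution descriptors are built once per lambda in the configured grid
    (lambdas not below the shortest available chain are dropped with a notice).
    """
    frame = Frame(dataset.locations)
    go_rows: list[np.ndarray] = []
    go_y: list[int] = []
    go_vecs: list[GOVector] = []
    fund_rows: list[np.ndarray] = []
    fund_y: list[int] = []
    pse_rows: dict[int, list[np.ndarray]] = {}
    pse_y: dict[int, list[int]] = {}

    min_len = min(
        (fs.pssm.length for fs in features.values() if fs.pssm is not None),
        default=0,
    )
    usable_lambdas = [l for l in config.lambda_grid if l < max(min_len, 1)]
    dropped = set(config.lambda_grid) - set(usable_lambdas)
    if dropped and min_len:
        logger.warning(
            "lambda values %s dropped: not below shortest matrix length %d",
            sorted(dropped),
            min_len,
        )

    pse_cache: dict[tuple[str, int], np.ndarray] = {}
    for rec in dataset:
        fs = features.get(rec.id)
        if fs is None:
            raise KeyError(f"no features supplied for protein {rec.id!r}")
        for label in sorted(rec.labels):
            q = frame.index(label)
            if fs.go is not None and not fs.go.is_zero:
                go_rows.append(fs.go.to_array())
                go_y.append(q)
                go_vecs.append(fs.go)
            if fs.fund is not None and not fs.fund.is_zero:
                fund_rows.append(fs.fund.to_array())
                fund_y.append(q)
            if fs.pssm is not None:
                for lam in usable_lambdas:
                    if lam >= fs.pssm.length:
                        continue
                    key = (rec.id, lam)
                    if key not in pse_cache:
                        pse_cache[key] = psepssm_vector(fs.pssm, lam).to_array()
                    pse_rows.setdefault(lam, []).append(pse_cache[key])
                    pse_y.setdefault(lam, []).append(q)

    model = TrainedModel(frame=frame, config=config, go_vectors=go_vecs)
    if go_rows:
        model.go_training, model.go_gamma = _fit_mode(
            np.array(go_rows), np.array(go_y), frame, config, etknn.distance_angular
        )
    if fund_rows:
        model.fund_training, model.fund_gamma = _fit_mode(
            np.array(fund_rows), np.array(fund_y), frame, config, etknn.distance_angular
        )
    for lam in sorted(pse_rows):
        model.pse_training[lam], model.pse_gamma[lam] = _fit_mode(
            np.array(pse_rows[lam]),
            np.array(pse_y[lam]),
            frame,
            config,
            etknn.distance_euclidean,
        )
    return model


def route(features: FeatureSet, model: TrainedModel) -> tuple[str, ...]:
    """Choose the descriptor modes for a query: GO alone, else domain+evolution.

    The GO engine is used exclusively when the query's GO vector is productive
    against the model's GO training vectors.  Otherwise whichever of the
    domain and evolution representations exist are fused; a query with none is
    unroutable.
    """
    if (
        features.go is not None
        and model.go_training is not None
        and is_productive(features.go, model.go_vectors)
    ):
        return (GO_MODE,)
    fallback = []
    if features.fund is not None and not features.fund.is_zero and model.fund_training:
        fallback.append(FUND_MODE)
    if features.pssm is not None and model.pse_training:
        fallback.append(PSE_MODE)
    if not fallback:
        raise UnroutableQueryError(
            "query has no productive GO vector and no domain/evolution features"
        )
    return tuple(fallback)


def _member_votes_for_mode(
    query: np.ndarray,
    training: TrainingSet,
    gamma: np.ndarray,
    mode: str,
    lambda_: int | None,
    config: EnsembleConfig,
    distance: etknn.DistanceFn,
) -> list[MemberVote]:
    votes = []
    for k in config.k_grid:
        if k > len(training):
            continue
        params = ETKNNParams(k=k, alpha=config.alpha, gamma=gamma)
        masses = etknn.belief_scores(query, training, params, distance)
        votes.append(MemberVote(mode, k, lambda_, masses.argmax_classes()))
    return votes


def run_members(
    features: FeatureSet,
    model: TrainedModel,
    config: EnsembleConfig,
    plan: Sequence[str] | None = None,
) -> list[MemberVote]:
    """Run every grid member of the routed plan and collect its vote.

    One member per (mode, K) for the binary modes and per (K, lambda) for the
    evolution mode.  A member's vote is the set of classes tying its maximal
    combined singleton mass; splitting exact ties (rather than drawing one
    class at random) keeps the fused tally deterministic and lets a balanced
    two-location query support both of its locations.
    """
    if plan is None:
        plan = route(features, model)
    votes: list[MemberVote] = []
    if GO_MODE in plan:
        assert features.go is not None and model.go_training is not None
        votes += _member_votes_for_mode(
            features.go.to_array(),
            model.go_training,
            model.go_gamma,
            GO_MODE,
            None,
            config,
            etknn.distance_angular,
        )
    if FUND_MODE in plan:
        assert features.fund is not None and model.fund_training is not None
        votes += _member_votes_for_mode(
            features.fund.to_array(),
            model.fund_training,
            model.fund_gamma,
            FUND_MODE,
            None,
            config,
            etknn.distance_angular,
        )
    if PSE_MODE in plan:
        assert features.pssm is not None
        for lam, training in sorted(model.pse_training.items()):
            if lam >= features.pssm.length:
                continue
            qvec = psepssm_vector(features.pssm, lam).to_array()
            votes += _member_votes_for_mode(
                qvec,
                training,
                model.pse_gamma[lam],
                PSE_MODE,
                lam,
                config,
                etknn.distance_euclidean,
            )
    if not votes:
        raise UnroutableQueryError("no ensemble member could vote on the query")
    return votes


def fuse_votes(votes: Sequence[MemberVote], config: EnsembleConfig) -> FusedScores:
    """Tally member votes into normalized per-location scores.

    Each member carries its mode's weight, split equally among the classes it
    tied on; scores are normalized to sum to 1 over the locations that
    received any vote mass.
    """
    if not votes:
        raise ValueError("need at least one member vote")
    tally: dict[str, float] = {}
    total = 0.0
    for vote in votes:
        weight = float(config.mode_weights.get(vote.mode, 1.0))
        if weight == 0.0 or not vote.classes:
            continue
        share = weight / len(vote.classes)
        for cls in vote.classes:
            tally[cls] = tally.get(cls, 0.0) + share
        total += weight
    if total <= 0.0:
        raise ValueError("all member votes carry zero weight")
    return FusedScores({c: v / total for c, v in tally.items()}, list(votes))


def decide_locations(fused: FusedScores, config: EnsembleConfig) -> frozenset[str]:
    """Report every location scoring at least tau times the maximum.

    Always contains the argmax (so never empty); at tau = 1 only exact maxima
    survive; lowering tau can only add locations.
    """
    cutoff = config.tau * fused.max_score
    return frozenset(c for c, v in fused.scores.items() if v >= cutoff - 1e-12)


def predict(
    features: FeatureSet,
    model: TrainedModel,
    config: EnsembleConfig | None = None,
    protein_id: str = "?",
) -> tuple[frozenset[str], FusedScores]:
    """Route, run all grid members, fuse their votes, and decide the label set."""
    if config is None:
        config = model.config
    try:
        plan = route(features, model)
        votes = run_members(features, model, config, plan)
    except UnroutableQueryError as exc:
        raise UnroutableQueryError(f"protein {protein_id!r}: {exc}") from None
    fused = fuse_votes(votes, config)
    return decide_locations(fused, config), fused


def make_jackknife_builder(
    features: Mapping[str, FeatureSet],
    locations: tuple[str, ...],
    config: EnsembleConfig,
):
    """Model-builder closure for leave-one-out evaluation.

    Returns a callable mapping a training protein list to a predictor
    ``ProteinRecord -> set of locations``, rebuilding the full ensemble on
    each fold.
    """

    def builder(train_records: Sequence[ProteinRecord]):
        subset = LocativeDataset(list(train_records), locations)
        model = train_model(subset, features, config)

        def predict_fn(record: ProteinRecord) -> set[str]:
            labels, _ = predict(features[record.id], model, config, record.id)
            return set(labels)

        return predict_fn

    return builder
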