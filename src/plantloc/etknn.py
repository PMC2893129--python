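"""Evidence-theoretic K-nearest-neighbor classification.

Each of a query's K nearest training neighbors contributes a basic belief
assignment: mass ``alpha * exp(-gamma_q * d^2)`` on the neighbor's class
singleton and the remainder on the whole frame.  The K assignments are
aggregated with Dempster's (normalized) rule of combination and the query is
assigned to the class of maximal combined singleton mass, which for this
evidence structure equals its belief.  The "optimized" variant fits the
per-class rates ``gamma_q`` by descending a leave-one-out squared error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

#: Tolerance used both for mass-sum checks and exact-tie detection.
MASS_TOL = 1e-9

DistanceFn = Callable[[np.ndarray, np.ndarray], float]


class ZeroVectorError(ValueError):
    """Angular distance is undefined for a zero vector."""


class DegenerateEvidenceError(ValueError):
    """Dempster combination with total conflict (normalizer zero)."""


class OptimizationError(RuntimeError):
    """The rate-parameter fit produced a non-finite error."""


@dataclass(frozen=True)
class Frame:
    """The ordered set of candidate location classes."""

    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a frame needs at least 2 classes")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("frame classes must be unique")

    def __len__(self) -> int:
        return len(self.classes)

    def index(self, label: str) -> int:
        return self.classes.index(label)


@dataclass
class TrainingSet:
    """Descriptor vectors with integer class labels, one row per locative entry.

    A protein annotated with two locations appears twice, once per label, with
    identical feature rows.
    """

    X: np.ndarray
    y: np.ndarray
    frame: Frame

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.y.size and (self.y.min() < 0 or self.y.max() >= len(self.frame)):
            raise ValueError("labels outside the frame")

    def __len__(self) -> int:
        return int(self.X.shape[0])


@dataclass(frozen=True)
class ETKNNParams:
    """Classifier parameters: neighbor count, evidence scale, per-class rates."""

    k: int
    alpha: float = 0.95
    gamma: np.ndarray | None = None  # shape (M,), positive

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma is not None:
            g = np.asarray(self.gamma, dtype=np.float64)
            if (g <= 0).any():
                raise ValueError("all gamma rates must be positive")
            object.__setattr__(self, "gamma", g)

    def gamma_for(self, m: int) -> np.ndarray:
        return np.ones(m) if self.gamma is None else np.asarray(self.gamma)


@dataclass
class MassFunction:
    """Dempster-Shafer masses over class singletons plus the whole frame.

    Only singletons and the frame itself ever carry mass here: the neighbor
    evidence has that structure and it is closed under Dempster combination.
    """

    frame: Frame
    singletons: np.ndarray
    omega: float

    def __post_init__(self) -> None:
        self.singletons = np.asarray(self.singletons, dtype=np.float64)
        if self.singletons.shape != (len(self.frame),):
            raise ValueError("one singleton mass per frame class required")
        if (self.singletons < -MASS_TOL).any() or self.omega < -MASS_TOL:
            raise ValueError("masses must be non-negative")
        total = float(self.singletons.sum() + self.omega)
        if abs(total - 1.0) > MASS_TOL:
            raise ValueError(f"masses must sum to 1 (got {total!r})")

    @classmethod
    def vacuous(cls, frame: Frame) -> "MassFunction":
        return cls(frame, np.zeros(len(frame)), 1.0)

    def mass(self, label: str) -> float:
        return float(self.singletons[self.frame.index(label)])

    def argmax_classes(self, tol: float = MASS_TOL) -> tuple[str, ...]:
        """Classes whose singleton mass ties the maximum within ``tol``."""
        top = float(self.singletons.max())
        tied = np.flatnonzero(self.singletons >= top - tol)
        return tuple(self.frame.classes[i] for i in tied)


def distance_angular(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v); in [0, 2], zero for parallel vectors.

    Undefined (raises) when either vector is zero — non-productive binary
    descriptors must be filtered out before distance computation.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("angular distance undefined for a zero vector")
    return float(1.0 - float(u @ v) / (nu * nv))


def distance_euclidean(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


def bba_from_neighbor(
    d: float, class_q: int, params: ETKNNParams, frame: Frame
) -> MassFunction:
    """One neighbor's basic belief assignment.

    Mass ``alpha * exp(-gamma_q * d^2)`` goes on the neighbor's class
    singleton; the remainder stays on the whole frame (ignorance).
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    gamma = params.gamma_for(len(frame))
    s = params.alpha * math.exp(-float(gamma[class_q]) * d * d)
    singletons = np.zeros(len(frame))
    singletons[class_q] = s
    return MassFunction(frame, singletons, 1.0 - s)


def dempster_combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Normalized orthogonal sum of two singleton+frame mass functions.

    Conflict (mass on empty intersections of differing singletons) is
    renormalized away; total conflict is an error.  Commutative and
    associative, with the vacuous mass as identity.
    """
    if m1.frame != m2.frame:
        raise ValueError("mass functions defined on different frames")
    s1, w1 = m1.singletons, m1.omega
    s2, w2 = m2.singletons, m2.omega
    singletons = s1 * s2 + s1 * w2 + w1 * s2
    omega = w1 * w2
    norm = float(singletons.sum() + omega)
    if norm <= 0.0:
        raise DegenerateEvidenceError("total conflict: combination undefined")
    return MassFunction(m1.frame, singletons / norm, omega / norm)


def _neighbor_indices(dists: np.ndarray, k: int) -> np.ndarray:
    """Indices of the K nearest points, extended to include exact-distance ties.

    Including every point tied with the K-th distance keeps the neighbor set
    well defined (independent of storage order) when many training points are
    equidistant, as happens with identical descriptor vectors.
    """
    order = np.argsort(dists, kind="stable")
    kth = dists[order[min(k, dists.size) - 1]]
    cutoff = kth + MASS_TOL * max(1.0, abs(kth))
    return order[dists[order] <= cutoff]


def belief_scores(
    query: np.ndarray,
    training: TrainingSet,
    params: ETKNNParams,
    distance: DistanceFn = distance_euclidean,
) -> MassFunction:
    """Combined masses from the query's K nearest neighbors' evidence.

    Each neighbor's assignment is folded with Dempster's rule.  The fold is
    evaluated in closed product form (grouping neighbors by class), which is
    the exact orthogonal sum for this evidence structure and is independent of
    neighbor processing order.
    """
    if len(training) == 0:
        raise ValueError("empty training set")
    if params.k > len(training):
        raise ValueError(f"K={params.k} exceeds training size {len(training)}")
    dists = np.array([distance(query, row) for row in training.X])
    idx = _neighbor_indices(dists, params.k)
    m = len(training.frame)
    gamma = params.gamma_for(m)
    s = params.alpha * np.exp(-gamma[training.y[idx]] * dists[idx] ** 2)
    w = 1.0 - s
    # For BBAs with mass s_i on singleton y_i and 1-s_i on the frame, the
    # orthogonal sum has unnormalized masses
    #   m({q}) = prod_{i: y_i != q} w_i * (1 - prod_{i: y_i = q} w_i)
    #   m(frame) = prod_i w_i
    log_w = np.log(w)
    log_w_by_class = np.zeros(m)
    np.add.at(log_w_by_class, training.y[idx], log_w)
    w_all = float(np.exp(log_w_by_class.sum()))
    w_q = np.exp(log_w_by_class)
    with np.errstate(divide="ignore", invalid="ignore"):
        others = np.where(w_q > 0, w_all / w_q, 0.0)
    singletons = others * (1.0 - w_q)
    norm = float(singletons.sum() + w_all)
    if norm <= 0.0:
        raise DegenerateEvidenceError("total conflict: combination undefined")
    return MassFunction(training.frame, singletons / norm, w_all / norm)


def classify(
    query: np.ndarray,
    training: TrainingSet,
    params: ETKNNParams,
    distance: DistanceFn = distance_euclidean,
    rng: np.random.Generator | None = None,
) -> str:
    """Assign the query to the class of maximal combined singleton mass.

    Exact ties (within ``MASS_TOL``) are broken by a uniform draw from the
    supplied generator (or a fresh seeded one), so results are reproducible
    under a fixed seed.
    """
    masses = belief_scores(query, training, params, distance)
    tied = masses.argmax_classes()
    if len(tied) == 1:
        return tied[0]
    if rng is None:
        rng = np.random.default_rng(0)
    return tied[int(rng.integers(len(tied)))]


def _loo_error(
    training: TrainingSet,
    params: ETKNNParams,
    gamma: np.ndarray,
    distance: DistanceFn,
) -> float:
    """Leave-one-out squared error between combined masses and one-hot targets."""
    n = len(training)
    m = len(training.frame)
    k = min(params.k, n - 1)
    trial = replace(params, k=k, gamma=gamma)
    err = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        rest = TrainingSet(training.X[keep], training.y[keep], training.frame)
        masses = belief_scores(training.X[i], rest, trial, distance)
        target = np.zeros(m)
        target[training.y[i]] = 1.0
        err += float(((masses.singletons - target) ** 2).sum())
    return err / n


def initial_gammas(
    training: TrainingSet,
    distance: DistanceFn = distance_euclidean,
    floor: float = 1e-6,
) -> np.ndarray:
    """Per-class rate initialization: inverse mean within-class squared distance.

    Classes whose members are all coincident (mean squared distance 0, as in
    noise-free fixtures) or singletons fall back to a rate of 1.
    """
    m = len(training.frame)
    gamma = np.ones(m)
    for q in range(m):
        rows = training.X[training.y == q]
        if rows.shape[0] < 2:
            continue
        total, count = 0.0, 0
        for i in range(rows.shape[0]):
            for j in range(i + 1, rows.shape[0]):
                total += distance(rows[i], rows[j]) ** 2
                count += 1
        mean_sq = total / count
        if mean_sq > floor:
            gamma[q] = 1.0 / mean_sq
    return gamma


def optimize_gammas(
    training: TrainingSet,
    params: ETKNNParams,
    max_iter: int = 20,
    tol: float = 1e-6,
    seed: int = 0,
    distance: DistanceFn = distance_euclidean,
) -> ETKNNParams:
    """Fit per-class rates by descending the leave-one-out squared error.

    Plain gradient descent in log-rate space (keeping rates positive) with a
    numeric forward-difference gradient and backtracking step halving, so the
    error over accepted steps is non-increasing and never exceeds the error of
    the initial rates.  Deterministic for fixed inputs; ``seed`` is accepted
    for interface symmetry but the procedure draws no random numbers.
    """
    if len(np.unique(training.y)) < 2:
        raise ValueError("need at least 2 classes to fit rates")
    m = len(training.frame)
    gamma = params.gamma_for(m).copy()
    if params.gamma is None:
        gamma = initial_gammas(training, distance)
    log_g = np.log(gamma)
    err = _loo_error(training, params, np.exp(log_g), distance)
    if not math.isfinite(err):
        raise OptimizationError("initial leave-one-out error is non-finite")
    step = 0.5
    h = 1e-4
    for _ in range(max_iter):
        grad = np.zeros(m)
        for q in range(m):
            bumped = log_g.copy()
            bumped[q] += h
            e_plus = _loo_error(training, params, np.exp(bumped), distance)
            if not math.isfinite(e_plus):
                raise OptimizationError("leave-one-out error became non-finite")
            grad[q] = (e_plus - err) / h
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol:
            break
        trial_step = step
        improved = False
        while trial_step > 1e-6:
            cand = log_g - trial_step * grad / max(gnorm, 1.0)
            e_cand = _loo_error(training, params, np.exp(cand), distance)
            if e_cand < err - 1e-12:
                log_g, err = cand, e_cand
                improved = True
                break
            trial_step /= 2.0
        if not improved:
            break
    return replace(params, gamma=np.exp(log_g))
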