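"""Locative-protein accounting and jackknife evaluation.

All success rates are computed over locative entries: a protein with k true
locations contributes k scored pairs, each counted correct iff its location
appears in the predicted set.  Predicted labels outside the truth are tallied
as over-predictions and missed true labels as under-predictions, separately
from the success count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .records import LocativeDataset, ProteinRecord

logger = logging.getLogger(__name__)

ModelBuilder = Callable[[Sequence[ProteinRecord]], Callable[[ProteinRecord], set]]


@dataclass(frozen=True)
class DatasetBreakdown:
    """Counts of proteins by number of annotated locations.

    ``counts[k]`` is the number of different proteins with exactly k
    locations; their sum is the number of different proteins ``n_dif``.
    """

    counts: Mapping[int, int]
    m: int = 12

    def __post_init__(self) -> None:
        for k, n in self.counts.items():
            if k < 1 or k > self.m:
                raise ValueError(f"location count {k} outside [1, {self.m}]")
            if n < 0:
                raise ValueError("breakdown counts must be non-negative")

    @property
    def n_dif(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_dataset(cls, dataset: LocativeDataset) -> "DatasetBreakdown":
        return cls(dataset.label_counts(), m=len(dataset.locations))


@dataclass
class EvalReport:
    """Per-location and overall locative success with over/under tallies."""

    per_location_correct: dict[str, int]
    per_location_total: dict[str, int]
    over_predictions: int
    under_predictions: int

    @property
    def overall_correct(self) -> int:
        return sum(self.per_location_correct.values())

    @property
    def overall_total(self) -> int:
        return sum(self.per_location_total.values())

    @property
    def overall_rate(self) -> float:
        if self.overall_total == 0:
            raise ZeroDivisionError("report has no locative entries")
        return self.overall_correct / self.overall_total

    def location_rate(self, location: str) -> float:
        return self.per_location_correct[location] / self.per_location_total[location]

    def summary_lines(self) -> list[str]:
        """Human-readable table: location, correct/total = rate."""
        lines = []
        width = max((len(l) for l in self.per_location_total), default=8)
        for loc in sorted(self.per_location_total):
            c = self.per_location_correct[loc]
            t = self.per_location_total[loc]
            lines.append(f"{loc:<{width}}  {c}/{t} = {100.0 * c / t:.1f}%")
        lines.append(
            f"{'total':<{width}}  {self.overall_correct}/{self.overall_total}"
            f" = {100.0 * self.overall_rate:.1f}%"
        )
        lines.append(f"over-predictions: {self.over_predictions}")
        lines.append(f"under-predictions: {self.under_predictions}")
        return lines


def count_locative(breakdown: DatasetBreakdown) -> int:
    """Total locative proteins: sum over k of k * (proteins with k locations)."""
    return sum(k * n for k, n in breakdown.counts.items())


def multi_location_fraction(
    dataset: LocativeDataset | DatasetBreakdown,
) -> float:
    """Percentage of different proteins annotated with more than one location."""
    breakdown = (
        dataset
        if isinstance(dataset, DatasetBreakdown)
        else DatasetBreakdown.from_dataset(dataset)
    )
    if breakdown.n_dif == 0:
        raise ZeroDivisionError("empty dataset")
    multi = sum(n for k, n in breakdown.counts.items() if k >= 2)
    return 100.0 * multi / breakdown.n_dif


def score_predictions(
    truth_sets: Mapping[str, set],
    predicted_sets: Mapping[str, set],
    locations: Sequence[str] | None = None,
) -> EvalReport:
    """Score multi-label predictions over locative entries.

    Each (protein, true location) pair is correct iff the location is in the
    predicted set; extra predicted labels count as over-predictions and missed
    true labels as under-predictions (tracked separately — they do not void
    correct hits).
    """
    if set(truth_sets) != set(predicted_sets):
        missing = set(truth_sets) ^ set(predicted_sets)
        raise KeyError(f"truth/prediction protein ids differ: {sorted(missing)[:5]}")
    if locations is None:
        locations = sorted({loc for labels in truth_sets.values() for loc in labels})
    correct = {loc: 0 for loc in locations}
    total = {loc: 0 for loc in locations}
    over = under = 0
    for pid, truth in truth_sets.items():
        pred = set(predicted_sets[pid])
        for loc in truth:
            total[loc] += 1
            if loc in pred:
                correct[loc] += 1
        over += len(pred - truth)
        under += len(truth - pred)
    total = {loc: t for loc, t in total.items() if t > 0}
    correct = {loc: correct[loc] for loc in total}
    return EvalReport(correct, total, over, under)


def jackknife(
    dataset: LocativeDataset,
    model_builder: ModelBuilder,
    seed: int = 0,
) -> EvalReport:
    """Leave-one-out evaluation over different proteins.

    Each different protein — all its locative entries together — is withheld
    once, the model is rebuilt on the remainder, and the withheld protein's
    location set is predicted and scored.  The withheld protein never appears
    in its own training set (asserted by id).  Deterministic for a fixed seed.
    """
    location_sizes: dict[str, int] = {}
    for rec in dataset:
        for loc in rec.labels:
            location_sizes[loc] = location_sizes.get(loc, 0) + 1
    for loc, n in sorted(location_sizes.items()):
        if n < 2:
            logger.warning(
                "location %r has a single member; its fold cannot be learned", loc
            )
    truth: dict[str, set] = {}
    predicted: dict[str, set] = {}
    for i, held_out in enumerate(dataset.proteins):
        train_records = [r for j, r in enumerate(dataset.proteins) if j != i]
        assert all(r.id != held_out.id for r in train_records), "leakage"
        predict_fn = model_builder(train_records)
        truth[held_out.id] = set(held_out.labels)
        predicted[held_out.id] = set(predict_fn(held_out))
    return score_predictions(truth, predicted, dataset.locations)
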