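"""Categorical trial outcomes derived from longitudinal pain scores.

Each participant is scored at weeks 4, 8 and 12 as one of three mutually
exclusive categories: quit the study drug, stayed on drug with an
efficacious response, or stayed on drug without an efficacious response.
Efficacy means a reduction of at least half of the baseline pain score.
Quitting is absorbing: once a participant quits, every later visit is
recorded as quit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping

import numpy as np

from .errors import InvalidInputError

DEFAULT_VISIT_WEEKS: tuple[int, ...] = (4, 8, 12)

#: Fraction of baseline pain at or below which a response counts as efficacious.
EFFICACY_REDUCTION = 0.5


class OutcomeCategory(IntEnum):
    """Three-category visit outcome (one-hot components of the response vector)."""

    QUIT = 0
    NOTQUIT_EFF = 1
    NOTQUIT_NOEFF = 2


@dataclass
class PatientRecord:
    """One participant's arm assignment and longitudinal categorical outcomes.

    ``visit_outcomes`` maps a scheduled visit week to its observed category;
    a missing key means the visit has not been observed yet.
    """

    patient_id: str
    arm: int
    enrollment_week: float = 0.0
    baseline_pain: float = float("nan")
    visit_outcomes: dict[int, OutcomeCategory] = field(default_factory=dict)

    def latest_observed(self, before_week: int) -> tuple[int, OutcomeCategory] | None:
        """Latest observed (week, outcome) strictly before ``before_week``."""
        best = None
        for week, cat in self.visit_outcomes.items():
            if week < before_week and (best is None or week > best[0]):
                best = (week, cat)
        return best


@dataclass(frozen=True)
class Violation:
    """One finding from :func:`validate_record`."""

    severity: str  # "error" | "warning"
    message: str

    @property
    def is_error(self) -> bool:
        return self.severity == "error"


def classify_outcome(
    baseline_pain: float,
    followup_pain: float | None,
    quit: bool,
) -> OutcomeCategory:
    """Classify a single visit from raw pain scores and quit status.

    Quit dominates; otherwise the visit is efficacious iff the follow-up
    score is at most half of baseline (the boundary is inclusive).

    Raises
    ------
    InvalidInputError
        If ``baseline_pain`` is not positive (a reduction fraction would be
        undefined), or ``quit`` is false with no follow-up score.
    """
    if not baseline_pain > 0:
        raise InvalidInputError(
            f"baseline pain must be positive, got {baseline_pain!r}"
        )
    if quit:
        return OutcomeCategory.QUIT
    if followup_pain is None or (isinstance(followup_pain, float) and np.isnan(followup_pain)):
        raise InvalidInputError("follow-up pain score required when quit is false")
    if followup_pain <= EFFICACY_REDUCTION * baseline_pain:
        return OutcomeCategory.NOTQUIT_EFF
    return OutcomeCategory.NOTQUIT_NOEFF


def validate_record(
    record: PatientRecord,
    schedule: tuple[int, ...] = DEFAULT_VISIT_WEEKS,
    pain_range: tuple[float, float] | None = None,
) -> list[Violation]:
    """Check a record against the visit schedule and monotone-quit rule.

    Non-monotone quit patterns and off-schedule visit weeks are errors.
    A gap (a later visit observed while an earlier one is absent) is a
    warning only — multisite data entry is asynchronous and later visits
    routinely arrive first. An optional ``pain_range`` flags out-of-range
    baseline scores as warnings.
    """
    report: list[Violation] = []
    for week in record.visit_outcomes:
        if week not in schedule:
            report.append(
                Violation("error", f"visit week {week} not in schedule {schedule}")
            )
    quit_seen_at: int | None = None
    gap_open = False
    for week in sorted(schedule):
        cat = record.visit_outcomes.get(week)
        if cat is None:
            gap_open = True
            continue
        if gap_open:
            report.append(
                Violation(
                    "warning",
                    f"week-{week} outcome observed while an earlier scheduled "
                    "visit is absent",
                )
            )
            gap_open = False
        if quit_seen_at is not None and cat is not OutcomeCategory.QUIT:
            report.append(
                Violation(
                    "error",
                    f"non-monotone quit: QUIT at week {quit_seen_at} followed by "
                    f"{cat.name} at week {week}",
                )
            )
        if cat is OutcomeCategory.QUIT and quit_seen_at is None:
            quit_seen_at = week
    if pain_range is not None and not np.isnan(record.baseline_pain):
        lo, hi = pain_range
        if not lo <= record.baseline_pain <= hi:
            report.append(
                Violation(
                    "warning",
                    f"baseline pain {record.baseline_pain} outside [{lo}, {hi}]",
                )
            )
    return report


def tally_counts(
    records: Iterable[PatientRecord],
    arm: int,
    visit_week: int,
    n_arms: int | None = None,
    schedule: tuple[int, ...] = DEFAULT_VISIT_WEEKS,
) -> np.ndarray:
    """Count observed outcomes per category for one arm at one visit.

    Returns an integer triple ``(n_quit, n_eff, n_noeff)`` over records on
    ``arm`` with an observed outcome at ``visit_week``; unobserved visits
    are excluded, so the triple sums to the number of observed outcomes.
    """
    if visit_week not in schedule:
        raise InvalidInputError(f"visit week {visit_week} not in schedule {schedule}")
    if arm < 1 or (n_arms is not None and arm > n_arms):
        raise InvalidInputError(f"unknown arm {arm}")
    counts = np.zeros(3, dtype=np.int64)
    for rec in records:
        if rec.arm != arm:
            continue
        cat = rec.visit_outcomes.get(visit_week)
        if cat is not None:
            counts[int(cat)] += 1
    return counts


def records_to_arrays(
    records: Iterable[PatientRecord],
    schedule: tuple[int, ...] = DEFAULT_VISIT_WEEKS,
) -> tuple[np.ndarray, np.ndarray]:
    """Pack records into (arms, outcome-code matrix) for vectorized analysis.

    Outcome codes follow :class:`OutcomeCategory`; ``-1`` marks an
    unobserved visit. Column order follows ``schedule``.
    """
    recs = list(records)
    arms = np.fromiter((r.arm for r in recs), dtype=np.int64, count=len(recs))
    codes = np.full((len(recs), len(schedule)), -1, dtype=np.int8)
    for i, rec in enumerate(recs):
        for j, week in enumerate(schedule):
            cat = rec.visit_outcomes.get(week)
            if cat is not None:
                codes[i, j] = int(cat)
    return arms, codes


def arrays_to_records(
    arms: np.ndarray,
    codes: np.ndarray,
    schedule: tuple[int, ...] = DEFAULT_VISIT_WEEKS,
    enrollment_weeks: np.ndarray | None = None,
) -> list[PatientRecord]:
    """Inverse of :func:`records_to_arrays` with synthetic sequential ids."""
    out = []
    for i in range(len(arms)):
        visits = {
            int(week): OutcomeCategory(int(codes[i, j]))
            for j, week in enumerate(schedule)
            if codes[i, j] >= 0
        }
        out.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                arm=int(arms[i]),
                enrollment_week=float(enrollment_weeks[i]) if enrollment_weeks is not None else 0.0,
                baseline_pain=float("nan"),
                visit_outcomes=visits,
            )
        )
    return out
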