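"""Descriptive statistics for multitasked observation logs.

Time-budget estimation in a multitasked log must not double-count: if two
tasks of the same slice overlap, each observed second still contributes one
second to that slice.  All time quantities here are therefore computed as
interval unions *within a session* and summed across sessions (wall-clock
overlap between different physicians' sessions is distinct observation
time).  The denominator of an overall proportion is scheduled session time
— the total observation time — which may include seconds with no recorded
task; group- or slice-specific proportions use the slice's own task time as
denominator and the numerator is the within-session intersection of the two
slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .events import ALL, ObservationDataset, Selector, TaskRecord
from .intervals import (
    IntervalSet,
    concurrency_profile,
    intersect_length,
    normalize,
)

__all__ = [
    "EstimatorError",
    "ProportionEstimate",
    "RateEstimate",
    "time_on",
    "proportion_of_time",
    "multitask_fraction",
    "interruption_rate",
    "fraction_tasks_interrupted",
    "interruption_reason_breakdown",
    "minutes_per_hour",
    "patients_per_session",
    "slice_interval_sets",
]


class EstimatorError(ValueError):
    """Domain error: undefined estimate (e.g. zero denominator/empty slice)."""


@dataclass(frozen=True)
class ProportionEstimate:
    """A time proportion with its numerator/denominator in seconds."""

    numerator_seconds: int
    denominator_seconds: int

    @property
    def proportion(self) -> float:
        return self.numerator_seconds / self.denominator_seconds

    @property
    def as_percent(self) -> float:
        return 100.0 * self.proportion

    @property
    def minutes_per_hour(self) -> float:
        return 60.0 * self.proportion

    def __post_init__(self):
        if self.denominator_seconds <= 0:
            raise EstimatorError("proportion denominator must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """An event rate: count per hours of exposure."""

    event_count: int
    exposure_hours: float

    @property
    def rate_per_hour(self) -> float:
        return self.event_count / self.exposure_hours

    def __post_init__(self):
        if self.exposure_hours <= 0:
            raise EstimatorError("rate exposure must be positive")
        if self.event_count < 0:
            raise EstimatorError("event count must be non-negative")


# ---------------------------------------------------------------------------
# Slice intervals
# ---------------------------------------------------------------------------


def slice_interval_sets(
    dataset: ObservationDataset, selector: Selector
) -> dict[str, IntervalSet]:
    """Per-session normalized interval sets of selector-matching records.

    Offsets are integer seconds from each session's start, clipped to the
    session window.
    """
    session_map = dataset.session_map()
    pairs: dict[str, list[tuple[int, int]]] = {sid: [] for sid in session_map}
    for r in dataset.records:
        session = session_map.get(r.session_id)
        if session is None or not selector.matches(r, session):
            continue
        s0 = int((r.start - session.session_start).total_seconds())
        s1 = int((r.end - session.session_start).total_seconds())
        s0 = max(s0, 0)
        s1 = min(s1, session.duration_seconds)
        if s1 > s0:
            pairs[r.session_id].append((s0, s1))
    return {sid: normalize(p) for sid, p in pairs.items()}


def time_on(dataset: ObservationDataset, selector: Selector) -> int:
    """Seconds spent on the slice, each second counted at most once.

    Union semantics within each session ("accounting for any multitasking"),
    summed over sessions.
    """
    return sum(s.total_length for s in slice_interval_sets(dataset, selector).values())


def proportion_of_time(
    dataset: ObservationDataset,
    numerator_selector: Selector,
    denominator_selector: Optional[Selector] = None,
) -> ProportionEstimate:
    """Proportion of time on the numerator slice.

    With no denominator selector the denominator is the total observation
    time (scheduled session time).  With a denominator slice, the
    denominator is that slice's own task time and the numerator is the
    within-session intersection of numerator and denominator slices —
    group-specific denominators.
    """
    if denominator_selector is None or denominator_selector == ALL:
        den = dataset.total_observation_seconds
        if den <= 0:
            raise EstimatorError("total observation time is zero")
        num = time_on(dataset, numerator_selector)
        return ProportionEstimate(num, den)
    num_sets = slice_interval_sets(dataset, numerator_selector)
    den_sets = slice_interval_sets(dataset, denominator_selector)
    den = sum(s.total_length for s in den_sets.values())
    if den <= 0:
        raise EstimatorError("denominator slice has zero time")
    num = sum(
        intersect_length(num_sets[sid], den_sets[sid]) for sid in den_sets
    )
    return ProportionEstimate(num, den)


def _session_profiles(dataset: ObservationDataset):
    session_map = dataset.session_map()
    by_session = dataset.records_by_session()
    for sid, records in by_session.items():
        session = session_map[sid]
        triples = []
        for r in records:
            s0 = max(int((r.start - session.session_start).total_seconds()), 0)
            s1 = min(
                int((r.end - session.session_start).total_seconds()),
                session.duration_seconds,
            )
            if s1 > s0:
                triples.append((r.record_id, s0, s1))
        yield sid, concurrency_profile(triples)


def multitask_fraction(
    dataset: ObservationDataset, selector: Selector
) -> ProportionEstimate:
    """Fraction of the slice's task time during which ≥ 2 tasks were active.

    The numerator counts seconds that lie inside the slice's intervals and
    during which the session's overall concurrency (any tasks, matching or
    not) is at least two; the denominator is the slice's task time.
    """
    sel_sets = slice_interval_sets(dataset, selector)
    den = sum(s.total_length for s in sel_sets.values())
    if den <= 0:
        raise EstimatorError("selector matches zero task time")
    num = 0
    for sid, profile in _session_profiles(dataset):
        multi = profile.multitask_set()
        if len(multi) and len(sel_sets[sid]):
            num += intersect_length(multi, sel_sets[sid])
    return ProportionEstimate(num, den)


def interruption_rate(
    dataset: ObservationDataset, exposure_selector: Optional[Selector] = None
) -> RateEstimate:
    """Interruptions per hour, overall or during a slice's task time.

    Overall: count of all interruption records over total observation time.
    Slice-specific: interruptions whose start second falls while a
    selector-matching task (other than the interruption itself) is active,
    over the slice's task time.
    """
    interruptions = [r for r in dataset.records if r.is_interruption]
    if exposure_selector is None or exposure_selector == ALL:
        hours = dataset.total_observation_hours
        if hours <= 0:
            raise EstimatorError("total observation time is zero")
        return RateEstimate(len(interruptions), hours)
    sel_sets = slice_interval_sets(dataset, exposure_selector)
    exposure_seconds = sum(s.total_length for s in sel_sets.values())
    if exposure_seconds <= 0:
        raise EstimatorError("exposure slice has zero time")
    session_map = dataset.session_map()
    count = 0
    for r in interruptions:
        session = session_map.get(r.session_id)
        if session is None:
            continue
        t = int((r.start - session.session_start).total_seconds())
        sel = sel_sets[r.session_id]
        # membership test: does any selector interval contain second t?
        # exclude the interruption's own interval when it matches the selector
        if _contains_second(sel, t, dataset, r, exposure_selector, session):
            count += 1
    return RateEstimate(count, exposure_seconds / 3600.0)


def _contains_second(sel_set, t, dataset, interruption, selector, session) -> bool:
    data = sel_set.data
    if data.size == 0:
        return False
    idx = int(np.searchsorted(data[:, 0], t, side="right")) - 1
    if idx < 0 or t >= data[idx, 1]:
        return False
    if not selector.matches(interruption, session):
        return True
    # the interruption itself matches the slice: require another matching
    # record active at t
    for other in dataset.records:
        if other.record_id == interruption.record_id or other.session_id != interruption.session_id:
            continue
        if not selector.matches(other, session):
            continue
        o0 = int((other.start - session.session_start).total_seconds())
        o1 = int((other.end - session.session_start).total_seconds())
        if o0 <= t < o1:
            return True
    return False


def fraction_tasks_interrupted(
    dataset: ObservationDataset, selector: Selector
) -> ProportionEstimate:
    """Share of matching task *instances* hit by at least one interruption.

    Instance-based, not time-based: a task interrupted three times counts
    once in the numerator.
    """
    session_map = dataset.session_map()
    matching = [
        r
        for r in dataset.records
        if r.session_id in session_map and selector.matches(r, session_map[r.session_id])
    ]
    if not matching:
        raise EstimatorError("selector matches no task instance")
    interrupted_ids = {
        r.interrupts_record_id for r in dataset.records if r.is_interruption
    }
    num = sum(1 for r in matching if r.record_id in interrupted_ids)
    return ProportionEstimate(num, len(matching))


def interruption_reason_breakdown(
    dataset: ObservationDataset, target_selector: Selector
) -> dict[str, float]:
    """Distribution of interrupting-task categories over a target slice.

    For interruptions whose *target* matches ``target_selector``, tally the
    interrupting record's what-category; fractions sum to 1.
    """
    session_map = dataset.session_map()
    record_map = dataset.record_map()
    tally: dict[str, int] = {}
    total = 0
    for r in dataset.records:
        if not r.is_interruption:
            continue
        target = record_map.get(r.interrupts_record_id or "")
        if target is None:
            continue
        session = session_map.get(target.session_id)
        if session is None or not target_selector.matches(target, session):
            continue
        tally[r.what] = tally.get(r.what, 0) + 1
        total += 1
    if total == 0:
        raise EstimatorError("no interruption targets the slice")
    return {what: n / total for what, n in sorted(tally.items())}


def minutes_per_hour(proportion: float) -> float:
    """Convert a time proportion to minutes per observed hour."""
    if not 0.0 <= proportion <= 1.0:
        raise EstimatorError(f"proportion {proportion} outside [0, 1]")
    return proportion * 60.0


def patients_per_session(
    dataset: ObservationDataset,
) -> tuple[float, float, float]:
    """Session-level mean patients: (total, new, follow-up).

    The total mean is exactly the sum of the new and follow-up means.
    """
    if not dataset.sessions:
        raise EstimatorError("no sessions")
    n = len(dataset.sessions)
    mean_new = sum(s.n_new_patients for s in dataset.sessions) / n
    mean_fu = sum(s.n_followup_patients for s in dataset.sessions) / n
    return (mean_new + mean_fu, mean_new, mean_fu)
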