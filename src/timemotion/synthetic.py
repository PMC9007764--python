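"""Synthetic observation-session generator with known ground truth.

Emulates continuous two-hour direct-observation sessions of emergency
department physicians: sequential task intervals drawn from a configurable
per-category time budget, multitasking as overlapping task starts,
interruptions as linked task records arriving at a Poisson rate, new /
follow-up patient counts, and paired observer logs with boundary jitter,
label confusion and missed tasks for inter-rater reliability testing.

Generation model
----------------
Tasks are sampled sequentially.  A category is drawn with probability
proportional to budget/mean-duration (so expected *time* share is
proportional to the budget), its duration is exponential with the category
mean, truncated at session end.  With probability ``multitask_probability``
the next task starts before the current one ends, the overlap uniform over
the current task's duration; otherwise an exponential idle gap follows,
whose mean is solved so that each category's expected share of *session*
time equals its configured budget.  Budgets may sum to more than 1 when
multitasking is frequent enough; an infeasible combination raises
:class:`GeneratorConfigError`.

Interruption events are a homogeneous Poisson count at the configured rate
per session hour, with event times placed uniformly over task-covered
seconds so every interruption has a resolvable target task; each becomes a
linked ``TaskRecord`` whose category follows a configurable interrupter
distribution.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np

from .events import (
    DRUG_SPLIT_CATEGORIES,
    NONE_LABEL,
    ObservationDataset,
    Selector,
    SessionRecord,
    TaskRecord,
    WHAT_CATEGORIES,
)
from .estimators import time_on
from .intervals import normalize

__all__ = [
    "GeneratorConfigError",
    "GeneratorConfig",
    "ObserverErrorModel",
    "generate_dataset",
    "generate_observer_pair",
    "study_config",
    "parse_budget_key",
    "budget_selector",
]


class GeneratorConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


def parse_budget_key(key: str) -> tuple[str, str]:
    """Split a budget key 'What|subcategory' into (what, subcategory)."""
    if "|" in key:
        what, sub = key.split("|", 1)
    else:
        what, sub = key, NONE_LABEL
    if what not in WHAT_CATEGORIES:
        raise GeneratorConfigError(f"unknown what category in budget key {key!r}")
    return what, sub


def budget_selector(key: str) -> Selector:
    """Selector matching the records generated under one budget key."""
    what, sub = parse_budget_key(key)
    return Selector.make(what=what, subcategory=sub)


# who/how label mixtures per category: (who, how, weight)
_DEFAULT_LABEL_MODEL: dict[str, list[tuple[str, str, float]]] = {
    "Professional communication": [
        ("Patient", "Direct", 2.0),
        ("Next of kin", "Direct", 0.4),
        ("Another physician", "Direct", 4.0),
        ("Another physician", "Telephone", 1.5),
        ("Nurse", "Direct", 2.5),
        ("Other hospital", "Telephone", 0.2),
        ("Others", "Direct", 0.4),
    ],
    "Gather information": [
        ("Patient", "Direct", 4.0),
        ("Next of kin", "Direct", 0.4),
        (NONE_LABEL, "On paper", 1.5),
        (NONE_LABEL, "On computer", 6.0),
        (NONE_LABEL, "On smartphone", 0.3),
        (NONE_LABEL, "With Prescription Intermediary", 0.3),
    ],
    "Documentation": [
        (NONE_LABEL, "On paper", 1.5),
        (NONE_LABEL, "On computer", 4.0),
        (NONE_LABEL, "With dictaphone", 0.4),
    ],
    "Examination/Treatment": [("Patient", "Direct", 1.0)],
    "Social": [(NONE_LABEL, NONE_LABEL, 1.0)],
    "Unknown": [("Unknown", NONE_LABEL, 1.0)],
    "Hygiene": [(NONE_LABEL, NONE_LABEL, 1.0)],
    "Movement": [(NONE_LABEL, NONE_LABEL, 1.0)],
    "Outside ED": [(NONE_LABEL, NONE_LABEL, 1.0)],
}

_DEFAULT_WHERE = (
    ("Patient room", 0.40),
    ("Physician work station", 0.35),
    ("Corridor", 0.15),
    ("Triage area", 0.05),
    ("Other", 0.05),
)


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic observation data.

    ``category_budget`` maps 'What|subcategory' keys to target fractions of
    *session* time; ``mean_task_duration_s`` is a scalar or a per-key
    mapping.  The affiliation composition follows the 3:1 medical:surgical
    design and experience is balanced 1:1.
    """

    n_physicians: int = 31
    sessions_per_physician: int = 1
    session_hours: float = 2.0
    affiliation_ratio: tuple[int, int] = (3, 1)
    category_budget: dict[str, float] = field(
        default_factory=lambda: {
            "Examination/Treatment": 0.06,
            "Gather information|non-drug-related": 0.29,
            "Gather information|drug-related": 0.07,
            "Documentation|non-drug-related": 0.18,
            "Documentation|drug-related": 0.07,
            "Professional communication|non-drug-related": 0.20,
            "Professional communication|drug-related": 0.06,
            "Social|professional": 0.03,
            "Social|non-professional": 0.03,
        }
    )
    mean_task_duration_s: float | dict[str, float] = 60.0
    multitask_probability: float = 0.15
    interruption_rate_per_hour: float = 4.0
    interruption_mean_duration_s: float = 20.0
    interrupter_distribution: dict[str, float] = field(
        default_factory=lambda: {
            "Professional communication|non-drug-related": 0.70,
            "Examination/Treatment": 0.15,
            "Social|non-professional": 0.15,
        }
    )
    patient_rate: tuple[float, float] = (2.0, 0.7)  # mean new, follow-up per session
    where_vocabulary: Sequence[tuple[str, float]] = _DEFAULT_WHERE
    label_model: Optional[dict[str, list[tuple[str, str, float]]]] = None
    base_start: datetime = datetime(2018, 10, 16, 9, 0, 0)
    seed: int = 0

    def mean_duration(self, key: str) -> float:
        if isinstance(self.mean_task_duration_s, Mapping):
            return float(
                self.mean_task_duration_s.get(
                    key,
                    self.mean_task_duration_s.get("default", 60.0),
                )
            )
        return float(self.mean_task_duration_s)


@dataclass
class ObserverErrorModel:
    """Recording-error model for the second observer of a paired log."""

    boundary_jitter_sd_s: float = 2.0
    label_confusion_prob: float | dict[str, float] = 0.05
    miss_prob: float = 0.02

    def confusion(self, dim: str) -> float:
        if isinstance(self.label_confusion_prob, Mapping):
            return float(self.label_confusion_prob.get(dim, 0.0))
        return float(self.label_confusion_prob)


def study_config(seed: int = 0) -> GeneratorConfig:
    """Study-emulation preset: budgets set to the published time-budget table.

    A demonstration preset reproducing the study's headline conditions
    (category time shares, 4.0 interruptions/hour, 2.0 new + 0.7 follow-up
    patients per session, ~92 observation hours); not a basis for
    reproducing published confidence-interval bounds.
    """
    budgets = {
        "Examination/Treatment": 0.056,
        "Professional communication|non-drug-related": 0.203,
        "Gather information|non-drug-related": 0.294,
        "Documentation|non-drug-related": 0.177,
        "Unknown": 0.008,
        "Social|professional": 0.034,
        "Social|non-professional": 0.033,
        "Hygiene": 0.010,
        "Movement": 0.059,
        "Outside ED": 0.027,
        "Professional communication|drug-related": 0.059,
        "Gather information|drug-related": 0.070,
        "Documentation|drug-related": 0.066,
    }
    means = {
        "Examination/Treatment": 74.0,
        "Professional communication|non-drug-related": 40.0,
        "Gather information|non-drug-related": 58.0,
        "Documentation|non-drug-related": 107.0,
        "Unknown": 229.0,
        "Social|professional": 43.0,
        "Social|non-professional": 43.0,
        "Hygiene": 18.0,
        "Movement": 21.0,
        "Outside ED": 132.0,
        "Professional communication|drug-related": 39.0,
        "Gather information|drug-related": 48.0,
        "Documentation|drug-related": 58.0,
    }
    return GeneratorConfig(
        n_physicians=23,
        sessions_per_physician=2,
        category_budget=budgets,
        mean_task_duration_s=means,
        multitask_probability=0.22,
        interruption_rate_per_hour=4.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _gap_mean(
    budget_sum: float, mean_step_s: float, p_multi: float, session_seconds: float
) -> float:
    """Mean idle gap so category session-time shares hit their budgets.

    Expected wall-clock advance per task is S·(1 − p/2) from the task chain
    (overlap uniform over the task) plus (1 − p)·g idle; solving
    S / advance = ΣB for g.  The task in flight when the session ends is
    truncated, losing on average about one busy-fraction-weighted task
    residual per session; the target is inflated accordingly so *realized*
    budgets are unbiased for the configured ones.
    """
    if budget_sum <= 0:
        raise GeneratorConfigError("budget sum must be positive")
    chain_factor = 1.0 - p_multi / 2.0
    busy_fraction = min(budget_sum * chain_factor, 1.0)
    truncation_share = busy_fraction * mean_step_s / max(session_seconds, 1.0)
    effective_budget = budget_sum / max(1.0 - truncation_share / max(budget_sum, 1e-9), 1e-9)
    target_advance = mean_step_s / effective_budget
    chain_advance = mean_step_s * chain_factor
    if p_multi >= 1.0:
        if budget_sum > 2.0 + 1e-9:
            raise GeneratorConfigError("budgets infeasible even with full multitasking")
        return 0.0
    g = (target_advance - chain_advance) / (1.0 - p_multi)
    if g < -1e-9:
        raise GeneratorConfigError(
            f"budgets sum to {budget_sum:.3f}, infeasible at "
            f"multitask_probability={p_multi}: would need negative idle time"
        )
    return max(g, 0.0)


def _draw_labels(rng, key: str, config: GeneratorConfig) -> tuple[str, str, str]:
    what, _ = parse_budget_key(key)
    model = (config.label_model or {}).get(key) or (config.label_model or {}).get(
        what
    ) or _DEFAULT_LABEL_MODEL[what]
    weights = np.asarray([w for _, _, w in model], dtype=float)
    i = int(rng.choice(len(model), p=weights / weights.sum()))
    who, how, _ = model[i]
    wlabels = [w for w, _ in config.where_vocabulary]
    wweights = np.asarray([p for _, p in config.where_vocabulary], dtype=float)
    where = str(rng.choice(wlabels, p=wweights / wweights.sum()))
    return where, how, who


def _generate_session_tasks(
    rng: np.random.Generator,
    config: GeneratorConfig,
    session: SessionRecord,
    id_prefix: str,
) -> list[TaskRecord]:
    T = session.duration_seconds
    keys = sorted(config.category_budget)
    budgets = np.asarray([config.category_budget[k] for k in keys], dtype=float)
    if np.any(budgets < 0):
        raise GeneratorConfigError("budgets must be non-negative")
    keep = budgets > 0
    keys = [k for k, m in zip(keys, keep) if m]
    budgets = budgets[keep]
    records: list[TaskRecord] = []
    if not keys:
        return records
    means = np.asarray([config.mean_duration(k) for k in keys], dtype=float)
    if np.any(means <= 0):
        raise GeneratorConfigError("mean task durations must be positive")
    weights = budgets / means
    weights = weights / weights.sum()
    mean_step = float(np.sum(weights * means))
    gap_mean = _gap_mean(
        float(budgets.sum()), mean_step, config.multitask_probability, float(T)
    )

    t = 0.0
    n = 0
    while t < T:
        i = int(rng.choice(len(keys), p=weights))
        d = rng.exponential(means[i])
        # floor both endpoints: the next sequential task starts at
        # int(t + d + gap) >= int(t + d), so rounding can never create
        # spurious 1 s overlaps between sequential tasks
        start = int(t)
        end = min(int(t + d), T)
        if end > start:
            what, sub = parse_budget_key(keys[i])
            where, how, who = _draw_labels(rng, keys[i], config)
            n += 1
            records.append(
                TaskRecord(
                    record_id=f"{id_prefix}T{n:04d}",
                    session_id=session.session_id,
                    what=what,
                    subcategory=sub,
                    where_label=where,
                    how_label=how,
                    who_label=who,
                    start=session.session_start + timedelta(seconds=start),
                    end=session.session_start + timedelta(seconds=end),
                )
            )
        if rng.random() < config.multitask_probability:
            t = t + rng.uniform(0.0, 1.0) * d
        else:
            t = t + d + (rng.exponential(gap_mean) if gap_mean > 0 else 0.0)
        t = max(t, start + 1.0)  # guarantee progress at 1 s resolution
    return records


def _place_interruptions(
    rng: np.random.Generator,
    config: GeneratorConfig,
    session: SessionRecord,
    tasks: list[TaskRecord],
    id_prefix: str,
) -> list[TaskRecord]:
    lam = config.interruption_rate_per_hour * (session.duration_seconds / 3600.0)
    if lam <= 0 or not tasks:
        return []
    n_events = int(rng.poisson(lam))
    if n_events == 0:
        return []
    offsets = [
        (
            int((r.start - session.session_start).total_seconds()),
            int((r.end - session.session_start).total_seconds()),
        )
        for r in tasks
    ]
    covered = normalize(offsets)
    total = covered.total_length
    if total == 0:
        return []
    # uniform second over the covered set via cumulative lengths
    lengths = covered.data[:, 1] - covered.data[:, 0]
    cum = np.cumsum(lengths)
    ikeys = sorted(config.interrupter_distribution)
    iprobs = np.asarray([config.interrupter_distribution[k] for k in ikeys], dtype=float)
    iprobs = iprobs / iprobs.sum()
    out: list[TaskRecord] = []
    for j in range(n_events):
        u = int(rng.integers(0, total))
        seg = int(np.searchsorted(cum, u, side="right"))
        t = int(covered.data[seg, 0] + (u - (cum[seg - 1] if seg else 0)))
        active = [r for r, (a, b) in zip(tasks, offsets) if a <= t < b]
        target = active[int(rng.integers(0, len(active)))]
        key = ikeys[int(rng.choice(len(ikeys), p=iprobs))]
        what, sub = parse_budget_key(key)
        where, how, who = _draw_labels(rng, key, config)
        d = max(1, int(round(rng.exponential(config.interruption_mean_duration_s))))
        end = min(t + d, session.duration_seconds)
        if end <= t:
            continue
        out.append(
            TaskRecord(
                record_id=f"{id_prefix}I{j + 1:03d}",
                session_id=session.session_id,
                what=what,
                subcategory=sub,
                where_label=where,
                how_label=how,
                who_label=who,
                start=session.session_start + timedelta(seconds=t),
                end=session.session_start + timedelta(seconds=end),
                is_interruption=True,
                interrupts_record_id=target.record_id,
            )
        )
    return out


def _group_assignment(rng: np.random.Generator, config: GeneratorConfig):
    n = config.n_physicians
    m_ratio, s_ratio = config.affiliation_ratio
    n_surgical = max(1, round(n * s_ratio / (m_ratio + s_ratio))) if s_ratio else 0
    if n >= 4 and n_surgical:
        n_surgical = max(2, n_surgical)  # keep both groups testable
    affiliations = ["Medical"] * (n - n_surgical) + ["Surgical"] * n_surgical
    rng.shuffle(affiliations)
    n_exp = n // 2
    experience = ["experienced"] * n_exp + ["inexperienced"] * (n - n_exp)
    rng.shuffle(experience)
    return affiliations, experience


def generate_dataset(config: GeneratorConfig) -> ObservationDataset:
    """Generate a full observation dataset; deterministic given the seed.

    The realised per-key time budgets are recorded in
    ``dataset.meta["realized_budgets"]`` as fractions of total observation
    time.
    """
    if config.sessions_per_physician not in (1, 2):
        raise GeneratorConfigError("sessions_per_physician must be 1 or 2")
    if not 0.0 <= config.multitask_probability <= 1.0:
        raise GeneratorConfigError("multitask_probability must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    affiliations, experience = _group_assignment(rng, config)
    sessions: list[SessionRecord] = []
    records: list[TaskRecord] = []
    day = 0
    for i in range(config.n_physicians):
        pid = f"P{i + 1:03d}"
        for j in range(config.sessions_per_physician):
            sid = f"{pid}S{j + 1}"
            start = config.base_start + timedelta(days=day)
            day += 1
            session = SessionRecord(
                session_id=sid,
                physician_id=pid,
                affiliation=affiliations[i],
                experience=experience[i],
                session_start=start,
                session_end=start + timedelta(seconds=int(config.session_hours * 3600)),
                n_new_patients=int(rng.poisson(config.patient_rate[0])),
                n_followup_patients=int(rng.poisson(config.patient_rate[1])),
            )
            sessions.append(session)
            tasks = _generate_session_tasks(rng, config, session, f"{sid}-")
            inter = _place_interruptions(rng, config, session, tasks, f"{sid}-")
            records.extend(tasks)
            records.extend(inter)
    dataset = ObservationDataset(sessions=sessions, records=records)
    total = dataset.total_observation_seconds
    realized = {}
    if total > 0:
        for key in sorted(config.category_budget):
            realized[key] = time_on(dataset, budget_selector(key)) / total
    dataset.meta["realized_budgets"] = realized
    dataset.meta["n_interruptions"] = sum(1 for r in records if r.is_interruption)
    dataset.meta["seed"] = config.seed
    return dataset


# ---------------------------------------------------------------------------
# Paired observer logs
# ---------------------------------------------------------------------------


def _confuse(rng, label: str, vocabulary: Sequence[str]) -> str:
    pool = [v for v in vocabulary if v != label]
    if not pool:
        return label
    return pool[int(rng.integers(0, len(pool)))]


def generate_observer_pair(
    dataset: ObservationDataset,
    error_model: ObserverErrorModel,
    seed: int = 0,
) -> tuple[ObservationDataset, ObservationDataset]:
    """Paired observer logs: (A = input, B = error-perturbed copy).

    Observer B's copy has task boundaries jittered by rounded Gaussian
    noise, labels confused per dimension with the configured probabilities,
    and tasks dropped with ``miss_prob`` (interruptions of dropped tasks are
    dropped too).  Interruption starts are re-clamped into their target's
    interval so the perturbed log remains structurally valid.
    """
    rng = np.random.default_rng(seed)
    session_map = dataset.session_map()
    vocab = {
        "what": sorted({r.what for r in dataset.records} | set(WHAT_CATEGORIES)),
        "where": sorted({r.where_label for r in dataset.records}),
        "how": sorted({r.how_label for r in dataset.records}),
        "who": sorted({r.who_label for r in dataset.records}),
    }
    dropped: set[str] = set()
    out: list[TaskRecord] = []
    # first pass: non-interruptions
    base_order = [r for r in dataset.records if not r.is_interruption] + [
        r for r in dataset.records if r.is_interruption
    ]
    perturbed: dict[str, TaskRecord] = {}
    for r in base_order:
        if r.is_interruption and r.interrupts_record_id in dropped:
            dropped.add(r.record_id)
            continue
        if rng.random() < error_model.miss_prob:
            dropped.add(r.record_id)
            continue
        session = session_map[r.session_id]
        s0 = int((r.start - session.session_start).total_seconds())
        s1 = int((r.end - session.session_start).total_seconds())
        if error_model.boundary_jitter_sd_s > 0:
            s0 += int(round(rng.normal(0.0, error_model.boundary_jitter_sd_s)))
            s1 += int(round(rng.normal(0.0, error_model.boundary_jitter_sd_s)))
        s0 = min(max(s0, 0), session.duration_seconds - 1)
        s1 = min(max(s1, s0 + 1), session.duration_seconds)
        what, sub = r.what, r.subcategory
        if rng.random() < error_model.confusion("what"):
            what = _confuse(rng, what, vocab["what"])
            if what in DRUG_SPLIT_CATEGORIES:
                if sub not in ("drug-related", "non-drug-related"):
                    sub = ("drug-related", "non-drug-related")[int(rng.integers(0, 2))]
            elif what == "Social":
                sub = ("professional", "non-professional")[int(rng.integers(0, 2))]
            else:
                sub = NONE_LABEL
        where = r.where_label
        if rng.random() < error_model.confusion("where"):
            where = _confuse(rng, where, vocab["where"])
        how = r.how_label
        if rng.random() < error_model.confusion("how"):
            how = _confuse(rng, how, vocab["how"])
        who = r.who_label
        if rng.random() < error_model.confusion("who"):
            who = _confuse(rng, who, vocab["who"])
        perturbed[r.record_id] = replace(
            r,
            what=what,
            subcategory=sub,
            where_label=where,
            how_label=how,
            who_label=who,
            start=session.session_start + timedelta(seconds=s0),
            end=session.session_start + timedelta(seconds=s1),
        )
    # second pass: repair interruption containment after jitter
    for rid, r in perturbed.items():
        if not r.is_interruption:
            continue
        target = perturbed.get(r.interrupts_record_id or "")
        if target is None:
            perturbed[rid] = replace(r, is_interruption=False, interrupts_record_id=None)
            continue
        if not (target.start <= r.start < target.end):
            session = session_map[r.session_id]
            new_start = min(max(r.start, target.start), target.end - timedelta(seconds=1))
            new_end = max(r.end, new_start + timedelta(seconds=1))
            if new_end > session.session_end:
                new_end = session.session_end
                new_start = min(new_start, new_end - timedelta(seconds=1))
            perturbed[rid] = replace(r, start=new_start, end=new_end)
    order = {r.record_id: i for i, r in enumerate(dataset.records)}
    out = sorted(perturbed.values(), key=lambda r: order[r.record_id])
    observer_b = ObservationDataset(
        sessions=copy.deepcopy(dataset.sessions), records=out
    )
    return dataset, observer_b
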