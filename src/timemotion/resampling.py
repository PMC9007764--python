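"""Nonparametric inference for observation-log statistics.

Sessions of the same physician are not independent, so the resampling unit
("cluster") is the physician by default: the cluster bootstrap resamples
physicians with replacement — carrying all their sessions and records — and
forms percentile confidence intervals; the Monte Carlo group test permutes
physicians' group labels (affiliation or experience), preserving the
empirical group sizes, and recomputes the difference in group-specific
proportions.

Any callable ``statistic_fn(dataset) -> float`` works.  Statistics whose
value is a ratio of sums over clusters (time proportions, event rates,
session means — which covers everything the pipeline reports) additionally
implement the :class:`ClusterSummable` protocol; resampling then reduces to
summing per-cluster sufficient statistics, which makes thousands of
replicates cheap without changing any value: for these statistics the
combined value over concatenated clusters is identical to recomputing on
the rebuilt dataset because within-session interval unions are unaffected
by which clusters surround them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .events import ALL, ObservationDataset, Selector
from .estimators import (
    EstimatorError,
    interruption_rate,
    proportion_of_time,
    slice_interval_sets,
    time_on,
)
from .intervals import intersect_length

__all__ = [
    "ResamplingError",
    "BootstrapResult",
    "MonteCarloTestResult",
    "ClusterSummable",
    "TimeProportionStatistic",
    "InterruptionRateStatistic",
    "SessionMeanStatistic",
    "bootstrap_ci",
    "monte_carlo_group_test",
    "derive_seed",
]


class ResamplingError(RuntimeError):
    """Raised when resampling cannot produce a valid result."""


def derive_seed(seed: int, *tokens: object) -> int:
    """Deterministically derive a sub-seed (< 2^31) from a global seed."""
    return zlib.crc32(repr((int(seed),) + tokens).encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@runtime_checkable
class ClusterSummable(Protocol):
    """Statistic expressible as a function of cluster-wise sums."""

    def cluster_components(self, cluster_datasets: Sequence[ObservationDataset]) -> np.ndarray:
        """Per-cluster component rows (k clusters × m components)."""

    def combine_sums(self, sums: np.ndarray) -> np.ndarray:
        """Statistic value(s) from component sums (rows → values)."""

    def __call__(self, dataset: ObservationDataset) -> float: ...


@dataclass(frozen=True)
class TimeProportionStatistic:
    """Proportion of time on a slice (optionally with a slice denominator)."""

    numerator: Selector
    denominator: Optional[Selector] = None

    def __call__(self, dataset: ObservationDataset) -> float:
        return proportion_of_time(dataset, self.numerator, self.denominator).proportion

    def cluster_components(self, cluster_datasets):
        rows = []
        for sub in cluster_datasets:
            if self.denominator is None or self.denominator == ALL:
                rows.append((time_on(sub, self.numerator), sub.total_observation_seconds))
            else:
                num_sets = slice_interval_sets(sub, self.numerator)
                den_sets = slice_interval_sets(sub, self.denominator)
                num = sum(
                    intersect_length(num_sets[sid], den_sets[sid]) for sid in den_sets
                )
                den = sum(s.total_length for s in den_sets.values())
                rows.append((num, den))
        return np.asarray(rows, dtype=np.float64)

    def combine_sums(self, sums: np.ndarray) -> np.ndarray:
        sums = np.atleast_2d(sums)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sums[:, 1] > 0, sums[:, 0] / sums[:, 1], np.nan)


@dataclass(frozen=True)
class InterruptionRateStatistic:
    """Interruptions per hour, overall or during a slice's task time."""

    exposure: Optional[Selector] = None

    def __call__(self, dataset: ObservationDataset) -> float:
        return interruption_rate(dataset, self.exposure).rate_per_hour

    def cluster_components(self, cluster_datasets):
        rows = []
        for sub in cluster_datasets:
            try:
                est = interruption_rate(sub, self.exposure)
                rows.append((est.event_count, est.exposure_hours))
            except EstimatorError:
                rows.append((0.0, 0.0))
        return np.asarray(rows, dtype=np.float64)

    def combine_sums(self, sums: np.ndarray) -> np.ndarray:
        sums = np.atleast_2d(sums)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sums[:, 1] > 0, sums[:, 0] / sums[:, 1], np.nan)


@dataclass(frozen=True)
class SessionMeanStatistic:
    """Session-level mean of a patient count: 'total', 'new' or 'followup'."""

    kind: str = "total"

    def _value(self, s) -> float:
        if self.kind == "total":
            return s.n_new_patients + s.n_followup_patients
        if self.kind == "new":
            return s.n_new_patients
        if self.kind == "followup":
            return s.n_followup_patients
        raise ValueError(f"unknown kind {self.kind!r}")

    def __call__(self, dataset: ObservationDataset) -> float:
        if not dataset.sessions:
            raise EstimatorError("no sessions")
        return sum(self._value(s) for s in dataset.sessions) / len(dataset.sessions)

    def cluster_components(self, cluster_datasets):
        return np.asarray(
            [
                (sum(self._value(s) for s in sub.sessions), len(sub.sessions))
                for sub in cluster_datasets
            ],
            dtype=np.float64,
        )

    def combine_sums(self, sums: np.ndarray) -> np.ndarray:
        sums = np.atleast_2d(sums)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sums[:, 1] > 0, sums[:, 0] / sums[:, 1], np.nan)


# ---------------------------------------------------------------------------
# Cluster handling
# ---------------------------------------------------------------------------


def split_clusters(
    dataset: ObservationDataset, cluster: str = "physician"
) -> list[tuple[str, ObservationDataset]]:
    """Split a dataset into per-cluster sub-datasets (sorted by key)."""
    if cluster == "physician":
        key_of_session = {s.session_id: s.physician_id for s in dataset.sessions}
    elif cluster == "session":
        key_of_session = {s.session_id: s.session_id for s in dataset.sessions}
    else:
        raise ValueError(f"unknown cluster unit {cluster!r}")
    sessions: dict[str, list] = {}
    for s in dataset.sessions:
        sessions.setdefault(key_of_session[s.session_id], []).append(s)
    records: dict[str, list] = {k: [] for k in sessions}
    for r in dataset.records:
        k = key_of_session.get(r.session_id)
        if k is not None:
            records[k].append(r)
    return [
        (k, ObservationDataset(sessions=sessions[k], records=records[k]))
        for k in sorted(sessions)
    ]


def _concat(subs: Sequence[ObservationDataset]) -> ObservationDataset:
    """Concatenate resampled clusters into one dataset.

    A cluster drawn more than once must contribute its sessions multiple
    times as *distinct* sessions, so identifiers are suffixed per occurrence
    ('#1', '#2', ...) — otherwise duplicated records would collapse into one
    session and the replicate would under-weight that cluster.
    """
    from dataclasses import replace as _replace

    sessions, records = [], []
    for j, sub in enumerate(subs):
        suffix = f"#{j}"
        for s in sub.sessions:
            sessions.append(
                _replace(
                    s,
                    session_id=s.session_id + suffix,
                    physician_id=s.physician_id + suffix,
                )
            )
        for r in sub.records:
            records.append(
                _replace(
                    r,
                    record_id=r.record_id + suffix,
                    session_id=r.session_id + suffix,
                    interrupts_record_id=(
                        r.interrupts_record_id + suffix
                        if r.interrupts_record_id
                        else None
                    ),
                )
            )
    return ObservationDataset(sessions=sessions, records=records)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    point_estimate: float
    ci_low: float
    ci_high: float
    level: float
    n_replicates: int
    seed: int
    replicate_values: np.ndarray = field(repr=False)
    n_dropped: int = 0


def bootstrap_ci(
    dataset: ObservationDataset,
    statistic_fn: Callable[[ObservationDataset], float],
    level: float = 0.95,
    n_replicates: int = 10_000,
    seed: int = 0,
    cluster: str = "physician",
    max_dropped_fraction: float = 0.10,
) -> BootstrapResult:
    """Cluster-bootstrap percentile confidence interval.

    Clusters (physicians by default, with all their sessions and records)
    are resampled with replacement to the original cluster count; the
    percentile interval at ``level`` is taken over replicate statistics.
    Replicates on which the statistic is undefined are dropped and counted;
    more than ``max_dropped_fraction`` dropped is an error.  Deterministic
    given ``seed``.
    """
    clusters = split_clusters(dataset, cluster)
    if len(clusters) < 2:
        raise ResamplingError("need at least two clusters to bootstrap")
    subs = [sub for _, sub in clusters]
    point = float(statistic_fn(dataset))
    rng = np.random.default_rng(seed)
    k = len(subs)

    if isinstance(statistic_fn, ClusterSummable):
        comp = statistic_fn.cluster_components(subs)  # (k, m)
        idx = rng.integers(0, k, size=(n_replicates, k))
        sums = comp[idx].sum(axis=1)  # (B, m)
        values = np.asarray(statistic_fn.combine_sums(sums), dtype=np.float64)
    else:
        vals = []
        for _ in range(n_replicates):
            pick = rng.integers(0, k, size=k)
            try:
                vals.append(float(statistic_fn(_concat([subs[i] for i in pick]))))
            except (EstimatorError, ZeroDivisionError):
                vals.append(np.nan)
        values = np.asarray(vals, dtype=np.float64)

    good = values[np.isfinite(values)]
    n_dropped = n_replicates - good.size
    if n_dropped > max_dropped_fraction * n_replicates:
        raise ResamplingError(
            f"{n_dropped}/{n_replicates} bootstrap replicates degenerate"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(good, [alpha, 1.0 - alpha])
    return BootstrapResult(
        point_estimate=point,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        n_replicates=n_replicates,
        seed=seed,
        replicate_values=good,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Monte Carlo permutation test
# ---------------------------------------------------------------------------


@dataclass
class MonteCarloTestResult:
    observed_statistic: float
    n_permutations: int
    p_value: float
    seed: int
    group_labels: tuple[str, str] = ("", "")


def monte_carlo_group_test(
    dataset: ObservationDataset,
    group_field: str,
    statistic_fn: Callable[[ObservationDataset], float],
    n_permutations: int = 9_999,
    seed: int = 0,
) -> MonteCarloTestResult:
    """Two-sided Monte Carlo permutation test of a two-group contrast.

    The observed statistic is the difference of the group-wise statistic
    values (group-specific denominators arise naturally because the
    statistic is evaluated on each group's own sessions).  Permutations
    reassign the group labels over physicians, preserving the empirical
    group sizes; the p-value uses the add-one formula
    ``(1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_permutations)``.
    """
    if group_field not in ("affiliation", "experience"):
        raise ValueError(f"unknown group field {group_field!r}")
    clusters = split_clusters(dataset, "physician")
    labels = []
    for key, sub in clusters:
        values = {getattr(s, group_field) for s in sub.sessions}
        if len(values) != 1:
            raise ResamplingError(f"physician {key} has inconsistent {group_field}")
        labels.append(values.pop())
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ResamplingError(
            f"group test needs exactly two {group_field} labels, got {uniq}"
        )
    lab_arr = np.asarray([uniq.index(l) for l in labels])
    n0 = int(np.sum(lab_arr == 0))
    n1 = int(np.sum(lab_arr == 1))
    if n0 < 2 or n1 < 2:
        raise ResamplingError("need at least two physicians per group")
    subs = [sub for _, sub in clusters]
    k = len(subs)
    rng = np.random.default_rng(seed)

    if isinstance(statistic_fn, ClusterSummable):
        comp = statistic_fn.cluster_components(subs)  # (k, m)

        def contrast(assign: np.ndarray) -> float:
            s0 = comp[assign == 0].sum(axis=0)[None, :]
            s1 = comp[assign == 1].sum(axis=0)[None, :]
            v0 = float(statistic_fn.combine_sums(s0)[0])
            v1 = float(statistic_fn.combine_sums(s1)[0])
            return v0 - v1

    else:

        def contrast(assign: np.ndarray) -> float:
            d0 = _concat([subs[i] for i in np.flatnonzero(assign == 0)])
            d1 = _concat([subs[i] for i in np.flatnonzero(assign == 1)])
            return float(statistic_fn(d0)) - float(statistic_fn(d1))

    t_obs = contrast(lab_arr)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        assign = np.ones(k, dtype=np.int64)
        assign[perm[:n0]] = 0
        if abs(contrast(assign)) >= abs(t_obs):
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MonteCarloTestResult(
        observed_statistic=t_obs,
        n_permutations=n_permutations,
        p_value=p,
        seed=seed,
        group_labels=(uniq[0], uniq[1]),
    )
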