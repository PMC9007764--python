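"""Exact set algebra on half-open integer-second time intervals.

Multitasked event logs contain overlapping task intervals; computing "time
spent on X" therefore needs union semantics (each second counted once per
slice) and multitasking statistics need a segmentation of the timeline into
stretches of constant concurrency.  Everything here is exact integer
arithmetic on half-open ``[start, end)`` pairs: adjacent intervals do not
overlap and no tolerance is ever required.

Production code uses sorted-merge / sweep-line algorithms (O(n log n)); the
per-second boolean-array oracle used to verify them lives in the test suite
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = [
    "IntervalError",
    "IntervalSet",
    "normalize",
    "union",
    "union_length",
    "intersect",
    "intersect_length",
    "ConcurrencySegment",
    "ConcurrencyProfile",
    "concurrency_profile",
]


class IntervalError(ValueError):
    """Raised for degenerate intervals (end <= start)."""


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Merge already sorted-by-start intervals, coalescing overlap/adjacency."""
    if starts.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    # running maximum of ends; a new merged block begins where start > max end so far
    run_max = np.maximum.accumulate(ends)
    new_block = np.empty(starts.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > run_max[:-1]
    idx_new = np.flatnonzero(new_block)
    last_of_block = np.append(idx_new[1:] - 1, starts.size - 1)
    out = np.empty((idx_new.size, 2), dtype=np.int64)
    out[:, 0] = starts[idx_new]
    out[:, 1] = run_max[last_of_block]  # block end = running max at its last member
    return out


@dataclass(frozen=True)
class IntervalSet:
    """Canonical sorted, disjoint, non-adjacent set of half-open intervals."""

    data: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    @staticmethod
    def from_pairs(pairs: Iterable[tuple[int, int]]) -> "IntervalSet":
        return normalize(pairs)

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return [(int(a), int(b)) for a, b in self.data]

    @property
    def total_length(self) -> int:
        if self.data.size == 0:
            return 0
        return int(np.sum(self.data[:, 1] - self.data[:, 0]))

    def __len__(self) -> int:
        return self.data.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.data.shape == other.data.shape and bool(
            np.array_equal(self.data, other.data)
        )

    def __hash__(self):  # pragma: no cover - frozen dataclass requirement
        return hash(tuple(map(tuple, self.data)))


def normalize(pairs: Iterable[tuple[int, int]]) -> IntervalSet:
    """Canonicalise raw (start, end) pairs: sort and merge overlap/adjacency.

    Total length is preserved for already-disjoint input; overlapping input
    is merged so that every covered second counts once.  Raises
    :class:`IntervalError` for any pair with ``end <= start``.
    """
    arr = np.asarray(list(pairs), dtype=np.int64)
    if arr.size == 0:
        return IntervalSet()
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise IntervalError("expected a sequence of (start, end) pairs")
    if np.any(arr[:, 1] <= arr[:, 0]):
        bad = arr[arr[:, 1] <= arr[:, 0]][0]
        raise IntervalError(f"degenerate interval ({bad[0]}, {bad[1]}): end must exceed start")
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    return IntervalSet(_merge_sorted(arr[:, 0], arr[:, 1]))


def union(*sets: IntervalSet) -> IntervalSet:
    """Union of interval sets (each second covered at most once)."""
    blocks = [s.data for s in sets if s.data.size]
    if not blocks:
        return IntervalSet()
    arr = np.concatenate(blocks, axis=0)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    return IntervalSet(_merge_sorted(arr[:, 0], arr[:, 1]))


def union_length(*sets: IntervalSet) -> int:
    """Length in seconds of the union of the given sets."""
    return union(*sets).total_length


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Intersection of two normalized interval sets (two-pointer sweep)."""
    out: list[tuple[int, int]] = []
    i = j = 0
    A, B = a.data, b.data
    while i < len(A) and j < len(B):
        lo = max(A[i, 0], B[j, 0])
        hi = min(A[i, 1], B[j, 1])
        if lo < hi:
            out.append((int(lo), int(hi)))
        if A[i, 1] <= B[j, 1]:
            i += 1
        else:
            j += 1
    if not out:
        return IntervalSet()
    return IntervalSet(np.asarray(out, dtype=np.int64))


def intersect_length(a: IntervalSet, b: IntervalSet) -> int:
    """Length of A ∩ B; symmetric and bounded by min(total lengths)."""
    return intersect(a, b).total_length


# ---------------------------------------------------------------------------
# Concurrency segmentation (multitasking)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcurrencySegment:
    start: int
    end: int
    active: frozenset

    @property
    def concurrency(self) -> int:
        return len(self.active)


@dataclass
class ConcurrencyProfile:
    """Partition of the covered timeline into constant-concurrency segments."""

    segments: list[ConcurrencySegment] = field(default_factory=list)

    def multitask_set(self, min_active: int = 2) -> IntervalSet:
        """Union of segments where at least ``min_active`` tasks run at once."""
        pairs = [(s.start, s.end) for s in self.segments if s.concurrency >= min_active]
        if not pairs:
            return IntervalSet()
        return normalize(pairs)

    def covered_set(self) -> IntervalSet:
        pairs = [(s.start, s.end) for s in self.segments]
        if not pairs:
            return IntervalSet()
        return normalize(pairs)


def concurrency_profile(
    records: Iterable[tuple[Hashable, int, int]]
) -> ConcurrencyProfile:
    """Sweep-line segmentation of possibly overlapping task intervals.

    ``records`` are (id, start, end) triples from one session.  Consecutive
    emitted segments differ in active set; stretches with no active task are
    not emitted (the profile partitions the union of the inputs).
    """
    items = list(records)
    events: list[tuple[int, int, Hashable]] = []
    for rid, start, end in items:
        if end <= start:
            raise IntervalError(f"degenerate interval ({start}, {end}) for record {rid!r}")
        events.append((int(start), 1, rid))
        events.append((int(end), 0, rid))
    if not events:
        return ConcurrencyProfile()
    # process ends before starts at equal time: half-open adjacency is not overlap
    events.sort(key=lambda e: (e[0], e[1]))
    segments: list[ConcurrencySegment] = []
    active: set = set()
    prev_t: int | None = None
    for t, kind, rid in events:
        if prev_t is not None and active and t > prev_t:
            seg = ConcurrencySegment(prev_t, t, frozenset(active))
            if segments and segments[-1].end == seg.start and segments[-1].active == seg.active:
                segments[-1] = ConcurrencySegment(segments[-1].start, seg.end, seg.active)
            else:
                segments.append(seg)
        if kind == 1:
            active.add(rid)
        else:
            active.discard(rid)
        prev_t = t
    return ConcurrencyProfile(segments)
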