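"""Shared fixtures: compact dataset builders and per-second brute-force oracles.

The oracles deliberately use naive per-second boolean arrays — the slow,
obviously-correct counterpart to the sweep-line production code.
"""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from timemotion.events import (
    ObservationDataset,
    SessionRecord,
    TaskRecord,
)

BASE = datetime(2018, 10, 16, 9, 0, 0)


def make_session(
    sid="S1",
    physician="P1",
    duration_s=7200,
    affiliation="Medical",
    experience="experienced",
    start=BASE,
    new=2,
    followup=1,
) -> SessionRecord:
    return SessionRecord(
        session_id=sid,
        physician_id=physician,
        affiliation=affiliation,
        experience=experience,
        session_start=start,
        session_end=start + timedelta(seconds=duration_s),
        n_new_patients=new,
        n_followup_patients=followup,
    )


def make_record(
    rid,
    sid="S1",
    what="Documentation",
    sub="drug-related",
    where="Physician work station",
    how="On computer",
    who="none",
    start_s=0,
    end_s=60,
    session_start=BASE,
    is_interruption=False,
    interrupts=None,
) -> TaskRecord:
    return TaskRecord(
        record_id=rid,
        session_id=sid,
        what=what,
        subcategory=sub,
        where_label=where,
        how_label=how,
        who_label=who,
        start=session_start + timedelta(seconds=start_s),
        end=session_start + timedelta(seconds=end_s),
        is_interruption=is_interruption,
        interrupts_record_id=interrupts,
    )


@pytest.fixture
def tiny_dataset() -> ObservationDataset:
    """One 2 h session: two sequential tasks, one linked interruption."""
    session = make_session()
    records = [
        make_record("R1", what="Gather information", sub="non-drug-related",
                    how="Direct", who="Patient", start_s=0, end_s=600),
        make_record("R2", what="Documentation", sub="drug-related",
                    how="On paper", start_s=600, end_s=1200),
        make_record("R3", what="Professional communication", sub="non-drug-related",
                    how="Direct", who="Nurse", start_s=700, end_s=760,
                    is_interruption=True, interrupts="R2"),
    ]
    return ObservationDataset(sessions=[session], records=records)


# ---------------------------------------------------------------------------
# Per-second brute-force oracles
# ---------------------------------------------------------------------------


def oracle_cover(pairs, horizon: int) -> np.ndarray:
    """Boolean per-second coverage array for (start, end) half-open pairs."""
    cover = np.zeros(horizon, dtype=bool)
    for a, b in pairs:
        cover[max(a, 0) : min(b, horizon)] = True
    return cover


def oracle_union_length(pairs, horizon: int) -> int:
    return int(oracle_cover(pairs, horizon).sum())


def oracle_intersect_length(pairs_a, pairs_b, horizon: int) -> int:
    return int((oracle_cover(pairs_a, horizon) & oracle_cover(pairs_b, horizon)).sum())


def oracle_concurrency(triples, horizon: int) -> np.ndarray:
    """Per-second active-task count for (id, start, end) triples."""
    count = np.zeros(horizon, dtype=int)
    for _, a, b in triples:
        count[max(a, 0) : min(b, horizon)] += 1
    return count


def oracle_window_labels(records, dims, horizon: int, session_start=BASE):
    """Per-second active label sets per dimension (window_seconds=1 oracle)."""
    from timemotion.agreement import IDLE_LABEL, _DIM_ATTR

    out = [{d: set() for d in dims} for _ in range(horizon)]
    for r in records:
        a = int((r.start - session_start).total_seconds())
        b = int((r.end - session_start).total_seconds())
        for t in range(max(a, 0), min(b, horizon)):
            for d in dims:
                out[t][d].add(getattr(r, _DIM_ATTR[d]))
    return [
        {d: frozenset(s[d]) if s[d] else frozenset({IDLE_LABEL}) for d in dims}
        for s in out
    ]


def random_pairs(rng: np.random.Generator, n: int, horizon: int):
    starts = rng.integers(0, horizon - 1, size=n)
    lengths = 1 + rng.integers(0, max(horizon // 8, 2), size=n)
    ends = np.minimum(starts + lengths, horizon)
    keep = ends > starts
    return list(zip(starts[keep].tolist(), ends[keep].tolist()))
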