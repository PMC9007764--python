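"""Inter-rater reliability on one-second observation windows.

Two observers independently record the same session; agreement is scored on
aligned fixed-width time windows (default one second).  Each window carries,
per dimension (what/where/how/who), the *set* of labels of all tasks active
during any part of the window — set-valued because of multitasking, with an
idle sentinel filling uncovered windows.

The chance-adjusted coefficient is iota, a multivariate generalisation of
Cohen's kappa: with per-window distance d(i) = Σ over dimensions of
δ(Aᵢ, Bᵢ), the observed disagreement Dₒ is the mean distance over the n
aligned windows and the expected disagreement Dₑ is the mean of the same
distance over all n² cross pairs (window i of observer A against window j
of observer B — Cohen-style per-observer marginals); the score is
1 − Dₒ/Dₑ.  The set distance δ is 1 − Jaccard similarity, which degrades to
plain 0/1 mismatch for singleton labels, so for a single dimension with
singleton labels iota is exactly Cohen's kappa.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .events import ObservationDataset, SessionRecord, TaskRecord

__all__ = [
    "IDLE_LABEL",
    "DEFAULT_DIMS",
    "AgreementError",
    "AgreementUndefinedError",
    "WindowSequence",
    "AgreementScore",
    "discretize_to_windows",
    "session_window_sequence",
    "cohens_kappa",
    "iota",
    "mean_agreement",
]

#: Sentinel label for windows with no active task in a dimension.
IDLE_LABEL = "__idle__"

#: The four observation dimensions.
DEFAULT_DIMS = ("what", "where", "how", "who")

_DIM_ATTR = {
    "what": "what",
    "subcategory": "subcategory",
    "where": "where_label",
    "how": "how_label",
    "who": "who_label",
}


class AgreementError(ValueError):
    """Invalid agreement input (misaligned sequences, unknown dimension)."""


class AgreementUndefinedError(AgreementError):
    """Chance-corrected score undefined (expected disagreement is zero)."""


@dataclass
class WindowSequence:
    """Aligned per-window multivariate label sets for one observer."""

    dims: tuple[str, ...]
    windows: list[dict[str, frozenset[str]]]
    window_seconds: int = 1

    def __len__(self) -> int:
        return len(self.windows)

    def labels(self, dim: str) -> list[frozenset[str]]:
        if dim not in self.dims:
            raise AgreementError(f"dimension {dim!r} not in sequence dims {self.dims}")
        return [w[dim] for w in self.windows]


@dataclass(frozen=True)
class AgreementScore:
    """Chance-adjusted agreement: score = 1 − observed/expected disagreement."""

    observed_disagreement: float
    expected_disagreement: float

    @property
    def score(self) -> float:
        return 1.0 - self.observed_disagreement / self.expected_disagreement


def discretize_to_windows(
    records: Sequence[TaskRecord],
    dims: Sequence[str] = DEFAULT_DIMS,
    window_seconds: int = 1,
    span: tuple[int, int] | None = None,
    origin=None,
) -> WindowSequence:
    """Label each window with the set of labels of tasks active in it.

    ``records`` come from one observer and one session.  Offsets are seconds
    from ``origin`` (default: the earliest record start).  ``span`` fixes the
    covered second range ``[lo, hi)``; windows without any active task get
    the idle sentinel in every dimension.  A task is active in a window if
    its interval intersects any part of the window.
    """
    dims = tuple(dims)
    for d in dims:
        if d not in _DIM_ATTR:
            raise AgreementError(f"unknown dimension {d!r}")
    if window_seconds < 1:
        raise AgreementError("window_seconds must be >= 1")
    if origin is None:
        if not records:
            origin_ts = None
        else:
            origin_ts = min(r.start for r in records)
    else:
        origin_ts = origin
    offsets = []
    for r in records:
        s0 = int((r.start - origin_ts).total_seconds())
        s1 = int((r.end - origin_ts).total_seconds())
        offsets.append((r, s0, s1))
    if span is None:
        if not offsets:
            raise AgreementError("empty record list needs an explicit span")
        lo = min(s0 for _, s0, _ in offsets)
        hi = max(s1 for _, _, s1 in offsets)
    else:
        lo, hi = span
    n_windows = max(0, -(-(hi - lo) // window_seconds))
    sets: list[dict[str, set[str]]] = [
        {d: set() for d in dims} for _ in range(n_windows)
    ]
    for r, s0, s1 in offsets:
        w0 = max((s0 - lo) // window_seconds, 0)
        w1 = min(-(-(s1 - lo) // window_seconds), n_windows)
        for w in range(w0, w1):
            for d in dims:
                sets[w][d].add(getattr(r, _DIM_ATTR[d]))
    windows = [
        {d: frozenset(s[d]) if s[d] else frozenset({IDLE_LABEL}) for d in dims}
        for s in sets
    ]
    return WindowSequence(dims=dims, windows=windows, window_seconds=window_seconds)


def session_window_sequence(
    dataset: ObservationDataset,
    session_id: str,
    dims: Sequence[str] = DEFAULT_DIMS,
    window_seconds: int = 1,
) -> WindowSequence:
    """Window sequence for one session, spanning the full session window."""
    session = dataset.session_map().get(session_id)
    if session is None:
        raise AgreementError(f"unknown session {session_id!r}")
    records = [r for r in dataset.records if r.session_id == session_id]
    return discretize_to_windows(
        records,
        dims=dims,
        window_seconds=window_seconds,
        span=(0, session.duration_seconds),
        origin=session.session_start,
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def _jaccard_distance(a: frozenset, b: frozenset) -> float:
    """1 − |A∩B|/|A∪B|; exactly 0/1 mismatch for singletons."""
    if a == b:
        return 0.0
    inter = len(a & b)
    if inter == 0:
        return 1.0
    return 1.0 - inter / len(a | b)


def _check_aligned(seq_a: WindowSequence, seq_b: WindowSequence, dims) -> None:
    if len(seq_a) != len(seq_b):
        raise AgreementError(
            f"sequences cover different spans: {len(seq_a)} vs {len(seq_b)} windows"
        )
    if len(seq_a) == 0:
        raise AgreementError("empty window sequences")
    for d in dims:
        if d not in seq_a.dims or d not in seq_b.dims:
            raise AgreementError(f"dimension {d!r} missing from a sequence")


def _dim_disagreements(
    labels_a: list[frozenset], labels_b: list[frozenset]
) -> tuple[float, float]:
    """(observed, expected) mean Jaccard distance for one dimension.

    Expected is over all n² cross pairs; computed via value counts of the
    distinct label sets of each observer, so cost is O(n + u_a·u_b) rather
    than O(n²).
    """
    n = len(labels_a)
    d_obs = sum(_jaccard_distance(a, b) for a, b in zip(labels_a, labels_b)) / n
    ca = Counter(labels_a)
    cb = Counter(labels_b)
    total = 0.0
    for sa, na in ca.items():
        for sb, nb in cb.items():
            dist = _jaccard_distance(sa, sb)
            if dist:
                total += na * nb * dist
    d_exp = total / (n * n)
    return d_obs, d_exp


def iota(
    seq_a: WindowSequence,
    seq_b: WindowSequence,
    dims: Sequence[str] | None = None,
) -> AgreementScore:
    """Multivariate chance-adjusted agreement over aligned windows.

    Per-window distance sums the per-dimension set distances; Dₒ averages it
    over aligned windows and Dₑ over all n² cross pairs.  Raises
    :class:`AgreementUndefinedError` when Dₑ = 0 (both observers constant
    and identical — chance correction impossible).
    """
    dims = tuple(dims) if dims is not None else seq_a.dims
    _check_aligned(seq_a, seq_b, dims)
    d_obs = 0.0
    d_exp = 0.0
    for d in dims:
        o, e = _dim_disagreements(seq_a.labels(d), seq_b.labels(d))
        d_obs += o
        d_exp += e
    if d_exp == 0.0:
        raise AgreementUndefinedError(
            "expected disagreement is zero; iota undefined"
        )
    return AgreementScore(observed_disagreement=d_obs, expected_disagreement=d_exp)


def cohens_kappa(
    seq_a: WindowSequence, seq_b: WindowSequence, dim: str
) -> AgreementScore:
    """Cohen's kappa on one dimension with singleton labels per window.

    κ = (Pₒ − Pₑ)/(1 − Pₑ) with Pₒ the fraction of agreeing windows and Pₑ
    the chance agreement from the two observers' marginal label
    distributions; identical to ``iota`` restricted to this dimension.
    """
    _check_aligned(seq_a, seq_b, (dim,))
    labels_a = seq_a.labels(dim)
    labels_b = seq_b.labels(dim)
    for lab in labels_a + labels_b:
        if len(lab) != 1:
            raise AgreementError(
                "cohens_kappa requires singleton labels; use iota for set-valued windows"
            )
    d_obs, d_exp = _dim_disagreements(labels_a, labels_b)
    if d_exp == 0.0:
        raise AgreementUndefinedError(
            "both raters constant and equal; kappa undefined"
        )
    return AgreementScore(observed_disagreement=d_obs, expected_disagreement=d_exp)


def mean_agreement(scores: Iterable[float | AgreementScore]) -> float:
    """Arithmetic mean of agreement scores."""
    values = [s.score if isinstance(s, AgreementScore) else float(s) for s in scores]
    if not values:
        raise AgreementError("mean of empty score list")
    return sum(values) / len(values)
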