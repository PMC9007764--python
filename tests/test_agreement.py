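"""Windowing, Cohen's kappa and the multivariate iota score."""

import numpy as np
import pytest

from timemotion.agreement import (
    IDLE_LABEL,
    AgreementError,
    AgreementUndefinedError,
    WindowSequence,
    cohens_kappa,
    discretize_to_windows,
    iota,
    mean_agreement,
    session_window_sequence,
)
from timemotion.events import ObservationDataset
from timemotion.synthetic import GeneratorConfig, generate_dataset

from conftest import make_record, make_session, oracle_window_labels

DIMS2 = ("what", "how")


def seq_from_labels(labels, dim="what"):
    """Singleton-label WindowSequence for one dimension."""
    return WindowSequence(
        dims=(dim,), windows=[{dim: frozenset({l})} for l in labels]
    )


def brute_force_iota(seq_a, seq_b, dims):
    """Exhaustive double-loop Dₒ/Dₑ computation (the independent oracle)."""

    def dist(wa, wb):
        total = 0.0
        for d in dims:
            a, b = wa[d], wb[d]
            total += 1.0 - len(a & b) / len(a | b)
        return total

    n = len(seq_a.windows)
    d_obs = sum(dist(a, b) for a, b in zip(seq_a.windows, seq_b.windows)) / n
    d_exp = (
        sum(dist(a, b) for a in seq_a.windows for b in seq_b.windows) / n**2
    )
    return 1.0 - d_obs / d_exp


class TestDiscretize:
    def test_single_task_fills_every_window(self):
        sess = make_session(duration_s=100)
        ds = ObservationDataset(
            sessions=[sess], records=[make_record("R1", start_s=0, end_s=100)]
        )
        seq = session_window_sequence(ds, "S1", dims=("what",))
        assert len(seq) == 100
        assert all(w["what"] == frozenset({"Documentation"}) for w in seq.windows)

    def test_overlap_gives_set_valued_windows(self):
        records = [
            make_record("R1", what="Documentation", start_s=0, end_s=10),
            make_record("R2", what="Gather information", sub="non-drug-related",
                        start_s=5, end_s=15),
        ]
        seq = discretize_to_windows(records, dims=("what",), span=(0, 20))
        assert seq.windows[7]["what"] == frozenset(
            {"Documentation", "Gather information"}
        )
        assert seq.windows[17]["what"] == frozenset({IDLE_LABEL})

    def test_wide_window_marks_partial_overlap_active(self):
        records = [make_record("R1", start_s=3, end_s=5)]
        seq = discretize_to_windows(records, dims=("what",), span=(0, 20), window_seconds=10)
        assert len(seq) == 2
        assert seq.windows[0]["what"] == frozenset({"Documentation"})
        assert seq.windows[1]["what"] == frozenset({IDLE_LABEL})

    @pytest.mark.parametrize("seed", range(3))
    def test_random_session_matches_per_second_oracle(self, seed):
        ds = generate_dataset(
            GeneratorConfig(n_physicians=1, session_hours=0.2,
                            multitask_probability=0.4, seed=seed)
        )
        sid = ds.sessions[0].session_id
        dims = ("what", "where", "how", "who")
        seq = session_window_sequence(ds, sid, dims=dims)
        horizon = ds.sessions[0].duration_seconds
        recs = [r for r in ds.records if r.session_id == sid]
        expected = oracle_window_labels(
            recs, dims, horizon, session_start=ds.sessions[0].session_start
        )
        assert seq.windows == expected


class TestKappa:
    def test_identical_sequences(self):
        a = seq_from_labels(["x", "y", "x", "z", "y"])
        b = seq_from_labels(["x", "y", "x", "z", "y"])
        assert cohens_kappa(a, b, "what").score == pytest.approx(1.0)

    def test_hand_computed_confusion_matrix(self):
        """Counts [[20,5],[10,15]] over 50 windows: Pₒ=0.7, Pₑ=0.5, κ=0.4."""
        la = ["A"] * 25 + ["B"] * 25
        lb = ["A"] * 20 + ["B"] * 5 + ["A"] * 10 + ["B"] * 15
        k = cohens_kappa(seq_from_labels(la), seq_from_labels(lb), "what")
        assert k.observed_disagreement == pytest.approx(0.3)
        assert k.expected_disagreement == pytest.approx(0.5)
        assert k.score == pytest.approx(0.4)

    def test_constant_equal_raters_undefined(self):
        a = seq_from_labels(["x"] * 10)
        with pytest.raises(AgreementUndefinedError):
            cohens_kappa(a, seq_from_labels(["x"] * 10), "what")

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(3)
        labels = ["a", "b", "c"]
        la = [labels[i] for i in rng.integers(0, 3, size=60)]
        lb = [labels[i] for i in rng.integers(0, 3, size=60)]
        a, b = seq_from_labels(la), seq_from_labels(lb)
        assert cohens_kappa(a, b, "what").score == pytest.approx(
            brute_force_iota(a, b, ("what",))
        )

    def test_set_valued_windows_rejected(self):
        a = WindowSequence(dims=("what",), windows=[{"what": frozenset({"x", "y"})}])
        with pytest.raises(AgreementError):
            cohens_kappa(a, a, "what")


class TestIota:
    def test_identical_multivariate_sequences(self):
        rng = np.random.default_rng(0)
        windows = [
            {"what": frozenset({str(rng.integers(0, 3))}),
             "how": frozenset({str(rng.integers(0, 2))})}
            for _ in range(30)
        ]
        a = WindowSequence(dims=DIMS2, windows=windows)
        b = WindowSequence(dims=DIMS2, windows=list(windows))
        assert iota(a, b, DIMS2).score == pytest.approx(1.0)

    def test_reduces_to_kappa_for_one_singleton_dimension(self):
        rng = np.random.default_rng(17)
        labels = ["a", "b", "c", "d"]
        la = [labels[i] for i in rng.integers(0, 4, size=80)]
        lb = [labels[i] for i in rng.integers(0, 4, size=80)]
        a, b = seq_from_labels(la), seq_from_labels(lb)
        assert iota(a, b, ("what",)).score == pytest.approx(
            cohens_kappa(a, b, "what").score
        )

    def test_toy_example_matches_exhaustive_double_loop(self):
        rng = np.random.default_rng(5)
        def rand_set(pool):
            k = int(rng.integers(1, 3))
            return frozenset(rng.choice(pool, size=k, replace=False).tolist())

        wa = [
            {"what": rand_set(["a", "b", "c"]), "how": rand_set(["p", "q"])}
            for _ in range(10)
        ]
        wb = [
            {"what": rand_set(["a", "b", "c"]), "how": rand_set(["p", "q"])}
            for _ in range(10)
        ]
        a = WindowSequence(dims=DIMS2, windows=wa)
        b = WindowSequence(dims=DIMS2, windows=wb)
        assert iota(a, b, DIMS2).score == pytest.approx(brute_force_iota(a, b, DIMS2))

    def test_score_at_most_one_and_one_iff_identical(self):
        a = seq_from_labels(["a", "b", "a", "c"])
        b = seq_from_labels(["a", "b", "c", "c"])
        s = iota(a, b, ("what",))
        assert s.score < 1.0
        ident = seq_from_labels(["a", "b", "a", "c"])
        assert iota(a, ident, ("what",)).score == pytest.approx(1.0)

    def test_degrading_agreement_never_increases_iota(self):
        rng = np.random.default_rng(8)
        labels = ["a", "b", "c"]
        base = [labels[i] for i in rng.integers(0, 3, size=100)]
        a = seq_from_labels(base)
        prev = iota(a, seq_from_labels(list(base)), ("what",)).score
        corrupted = list(base)
        flip_order = rng.permutation(100)
        scores = [prev]
        for n_flipped, idx in enumerate(flip_order[:40], start=1):
            corrupted[idx] = {"a": "b", "b": "c", "c": "a"}[corrupted[idx]]
            scores.append(iota(a, seq_from_labels(list(corrupted)), ("what",)).score)
        # monotone trend up to small non-monotonic steps from changing marginals
        assert scores[-1] < scores[0]
        assert all(s2 <= s1 + 0.08 for s1, s2 in zip(scores, scores[1:]))

    def test_independent_random_sequences_near_zero(self):
        rng = np.random.default_rng(21)
        labels = ["a", "b", "c", "d"]
        n = 4000
        la = [labels[i] for i in rng.integers(0, 4, size=n)]
        lb = [labels[i] for i in rng.integers(0, 4, size=n)]
        s = iota(seq_from_labels(la), seq_from_labels(lb), ("what",)).score
        assert abs(s) < 0.05

    def test_misaligned_sequences_rejected(self):
        a = seq_from_labels(["a", "b"])
        b = seq_from_labels(["a", "b", "c"])
        with pytest.raises(AgreementError):
            iota(a, b, ("what",))


class TestMeanAgreement:
    def test_published_session_scores_average(self):
        assert mean_agreement([0.781, 0.622, 0.867]) == pytest.approx(0.7567, abs=5e-5)
        assert round(mean_agreement([0.781, 0.622, 0.867]), 2) == 0.76

    def test_single_and_equal_scores(self):
        assert mean_agreement([0.5]) == 0.5
        assert mean_agreement([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_empty_raises(self):
        with pytest.raises(AgreementError):
            mean_agreement([])
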