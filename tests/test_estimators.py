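"""Descriptive estimators: union semantics, interruption stats, conversions."""

import numpy as np
import pytest

from timemotion.events import ALL, ObservationDataset, Selector
from timemotion.estimators import (
    EstimatorError,
    fraction_tasks_interrupted,
    interruption_rate,
    interruption_reason_breakdown,
    minutes_per_hour,
    multitask_fraction,
    patients_per_session,
    proportion_of_time,
    time_on,
)
from timemotion.synthetic import GeneratorConfig, generate_dataset

from conftest import make_record, make_session, oracle_concurrency, oracle_cover

DRUG = Selector.make(subcategory="drug-related")


def single_session(records, duration_s=3600):
    return ObservationDataset(sessions=[make_session(duration_s=duration_s)], records=records)


class TestTimeOn:
    def test_nothing_matches(self, tiny_dataset):
        assert time_on(tiny_dataset, Selector.make(what="Hygiene")) == 0

    def test_single_task(self):
        ds = single_session([make_record("R1", start_s=0, end_s=600)])
        assert time_on(ds, DRUG) == 600

    def test_overlapping_matching_tasks_counted_once(self):
        ds = single_session(
            [
                make_record("R1", start_s=0, end_s=600),
                make_record("R2", start_s=300, end_s=900),
            ]
        )
        assert time_on(ds, DRUG) == 900  # not 1200

    def test_cross_session_times_add(self):
        s1 = make_session(sid="S1", physician="P1")
        s2 = make_session(sid="S2", physician="P2")  # same wall-clock window
        ds = ObservationDataset(
            sessions=[s1, s2],
            records=[
                make_record("R1", sid="S1", start_s=0, end_s=600),
                make_record("R2", sid="S2", start_s=0, end_s=600),
            ],
        )
        # identical wall-clock seconds in different sessions are distinct time
        assert time_on(ds, DRUG) == 1200


class TestProportion:
    def test_half_session(self):
        ds = single_session([make_record("R1", start_s=0, end_s=1800)])
        est = proportion_of_time(ds, DRUG)
        assert est.proportion == pytest.approx(0.5)
        assert est.as_percent == pytest.approx(50.0)

    def test_identity_with_slice_denominator(self):
        ds = single_session([make_record("R1", start_s=0, end_s=1800)])
        est = proportion_of_time(ds, DRUG, DRUG)
        assert est.proportion == 1.0

    def test_slice_denominator_uses_intersection(self):
        # numerator task overlaps the denominator slice for 300 of 600 s
        ds = single_session(
            [
                make_record("R1", what="Documentation", sub="drug-related",
                            start_s=0, end_s=600),
                make_record("R2", what="Gather information", sub="drug-related",
                            how="Direct", who="Patient", start_s=300, end_s=900),
            ]
        )
        num = Selector.make(what="Gather information")
        den = Selector.make(what="Documentation")
        est = proportion_of_time(ds, num, den)
        assert est.numerator_seconds == 300
        assert est.denominator_seconds == 600

    def test_zero_denominator_raises(self):
        ds = single_session([make_record("R1")])
        with pytest.raises(EstimatorError):
            proportion_of_time(ds, DRUG, Selector.make(what="Hygiene"))

    def test_category_slices_sum_exceeds_one_by_overlap(self):
        """Σ category proportions = union + cross-category multitask overlap."""
        ds = generate_dataset(
            GeneratorConfig(n_physicians=4, session_hours=1.0,
                            multitask_probability=0.4, seed=9)
        )
        whats = sorted({r.what for r in ds.records})
        total = ds.total_observation_seconds
        sum_slices = sum(
            proportion_of_time(ds, Selector.make(what=w)).proportion for w in whats
        )
        union_all = proportion_of_time(ds, ALL).proportion
        # per-second oracle: seconds counted in k categories contribute k times
        smap = ds.session_map()
        per_second_sum = 0
        for sid, sess in smap.items():
            recs = [r for r in ds.records if r.session_id == sid]
            for w in whats:
                pairs = [
                    (
                        int((r.start - sess.session_start).total_seconds()),
                        int((r.end - sess.session_start).total_seconds()),
                    )
                    for r in recs
                    if r.what == w
                ]
                per_second_sum += int(oracle_cover(pairs, sess.duration_seconds).sum())
        assert sum_slices == pytest.approx(per_second_sum / total)
        assert sum_slices >= union_all


class TestMultitaskFraction:
    def test_no_overlap_is_zero(self):
        ds = single_session(
            [
                make_record("R1", start_s=0, end_s=100),
                make_record("R2", start_s=100, end_s=200),
            ]
        )
        assert multitask_fraction(ds, DRUG).proportion == 0.0

    def test_nested_matching_task_fully_concurrent(self):
        ds = single_session(
            [
                make_record("R1", what="Examination/Treatment", sub="none",
                            how="Direct", who="Patient", start_s=0, end_s=1000),
                make_record("R2", start_s=200, end_s=400),
            ]
        )
        assert multitask_fraction(ds, DRUG).proportion == 1.0

    def test_zero_selector_time_raises(self):
        ds = single_session([make_record("R1")])
        with pytest.raises(EstimatorError):
            multitask_fraction(ds, Selector.make(what="Hygiene"))

    @pytest.mark.parametrize("seed", range(3))
    def test_random_sessions_against_oracle(self, seed):
        ds = generate_dataset(
            GeneratorConfig(n_physicians=2, session_hours=0.5,
                            multitask_probability=0.3, seed=seed)
        )
        est = multitask_fraction(ds, DRUG)
        smap = ds.session_map()
        num = den = 0
        for sid, sess in smap.items():
            recs = [r for r in ds.records if r.session_id == sid]
            T = sess.duration_seconds
            triples = [
                (
                    r.record_id,
                    int((r.start - sess.session_start).total_seconds()),
                    int((r.end - sess.session_start).total_seconds()),
                )
                for r in recs
            ]
            counts = oracle_concurrency(triples, T)
            sel_pairs = [
                (a, b)
                for (rid, a, b), r in zip(triples, recs)
                if r.subcategory == "drug-related"
            ]
            sel_cover = oracle_cover(sel_pairs, T)
            num += int((sel_cover & (counts >= 2)).sum())
            den += int(sel_cover.sum())
        assert (est.numerator_seconds, est.denominator_seconds) == (num, den)


class TestInterruptions:
    def test_published_overall_rate_arithmetic(self):
        # 368 events over 91.4 h -> 4.03 -> 4.0 at one decimal
        from timemotion.estimators import RateEstimate

        est = RateEstimate(event_count=368, exposure_hours=91.4)
        assert est.rate_per_hour == pytest.approx(4.026, abs=0.001)
        assert round(est.rate_per_hour, 1) == 4.0

    def test_no_interruptions_rate_zero(self):
        ds = single_session([make_record("R1")])
        assert interruption_rate(ds).rate_per_hour == 0.0

    def test_slice_rate_counts_starts_in_slice(self, tiny_dataset):
        # the single interruption starts at 700 s, inside the drug-related task
        est = interruption_rate(tiny_dataset, DRUG)
        assert est.event_count == 1
        assert est.exposure_hours == pytest.approx(600 / 3600)
        est2 = interruption_rate(tiny_dataset, Selector.make(what="Gather information"))
        assert est2.event_count == 0

    def test_overall_count_conservation(self):
        ds = generate_dataset(GeneratorConfig(n_physicians=4, seed=2))
        est = interruption_rate(ds)
        assert est.event_count == sum(1 for r in ds.records if r.is_interruption)


def _interrupted_doc_fixture(n_tasks=9, n_interrupted=5):
    """Drug-related documentation tasks, a subset interrupted once each."""
    records = []
    for i in range(n_tasks):
        records.append(
            make_record(f"D{i}", what="Documentation", sub="drug-related",
                        start_s=i * 300, end_s=i * 300 + 200)
        )
    for i in range(n_interrupted):
        records.append(
            make_record(
                f"I{i}", what="Professional communication", sub="non-drug-related",
                how="Direct", who="Nurse",
                start_s=i * 300 + 50, end_s=i * 300 + 80,
                is_interruption=True, interrupts=f"D{i}",
            )
        )
    return single_session(records)


class TestTaskInterruptionStats:
    def test_no_interruptions_fraction_zero(self):
        ds = single_session([make_record("R1")])
        assert fraction_tasks_interrupted(ds, DRUG).proportion == 0.0

    def test_every_task_interrupted(self):
        ds = _interrupted_doc_fixture(n_tasks=4, n_interrupted=4)
        sel = Selector.make(what="Documentation", include_interruptions=False)
        assert fraction_tasks_interrupted(ds, sel).proportion == 1.0

    def test_five_of_nine_mirrors_published_share(self):
        ds = _interrupted_doc_fixture(n_tasks=9, n_interrupted=5)
        sel = Selector.make(what="Documentation", subcategory="drug-related")
        est = fraction_tasks_interrupted(ds, sel)
        assert est.proportion == pytest.approx(5 / 9)
        assert round(est.as_percent, 1) == 55.6

    def test_reason_breakdown_sums_to_one(self):
        # 40 interruptions of drug-related documentation, 33 by communication
        records = [
            make_record("T1", what="Documentation", sub="drug-related",
                        start_s=0, end_s=3000)
        ]
        for i in range(40):
            what = "Professional communication" if i < 33 else "Movement"
            sub = "non-drug-related" if i < 33 else "none"
            records.append(
                make_record(f"I{i}", what=what, sub=sub, how="none", who="none",
                            start_s=10 + i * 70, end_s=30 + i * 70,
                            is_interruption=True, interrupts="T1")
            )
        ds = single_session(records)
        dist = interruption_reason_breakdown(
            ds, Selector.make(what="Documentation", subcategory="drug-related")
        )
        assert dist["Professional communication"] == pytest.approx(0.825)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_all_communication_interrupters(self, tiny_dataset):
        dist = interruption_reason_breakdown(tiny_dataset, DRUG)
        assert dist == {"Professional communication": 1.0}

    def test_no_qualifying_interruptions_raises(self):
        ds = single_session([make_record("R1")])
        with pytest.raises(EstimatorError):
            interruption_reason_breakdown(ds, DRUG)


class TestConversionsAndPatients:
    @pytest.mark.parametrize(
        "prop,expected",
        [(0.129, 7.74), (0.0, 0.0), (0.143, 8.58), (1.0, 60.0)],
    )
    def test_minutes_per_hour(self, prop, expected):
        assert minutes_per_hour(prop) == pytest.approx(expected)

    def test_published_conversions_at_one_decimal(self):
        # 14.3% -> 8.58 -> printed 8.6
        assert round(minutes_per_hour(0.143), 1) == 8.6

    def test_out_of_range_raises(self):
        with pytest.raises(EstimatorError):
            minutes_per_hour(1.2)
        with pytest.raises(EstimatorError):
            minutes_per_hour(-0.1)

    def test_patients_means(self):
        sessions = [
            make_session(sid=f"S{i}", physician=f"P{i}", new=n, followup=f)
            for i, (n, f) in enumerate([(2, 1), (2, 0), (2, 1)])
        ]
        ds = ObservationDataset(sessions=sessions)
        total, new, fu = patients_per_session(ds)
        assert new == pytest.approx(2.0)
        assert fu == pytest.approx(2 / 3)
        assert total == pytest.approx(new + fu)

    def test_zero_patients(self):
        ds = ObservationDataset(sessions=[make_session(new=0, followup=0)])
        assert patients_per_session(ds) == (0.0, 0.0, 0.0)

    def test_empty_dataset_raises(self):
        with pytest.raises(EstimatorError):
            patients_per_session(ObservationDataset())
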