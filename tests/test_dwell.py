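import numpy as np
import pytest

from bek import (
    binarize_trace,
    count_bleach_steps,
    detect_depolymerization_onset,
    dwell_summary,
    estimate_uncap_probability,
    visits_until_uncapping,
)
from bek.dwell import PresenceIntervals, UncapVisitRecord, intervals_from_binary
from bek.observe import ChannelTrace


def trace_from(values, dt=1.0):
    return ChannelTrace(0, "twinfilin", dt, np.asarray(values, dtype=float))


def intervals(pairs, dt=1.0, t0=0.0):
    return PresenceIntervals(
        filament_id=0,
        intervals=list(pairs),
        frame_interval=dt,
        single_frame_flags=[e - s == 1 for s, e in pairs],
        t0=t0,
    )


class TestBinarize:
    def test_dark_trace_has_no_intervals(self):
        iv = binarize_trace(trace_from(np.zeros(50)), threshold=0.5)
        assert iv.intervals == []

    def test_clean_pulse_duration(self):
        v = np.zeros(40)
        v[10:20] = 1.0
        iv = binarize_trace(trace_from(v), threshold=0.5)
        assert iv.intervals == [(10, 20)]
        assert iv.durations()[0] == 10.0
        assert iv.single_frame_flags == [False]

    def test_gap_tolerance_merges_runs(self):
        v = np.zeros(20)
        v[5:10] = 1.0
        v[11:15] = 1.0
        strict = binarize_trace(trace_from(v), threshold=0.5)
        merged = binarize_trace(trace_from(v), threshold=0.5, gap_tolerance=1)
        assert len(strict.intervals) == 2
        assert merged.intervals == [(5, 15)]

    def test_min_frames_drops_blips(self):
        v = np.zeros(20)
        v[3] = 1.0
        v[8:12] = 1.0
        iv = binarize_trace(trace_from(v), threshold=0.5, min_frames=2)
        assert iv.intervals == [(8, 12)]

    def test_single_frame_interval_is_flagged_lower_bound(self):
        v = np.zeros(10)
        v[4] = 1.0
        iv = binarize_trace(trace_from(v), threshold=0.5)
        assert iv.single_frame_flags == [True]

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            binarize_trace(trace_from([]), threshold=0.5)

    def test_auto_threshold_separates_levels(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 0.05, 100), rng.normal(1, 0.05, 50)])
        iv = binarize_trace(trace_from(v), threshold="auto")
        assert iv.intervals == [(100, 150)]


class TestDwellSummary:
    def test_single_event_has_undefined_sem(self):
        s = dwell_summary(intervals([(0, 7)], dt=0.2))
        assert s.mean == pytest.approx(1.4)
        assert s.sem == 0.0 and not s.sem_defined

    def test_hand_computed_mean_and_sem(self):
        s = dwell_summary([1.0, 2.0, 3.0])
        assert s.mean == 2.0
        assert s.sem == pytest.approx(1.0 / np.sqrt(3), abs=1e-12)

    def test_pools_across_filaments(self):
        s = dwell_summary([intervals([(0, 2)]), intervals([(5, 9)])])
        assert s.n_events == 2 and s.mean == 3.0

    def test_exponential_dwells_recovered(self):
        rng = np.random.default_rng(1)
        d = rng.exponential(1.9, 5000)
        s = dwell_summary(d)
        assert abs(s.mean - 1.9) < 3 * s.sem

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            dwell_summary([])


class TestVisitsUntilUncapping:
    def test_counts_visits_up_to_uncap(self):
        iv = intervals([(0, 3), (10, 12), (20, 24)])
        rec = visits_until_uncapping(iv, t_uncap=22.0)
        assert rec.n_visits == 3 and rec.resolved

    def test_spontaneous_uncap_counts_zero_visits(self):
        rec = visits_until_uncapping(intervals([]), t_uncap=5.0)
        assert rec.n_visits == 0 and rec.resolved

    def test_visits_after_uncap_excluded(self):
        iv = intervals([(0, 3), (10, 12), (20, 24)])
        assert visits_until_uncapping(iv, 12.5).n_visits == 2

    def test_uncap_before_trace_rejected(self):
        with pytest.raises(ValueError):
            visits_until_uncapping(intervals([(0, 3)], t0=10.0), t_uncap=5.0)

    def test_unresolved_filament(self):
        rec = visits_until_uncapping(intervals([(0, 3)]), t_uncap=None)
        assert not rec.resolved and rec.n_visits == 1


class TestUncapProbability:
    def test_every_visit_succeeds(self):
        recs = [UncapVisitRecord(i, 1, 10.0, True) for i in range(5)]
        p, _ = estimate_uncap_probability(recs)
        assert p == 1.0

    def test_reciprocal_of_mean_visit_count(self):
        # ~31 visits per uncapping implies p ~ 1/31
        recs = [UncapVisitRecord(0, 31, 1.0, True), UncapVisitRecord(1, 30.8, 1.0, True)]
        p, _ = estimate_uncap_probability(recs)
        assert p == pytest.approx(1 / 30.9, abs=1e-6)

    def test_geometric_simulation_recovery(self):
        rng = np.random.default_rng(3)
        counts = rng.geometric(0.2, 5000)
        recs = [UncapVisitRecord(i, int(c), 1.0, True) for i, c in enumerate(counts)]
        p, (lo, hi) = estimate_uncap_probability(recs, seed=0)
        assert 0.18 < p < 0.22
        assert lo < p < hi

    def test_no_resolved_records_rejected(self):
        with pytest.raises(ValueError):
            estimate_uncap_probability([UncapVisitRecord(0, 3, float("nan"), False)])


class TestBleachSteps:
    def test_flat_trace_has_no_steps(self):
        assert count_bleach_steps(trace_from(np.ones(60)), min_step=0.5) == 0

    def test_noiseless_staircase(self):
        v = np.concatenate([np.full(40, 2.0), np.full(40, 1.0), np.zeros(40)])
        assert count_bleach_steps(trace_from(v), min_step=0.5) == 2

    def test_single_step_detected_under_noise(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(1000):
            v = np.concatenate([np.ones(60), np.zeros(60)]) + rng.normal(0, 0.1, 120)
            hits += count_bleach_steps(trace_from(v), min_step=0.5) == 1
        assert hits >= 950

    def test_upward_changes_not_counted(self):
        v = np.concatenate([np.zeros(40), np.ones(40)])
        assert count_bleach_steps(trace_from(v), min_step=0.5) == 0


class TestDepolymerizationOnset:
    def test_onset_at_first_sustained_decrease(self):
        v = np.concatenate([np.linspace(0, 5, 51), np.linspace(5, 3, 21)[1:]])
        t = detect_depolymerization_onset(ChannelTrace(0, "length", 1.0, v))
        assert t == pytest.approx(50.0)

    def test_growing_filament_has_no_onset(self):
        v = np.linspace(0, 5, 60)
        assert detect_depolymerization_onset(ChannelTrace(0, "length", 1.0, v)) is None


class TestIntervalInvariants:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            intervals([(0, 5), (3, 8)])

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            intervals([(4, 4)])

    def test_round_trip_binary_vector(self):
        rng = np.random.default_rng(5)
        on = rng.random(200) < 0.3
        iv = intervals_from_binary(on, 1.0)
        rebuilt = np.zeros(200, dtype=bool)
        for s, e in iv.intervals:
            rebuilt[s:e] = True
        assert np.array_equal(on, rebuilt)
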