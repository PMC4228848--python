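"""Half-amplitude idealization, NPo/Po, dwell and amplitude fitting."""

import math

import numpy as np
import pytest

from conftest import truth_events
from patchdose.idealize import (
    IdealizedRecord,
    NoOpenEventsError,
    compute_npo,
    estimate_unitary_amplitude,
    extract_open_dwells,
    fit_amplitude_histogram,
    fit_dwell_exponentials,
    idealize_half_amplitude,
    summarize_patch,
    track_baseline,
)
from patchdose.simulate import GatingModel, render_trace, simulate_gating


def make_record(levels, durations, dt_ms=0.05):
    levels = np.asarray(levels)
    durations = np.asarray(durations, float)
    starts = np.concatenate(([0.0], np.cumsum(durations)[:-1]))
    return IdealizedRecord(
        levels=levels,
        starts_ms=starts,
        durations_ms=durations,
        total_duration_ms=float(durations.sum()),
        n_levels_observed=int(levels.max()),
        dt_ms=dt_ms,
    )


class TestBaseline:
    def test_flat_closed_trace_gives_zero(self):
        x = np.zeros(20_000)
        b = track_baseline(x, dt_ms=0.05)
        assert np.allclose(b, 0.0)

    def test_linear_drift_tracked_exactly(self):
        # +1 pA over 10 s, no openings, no noise: piecewise-linear baseline
        # with per-segment medians reproduces the ramp exactly
        n = 200_000
        dt = 0.05
        drift = np.linspace(0.0, 1.0, n)
        b = track_baseline(drift, dt_ms=dt, unitary_amplitude=5.0)
        assert np.max(np.abs(b - drift)) < 1e-9

    def test_drift_with_noise_and_openings(self, atp1_trace):
        model, trace = atp1_trace
        drift = np.linspace(0.0, 1.0, len(trace.samples))
        b = track_baseline(
            trace.samples + drift, trace.dt_ms, unitary_amplitude=5.0
        )
        err = np.abs(b - drift)
        assert np.max(err) < 0.2 * 5.0  # within 0.2x unitary amplitude

    def test_amplitude_auto_estimate(self, atp1_trace):
        model, trace = atp1_trace
        b = track_baseline(trace.samples, trace.dt_ms)
        amp = estimate_unitary_amplitude(trace.samples, b)
        assert amp == pytest.approx(5.0, abs=0.5)


class TestIdealization:
    def test_single_opening_noiseless(self):
        dt = 0.05
        x = np.zeros(4000)
        x[1000:1200] = 5.0  # 10 ms opening
        rec = idealize_half_amplitude(x, 0.0, 5.0, dt, dead_time_ms=0.0)
        assert list(rec.levels) == [0, 1, 0]
        assert rec.durations_ms[1] == pytest.approx(10.0)
        assert rec.starts_ms[1] == pytest.approx(50.0)

    def test_overlapping_openings_level_two(self):
        dt = 0.05
        x = np.zeros(4000)
        x[1000:1400] += 5.0
        x[1200:1600] += 5.0
        rec = idealize_half_amplitude(x, 0.0, 5.0, dt, dead_time_ms=0.0)
        assert list(rec.levels) == [0, 1, 2, 1, 0]
        assert rec.durations_ms[2] == pytest.approx(10.0)

    def test_exact_event_reproduction_noise_free(self, noiseless_two_state):
        model, trace = noiseless_two_state
        rec = idealize_half_amplitude(
            trace.samples, 0.0, 5.0, trace.dt_ms, dead_time_ms=0.0
        )
        lv, du = truth_events(trace)
        assert np.array_equal(rec.levels, lv)
        assert np.allclose(rec.durations_ms, du)

    def test_max_levels_truncation_flag(self):
        x = np.full(1000, 15.0)
        x[:100] = 0.0
        rec = idealize_half_amplitude(x, 0.0, 5.0, 0.05, max_levels=2, dead_time_ms=0.0)
        assert rec.truncated
        assert rec.n_levels_observed == 2

    def test_dead_time_absorbs_short_events(self):
        dt = 0.05
        x = np.zeros(1000)
        x[500:502] = 5.0  # 0.1 ms blip
        rec = idealize_half_amplitude(x, 0.0, 5.0, dt, dead_time_ms=0.2)
        assert list(rec.levels) == [0]

    def test_recovered_npo_monotone_in_opening_rate(self):
        # raising the true opening rate never decreases recovered NPo
        npos = []
        for tau_closed in (40.0, 20.0, 10.0, 5.0):
            model = GatingModel.two_state(2.0, tau_closed, n_channels=2)
            paths = simulate_gating(model, 20_000.0, seed=55)
            trace = render_trace(model, paths, seed=56)
            b = track_baseline(trace.samples, trace.dt_ms, unitary_amplitude=5.0)
            rec = idealize_half_amplitude(trace.samples, b, 5.0, trace.dt_ms)
            npos.append(compute_npo(rec).npo)
        assert all(b >= a for a, b in zip(npos, npos[1:]))


class TestNpo:
    def test_all_closed_record(self):
        rec = make_record([0], [1000.0])
        s = compute_npo(rec)
        assert s.npo == 0.0 and s.po == 0.0 and s.n_max == 0

    def test_single_channel_always_open(self):
        rec = make_record([1], [1000.0])
        s = compute_npo(rec)
        assert s.po == 1.0 and s.npo == 1.0 and s.n_max == 1

    def test_level_weighted_example(self):
        # brute-force per-sample occupancy oracle: (100*1 + 50*2)/1000 = 0.2
        rec = make_record([1, 2, 0], [100.0, 50.0, 850.0])
        s = compute_npo(rec)
        assert s.npo == pytest.approx(0.2)
        assert s.po == pytest.approx(0.1)
        assert s.n_max == 2
        # per-sample reconstruction agrees
        samples = np.concatenate(
            [np.full(2000, 1), np.full(1000, 2), np.full(17000, 0)]
        )
        assert s.npo == pytest.approx(samples.mean())

    def test_time_reversal_invariance(self):
        rec = make_record([0, 1, 2, 1, 0], [100.0, 20.0, 5.0, 30.0, 845.0])
        rev = make_record([0, 1, 2, 1, 0][::-1], [845.0, 30.0, 5.0, 20.0, 100.0])
        a, b = compute_npo(rec), compute_npo(rev)
        assert a.npo == pytest.approx(b.npo)
        assert a.po == pytest.approx(b.po)
        assert 0.0 <= a.po <= 1.0

    def test_zero_duration_rejected(self):
        rec = make_record([0], [1.0])
        rec.total_duration_ms = 0.0
        with pytest.raises(ValueError):
            compute_npo(rec)


class TestOpenDwells:
    def test_single_opening(self):
        rec = make_record([0, 1, 0], [10.0, 10.0, 10.0])
        assert list(extract_open_dwells(rec)) == [10.0]

    def test_multilevel_sojourn_is_one_dwell(self):
        rec = make_record([0, 1, 2, 1, 0], [10.0, 4.0, 2.0, 3.0, 10.0])
        dwells = extract_open_dwells(rec)
        assert list(dwells) == [pytest.approx(9.0)]

    def test_empirical_mean_matches_ground_truth_scan(self, noiseless_two_state):
        model, trace = noiseless_two_state
        rec = idealize_half_amplitude(
            trace.samples, 0.0, 5.0, trace.dt_ms, dead_time_ms=0.0
        )
        dwells = extract_open_dwells(rec)
        # oracle: dwells scanned directly from the sampled ground-truth path
        lv, du = truth_events(trace)
        oracle = [d for l, d in zip(lv, du) if l >= 1]
        assert len(dwells) == len(oracle)
        assert dwells.mean() == pytest.approx(np.mean(oracle), rel=1e-12)


class TestDwellFit:
    def test_single_component_mle_is_sample_mean(self):
        data = np.array([2.0, 4.0, 6.0] * 4)  # >=10 durations required
        fit = fit_dwell_exponentials(data, max_components=1)
        assert fit.n_components == 1
        assert fit.taus[0] == pytest.approx(4.0, rel=1e-6)

    def test_single_exponential_recovery(self):
        rng = np.random.default_rng(1234)
        data = rng.exponential(2.0, 5000)
        fit = fit_dwell_exponentials(data, max_components=3, seed=1)
        assert fit.n_components == 1
        assert fit.taus[0] == pytest.approx(2.0, rel=0.05)

    def test_dead_time_truncation_preserves_tau(self):
        rng = np.random.default_rng(99)
        data = rng.exponential(2.0, 5000)
        data = data[data > 0.2] # observed only above the dead time
        fit = fit_dwell_exponentials(data, max_components=1, dead_time_ms=0.2)
        assert fit.taus[0] == pytest.approx(2.0, rel=0.05)

    def test_mean_dwell_nondecreasing_in_dead_time(self, atp1_trace):
        model, trace = atp1_trace
        b = track_baseline(trace.samples, trace.dt_ms, unitary_amplitude=5.0)
        means = []
        for dead in (0.1, 0.3, 0.6):
            rec = idealize_half_amplitude(
                trace.samples, b, 5.0, trace.dt_ms, dead_time_ms=dead
            )
            means.append(extract_open_dwells(rec).mean())
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_too_few_durations(self):
        with pytest.raises(ValueError):
            fit_dwell_exponentials(np.ones(5))


class TestAmplitudeFit:
    def test_noiseless_openings_exact_mean(self):
        dt = 0.05
        x = np.zeros(10_000)
        for start in range(1000, 9000, 2000):
            x[start:start + 100] = 5.0  # 5-ms openings
        rec = idealize_half_amplitude(x, 0.0, 5.0, dt, dead_time_ms=0.0)
        fit = fit_amplitude_histogram(x, rec)
        assert fit.mean == pytest.approx(5.0, abs=1e-9)
        assert fit.sd <= 1e-6

    def test_noisy_trace_recovers_amplitude(self, atp1_trace):
        model, trace = atp1_trace
        b = track_baseline(trace.samples, trace.dt_ms, unitary_amplitude=5.0)
        rec = idealize_half_amplitude(trace.samples, b, 5.0, trace.dt_ms)
        fit = fit_amplitude_histogram(trace.samples, rec, b)
        assert fit.mean == pytest.approx(5.0, abs=0.2)

    def test_all_closed_trace_raises_no_open_events(self):
        x = np.zeros(1000)
        rec = idealize_half_amplitude(x, 0.0, 5.0, 0.05)
        with pytest.raises(NoOpenEventsError):
            fit_amplitude_histogram(x, rec)


def test_summarize_patch_end_to_end(atp1_trace):
    model, trace = atp1_trace
    b = track_baseline(trace.samples, trace.dt_ms, unitary_amplitude=5.0)
    rec = idealize_half_amplitude(trace.samples, b, 5.0, trace.dt_ms, dead_time_ms=0.1)
    s = summarize_patch(trace.samples, rec, b, dead_time_ms=0.1, seed=0)
    gt = trace.ground_truth
    assert s.npo == pytest.approx(gt["true_npo"], rel=0.10)
    assert s.n_max == gt["n_channels"]
    assert s.amplitude_pA == pytest.approx(5.0, abs=0.2)
    assert math.isfinite(s.mean_open_dwell_ms)
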