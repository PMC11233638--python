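"""IPSC and spike-train feature extraction."""

import numpy as np
import pytest

from cerebmotif import (
    SpikeTrain,
    SweepSet,
    amplitude_isi_correlation,
    branch_index,
    classify_connected,
    disparity_index,
    fit_decay_double_exp,
    ipsc_amplitude,
    isi_ratio,
    rise_time_20_80,
)
from cerebmotif.signal_features import (
    ExcludedTrialError,
    InsufficientDataError,
    read_spike_trains,
    read_sweeps,
    write_sweeps,
)
from cerebmotif.synthetic import SimEphysConfig, simulate_spike_train, simulate_sweeps


def _sweepset(traces, dt=0.1, onset=20.0):
    return SweepSet(sampling_interval_ms=dt, stim_onset_ms=onset, sweeps=np.atleast_2d(traces))


class TestIpscAmplitude:
    def test_flat_sweep_is_zero(self):
        amp, per = ipsc_amplitude(_sweepset(np.zeros(1000)))
        assert amp == 0.0 and per[0] == 0.0

    def test_step_above_baseline(self):
        trace = np.zeros(1000)
        trace[250:400] = 120.0  # step 5 ms after the 20 ms onset
        amp, _ = ipsc_amplitude(_sweepset(trace))
        assert amp == pytest.approx(120.0)

    def test_noiseless_synthetic_exact(self):
        sweeps, truth = simulate_sweeps(SimEphysConfig(noise_sd_pA=0.0, failure_prob=0.0))
        amp, _ = ipsc_amplitude(sweeps)
        assert amp == pytest.approx(truth["amplitude_pA"], abs=1e-9)

    def test_noisy_synthetic_within_three_sigma(self):
        cfg = SimEphysConfig(amplitude_pA=91.2, noise_sd_pA=2.0, n_sweeps=10, seed=3)
        sweeps, _ = simulate_sweeps(cfg)
        amp, _ = ipsc_amplitude(sweeps)
        assert amp == pytest.approx(91.2, abs=3 * 2.0)

    def test_baseline_offset_invariance(self):
        sweeps, _ = simulate_sweeps(SimEphysConfig(noise_sd_pA=1.0, seed=4))
        shifted = SweepSet(
            sampling_interval_ms=sweeps.sampling_interval_ms,
            stim_onset_ms=sweeps.stim_onset_ms,
            sweeps=sweeps.sweeps + 500.0,
        )
        a0, _ = ipsc_amplitude(sweeps)
        a1, _ = ipsc_amplitude(shifted)
        assert a1 == pytest.approx(a0, rel=1e-12)


class TestRiseTime:
    def test_linear_ramp(self):
        # ramp 0 -> peak over 10 ms: 20% at 2 ms, 80% at 8 ms
        dt = 0.1
        trace = np.concatenate([np.linspace(0, 100, 101), np.full(100, 100.0)])
        rt = rise_time_20_80(trace, baseline=0.0, sampling_interval_ms=dt)
        assert rt == pytest.approx(6.0, abs=dt)

    def test_saturating_exponential_closed_form(self):
        dt = 0.01
        tau = 2.0
        t = np.arange(0, 30, dt)
        trace = 100 * (1 - np.exp(-t / tau))
        rt = rise_time_20_80(trace, baseline=0.0, sampling_interval_ms=dt)
        assert rt == pytest.approx(tau * np.log(4), rel=0.01)

    def test_instantaneous_step_is_subsample(self):
        # a one-sample step resolves below one sampling interval by
        # interpolation (0.6 dt: the 20% and 80% crossings share one segment)
        dt = 0.1
        trace = np.concatenate([np.zeros(50), np.full(50, 80.0)])
        rt = rise_time_20_80(trace, baseline=0.0, sampling_interval_ms=dt)
        assert rt < dt

    def test_zero_peak_undefined(self):
        assert rise_time_20_80(np.zeros(100), 0.0, 0.1) is None


class TestDecayFit:
    def test_collapsed_single_exponential(self):
        dt = 0.05
        t = np.arange(0, 80, dt)
        y = 90 * np.exp(-t / 5.0)
        fit = fit_decay_double_exp(y, dt)
        assert fit.tau_weighted_ms == pytest.approx(5.0, rel=0.01)

    def test_weighted_tau_arithmetic(self):
        dt = 0.05
        t = np.arange(0, 120, dt)
        y = 50 * np.exp(-t / 2.0) + 50 * np.exp(-t / 10.0)
        fit = fit_decay_double_exp(y, dt)
        assert fit.tau1_ms <= fit.tau2_ms
        assert fit.tau_weighted_ms == pytest.approx(6.0, rel=0.02)

    def test_weighted_tau_is_convex_combination(self):
        dt = 0.05
        t = np.arange(0, 120, dt)
        rng = np.random.default_rng(0)
        y = 60 * np.exp(-t / 3.0) + 30 * np.exp(-t / 15.0) + rng.normal(0, 1, t.size)
        fit = fit_decay_double_exp(y, dt)
        assert fit.tau1_ms - 1e-9 <= fit.tau_weighted_ms <= fit.tau2_ms + 1e-9

    def test_short_segment_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_decay_double_exp(np.ones(10), 0.1)


class TestClassifyConnected:
    def test_flat_noise_not_responsive(self):
        rng = np.random.default_rng(8)
        traces = rng.normal(0, 2.0, size=(8, 1000))
        responsive, failure = classify_connected(_sweepset(traces))
        assert not responsive
        assert failure == 1.0

    def test_six_of_eight_successes(self):
        sweeps, truth = simulate_sweeps(
            SimEphysConfig(n_sweeps=8, noise_sd_pA=1.0, failure_prob=0.0, seed=2)
        )
        traces = sweeps.sweeps.copy()
        traces[6:] = np.random.default_rng(0).normal(0, 1.0, size=(2, traces.shape[1]))
        responsive, failure = classify_connected(_sweepset(traces))
        assert responsive
        assert failure == pytest.approx(0.25)

    @pytest.mark.parametrize("n_success, expect", [(0, False), (2, False), (3, True), (6, True)])
    def test_decision_boundary_at_half(self, n_success, expect):
        sweeps, _ = simulate_sweeps(
            SimEphysConfig(n_sweeps=6, noise_sd_pA=1.0, failure_prob=0.0, seed=5)
        )
        traces = sweeps.sweeps.copy()
        rng = np.random.default_rng(1)
        traces[n_success:] = rng.normal(0, 1.0, size=(6 - n_success, traces.shape[1]))
        responsive, _ = classify_connected(_sweepset(traces))
        assert responsive is expect

    def test_monotone_in_amplitude(self):
        sweeps, _ = simulate_sweeps(
            SimEphysConfig(n_sweeps=6, noise_sd_pA=1.0, failure_prob=0.3, seed=6)
        )
        responsive0, _ = classify_connected(sweeps)
        boosted = SweepSet(
            sampling_interval_ms=sweeps.sampling_interval_ms,
            stim_onset_ms=sweeps.stim_onset_ms,
            sweeps=sweeps.sweeps * 3.0,
        )
        responsive1, _ = classify_connected(boosted)
        assert responsive1 >= responsive0

    def test_too_few_sweeps_rejected(self):
        with pytest.raises(InsufficientDataError):
            classify_connected(_sweepset(np.zeros((2, 1000))))


class TestScalarFeatures:
    @pytest.mark.parametrize(
        "values, expected",
        [([100, 100], 0.0), ([50, 150], 0.70710678), ([60, 80, 100], 0.25)],
    )
    def test_disparity_index(self, values, expected):
        assert disparity_index(values) == pytest.approx(expected)

    def test_disparity_index_single_value_missing(self):
        assert disparity_index([42.0]) is None

    @pytest.mark.parametrize(
        "crossings, primaries, expected", [(10, 5, 2.0), (0, 3, 0.0), (7, 2, 3.5)]
    )
    def test_branch_index(self, crossings, primaries, expected):
        assert branch_index(crossings, primaries) == expected

    def test_branch_index_requires_primaries(self):
        with pytest.raises(ValueError):
            branch_index(4, 0)

    def test_amplitude_isi_correlation_hand_case(self):
        pairs = [(0, 0), (1, 1), (2, 0), (3, 1)]
        assert amplitude_isi_correlation(pairs) == pytest.approx(0.2)

    def test_amplitude_isi_correlation_degenerate(self):
        assert amplitude_isi_correlation([(1, 5), (2, 5), (3, 5)]) is None
        with pytest.raises(InsufficientDataError):
            amplitude_isi_correlation([(1, 2), (3, 4)])

    def test_perfectly_linear_pairs(self):
        pairs = [(10, 1.0), (20, 1.2), (30, 1.4), (40, 1.6)]
        assert amplitude_isi_correlation(pairs) == pytest.approx(1.0)


class TestIsiRatio:
    def test_regular_train_unperturbed(self):
        spikes = np.arange(0, 500, 20.0) + 0.5
        train = SpikeTrain(spike_times=spikes, stim_time_ms=250.0)
        assert isi_ratio(train) == pytest.approx(1.0)

    def test_stretched_post_stimulus_interval(self):
        spikes = list(np.arange(0, 260, 20.0))
        # interval containing the 253 ms offset runs 240 -> 270 (30 ms)
        spikes += [270.0] + list(np.arange(290, 400, 20.0))
        train = SpikeTrain(spike_times=np.array(spikes), stim_time_ms=250.0)
        assert isi_ratio(train) == pytest.approx(1.5)

    def test_pause_generator_round_trip(self):
        cfg = SimEphysConfig(pause_factor=1.57, isi_cv=1e-6, seed=7)
        train = simulate_spike_train(cfg, stim_time_ms=250.0)
        assert isi_ratio(train) == pytest.approx(1.57, rel=1e-3)

    def test_slow_firing_excluded(self):
        cfg = SimEphysConfig(firing_rate_hz=15.0, seed=1)
        train = simulate_spike_train(cfg, stim_time_ms=250.0)
        with pytest.raises(ExcludedTrialError, match="Hz"):
            isi_ratio(train)

    def test_bursting_excluded(self):
        # burst triplets separated by long silences: ISI CV > 1 at >= 20 Hz
        isis = np.tile([2.0, 2.0, 2.0, 100.0], 10)
        spikes = np.cumsum(np.concatenate([[5.0], isis]))
        train = SpikeTrain(spike_times=spikes, stim_time_ms=spikes[-5] + 1.0)
        with pytest.raises(ExcludedTrialError, match="burst"):
            isi_ratio(train)

    def test_needs_spikes_on_both_sides(self):
        train = SpikeTrain(spike_times=np.array([10.0, 30.0, 50.0]), stim_time_ms=100.0)
        with pytest.raises(InsufficientDataError):
            isi_ratio(train)

    def test_first_complete_mode(self):
        spikes = np.arange(0, 500, 20.0)
        train = SpikeTrain(spike_times=spikes, stim_time_ms=250.0)
        assert isi_ratio(train, mode="first_complete") == pytest.approx(1.0)


class TestFileIO:
    def test_sweeps_round_trip(self, tmp_path):
        sweeps, _ = simulate_sweeps(SimEphysConfig(n_sweeps=3, seed=0))
        data, meta = tmp_path / "s.csv", tmp_path / "s.meta"
        write_sweeps(sweeps, data, meta)
        back = read_sweeps(data, meta)
        assert back.stim_onset_ms == sweeps.stim_onset_ms
        assert np.allclose(back.sweeps, sweeps.sweeps)

    def test_spike_train_tables(self, tmp_path):
        sp = tmp_path / "spikes.csv"
        st = tmp_path / "stims.csv"
        sp.write_text(
            "trial_id,spike_time_ms\nt1,10\nt1,30\nt1,55\nt2,5\nt2,25\nt2,50\n"
        )
        st.write_text("trial_id,stim_time_ms\nt1,40\nt2,30\n")
        trains = read_spike_trains(sp, st)
        assert [t.trial_id for t in trains] == ["t1", "t2"]
        assert trains[0].stim_time_ms == 40.0
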