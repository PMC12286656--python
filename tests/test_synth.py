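"""Synthetic-session generator: schedules, kernels, LFP, eye traces."""

import numpy as np
import pytest
from scipy.signal import welch

from affectdyn import synth
from affectdyn.behavior import EyeTrace
from affectdyn.spectral import BANDS, band_phase


class TestEventSchedule:
    def test_standard_session_counts_and_labels(self):
        sched = synth.make_event_schedule(20, 20, 8, 0.25, 3.0, (45, 90), seed=1)
        assert len(sched) == 320
        assert np.all(np.diff(sched.onsets) > 0)
        pre_trials = np.unique(sched.trial[sched.condition == "pre"])
        np.testing.assert_array_equal(pre_trials, np.arange(20))
        drug_trials = np.unique(sched.trial[sched.condition == "drug"])
        np.testing.assert_array_equal(drug_trials, np.arange(20, 40))
        assert set(sched.puff_index) == set(range(8))

    def test_minimal_schedule_deterministic_onset(self):
        sched = synth.make_event_schedule(1, 0, 1, 0.25, 3.0, (45, 45), seed=0)
        assert len(sched) == 1
        assert sched.onsets[0] == 150.0  # first series at the configured start

    def test_seeded_determinism(self):
        a = synth.make_event_schedule(5, 5, 8, 0.25, 3.0, (45, 90), seed=3)
        b = synth.make_event_schedule(5, 5, 8, 0.25, 3.0, (45, 90), seed=3)
        np.testing.assert_array_equal(a.onsets, b.onsets)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_trials_pre=-1),
            dict(puff_duration=0.0),
            dict(inter_puff_interval=0.2),  # <= puff duration
            dict(inter_trial_range=(0.0, 10.0)),
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        base = dict(n_trials_pre=2, n_trials_post=2, puffs_per_series=8,
                    puff_duration=0.25, inter_puff_interval=3.0,
                    inter_trial_range=(45, 90), seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            synth.make_event_schedule(**base)

    def test_csv_roundtrip(self, tmp_path, small_schedule):
        path = tmp_path / "events.csv"
        small_schedule.write_csv(path)
        back = type(small_schedule).read_csv(path)
        np.testing.assert_allclose(back.onsets, small_schedule.onsets)
        assert list(back.condition) == list(small_schedule.condition)


def _single_unit_truth(archetype, tau_persist, seed=0):
    truth = synth.default_ground_truth(seed=seed, n_units=1, n_channels=2,
                                       tau_persist=tau_persist)
    truth.units.loc[0, "archetype"] = archetype
    truth.units.loc[0, "amplitude"] = 10.0
    truth.units.loc[0, "baseline"] = 5.0
    truth.intrinsic_sd = 0.0
    return truth


def _single_puff_schedule():
    return synth.make_event_schedule(1, 0, 1, 0.25, 3.0, (45, 45), seed=0,
                                     first_onset=5.0)


class TestPopulation:
    def test_fast_transient_back_to_baseline_by_half_second(self):
        truth = _single_unit_truth("fast_transient", {"pre": 10.0})
        sched = _single_puff_schedule()
        act = synth.simulate_population(sched, truth, noise_sd=0.0, t_end=20.0)
        i_half = act.time_slice(5.5, 5.51)[0]
        baseline = 5.0
        assert abs(act.rates[0, i_half] - baseline) <= 0.01 * baseline
        # and it did respond
        assert act.rates[0].max() > baseline + 5.0

    def test_delayed_persistent_exact_exponential_decay(self):
        """Rate at (peak time + tau) = baseline + peak_excess / e exactly."""
        truth = _single_unit_truth("delayed_persistent", {"pre": 10.0})
        sched = _single_puff_schedule()
        act = synth.simulate_population(sched, truth, noise_sd=0.0, t_end=40.0)
        trace = act.rates[0]
        i_peak = int(np.argmax(trace))
        peak_excess = trace[i_peak] - 5.0
        i_tau = i_peak + int(round(10.0 / act.bin_width))
        assert trace[i_tau] == pytest.approx(5.0 + peak_excess / np.e, rel=1e-6)

    def test_unmodulated_unit_flat(self):
        truth = _single_unit_truth("unmodulated", {"pre": 10.0})
        sched = _single_puff_schedule()
        act = synth.simulate_population(sched, truth, noise_sd=0.0, t_end=20.0)
        np.testing.assert_allclose(act.rates[0], 5.0)

    def test_rates_nonnegative_and_deterministic(self, small_schedule, small_truth):
        a = synth.simulate_population(small_schedule, small_truth, noise_sd=2.0)
        b = synth.simulate_population(small_schedule, small_truth, noise_sd=2.0)
        assert np.all(a.rates >= 0)
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_condition_mismatch_rejected(self, small_schedule):
        truth = synth.default_ground_truth(seed=0, tau_persist={"pre": 10.0})
        with pytest.raises(ValueError, match="condition"):
            synth.simulate_population(small_schedule, truth)


class TestLFP:
    def test_pure_power_law_slope(self):
        """With nothing planted, the log-log spectral slope is ~ -chi."""
        truth = synth.default_ground_truth(seed=2, n_channels=1, chi=2.0)
        truth.planted_factors = []
        truth.planted_oscillations = []
        truth.coupled_pairs = []
        sched = _single_puff_schedule()
        lfp = synth.simulate_lfp(sched, truth, fs=200.0, duration=300.0)
        f, p = welch(lfp[0], fs=200.0, nperseg=4096)
        sel = (f >= 1.0) & (f <= 50.0)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.25)

    def test_drug_gated_oscillation_power_ratio(self):
        """A 4 Hz oscillation planted only in the drug epoch shows up as a
        drug-over-pre power excess near 4 Hz."""
        truth = synth.default_ground_truth(seed=3, n_channels=1)
        truth.planted_factors = []
        truth.coupled_pairs = []
        sched = synth.make_event_schedule(2, 2, 8, 0.25, 3.0, (45, 50), seed=3,
                                          first_onset=60.0)
        fs = 200.0
        lfp = synth.simulate_lfp(sched, truth, fs=fs)
        pre = sched.for_condition("pre")
        drug = sched.for_condition("drug")
        seg_pre = lfp[0][int(pre.onsets[0] * fs):int((pre.onsets[-1] + 20) * fs)]
        seg_drug = lfp[0][int(drug.onsets[0] * fs):int((drug.onsets[-1] + 20) * fs)]
        f, p_pre = welch(seg_pre, fs=fs, nperseg=2048)
        _, p_drug = welch(seg_drug, fs=fs, nperseg=2048)
        band = (f >= 3.5) & (f <= 4.5)
        out = (f >= 8.0) & (f <= 12.0)
        ratio_in = p_drug[band].mean() / p_pre[band].mean()
        ratio_out = p_drug[out].mean() / p_pre[out].mean()
        assert ratio_in > 3.0
        assert ratio_out < 2.0

    def test_coupled_pair_constant_phase_offset(self):
        truth = synth.default_ground_truth(seed=4, n_channels=2)
        truth.planted_factors = []
        truth.planted_oscillations = []
        truth.coupled_pairs = [synth.CoupledPair(0, 1, freq=20.0, bandwidth=6.0,
                                                 lag_rad=np.pi / 4,
                                                 amplitude=20.0)]
        sched = _single_puff_schedule()
        fs = 200.0
        lfp = synth.simulate_lfp(sched, truth, fs=fs, duration=120.0)
        phi = band_phase(lfp[0], BANDS["beta"], fs) - band_phase(lfp[1], BANDS["beta"], fs)
        mid = slice(int(10 * fs), int(110 * fs))
        plv = np.abs(np.mean(np.exp(1j * phi[mid])))
        assert plv > 0.95

    def test_nyquist_violation_rejected(self, small_schedule):
        truth = synth.default_ground_truth(seed=0, n_channels=1)
        truth.planted_oscillations = [
            synth.PlantedOscillation(freq=150.0, bandwidth=2.0, amplitude=1.0,
                                     conditions=("pre",))
        ]
        with pytest.raises(ValueError, match="Nyquist"):
            synth.simulate_lfp(small_schedule, truth, fs=200.0)


class TestEyeTraces:
    def test_zero_noise_zero_blink_equals_model(self, small_schedule):
        truth = synth.default_ground_truth(seed=5)
        traces = synth.simulate_eye_trace(small_schedule, truth,
                                          blink_amplitude=0.0, noise_sd=0.0)
        from affectdyn.dynamics import evaluate
        tr = traces[0]
        ev = small_schedule.select(small_schedule.trial == tr.trial)
        rel = ev.onsets - ev.onsets[0]
        intervals = [(a, a + d) for a, d in zip(rel, ev.durations)]
        s, tb, tp = truth.model_params.for_condition(tr.condition)
        expected = np.clip(evaluate(s, tb, tp, tr.time, intervals), 0, 1)
        np.testing.assert_allclose(tr.closure, expected, atol=1e-12)

    def test_zero_input_flat_plus_blinks(self, small_schedule):
        truth = synth.default_ground_truth(seed=5, s=0.0)
        traces = synth.simulate_eye_trace(small_schedule, truth,
                                          blink_amplitude=0.4, noise_sd=0.0)
        tr = traces[0]
        # before the series: exactly zero; blink peaks reach the amplitude
        assert np.all(tr.closure[tr.time < 0] == 0.0)
        assert tr.closure.max() == pytest.approx(0.4, abs=0.01)

    def test_shorter_tau_reduces_late_closure(self, small_schedule):
        truth = synth.default_ground_truth(
            seed=6, tau_persist={"pre": 10.0, "drug": 0.3, "post": 8.0})
        traces = synth.simulate_eye_trace(small_schedule, truth, noise_sd=0.0)
        late = {}
        for cond in ("pre", "drug"):
            ev = small_schedule.for_condition(cond)
            last_rel = ev.onsets[ev.puff_index == ev.puff_index.max()][0] \
                - ev.onsets[ev.puff_index == 0][0]
            vals = [t.window_mean(last_rel + 0.3, last_rel + 0.8)
                    for t in traces if t.condition == cond]
            late[cond] = np.mean(vals)
        assert late["drug"] < late["pre"]

    def test_bounds_and_type(self, small_eyes):
        for tr in small_eyes:
            assert isinstance(tr, EyeTrace)
            assert tr.closure.min() >= 0.0 and tr.closure.max() <= 1.0


def test_ground_truth_json_roundtrip(tmp_path, small_truth):
    path = tmp_path / "truth.json"
    small_truth.to_json(path)
    back = synth.GroundTruth.from_json(path)
    assert back.model_params.tau_persist == dict(small_truth.model_params.tau_persist)
    assert list(back.units["archetype"]) == list(small_truth.units["archetype"])
    assert back.planted_oscillations == small_truth.planted_oscillations
    assert back.coupled_pairs == small_truth.coupled_pairs
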