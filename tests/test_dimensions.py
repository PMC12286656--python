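"""Coding dimensions, orthogonalization, projections, d' traces."""

import numpy as np
import pandas as pd
import pytest

from affectdyn import dimensions, spiking, synth
from affectdyn.core import PopulationActivity
from affectdyn.dimensions import CodingDimension


def _activity(rates, bin_width=0.01, t_start=0.0, regions=None):
    n = rates.shape[0]
    sites = pd.DataFrame({
        "site_id": [f"s{i}" for i in range(n)],
        "region": regions if regions is not None else ["X"] * n,
    })
    return PopulationActivity(rates=rates, bin_width=bin_width, sites=sites,
                              t_start=t_start)


def _dim(weights, normalization="unit_norm"):
    return CodingDimension(np.asarray(weights, float),
                           [f"s{i}" for i in range(len(weights))],
                           (0.0, 1.0), (-1.0, 0.0), normalization)


class TestCodingDimension:
    def test_single_site_weight_arithmetic(self):
        """Means 2 vs 1 with unit variances give raw weight 1/sqrt(2)."""
        rng = np.random.default_rng(0)
        n_events, n_bins = 4000, 200
        rates = np.zeros((1, n_events * n_bins))
        onsets = np.arange(n_events) * 2.0 + 1.0
        act = _activity(rates, bin_width=0.01)
        # per-event values: reference ~ N(1,1), target ~ N(2,1), constant in window
        ref_vals = rng.normal(1, 1, n_events)
        tgt_vals = rng.normal(2, 1, n_events)
        for k, onset in enumerate(onsets):
            i = int(onset / 0.01)
            act.rates[0, i - 100:i] = ref_vals[k]
            act.rates[0, i:i + 100] = tgt_vals[k]
        dim = dimensions.coding_dimension(act, onsets, target=(0.0, 1.0),
                                          reference=(-1.0, 0.0),
                                          normalization="unit_norm")
        # normalization maps the single weight to 1; check the raw value
        mt, mr = tgt_vals.mean(), ref_vals.mean()
        vt, vr = tgt_vals.var(ddof=1), ref_vals.var(ddof=1)
        expected = (mt - mr) / np.sqrt(vt + vr)
        assert expected == pytest.approx(1 / np.sqrt(2), rel=0.1)
        assert dim.weights[0] == 1.0

    def test_degenerate_dimension_rejected(self):
        act = _activity(np.ones((3, 1000)))
        onsets = np.array([3.0, 6.0])
        with pytest.raises(ValueError, match="degenerate"):
            dimensions.coding_dimension(act, onsets, target=(0.0, 1.0))

    def test_two_identical_sites_share_weight_under_sum_abs(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 4000)
        rates = np.vstack([base, base])
        onsets = np.arange(5.0, 35.0, 3.0)
        act = _activity(rates)
        act.rates[:, :] += 0.0
        for onset in onsets:
            i = int(onset / 0.01)
            act.rates[:, i:i + 50] += 2.0
        dim = dimensions.coding_dimension(act, onsets, target=(0.0, 0.5),
                                          normalization="sum_abs")
        assert dim.weights[0] == pytest.approx(dim.weights[1])
        assert abs(dim.weights).sum() == pytest.approx(1.0)


class TestOrthogonalize:
    def test_gram_schmidt_arithmetic(self):
        dim = _dim([1 / np.sqrt(2), 1 / np.sqrt(2)])
        nuis = _dim([1.0, 0.0])
        out = dimensions.orthogonalize(dim, nuis)
        np.testing.assert_allclose(out.weights, [0.0, 1.0], atol=1e-12)

    def test_orthogonal_input_unchanged(self):
        dim = _dim([0.0, 1.0])
        nuis = _dim([1.0, 0.0])
        out = dimensions.orthogonalize(dim, nuis)
        np.testing.assert_allclose(out.weights, dim.weights, atol=1e-12)

    def test_parallel_input_rejected(self):
        dim = _dim([0.6, 0.8])
        with pytest.raises(ValueError, match="parallel"):
            dimensions.orthogonalize(dim, dim)


class TestProject:
    def test_single_site_unit_weight_returns_site_trace(self):
        rng = np.random.default_rng(2)
        rates = rng.normal(5, 1, (1, 3000))
        act = _activity(rates)
        dim = _dim([1.0])
        t, proj = dimensions.project(act, dim, onsets=None)
        np.testing.assert_allclose(proj, rates[0])

    def test_flat_activity_projects_to_zero_after_baseline(self):
        act = _activity(np.full((3, 3000), 4.0))
        dim = _dim([0.5, 0.5, np.sqrt(0.5)])
        t, proj = dimensions.project(act, dim, onsets=np.array([10.0, 20.0]))
        np.testing.assert_allclose(proj, 0.0, atol=1e-12)

    def test_site_mismatch_rejected(self):
        act = _activity(np.zeros((3, 1000)))
        dim = _dim([1.0, 0.0])
        with pytest.raises(ValueError, match="site mismatch"):
            dimensions.project(act, dim, onsets=None)

    def test_zero_weight_site_does_not_change_projection(self):
        rng = np.random.default_rng(3)
        rates = rng.normal(0, 1, (3, 3000))
        act3 = _activity(rates)
        w = np.array([0.6, 0.4, 0.0])
        dim3 = CodingDimension(w / np.abs(w).sum(), ["s0", "s1", "s2"],
                               (0, 1), (-1, 0), "sum_abs")
        act2 = _activity(rates[:2])
        w2 = np.array([0.6, 0.4])
        dim2 = CodingDimension(w2 / np.abs(w2).sum(), ["s0", "s1"],
                               (0, 1), (-1, 0), "sum_abs")
        _, p3 = dimensions.project(act3, dim3, onsets=np.array([10.0]))
        _, p2 = dimensions.project(act2, dim2, onsets=np.array([10.0]))
        np.testing.assert_allclose(p3, p2, atol=1e-12)


class TestEmotionDimension:
    def test_orthogonal_to_fast_dimension(self, small_schedule, small_activity):
        modulated = spiking.significant_modulation(small_activity, small_schedule)
        emo = dimensions.emotion_dimension(small_activity, small_schedule,
                                           include=modulated)
        sched = small_schedule.for_condition("pre")
        trials = np.unique(sched.trial)
        fast_onsets = sched.onsets[np.isin(sched.trial, trials[-4:])]
        sub = PopulationActivity(
            small_activity.rates[modulated], small_activity.bin_width,
            small_activity.sites.loc[modulated].reset_index(drop=True),
            small_activity.t_start)
        fast = dimensions.coding_dimension(sub, fast_onsets, target=(0.0, 0.2),
                                           reference=(-0.2, 0.0))
        assert abs(emo.weights[modulated] @ fast.weights) <= 1e-10

    def test_recovers_planted_persistent_units(self, small_schedule,
                                               small_activity, small_truth):
        modulated = spiking.significant_modulation(small_activity, small_schedule)
        emo = dimensions.emotion_dimension(small_activity, small_schedule,
                                           include=modulated)
        persistent = small_truth.units["archetype"].isin(
            ["fast_persistent", "delayed_persistent"]).to_numpy()
        n_top = max(int(round(0.1 * len(emo.weights))), persistent.sum())
        top = np.argsort(-np.abs(emo.weights))[:n_top]
        overlap = np.isin(np.nonzero(persistent)[0], top).mean()
        assert overlap >= 0.8

    def test_fast_only_population_degenerates(self):
        """A population with no persistent signal has an emotion dimension
        parallel to the fast dimension (up to noise) or zero."""
        sched = synth.make_event_schedule(4, 0, 8, 0.25, 3.0, (45, 60), seed=9)
        truth = synth.default_ground_truth(seed=9, n_units=12)
        truth.units["archetype"] = "fast_transient"
        truth.intrinsic_sd = 0.0
        act = synth.simulate_population(sched, truth, noise_sd=0.0)
        with pytest.raises(ValueError):
            dimensions.emotion_dimension(act, sched)


class TestDPrime:
    def test_identical_distributions_give_zero(self):
        rng = np.random.default_rng(4)
        times = np.arange(-1.0, 2.0, 0.01)
        proj = rng.normal(0, 1, (50, len(times)))
        d = dimensions.dprime_trace(proj, times)
        assert np.nanmax(np.abs(d)) < 1.0  # fluctuations only

    def test_unit_shift_unit_variance_gives_unit_dprime(self):
        rng = np.random.default_rng(5)
        times = np.arange(-1.0, 1.0, 0.01)
        n_ev = 20000
        proj = rng.normal(0, 1, (n_ev, len(times)))
        proj[:, times >= 0] += 1.0
        # baseline is each event's mean over 1 s (100 bins): its variance is
        # var/100, so compare against the exact pooled expression
        d = dimensions.dprime_trace(proj, times)
        post = d[times >= 0]
        expected = 1.0 / np.sqrt((1.0 + 0.01) / 2)
        assert np.nanmean(post) == pytest.approx(expected, rel=0.05)

    def test_dprime_linear_in_shift(self):
        rng = np.random.default_rng(6)
        times = np.arange(-1.0, 1.0, 0.01)
        base = rng.normal(0, 1, (5000, len(times)))
        d1 = dimensions.dprime_trace(
            base + np.where(times >= 0, 1.0, 0.0), times)
        d2 = dimensions.dprime_trace(
            base + np.where(times >= 0, 2.0, 0.0), times)
        ratio = np.nanmean(d2[times >= 0]) / np.nanmean(d1[times >= 0])
        assert ratio == pytest.approx(2.0, rel=0.05)
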