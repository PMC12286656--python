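"""Intrinsic timescale, PLV, pairwise correlations, subnetwork coupling."""

import numpy as np
import pandas as pd
import pytest

from affectdyn import netstate, synth
from affectdyn.core import PopulationActivity
from affectdyn.dimensions import CodingDimension
from affectdyn.netstate import CouplingResult
from affectdyn.spectral import BANDS


def _ar1(rng, n, phi, sd=1.0):
    x = np.empty(n)
    x[0] = rng.normal(0, sd / np.sqrt(1 - phi ** 2))
    innov = rng.normal(0, sd, n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i]
    return x


class TestIntrinsicTimescale:
    def test_analytic_exponential_recovered_exactly(self):
        """Feeding the fit its own model: a series whose autocorrelation is
        exactly exponential must be recovered to high precision."""
        dt, tau = 0.01, 0.4
        # construct a series with analytically exponential acf via AR(1)
        phi = np.exp(-dt / tau)
        rng = np.random.default_rng(0)
        # bypass sampling noise: fit the acf of a very long series
        x = _ar1(rng, 400_000, phi)
        fit = netstate.intrinsic_timescale(x, dt)
        assert fit.converged and not fit.flagged
        assert fit.b == pytest.approx(tau, rel=0.05)

    def test_ar1_timescale_monte_carlo(self):
        """AR(1) with phi = 0.98 at 10 ms: true tau = -dt/ln(phi) ~ 0.495 s;
        the median fitted b over independent 30 s realizations is within
        15%."""
        dt = 0.01
        tau_true = -dt / np.log(0.98)
        rng = np.random.default_rng(1)
        bs = []
        for _ in range(30):
            x = _ar1(rng, 3000, 0.98)
            fit = netstate.intrinsic_timescale(x, dt)
            if fit.converged:
                bs.append(fit.b)
        assert abs(np.median(bs) - tau_true) / tau_true <= 0.15

    def test_white_noise_flagged(self):
        rng = np.random.default_rng(2)
        fit = netstate.intrinsic_timescale(rng.normal(0, 1, 5000), 0.01)
        assert fit.flagged

    def test_invariant_to_linear_rescaling(self):
        rng = np.random.default_rng(3)
        x = _ar1(rng, 5000, 0.95)
        f1 = netstate.intrinsic_timescale(x, 0.01)
        f2 = netstate.intrinsic_timescale(5.0 * x + 2.0, 0.01)
        assert f1.b == pytest.approx(f2.b, rel=1e-6)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            netstate.intrinsic_timescale(np.zeros(100), 0.01)


class TestPLV:
    FS = 200.0

    def test_identical_signals_give_unit_plv(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, int(30 * self.FS))
        _, plv = netstate.plv_over_time(x, x, BANDS["beta"], self.FS)
        assert np.all(plv >= 1.0 - 1e-9)

    def test_constant_phase_offset_gives_unit_plv(self):
        t = np.arange(0, 30, 1 / self.FS)
        x = np.sin(2 * np.pi * 20 * t)
        y = np.sin(2 * np.pi * 20 * t + 0.7)
        _, plv = netstate.plv_over_time(x, y, BANDS["beta"], self.FS)
        # filter transients perturb the first/last windows slightly
        assert np.all(plv[1:-1] >= 1.0 - 1e-6)
        assert np.all(plv >= 0.999)

    def test_independent_noise_low_plv(self):
        rng = np.random.default_rng(5)
        n = int(600 * self.FS)
        x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
        band = BANDS["beta"]
        _, plv = netstate.plv_over_time(x, y, band, self.FS)
        assert plv.mean() < 0.2

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(6)
        n = int(60 * self.FS)
        x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
        _, p1 = netstate.plv_over_time(x, y, BANDS["beta"], self.FS)
        _, p2 = netstate.plv_over_time(10 * x, 0.1 * y, BANDS["beta"], self.FS)
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="window"):
            netstate.plv_over_time(np.zeros(100), np.zeros(100),
                                   BANDS["beta"], self.FS, window=5.0)


def _corr_activity(rates, bin_width=0.01):
    sites = pd.DataFrame({"site_id": [f"s{i}" for i in range(rates.shape[0])],
                          "region": "X"})
    return PopulationActivity(rates, bin_width, sites)


class TestPairwiseCorrelations:
    def test_duplicated_site_perfectly_correlated(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 4000)
        act = _corr_activity(np.vstack([base, base, rng.normal(0, 1, 4000)]))
        out = netstate.pairwise_correlations(act, {"pre": [(0.0, 30.0)]})
        r = out.values["pre"][0]
        assert r[0, 1] == pytest.approx(1.0)
        assert np.isnan(r[0, 0])

    def test_independent_sites_weak_correlations(self):
        rng = np.random.default_rng(8)
        act = _corr_activity(rng.normal(0, 1, (10, 3000)))
        out = netstate.pairwise_correlations(act, {"pre": [(0.0, 30.0)]})
        r = out.values["pre"][0]
        vals = np.abs(r[np.triu_indices(10, 1)])
        assert np.quantile(vals, 0.95) < 0.06

    def test_anticorrelated_pair(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, 2000)
        act = _corr_activity(np.vstack([base, -base]))
        out = netstate.pairwise_correlations(act, {"pre": [(0.0, 20.0)]})
        assert out.values["pre"][0][0, 1] == pytest.approx(-1.0)

    def test_zero_variance_site_flagged(self):
        rng = np.random.default_rng(10)
        act = _corr_activity(np.vstack([np.full(2000, 3.0),
                                        rng.normal(0, 1, 2000)]))
        out = netstate.pairwise_correlations(act, {"pre": [(0.0, 20.0)]})
        assert np.isnan(out.values["pre"][0][0, 1])


class TestSubnetworkCoupling:
    def _coupling(self, pre, drug, n_sites):
        ids = [f"s{i}" for i in range(n_sites)]
        return CouplingResult(values={"pre": pre, "drug": drug},
                              site_ids=ids, kind="corr")

    def _dim(self, weights):
        return CodingDimension(np.asarray(weights, float),
                               [f"s{i}" for i in range(len(weights))],
                               (0, 1), (-1, 0), "unit_norm")

    def test_unchanged_coupling_gives_unit_ratio(self):
        rng = np.random.default_rng(11)
        n = 10
        mats = 0.5 + 0.05 * rng.normal(0, 1, (4, n, n))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        coupling = self._coupling(mats[:2], mats[2:], n)
        dim = self._dim(rng.normal(0, 1, n))
        stat, members = netstate.subnetwork_coupling_change(
            coupling, dim, top_percentile=0.0, mode="corr_normalize")
        assert stat == pytest.approx(1.0, abs=0.1)
        assert len(members) == n

    def test_planted_drop_recovered_within_10pct(self):
        rng = np.random.default_rng(12)
        n = 20
        w = np.zeros(n)
        w[:4] = 3.0  # persistent sites
        w += rng.normal(0, 0.1, n)
        base = 0.6 * np.ones((3, n, n)) + 0.01 * rng.normal(0, 1, (3, n, n))
        drug = base.copy()
        drug[:, :4, :4] *= 0.5  # 50% coupling drop among persistent sites
        stat, members = netstate.subnetwork_coupling_change(
            self._coupling(base, drug, n), self._dim(w),
            top_percentile=80.0, mode="corr_normalize")
        assert stat == pytest.approx(0.5, rel=0.1)

    def test_zscore_mode_centered_on_zero_under_null(self):
        rng = np.random.default_rng(13)
        n = 8
        mats = 0.4 + 0.05 * rng.normal(0, 1, (12, n, n))
        stat, _ = netstate.subnetwork_coupling_change(
            self._coupling(mats[:6], mats[6:], n), self._dim(rng.normal(0, 1, n)),
            top_percentile=0.0, mode="plv_zscore")
        assert abs(stat) < 1.0

    def test_tiny_subnetwork_rejected(self):
        rng = np.random.default_rng(14)
        n = 5
        mats = np.ones((2, n, n))
        w = np.zeros(n)
        w[0] = 1.0
        with pytest.raises(ValueError, match="fewer than 2"):
            netstate.subnetwork_coupling_change(
                self._coupling(mats, mats, n), self._dim(w), top_percentile=99.0)


class TestOnSyntheticSession:
    def test_drug_shortens_timescale_and_decouples(self):
        """One seeded session reproduces the drug-condition direction:
        shorter baseline intrinsic timescale and reduced persistent-pair
        coupling."""
        sched = synth.make_event_schedule(4, 4, 8, 0.25, 3.0, (45, 55), seed=31)
        truth = synth.default_ground_truth(seed=31, n_units=40)
        act = synth.simulate_population(sched, truth, noise_sd=1.0)
        persistent_mask = truth.units["archetype"].isin(
            ["fast_persistent", "delayed_persistent"]).to_numpy()
        w = np.where(persistent_mask, 1.0, 0.0)
        dim = CodingDimension(w / np.linalg.norm(w),
                              list(act.sites["site_id"]), (0.5, 1.0),
                              (-1.0, 0.0), "unit_norm")
        taus = {}
        windows = {}
        for cond in ("pre", "drug"):
            spans = [(t0 - 30.0, t0) for t0 in sched.series_starts(cond)]
            windows[cond] = spans
            vals = []
            for (t0, t1) in spans:
                series = dim.weights @ act.rates[:, act.time_slice(t0, t1)]
                fit = netstate.intrinsic_timescale(series, act.bin_width)
                if fit.converged and not fit.flagged:
                    vals.append(fit.b)
            taus[cond] = np.median(vals)
        assert taus["drug"] < taus["pre"]

        coupling = netstate.pairwise_correlations(act, windows)
        stat, _ = netstate.subnetwork_coupling_change(
            coupling, dim, top_percentile=90.0, mode="corr_normalize")
        assert stat < 1.0
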