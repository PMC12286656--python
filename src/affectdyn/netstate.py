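"""Baseline network-state measures: intrinsic timescale, phase-locking
value, pairwise rate correlations, and persistent-subnetwork coupling
change.

The intrinsic timescale is the decay constant b of a * exp(-lag / b) + c
fitted to the autocorrelation of a baseline population-projection time
series, from the autocorrelation peak to 2.5 s beyond it.  Phase-locking
value (PLV; inter-site phase clustering over time) is the magnitude of the
circular mean of instantaneous band-limited phase differences in sliding
windows.  Subnetwork coupling change restricts edges to sites with the
largest |persistent-dimension weight| and compares drug-condition coupling
to its preinfusion reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import correlate

from .dimensions import CodingDimension
from .core import PopulationActivity
from .spectral import BandDefinition, band_phase

__all__ = [
    "TimescaleFit",
    "CouplingResult",
    "intrinsic_timescale",
    "plv_over_time",
    "pairwise_correlations",
    "subnetwork_coupling_change",
]


@dataclass
class TimescaleFit:
    a: float
    b: float  # seconds; the intrinsic timescale
    c: float
    converged: bool
    flagged: bool  # True when the fit should be excluded downstream

    def __iter__(self):
        return iter((self.a, self.b, self.c))


def autocorrelation(series: np.ndarray) -> np.ndarray:
    """Biased (divide-by-N) autocorrelation of the mean-subtracted series at
    non-negative lags, normalized to 1 at lag zero."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = len(x)
    full = correlate(x, x, mode="full")
    acf = full[n - 1:] / n
    if acf[0] == 0:
        raise ValueError("zero-variance series has no autocorrelation")
    return acf / acf[0]


def intrinsic_timescale(
    series: np.ndarray,
    dt: float,
    max_lag: float = 2.5,
    init: tuple[float, float, float] = (1.0, 0.2, 0.0),
) -> TimescaleFit:
    """Exponential-decay fit to the autocorrelation of a baseline series.

    Fits a * exp(-lag / b) + c over lags from the autocorrelation peak to
    ``max_lag`` seconds beyond it; b is the intrinsic timescale.
    Non-convergence and implausibly small b (< 2 dt, white-noise regime)
    are flagged for downstream exclusion.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 4 * max_lag / dt:
        raise ValueError("series too short: need length >= 4 * max_lag")
    acf = autocorrelation(series)
    lags = np.arange(len(acf)) * dt
    peak = int(np.argmax(acf))
    sel = (lags >= lags[peak]) & (lags <= lags[peak] + max_lag)
    x = lags[sel] - lags[peak]
    y = acf[sel]

    def model(lag, a, b, c):
        return a * np.exp(-lag / b) + c

    try:
        popt, _ = curve_fit(model, x, y, p0=init, maxfev=10000,
                            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]))
        converged = True
    except RuntimeError:
        return TimescaleFit(np.nan, np.nan, np.nan, converged=False, flagged=True)
    a, b, c = (float(v) for v in popt)
    return TimescaleFit(a, b, c, converged=converged, flagged=b < 2 * dt)


def plv_over_time(
    x: np.ndarray,
    y: np.ndarray,
    band: BandDefinition,
    fs: float,
    window: float = 5.0,
    stride: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window phase-locking value between two channels.

    Both signals are band-passed (zero-phase fifth-order Butterworth), the
    instantaneous analytic phase difference is taken, and each window's PLV
    is |mean(exp(i * dphi))|.  Returns (window centers, PLV).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    n_win = int(round(window * fs))
    if n_win > len(x):
        raise ValueError("window longer than the signals")
    n_stride = n_win if stride is None else int(round(stride * fs))
    dphi = band_phase(x, band, fs) - band_phase(y, band, fs)
    phasors = np.exp(1j * dphi)
    starts = np.arange(0, len(x) - n_win + 1, n_stride)
    plv = np.array([np.abs(phasors[s:s + n_win].mean()) for s in starts])
    centers = (starts + n_win / 2.0) / fs
    return centers, plv


@dataclass
class CouplingResult:
    """Per-window site-pair coupling (PLV or Pearson correlation).

    ``values[condition]`` is (n_windows, n_sites, n_sites), symmetric with
    NaN diagonal; zero-variance sites yield NaN rows/columns."""

    values: dict[str, np.ndarray]
    site_ids: list[str]
    kind: str  # "plv" | "corr"
    window: float = np.nan


def pairwise_correlations(
    activity: PopulationActivity,
    windows: Mapping[str, Sequence[tuple[float, float]]],
) -> CouplingResult:
    """Pearson correlations between all site pairs in baseline windows.

    ``windows`` maps condition -> list of (t0, t1) epochs (canonically the
    30 s preceding each stimulus series).  Zero-variance sites are flagged
    missing (NaN) for all of their pairs.
    """
    values = {}
    for cond, spans in windows.items():
        mats = []
        for (t0, t1) in spans:
            seg = activity.rates[:, activity.time_slice(t0, t1)]
            sd = seg.std(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.corrcoef(seg)
            r[sd == 0, :] = np.nan
            r[:, sd == 0] = np.nan
            np.fill_diagonal(r, np.nan)
            mats.append(r)
        values[cond] = np.stack(mats)
    return CouplingResult(values=values, site_ids=list(activity.sites["site_id"]),
                          kind="corr")


def subnetwork_coupling_change(
    coupling: CouplingResult,
    dim: CodingDimension,
    drug_condition: str = "drug",
    reference_condition: str = "pre",
    top_percentile: float = 90.0,
    mode: str = "corr_normalize",
) -> tuple[float, list[str]]:
    """Coupling change among high-|weight| persistent sites.

    Sites in the top (100 - top_percentile)% of |persistent-dimension
    weight| form the subnetwork (``top_percentile=0`` keeps everyone).
    Edges with both endpoints inside are aggregated:

    * ``plv_zscore``  - each edge's drug-window mean is z-scored against its
      preinfusion windows; the statistic is the mean edge z (0 = no change).
    * ``corr_normalize`` - mean drug-edge coupling divided by mean
      preinfusion-edge coupling (1 = no change).
    """
    if coupling.site_ids != dim.site_ids:
        raise ValueError("coupling and dimension cover different site sets")
    w = np.abs(dim.weights)
    if top_percentile <= 0:
        members = np.ones(len(w), dtype=bool)
    else:
        members = w >= np.percentile(w, top_percentile)
    idx = np.nonzero(members)[0]
    if len(idx) < 2:
        raise ValueError("subnetwork has fewer than 2 sites")
    iu = np.triu_indices(len(idx), k=1)

    def edge_values(cond):
        sub = coupling.values[cond][:, idx[:, None], idx[None, :]]
        return sub[:, iu[0], iu[1]]  # (n_windows, n_edges)

    drug = edge_values(drug_condition)
    ref = edge_values(reference_condition)
    if mode == "plv_zscore":
        mu = np.nanmean(ref, axis=0)
        sd = np.nanstd(ref, axis=0, ddof=1)
        sd = np.where(sd == 0, np.nan, sd)
        z = (np.nanmean(drug, axis=0) - mu) / sd
        stat = float(np.nanmean(z))
    elif mode == "corr_normalize":
        stat = float(np.nanmean(drug) / np.nanmean(ref))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return stat, [coupling.site_ids[i] for i in idx]
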