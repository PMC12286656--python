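"""Single-unit analyses: modulation screening, peri-puff response
clustering, cluster-by-region composition, and regional rise/decay timing.

Units are screened for puff modulation by paired t-tests over canonical
window pairs (any uncorrected p < alpha flags the unit).  Modulated units'
trial-averaged peri-puff responses are clustered by a deterministic
PCA -> Ward pipeline (a reproducible stand-in for neighbor-graph embedding
clustering; downstream analyses depend only on archetype separation).
Regional composition is tested against an equal-probability categorical
null, and regional response timing is summarized as the time for the d'
trace to rise to, and decay back to, 25% of its peak.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binomtest, ttest_rel
from statsmodels.stats.multitest import multipletests

from ._seeding import substream
from .core import EventSchedule, PopulationActivity

__all__ = [
    "MODULATION_WINDOW_PAIRS",
    "significant_modulation",
    "peri_puff_means",
    "cluster_responses",
    "cluster_region_composition",
    "rise_decay_times",
    "rise_decay_from_trace",
    "dprime_vs_baseline",
]

#: Paired windows for the modulation screen, as (alignment, window) pairs.
#: alignment: "puff" = every puff; "first"/"last" = first/last puff of series.
MODULATION_WINDOW_PAIRS = [
    (("puff", (-1.0, 0.0)), ("puff", (0.0, 0.2))),
    (("puff", (-1.0, 0.0)), ("puff", (0.3, 0.8))),
    (("puff", (-1.0, 0.0)), ("puff", (1.0, 2.0))),
    (("first", (-1.0, 0.0)), ("last", (-1.0, 0.0))),
    (("first", (0.0, 1.0)), ("last", (0.0, 1.0))),
]


def _aligned_means(
    activity: PopulationActivity, sched: EventSchedule,
    alignment: str, window: tuple[float, float],
) -> np.ndarray:
    if alignment == "puff":
        onsets = sched.onsets
    elif alignment == "first":
        onsets = sched.series_starts()
    elif alignment == "last":
        onsets = sched.series_ends()
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    tensor = activity.peri_event(onsets, window)
    return tensor.mean(axis=2)  # (events, sites)


def significant_modulation(
    activity: PopulationActivity,
    schedule: EventSchedule,
    alpha: float = 0.01,
    conditions: tuple[str, ...] = ("pre",),
) -> np.ndarray:
    """Boolean per unit: any paired t-test over the canonical window pairs
    has uncorrected p < alpha.

    Per-puff pairs are paired across puff events; series pairs across series.
    Constant-rate (zero-variance-difference) comparisons never flag.
    """
    sched = schedule.select(np.isin(schedule.condition, conditions))
    if len(np.unique(sched.trial)) < 2:
        raise ValueError("need at least 2 trials for paired tests")
    flagged = np.zeros(activity.n_sites, dtype=bool)
    for (align_a, win_a), (align_b, win_b) in MODULATION_WINDOW_PAIRS:
        a = _aligned_means(activity, sched, align_a, win_a)
        b = _aligned_means(activity, sched, align_b, win_b)
        diffs = b - a
        import warnings
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # zero-variance comparisons are handled explicitly below
            warnings.simplefilter("ignore", category=RuntimeWarning)
            res = ttest_rel(b, a, axis=0)
        p = np.where(np.ptp(diffs, axis=0) == 0, 1.0, res.pvalue)
        p = np.nan_to_num(p, nan=1.0)
        flagged |= p < alpha
    return flagged


def peri_puff_means(
    activity: PopulationActivity,
    schedule: EventSchedule,
    window: tuple[float, float] = (-1.0, 2.0),
    baseline: tuple[float, float] = (-1.0, 0.0),
    conditions: tuple[str, ...] = ("pre",),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit mean peri-puff trace, baseline-subtracted.

    Averaged across all puffs of the given conditions; returns
    (times, traces) with traces shaped (units, bins).
    """
    sched = schedule.select(np.isin(schedule.condition, conditions))
    tensor = activity.peri_event(sched.onsets, window)
    times = activity.peri_event_times(window)
    traces = tensor.mean(axis=0)  # (units, bins)
    bsel = (times >= baseline[0]) & (times < baseline[1])
    return times, traces - traces[:, bsel].mean(axis=1, keepdims=True)


def _decay_to_frac_time(trace: np.ndarray, times: np.ndarray,
                        frac: float = 0.25) -> float:
    """Time for a cluster-mean trace to decay to ``frac`` of its peak."""
    post = times >= 0
    t_post, y = times[post], trace[post]
    i_peak = int(np.argmax(y))
    peak = y[i_peak]
    if peak <= 0:
        return float("inf")
    below = np.nonzero(y[i_peak:] <= frac * peak)[0]
    return float(t_post[i_peak + below[0]]) if len(below) else float("inf")


def cluster_responses(
    traces: np.ndarray,
    times: np.ndarray,
    k: int | None = None,
    k_grid: range = range(2, 9),
    n_pcs: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster per-unit peri-puff traces.

    Pipeline: per-unit z-score across the window -> PCA (<= ``n_pcs``
    components) -> Ward agglomerative clustering, with the cluster count
    chosen by silhouette over ``k_grid`` unless fixed.  Clusters are
    relabelled in order of the time for the cluster-mean activity to decay
    to 25% of its peak (fast-decaying clusters first).  Returns
    (labels, cluster_means).
    """
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    traces = np.asarray(traces, dtype=float)
    n_units = traces.shape[0]
    if n_units < 10:
        raise ValueError("refusing to cluster fewer than 10 units")
    sd = traces.std(axis=1, keepdims=True)
    z = (traces - traces.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)

    if np.allclose(z, z[0], atol=1e-12):
        # identical units: a single cluster is the only valid answer
        return np.zeros(n_units, dtype=int), traces.mean(axis=0, keepdims=True)

    n_comp = min(n_pcs, n_units - 1, z.shape[1])
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(z)

    if k is None:
        best_k, best_score = None, -np.inf
        for kk in k_grid:
            if kk >= n_units:
                continue
            labels = AgglomerativeClustering(n_clusters=kk, linkage="ward").fit_predict(pcs)
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(pcs, labels)
            if score > best_score:
                best_k, best_score = kk, score
        if best_k is None:
            return np.zeros(n_units, dtype=int), traces.mean(axis=0, keepdims=True)
        k = best_k
    if k == 1:
        return np.zeros(n_units, dtype=int), traces.mean(axis=0, keepdims=True)
    labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(pcs)

    means = np.vstack([traces[labels == c].mean(axis=0) for c in range(k)])
    decay = [_decay_to_frac_time(means[c], times) for c in range(k)]
    order = np.argsort(decay, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels], means[order]


def cluster_region_composition(
    labels: np.ndarray,
    regions: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(region, cluster) fraction with a binomial test against the
    equal-probability categorical null, BH-corrected across all tests."""
    labels = np.asarray(labels)
    regions = np.asarray(regions)
    clusters = np.unique(labels)
    k = len(clusters)
    rows = []
    for region in np.unique(regions):
        sel = regions == region
        n = int(sel.sum())
        for c in clusters:
            count = int(np.sum(labels[sel] == c))
            if k == 1:
                p = 1.0
            else:
                p = binomtest(count, n, 1.0 / k, alternative="two-sided").pvalue
            rows.append({"region": region, "cluster": int(c), "n_region": n,
                         "count": count, "fraction": count / n, "p": p})
    df = pd.DataFrame(rows)
    if len(df) and k > 1:
        rej, p_adj, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
        df["p_adj"] = p_adj
        df["flagged"] = rej
    else:
        df["p_adj"] = 1.0
        df["flagged"] = False
    return df


def dprime_vs_baseline(
    tensor: np.ndarray, times: np.ndarray, baseline: tuple[float, float] = (-1.0, 0.0)
) -> np.ndarray:
    """d' time series of a (replicates, bins) trace set against the per
    replicate baseline mean; combined-SD normalization sqrt(var_t + var_b)."""
    bsel = (times >= baseline[0]) & (times < baseline[1])
    base = tensor[:, bsel].mean(axis=1)
    mb, vb = base.mean(), base.var(ddof=1)
    mt = tensor.mean(axis=0)
    vt = tensor.var(axis=0, ddof=1)
    pooled = vt + vb
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (mt - mb) / np.sqrt(pooled)
    return np.where(pooled == 0, np.nan, d)


def rise_decay_from_trace(
    d: np.ndarray, times: np.ndarray, threshold_frac: float,
    min_peak: float, max_latency: float,
) -> tuple[float, float, float, float] | None:
    """(rise, decay, peak, latency) or None when the exclusion rules fire.

    Decay may be NaN (undefined-flagged) when the trace never falls back
    below threshold after its peak."""
    post = times >= 0
    t_post = times[post]
    y = np.nan_to_num(d[post], nan=-np.inf)
    i_peak = int(np.argmax(y))
    peak, latency = float(y[i_peak]), float(t_post[i_peak])
    if peak < min_peak or latency > max_latency:
        return None
    thr = threshold_frac * peak
    above = np.nonzero(y[: i_peak + 1] >= thr)[0]
    rise = float(t_post[above[0]])
    below = np.nonzero(y[i_peak:] <= thr)[0]
    decay = float(t_post[i_peak + below[0]]) if len(below) else float("nan")
    return rise, decay, peak, latency


def rise_decay_times(
    activity: PopulationActivity,
    schedule: EventSchedule,
    labels: np.ndarray,
    threshold_frac: float = 0.25,
    min_peak_dprime: float = 1.3,
    max_peak_latency: float = 0.75,
    window: tuple[float, float] = (-1.0, 2.5),
    n_boot: int = 1000,
    conditions: tuple[str, ...] = ("pre",),
    n_puffs_per_series: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Regional rise/decay times of puff-triggered d' traces.

    Uses the first ``n_puffs_per_series`` puffs of each series (largest
    rate excursions from baseline).  Within each region, units are averaged
    within response cluster; each cluster's d' trace yields rise (first time
    d' reaches 25% of peak) and decay (first time after the peak it falls
    back to 25%); regional values are cluster-fraction-weighted averages.
    Clusters with peak d' below ``min_peak_dprime`` or peak latency beyond
    ``max_peak_latency`` are excluded.  Percentile CIs come from
    bootstrapping puff replicates.
    """
    sched = schedule.select(
        np.isin(schedule.condition, conditions)
        & (schedule.puff_index < n_puffs_per_series)
    )
    tensor = activity.peri_event(sched.onsets, window)  # (reps, units, bins)
    times = activity.peri_event_times(window)
    regions = activity.sites["region"].to_numpy()
    labels = np.asarray(labels)
    rng = substream(seed, "rise_decay_bootstrap")

    def regional_values(rep_idx):
        vals = {}
        for region in np.unique(regions):
            entries = []
            for c in np.unique(labels[regions == region]):
                sel = (regions == region) & (labels == c)
                cluster_trace = tensor[rep_idx][:, sel, :].mean(axis=1)
                rd = rise_decay_from_trace(
                    dprime_vs_baseline(cluster_trace, times),
                    times, threshold_frac, min_peak_dprime, max_peak_latency,
                )
                if rd is not None:
                    entries.append((rd[0], rd[1], int(sel.sum())))
            if entries:
                wts = np.array([e[2] for e in entries], float)
                wts /= wts.sum()
                rise = float(np.sum(wts * [e[0] for e in entries]))
                decays = np.array([e[1] for e in entries])
                dw = wts[np.isfinite(decays)]
                decay = (float(np.sum(dw / dw.sum() * decays[np.isfinite(decays)]))
                         if dw.sum() > 0 else float("nan"))
                vals[region] = (rise, decay)
        return vals

    n_reps = tensor.shape[0]
    point = regional_values(np.arange(n_reps))
    boots: dict[str, list[tuple[float, float]]] = {r: [] for r in point}
    for _ in range(n_boot):
        idx = rng.integers(0, n_reps, n_reps)
        for r, v in regional_values(idx).items():
            if r in boots:
                boots[r].append(v)
    rows = []
    for region, (rise, decay) in point.items():
        b = np.array(boots[region]) if boots[region] else np.empty((0, 2))
        rows.append({
            "region": region, "rise_s": rise, "decay_s": decay,
            "rise_ci_lo": np.nanpercentile(b[:, 0], 2.5) if len(b) else np.nan,
            "rise_ci_hi": np.nanpercentile(b[:, 0], 97.5) if len(b) else np.nan,
            "decay_ci_lo": np.nanpercentile(b[:, 1], 2.5) if len(b) else np.nan,
            "decay_ci_hi": np.nanpercentile(b[:, 1], 97.5) if len(b) else np.nan,
        })
    return pd.DataFrame(rows)
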