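"""Population coding dimensions and projections.

A coding dimension assigns each site (iEEG channel band-power envelope or
single unit) a weight

    w_i = (mean_target_i - mean_reference_i) / sqrt(var_target_i + var_reference_i)

with means and variances taken across events, then normalizes the weight
vector (unit L2 norm for units, sum of absolute weights for channels).
Projections of population activity onto a dimension summarize the whole
population as one trace per event.  The emotion-like dimension contrasts
post-series with pre-series activity and is orthogonalized against the fast
per-puff response dimension so it cannot merely re-express the reflexive
response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EventSchedule, PopulationActivity

__all__ = [
    "CodingDimension",
    "coding_dimension",
    "orthogonalize",
    "project",
    "emotion_dimension",
    "dprime_trace",
]

#: Default training/quantification windows (seconds from event onset).
PUFF_PERSISTENT_TRAIN = (0.5, 1.0)
PUFF_PERSISTENT_QUANTIFY = (1.0, 2.0)
TONE_PERSISTENT_TRAIN = (0.15, 0.35)
TONE_PERSISTENT_QUANTIFY = (0.35, 0.5)
FAST_TRAIN = (0.0, 0.07)
REFERENCE_PREPUFF = (-1.0, 0.0)


@dataclass
class CodingDimension:
    weights: np.ndarray
    site_ids: list[str]
    target_window: tuple[float, float]
    reference_window: tuple[float, float]
    normalization: str  # "unit_norm" | "sum_abs"
    condition: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("coding dimension weights must be finite")

    def normalized(self) -> "CodingDimension":
        w = self.weights
        if self.normalization == "unit_norm":
            norm = np.linalg.norm(w)
        elif self.normalization == "sum_abs":
            norm = np.abs(w).sum()
        else:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if norm == 0:
            raise ValueError("degenerate coding dimension: all weights zero")
        return CodingDimension(w / norm, self.site_ids, self.target_window,
                               self.reference_window, self.normalization,
                               self.condition)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site_id": self.site_ids, "weight": self.weights})


def _window_stats(
    tensor: np.ndarray, times: np.ndarray, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Across-event mean and variance of per-event window means.

    ``tensor`` is (events, sites, bins)."""
    sel = (times >= window[0]) & (times < window[1])
    if not np.any(sel):
        raise ValueError(f"window {window} outside tensor extent")
    per_event = tensor[:, :, sel].mean(axis=2)  # (events, sites)
    return per_event.mean(axis=0), per_event.var(axis=0, ddof=1)


def coding_dimension(
    activity: PopulationActivity,
    onsets: np.ndarray,
    target: tuple[float, float],
    reference: tuple[float, float] = REFERENCE_PREPUFF,
    normalization: str = "unit_norm",
    condition: str = "",
) -> CodingDimension:
    """Discriminating dimension between a target and a reference window.

    Sites with zero pooled variance get weight zero; if every site is
    degenerate the dimension is undefined and an error is raised.
    """
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) < 2:
        raise ValueError("need at least 2 events to estimate variances")
    lo = min(target[0], reference[0])
    hi = max(target[1], reference[1])
    tensor = activity.peri_event(onsets, (lo, hi))
    times = activity.peri_event_times((lo, hi))
    mt, vt = _window_stats(tensor, times, target)
    mr, vr = _window_stats(tensor, times, reference)
    pooled = vt + vr
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (mt - mr) / np.sqrt(pooled)
    raw = np.where(pooled == 0, 0.0, raw)
    dim = CodingDimension(raw, list(activity.sites["site_id"]), tuple(target),
                          tuple(reference), normalization, condition)
    return dim.normalized()


def orthogonalize(dim: CodingDimension, nuisance: CodingDimension) -> CodingDimension:
    """Component of ``dim`` orthogonal to ``nuisance`` (Gram-Schmidt, the
    thin-QR second column), re-normalized under dim's convention."""
    if dim.site_ids != nuisance.site_ids:
        raise ValueError("dimensions are defined over different site sets")
    u = nuisance.weights
    denom = u @ u
    if denom == 0:
        raise ValueError("nuisance dimension is zero")
    residual = dim.weights - (dim.weights @ u) / denom * u
    if np.linalg.norm(residual) < 1e-10 * max(np.linalg.norm(dim.weights), 1e-300):
        raise ValueError("dimension is parallel to the nuisance dimension")
    out = CodingDimension(residual, dim.site_ids, dim.target_window,
                          dim.reference_window, dim.normalization, dim.condition)
    return out.normalized()


def project(
    activity: PopulationActivity,
    dim: CodingDimension,
    onsets: np.ndarray | None = None,
    window: tuple[float, float] = (-1.0, 3.0),
    zscore_window: tuple[float, float] | None = (-0.5, 1.5),
    baseline_window: tuple[float, float] | None = (-0.5, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Project activity onto a coding dimension.

    With ``onsets`` given, returns (times, projections) where projections is
    (events, bins) over ``window`` around each onset; each event trace is
    z-scored within ``zscore_window`` and baseline-subtracted over
    ``baseline_window`` (both half-open, relative seconds; pass None to
    skip).  Without onsets, returns the full-session projection time series
    (times, 1D trace) with no windowed post-processing.
    """
    ids = list(activity.sites["site_id"])
    if ids != dim.site_ids:
        raise ValueError(
            "site mismatch between activity and coding dimension "
            f"({len(ids)} vs {len(dim.site_ids)} sites); no silent subsetting"
        )
    if onsets is None:
        return activity.times, dim.weights @ activity.rates
    tensor = activity.peri_event(np.asarray(onsets, float), window)
    times = activity.peri_event_times(window)
    proj = np.einsum("s,esb->eb", dim.weights, tensor)
    if zscore_window is not None:
        sel = (times >= zscore_window[0]) & (times < zscore_window[1])
        mu = proj[:, sel].mean(axis=1, keepdims=True)
        sd = proj[:, sel].std(axis=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        proj = (proj - mu) / sd
    if baseline_window is not None:
        sel = (times >= baseline_window[0]) & (times < baseline_window[1])
        proj = proj - proj[:, sel].mean(axis=1, keepdims=True)
    return times, proj


def emotion_dimension(
    activity: PopulationActivity,
    schedule: EventSchedule,
    include: np.ndarray | None = None,
    condition: str = "pre",
    target_offset: float = 5.0,
    target_duration: float = 1.0,
    n_fast_trials: int = 4,
) -> CodingDimension:
    """Emotion-like neural dimension.

    Weights contrast a 1 s window starting ``target_offset`` seconds after
    the last puff of each training-condition series against a 750 ms window
    ending 250 ms before the first puff, then are orthogonalized against the
    fast per-puff dimension (built from the last ``n_fast_trials`` series,
    200 ms post vs 200 ms pre each puff) and unit-normalized.  ``include``
    restricts the population to puff-modulated sites (weights for excluded
    sites are reported as zero so the site set is preserved).
    """
    sub = activity
    if include is not None:
        include = np.asarray(include, dtype=bool)
        sub = PopulationActivity(
            activity.rates[include], activity.bin_width,
            activity.sites.loc[include].reset_index(drop=True), activity.t_start,
        )
    sched = schedule.for_condition(condition)
    first = sched.series_starts()
    last = sched.series_ends()
    # target: relative to the last puff of each series
    lo_t, hi_t = target_offset, target_offset + target_duration
    tensor_t = sub.peri_event(last, (lo_t, hi_t))
    per_event_t = tensor_t.mean(axis=2)
    # reference: relative to the first puff of each series
    tensor_r = sub.peri_event(first, (-1.0, -0.25))
    per_event_r = tensor_r.mean(axis=2)
    mt, vt = per_event_t.mean(axis=0), per_event_t.var(axis=0, ddof=1)
    mr, vr = per_event_r.mean(axis=0), per_event_r.var(axis=0, ddof=1)
    pooled = vt + vr
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (mt - mr) / np.sqrt(pooled)
    w = np.where(pooled == 0, 0.0, w)
    raw = CodingDimension(w, list(sub.sites["site_id"]), (lo_t, hi_t),
                          (-1.0, -0.25), "unit_norm", condition).normalized()

    # fast per-puff nuisance from the saturated tail of the training series
    trials = np.unique(sched.trial)
    fast_trials = trials[-n_fast_trials:]
    fast_onsets = sched.onsets[np.isin(sched.trial, fast_trials)]
    nuisance = coding_dimension(sub, fast_onsets, target=(0.0, 0.2),
                                reference=(-0.2, 0.0),
                                normalization="unit_norm", condition=condition)
    emo = orthogonalize(raw, nuisance)

    if include is None:
        return emo
    full = np.zeros(activity.n_sites)
    full[include] = emo.weights
    return CodingDimension(full, list(activity.sites["site_id"]),
                           emo.target_window, emo.reference_window,
                           "unit_norm", condition).normalized()


def dprime_trace(
    projections: np.ndarray,
    times: np.ndarray,
    baseline: float = 1.0,
) -> np.ndarray:
    """Detectability (d') per time bin of an (events, bins) projection.

    d'(t) = (mean_t - mean_baseline) / sqrt((var_t + var_baseline) / 2),
    across events; the baseline distribution is each event's mean over the
    ``baseline`` seconds preceding t = 0.  Bins with zero pooled variance
    are returned as NaN (flagged).
    """
    projections = np.asarray(projections, dtype=float)
    if projections.shape[0] < 2:
        raise ValueError("need at least 2 events")
    base_sel = (times >= -baseline) & (times < 0.0)
    if not np.any(base_sel):
        raise ValueError("baseline window outside trace extent")
    base = projections[:, base_sel].mean(axis=1)
    mb, vb = base.mean(), base.var(ddof=1)
    mt = projections.mean(axis=0)
    vt = projections.var(axis=0, ddof=1)
    pooled = (vt + vb) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (mt - mb) / np.sqrt(pooled)
    return np.where(pooled == 0, np.nan, d)
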