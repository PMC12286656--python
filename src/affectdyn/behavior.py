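"""Eye-closure quantification.

An eyepuff evokes a multiphasic eyelid response: a stereotyped reflexive
blink immediately after the puff, then a slower, variable "affective"
partial closure.  This module normalizes raw closure traces, summarizes the
early (reflexive) and late (affective) windows per trial, and produces
blink-masked per-condition mean traces suitable for fitting the two-phase
state model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import EventSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "EyeTrace",
    "ClosureSummary",
    "normalize_trace",
    "window_summary",
    "affective_series_trace",
    "summarize_trials",
]

#: Early (reflexive) and late (affective) closure windows, seconds after
#: puff onset, half-open.
EARLY_WINDOW = (0.1, 0.2)
LATE_WINDOW = (0.3, 0.8)


@dataclass
class EyeTrace:
    """Eye closure in [0, 1] on a fixed-rate time axis (seconds relative to
    trial start; the first puff of the series is at t = 0)."""

    time: np.ndarray
    closure: np.ndarray
    trial: int
    condition: str

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.closure = np.asarray(self.closure, dtype=float)
        if self.time.shape != self.closure.shape:
            raise ValueError("time and closure must have matching shapes")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.closure)):
            raise ValueError("closure trace contains non-finite values")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def window_mean(self, t0: float, t1: float) -> float:
        sel = (self.time >= t0) & (self.time < t1)
        if not np.any(sel):
            raise ValueError(f"window [{t0}, {t1}) outside trace extent")
        return float(self.closure[sel].mean())


@dataclass
class ClosureSummary:
    trial: int
    condition: str
    early_mean: float
    late_mean: float
    late_over_early: float | None  # None when undefined (early_mean <= 0)


def normalize_trace(
    trace: EyeTrace,
    baseline_window: tuple[float, float],
    reference_baseline: float,
) -> EyeTrace:
    """Baseline-subtract and rescale a raw closure trace.

    output = (closure - mean over baseline_window) / (1 - reference_baseline),
    where ``reference_baseline`` is the pre-trial baseline averaged across the
    first two trials of the session (when the eye is fully open).
    """
    if not (0.0 <= reference_baseline < 1.0):
        raise ValueError(
            f"reference_baseline={reference_baseline} degenerate; must be in [0, 1)"
        )
    base = trace.window_mean(*baseline_window)
    scaled = (trace.closure - base) / (1.0 - reference_baseline)
    return replace(trace, closure=scaled)


def window_summary(
    trace: EyeTrace,
    puff_onset: float,
    early: tuple[float, float] = EARLY_WINDOW,
    late: tuple[float, float] = LATE_WINDOW,
) -> ClosureSummary:
    """Early/late closure means around one puff, and their ratio.

    Windows are half-open [start, stop) in seconds relative to ``puff_onset``.
    The ratio is flagged undefined (None) when the early mean is not
    positive; callers drop such trials rather than propagate NaN.
    """
    e = trace.window_mean(puff_onset + early[0], puff_onset + early[1])
    l = trace.window_mean(puff_onset + late[0], puff_onset + late[1])
    ratio = l / e if e > 0 else None
    return ClosureSummary(trace.trial, trace.condition, e, l, ratio)


def summarize_trials(
    traces: list[EyeTrace],
    schedule: EventSchedule,
    puff_index: int = 0,
    exclude_first_trial: bool = True,
    early: tuple[float, float] = EARLY_WINDOW,
    late: tuple[float, float] = LATE_WINDOW,
) -> pd.DataFrame:
    """Per-trial early/late summary table for one puff of each series.

    The first trial of the session is excluded by default.  Trials with an
    undefined ratio are dropped with a logged count.
    """
    rows = []
    n_undefined = 0
    first_trial = int(schedule.trial.min())
    for trace in traces:
        if exclude_first_trial and trace.trial == first_trial:
            continue
        ev = schedule.select(
            (schedule.trial == trace.trial) & (schedule.puff_index == puff_index)
        )
        if len(ev) != 1:
            raise ValueError(f"trial {trace.trial} lacks puff {puff_index}")
        # onsets relative to the trial's series start
        series_start = schedule.select(
            (schedule.trial == trace.trial) & (schedule.puff_index == 0)
        ).onsets[0]
        s = window_summary(trace, ev.onsets[0] - series_start, early, late)
        if s.late_over_early is None:
            n_undefined += 1
            continue
        rows.append(
            {
                "trial": s.trial,
                "condition": s.condition,
                "early": s.early_mean,
                "late": s.late_mean,
                "ratio": s.late_over_early,
            }
        )
    if n_undefined:
        logger.info("dropped %d trials with undefined late/early ratio", n_undefined)
    return pd.DataFrame(rows)


def affective_series_trace(
    traces: list[EyeTrace],
    schedule: EventSchedule,
    blink_mask: float = 0.75,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Blink-masked mean closure trace per condition.

    Samples within ``blink_mask`` seconds after each puff onset are marked
    missing (NaN); remaining samples are averaged across trials within each
    condition.  Returns ``{condition: (time, masked_mean)}``, the input to
    the two-phase model fit.
    """
    by_condition: dict[str, list[np.ndarray]] = {}
    time_axis: dict[str, np.ndarray] = {}
    for trace in traces:
        ev = schedule.select(schedule.trial == trace.trial)
        if len(ev) == 0:
            raise ValueError(f"no events for trial {trace.trial}")
        rel_onsets = ev.onsets - ev.onsets[ev.puff_index == 0][0]
        masked = trace.closure.astype(float).copy()
        if blink_mask > 0:
            for onset in rel_onsets:
                masked[(trace.time >= onset) & (trace.time < onset + blink_mask)] = np.nan
        if np.all(np.isnan(masked)):
            raise ValueError("blink mask removed every sample of a trial")
        by_condition.setdefault(trace.condition, []).append(masked)
        time_axis[trace.condition] = trace.time
    out = {}
    for cond, stack in by_condition.items():
        arr = np.vstack(stack)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean = np.nanmean(arr, axis=0)
        if np.all(np.isnan(mean)):
            raise ValueError(f"condition {cond}: all samples masked")
        out[cond] = (time_axis[cond], mean)
    return out
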