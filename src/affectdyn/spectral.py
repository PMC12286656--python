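"""Multitaper peri-event spectrograms and band-limited power envelopes.

Spectrograms use DPSS (Slepian) tapers with taper count floor(2*TBW) - 1
(3 tapers at time-bandwidth 2).  Peri-event tensors are doubly z-scored:
first per frequency against a long session baseline, then per frequency
against a short pre-event baseline for each event, which isolates
puff-specific spectrotemporal structure from slow session-wide drifts.
Band envelopes are the squared magnitude of the analytic signal after a
zero-phase fifth-order Butterworth band-pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.signal.windows import dpss

from .core import EventSchedule

__all__ = [
    "BandDefinition",
    "BANDS",
    "PeriEventTensor",
    "multitaper_spectrogram",
    "double_zscore",
    "band_envelope",
    "band_phase",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low < self.high < fs / 2.0):
            raise ValueError(
                f"band {self.name} ({self.low}-{self.high} Hz) invalid for fs={fs}"
            )


#: Canonical frequency bands ("broadband" = unfiltered signal).
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
    "low_gamma": BandDefinition("low_gamma", 30.0, 50.0),
    "high_gamma": BandDefinition("high_gamma", 65.0, 95.0),
}


def band_table() -> pd.DataFrame:
    return pd.DataFrame(
        [(b.name, b.low, b.high) for b in BANDS.values()],
        columns=["name", "low_hz", "high_hz"],
    )


@dataclass
class PeriEventTensor:
    """(event, time, frequency) z-scored power with event metadata."""

    values: np.ndarray
    times: np.ndarray  # seconds relative to event onset
    freqs: np.ndarray
    events: pd.DataFrame  # trial, puff_index, condition per event
    channel: str = ""
    excluded_freqs: np.ndarray | None = None

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("tensor values must be (event, time, frequency)")
        if np.any(np.diff(self.times) <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("axes must be strictly increasing")

    def select_events(self, mask: np.ndarray) -> "PeriEventTensor":
        return PeriEventTensor(
            self.values[mask], self.times, self.freqs,
            self.events.loc[mask].reset_index(drop=True), self.channel,
            self.excluded_freqs,
        )


from functools import lru_cache


@lru_cache(maxsize=16)
def _dpss_cached(n_win: int, time_bandwidth: float, n_tapers: int) -> np.ndarray:
    return dpss(n_win, time_bandwidth, Kmax=n_tapers)


def multitaper_spectrogram(
    signal: np.ndarray,
    fs: float,
    time_bandwidth: float = 2.0,
    window: float = 0.4,
    stride: float = 0.05,
    fmin: float = 1.0,
    fmax: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding multitaper power estimate.

    Returns (times, freqs, power) with ``times`` the window centers and
    ``power`` shaped (n_windows, n_freqs).  Each window is mean-detrended,
    tapered with floor(2*TBW) - 1 DPSS tapers, and the taper periodograms
    averaged.
    """
    signal = np.asarray(signal, dtype=float)
    n_win = int(round(window * fs))
    n_stride = int(round(stride * fs))
    if n_win < 8:
        raise ValueError("window too short: need window*fs >= 8 samples")
    if n_stride > n_win:
        raise ValueError("stride must not exceed window")
    if len(signal) < n_win:
        raise ValueError("signal shorter than one window")
    n_tapers = int(np.floor(2 * time_bandwidth)) - 1
    if n_tapers < 1:
        raise ValueError("time_bandwidth too small for any taper")
    tapers = _dpss_cached(n_win, float(time_bandwidth), n_tapers)  # (K, n_win)

    starts = np.arange(0, len(signal) - n_win + 1, n_stride)
    idx = starts[:, None] + np.arange(n_win)[None, :]
    segments = signal[idx]  # (n_windows, n_win)
    segments = segments - segments.mean(axis=1, keepdims=True)
    # (n_windows, K, n_win) -> periodograms averaged over tapers
    tapered = segments[:, None, :] * tapers[None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    power = (np.abs(spec) ** 2).mean(axis=1) * (2.0 / (fs * n_win))
    freqs = np.fft.rfftfreq(n_win, 1.0 / fs)
    sel = (freqs >= fmin) & (freqs <= fmax)
    times = (starts + n_win / 2.0) / fs
    return times, freqs[sel], power[:, sel]


def double_zscore(
    times: np.ndarray,
    freqs: np.ndarray,
    power: np.ndarray,
    schedule: EventSchedule,
    session_baseline: tuple[float, float],
    per_event_baseline: float = 1.5,
    event_window: tuple[float, float] = (-0.5, 1.5),
    channel: str = "",
) -> PeriEventTensor:
    """Double z-scoring of a spectrogram into a peri-event tensor.

    Per frequency: z-score against the session baseline epoch (canonically
    the 2 minutes preceding the assay); then cut a window around every event
    and z-score per frequency against that event's ``per_event_baseline``
    seconds pre-onset.  Frequencies with zero baseline variance are flagged
    and excluded (NaN).
    """
    power = np.asarray(power, dtype=float)
    sb = (times >= session_baseline[0]) & (times < session_baseline[1])
    if not np.any(sb):
        raise ValueError("session baseline epoch not covered by spectrogram")
    mu = power[sb].mean(axis=0)
    sd = power[sb].std(axis=0)
    bad = sd == 0
    sd_safe = np.where(bad, 1.0, sd)
    z1 = (power - mu) / sd_safe
    z1[:, bad] = np.nan

    dt = float(np.median(np.diff(times)))
    cut0, cut1 = -float(per_event_baseline), float(event_window[1])
    n_bins = int(round((cut1 - cut0) / dt))
    rel = cut0 + np.arange(n_bins) * dt
    tensors = np.empty((len(schedule), n_bins, len(freqs)))
    for k, onset in enumerate(schedule.onsets):
        i0 = int(np.searchsorted(times, onset + cut0 - dt / 2))
        if i0 < 0 or i0 + n_bins > len(times):
            raise ValueError(f"baseline/window for event at t={onset} not covered")
        tensors[k] = z1[i0:i0 + n_bins]
    base = rel < 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mu2 = np.nanmean(tensors[:, base, :], axis=1, keepdims=True)
        sd2 = np.nanstd(tensors[:, base, :], axis=1, keepdims=True)
    bad2 = np.squeeze(sd2, axis=1) == 0  # (event, freq)
    sd2 = np.where(sd2 == 0, 1.0, sd2)
    z2 = (tensors - mu2) / sd2
    z2[np.broadcast_to(bad2[:, None, :], z2.shape)] = np.nan

    keep = (rel >= event_window[0]) & (rel < event_window[1])
    return PeriEventTensor(
        values=z2[:, keep, :],
        times=rel[keep],
        freqs=np.asarray(freqs, dtype=float),
        events=pd.DataFrame(
            {
                "trial": schedule.trial,
                "puff_index": schedule.puff_index,
                "condition": schedule.condition,
            }
        ),
        channel=channel,
        excluded_freqs=np.asarray(freqs)[bad] if np.any(bad) else None,
    )


def _band_sos(band: BandDefinition, fs: float):
    return butter(5, [band.low, band.high], btype="bandpass", fs=fs, output="sos")


def band_envelope(
    signal: np.ndarray,
    band: BandDefinition,
    fs: float,
    zscore_epoch: tuple[float, float] | None = None,
) -> np.ndarray:
    """Band-limited power envelope: |analytic signal|^2 after a zero-phase
    (forward-backward) fifth-order Butterworth band-pass.  If
    ``zscore_epoch`` (seconds) is given, the envelope is z-scored over that
    epoch (canonically a 20-minute epoch starting 10 min before the assay)."""
    band.validate(fs)
    filtered = sosfiltfilt(_band_sos(band, fs), np.asarray(signal, dtype=float))
    env = np.abs(hilbert(filtered)) ** 2
    if zscore_epoch is not None:
        i0, i1 = (int(round(t * fs)) for t in zscore_epoch)
        ref = env[max(i0, 0):i1]
        if ref.size == 0 or ref.std() == 0:
            raise ValueError("degenerate z-scoring epoch for band envelope")
        env = (env - ref.mean()) / ref.std()
    return env


def band_phase(signal: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Instantaneous phase of the band-limited analytic signal (zero-phase
    filtering preserves phase)."""
    band.validate(fs)
    filtered = sosfiltfilt(_band_sos(band, fs), np.asarray(signal, dtype=float))
    return np.angle(hilbert(filtered))
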