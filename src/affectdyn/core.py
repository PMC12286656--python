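"""Shared data containers: event schedules and population activity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EventSchedule", "PopulationActivity"]


@dataclass
class EventSchedule:
    """Stimulus events grouped into series (trials) with condition labels.

    onsets are absolute session times in seconds and strictly increasing;
    each event carries its trial index, its position within the puff series,
    and the condition label of its trial.
    """

    onsets: np.ndarray
    durations: np.ndarray
    trial: np.ndarray
    puff_index: np.ndarray
    condition: np.ndarray

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.trial = np.asarray(self.trial, dtype=int)
        self.puff_index = np.asarray(self.puff_index, dtype=int)
        self.condition = np.asarray(self.condition, dtype=object)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.condition:
            if c not in seen:
                seen.append(c)
        return seen

    def select(self, mask: np.ndarray) -> "EventSchedule":
        return EventSchedule(
            self.onsets[mask], self.durations[mask], self.trial[mask],
            self.puff_index[mask], self.condition[mask],
        )

    def for_condition(self, condition: str) -> "EventSchedule":
        return self.select(self.condition == condition)

    def series_starts(self, condition: str | None = None) -> np.ndarray:
        """Onset of the first puff of each series (optionally one condition)."""
        sched = self if condition is None else self.for_condition(condition)
        return sched.onsets[sched.puff_index == 0]

    def series_ends(self, condition: str | None = None) -> np.ndarray:
        """Onset of the last puff of each series."""
        sched = self if condition is None else self.for_condition(condition)
        last = sched.puff_index == sched.puff_index.max()
        return sched.onsets[last]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onsets,
                "duration_s": self.durations,
                "trial": self.trial,
                "puff_index": self.puff_index,
                "condition": self.condition,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventSchedule":
        return cls(
            df["onset_s"].to_numpy(), df["duration_s"].to_numpy(),
            df["trial"].to_numpy(), df["puff_index"].to_numpy(),
            df["condition"].to_numpy(),
        )

    @classmethod
    def read_csv(cls, path) -> "EventSchedule":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class PopulationActivity:
    """Sites x time matrix of rates or band power with site metadata.

    ``rates[i, j]`` is the activity of site i in the bin starting at
    ``t_start + j * bin_width``.  Sites carry an id and a region label; the
    same container serves binned unit firing rates (mouse) and band-power
    envelopes (human channels).
    """

    rates: np.ndarray
    bin_width: float
    sites: pd.DataFrame
    t_start: float = 0.0

    def __post_init__(self):
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if len(self.sites) != self.rates.shape[0]:
            raise ValueError("site metadata does not match rate matrix")

    @property
    def n_sites(self) -> int:
        return self.rates.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.rates.shape[1]) * self.bin_width

    def time_slice(self, t0: float, t1: float) -> np.ndarray:
        """Column indices for the half-open window [t0, t1)."""
        i0 = int(np.ceil((t0 - self.t_start) / self.bin_width - 1e-9))
        i1 = int(np.ceil((t1 - self.t_start) / self.bin_width - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.rates.shape[1])
        if i1 <= i0:
            raise ValueError(f"window [{t0}, {t1}) outside recording")
        return np.arange(i0, i1)

    def window_mean(self, t0: float, t1: float) -> np.ndarray:
        """Per-site mean over [t0, t1)."""
        return self.rates[:, self.time_slice(t0, t1)].mean(axis=1)

    def peri_event(self, onsets: np.ndarray, window: tuple[float, float]) -> np.ndarray:
        """Cut aligned windows: (events, sites, bins) for ``window`` around
        each onset (half-open, relative seconds)."""
        n_bins = int(round((window[1] - window[0]) / self.bin_width))
        out = np.empty((len(onsets), self.n_sites, n_bins))
        for k, onset in enumerate(np.asarray(onsets, float)):
            i0 = int(np.floor((onset + window[0] - self.t_start) / self.bin_width + 1e-9))
            if i0 < 0 or i0 + n_bins > self.rates.shape[1]:
                raise ValueError(f"peri-event window around t={onset} outside recording")
            out[k] = self.rates[:, i0:i0 + n_bins]
        return out

    def peri_event_times(self, window: tuple[float, float]) -> np.ndarray:
        n_bins = int(round((window[1] - window[0]) / self.bin_width))
        return window[0] + np.arange(n_bins) * self.bin_width
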