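"""HDF5 persistence for continuous signals, binned rates, and peri-event
tensors (axes and acquisition parameters stored as attributes)."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .core import PopulationActivity
from .spectral import PeriEventTensor

__all__ = [
    "save_activity", "load_activity",
    "save_lfp", "load_lfp",
    "save_tensor", "load_tensor",
]


def save_activity(path, activity: PopulationActivity) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("rates", data=activity.rates)
        d.attrs["bin_width"] = activity.bin_width
        d.attrs["t_start"] = activity.t_start
        for col in activity.sites.columns:
            f.create_dataset(
                f"sites/{col}",
                data=np.asarray(activity.sites[col]).astype("S"))


def load_activity(path) -> PopulationActivity:
    with h5py.File(path, "r") as f:
        d = f["rates"]
        sites = pd.DataFrame({
            col: [v.decode() for v in f[f"sites/{col}"][()]]
            for col in f["sites"]
        })
        return PopulationActivity(
            rates=d[()], bin_width=float(d.attrs["bin_width"]),
            sites=sites, t_start=float(d.attrs["t_start"]))


def save_lfp(path, lfp: np.ndarray, fs: float,
             channel_regions: list[str] | None = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("lfp", data=lfp)
        d.attrs["fs"] = fs
        if channel_regions is not None:
            f.create_dataset("channel_regions",
                             data=np.asarray(channel_regions, dtype="S"))


def load_lfp(path) -> tuple[np.ndarray, float, list[str] | None]:
    with h5py.File(path, "r") as f:
        d = f["lfp"]
        regions = ([v.decode() for v in f["channel_regions"][()]]
                   if "channel_regions" in f else None)
        return d[()], float(d.attrs["fs"]), regions


def save_tensor(path, tensor: PeriEventTensor) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=tensor.values)
        d.attrs["channel"] = tensor.channel
        f.create_dataset("times", data=tensor.times)
        f.create_dataset("freqs", data=tensor.freqs)
        f.create_dataset("events/trial", data=tensor.events["trial"].to_numpy())
        f.create_dataset("events/puff_index",
                         data=tensor.events["puff_index"].to_numpy())
        f.create_dataset(
            "events/condition",
            data=tensor.events["condition"].to_numpy().astype("S"))
        if tensor.excluded_freqs is not None:
            f.create_dataset("excluded_freqs", data=tensor.excluded_freqs)


def load_tensor(path) -> PeriEventTensor:
    with h5py.File(path, "r") as f:
        events = pd.DataFrame({
            "trial": f["events/trial"][()],
            "puff_index": f["events/puff_index"][()],
            "condition": np.array([v.decode() for v in f["events/condition"][()]],
                                  dtype=object),
        })
        excluded = f["excluded_freqs"][()] if "excluded_freqs" in f else None
        return PeriEventTensor(
            values=f["values"][()], times=f["times"][()], freqs=f["freqs"][()],
            events=events, channel=str(f["values"].attrs["channel"]),
            excluded_freqs=excluded)
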