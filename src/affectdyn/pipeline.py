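"""Configuration-driven orchestration of the synthetic end-to-end pipeline.

A PipelineConfig (YAML file or plain dict) selects stages and overrides
per-stage parameters; ``run_pipeline`` executes the requested stages in
dependency order on one seeded synthetic session and writes tables (CSV) and
metadata (JSON) under the output directory.  Every output bundle embeds the
seed, the config hash, and the package version, and the log reports
per-stage counts (events, sites, exclusions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import behavior, dimensions, dynamics, factors, netstate, oscillations
from . import permcluster, spiking, synth
from .spectral import double_zscore, multitaper_spectrogram

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

#: Stage execution order (dependencies run first).
STAGES = ("synth", "behavior", "spectral", "factors", "permcluster",
          "dimensions", "spiking", "dynamics", "netstate", "oscillations")

_STAGE_DEPS = {
    "behavior": ("synth",),
    "spectral": ("synth",),
    "factors": ("spectral",),
    "permcluster": ("spectral",),
    "dimensions": ("synth",),
    "spiking": ("synth",),
    "dynamics": ("behavior",),
    "netstate": ("synth", "dimensions"),
    "oscillations": ("synth",),
}

_DEFAULTS: dict[str, dict[str, Any]] = {
    "synth": {
        "n_trials_pre": 6, "n_trials_post": 6, "n_trials_recovery": 4,
        "n_units": 50, "n_channels": 12, "bin_width": 0.01,
        "rate_noise_sd": 1.0, "eye_noise_sd": 0.02, "lfp_fs": 200.0,
        "tau_persist": {"pre": 10.0, "drug": 1.0, "post": 8.0},
    },
    "behavior": {"blink_mask": 0.75},
    "spectral": {"n_channels_used": 4, "event_window": [-0.5, 1.5]},
    "factors": {"k_grid": [2, 4, 6, 8], "window": [0.0, 1.4]},
    "permcluster": {"n_perm": 500, "forming_alpha": 0.01},
    "dimensions": {},
    "spiking": {"n_boot": 200},
    "dynamics": {"n_starts": 6},
    "netstate": {"band": "beta", "top_percentile": 90.0},
    "oscillations": {"segment_length": 60.0, "psd_window": 10.0,
                     "psd_stride": 5.0, "tbw": 4.0},
}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        unknown = set(self.params) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown parameter sections: {sorted(unknown)}")
        for stage, overrides in self.params.items():
            bad = set(overrides) - set(_DEFAULTS[stage])
            if bad:
                raise ValueError(f"unknown keys in [{stage}]: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {"seed", "output_dir", "stages", "params"}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(**raw)

    def stage_params(self, stage: str) -> dict[str, Any]:
        merged = dict(_DEFAULTS[stage])
        merged.update(self.params.get(stage, {}))
        return merged

    def hash(self) -> str:
        blob = json.dumps(
            {"seed": self.seed, "stages": self.stages, "params": self.params},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | Mapping[str, Any]) -> dict[str, Any]:
    """Execute the requested stages in dependency order.

    Returns the in-memory result bundle; tables are also written under the
    configured output directory with a metadata stamp.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(**config)
    for stage in config.stages:
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in config.stages:
                raise ValueError(f"stage {stage!r} requires {dep!r} to run first")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    for stage in STAGES:
        if stage in config.stages:
            logger.info("running stage %s", stage)
            _RUNNERS[stage](config, results, outdir)
    meta = {"seed": config.seed, "config_hash": config.hash(),
            "version": __version__, "stages": config.stages}
    (outdir / "pipeline_meta.json").write_text(json.dumps(meta, indent=1))
    results["meta"] = meta
    return results


# ---------------------------------------------------------------------------
# Stage runners


def _run_synth(config, results, outdir):
    p = config.stage_params("synth")
    seed = config.seed
    truth = synth.default_ground_truth(
        seed=seed, n_units=p["n_units"], n_channels=p["n_channels"],
        tau_persist=dict(p["tau_persist"]),
    )
    schedule = synth.make_event_schedule(
        n_trials_pre=p["n_trials_pre"], n_trials_post=p["n_trials_post"],
        n_trials_recovery=p["n_trials_recovery"], seed=seed,
    )
    activity = synth.simulate_population(schedule, truth,
                                         bin_width=p["bin_width"],
                                         noise_sd=p["rate_noise_sd"])
    eyes = synth.simulate_eye_trace(schedule, truth, noise_sd=p["eye_noise_sd"])
    lfp = synth.simulate_lfp(schedule, truth, fs=p["lfp_fs"])
    schedule.write_csv(outdir / "events.csv")
    truth.to_json(outdir / "ground_truth.json")
    logger.info("synth: %d events, %d units, %d channels",
                len(schedule), activity.n_sites, truth.n_channels)
    results["synth"] = {"truth": truth, "schedule": schedule,
                        "activity": activity, "eyes": eyes, "lfp": lfp,
                        "lfp_fs": p["lfp_fs"]}


def _run_behavior(config, results, outdir):
    p = config.stage_params("behavior")
    s = results["synth"]
    table = behavior.summarize_trials(s["eyes"], s["schedule"])
    table.to_csv(outdir / "closure_summary.csv", index=False)
    affective = behavior.affective_series_trace(s["eyes"], s["schedule"],
                                                blink_mask=p["blink_mask"])
    results["behavior"] = {"summary": table, "affective": affective}


def _run_spectral(config, results, outdir):
    p = config.stage_params("spectral")
    s = results["synth"]
    fs = s["lfp_fs"]
    schedule, lfp = s["schedule"], s["lfp"]
    baseline = (schedule.onsets[0] - 130.0, schedule.onsets[0] - 10.0)
    tensors = {}
    for ch in range(min(p["n_channels_used"], lfp.shape[0])):
        times, freqs, power = multitaper_spectrogram(lfp[ch], fs)
        tensors[f"ch{ch:02d}"] = double_zscore(
            times, freqs, power, schedule, session_baseline=baseline,
            event_window=tuple(p["event_window"]), channel=f"ch{ch:02d}",
        )
    results["spectral"] = {"tensors": tensors}


def _run_factors(config, results, outdir):
    p = config.stage_params("factors")
    tensors = results["spectral"]["tensors"]
    train, test, channels, tf_shape, split = factors.build_response_matrix(
        tensors, window=tuple(p["window"]))
    curve, k = factors.select_k(train, test, p["k_grid"], seed=config.seed)
    fset = factors.fit_sign_split_nmf(train, (k + 1) // 2, max(k // 2, 1),
                                      seed=config.seed, channels=channels,
                                      tf_shape=tf_shape)
    contrasts = factors.compare_loadings(fset, tensors, split, seed=config.seed)
    curve.to_csv(outdir / "nmf_ev_curve.csv", index=False)
    contrasts.to_csv(outdir / "nmf_loading_contrasts.csv", index=False)
    results["factors"] = {"factorset": fset, "curve": curve, "k": k,
                          "contrasts": contrasts, "split": split}


def _run_permcluster(config, results, outdir):
    p = config.stage_params("permcluster")
    tensors = results["spectral"]["tensors"]
    region_results = []
    for ch, tensor in tensors.items():
        pre = tensor.select_events((tensor.events["condition"] == "pre").to_numpy())
        drug = tensor.select_events((tensor.events["condition"] == "drug").to_numpy())
        n = min(pre.values.shape[0], drug.values.shape[0])
        diff = np.nan_to_num(drug.values[:n] - pre.values[:n])
        region_results.append(permcluster.paired_cluster_test(
            diff, forming_alpha=p["forming_alpha"], n_perm=p["n_perm"],
            seed=config.seed, region=ch,
        ))
    flagged = permcluster.fdr_across_regions(region_results)
    rows = [{"region": r.region, "min_p": r.min_p,
             "n_clusters": len(r.clusters),
             "flagged": r.region in flagged} for r in region_results]
    pd.DataFrame(rows).to_csv(outdir / "cluster_tests.csv", index=False)
    results["permcluster"] = {"results": region_results, "flagged": flagged}


def _run_dimensions(config, results, outdir):
    s = results["synth"]
    activity, schedule, truth = s["activity"], s["schedule"], s["truth"]
    modulated = spiking.significant_modulation(activity, schedule)
    logger.info("dimensions: %d/%d units puff-modulated",
                int(modulated.sum()), activity.n_sites)
    # train on first-puff events: later puffs carry the accumulated state,
    # which would dominate the event-to-event variance term of the weights
    persistent = dimensions.coding_dimension(
        activity, schedule.series_starts("pre"),
        target=dimensions.PUFF_PERSISTENT_TRAIN, normalization="unit_norm")
    emotion = dimensions.emotion_dimension(activity, schedule, include=modulated)
    emotion.to_frame().to_csv(outdir / "emotion_dimension.csv", index=False)
    projections = {}
    for cond in schedule.conditions:
        t, proj = dimensions.project(activity, persistent,
                                     schedule.for_condition(cond).onsets)
        projections[cond] = (t, proj)
    results["dimensions"] = {"modulated": modulated, "persistent": persistent,
                             "emotion": emotion, "projections": projections}


def _run_spiking(config, results, outdir):
    p = config.stage_params("spiking")
    s = results["synth"]
    activity, schedule = s["activity"], s["schedule"]
    modulated = results["dimensions"]["modulated"] if "dimensions" in results \
        else spiking.significant_modulation(activity, schedule)
    sub = activity.rates[modulated]
    from .core import PopulationActivity
    subact = PopulationActivity(sub, activity.bin_width,
                                activity.sites.loc[modulated].reset_index(drop=True),
                                activity.t_start)
    times, traces = spiking.peri_puff_means(subact, schedule)
    labels, means = spiking.cluster_responses(traces, times, seed=config.seed)
    comp = spiking.cluster_region_composition(labels,
                                              subact.sites["region"].to_numpy())
    timing = spiking.rise_decay_times(subact, schedule, labels,
                                      n_boot=p["n_boot"], seed=config.seed)
    comp.to_csv(outdir / "cluster_region_composition.csv", index=False)
    timing.to_csv(outdir / "rise_decay_times.csv", index=False)
    results["spiking"] = {"labels": labels, "cluster_means": means,
                          "composition": comp, "timing": timing}


def _run_dynamics(config, results, outdir):
    p = config.stage_params("dynamics")
    affective = results["behavior"]["affective"]
    intervals, _ = dynamics.puff_train_schedule()
    traces = {}
    for cond in ("pre", "drug"):
        t, y = affective[cond]
        sel = t >= -1e-6
        traces[cond] = y[sel]
    dt = float(np.median(np.diff(affective["pre"][0])))
    fit = dynamics.fit(traces, dt, intervals, free=("tau_persist",),
                       n_starts=p["n_starts"], seed=config.seed)
    null = dynamics.fit(traces, dt, intervals, free=(),
                        n_starts=p["n_starts"], seed=config.seed)
    n_t = len(traces["pre"])
    ev = dynamics.variance_explained(
        traces, dynamics.predict(fit, dt, n_t, intervals),
        dynamics.predict(null, dt, n_t, intervals))
    out = {"params": fit.params, "variance_explained": ev,
           "at_bound": fit.at_bound}
    (outdir / "model_fit.json").write_text(json.dumps(out, indent=1))
    results["dynamics"] = {"fit": fit, "null": null, "ev": ev}


def _run_netstate(config, results, outdir):
    p = config.stage_params("netstate")
    s = results["synth"]
    activity, schedule = s["activity"], s["schedule"]
    persistent = results["dimensions"]["persistent"]
    rows = []
    windows = {}
    for cond in ("pre", "drug"):
        starts = schedule.series_starts(cond)
        spans = [(t0 - 30.0, t0) for t0 in starts if t0 - 30.0 >= activity.t_start]
        windows[cond] = spans
        taus = []
        for (t0, t1) in spans:
            seg = activity.rates[:, activity.time_slice(t0, t1)]
            series = persistent.weights @ seg
            fit = netstate.intrinsic_timescale(series, activity.bin_width)
            if fit.converged and not fit.flagged:
                taus.append(fit.b)
        rows.append({"condition": cond, "intrinsic_timescale_s": np.mean(taus)
                     if taus else np.nan, "n_windows": len(taus)})
    coupling = netstate.pairwise_correlations(activity, windows)
    change, members = netstate.subnetwork_coupling_change(
        coupling, persistent, top_percentile=p["top_percentile"])
    pd.DataFrame(rows).to_csv(outdir / "intrinsic_timescale.csv", index=False)
    results["netstate"] = {"timescales": pd.DataFrame(rows),
                           "coupling_change": change, "members": members}


def _run_oscillations(config, results, outdir):
    p = config.stage_params("oscillations")
    s = results["synth"]
    schedule, lfp, fs = s["schedule"], s["lfp"], s["lfp_fs"]
    ch = 0
    pre_end = schedule.for_condition("pre").onsets[-1]
    drug_sched = schedule.for_condition("drug")
    seg_kwargs = dict(fs=fs, tbw=p["tbw"], window=p["psd_window"],
                      stride=p["psd_stride"], segment_length=p["segment_length"])
    base_sig = lfp[ch][: int(pre_end * fs)]
    drug_sig = lfp[ch][int(drug_sched.onsets[0] * fs):
                       int((drug_sched.onsets[-1]) * fs)]
    segments = {
        "baseline": oscillations.aperiodic_removed_psd(base_sig, **seg_kwargs),
        "drug": oscillations.aperiodic_removed_psd(drug_sig, **seg_kwargs),
    }
    clusters = oscillations.detect_and_cluster_peaks(segments)
    unique = oscillations.drug_unique_peaks(clusters["baseline"], clusters["drug"])
    unique.to_csv(outdir / "drug_unique_oscillations.csv", index=False)
    results["oscillations"] = {"clusters": clusters, "unique": unique}


_RUNNERS = {
    "synth": _run_synth,
    "behavior": _run_behavior,
    "spectral": _run_spectral,
    "factors": _run_factors,
    "permcluster": _run_permcluster,
    "dimensions": _run_dimensions,
    "spiking": _run_spiking,
    "dynamics": _run_dynamics,
    "netstate": _run_netstate,
    "oscillations": _run_oscillations,
}
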