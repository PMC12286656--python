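"""Seeded synthetic sessions with stored ground truth.

Emulates the structure of a cross-species eyepuff session so that every
downstream analysis stage is testable against known planted structure:

* an event schedule of puff series (8 x 250 ms at 3 s intervals per trial,
  20 trials before and 20 after "drug" onset, 45-90 s between trials);
* a population of units drawn from response archetypes (fast-transient,
  fast-persistent, delayed-persistent, suppressed, unmodulated) whose
  persistence time constant follows the condition-specific tau_persist of
  the two-phase model;
* multichannel 1/f LFP surrogate with planted band-limited oscillations
  (condition-gated), planted evoked spectrotemporal factors, and
  phase-coupled channel pairs;
* eye-closure traces = two-phase-model affective component + stereotyped
  reflexive blink kernel + noise, clipped to [0, 1].

Everything is a pure function of (config, seed); identical inputs give
bit-identical outputs via named substreams (see _seeding).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from ._seeding import substream
from .behavior import EyeTrace
from .core import EventSchedule, PopulationActivity
from .dynamics import BiphasicParams, evaluate

__all__ = [
    "ARCHETYPES",
    "KernelSpec",
    "PlantedFactor",
    "PlantedOscillation",
    "CoupledPair",
    "GroundTruth",
    "make_event_schedule",
    "default_ground_truth",
    "archetype_kernel",
    "simulate_population",
    "simulate_lfp",
    "simulate_eye_trace",
]


# ---------------------------------------------------------------------------
# Ground truth record


@dataclass(frozen=True)
class KernelSpec:
    """Piecewise two-phase unit response kernel.

    Zero until ``latency``; saturating rise (1 - exp(-t/rise_tau)) for
    ``rise_duration`` seconds; then exact exponential decay with
    ``decay_tau`` (None = use the condition's tau_persist).  ``sign`` = -1
    for suppressed units.  The pure-exponential decay phase makes rise and
    decay times closed-form checkable.
    """

    latency: float
    rise_tau: float
    rise_duration: float
    decay_tau: float | None
    sign: int = 1


#: Default archetype kernels.  Persistent archetypes inherit their decay
#: constant from the condition-specific tau_persist of the ground truth.
ARCHETYPES: dict[str, KernelSpec | None] = {
    "fast_transient": KernelSpec(0.02, 0.03, 0.25, 0.04),
    "fast_persistent": KernelSpec(0.02, 0.05, 0.25, None),
    "delayed_persistent": KernelSpec(0.25, 0.25, 0.75, None),
    "suppressed": KernelSpec(0.05, 0.08, 0.20, 0.10, sign=-1),
    "unmodulated": None,
}


@dataclass(frozen=True)
class PlantedFactor:
    """Evoked spectrotemporal template: band-limited power change in a time
    window after each puff, scaled per channel by ``loadings``."""

    name: str
    band: tuple[float, float]
    window: tuple[float, float]  # seconds relative to puff onset
    sign: int  # +1 power increase, -1 power decrease
    amplitude: float
    loadings: tuple[float, ...]


@dataclass(frozen=True)
class PlantedOscillation:
    """Narrowband oscillation gated by condition membership."""

    freq: float
    bandwidth: float
    amplitude: float
    conditions: tuple[str, ...]
    channels: tuple[int, ...] | None = None


@dataclass(frozen=True)
class CoupledPair:
    """Channels i and j share a narrowband component with a fixed phase lag;
    ``condition_gain`` optionally scales the shared component per condition."""

    i: int
    j: int
    freq: float
    bandwidth: float
    lag_rad: float
    amplitude: float = 1.0
    condition_gain: tuple[tuple[str, float], ...] | None = None


@dataclass
class GroundTruth:
    """Everything planted into one synthetic session, recoverable downstream.

    Persistent units additionally carry slow baseline rate fluctuations:
    an Ornstein-Uhlenbeck latent with condition-specific timescale
    ``intrinsic_timescale``, mixed between a component shared across the
    persistent subnetwork (weight ``coupling_gain``, condition-specific)
    and private components, so that both the baseline intrinsic timescale
    and the within-subnetwork coupling are planted, condition-dependent
    quantities.
    """

    model_params: BiphasicParams
    units: pd.DataFrame  # unit_id, archetype, region, baseline, amplitude
    planted_factors: list[PlantedFactor]
    planted_oscillations: list[PlantedOscillation]
    coupled_pairs: list[CoupledPair]
    n_channels: int
    channel_regions: list[str]
    chi: float
    seed: int
    intrinsic_timescale: dict[str, float] = field(
        default_factory=lambda: {"pre": 0.5, "drug": 0.1, "post": 0.4})
    coupling_gain: dict[str, float] = field(
        default_factory=lambda: {"pre": 0.8, "drug": 0.3, "post": 0.7})
    intrinsic_sd: float = 1.5

    def to_json(self, path) -> None:
        d = {
            "model_params": {
                "s": self.model_params.s,
                "tau_broadcast": self.model_params.tau_broadcast,
                "tau_persist": dict(self.model_params.tau_persist),
            },
            "intrinsic_timescale": dict(self.intrinsic_timescale),
            "coupling_gain": dict(self.coupling_gain),
            "intrinsic_sd": self.intrinsic_sd,
            "units": self.units.to_dict(orient="list"),
            "planted_factors": [asdict(f) for f in self.planted_factors],
            "planted_oscillations": [asdict(o) for o in self.planted_oscillations],
            "coupled_pairs": [asdict(c) for c in self.coupled_pairs],
            "n_channels": self.n_channels,
            "channel_regions": list(self.channel_regions),
            "chi": self.chi,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            model_params=BiphasicParams(**d["model_params"]),
            units=pd.DataFrame(d["units"]),
            planted_factors=[
                PlantedFactor(
                    name=f["name"], band=tuple(f["band"]), window=tuple(f["window"]),
                    sign=f["sign"], amplitude=f["amplitude"],
                    loadings=tuple(f["loadings"]),
                )
                for f in d["planted_factors"]
            ],
            planted_oscillations=[
                PlantedOscillation(
                    freq=o["freq"], bandwidth=o["bandwidth"], amplitude=o["amplitude"],
                    conditions=tuple(o["conditions"]),
                    channels=None if o["channels"] is None else tuple(o["channels"]),
                )
                for o in d["planted_oscillations"]
            ],
            coupled_pairs=[
                CoupledPair(
                    i=c["i"], j=c["j"], freq=c["freq"], bandwidth=c["bandwidth"],
                    lag_rad=c["lag_rad"], amplitude=c["amplitude"],
                    condition_gain=None if c["condition_gain"] is None
                    else tuple((k, v) for k, v in c["condition_gain"]),
                )
                for c in d["coupled_pairs"]
            ],
            n_channels=d["n_channels"],
            channel_regions=list(d["channel_regions"]),
            chi=d["chi"],
            seed=d["seed"],
            intrinsic_timescale=dict(d["intrinsic_timescale"]),
            coupling_gain=dict(d["coupling_gain"]),
            intrinsic_sd=d["intrinsic_sd"],
        )


# ---------------------------------------------------------------------------
# Event schedule


def make_event_schedule(
    n_trials_pre: int = 20,
    n_trials_post: int = 20,
    puffs_per_series: int = 8,
    puff_duration: float = 0.25,
    inter_puff_interval: float = 3.0,
    inter_trial_range: tuple[float, float] = (45.0, 90.0),
    seed: int = 0,
    n_trials_recovery: int = 0,
    first_onset: float = 150.0,
    post_label: str = "drug",
) -> EventSchedule:
    """Puff-series schedule with pre -> drug (-> post) condition labels.

    Each series is ``puffs_per_series`` puffs of ``puff_duration`` seconds at
    ``inter_puff_interval`` spacing (onset to onset).  Gaps between series
    are drawn uniformly from ``inter_trial_range`` (measured from the last
    puff offset to the next series onset).  ``first_onset`` leaves room for a
    pre-assay baseline epoch.
    """
    if n_trials_pre < 0 or n_trials_post < 0 or n_trials_recovery < 0:
        raise ValueError("trial counts must be non-negative")
    n_trials = n_trials_pre + n_trials_post + n_trials_recovery
    if n_trials <= 0 or puffs_per_series <= 0:
        raise ValueError("need at least one trial and one puff per series")
    if puff_duration <= 0 or inter_puff_interval <= 0:
        raise ValueError("durations must be positive")
    if inter_puff_interval <= puff_duration and puffs_per_series > 1:
        raise ValueError("inter_puff_interval must exceed puff_duration")
    lo, hi = inter_trial_range
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid inter_trial_range {inter_trial_range}")

    rng = substream(seed, "event_schedule")
    gaps = rng.uniform(lo, hi, size=n_trials)  # gap before each trial; [0] unused

    onsets, durations, trials, puff_idx, condition = [], [], [], [], []
    t = float(first_onset)
    for k in range(n_trials):
        if k > 0:
            t = onsets[-1] + puff_duration + gaps[k]
        if k < n_trials_pre:
            label = "pre"
        elif k < n_trials_pre + n_trials_post:
            label = post_label
        else:
            label = "post"
        for p in range(puffs_per_series):
            onsets.append(t + p * inter_puff_interval)
            durations.append(puff_duration)
            trials.append(k)
            puff_idx.append(p)
            condition.append(label)
    return EventSchedule(
        np.array(onsets), np.array(durations), np.array(trials),
        np.array(puff_idx), np.array(condition, dtype=object),
    )


# ---------------------------------------------------------------------------
# Default session configuration (the study conditions)


def default_ground_truth(
    seed: int = 0,
    n_units: int = 50,
    n_channels: int = 12,
    s: float = 0.6,
    tau_broadcast: float = 0.15,
    tau_persist: dict[str, float] | None = None,
    chi: float = 2.0,
    regions: tuple[str, ...] = ("PAG", "VPM", "MD", "ORB", "PMC"),
) -> GroundTruth:
    """Standard synthetic session: archetype mix with persistent units as a
    tenth of the population, two evoked factors (one positive high-frequency,
    one negative low-frequency), a drug-gated 4 Hz oscillation, and one
    phase-coupled channel pair."""
    if tau_persist is None:
        tau_persist = {"pre": 10.0, "drug": 1.0, "post": 8.0}
    rng = substream(seed, "ground_truth")

    # archetype mix: persistent units are 10% of the population
    n_persist = max(1, round(0.10 * n_units))
    n_fp = n_persist // 2
    n_dp = n_persist - n_fp
    n_sup = round(0.10 * n_units)
    n_ft = round(0.40 * n_units)
    n_un = n_units - (n_fp + n_dp + n_sup + n_ft)
    archetypes = (
        ["fast_persistent"] * n_fp + ["delayed_persistent"] * n_dp
        + ["fast_transient"] * n_ft + ["suppressed"] * n_sup
        + ["unmodulated"] * n_un
    )
    order = rng.permutation(n_units)
    archetypes = [archetypes[i] for i in order]
    amp_default = {
        "fast_transient": 12.0, "fast_persistent": 8.0, "delayed_persistent": 8.0,
        "suppressed": 6.0, "unmodulated": 0.0,
    }
    units = pd.DataFrame(
        {
            "unit_id": [f"u{i:03d}" for i in range(n_units)],
            "archetype": archetypes,
            "region": [regions[i % len(regions)] for i in range(n_units)],
            "baseline": rng.uniform(4.0, 8.0, n_units).round(3),
            "amplitude": [
                round(amp_default[a] * float(np.exp(rng.normal(0.0, 0.2))), 3)
                for a in archetypes
            ],
        }
    )

    ch_loadings_pos = rng.uniform(0.2, 1.0, n_channels).round(3)
    ch_loadings_neg = rng.uniform(0.2, 1.0, n_channels).round(3)
    factors = [
        PlantedFactor(
            "fast_highgamma", band=(65.0, 95.0), window=(0.05, 0.6), sign=+1,
            amplitude=1.5, loadings=tuple(ch_loadings_pos),
        ),
        PlantedFactor(
            "slow_lowfreq_drop", band=(8.0, 20.0), window=(0.4, 1.4), sign=-1,
            amplitude=0.8, loadings=tuple(ch_loadings_neg),
        ),
    ]
    oscillations = [
        PlantedOscillation(freq=4.0, bandwidth=1.0, amplitude=3.0,
                           conditions=("drug",), channels=None),
    ]
    pairs = [
        # amplitude comparable to the beta-band background so the planted
        # coupling drop is visible in PLV rather than saturating at 1
        CoupledPair(i=0, j=1, freq=20.0, bandwidth=6.0, lag_rad=np.pi / 4,
                    amplitude=0.015,
                    condition_gain=(("pre", 1.0), ("drug", 0.4), ("post", 1.0))),
    ]
    return GroundTruth(
        model_params=BiphasicParams(s=s, tau_broadcast=tau_broadcast,
                                    tau_persist=dict(tau_persist)),
        units=units,
        planted_factors=factors,
        planted_oscillations=oscillations,
        coupled_pairs=pairs,
        n_channels=n_channels,
        channel_regions=[regions[i % len(regions)] for i in range(n_channels)],
        chi=chi,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Population rates


def archetype_kernel(
    spec: KernelSpec | None,
    t: np.ndarray,
    tau_persist: float,
) -> np.ndarray:
    """Evaluate an archetype kernel at times ``t`` (seconds from puff onset)."""
    t = np.asarray(t, dtype=float)
    if spec is None:
        return np.zeros_like(t)
    decay = spec.decay_tau if spec.decay_tau is not None else tau_persist
    k = np.zeros_like(t)
    rise = (t >= spec.latency) & (t < spec.latency + spec.rise_duration)
    k[rise] = 1.0 - np.exp(-(t[rise] - spec.latency) / spec.rise_tau)
    peak = 1.0 - np.exp(-spec.rise_duration / spec.rise_tau)
    tail = t >= spec.latency + spec.rise_duration
    k[tail] = peak * np.exp(-(t[tail] - spec.latency - spec.rise_duration) / decay)
    return spec.sign * k


def _condition_epochs(schedule: EventSchedule, t_start: float, t_end: float
                      ) -> list[tuple[float, float, str]]:
    """Partition [t_start, t_end) into condition epochs; boundaries fall at
    the midpoint between the last event of one condition and the first of
    the next."""
    conds = schedule.conditions
    epochs = []
    lo = t_start
    for i, cond in enumerate(conds):
        sel = schedule.condition == cond
        if i + 1 < len(conds):
            nxt = schedule.condition == conds[i + 1]
            hi = 0.5 * (schedule.onsets[sel][-1] + schedule.durations[sel][-1]
                        + schedule.onsets[nxt][0])
        else:
            hi = t_end
        epochs.append((lo, hi, cond))
        lo = hi
    return epochs


def _ou_latent(rng: np.random.Generator, n_bins: int, bin_width: float,
               epochs: list[tuple[float, float, str]], t_start: float,
               timescales: dict[str, float]) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck latent whose timescale switches with
    the condition epoch (exact AR(1) discretization, continuous across
    boundaries)."""
    from scipy.signal import lfilter

    z = np.empty(n_bins)
    noise = rng.normal(0.0, 1.0, n_bins)
    z_prev = noise[0]
    for k, (lo, hi, cond) in enumerate(epochs):
        i0 = max(int(np.floor((lo - t_start) / bin_width)), 0)
        i1 = min(int(np.floor((hi - t_start) / bin_width)), n_bins)
        if k == len(epochs) - 1:
            i1 = n_bins  # the final epoch always covers the end of the grid
        if i1 <= i0:
            continue
        phi = np.exp(-bin_width / timescales[cond])
        w = noise[i0:i1] * np.sqrt(1.0 - phi ** 2)
        seg, _ = lfilter([1.0], [1.0, -phi], w, zi=[phi * z_prev])
        z[i0:i1] = seg
        z_prev = seg[-1]
    return z


def simulate_population(
    schedule: EventSchedule,
    truth: GroundTruth,
    bin_width: float = 0.01,
    noise_sd: float = 1.0,
    t_start: float = 0.0,
    t_end: float | None = None,
    rectify: bool = True,
) -> PopulationActivity:
    """Binned unit rates: baseline + archetype kernels on the event train +
    i.i.d. Gaussian noise, rectified at zero."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    for a in truth.units["archetype"]:
        if a not in ARCHETYPES:
            raise ValueError(f"no kernel defined for archetype {a!r}")
    missing = set(schedule.conditions) - set(truth.model_params.tau_persist)
    if missing:
        raise ValueError(f"schedule conditions {missing} absent from ground truth")
    if t_end is None:
        t_end = float(schedule.onsets[-1] + schedule.durations[-1] + 60.0)
    n_bins = int(round((t_end - t_start) / bin_width))
    grid = t_start + np.arange(n_bins) * bin_width

    n_units = len(truth.units)
    rates = np.tile(truth.units["baseline"].to_numpy()[:, None], (1, n_bins))
    amps = truth.units["amplitude"].to_numpy()
    arch = truth.units["archetype"].to_numpy()

    kernel_cache: dict[tuple[str, str], np.ndarray] = {}
    for onset, cond in zip(schedule.onsets, schedule.condition):
        tau_p = float(truth.model_params.tau_persist[cond])
        for a in np.unique(arch):
            spec = ARCHETYPES[a]
            if spec is None:
                continue
            key = (a, cond)
            if key not in kernel_cache:
                decay = spec.decay_tau if spec.decay_tau is not None else tau_p
                support = spec.latency + spec.rise_duration + 12.0 * decay
                n_k = int(round(support / bin_width))
                kernel_cache[key] = archetype_kernel(
                    spec, np.arange(n_k) * bin_width, tau_p
                )
            k = kernel_cache[key]
            i0 = int(np.floor((onset - t_start) / bin_width + 1e-9))
            if i0 >= n_bins:
                continue
            j0, j1 = max(i0, 0), min(i0 + len(k), n_bins)
            if j1 <= j0:
                continue
            sel = arch == a
            rates[sel, j0:j1] += np.outer(amps[sel], k[j0 - i0 : j1 - i0])

    # intrinsic baseline fluctuations of the persistent subnetwork: a shared
    # OU latent (weight = condition coupling gain) plus private OU latents,
    # all with the condition-specific intrinsic timescale
    persistent = np.array([ARCHETYPES[a] is not None and ARCHETYPES[a].decay_tau is None
                           for a in arch])
    if truth.intrinsic_sd > 0 and np.any(persistent):
        epochs = _condition_epochs(schedule, t_start, t_end)
        gain = np.zeros(n_bins)
        for (lo, hi, cond) in epochs:
            i0 = max(int(np.floor((lo - t_start) / bin_width)), 0)
            i1 = min(int(np.floor((hi - t_start) / bin_width)), n_bins)
            gain[i0:i1] = truth.coupling_gain[cond]
        shared = _ou_latent(substream(truth.seed, "intrinsic_shared"), n_bins,
                            bin_width, epochs, t_start, truth.intrinsic_timescale)
        for u in np.nonzero(persistent)[0]:
            private = _ou_latent(substream(truth.seed, f"intrinsic_u{u}"), n_bins,
                                 bin_width, epochs, t_start,
                                 truth.intrinsic_timescale)
            rates[u] += truth.intrinsic_sd * (
                gain * shared + np.sqrt(1.0 - gain ** 2) * private
            )

    if noise_sd > 0:
        rng = substream(truth.seed, "population_noise")
        rates = rates + rng.normal(0.0, noise_sd, size=rates.shape)
    if rectify:
        np.clip(rates, 0.0, None, out=rates)
    sites = truth.units[["unit_id", "region", "archetype"]].rename(
        columns={"unit_id": "site_id"}
    )
    return PopulationActivity(rates=rates, bin_width=bin_width, sites=sites,
                              t_start=t_start)


# ---------------------------------------------------------------------------
# LFP surrogate


def _one_over_f(rng: np.random.Generator, n: int, fs: float, chi: float) -> np.ndarray:
    """Unit-variance 1/f^chi noise by spectral shaping of white noise."""
    white = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-chi / 2.0)
    x = np.fft.irfft(spec * gain, n)
    return x / x.std()


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                freq: float, bandwidth: float) -> np.ndarray:
    """Unit-variance narrowband Gaussian noise centred on ``freq``."""
    lo = max(freq - bandwidth / 2.0, 0.1)
    hi = min(freq + bandwidth / 2.0, fs / 2.0 - 0.1)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
    return x / x.std()


def _condition_envelope(
    schedule: EventSchedule, conditions: tuple[str, ...],
    n: int, fs: float, margin: float = 30.0, ramp: float = 1.0,
) -> np.ndarray:
    """Smooth 0/1 gate covering the epochs of the given conditions."""
    t = np.arange(n) / fs
    env = np.zeros(n)
    for cond in conditions:
        sel = schedule.condition == cond
        if not np.any(sel):
            continue
        t0 = schedule.onsets[sel][0] - margin
        t1 = schedule.onsets[sel][-1] + schedule.durations[sel][-1] + margin
        env = np.maximum(env, np.clip((t - t0) / ramp, 0, 1) * np.clip((t1 - t) / ramp, 0, 1))
    return env


def _event_envelope(
    schedule: EventSchedule, window: tuple[float, float],
    n: int, fs: float, ramp: float = 0.05,
) -> np.ndarray:
    """Smooth gate over [onset+window[0], onset+window[1]) for every event."""
    t = np.arange(n) / fs
    env = np.zeros(n)
    for onset in schedule.onsets:
        a, b = onset + window[0], onset + window[1]
        env = np.maximum(env, np.clip((t - a) / ramp, 0, 1) * np.clip((b - t) / ramp, 0, 1))
    return env


def simulate_lfp(
    schedule: EventSchedule,
    truth: GroundTruth,
    fs: float = 200.0,
    duration: float | None = None,
    background_amplitude: float = 1.0,
) -> np.ndarray:
    """Multichannel LFP surrogate, shape (n_channels, n_samples).

    Each channel is 1/f^chi background, plus planted narrowband oscillations
    gated by their condition epochs, plus evoked band-limited bursts (positive
    factors) or band-limited attenuation of the background (negative factors)
    after each puff, plus shared lagged narrowband components for coupled
    channel pairs.
    """
    if fs < 200.0:
        raise ValueError("fs must be >= 200 Hz")
    for osc in truth.planted_oscillations:
        if osc.freq >= fs / 2:
            raise ValueError(f"oscillation at {osc.freq} Hz >= Nyquist ({fs / 2} Hz)")
    if duration is None:
        duration = float(schedule.onsets[-1] + schedule.durations[-1] + 60.0)
    if duration < schedule.onsets[-1] + schedule.durations[-1]:
        raise ValueError("duration does not cover the event schedule")
    n = int(round(duration * fs))
    n_ch = truth.n_channels
    out = np.empty((n_ch, n))

    for ch in range(n_ch):
        rng = substream(truth.seed, f"lfp_background_ch{ch}")
        out[ch] = background_amplitude * _one_over_f(rng, n, fs, truth.chi)

    # evoked factors
    for fi, fac in enumerate(truth.planted_factors):
        env = _event_envelope(schedule, fac.window, n, fs)
        if fac.sign > 0:
            for ch in range(n_ch):
                rng = substream(truth.seed, f"factor{fi}_ch{ch}")
                burst = _narrowband(rng, n, fs, np.mean(fac.band),
                                    fac.band[1] - fac.band[0])
                out[ch] += fac.amplitude * fac.loadings[ch] * env * burst
        else:
            sos = butter(4, list(fac.band), btype="bandpass", fs=fs, output="sos")
            for ch in range(n_ch):
                band_part = sosfiltfilt(sos, out[ch])
                g = np.clip(fac.amplitude * fac.loadings[ch] * env, 0.0, 0.95)
                out[ch] -= g * band_part

    # condition-gated oscillations
    for oi, osc in enumerate(truth.planted_oscillations):
        env = _condition_envelope(schedule, osc.conditions, n, fs)
        chans = range(n_ch) if osc.channels is None else osc.channels
        for ch in chans:
            rng = substream(truth.seed, f"osc{oi}_ch{ch}")
            out[ch] += osc.amplitude * env * _narrowband(rng, n, fs, osc.freq,
                                                         osc.bandwidth)

    # phase-coupled pairs: shared narrowband component, channel j lagged
    for pi, pair in enumerate(truth.coupled_pairs):
        rng = substream(truth.seed, f"coupled_pair{pi}")
        shared = _narrowband(rng, n, fs, pair.freq, pair.bandwidth)
        shift = int(round(pair.lag_rad / (2.0 * np.pi * pair.freq) * fs))
        lagged = np.roll(shared, shift)
        if pair.condition_gain is None:
            gain = np.ones(n)
        else:
            gain = np.zeros(n)
            for cond, g in pair.condition_gain:
                gain += g * _condition_envelope(schedule, (cond,), n, fs)
        out[pair.i] += pair.amplitude * gain * shared
        out[pair.j] += pair.amplitude * gain * lagged
    return out


# ---------------------------------------------------------------------------
# Eye traces


def blink_kernel(t: np.ndarray, amplitude: float, duration: float) -> np.ndarray:
    """Stereotyped reflexive blink: raised cosine of ``duration`` seconds."""
    k = np.zeros_like(t)
    sel = (t >= 0) & (t < duration)
    k[sel] = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * t[sel] / duration))
    return k


def simulate_eye_trace(
    schedule: EventSchedule,
    truth: GroundTruth,
    blink_amplitude: float = 0.35,
    blink_duration: float = 0.30,
    noise_sd: float = 0.02,
    fs: float = 50.0,
    window: tuple[float, float] = (-5.0, 54.0),
) -> list[EyeTrace]:
    """Per-trial eye-closure traces (time axis relative to series start).

    closure(t) = affective component (two-phase model driven by the trial's
    puff train) + reflexive blink kernel after each puff onset + Gaussian
    noise, clipped to [0, 1].
    """
    if not (0.0 <= blink_amplitude <= 1.0):
        raise ValueError("blink_amplitude must be in [0, 1]")
    if blink_duration <= 0:
        raise ValueError("blink_duration must be positive")
    rng = substream(truth.seed, "eye_noise")
    t = np.arange(window[0], window[1], 1.0 / fs)
    traces = []
    for trial in np.unique(schedule.trial):
        ev = schedule.select(schedule.trial == trial)
        cond = str(ev.condition[0])
        rel = ev.onsets - ev.onsets[0]
        intervals = [(float(a), float(a + d)) for a, d in zip(rel, ev.durations)]
        s, tau_b, tau_p = truth.model_params.for_condition(cond)
        affective = evaluate(s, tau_b, tau_p, t, intervals)
        blinks = np.zeros_like(t)
        for onset in rel:
            blinks += blink_kernel(t - onset, blink_amplitude, blink_duration)
        closure = affective + blinks
        if noise_sd > 0:
            closure = closure + rng.normal(0.0, noise_sd, size=t.shape)
        traces.append(EyeTrace(time=t.copy(), closure=np.clip(closure, 0.0, 1.0),
                               trial=int(trial), condition=cond))
    return traces
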