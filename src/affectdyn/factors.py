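"""Sign-split NMF of peri-puff z-scored spectrograms across channels.

Z-scored spectrograms carry both signs, so the channel x (time*frequency)
response matrix is split into its positive part and the absolute value of
its negative part; each part is factored separately by non-negative matrix
factorization (Frobenius loss, deterministic NNDSVD initialization).  The
signed reconstruction is W_pos @ H_pos - W_neg @ H_neg.  The factor count is
chosen on held-out trials: loadings for test data are refit by non-negative
least squares against the fixed templates H, and the elbow of the held-out
explained-variance curve is taken at the maximum discrete second difference
(deterministic surrogate for a visual elbow; ties break to the smaller k).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import ttest_rel

from ._seeding import substream
from .spectral import PeriEventTensor

logger = logging.getLogger(__name__)

__all__ = [
    "FactorSet",
    "build_response_matrix",
    "fit_sign_split_nmf",
    "select_k",
    "nnls_loadings",
    "held_out_ev",
    "compare_loadings",
    "loading_contrast",
]


@dataclass
class FactorSet:
    """Sign-split factorization result.

    H_pos/H_neg are non-negative factor templates over the flattened
    (time, frequency) axis; W_pos/W_neg the non-negative channel loadings.
    """

    W_pos: np.ndarray
    H_pos: np.ndarray
    W_neg: np.ndarray
    H_neg: np.ndarray
    channels: list[str] = field(default_factory=list)
    tf_shape: tuple[int, int] | None = None

    @property
    def k_pos(self) -> int:
        return self.H_pos.shape[0]

    @property
    def k_neg(self) -> int:
        return self.H_neg.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.W_pos @ self.H_pos - self.W_neg @ self.H_neg

    def templates(self) -> list[tuple[str, np.ndarray]]:
        """(sign tag, template) for every factor, positive factors first."""
        out = [("positive", h) for h in self.H_pos]
        out += [("negative", h) for h in self.H_neg]
        return out


def build_response_matrix(
    tensors: Mapping[str, PeriEventTensor],
    window: tuple[float, float] = (0.0, 1.4),
    train_conditions: tuple[str, ...] = ("pre", "post"),
) -> tuple[np.ndarray, np.ndarray, list[str], tuple[int, int], dict]:
    """Stack per-channel trial-averaged spectrograms into train/test matrices.

    Trials from the training conditions are split alternately (every other
    trial trains, the rest test).  Each channel's events are averaged within
    the split, cropped to ``window`` seconds from puff onset, flattened, and
    stacked into (channels x time*frequency) matrices.
    """
    channels = list(tensors)
    first = tensors[channels[0]]
    tsel = (first.times >= window[0]) & (first.times < window[1])
    tf_shape = (int(tsel.sum()), len(first.freqs))
    cond_mask = first.events["condition"].isin(train_conditions).to_numpy()
    trials = np.unique(first.events.loc[cond_mask, "trial"])
    if len(trials) < 2:
        raise ValueError("need at least 2 trials to split train/test")
    train_trials, test_trials = trials[::2], trials[1::2]

    def stack(trial_set):
        rows = []
        for ch in channels:
            t = tensors[ch]
            if len(t.times) != len(first.times) or len(t.freqs) != len(first.freqs):
                raise ValueError("channels must share time/frequency axes")
            sel = t.events["condition"].isin(train_conditions).to_numpy() & t.events[
                "trial"
            ].isin(trial_set).to_numpy()
            rows.append(t.values[sel][:, tsel, :].mean(axis=0).ravel())
        return np.vstack(rows)

    split = {"train_trials": train_trials.tolist(), "test_trials": test_trials.tolist(),
             "conditions": list(train_conditions), "window": list(window)}
    return stack(train_trials), stack(test_trials), channels, tf_shape, split


def _split_signs(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = np.nan_to_num(np.asarray(matrix, dtype=float))
    return np.clip(m, 0.0, None), np.clip(-m, 0.0, None)


def fit_sign_split_nmf(
    train: np.ndarray,
    k_pos: int,
    k_neg: int,
    seed: int = 0,
    max_iter: int = 2000,
    channels: Sequence[str] | None = None,
    tf_shape: tuple[int, int] | None = None,
) -> FactorSet:
    """Factor the positive and negative parts of a signed response matrix.

    NNDSVD initialization makes the fit deterministic; the seed only breaks
    degenerate ties inside the solver.
    """
    from sklearn.decomposition import NMF

    if k_pos < 1 or k_neg < 1:
        raise ValueError("k_pos and k_neg must be >= 1")
    pos, neg = _split_signs(train)

    def _fit(part, k):
        if not np.any(part):
            warnings.warn("all-zero sign split; returning empty factors", stacklevel=3)
            return np.zeros((part.shape[0], 0)), np.zeros((0, part.shape[1]))
        k_eff = min(k, min(part.shape))
        model = NMF(n_components=k_eff, init="nndsvd", max_iter=max_iter,
                    random_state=seed, tol=1e-7)
        with warnings.catch_warnings():
            # near-exact factorizations keep a tiny residual gradient; the
            # iteration cap is part of the deterministic recipe
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            W = model.fit_transform(part)
        return W, model.components_

    W_pos, H_pos = _fit(pos, k_pos)
    W_neg, H_neg = _fit(neg, k_neg)
    return FactorSet(W_pos, H_pos, W_neg, H_neg,
                     channels=list(channels) if channels else [],
                     tf_shape=tf_shape)


def nnls_loadings(matrix: np.ndarray, fs: FactorSet) -> tuple[np.ndarray, np.ndarray]:
    """Refit per-channel loadings against fixed templates by non-negative
    least squares (positive part against H_pos, negative against H_neg)."""
    pos, neg = _split_signs(matrix)

    def _solve(part, H):
        if H.shape[0] == 0:
            return np.zeros((part.shape[0], 0))
        return np.vstack([nnls(H.T, row)[0] for row in part])

    return _solve(pos, fs.H_pos), _solve(neg, fs.H_neg)


def held_out_ev(test: np.ndarray, fs: FactorSet) -> float:
    """Explained variance on held-out data with loadings refit by NNLS
    against the fixed templates: 1 - ||test - recon||^2 / ||test - mean||^2."""
    Wp, Wn = nnls_loadings(test, fs)
    recon = Wp @ fs.H_pos - Wn @ fs.H_neg
    resid = np.linalg.norm(test - recon) ** 2
    base = np.linalg.norm(test - test.mean()) ** 2
    return float(1.0 - resid / base) if base > 0 else 0.0


def select_k(
    train: np.ndarray,
    test: np.ndarray,
    k_grid: Sequence[int],
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Held-out explained-variance curve over total factor counts and the
    elbow choice.

    Each total k is split evenly between positive and negative factors
    (positive gets the extra one when odd).  The elbow is the grid point with
    the maximum discrete second difference of held-out EV (using EV = 0 at
    k = 0); ties go to the smaller k.  The last grid point cannot be an
    elbow (no following gain to compare against).
    """
    ks = sorted(int(k) for k in k_grid)
    if any(k < 2 for k in ks):
        raise ValueError("total factor counts must be >= 2 (one per sign)")
    evs = []
    for k in ks:
        kp, kn = (k + 1) // 2, k // 2
        fs = fit_sign_split_nmf(train, kp, max(kn, 1), seed=seed)
        evs.append(held_out_ev(test, fs))
    curve = pd.DataFrame({"k": ks, "held_out_ev": evs})
    extended = np.concatenate([[0.0], np.asarray(evs)])
    gains = np.diff(extended)  # gain achieved arriving at each grid k
    # second difference: gain at k minus gain at the next grid point
    d2 = gains[:-1] - gains[1:]
    elbow = int(ks[int(np.argmax(d2))]) if len(d2) else int(ks[0])
    return curve, elbow


def compare_loadings(
    fs: FactorSet,
    tensors: Mapping[str, PeriEventTensor],
    split: dict,
    loading_floor: float = 0.1,
    infusion_condition: str = "drug",
    reference_conditions: tuple[str, ...] = ("pre", "post"),
    groups: Mapping[str, str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-factor condition contrast of channel loadings.

    Loadings for every condition are refit on test trials against the fixed
    templates.  Channels whose mean reference loading on a factor is below
    ``loading_floor`` are excluded from that factor.  The contrast is
    infusion minus the mean of the reference conditions, tested by a
    hierarchical bootstrap over participants then channels when a
    channel -> participant mapping is supplied (preserving the grouping
    structure), otherwise by a paired t-test across channels.
    """
    channels = list(tensors)
    window = tuple(split["window"])
    test_trials = set(split["test_trials"])

    def condition_matrix(cond):
        rows = []
        for ch in channels:
            t = tensors[ch]
            tsel = (t.times >= window[0]) & (t.times < window[1])
            sel = (t.events["condition"] == cond).to_numpy()
            trial_sel = t.events["trial"].isin(test_trials).to_numpy()
            use = sel & trial_sel if np.any(sel & trial_sel) else sel
            rows.append(t.values[use][:, tsel, :].mean(axis=0).ravel())
        return np.vstack(rows)

    loads = {}
    for cond in (infusion_condition, *reference_conditions):
        Wp, Wn = nnls_loadings(condition_matrix(cond), fs)
        loads[cond] = np.hstack([Wp, Wn])  # channels x (k_pos + k_neg)

    ref = np.mean([loads[c] for c in reference_conditions], axis=0)
    inf = loads[infusion_condition]
    signs = ["positive"] * fs.k_pos + ["negative"] * fs.k_neg
    return loading_contrast(inf, ref, channels, signs=signs,
                            loading_floor=loading_floor, groups=groups,
                            n_boot=n_boot, seed=seed)


def loading_contrast(
    infusion: np.ndarray,
    reference: np.ndarray,
    channels: Sequence[str],
    signs: Sequence[str] | None = None,
    loading_floor: float = 0.1,
    groups: Mapping[str, str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-factor infusion-vs-reference loading contrast.

    ``infusion`` and ``reference`` are (channels x factors) loading
    matrices.  Per factor, channels below ``loading_floor`` mean reference
    loading are excluded; the contrast is the mean channel difference,
    tested by a hierarchical bootstrap (participants, then channels) when
    ``groups`` maps channels to participants, otherwise a paired t-test.
    """
    n_factors = infusion.shape[1]
    if signs is None:
        signs = [""] * n_factors
    if np.isinf(loading_floor):
        warnings.warn("loading floor excludes every channel", stacklevel=2)

    rng = substream(seed, "loading_bootstrap")
    rows = []
    for f in range(n_factors):
        keep = reference[:, f] >= loading_floor
        n_kept = int(keep.sum())
        if n_kept == 0:
            rows.append({"factor": f, "sign": signs[f], "contrast": np.nan,
                         "p": np.nan, "n_channels": 0, "defined": False})
            continue
        diffs = infusion[keep, f] - reference[keep, f]
        contrast = float(diffs.mean())
        if groups is not None:
            by_part: dict[str, list[float]] = {}
            kept_channels = [c for c, k in zip(channels, keep) if k]
            for ch, d in zip(kept_channels, diffs):
                by_part.setdefault(groups[ch], []).append(d)
            parts = [np.asarray(v) for v in by_part.values()]
            stats = np.empty(n_boot)
            for b in range(n_boot):
                chosen = [parts[i] for i in rng.integers(0, len(parts), len(parts))]
                stats[b] = np.mean(
                    np.concatenate([p[rng.integers(0, len(p), len(p))] for p in chosen])
                )
            p = 2.0 * min(float(np.mean(stats >= 0)), float(np.mean(stats <= 0)))
            p = float(np.clip(p, 1.0 / n_boot, 1.0))
        elif n_kept >= 2 and np.ptp(diffs) > 0:
            p = float(ttest_rel(infusion[keep, f], reference[keep, f]).pvalue)
        else:
            p = np.nan
        rows.append({"factor": f, "sign": signs[f], "contrast": contrast,
                     "p": p, "n_channels": n_kept, "defined": True})
    return pd.DataFrame(rows)


def group_loadings(
    fs: FactorSet, W: np.ndarray, groups: Mapping[str, str],
    normalize: bool = True,
) -> pd.DataFrame:
    """Mean loading per (group, factor); optionally normalized per group
    across factors (visualization convention)."""
    channels = fs.channels
    labels = sorted(set(groups[c] for c in channels))
    out = np.zeros((len(labels), W.shape[1]))
    for gi, g in enumerate(labels):
        sel = [i for i, c in enumerate(channels) if groups[c] == g]
        out[gi] = W[sel].mean(axis=0)
    if normalize:
        sums = out.sum(axis=1, keepdims=True)
        out = np.divide(out, sums, out=np.zeros_like(out), where=sums > 0)
    return pd.DataFrame(out, index=labels,
                        columns=[f"factor_{i}" for i in range(W.shape[1])])
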