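"""Paired cluster-based permutation testing of peri-event spectrotemporal
condition differences.

Each event contributes a paired (infusion minus reference) difference map
over (time, frequency).  A one-sample t statistic is computed per cell;
cells exceeding the two-sided cluster-forming threshold are grouped into
4-connected clusters within sign, each scored by its mass (sum of t).  The
null distribution of the maximum cluster mass is built by randomly flipping
the sign of whole events (exact under a symmetric null), and cluster
p-values are (1 + #{null >= observed}) / (1 + n_perm).  Minimum p-values
are corrected across regions by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from ._seeding import substream

__all__ = ["Cluster", "ClusterResult", "paired_cluster_test", "fdr_across_regions"]

#: 4-neighbour connectivity in (time, frequency).
_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Cluster:
    cells: np.ndarray  # (n_cells, 2) int indices into (time, frequency)
    mass: float
    p: float
    sign: int


@dataclass
class ClusterResult:
    t_map: np.ndarray
    clusters: list[Cluster]
    region: str = ""
    n_events: int = 0
    forming_threshold: float = np.nan

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    """One-sample t across axis 0 with zero-variance cells mapped to t=0."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _cluster_masses(t_map: np.ndarray, thr: float) -> list[tuple[np.ndarray, float, int]]:
    out = []
    for sign in (1, -1):
        mask = (sign * t_map) > thr
        labels, n = ndimage.label(mask, structure=_STRUCTURE)
        for lab in range(1, n + 1):
            cells = np.argwhere(labels == lab)
            mass = float(t_map[labels == lab].sum())
            out.append((cells, mass, sign))
    return out


def paired_cluster_test(
    diff: np.ndarray,
    forming_alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    region: str = "",
) -> ClusterResult:
    """Cluster permutation test on per-event paired difference maps.

    ``diff`` is (events, time, frequency); rows are paired differences (for
    the puff assay, paired by position in the puff sequence).  Refuses
    n_perm < 100 (p-values too unstable to interpret).
    """
    diff = np.asarray(diff, dtype=float)
    if diff.ndim != 3:
        raise ValueError("diff must be (events, time, frequency)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for stable p-values")
    n_events, n_t, n_f = diff.shape
    if n_events < 2:
        raise ValueError("need at least 2 paired events")
    thr = float(t_dist.ppf(1.0 - forming_alpha / 2.0, df=n_events - 1))

    t_map = _t_one_sample(diff)
    observed = _cluster_masses(t_map, thr)

    # Sign-flip null: t is recomputable from the flipped mean alone because
    # sum(x^2) is flip-invariant.
    X = diff.reshape(n_events, -1)
    sum_sq = (X ** 2).sum(axis=0)
    rng = substream(seed, "cluster_permutation")
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_events))
    means = signs @ X / n_events  # (n_perm, n_t*n_f)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (sum_sq[None, :] - n_events * means ** 2) / (n_events - 1)
        var = np.clip(var, 0.0, None)
        t_null = means / np.sqrt(var / n_events)
    t_null = np.nan_to_num(t_null).reshape(n_perm, n_t, n_f)

    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        masses = _cluster_masses(t_null[i], thr)
        if masses:
            null_max[i] = max(abs(m) for _, m, _ in masses)

    clusters = []
    for cells, mass, sign in observed:
        p = float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm))
        clusters.append(Cluster(cells=cells, mass=mass, p=p, sign=sign))
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(t_map=t_map, clusters=clusters, region=region,
                         n_events=n_events, forming_threshold=thr)


def unpaired_cluster_test(
    a: np.ndarray,
    b: np.ndarray,
    forming_alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    region: str = "",
) -> ClusterResult:
    """Unpaired fallback: two-sample t maps with a group-label permutation
    null (the paired-by-sequence-position constraint relaxed)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for stable p-values")
    pooled = np.concatenate([a, b], axis=0)
    n_a = a.shape[0]
    n = pooled.shape[0]
    thr = float(t_dist.ppf(1.0 - forming_alpha / 2.0, df=n - 2))

    def t_two(x, y):
        vx, vy = x.var(axis=0, ddof=1), y.var(axis=0, ddof=1)
        sp = np.sqrt(((len(x) - 1) * vx + (len(y) - 1) * vy) / (len(x) + len(y) - 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (x.mean(axis=0) - y.mean(axis=0)) / (
                sp * np.sqrt(1.0 / len(x) + 1.0 / len(y))
            )
        return np.where(sp == 0, 0.0, t)

    t_map = t_two(a, b)
    observed = _cluster_masses(t_map, thr)
    rng = substream(seed, "cluster_permutation_unpaired")
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        tp = t_two(pooled[perm[:n_a]], pooled[perm[n_a:]])
        masses = _cluster_masses(tp, thr)
        if masses:
            null_max[i] = max(abs(m) for _, m, _ in masses)
    clusters = [
        Cluster(cells=c, mass=m, sign=s,
                p=float((1 + np.sum(null_max >= abs(m))) / (1 + n_perm)))
        for c, m, s in observed
    ]
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(t_map=t_map, clusters=clusters, region=region,
                         n_events=n, forming_threshold=thr)


def fdr_across_regions(
    results: list[ClusterResult],
    q: float = 0.01,
    report_alpha: float = 0.01,
) -> dict[str, list[Cluster]]:
    """Benjamini-Hochberg correction of per-region minimum cluster p-values.

    Returns, for every region whose corrected minimum p falls below ``q``,
    all of its clusters with raw p below ``report_alpha``.
    """
    if not results:
        return {}
    min_ps = np.array([r.min_p for r in results])
    reject, _, _, _ = multipletests(min_ps, alpha=q, method="fdr_bh")
    out: dict[str, list[Cluster]] = {}
    for r, rej in zip(results, reject):
        if rej:
            out[r.region] = [c for c in r.clusters if c.p < report_alpha]
    return out
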