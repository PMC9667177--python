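"""Cluster-based permutation testing over channel x frequency x time.

The univariate retrieval-success and theta-band condition contrasts are
tested nonparametrically: dependent-sample t-tests per (channel, frequency,
time) cell at alpha = 0.05, supra-threshold cells grouped into
same-sign connected clusters (channel neighbors from the montage graph;
+-1 grid step in frequency and in time; a simultaneous frequency+time step
is NOT a neighbor), cluster mass = summed t, and the familywise-corrected
Monte-Carlo p of each cluster evaluated against the null distribution of the
maximum |mass| under random within-subject condition swaps (10 000 draws by
default).  Because the null pools both signs via |mass|, comparing a
cluster's p to alpha is a two-tailed test at alpha (0.025 per tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TMap:
    """Dependent-sample t per cell plus the geometry needed for clustering."""

    t: np.ndarray  # (n_channels, n_freqs, n_times)
    df: int
    channel_names: list[str]
    freqs: np.ndarray
    times: np.ndarray
    alpha: float = 0.05

    @property
    def t_crit(self) -> float:
        return float(stats.t.ppf(1.0 - self.alpha / 2.0, self.df))


@dataclass
class Cluster:
    cells: np.ndarray  # flat indices into the (ch, freq, time) grid
    sign: int
    mass: float
    p: float = np.nan
    significant: bool = False


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_max_mass: np.ndarray
    n_draws: int
    shape: tuple
    alpha: float = 0.05

    def table(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusters):
            ch, fr, ti = np.unravel_index(c.cells, self.shape)
            rows.append(
                dict(
                    cluster=i,
                    sign=c.sign,
                    mass=c.mass,
                    p=c.p,
                    significant=c.significant,
                    n_cells=len(c.cells),
                    channel_extent=len(set(ch)),
                    freq_extent=len(set(fr)),
                    time_extent=len(set(ti)),
                )
            )
        return pd.DataFrame(rows)


def dependent_t_map(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    channel_names: list[str],
    freqs: np.ndarray,
    times: np.ndarray,
    alpha: float = 0.05,
) -> TMap:
    """Paired t per cell over subjects for two (n_subj, ch, freq, time) arrays."""
    cond_a, cond_b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("condition arrays must have identical shape (same subjects)")
    n = cond_a.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    d = cond_a - cond_b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.finfo(float).tiny, sd)
    t = mean / (sd / np.sqrt(n))
    return TMap(t, n - 1, list(channel_names), np.asarray(freqs),
                np.asarray(times), alpha)


def _neighbor_lists(
    shape: tuple[int, int, int],
    chan_adj_idx: list[list[int]],
    connect_grid: bool = True,
) -> list[np.ndarray]:
    """Flat-index neighbor lists for the (ch, freq, time) lattice."""
    n_ch, n_f, n_t = shape
    nbrs: list[list[int]] = [[] for _ in range(n_ch * n_f * n_t)]

    def flat(c, f, t):
        return (c * n_f + f) * n_t + t

    for c in range(n_ch):
        for f in range(n_f):
            for t in range(n_t):
                i = flat(c, f, t)
                if connect_grid:
                    if f > 0:
                        nbrs[i].append(flat(c, f - 1, t))
                    if f < n_f - 1:
                        nbrs[i].append(flat(c, f + 1, t))
                    if t > 0:
                        nbrs[i].append(flat(c, f, t - 1))
                    if t < n_t - 1:
                        nbrs[i].append(flat(c, f, t + 1))
                for c2 in chan_adj_idx[c]:
                    nbrs[i].append(flat(c2, f, t))
    return [np.array(x, dtype=np.int64) for x in nbrs]


def _adjacency_indices(
    channel_names: list[str], adjacency: dict[str, set[str]] | None
) -> list[list[int]]:
    if adjacency is None:
        return [[] for _ in channel_names]
    pos = {n: i for i, n in enumerate(channel_names)}
    out = []
    for n in channel_names:
        out.append(sorted(pos[m] for m in adjacency.get(n, ()) if m in pos))
    return out


def _find_clusters(
    t_flat: np.ndarray, t_crit: float, nbrs: list[np.ndarray]
) -> list[Cluster]:
    """Same-sign connected components of supra-threshold cells (flood fill)."""
    supra = np.abs(t_flat) > t_crit
    sign = np.sign(t_flat)
    visited = np.zeros(t_flat.shape[0], dtype=bool)
    clusters = []
    for start in np.flatnonzero(supra):
        if visited[start]:
            continue
        s = sign[start]
        stack = [start]
        visited[start] = True
        members = []
        while stack:
            i = stack.pop()
            members.append(i)
            for j in nbrs[i]:
                if supra[j] and not visited[j] and sign[j] == s:
                    visited[j] = True
                    stack.append(int(j))
        members = np.array(members, dtype=np.int64)
        clusters.append(Cluster(members, int(s), float(t_flat[members].sum())))
    return clusters


def form_clusters(
    tmap: TMap,
    adjacency: dict[str, set[str]] | None,
    connect_grid: bool = True,
) -> list[Cluster]:
    """Supra-threshold same-sign clusters with summed-t masses."""
    shape = tmap.t.shape
    nbrs = _neighbor_lists(
        shape, _adjacency_indices(tmap.channel_names, adjacency), connect_grid
    )
    return _find_clusters(tmap.t.ravel(), tmap.t_crit, nbrs)


def _t_from_diffs(diffs_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized paired t for sign-flipped differences.

    ``diffs_flat``: (n_subj, n_cells); ``signs``: (n_draws, n_subj) of +-1.
    Sign flips leave the squared values unchanged, so only the mean varies.
    """
    n = diffs_flat.shape[0]
    sum_sq = (diffs_flat**2).sum(axis=0)  # (n_cells,)
    mean = signs @ diffs_flat / n  # (n_draws, n_cells)
    var = (sum_sq[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, np.finfo(float).tiny)
    return mean / np.sqrt(var / n)


def cluster_permutation_p(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    channel_names: list[str],
    freqs: np.ndarray,
    times: np.ndarray,
    adjacency: dict[str, set[str]] | None,
    n_draws: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    connect_grid: bool = True,
) -> ClusterResult:
    """Monte-Carlo cluster p-values under within-subject condition swaps.

    Swapping a subject's two condition labels flips the sign of that
    subject's difference map, so the null is built by random sign flips of
    the per-subject differences.  Each draw's statistic is the maximum
    |summed t| over its clusters; observed cluster p = (1 + #{null >=
    |mass|}) / (1 + n_draws).
    """
    if n_draws < 100:
        raise ValueError("n_draws < 100 gives meaningless Monte-Carlo p-values")
    tmap = dependent_t_map(cond_a, cond_b, channel_names, freqs, times, alpha)
    shape = tmap.t.shape
    nbrs = _neighbor_lists(
        shape, _adjacency_indices(channel_names, adjacency), connect_grid
    )
    observed = _find_clusters(tmap.t.ravel(), tmap.t_crit, nbrs)

    diffs = (np.asarray(cond_a, float) - np.asarray(cond_b, float)).reshape(
        cond_a.shape[0], -1
    )
    rng = np.random.default_rng(seed)
    t_crit = tmap.t_crit
    null_max = np.zeros(n_draws)
    chunk = max(1, min(n_draws, int(2e7 // max(diffs.size, 1))))
    done = 0
    while done < n_draws:
        k = min(chunk, n_draws - done)
        signs = rng.choice([-1.0, 1.0], size=(k, diffs.shape[0]))
        t_null = _t_from_diffs(diffs, signs)
        for r in range(k):
            cl = _find_clusters(t_null[r], t_crit, nbrs)
            null_max[done + r] = max((abs(c.mass) for c in cl), default=0.0)
        done += k
    for c in observed:
        c.p = float((1.0 + (null_max >= abs(c.mass)).sum()) / (1.0 + n_draws))
        c.significant = c.p < alpha
    observed.sort(key=lambda c: c.p)
    return ClusterResult(observed, null_max, n_draws, shape, alpha)
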