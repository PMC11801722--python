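"""Temporal selectivity profiles and graph-based clustering.

Each included unit contributes a time series of two-sample t values contrasting
salient vs non-salient distractor responses in the RF; profiles are clustered
with a PhenoGraph-style pipeline: k-nearest neighbors by Euclidean distance,
edges weighted by the Jaccard index of shared neighbor sets, and Louvain
modularity maximization.  The number of clusters is emergent, not preset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.neighbors import NearestNeighbors
import networkx as nx

from .selectivity import InputError, difference_latency, LatencyEstimate


@dataclass
class SelectivityProfile:
    unit_id: str
    t_values: np.ndarray
    included: bool
    reason: str = ""


def t_profile(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    grid: np.ndarray,
    analysis_window: tuple[float, float] = (0.0, 300.0),
    baseline_window: tuple[float, float] = (-150.0, 0.0),
    alpha: float = 0.05,
    alpha_noise: float = 0.1,
    min_run: int = 10,
    unit_id: str = "",
) -> SelectivityProfile:
    """Per-bin two-sample t values for one unit with inclusion screening.

    Inclusion requires a run of at least ``min_run`` consecutive 1-ms bins with
    p < ``alpha`` inside the analysis window; units whose conditions already
    differ during the baseline (t test at ``alpha_noise``) are excluded as
    noisy.  Degenerate-variance bins get t = 0.
    """
    in_win = (grid >= analysis_window[0]) & (grid < analysis_window[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(rates_a, rates_b, axis=0)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)

    base = (grid >= baseline_window[0]) & (grid < baseline_window[1])
    base_a = rates_a[:, base].mean(axis=1)
    base_b = rates_b[:, base].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p_base = stats.ttest_ind(base_a, base_b)
    if np.isfinite(p_base) and p_base < alpha_noise:
        return SelectivityProfile(unit_id, t[in_win], False, "baseline condition difference")

    sig = p[in_win] < alpha
    run = best = 0
    for s in sig:
        run = run + 1 if s else 0
        best = max(best, run)
    if best < min_run:
        return SelectivityProfile(
            unit_id, t[in_win], False, f"no {min_run}-bin significant run"
        )
    return SelectivityProfile(unit_id, t[in_win], True)


def compute_t_profiles(
    unit_rates_a: list[np.ndarray],
    unit_rates_b: list[np.ndarray],
    grid: np.ndarray,
    unit_ids: list[str] | None = None,
    **kwargs,
) -> list[SelectivityProfile]:
    unit_ids = unit_ids or [f"u{i:03d}" for i in range(len(unit_rates_a))]
    return [
        t_profile(a, b, grid, unit_id=uid, **kwargs)
        for a, b, uid in zip(unit_rates_a, unit_rates_b, unit_ids)
    ]


# --------------------------------------------------------------------------
# PhenoGraph-style clustering
# --------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # contiguous from 0, ordered by descending cluster size
    k: int
    modularity: float
    graph: nx.Graph = field(repr=False, default=None)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def phenograph_cluster(
    profiles: np.ndarray,
    k: int = 40,
    seed: int = 0,
    resolution: float = 1.0,
    min_size: int = 3,
) -> ClusterAssignment:
    """kNN -> shared-neighbor (Jaccard) graph -> Louvain communities.

    Communities smaller than ``min_size`` are merged into the cluster with the
    nearest centroid.  Labels are invariant (up to renaming) to the order of
    the input rows.
    """
    x = np.asarray(profiles, dtype=float)
    n = x.shape[0]
    if n <= k:
        raise InputError(f"need more samples than neighbors: N={n} <= K={k}; reduce K")
    if np.allclose(x, x[0]):  # degenerate: identical profiles carry no structure
        g = nx.complete_graph(n)
        return ClusterAssignment(np.zeros(n, dtype=int), k, 0.0, g)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    idx = idx[:, 1:]  # drop self
    neighbor_sets = [set(row) for row in idx]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            a, b = (i, j) if i < j else (j, i)
            if g.has_edge(a, b):
                continue
            shared = len(neighbor_sets[a] & neighbor_sets[b])
            union = len(neighbor_sets[a] | neighbor_sets[b])
            if shared > 0:
                g.add_edge(a, b, weight=shared / union)
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    labels = np.empty(n, dtype=int)
    for c, members in enumerate(comms):
        for m in members:
            labels[m] = c
    # merge tiny communities into the nearest (by centroid) larger one
    sizes = np.bincount(labels)
    big = np.flatnonzero(sizes >= min_size)
    if big.size and (sizes < min_size).any():
        centroids = np.vstack([x[labels == c].mean(axis=0) for c in big])
        for c in np.flatnonzero(sizes < min_size):
            members = np.flatnonzero(labels == c)
            d = np.linalg.norm(centroids - x[members].mean(axis=0), axis=1)
            labels[members] = big[np.argmin(d)]
    # relabel contiguous by descending size
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[v] for v in labels])
    part = [set(np.flatnonzero(labels == c)) for c in range(labels.max() + 1)]
    mod = nx.community.modularity(g, part, weight="weight") if g.number_of_edges() else 0.0
    return ClusterAssignment(labels, k, float(mod), g)


# --------------------------------------------------------------------------
# cluster summaries
# --------------------------------------------------------------------------


@dataclass
class ClusterSummary:
    cluster: int
    n_units: int
    mean_a: np.ndarray  # baseline-subtracted condition means (time,)
    mean_b: np.ndarray
    difference: np.ndarray  # per-unit differences averaged (time,)
    sem: np.ndarray
    latency: LatencyEstimate


def cluster_summaries(
    labels: np.ndarray,
    unit_means_a: np.ndarray,
    unit_means_b: np.ndarray,
    grid: np.ndarray,
    baseline_window: tuple[float, float] = (-150.0, 0.0),
    latency_window: tuple[float, float] = (0.0, 300.0),
    latency_bin_ms: float = 5.0,
    alpha: float = 0.05,
) -> list[ClusterSummary]:
    """Baseline-subtracted condition means and difference latencies per cluster.

    ``unit_means_*`` are (units, time) condition-mean rates (normalized
    upstream).  Latency uses one-sample t tests across the cluster's units in
    5-ms bins with Bonferroni correction over the latency window.
    """
    base = (grid >= baseline_window[0]) & (grid < baseline_window[1])
    a0 = unit_means_a - unit_means_a[:, base].mean(axis=1, keepdims=True)
    b0 = unit_means_b - unit_means_b[:, base].mean(axis=1, keepdims=True)
    diff = a0 - b0

    lat_mask = (grid >= latency_window[0]) & (grid < latency_window[1])
    lat_grid = grid[lat_mask]
    n_bins = int(lat_grid.size // latency_bin_ms)
    bin_starts = lat_grid[0] + latency_bin_ms * np.arange(n_bins)

    out = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            warnings.warn(f"cluster {c} is empty; skipped")
            continue
        d = diff[members][:, lat_mask][:, : n_bins * int(latency_bin_ms)]
        d_binned = d.reshape(members.size, n_bins, int(latency_bin_ms)).mean(axis=2)
        lat = (
            difference_latency(d_binned, bin_starts, alpha=alpha)
            if members.size >= 2
            else LatencyEstimate(None)
        )
        out.append(
            ClusterSummary(
                cluster=int(c),
                n_units=int(members.size),
                mean_a=a0[members].mean(axis=0),
                mean_b=b0[members].mean(axis=0),
                difference=diff[members].mean(axis=0),
                sem=diff[members].std(axis=0, ddof=1) / np.sqrt(members.size)
                if members.size > 1
                else np.zeros(grid.size),
                latency=lat,
            )
        )
    return out
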