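"""Per-unit selectivity statistics.

Modulation index, nonparametric rank effect size, time-resolved AUROC with
per-unit shuffle nulls and a population-level permutation test with FDR
correction, difference-latency estimation, omega-squared percent explained
variance (PEV) with permutation z-scoring, and selectivity classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


class InputError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


# --------------------------------------------------------------------------
# scalar indices
# --------------------------------------------------------------------------


def modulation_index(fr1: float, fr2: float) -> float:
    """(FR1 - FR2) / (FR1 + FR2); NaN when both rates are zero."""
    if fr1 < 0 or fr2 < 0:
        raise InputError("firing rates must be nonnegative")
    s = fr1 + fr2
    if s == 0:
        return float("nan")
    return (fr1 - fr2) / s


def rank_effect_size(z: float, n: int) -> float:
    """Effect size r = z / sqrt(n) for rank tests (n observations)."""
    if n < 1:
        raise InputError("n must be >= 1")
    return z / np.sqrt(n)


# --------------------------------------------------------------------------
# AUROC
# --------------------------------------------------------------------------


def auroc_counts(a: np.ndarray, b: np.ndarray) -> float:
    """AUROC discriminating two spike-count samples via the criterion sweep.

    The ROC curve is built from the proportions of trials in which each
    condition's count exceeds a criterion swept from below zero to the maximum
    count; the trapezoidal area equals the Mann-Whitney statistic
    U/(n1*n2) with ties counted one half.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return float("nan")
    top = max(a.max(), b.max())
    criteria = np.concatenate([[-1.0], np.unique(np.concatenate([a, b])), [top + 1.0]])
    tpr = (a[:, None] > criteria[None, :]).mean(axis=0)
    fpr = (b[:, None] > criteria[None, :]).mean(axis=0)
    # criteria ascend -> rates descend; integrate over FPR ascending
    return float(np.trapezoid(tpr[::-1], fpr[::-1]))


@dataclass
class AurocSeries:
    auroc: np.ndarray  # (bins,)
    null: np.ndarray  # (n_shuffles, bins)
    window_starts: np.ndarray


def _rank_auroc_matrix(ranks: np.ndarray, idx: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """AUROC per bin from pooled mid-ranks and first-condition row indices."""
    r1 = ranks[idx, :].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def time_resolved_auroc(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    window_starts: np.ndarray,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
) -> AurocSeries:
    """Per-bin AUROC plus a per-unit shuffle null (labels permuted jointly
    across bins in each shuffle, preserving the temporal structure)."""
    rng = rng or np.random.default_rng()
    counts_a = np.atleast_2d(counts_a)
    counts_b = np.atleast_2d(counts_b)
    n1, n2 = counts_a.shape[0], counts_b.shape[0]
    obs = np.array(
        [auroc_counts(counts_a[:, j], counts_b[:, j]) for j in range(counts_a.shape[1])]
    )
    pooled = np.vstack([counts_a, counts_b])
    ranks = np.apply_along_axis(stats.rankdata, 0, pooled)
    null = np.empty((n_shuffles, pooled.shape[1]))
    for s in range(n_shuffles):
        idx = rng.permutation(n1 + n2)[:n1]
        null[s] = _rank_auroc_matrix(ranks, idx, n1, n2)
    return AurocSeries(obs, null, np.asarray(window_starts))


def population_auroc_test(
    unit_aurocs: np.ndarray,
    unit_nulls: np.ndarray,
    n_population_nulls: int = 1000,
    q: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Population test of the across-unit mean AUROC against its shuffle null.

    For each of ``n_population_nulls`` draws, one null value is selected per
    unit and averaged across units, giving a null distribution of population
    means per bin; two-sided p-values are then corrected across time bins with
    Benjamini-Hochberg at rate ``q``.  Returns ``(p_values, significant_mask)``.
    """
    rng = rng or np.random.default_rng()
    unit_aurocs = np.atleast_2d(unit_aurocs)  # (units, bins)
    if unit_nulls.ndim != 3 or unit_nulls.shape[0] != unit_aurocs.shape[0]:
        raise InputError("unit_nulls must be (units, shuffles, bins) matching unit_aurocs")
    n_units, n_shuf, n_bins = unit_nulls.shape
    obs = np.nanmean(unit_aurocs, axis=0)
    draws = rng.integers(0, n_shuf, size=(n_population_nulls, n_units))
    null_means = unit_nulls[np.arange(n_units)[None, :], draws, :].mean(axis=1)
    ge = (null_means >= obs[None, :]).sum(axis=0)
    le = (null_means <= obs[None, :]).sum(axis=0)
    p = 2.0 * (np.minimum(ge, le) + 1) / (n_population_nulls + 1)
    p = np.minimum(p, 1.0)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p, reject


# --------------------------------------------------------------------------
# latency
# --------------------------------------------------------------------------


@dataclass
class LatencyEstimate:
    latency_ms: float | None
    bin_width_ms: float = 5.0
    run_length: int = 5


def difference_latency(
    diffs: np.ndarray,
    bin_starts: np.ndarray,
    alpha: float = 0.05,
    run_length: int = 5,
    family_size: int | None = None,
) -> LatencyEstimate:
    """First bin opening a run of ``run_length`` Bonferroni-significant bins.

    ``diffs`` is a (samples, bins) matrix of condition differences in 5-ms
    bins; each bin is tested against zero with a one-sample t test at
    ``alpha / family_size`` (family defaults to the number of bins).
    """
    diffs = np.atleast_2d(diffs)
    n_bins = diffs.shape[1]
    if n_bins < run_length:
        raise InputError(f"need at least {run_length} bins, got {n_bins}")
    family = family_size or n_bins
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_1samp(diffs, 0.0, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    sig = p < alpha / family
    run = 0
    for j in range(n_bins):
        run = run + 1 if sig[j] else 0
        if run >= run_length:
            start = j - run_length + 1
            return LatencyEstimate(float(bin_starts[start]), run_length=run_length)
    return LatencyEstimate(None, run_length=run_length)


def latency_compare(
    latencies_a: list[float | None],
    latencies_b: list[float | None],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for the difference of group median latencies."""
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    a = np.array([x for x in latencies_a if x is not None], dtype=float)
    b = np.array([x for x in latencies_b if x is not None], dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups need at least one defined latency")
    rng = rng or np.random.default_rng()
    obs = abs(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(np.median(perm[: a.size]) - np.median(perm[a.size :]))
        if stat >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


# --------------------------------------------------------------------------
# omega-squared PEV
# --------------------------------------------------------------------------


@dataclass
class PEVResult:
    omega2: np.ndarray  # (windows,)
    z_pev: np.ndarray  # (windows,)
    window_starts: np.ndarray
    levels: np.ndarray


def _omega2(counts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Unbiased explained variance per window from one-way ANOVA sums of squares:
    omega2 = (SS_between - df_between * MSE) / (SS_total + MSE)."""
    levels, inv = np.unique(labels, return_inverse=True)
    k = levels.size
    n = counts.shape[0]
    grand = counts.mean(axis=0)
    group_sums = np.zeros((k, counts.shape[1]))
    np.add.at(group_sums, inv, counts)
    sizes = np.bincount(inv, minlength=k).astype(float)
    group_means = group_sums / sizes[:, None]
    ss_between = (sizes[:, None] * (group_means - grand) ** 2).sum(axis=0)
    ss_total = ((counts - grand) ** 2).sum(axis=0)
    df_b, df_e = k - 1, n - k
    mse = (ss_total - ss_between) / df_e
    with np.errstate(invalid="ignore", divide="ignore"):
        om = (ss_between - df_b * mse) / (ss_total + mse)
    return np.where(ss_total + mse == 0, 0.0, om)


def pev_omega2(
    counts: np.ndarray,
    labels: np.ndarray,
    window_starts: np.ndarray,
    n_shuffle: int = 200,
    rng: np.random.Generator | None = None,
) -> PEVResult:
    """Time-resolved omega-squared PEV of a location factor with permutation
    z-scoring (labels shuffled across trials, ``n_shuffle`` times)."""
    rng = rng or np.random.default_rng()
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    labels = np.asarray(labels)
    levels, cnt = np.unique(labels, return_counts=True)
    keep_levels = levels[cnt >= 2]
    if keep_levels.size < levels.size:
        warnings.warn(
            f"dropping levels with < 2 trials: {sorted(set(levels) - set(keep_levels))}"
        )
    if keep_levels.size < 2:
        raise InputError("need at least 2 levels with >= 2 trials each")
    keep = np.isin(labels, keep_levels)
    counts, labels = counts[keep], labels[keep]
    obs = _omega2(counts, labels)
    null = np.empty((n_shuffle, counts.shape[1]))
    lab = labels.copy()
    for s in range(n_shuffle):
        rng.shuffle(lab)
        null[s] = _omega2(counts, lab)
    mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mu) / sd
    z = np.where(sd == 0, np.nan, z)
    return PEVResult(obs, z, np.asarray(window_starts), keep_levels)


def classify_selectivity(
    z_target: np.ndarray,
    z_singleton: np.ndarray,
    window_starts: np.ndarray,
    threshold: float = 1.645,
    window: tuple[float, float] = (150.0, 200.0),
    window_width: float = 50.0,
) -> str:
    """target / singleton / mixed / nonselective from z-scored PEV in-window.

    A context is significant if its z-scored PEV strictly exceeds
    ``threshold`` (one-tailed) in any window fully inside ``window``.
    """
    starts = np.asarray(window_starts, dtype=float)
    sel = (starts >= window[0]) & (starts + window_width <= window[1] + 1e-9)
    if not sel.any():
        raise InputError("no PEV window inside the classification interval")
    sig_t = bool(np.nanmax(np.asarray(z_target)[sel]) > threshold)
    sig_s = bool(np.nanmax(np.asarray(z_singleton)[sel]) > threshold)
    if sig_t and sig_s:
        return "mixed"
    if sig_t:
        return "target"
    if sig_s:
        return "singleton"
    return "nonselective"
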