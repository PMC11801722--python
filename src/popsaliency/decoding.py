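"""Pseudo-population decoding with permutation inference.

Units recorded in different sessions are combined into pseudo-populations by
stratified trial resampling; a linear SVM decodes the RF content (2 classes)
or the stimulus location (5 classes, the contralateral hemifield positions)
from spike counts in sliding windows, with 5-fold cross-validation, joint
0-1 scaling of train and test data, shuffle nulls, and a two-sided
cluster-based permutation test over time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

log = logging.getLogger(__name__)


class InputError(ValueError):
    pass


@dataclass
class PseudoPopulation:
    """Resampled unit x sample count tensors.

    ``counts`` has shape (n_resamples, n_samples, n_units, n_windows) with
    exactly ``n_trials`` samples per label (balanced priors).
    """

    counts: np.ndarray
    labels: np.ndarray  # (n_samples,)
    window_starts: np.ndarray
    unit_index: np.ndarray  # indices of the units retained

    @property
    def n_resamples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_classes(self) -> int:
        return np.unique(self.labels).size


def build_pseudopopulation(
    unit_label_counts: list[dict[object, np.ndarray]],
    n_trials: int = 10,
    n_resamples: int = 50,
    seed: int = 0,
    window_starts: np.ndarray | None = None,
) -> PseudoPopulation:
    """Assemble balanced pseudo-trials by per-unit random draws.

    ``unit_label_counts[u][label]`` is a (trials, windows) count matrix for
    one unit and condition label.  Units with fewer than ``n_trials`` trials
    for any label are excluded (logged).  Draws are without replacement.
    """
    rng = np.random.default_rng(seed)
    labels_all = sorted({lab for d in unit_label_counts for lab in d}, key=str)
    keep = []
    for u, d in enumerate(unit_label_counts):
        ok = all(lab in d and d[lab].shape[0] >= n_trials for lab in labels_all)
        if ok:
            keep.append(u)
        else:
            log.info("unit %d excluded from pseudo-population (<%d trials)", u, n_trials)
    if not keep:
        raise InputError(f"no unit has >= {n_trials} trials for every label")
    n_windows = unit_label_counts[keep[0]][labels_all[0]].shape[1]
    y = np.repeat(np.arange(len(labels_all)), n_trials)
    counts = np.empty((n_resamples, y.size, len(keep), n_windows))
    for r in range(n_resamples):
        for ui, u in enumerate(keep):
            col = []
            for lab in labels_all:
                pool = unit_label_counts[u][lab]
                sel = rng.choice(pool.shape[0], size=n_trials, replace=False)
                col.append(pool[sel])
            counts[r, :, ui, :] = np.vstack(col)
    if window_starts is None:
        window_starts = np.arange(n_windows)
    return PseudoPopulation(counts, y, np.asarray(window_starts), np.asarray(keep))


@dataclass
class DecodingResult:
    accuracy: np.ndarray  # (n_resamples, n_windows)
    window_starts: np.ndarray
    chance: float
    null: np.ndarray | None = None  # (n_shuffles, n_windows)
    p_values: np.ndarray | None = None
    clusters: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)


def _scale01(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0, keepdims=True)
    rng_ = x.max(axis=0, keepdims=True) - lo
    rng_[rng_ == 0] = 1.0
    return (x - lo) / rng_


def _cv_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    folds: int,
    c: float,
    seed: int,
    scale_train_only: bool,
) -> float:
    """Stratified k-fold accuracy of a linear SVM on one window's samples."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    if not scale_train_only:
        x = _scale01(x)
    for train, test in skf.split(x, y):
        xtr, xte = x[train], x[test]
        if scale_train_only:
            lo = xtr.min(axis=0, keepdims=True)
            span = xtr.max(axis=0, keepdims=True) - lo
            span[span == 0] = 1.0
            xtr = (xtr - lo) / span
            xte = (xte - lo) / span
        clf = SVC(kernel="linear", C=c)
        clf.fit(xtr, y[train])
        correct += int((clf.predict(xte) == y[test]).sum())
    return correct / y.size


def decode_timecourse(
    pop: PseudoPopulation,
    folds: int = 5,
    c: float = 1.0,
    seed: int = 0,
    scale_train_only: bool = False,
) -> DecodingResult:
    """Linear-SVM decoding accuracy per window, averaged over CV folds.

    By default the 0-1 scaling is computed once per window over all samples
    and applied to train and test alike; ``scale_train_only=True`` gives the
    leakage-free variant.
    """
    _, n_samples, _, n_windows = pop.counts.shape
    counts_per_class = np.bincount(pop.labels).min()
    if counts_per_class < folds:
        raise InputError(f"need >= {folds} samples per label, got {counts_per_class}")
    acc = np.empty((pop.n_resamples, n_windows))
    for r in range(pop.n_resamples):
        for w in range(n_windows):
            acc[r, w] = _cv_accuracy(
                pop.counts[r, :, :, w], pop.labels, folds, c, seed + r, scale_train_only
            )
    return DecodingResult(acc, pop.window_starts, 1.0 / pop.n_classes)


def shuffle_null(
    pop: PseudoPopulation,
    n_shuffles: int = 500,
    folds: int = 5,
    c: float = 1.0,
    seed: int = 0,
    observed: DecodingResult | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Null accuracy distribution per window by shuffling trial labels.

    Returns ``(null, p)`` where ``null`` is (n_shuffles, n_windows); ``p`` is
    the upper-tail rank of the observed mean accuracy in the null when an
    observed result is supplied.
    """
    if n_shuffles < 100:
        log.warning("n_shuffles=%d < 100: p-values will be unstable", n_shuffles)
    rng = np.random.default_rng(seed)
    n_windows = pop.counts.shape[3]
    null = np.empty((n_shuffles, n_windows))
    for s in range(n_shuffles):
        r = s % pop.n_resamples
        y = rng.permutation(pop.labels)
        for w in range(n_windows):
            null[s, w] = _cv_accuracy(pop.counts[r, :, :, w], y, folds, c, seed + s, False)
    p = None
    if observed is not None:
        obs = observed.mean_accuracy
        p = ((null >= obs[None, :]).sum(axis=0) + 1) / (n_shuffles + 1)
    return null, p


# --------------------------------------------------------------------------
# cluster-based permutation test
# --------------------------------------------------------------------------


@dataclass
class TimeCluster:
    start: int
    end: int  # inclusive bin indices
    mass: float
    p: float


def _clusters_from_stat(t: np.ndarray, thresh: float) -> list[tuple[int, int, float]]:
    """Contiguous runs where |t| exceeds ``thresh``, same sign within a run."""
    out = []
    j = 0
    n = t.size
    while j < n:
        if abs(t[j]) > thresh:
            sign = np.sign(t[j])
            k = j
            while k + 1 < n and abs(t[k + 1]) > thresh and np.sign(t[k + 1]) == sign:
                k += 1
            out.append((j, k, float(t[j : k + 1].sum())))
            j = k + 1
        else:
            j += 1
    return out


def max_cluster_masses(t_mat: np.ndarray, thresh: float) -> np.ndarray:
    """Max |cluster mass| per row of a (perms, bins) t matrix (vectorized)."""
    p, b = t_mat.shape
    mask = np.abs(t_mat) > thresh
    signed = np.where(mask, t_mat, 0.0)
    # break clusters at sign changes and row boundaries
    flat = signed.reshape(-1)
    on = flat != 0.0
    sign = np.sign(flat)
    row_start = np.zeros(p * b, dtype=bool)
    row_start[::b] = True
    new_run = on & (
        ~np.roll(on, 1) | (sign != np.roll(sign, 1)) | row_start
    )
    run_id = np.cumsum(new_run) * on
    masses = np.zeros(p)
    if run_id.max() > 0:
        sums = np.abs(np.bincount(run_id, weights=flat))
        sums[0] = 0.0
        rows = np.zeros(run_id.max() + 1, dtype=int)
        first_idx = np.flatnonzero(new_run)
        rows[run_id[first_idx]] = first_idx // b
        np.maximum.at(masses, rows[1:], sums[1:])
    return masses


def cluster_permutation_test(
    series_a: np.ndarray,
    series_b: np.ndarray | float,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[TimeCluster]:
    """Two-sided cluster-based permutation test over time bins.

    ``series_a`` is (samples, bins); ``series_b`` is a paired (samples, bins)
    series or a scalar reference (e.g., chance level).  Per-bin one-sample t
    statistics of the paired differences form clusters of contiguous bins
    exceeding the two-sided threshold at ``alpha``; cluster mass (summed t) is
    compared against a sign-flip permutation distribution of maximal masses.
    """
    a = np.atleast_2d(np.asarray(series_a, dtype=float))
    if np.isscalar(series_b):
        diffs = a - float(series_b)
    else:
        b = np.atleast_2d(np.asarray(series_b, dtype=float))
        if b.shape != a.shape:
            raise InputError(f"series shapes differ: {a.shape} vs {b.shape}")
        diffs = a - b
    n, n_bins = diffs.shape
    if n < 2:
        raise InputError("need >= 2 paired samples")
    rng = np.random.default_rng(seed)
    thresh = stats.t.ppf(1 - alpha / 2, df=n - 1)

    def t_stat(d: np.ndarray) -> np.ndarray:
        sd = d.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        return d.mean(axis=0) / (sd / np.sqrt(n))

    t_obs = t_stat(diffs)
    clusters = _clusters_from_stat(t_obs, thresh)
    if not clusters:
        return []
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = np.empty((n_perm, n_bins))
    for i in range(n_perm):
        t_null[i] = t_stat(diffs * flips[i][:, None])
    null_max = max_cluster_masses(t_null, thresh)
    out = []
    for start, end, mass in clusters:
        p = float(((null_max >= abs(mass)).sum() + 1) / (n_perm + 1))
        out.append(TimeCluster(start, end, mass, p))
    return out


def significant_clusters(clusters: list[TimeCluster], alpha: float = 0.05) -> list[TimeCluster]:
    return [c for c in clusters if c.p < alpha]


def stratify_units(
    n_units_a: int,
    n_units_b: int,
    n_resamples: int = 50,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Subsample the larger population to the size of the smaller, per resample."""
    rng = np.random.default_rng(seed)
    m = min(n_units_a, n_units_b)
    idx_a, idx_b = [], []
    for _ in range(n_resamples):
        idx_a.append(np.sort(rng.choice(n_units_a, m, replace=False)))
        idx_b.append(np.sort(rng.choice(n_units_b, m, replace=False)))
    return idx_a, idx_b
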