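"""Behavioral statistics and the fast/slow median split.

Summaries of search behavior (first-saccade destination, search times per
display type, saccade counts) and the median split of trials by search time,
which links neural distractor suppression to behavioral performance: if more
strongly suppressed distractor responses speed up search, distractor-in-RF
firing should be lower on fast than on slow trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import window_mean
from .selectivity import auroc_counts, modulation_index


class InputError(ValueError):
    pass


#: probability of the first saccade landing on any one of the 8 positions
#: under random search
RANDOM_SEARCH_CHANCE = 1.0 / 8.0


@dataclass
class BehaviorSummary:
    n_trials: int
    first_saccade_to_singleton_rate: float
    first_saccade_chi2: float
    first_saccade_p: float
    median_search_time_ms: dict[str, float]
    search_time_comparisons: dict[tuple[str, str], float]  # rank-sum p-values
    mean_saccade_count: dict[str, float]
    median_first_saccade_latency_ms: dict[str, float]
    notes: list[str] = field(default_factory=list)


def summarize_behavior(trials: pd.DataFrame) -> BehaviorSummary:
    """Search-behavior summary with the random-search chance test.

    The first-saccade-to-singleton rate (singleton-present displays) is tested
    against the 1/8 = 12.5% expectation of random search with a chi-squared
    goodness-of-fit test; search times are compared across display types with
    Wilcoxon rank-sum tests.
    """
    if len(trials) == 0:
        raise InputError("no completed trials")
    present = trials[trials["singleton_pos"] >= 0]
    notes: list[str] = []
    if len(present):
        hits = int((present["first_saccade_pos"] == present["singleton_pos"]).sum())
        n = len(present)
        rate = hits / n
        expected = np.array([RANDOM_SEARCH_CHANCE, 1 - RANDOM_SEARCH_CHANCE]) * n
        chi2, p = stats.chisquare([hits, n - hits], expected)
    else:
        rate, chi2, p = float("nan"), float("nan"), float("nan")
        notes.append("no singleton-present trials; chance test skipped")

    medians, counts, latencies = {}, {}, {}
    for disp, grp in trials.groupby("display_type"):
        medians[disp] = float(grp["search_time_ms"].median())
        counts[disp] = float(grp["n_saccades"].mean())
        latencies[disp] = float(grp["first_saccade_latency_ms"].median())
    comparisons = {}
    display_types = sorted(medians)
    if len(display_types) < 2:
        notes.append("single display type; cross-type comparisons skipped")
    else:
        for i, a in enumerate(display_types):
            for b in display_types[i + 1 :]:
                _, pr = stats.ranksums(
                    trials.loc[trials["display_type"] == a, "search_time_ms"],
                    trials.loc[trials["display_type"] == b, "search_time_ms"],
                )
                comparisons[(a, b)] = float(pr)
    return BehaviorSummary(
        n_trials=len(trials),
        first_saccade_to_singleton_rate=float(rate),
        first_saccade_chi2=float(chi2),
        first_saccade_p=float(p),
        median_search_time_ms=medians,
        search_time_comparisons=comparisons,
        mean_saccade_count=counts,
        median_first_saccade_latency_ms=latencies,
        notes=notes,
    )


# --------------------------------------------------------------------------
# fast/slow median split
# --------------------------------------------------------------------------


def median_split(
    trials: pd.DataFrame,
    per_display_type: bool = True,
) -> pd.Series:
    """Label each trial 'fast' or 'slow' by the median search time.

    The split is computed within each display type by default (search-time
    distributions differ across displays).  Trials are stably sorted by search
    time (ties broken by trial order, which assigns tied-at-median trials
    alternately to the two halves); group sizes differ by at most one.
    """
    labels = pd.Series(index=trials.index, dtype=object)
    groups = trials.groupby("display_type").groups.values() if per_display_type else [
        trials.index
    ]
    for idx in groups:
        idx = pd.Index(idx)
        st = trials.loc[idx, "search_time_ms"]
        if st.nunique() == 1 and len(st) > 1:
            raise InputError("all search times equal; median split undefined")
        order = st.sort_values(kind="stable").index
        half = len(order) // 2
        labels.loc[order[:half]] = "fast"
        labels.loc[order[half:]] = "slow"
    labels.name = "speed"
    return labels


@dataclass
class SpeedContrast:
    condition: str
    modulation_indices: np.ndarray  # per unit, fast vs slow
    aurocs: np.ndarray  # per unit, fast vs slow
    n_fast: int
    n_slow: int


def median_split_contrast(
    rates: np.ndarray,
    grid: np.ndarray,
    trials: pd.DataFrame,
    split: pd.Series,
    conditions: dict[str, pd.Series] | None = None,
    window: tuple[float, float] = (150.0, 200.0),
    min_trials: int = 10,
) -> list[SpeedContrast]:
    """Fast-vs-slow modulation index and AUROC per unit and condition.

    ``rates`` is (units, trials, time); ``conditions`` maps a condition name
    to a boolean trial mask (defaults: singleton / non-singleton distractor in
    the RF on singleton-present displays, first saccade away from the RF).
    Negative modulation indices mean lower distractor-evoked firing on fast
    trials.
    """
    if conditions is None:
        away = trials["first_saccade_dir"] == "away_from_rf"
        present = trials["display_type"] == "singleton_present"
        conditions = {
            "singleton_in_rf": present & away & (trials["rf_content"] == "salient_distractor"),
            "nonsalient_in_rf": present
            & away
            & (trials["rf_content"] == "nonsalient_distractor"),
        }
    out = []
    wmeans = window_mean(rates, grid, window)  # (units, trials)
    for name, mask in conditions.items():
        fast = np.flatnonzero(mask & (split == "fast"))
        slow = np.flatnonzero(mask & (split == "slow"))
        if len(fast) < min_trials or len(slow) < min_trials:
            continue
        mis = np.array(
            [
                modulation_index(wmeans[u, fast].mean(), wmeans[u, slow].mean())
                for u in range(rates.shape[0])
            ]
        )
        aucs = np.array(
            [auroc_counts(wmeans[u, fast], wmeans[u, slow]) for u in range(rates.shape[0])]
        )
        out.append(SpeedContrast(name, mis, aucs, len(fast), len(slow)))
    return out
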