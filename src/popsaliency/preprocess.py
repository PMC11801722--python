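"""Raw sessions -> analysis-ready firing rates.

Saccade detection from eye traces (velocity + amplitude thresholds), Gaussian
spike-density estimation, across-condition max normalization, the visual
responsiveness screen, and contrast-based trial selection.

All analysis windows are half-open ``[a, b)`` ms relative to array onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .synth import Session


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class KernelParams:
    sigma_ms: float = 10.0
    truncation: float = 4.0  # kernel support in multiples of sigma

    def __post_init__(self):
        if self.sigma_ms <= 0:
            raise InputError("sigma must be > 0")


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    direction_rad: float


def detect_saccades(
    t_ms: np.ndarray,
    x_deg: np.ndarray,
    y_deg: np.ndarray,
    v_thresh: float = 50.0,
    amp_thresh: float = 0.4,
    merge_gap_ms: float = 10.0,
    min_duration_ms: float = 8.0,
) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detection.

    Instantaneous speed sqrt(vx^2 + vy^2) is computed with central differences
    on the position samples; suprathreshold segments closer than
    ``merge_gap_ms`` are merged, and a segment becomes an event only if its
    start-to-end displacement reaches ``amp_thresh`` and its duration reaches
    ``min_duration_ms``.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    if t_ms.size < 3:
        raise InputError("eye trace must have at least 3 samples")
    vx = np.gradient(np.asarray(x_deg, dtype=float), t_ms) * 1e3  # deg/s
    vy = np.gradient(np.asarray(y_deg, dtype=float), t_ms) * 1e3
    speed = np.hypot(vx, vy)
    above = speed > v_thresh
    if not above.any():
        return []
    # contiguous suprathreshold runs
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(np.flatnonzero(above & ~np.roll(above, 1)))
    if above[0]:
        starts = [0] + [s for s in starts if s != 0]
    ends = []
    for s in starts:
        e = s
        while e + 1 < above.size and above[e + 1]:
            e += 1
        ends.append(e)
    del edges
    # merge runs separated by short gaps
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and t_ms[s] - t_ms[merged[-1][1]] <= merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        if t_ms[e] - t_ms[s] < min_duration_ms:
            continue
        # displacement over the segment, padded one sample to catch the tails
        s0, e0 = max(s - 1, 0), min(e + 1, t_ms.size - 1)
        dx = x_deg[e0] - x_deg[s0]
        dy = y_deg[e0] - y_deg[s0]
        amp = float(np.hypot(dx, dy))
        if amp < amp_thresh:
            continue
        events.append(
            SaccadeEvent(
                onset_ms=float(t_ms[s]),
                offset_ms=float(t_ms[e]),
                amplitude_deg=amp,
                direction_rad=float(np.arctan2(dy, dx)),
            )
        )
    return events


def spike_density(
    spike_times: np.ndarray,
    grid: np.ndarray,
    kernel: KernelParams | None = None,
) -> np.ndarray:
    """Spike-density function (spikes/s) on a uniform ms grid.

    Spikes are binned at the grid step and convolved with a truncated Gaussian
    (no edge renormalization), so the time integral of the rate equals the
    in-window spike count up to truncation error.
    """
    kernel = kernel or KernelParams()
    grid = np.asarray(grid, dtype=float)
    dt = grid[1] - grid[0]
    edges = np.concatenate([grid, [grid[-1] + dt]])
    counts, _ = np.histogram(np.asarray(spike_times, dtype=float), bins=edges)
    rate = gaussian_filter1d(
        counts.astype(float), kernel.sigma_ms / dt, mode="constant", truncate=kernel.truncation
    )
    return rate * (1000.0 / dt)


def session_rates(
    session: Session,
    grid: np.ndarray | None = None,
    kernel: KernelParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed rates for every unit and trial.

    Returns ``(rates, grid)`` with ``rates`` of shape (units, trials, time)
    in spikes/s (float32).
    """
    if grid is None:
        grid = np.arange(-300.0, 500.0)
    rates = np.empty((session.n_units, session.n_trials, grid.size), dtype=np.float32)
    for u in range(session.n_units):
        for t in range(session.n_trials):
            rates[u, t] = spike_density(session.spikes[u][t], grid, kernel)
    return rates, grid


def sliding_window_counts(
    spike_times: list[np.ndarray],
    window_starts: np.ndarray,
    width_ms: float = 50.0,
) -> np.ndarray:
    """Spike counts per trial in sliding windows [start, start + width).

    Returns an array of shape (trials, windows).
    """
    starts = np.asarray(window_starts, dtype=float)
    counts = np.empty((len(spike_times), starts.size))
    for i, times in enumerate(spike_times):
        t = np.asarray(times, dtype=float)
        counts[i] = np.searchsorted(t, starts + width_ms) - np.searchsorted(t, starts)
    return counts


def window_mean(rates: np.ndarray, grid: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Mean over the half-open time window along the last axis."""
    m = (grid >= window[0]) & (grid < window[1])
    if not m.any():
        raise InputError(f"window {window} outside grid")
    return rates[..., m].mean(axis=-1)


def normalize_unit(
    condition_rates: dict[str, np.ndarray],
    grid: np.ndarray,
    window: tuple[float, float] = (40.0, 200.0),
) -> tuple[dict[str, np.ndarray], float, bool]:
    """Divide by the max across condition-mean rates in ``window``.

    ``condition_rates`` maps condition name -> (trials, time) rates of one
    unit.  Returns (normalized rates, scale, excluded) where ``excluded`` flags
    an all-zero normalization window (division undefined).
    """
    scale = 0.0
    for rates in condition_rates.values():
        mean_rate = rates.mean(axis=0)
        scale = max(scale, float(window_mean(mean_rate, grid, window)))
    if scale <= 0.0:
        return condition_rates, 0.0, True
    return {k: v / scale for k, v in condition_rates.items()}, scale, False


def screen_visual_responsive(
    trial_rates: np.ndarray,
    grid: np.ndarray,
    response_window: tuple[float, float] = (40.0, 120.0),
    baseline_window: tuple[float, float] = (-150.0, 0.0),
    alpha: float = 0.05,
) -> bool:
    """Paired t-test of per-trial response vs baseline window means."""
    if trial_rates.shape[0] < 2:
        raise InputError("need >= 2 trials for the responsiveness screen")
    resp = window_mean(trial_rates, grid, response_window)
    base = window_mean(trial_rates, grid, baseline_window)
    diff = resp - base
    if np.allclose(diff.std(ddof=1), 0.0):
        return False
    t, p = stats.ttest_rel(resp, base)
    return bool(p < alpha)


# --------------------------------------------------------------------------
# trial selection
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialFilter:
    display_types: tuple[str, ...]
    rf_content: tuple[str, ...]


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    cond_a: TrialFilter
    cond_b: TrialFilter
    away_only: bool = True
    labels: tuple[str, str] = ("cond_a", "cond_b")


#: named condition contrasts used throughout the analyses
CONTRASTS: dict[str, ContrastSpec] = {
    # singleton vs non-singleton distractor in the RF, singleton-present displays
    "singleton_vs_nonsalient_present": ContrastSpec(
        "singleton_vs_nonsalient_present",
        TrialFilter(("singleton_present",), ("salient_distractor",)),
        TrialFilter(("singleton_present",), ("nonsalient_distractor",)),
        labels=("singleton_in_rf", "nonsalient_in_rf"),
    ),
    # singleton-present vs singleton-absent displays (distractor in RF)
    "singleton_present_vs_absent": ContrastSpec(
        "singleton_present_vs_absent",
        TrialFilter(("singleton_present",), ("salient_distractor",)),
        TrialFilter(("singleton_absent",), ("nonsalient_distractor",)),
        labels=("singleton_in_rf", "absent_nonsalient_in_rf"),
    ),
    # same RF stimulus in salient vs non-salient (mixed-color) context
    "salient_context": ContrastSpec(
        "salient_context",
        TrialFilter(("singleton_present",), ("salient_distractor",)),
        TrialFilter(("mixed_color",), ("salient_distractor",)),
        labels=("salient_context", "nonsalient_context"),
    ),
    # behavioral relevance of the RF stimulus
    "target_vs_distractor": ContrastSpec(
        "target_vs_distractor",
        TrialFilter(("singleton_present",), ("target",)),
        TrialFilter(("singleton_present",), ("nonsalient_distractor",)),
        away_only=True,
        labels=("target_in_rf", "distractor_in_rf"),
    ),
}


@dataclass
class TrialSelection:
    contrast: ContrastSpec
    trials_a: np.ndarray
    trials_b: np.ndarray
    included: bool
    reason: str = ""


def _apply_filter(trials: pd.DataFrame, f: TrialFilter, away_only: bool) -> np.ndarray:
    m = trials["display_type"].isin(f.display_types) & trials["rf_content"].isin(f.rf_content)
    if away_only:
        m &= trials["first_saccade_dir"] == "away_from_rf"
    return trials.index[m].to_numpy()


def select_trials(
    session: Session,
    contrast: str | ContrastSpec,
    min_trials: int = 10,
) -> TrialSelection:
    """Per-condition trial sets for a contrast; enforces the >=10-trials rule."""
    if isinstance(contrast, str):
        try:
            contrast = CONTRASTS[contrast]
        except KeyError:
            raise InputError(
                f"unknown contrast {contrast!r}; known: {sorted(CONTRASTS)}"
            ) from None
    a = _apply_filter(session.trials, contrast.cond_a, contrast.away_only)
    b = _apply_filter(session.trials, contrast.cond_b, contrast.away_only)
    included = len(a) >= min_trials and len(b) >= min_trials
    reason = "" if included else f"fewer than {min_trials} qualifying trials per condition"
    return TrialSelection(contrast, a, b, included, reason)


def unit_qc(
    session: Session,
    rates: np.ndarray,
    grid: np.ndarray,
) -> pd.DataFrame:
    """Per-unit quality control: visual responsiveness and normalization scale."""
    rows = []
    for u, unit_id in enumerate(session.unit_ids):
        responsive = screen_visual_responsive(rates[u], grid)
        scale = float(window_mean(rates[u].mean(axis=0), grid, (40.0, 200.0)))
        rows.append(
            dict(
                unit_id=unit_id,
                visually_responsive=responsive,
                norm_scale=scale,
                excluded=not responsive or scale <= 0,
                exclusion_reason=""
                if responsive and scale > 0
                else ("not visually responsive" if scale > 0 else "no response in 40-200 ms"),
            )
        )
    return pd.DataFrame(rows)
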