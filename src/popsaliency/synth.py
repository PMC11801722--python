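"""Synthetic visual-search sessions with planted ground truth.

Emulates a free-viewing color-singleton search task: on each trial an array of
eight stimuli appears on a rhombus, one stimulus is the target, and (depending
on the display type) one distractor is a color singleton.  Units are assigned
response archetypes (singleton suppression, early enhancement followed by
suppression, sustained enhancement, or no singleton modulation) and low-rank
location tuning whose target/singleton population patterns span subspaces with
a controllable overlap, so every downstream stage of the pipeline has a
recovery test with known truth.

Spike trains are inhomogeneous Poisson; eye traces contain fixation jitter plus
sigmoidal saccades; search time is coupled to a per-trial latent state that
also modulates distractor-evoked firing, which plants a fast/slow behavioral
effect.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ARCHETYPES = ("suppression", "early_enh_late_supp", "enhancement", "nonselective")
DISPLAY_TYPES = ("singleton_present", "singleton_absent", "mixed_color")

#: positions contralateral to a right-hemisphere recording: the 3 left
#: hemifield locations plus the 2 vertical-meridian locations.
LEFT_HEMIFIELD = (2, 3, 4, 5, 6)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """A requested condition could not be generated."""


@dataclass(frozen=True)
class TaskLayout:
    """Eight-stimulus rhombus array; index 0 = right horizontal, counterclockwise."""

    n_positions: int = 8
    rf_position: int = 4  # contralateral (left) horizontal location
    eccentricity_deg: float = 6.0

    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_positions) / self.n_positions

    def position_xy(self, pos: int) -> tuple[float, float]:
        a = self.angles()[pos]
        return self.eccentricity_deg * np.cos(a), self.eccentricity_deg * np.sin(a)


@dataclass(frozen=True)
class GeometrySpec:
    """Planted population geometry.

    ``overlap`` maps to the cosine of every planted principal angle between the
    target-location and singleton-location pattern subspaces: 0 means all
    angles are 90 deg (orthogonal), 1 means identical subspaces.
    """

    d_true: int = 5
    overlap: float = 0.5

    def __post_init__(self):
        if not (1 <= self.d_true <= 5):
            raise ConfigurationError(f"d_true must be in [1, 5], got {self.d_true}")
        if not (0.0 <= self.overlap <= 1.0):
            raise ConfigurationError(f"overlap must be in [0, 1], got {self.overlap}")


# --- singleton gain profiles (multiplicative, on [0, 300) ms; 1 outside) ----

_GAIN_SEGMENTS = {
    # (t_on, t_off, gain); the profile is 1 elsewhere
    "suppression": [(75, 300, 0.70)],
    "early_enh_late_supp": [(25, 100, 1.35), (125, 300, 0.70)],
    "enhancement": [(75, 300, 1.30)],
    "nonselective": [],
}


def singleton_gain_profile(cluster_id: str, t_ms: np.ndarray) -> np.ndarray:
    """Multiplicative RF gain applied when the singleton sits in the RF."""
    gain = np.ones_like(t_ms, dtype=float)
    for t0, t1, g in _GAIN_SEGMENTS[cluster_id]:
        gain[(t_ms >= t0) & (t_ms < t1)] = g
    return gain


@dataclass
class UnitArchetype:
    cluster_id: str
    baseline_rate: float  # spikes/s
    visual_gain: float  # peak multiplicative gain of the visual transient
    target_tuning: np.ndarray  # additive drive (spikes/s) per target position
    singleton_tuning: np.ndarray  # additive drive (spikes/s) per singleton position

    def gain_profile(self, t_ms: np.ndarray) -> np.ndarray:
        return singleton_gain_profile(self.cluster_id, t_ms)


class Population(list):
    """List of :class:`UnitArchetype` with the planted geometry attached."""

    basis_target: np.ndarray  # N x d orthonormal
    basis_singleton: np.ndarray  # N x d orthonormal
    geometry: GeometrySpec


def _ramp(t_ms: np.ndarray, t_on: float = 40.0, t_full: float = 90.0) -> np.ndarray:
    """Visual response onset: 0 before t_on, linear to 1 at t_full, sustained."""
    return np.clip((t_ms - t_on) / (t_full - t_on), 0.0, 1.0)


def make_unit_population(
    n_units: int,
    cluster_mix: dict[str, float] | None = None,
    geometry: GeometrySpec | None = None,
    seed: int = 0,
    *,
    pattern_amplitude: float = 40.0,
    baseline_log_mean: float = 2.7,
    baseline_log_sd: float = 0.3,
) -> Population:
    """Draw unit archetypes with planted low-rank location tuning.

    The population target and singleton patterns are ``W = sqrt(N) * U @ L``
    with U an orthonormal N x d basis and L a d x 8 loading matrix; the two
    bases share principal angles ``arccos(overlap)`` by construction.
    ``pattern_amplitude`` is the Euclidean norm (spikes/s) of each per-location
    population pattern column.
    """
    if n_units < 1:
        raise ConfigurationError("n_units must be >= 1")
    cluster_mix = cluster_mix or {
        "suppression": 0.35,
        "early_enh_late_supp": 0.20,
        "enhancement": 0.15,
        "nonselective": 0.30,
    }
    unknown = set(cluster_mix) - set(ARCHETYPES)
    if unknown:
        raise ConfigurationError(f"unknown archetypes in mix: {sorted(unknown)}")
    props = np.array([cluster_mix.get(a, 0.0) for a in ARCHETYPES], dtype=float)
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ConfigurationError("cluster_mix must be nonnegative and sum to 1")
    geometry = geometry or GeometrySpec()

    rng = np.random.default_rng(seed)
    # largest-remainder apportionment of cluster counts
    raw = props * n_units
    counts = np.floor(raw).astype(int)
    rem = n_units - counts.sum()
    if rem:
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
    labels = np.repeat(np.arange(len(ARCHETYPES)), counts)
    rng.shuffle(labels)

    n_pos = 8
    # planted bases with principal angles arccos(overlap); tiny populations
    # (N < 2d) cannot host two subspaces at the requested angles, so the
    # effective dimensionality is reduced
    d = min(geometry.d_true, max(1, n_units // 2)) if n_units > 1 else 1
    q, _ = np.linalg.qr(rng.standard_normal((n_units, min(2 * d, n_units))))
    u_t = q[:, :d]
    v = q[:, d : 2 * d] if q.shape[1] >= 2 * d else u_t
    c = geometry.overlap
    u_s = c * u_t + np.sqrt(max(0.0, 1.0 - c * c)) * v
    u_s /= np.linalg.norm(u_s, axis=0, keepdims=True)
    # loadings: orthonormal rows, zero-mean across locations, so the planted
    # dimensions have equal strength and the centered pattern matrix has
    # exactly rank d
    zm = np.linalg.svd(np.eye(n_pos) - 1.0 / n_pos, full_matrices=False)[0][:, : n_pos - 1]

    def make_loadings() -> np.ndarray:
        z = rng.standard_normal((n_pos - 1, d))
        q, _ = np.linalg.qr(z)
        return (zm @ q[:, :d]).T  # d x n_pos

    scale = pattern_amplitude * np.sqrt(n_pos / d)
    w_t = scale * (u_t @ make_loadings())
    w_s = scale * (u_s @ make_loadings())

    baselines = rng.lognormal(baseline_log_mean, baseline_log_sd, n_units)
    gains = rng.uniform(1.5, 3.0, n_units)

    pop = Population(
        UnitArchetype(
            cluster_id=ARCHETYPES[labels[i]],
            baseline_rate=float(baselines[i]),
            visual_gain=float(gains[i]),
            target_tuning=w_t[i].copy(),
            singleton_tuning=w_s[i].copy(),
        )
        for i in range(n_units)
    )
    pop.basis_target = u_t
    pop.basis_singleton = u_s
    pop.geometry = geometry
    return pop


# --------------------------------------------------------------------------
# behavior model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorParams:
    """Generative behavioral model (the task literature gives no such model;
    parameters are the package's own defaults, see docs/methods.md)."""

    saccade_policy: str = "goal"  # "goal" (target-directed, singleton-avoidant) or "uniform"
    p_first_to_target: float = 0.55
    p_first_to_singleton: float = 0.015
    search_time_median_ms: float = 350.0
    singleton_absent_slowing: float = 1.12  # multiplicative on the median
    search_time_log_sd: float = 0.35
    coupling: float = 0.25  # latent state -> log search time
    rate_coupling: float = 0.15  # latent state -> distractor-evoked rate
    first_latency_median_ms: float = 185.0
    first_latency_log_sd: float = 0.12


_CONDITIONS: list[tuple[str, str]] = [
    ("singleton_present", "target"),
    ("singleton_present", "salient_distractor"),
    ("singleton_present", "nonsalient_distractor"),
    ("singleton_absent", "target"),
    ("singleton_absent", "nonsalient_distractor"),
    ("mixed_color", "target"),
    ("mixed_color", "salient_distractor"),
    ("mixed_color", "nonsalient_distractor"),
]


@dataclass
class Session:
    """One simulated recording session (the pipeline's sole input)."""

    unit_ids: list[str]
    spikes: list[list[np.ndarray]]  # [unit][trial] -> spike times, ms re array onset
    trials: pd.DataFrame
    eye_t: np.ndarray  # ms, 120 Hz grid
    eye: np.ndarray  # (n_trials, len(eye_t), 2) degrees
    layout: TaskLayout
    population: Population | None
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _rate_on_grid(
    unit: UnitArchetype,
    t_ms: np.ndarray,
    display: str,
    rf_content: str,
    target_pos: int,
    singleton_pos: int,
    state: float,
    rate_coupling: float,
) -> np.ndarray:
    """Mean firing rate (spikes/s) on the millisecond grid for one trial."""
    base = unit.baseline_rate * (1.0 + (unit.visual_gain - 1.0) * _ramp(t_ms))
    if display == "singleton_present" and rf_content == "salient_distractor":
        base = base * unit.gain_profile(t_ms)
    drive = unit.target_tuning[target_pos]
    if display == "singleton_present" and singleton_pos >= 0:
        drive = drive + unit.singleton_tuning[singleton_pos]
    evoked = base - unit.baseline_rate + drive * _ramp(t_ms)
    if rf_content != "target":
        evoked = evoked * np.exp(-rate_coupling * state)
    return np.maximum(unit.baseline_rate + evoked, 0.0)


def simulate_session(
    population: Population,
    layout: TaskLayout | None = None,
    n_trials_per_condition: int = 40,
    seed: int = 0,
    *,
    t_start: float = -500.0,
    t_stop: float = 800.0,
    behavior: BehaviorParams | None = None,
    conditions: list[tuple[str, str]] | None = None,
) -> Session:
    """Simulate inhomogeneous-Poisson spikes, trial metadata, and eye traces."""
    if n_trials_per_condition < 1:
        raise GenerationError("n_trials_per_condition must be >= 1")
    layout = layout or TaskLayout()
    behavior = behavior or BehaviorParams()
    conditions = conditions if conditions is not None else list(_CONDITIONS)
    for cond in conditions:
        if cond not in _CONDITIONS:
            raise GenerationError(f"unknown condition {cond!r}")

    rng = np.random.default_rng(seed)
    rf = layout.rf_position
    n_pos = layout.n_positions
    others = [p for p in range(n_pos) if p != rf]

    def stratified(pool: list[int], n: int) -> np.ndarray:
        """n draws balanced over pool (tile + shuffle), as in a blocked design."""
        reps = int(np.ceil(n / len(pool)))
        vals = np.tile(pool, reps)[:n]
        rng.shuffle(vals)
        return vals

    rows = []
    for display, rf_content in conditions:
        n = n_trials_per_condition
        if rf_content == "target":
            targets = np.full(n, rf)
        else:
            targets = stratified(others, n)
        if display == "singleton_absent":
            singles = np.full(n, -1)
        elif rf_content == "salient_distractor":
            singles = np.full(n, rf)
        else:
            pool = others if rf_content == "nonsalient_distractor" else list(range(n_pos))
            singles = stratified(pool, n)
            for i in range(n):  # singleton never coincides with the target;
                # swap with another trial to keep the location counts balanced
                if singles[i] == targets[i]:
                    for j in rng.permutation(n):
                        if singles[j] != targets[i] and singles[i] != targets[j]:
                            singles[i], singles[j] = singles[j], singles[i]
                            break
                    else:
                        alt = [p for p in pool if p != targets[i]]
                        singles[i] = alt[int(rng.integers(len(alt)))]
        for i in range(n):
            rows.append((display, int(targets[i]), int(singles[i]), rf_content))

    order = rng.permutation(len(rows))  # displays randomly interleaved
    rows = [rows[i] for i in order]
    n_trials = len(rows)

    # behavior: latent state couples distractor-evoked rate and search time
    state = rng.standard_normal(n_trials)
    trial_records = []
    saccade_plans = []
    for i, (display, target, singleton, rf_content) in enumerate(rows):
        lat = rng.lognormal(
            np.log(behavior.first_latency_median_ms), behavior.first_latency_log_sd
        )
        if behavior.saccade_policy == "uniform":
            first_pos = int(rng.integers(n_pos))
        else:
            u = rng.random()
            if singleton >= 0 and u < behavior.p_first_to_singleton:
                first_pos = singleton
            elif u < behavior.p_first_to_singleton + behavior.p_first_to_target:
                first_pos = target
            else:
                pool = [p for p in range(n_pos) if p != target and p != singleton]
                first_pos = int(rng.choice(pool))
        median = behavior.search_time_median_ms
        if display == "singleton_absent":
            median = median * behavior.singleton_absent_slowing
        st = rng.lognormal(
            np.log(median) - behavior.coupling * state[i], behavior.search_time_log_sd
        )
        st = float(max(st, lat + 60.0))
        n_sacc = 1 if first_pos == target else int(rng.choice([2, 3], p=[0.8, 0.2]))
        trial_records.append(
            dict(
                trial_id=i,
                display_type=display,
                target_pos=target,
                singleton_pos=singleton,
                rf_content=rf_content,
                first_saccade_pos=first_pos,
                first_saccade_dir="toward_rf" if first_pos == rf else "away_from_rf",
                first_saccade_latency_ms=round(float(lat), 3),
                n_saccades=n_sacc,
                search_time_ms=round(st, 3),
                array_onset_ms=0.0,
                latent_state=round(float(state[i]), 6),
            )
        )
        # saccade plan: first saccade; a corrective saccade to the target if needed
        x0, y0 = layout.position_xy(first_pos)
        plan = [(lat, float(np.hypot(x0, y0)), float(np.arctan2(y0, x0)))]
        if first_pos != target:
            t2 = max(lat + 120.0, st * 0.7)
            x1, y1 = layout.position_xy(target)
            plan.append(
                (t2, float(np.hypot(x1 - x0, y1 - y0)), float(np.arctan2(y1 - y0, x1 - x0)))
            )
        saccade_plans.append(plan)

    trials = pd.DataFrame(trial_records)

    # eye traces on a fixed 120 Hz grid
    eye_t = np.arange(-300.0, t_stop, 1000.0 / 120.0)
    eye = np.empty((n_trials, eye_t.size, 2))
    for i, plan in enumerate(saccade_plans):
        plan = [s for s in plan if s[0] < t_stop - 40.0]
        eye[i] = generate_eye_trace(eye_t, plan, rng=rng)

    # spikes
    t_grid = np.arange(t_start, t_stop)  # 1 ms bins
    n_units = len(population)
    spikes: list[list[np.ndarray]] = []
    for u, unit in enumerate(population):
        unit_spikes = []
        for i, rec in enumerate(trial_records):
            lam = (
                _rate_on_grid(
                    unit,
                    t_grid,
                    rec["display_type"],
                    rec["rf_content"],
                    rec["target_pos"],
                    rec["singleton_pos"],
                    state[i],
                    behavior.rate_coupling,
                )
                * 1e-3
            )
            counts = rng.poisson(lam)
            idx = np.repeat(np.arange(t_grid.size), counts)
            times = t_grid[idx] + rng.random(idx.size)
            unit_spikes.append(np.sort(times))
        spikes.append(unit_spikes)

    return Session(
        unit_ids=[f"u{u:03d}" for u in range(n_units)],
        spikes=spikes,
        trials=trials,
        eye_t=eye_t,
        eye=eye,
        layout=layout,
        population=population,
        seed=seed,
        config=dict(
            n_trials_per_condition=n_trials_per_condition,
            t_start=t_start,
            t_stop=t_stop,
            behavior=dataclasses.asdict(behavior),
            geometry=dataclasses.asdict(population.geometry),
        ),
    )


def generate_eye_trace(
    t_ms: np.ndarray,
    saccade_plan: list[tuple[float, float, float]],
    *,
    jitter_sd: float = 0.02,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fixation jitter plus sigmoidal saccade displacements.

    ``saccade_plan`` is a list of (onset ms, amplitude deg, direction rad) with
    increasing, non-overlapping onsets.  The logistic displacement profile has
    a 10-90% rise time of ``15 + 2*amplitude`` ms, so peak velocity exceeds
    50 deg/s for any amplitude >= 1 deg.
    """
    rng = rng or np.random.default_rng()
    onsets = [s[0] for s in saccade_plan]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise GenerationError("saccade onsets must be strictly increasing")
    durations = [15.0 + 2.0 * amp for _, amp, _ in saccade_plan]
    for (on_a, *_), dur_a, (on_b, *_) in zip(saccade_plan, durations, saccade_plan[1:]):
        if on_a + dur_a > on_b:
            raise GenerationError("overlapping saccades in plan")
    xy = rng.normal(0.0, jitter_sd, (t_ms.size, 2))
    for (onset, amp, direction), dur in zip(saccade_plan, durations):
        k = 2.0 * np.log(9.0) / dur  # logistic slope for the 10-90% rise
        prof = 1.0 / (1.0 + np.exp(-k * (t_ms - (onset + dur / 2.0))))
        xy[:, 0] += amp * np.cos(direction) * prof
        xy[:, 1] += amp * np.sin(direction) * prof
    return xy


# --------------------------------------------------------------------------
# planted ground truth helpers
# --------------------------------------------------------------------------


def noiseless_location_patterns(
    population: Population,
    context: str = "target",
    window: tuple[float, float] = (150.0, 200.0),
    layout: TaskLayout | None = None,
) -> np.ndarray:
    """Analytic mean-rate pattern (N x 8) per location of ``context``.

    Averages the generative rate model over the other factor (uniform over
    admissible positions) within ``window``; no Poisson noise, no clipping.
    """
    if context not in ("target", "singleton"):
        raise ConfigurationError("context must be 'target' or 'singleton'")
    layout = layout or TaskLayout()
    t = np.arange(window[0], window[1] + 1.0)
    n_pos = layout.n_positions
    n = len(population)
    patterns = np.zeros((n, n_pos))
    for p in range(n_pos):
        acc = np.zeros(n)
        count = 0
        for q in range(n_pos):
            if q == p:
                continue
            tgt, sng = (p, q) if context == "target" else (q, p)
            rf_content = (
                "target"
                if layout.rf_position == tgt
                else "salient_distractor"
                if layout.rf_position == sng
                else "nonsalient_distractor"
            )
            for i, unit in enumerate(population):
                base = unit.baseline_rate * (
                    1.0 + (unit.visual_gain - 1.0) * _ramp(t)
                )
                if rf_content == "salient_distractor":
                    base = base * unit.gain_profile(t)
                drive = unit.target_tuning[tgt] + unit.singleton_tuning[sng]
                acc[i] += float(np.mean(base + drive * _ramp(t)))
            count += 1
        patterns[:, p] = acc / count
    return patterns


def archetype_t_templates(
    t_ms: np.ndarray | None = None,
    scale: float = 6.0,
    smooth_sigma_ms: float = 10.0,
) -> dict[str, np.ndarray]:
    """Expected selectivity (t-value) time course per archetype.

    The template is the smoothed deviation of the archetype's singleton gain
    from 1, scaled to typical peak t values; it is the planted ground truth
    behind the temporal-profile clustering."""
    from scipy.ndimage import gaussian_filter1d

    t_ms = t_ms if t_ms is not None else np.arange(0.0, 300.0)
    out = {}
    for cid in ARCHETYPES:
        tmpl = scale * (singleton_gain_profile(cid, t_ms) - 1.0)
        out[cid] = gaussian_filter1d(tmpl, smooth_sigma_ms)
    return out


def planted_covariance(
    population: Population,
    context: str = "target",
    layout: TaskLayout | None = None,
) -> np.ndarray:
    """Noiseless N x N covariance of the planted location-tuning patterns.

    Built directly from the per-unit tuning vectors (the location-drive
    pathway of the rate model) over all 8 locations, centered across
    locations.  This is the ground truth that the condition-matrix covariance
    of the subspace analyses estimates; the RF-singleton gain pathway is an
    RF-content (not location-coding) effect and is deliberately excluded.
    """
    attr = "target_tuning" if context == "target" else "singleton_tuning"
    if context not in ("target", "singleton"):
        raise ConfigurationError("context must be 'target' or 'singleton'")
    p = np.vstack([getattr(u, attr) for u in population])
    p = p - p.mean(axis=1, keepdims=True)
    return p @ p.T / (p.shape[1] - 1)


def planted_principal_angles_deg(population: Population) -> np.ndarray:
    """Principal angles (deg) between the planted target/singleton bases."""
    from scipy.linalg import subspace_angles

    return np.degrees(subspace_angles(population.basis_target, population.basis_singleton))


# --------------------------------------------------------------------------
# session serialization (one directory per session, plain text)
# --------------------------------------------------------------------------


def save_session(session: Session, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(out / "trials.csv", index=False)
    rec = []
    for u, unit_id in enumerate(session.unit_ids):
        for t, times in enumerate(session.spikes[u]):
            for s in times:
                rec.append((unit_id, t, s))
    pd.DataFrame(rec, columns=["unit_id", "trial_id", "spike_time_ms"]).to_csv(
        out / "spikes.csv", index=False
    )
    n_trials, n_samp, _ = session.eye.shape
    eye = pd.DataFrame(
        {
            "trial_id": np.repeat(np.arange(n_trials), n_samp),
            "t_ms": np.tile(session.eye_t, n_trials),
            "x_deg": session.eye[:, :, 0].ravel(),
            "y_deg": session.eye[:, :, 1].ravel(),
        }
    )
    eye.to_csv(out / "eye.csv", index=False, float_format="%.5f")
    meta = {
        "layout": dataclasses.asdict(session.layout),
        "seed": session.seed,
        "config": session.config,
        "unit_ids": session.unit_ids,
        "unit_clusters": [u.cluster_id for u in session.population]
        if session.population
        else None,
        "basis_target": session.population.basis_target.tolist()
        if session.population
        else None,
        "basis_singleton": session.population.basis_singleton.tolist()
        if session.population
        else None,
    }
    (out / "session.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out


def load_session(in_dir: str | Path) -> Session:
    src = Path(in_dir)
    meta = json.loads((src / "session.json").read_text())
    trials = pd.read_csv(src / "trials.csv")
    spikes_df = pd.read_csv(src / "spikes.csv")
    unit_ids = meta["unit_ids"]
    n_trials = len(trials)
    spikes = [[np.empty(0) for _ in range(n_trials)] for _ in unit_ids]
    uidx = {u: i for i, u in enumerate(unit_ids)}
    for (unit_id, trial_id), grp in spikes_df.groupby(["unit_id", "trial_id"], sort=False):
        spikes[uidx[unit_id]][int(trial_id)] = np.sort(grp["spike_time_ms"].to_numpy())
    eye_df = pd.read_csv(src / "eye.csv")
    eye_t = np.sort(eye_df["t_ms"].unique())
    eye = np.zeros((n_trials, eye_t.size, 2))
    eye[:, :, 0] = eye_df["x_deg"].to_numpy().reshape(n_trials, eye_t.size)
    eye[:, :, 1] = eye_df["y_deg"].to_numpy().reshape(n_trials, eye_t.size)
    pop = None
    if meta.get("basis_target") is not None:
        pop = Population()
        pop.basis_target = np.asarray(meta["basis_target"])
        pop.basis_singleton = np.asarray(meta["basis_singleton"])
        pop.geometry = GeometrySpec(**meta["config"].get("geometry", {}))
    return Session(
        unit_ids=unit_ids,
        spikes=spikes,
        trials=trials,
        eye_t=eye_t,
        eye=eye,
        layout=TaskLayout(**meta["layout"]),
        population=pop,
        seed=meta["seed"],
        config=meta["config"],
    )
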