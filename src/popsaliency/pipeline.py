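"""End-to-end orchestration: simulate -> preprocess -> unit stats ->
clustering -> decoding -> subspaces -> behavior, with a serialized config,
per-stage outputs, and a summary report.

Every stage is a thin wrapper over the library modules; outputs are plain CSV
and JSON files in the run directory, and the full configuration (with its
hash) is stored alongside so a run can be reproduced exactly from
``config.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import clustering as clus
from . import decoding as dec
from . import preprocess as pre
from . import selectivity as sel
from . import subspace as sub
from . import synth

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "unit_stats",
    "clustering",
    "decoding",
    "subspace",
    "behavior",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the analysis conventions
    described in docs/methods.md."""

    seed: int = 0
    # generator
    n_units: int = 100
    n_trials_per_condition: int = 40
    overlap: float = 0.5
    d_true: int = 5
    cluster_mix: dict = field(
        default_factory=lambda: {
            "suppression": 0.35,
            "early_enh_late_supp": 0.20,
            "enhancement": 0.15,
            "nonselective": 0.30,
        }
    )
    # preprocessing
    kernel_sigma_ms: float = 10.0
    grid_start_ms: float = -300.0
    grid_stop_ms: float = 500.0
    min_trials: int = 10
    # selectivity
    auroc_shuffles: int = 500
    population_nulls: int = 1000
    pev_shuffles: int = 200
    pev_window_ms: float = 50.0
    pev_step_ms: float = 10.0
    selectivity_threshold: float = 1.645
    # clustering
    knn_k: int = 40
    louvain_resolution: float = 1.0
    # decoding
    decode_trials: int = 10
    decode_resamples: int = 50
    decode_folds: int = 5
    decode_shuffles: int = 500
    svm_c: float = 1.0
    cluster_test_permutations: int = 1000
    locations: tuple = tuple(synth.LEFT_HEMIFIELD)
    # subspace
    subspace_d: int = 5
    exclusive_v: float = 0.01
    subspace_window: tuple = (150.0, 200.0)
    subspace_restarts: int = 5
    scale_train_only: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["locations"] = list(d["locations"])
        d["subspace_window"] = list(d["subspace_window"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _window_starts(config: RunConfig) -> np.ndarray:
    return np.arange(
        config.grid_start_ms,
        config.grid_stop_ms - config.pev_window_ms + 1e-9,
        config.pev_step_ms,
    )


def location_label_counts(
    session: synth.Session,
    context: str,
    locations: tuple,
    window_starts: np.ndarray,
    width_ms: float,
) -> list[dict]:
    """Per-unit spike counts keyed by stimulus location, for decoding.

    ``context`` selects target or singleton location; only singleton-present
    trials with the location in ``locations`` enter.
    """
    col = "target_pos" if context == "target" else "singleton_pos"
    t = session.trials
    mask = (t["display_type"] == "singleton_present") & t[col].isin(locations)
    out = []
    for u in range(session.n_units):
        d = {}
        for loc in locations:
            idx = t.index[mask & (t[col] == loc)].to_numpy()
            if idx.size:
                d[int(loc)] = pre.sliding_window_counts(
                    [session.spikes[u][i] for i in idx], window_starts, width_ms
                )
        out.append(d)
    return out


def contrast_label_counts(
    session: synth.Session,
    contrast: str,
    window_starts: np.ndarray,
    width_ms: float,
    min_trials: int = 10,
) -> list[dict]:
    """Per-unit spike counts keyed by contrast condition (2-class decoding)."""
    selection = pre.select_trials(session, contrast, min_trials=min_trials)
    la, lb = selection.contrast.labels
    out = []
    for u in range(session.n_units):
        out.append(
            {
                la: pre.sliding_window_counts(
                    [session.spikes[u][i] for i in selection.trials_a],
                    window_starts,
                    width_ms,
                ),
                lb: pre.sliding_window_counts(
                    [session.spikes[u][i] for i in selection.trials_b],
                    window_starts,
                    width_ms,
                ),
            }
        )
    return out


def run(
    config: RunConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> Path:
    """Execute the pipeline; every stage writes its tables under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps({"config": config.to_dict(), "hash": config.digest()}, indent=1)
    )
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    state: dict = {}
    report = [f"# Pipeline run (config {config.digest()}, seed {config.seed})\n"]
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, out, state, report)
        except Exception as e:  # preserve partial outputs, name the stage
            (out / "report.md").write_text("\n".join(report))
            raise StageError(stage, e) from e
        log.info("stage %s: %.1f s", stage, time.time() - t0)
        report.append(f"\n_[stage {stage}: {time.time() - t0:.1f} s]_\n")
    (out / "report.md").write_text("\n".join(report))
    return out


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path, state: dict, report: list):
    pop = synth.make_unit_population(
        config.n_units,
        config.cluster_mix,
        synth.GeometrySpec(config.d_true, config.overlap),
        seed=config.seed,
    )
    session = synth.simulate_session(
        pop, n_trials_per_condition=config.n_trials_per_condition, seed=config.seed + 1
    )
    synth.save_session(session, out / "session")
    state["session"] = session
    report.append(
        f"## Simulation\n{session.n_units} units, {session.n_trials} trials "
        f"(overlap {config.overlap}, d_true {config.d_true})."
    )


def _require_session(config: RunConfig, out: Path, state: dict):
    if "session" not in state:
        session_dir = out / "session"
        if not session_dir.exists():
            raise RuntimeError("no session available; run the simulate stage first")
        state["session"] = synth.load_session(session_dir)
    return state["session"]


def _stage_preprocess(config: RunConfig, out: Path, state: dict, report: list):
    session = _require_session(config, out, state)
    grid = np.arange(config.grid_start_ms, config.grid_stop_ms)
    rates, grid = pre.session_rates(
        session, grid, pre.KernelParams(config.kernel_sigma_ms)
    )
    qc = pre.unit_qc(session, rates, grid)
    qc.to_csv(out / "unit_qc.csv", index=False)
    state["rates"], state["grid"], state["qc"] = rates, grid, qc
    report.append(
        f"## Preprocessing\n{int(qc['visually_responsive'].sum())}/{len(qc)} units "
        "visually responsive."
    )


def _stage_unit_stats(config: RunConfig, out: Path, state: dict, report: list):
    session = _require_session(config, out, state)
    rates, grid = state["rates"], state["grid"]
    rng = np.random.default_rng(config.seed + 2)
    selection = pre.select_trials(
        session, "singleton_vs_nonsalient_present", min_trials=config.min_trials
    )
    wmean = pre.window_mean(rates, grid, (150.0, 200.0))
    starts = _window_starts(config)
    rows = []
    mis = []
    for u, unit_id in enumerate(session.unit_ids):
        mi = sel.modulation_index(
            float(wmean[u, selection.trials_a].mean()),
            float(wmean[u, selection.trials_b].mean()),
        )
        mis.append(mi)
        # PEV for target and singleton location
        z_cls = {}
        for context in ("target", "singleton"):
            col = "target_pos" if context == "target" else "singleton_pos"
            t = session.trials
            mask = (t["display_type"] == "singleton_present") & t[col].isin(
                config.locations
            )
            counts = pre.sliding_window_counts(
                [session.spikes[u][i] for i in t.index[mask]],
                starts,
                config.pev_window_ms,
            )
            res = sel.pev_omega2(
                counts,
                t.loc[mask, col].to_numpy(),
                starts,
                n_shuffle=config.pev_shuffles,
                rng=rng,
            )
            z_cls[context] = res
        klass = sel.classify_selectivity(
            z_cls["target"].z_pev,
            z_cls["singleton"].z_pev,
            starts,
            threshold=config.selectivity_threshold,
            window_width=config.pev_window_ms,
        )
        rows.append(
            dict(
                unit_id=unit_id,
                contrast="singleton_vs_nonsalient_present",
                modulation_index=mi,
                z_pev_target=float(np.nanmax(z_cls["target"].z_pev)),
                z_pev_singleton=float(np.nanmax(z_cls["singleton"].z_pev)),
                selectivity_class=klass,
            )
        )
    stats_df = pd.DataFrame(rows)
    stats_df.to_csv(out / "unit_stats.csv", index=False)
    state["unit_stats"] = stats_df
    mis = np.asarray(mis)
    med = float(np.nanmedian(mis))
    frac = stats_df["selectivity_class"].value_counts(normalize=True).to_dict()
    report.append(
        "## Unit selectivity\n"
        f"Median singleton-vs-nonsalient modulation index: {med:+.3f}.\n"
        f"Selectivity classes: "
        + ", ".join(f"{k} {v:.0%}" for k, v in sorted(frac.items()))
    )


def _stage_clustering(config: RunConfig, out: Path, state: dict, report: list):
    session = _require_session(config, out, state)
    rates, grid = state["rates"], state["grid"]
    selection = pre.select_trials(
        session, "singleton_present_vs_absent", min_trials=config.min_trials
    )
    responsive = state["qc"]["visually_responsive"].to_numpy()
    profiles = clus.compute_t_profiles(
        [rates[u, selection.trials_a] for u in range(session.n_units)],
        [rates[u, selection.trials_b] for u in range(session.n_units)],
        grid,
        unit_ids=session.unit_ids,
    )
    included = np.array(
        [p.included and responsive[u] for u, p in enumerate(profiles)]
    )
    x = np.vstack([p.t_values for i, p in enumerate(profiles) if included[i]])
    k = min(config.knn_k, max(2, included.sum() - 1))
    assign = clus.phenograph_cluster(
        x, k=k, seed=config.seed + 3, resolution=config.louvain_resolution
    )
    labels_full = np.full(session.n_units, -1)
    labels_full[np.flatnonzero(included)] = assign.labels
    pd.DataFrame(
        {"unit_id": session.unit_ids, "cluster_label": labels_full}
    ).to_csv(out / "clusters.csv", index=False)

    # per-cluster summaries on normalized rates
    means_a, means_b, kept = [], [], []
    for u in np.flatnonzero(included):
        cond = {
            "a": rates[u, selection.trials_a],
            "b": rates[u, selection.trials_b],
        }
        norm, _, excluded = pre.normalize_unit(cond, grid)
        if excluded:
            continue
        means_a.append(norm["a"].mean(axis=0))
        means_b.append(norm["b"].mean(axis=0))
        kept.append(u)
    summaries = clus.cluster_summaries(
        labels_full[kept], np.vstack(means_a), np.vstack(means_b), grid
    )
    rows = []
    for s in summaries:
        for j, t_ms in enumerate(grid):
            rows.append(
                (s.cluster, t_ms, s.mean_a[j], s.mean_b[j], s.difference[j], s.sem[j])
            )
    pd.DataFrame(
        rows,
        columns=["cluster", "time_ms", "mean_rate_condA", "mean_rate_condB", "difference", "sem"],
    ).to_csv(out / "cluster_profiles.csv", index=False)
    state["clusters"] = assign
    state["cluster_summaries"] = summaries
    lat = {s.cluster: s.latency.latency_ms for s in summaries}
    report.append(
        f"## Profile clustering\n{assign.n_clusters} clusters "
        f"(K={k}, modularity {assign.modularity:.2f}); "
        f"difference latencies (ms): {lat}"
    )


def _stage_decoding(config: RunConfig, out: Path, state: dict, report: list):
    session = _require_session(config, out, state)
    starts = _window_starts(config)
    rng_seed = config.seed + 4
    results = {}
    rows = []
    sig = {}
    contrasts = {
        "rf_content": contrast_label_counts(
            session, "singleton_vs_nonsalient_present", starts, config.pev_window_ms,
            config.min_trials,
        ),
        "target_loc": location_label_counts(
            session, "target", config.locations, starts, config.pev_window_ms
        ),
        "singleton_loc": location_label_counts(
            session, "singleton", config.locations, starts, config.pev_window_ms
        ),
    }
    for name, counts in contrasts.items():
        pop = dec.build_pseudopopulation(
            counts,
            n_trials=config.decode_trials,
            n_resamples=config.decode_resamples,
            seed=rng_seed,
            window_starts=starts,
        )
        res = dec.decode_timecourse(
            pop,
            folds=config.decode_folds,
            c=config.svm_c,
            seed=rng_seed,
            scale_train_only=config.scale_train_only,
        )
        clusters = dec.cluster_permutation_test(
            res.accuracy,
            res.chance,
            n_perm=config.cluster_test_permutations,
            seed=rng_seed,
        )
        res.clusters = dec.significant_clusters(clusters)
        results[name] = res
        sig[name] = [
            dict(
                start_ms=float(starts[c.start]),
                end_ms=float(starts[c.end] + config.pev_window_ms),
                p=c.p,
            )
            for c in res.clusters
        ]
        for r in range(res.accuracy.shape[0]):
            for w, t0 in enumerate(starts):
                rows.append((name, float(t0), r, res.accuracy[r, w]))
    pd.DataFrame(
        rows, columns=["contrast", "window_start_ms", "resample", "accuracy"]
    ).to_csv(out / "decoding.csv", index=False)
    (out / "decoding_sig.json").write_text(json.dumps(sig, indent=1))
    state["decoding"] = results
    state["decoding_window_starts"] = starts
    peak = {k: float(v.mean_accuracy.max()) for k, v in results.items()}
    report.append(
        "## Decoding\nPeak accuracies: "
        + ", ".join(f"{k} {v:.0%}" for k, v in peak.items())
    )


def _stage_subspace(config: RunConfig, out: Path, state: dict, report: list):
    session = _require_session(config, out, state)
    rates, grid = state["rates"], state["grid"]
    if config.subspace_d > session.n_units:
        raise ValueError(
            f"subspace dimension d={config.subspace_d} exceeds N={session.n_units} units"
        )
    t = session.trials
    present = t["display_type"] == "singleton_present"
    cms = {}
    for context, col in [("target", "target_pos"), ("singleton", "singleton_pos")]:
        mask = present & t[col].isin(config.locations)
        cms[context] = sub.build_condition_matrix(
            rates[:, t.index[mask]],
            grid,
            t.loc[mask, col].to_numpy(),
            context,
            locations=config.locations,
            window=tuple(config.subspace_window),
        )
    cov = sub.CovariancePair(cms["target"].covariance(), cms["singleton"].covariance())
    model = sub.fit_subspace_model(
        cov,
        d=config.subspace_d,
        v=config.exclusive_v,
        seed=config.seed + 5,
        restarts=config.subspace_restarts,
    )
    align = {f"{b}|{c}": round(a, 4) for (b, c), a in model.alignment.items()}
    weights = model.weights("shared")
    classes = (
        state["unit_stats"]["selectivity_class"].to_numpy()
        if "unit_stats" in state
        else np.array(["unknown"] * session.n_units)
    )
    f_stat, p_anova = sub.weight_class_anova(weights, classes)
    payload = {
        "d": model.d,
        "v": model.v,
        "alignment": align,
        "shared_weight_anova": {"F": f_stat, "p": p_anova},
        "bases": {
            "orth_target": model.q_orth_target.tolist(),
            "orth_singleton": model.q_orth_singleton.tolist(),
            "excl_target": model.q_excl_target.tolist(),
            "excl_singleton": model.q_excl_singleton.tolist(),
            "shared": model.q_shared.tolist(),
        },
    }
    (out / "subspace_report.json").write_text(json.dumps(payload, indent=1))
    pd.DataFrame(
        {"unit_id": session.unit_ids, "shared_weight": weights, "selectivity_class": classes}
    ).to_csv(out / "subspace_weights.csv", index=False)
    state["subspace_model"] = model
    state["covariances"] = cov
    report.append(
        "## Subspaces\n"
        f"Alignment (basis|context): {align}\n"
        f"Shared-weight ANOVA across classes: F={f_stat:.2f}, p={p_anova:.2f}"
    )


def _stage_behavior(config: RunConfig, out: Path, state: dict, report: list):
    session = _require_session(config, out, state)
    summary = beh.summarize_behavior(session.trials)
    split = beh.median_split(session.trials)
    split.to_frame().assign(trial_id=session.trials["trial_id"]).to_csv(
        out / "speed_split.csv", index=False
    )
    contrasts = beh.median_split_contrast(
        state["rates"], state["grid"], session.trials, split, min_trials=config.min_trials
    )
    rows = [
        dict(
            condition=c.condition,
            median_modulation_index=float(np.nanmedian(c.modulation_indices)),
            mean_auroc=float(np.nanmean(c.aurocs)),
            n_fast=c.n_fast,
            n_slow=c.n_slow,
        )
        for c in contrasts
    ]
    pd.DataFrame(rows).to_csv(out / "behavior_contrasts.csv", index=False)
    pd.DataFrame(
        [
            dict(
                n_trials=summary.n_trials,
                first_saccade_to_singleton_rate=summary.first_saccade_to_singleton_rate,
                first_saccade_p=summary.first_saccade_p,
                **{
                    f"median_search_{k}": v
                    for k, v in summary.median_search_time_ms.items()
                },
            )
        ]
    ).to_csv(out / "behavior.csv", index=False)
    state["behavior"] = summary
    report.append(
        "## Behavior\n"
        f"First saccade to singleton: {summary.first_saccade_to_singleton_rate:.1%} "
        f"(chance 12.5%, p={summary.first_saccade_p:.3g}); "
        f"median search times: { {k: round(v) for k, v in summary.median_search_time_ms.items()} }; "
        f"fast-vs-slow median modulation indices: "
        + ", ".join(
            f"{r['condition']} {r['median_modulation_index']:+.3f}" for r in rows
        )
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "unit_stats": _stage_unit_stats,
    "clustering": _stage_clustering,
    "decoding": _stage_decoding,
    "subspace": _stage_subspace,
    "behavior": _stage_behavior,
}
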