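"""Calibration and recovery suites run against planted ground truth.

Each routine regenerates its inputs from the synthetic-data module (or a null
model), executes the corresponding analysis path, and returns the measured
quantity: decoder chance levels under label permutation, the exclusive-
subspace variance cap, archetype-clustering recovery, the overlap sweep of
cross-projected alignment, the fast/slow coupling contrast, and the empirical
error rates of the FDR and cluster-permutation procedures.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import behavior as beh
from . import clustering as clus
from . import decoding as dec
from . import preprocess as pre
from . import selectivity as sel
from . import subspace as sub
from . import synth


def _session_for_decoding(seed: int, n_units: int = 60, overlap: float = 0.5):
    pop = synth.make_unit_population(
        n_units, geometry=synth.GeometrySpec(5, overlap), seed=seed
    )
    return synth.simulate_session(pop, n_trials_per_condition=40, seed=seed + 1)


def random_search_chance(seed: int, n_trials_per_condition: int = 60) -> tuple[float, float]:
    """First-saccade-to-singleton rate under the uniform saccade policy.

    Returns (measured rate, analytic chance) in fractions; the analytic value
    is exactly 1/8 for an 8-position array.
    """
    pop = synth.make_unit_population(3, seed=seed)
    session = synth.simulate_session(
        pop,
        n_trials_per_condition=n_trials_per_condition,
        seed=seed + 1,
        behavior=synth.BehaviorParams(saccade_policy="uniform"),
    )
    summary = beh.summarize_behavior(session.trials)
    return summary.first_saccade_to_singleton_rate, beh.RANDOM_SEARCH_CHANCE


def decoder_chance(
    n_classes: int,
    seed: int,
    n_shuffles: int = 200,
    n_units: int = 60,
) -> float:
    """Mean label-shuffled decoding accuracy in the 150-200 ms window.

    5-class: target location over the contralateral positions; 2-class:
    RF content (singleton vs non-singleton distractor in the RF).
    """
    from .pipeline import contrast_label_counts, location_label_counts

    session = _session_for_decoding(seed, n_units)
    window = np.array([150.0])
    if n_classes == 5:
        counts = location_label_counts(
            session, "target", synth.LEFT_HEMIFIELD, window, 50.0
        )
        n_trials = 10
    elif n_classes == 2:
        counts = contrast_label_counts(
            session, "singleton_vs_nonsalient_present", window, 50.0
        )
        n_trials = 16
    else:
        raise ValueError("calibrated for 2 or 5 classes")
    pop = dec.build_pseudopopulation(
        counts, n_trials=n_trials, n_resamples=4, seed=seed + 2, window_starts=window
    )
    null, _ = dec.shuffle_null(pop, n_shuffles=n_shuffles, seed=seed + 3)
    return float(null.mean())


def exclusive_limit_variance(
    seed: int,
    n_units: int = 100,
    overlap: float = 0.5,
    d: int = 5,
    v: float = 0.01,
) -> dict[str, float]:
    """Limit-context variance captured by each fitted exclusive subspace.

    Builds target/singleton condition matrices from a synthetic session,
    fits both exclusive subspaces under the variance cap ``v``, and returns
    the alignment of each against the limit context's covariance
    (fractions; the constraint demands <= v + 1e-4).
    """
    pop = synth.make_unit_population(
        n_units, geometry=synth.GeometrySpec(5, overlap), seed=seed
    )
    session = synth.simulate_session(pop, n_trials_per_condition=40, seed=seed + 1)
    rates, grid = pre.session_rates(session, np.arange(100.0, 250.0))
    t = session.trials
    present = t["display_type"] == "singleton_present"
    cms = {}
    for context, col in [("target", "target_pos"), ("singleton", "singleton_pos")]:
        mask = present & t[col].isin(synth.LEFT_HEMIFIELD)
        cms[context] = sub.build_condition_matrix(
            rates[:, t.index[mask]], grid, t.loc[mask, col].to_numpy(), context
        )
    c_t = cms["target"].covariance()
    c_s = cms["singleton"].covariance()
    q_et, _ = sub.fit_exclusive(c_t, c_s, v=v, d=d, seed=seed)
    q_es, _ = sub.fit_exclusive(c_s, c_t, v=v, d=d, seed=seed)
    return {
        "target_exclusive_vs_singleton": sub.alignment_index(q_et, c_s, d),
        "singleton_exclusive_vs_target": sub.alignment_index(q_es, c_t, d),
    }


def archetype_recovery_ari(
    n_seeds: int = 20,
    seed: int = 0,
    n_per_cluster: int = 30,
    noise_sd: float = 0.6,
    k: int = 40,
) -> list[float]:
    """Adjusted Rand index of archetype recovery over seeded replicates.

    Profiles are the generator's planted archetype t-value templates
    (suppression / biphasic / enhancement) plus per-bin noise well below the
    template separation; each replicate re-draws noise and reclusters.
    """
    templates = synth.archetype_t_templates()
    kinds = ("suppression", "early_enh_late_supp", "enhancement")
    aris = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 + s)
        x, y = [], []
        for label, kind in enumerate(kinds):
            base = templates[kind]
            x.append(base + rng.normal(0.0, noise_sd, (n_per_cluster, base.size)))
            y.extend([label] * n_per_cluster)
        x = np.vstack(x)
        assign = clus.phenograph_cluster(x, k=min(k, x.shape[0] - 1), seed=seed + s)
        aris.append(float(adjusted_rand_score(np.array(y), assign.labels)))
    return aris


def overlap_alignment_sweep(
    overlaps=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_seeds: int = 10,
    seed: int = 0,
    n_units: int = 40,
    d: int = 5,
) -> np.ndarray:
    """Mean cross-projected alignment per planted overlap level.

    For each seed and overlap, fits the orthogonal subspace pair on the
    planted location-pattern covariances and measures the variance of the
    singleton context captured by the target subspace.
    """
    means = []
    for overlap in overlaps:
        vals = []
        for s in range(n_seeds):
            pop = synth.make_unit_population(
                n_units, geometry=synth.GeometrySpec(d, overlap), seed=seed + 100 * s
            )
            cov = sub.CovariancePair(
                synth.planted_covariance(pop, "target"),
                synth.planted_covariance(pop, "singleton"),
            )
            q_t, _, _ = sub.fit_orthogonal_pair(cov, d=d, seed=seed + s, restarts=3)
            vals.append(sub.alignment_index(q_t, cov.c_singleton, d))
        means.append(np.mean(vals))
    return np.asarray(means)


def coupling_median_modulation(seed: int, n_units: int = 12, n_trials: int = 60) -> float:
    """Median fast-vs-slow modulation index under the planted behavioral
    coupling (stronger distractor suppression on fast-search trials)."""
    pop = synth.make_unit_population(n_units, seed=seed)
    session = synth.simulate_session(
        pop,
        n_trials_per_condition=n_trials,
        seed=seed + 1,
        conditions=[
            ("singleton_present", "salient_distractor"),
            ("singleton_present", "nonsalient_distractor"),
        ],
    )
    rates, grid = pre.session_rates(session, np.arange(-100.0, 300.0))
    split = beh.median_split(session.trials)
    contrasts = beh.median_split_contrast(rates, grid, session.trials, split)
    all_indices = np.concatenate([c.modulation_indices for c in contrasts])
    return float(np.nanmedian(all_indices))


def fdr_empirical_fdp(
    n_sims: int = 200,
    seed: int = 0,
    n_units: int = 15,
    n_bins: int = 25,
    n_trials: int = 14,
    n_unit_shuffles: int = 100,
    n_population_nulls: int = 300,
) -> float:
    """Mean false discovery proportion of the population AUROC test under a
    null in which the two conditions share one distribution."""
    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(n_sims):
        aurocs = np.empty((n_units, n_bins))
        nulls = np.empty((n_units, n_unit_shuffles, n_bins))
        for u in range(n_units):
            a = rng.poisson(5.0, (n_trials, n_bins)).astype(float)
            b = rng.poisson(5.0, (n_trials, n_bins)).astype(float)
            s = sel.time_resolved_auroc(
                a, b, np.arange(n_bins), n_shuffles=n_unit_shuffles, rng=rng
            )
            aurocs[u], nulls[u] = s.auroc, s.null
        _, mask = sel.population_auroc_test(
            aurocs, nulls, n_population_nulls, rng=rng
        )
        fdps.append(mask.any() * 1.0)  # all discoveries are false under the null
    return float(np.mean(fdps))


def cluster_test_fwer(
    n_sims: int = 300,
    seed: int = 0,
    n_samples: int = 18,
    n_bins: int = 50,
    n_perm: int = 400,
) -> float:
    """Familywise error rate of the cluster-based permutation test on null
    (no condition difference) accuracy series."""
    rng = np.random.default_rng(seed)
    errors = 0
    for i in range(n_sims):
        a = rng.normal(0.5, 0.05, (n_samples, n_bins))
        b = rng.normal(0.5, 0.05, (n_samples, n_bins))
        clusters = dec.cluster_permutation_test(
            a, b, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        errors += bool(dec.significant_clusters(clusters))
    return errors / n_sims
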