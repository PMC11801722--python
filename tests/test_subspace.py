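"""Subspace geometry: condition-matrix construction, alignment index against
brute-force trace evaluation, orthogonal/exclusive/shared fits on constructed
covariances with known optima, an exhaustive-grid oracle for the manifold
optimizer, and planted-overlap recovery."""

import numpy as np
import pytest

from popsaliency import stiefel, subspace as sub, synth


def random_covariance(rng, n, rank=None, scales=None):
    rank = rank or n
    scales = np.asarray(scales) if scales is not None else rng.gamma(2.0, 1.0, rank)
    u, _ = np.linalg.qr(rng.standard_normal((n, rank)))
    return (u * scales) @ u.T, u, scales


class TestConditionMatrix:
    def test_row_count_is_locations_times_timepoints(self, rng):
        rates = rng.gamma(2.0, 5.0, (12, 40, 600)).astype(np.float32)
        grid = np.arange(-100.0, 500.0)
        locs = rng.integers(2, 7, 40)
        cm = sub.build_condition_matrix(rates, grid, locs, "target")
        assert cm.matrix.shape == (5 * 51, 12)
        assert cm.n_timepoints == 51
        assert np.allclose(cm.matrix.mean(axis=0), 0.0, atol=1e-4)

    def test_constant_unit_becomes_zero_column(self, rng):
        rates = rng.gamma(2.0, 5.0, (3, 30, 600)).astype(np.float32)
        rates[1] = 7.0
        grid = np.arange(-100.0, 500.0)
        locs = rng.integers(2, 7, 30)
        cm = sub.build_condition_matrix(rates, grid, locs, "target")
        assert np.allclose(cm.matrix[:, 1], 0.0, atol=1e-4)

    def test_location_order_does_not_change_covariance(self, rng):
        rates = rng.gamma(2.0, 5.0, (6, 30, 600)).astype(np.float32)
        grid = np.arange(-100.0, 500.0)
        locs = rng.integers(2, 7, 30)
        c1 = sub.build_condition_matrix(rates, grid, locs, "t", locations=(2, 3, 4, 5, 6))
        c2 = sub.build_condition_matrix(rates, grid, locs, "t", locations=(6, 4, 2, 5, 3))
        assert np.allclose(c1.covariance(), c2.covariance(), atol=1e-6)

    def test_missing_location_rejected(self, rng):
        rates = rng.gamma(2.0, 5.0, (3, 10, 600)).astype(np.float32)
        grid = np.arange(-100.0, 500.0)
        locs = np.full(10, 3)
        with pytest.raises(sub.InputError, match="location 4"):
            sub.build_condition_matrix(rates, grid, locs, "t", locations=(3, 4))


class TestAlignmentIndex:
    def test_top_eigenvectors_give_one(self, rng):
        c, u, _ = random_covariance(rng, 20)
        w, v = np.linalg.eigh(c)
        q = v[:, ::-1][:, :5]
        assert sub.alignment_index(q, c) == pytest.approx(1.0)

    def test_null_space_gives_zero(self, rng):
        c, u, _ = random_covariance(rng, 20, rank=5)
        full, _ = np.linalg.qr(rng.standard_normal((20, 20)))
        # project out the support to land in the null space
        q = full - u @ (u.T @ full)
        q, _ = np.linalg.qr(q)
        q = q[:, :5]
        assert sub.alignment_index(q, c) == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_trace(self, rng):
        c, *_ = random_covariance(rng, 15)
        q = stiefel.random_stiefel(15, 4, rng)
        brute = sum(q[:, j] @ c @ q[:, j] for j in range(4))
        denom = np.sort(np.linalg.eigvalsh(c))[::-1][:4].sum()
        assert sub.alignment_index(q, c) == pytest.approx(brute / denom, abs=1e-12)

    def test_bounded_by_one(self, rng):
        c, *_ = random_covariance(rng, 25)
        for _ in range(10):
            q = stiefel.random_stiefel(25, 5, rng)
            assert sub.alignment_index(q, c) <= 1.0 + 1e-12

    def test_rank_zero_rejected(self):
        with pytest.raises(sub.InputError):
            sub.alignment_index(np.eye(4, 2), np.zeros((4, 4)))


class TestOrthogonalPair:
    def test_disjoint_supports_fully_recovered(self, rng):
        n, d = 24, 4
        ua, _ = np.linalg.qr(rng.standard_normal((n, 2 * d)))
        c_t = ua[:, :d] @ np.diag([4.0, 3.0, 2.0, 1.0]) @ ua[:, :d].T
        c_s = ua[:, d:] @ np.diag([4.0, 3.0, 2.0, 1.0]) @ ua[:, d:].T
        q_t, q_s, res = sub.fit_orthogonal_pair(sub.CovariancePair(c_t, c_s), d=d, seed=0)
        assert sub.alignment_index(q_t, c_t) >= 0.99
        assert sub.alignment_index(q_s, c_s) >= 0.99
        assert np.abs(q_t.T @ q_s).max() < 1e-6

    def test_identical_covariances_split_top_eigenvectors(self, rng):
        """With C_T = C_S of rank 2d the optimum splits the top-2d eigenspace;
        the optimal objective value is known analytically."""
        n, d = 18, 3
        scales = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        c, _, _ = random_covariance(rng, n, rank=2 * d, scales=scales)
        _, _, res = sub.fit_orthogonal_pair(sub.CovariancePair(c, c), d=d, seed=1)
        optimum = scales.sum() / scales[:d].sum()
        assert res.value == pytest.approx(optimum, rel=1e-3)

    def test_planted_orthogonal_geometry_gives_low_cross_projection(self):
        pop = synth.make_unit_population(
            40, geometry=synth.GeometrySpec(5, 0.0), seed=2
        )
        cov = sub.CovariancePair(
            synth.planted_covariance(pop, "target"),
            synth.planted_covariance(pop, "singleton"),
        )
        q_t, q_s, _ = sub.fit_orthogonal_pair(cov, d=5, seed=2)
        assert sub.alignment_index(q_t, cov.c_singleton) <= 0.05
        assert sub.alignment_index(q_s, cov.c_target) <= 0.05

    def test_too_few_units_rejected(self, rng):
        c = np.eye(6)
        with pytest.raises(sub.InputError):
            sub.fit_orthogonal_pair(sub.CovariancePair(c, c), d=5)


class TestExclusive:
    def test_zero_limit_reduces_to_top_eigenvectors(self, rng):
        c, *_ = random_covariance(rng, 12)
        q, res = sub.fit_exclusive(c, np.zeros_like(c), d=3)
        assert sub.alignment_index(q, c) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_supports_leave_constraint_inactive(self, rng):
        n, d = 20, 3
        u, _ = np.linalg.qr(rng.standard_normal((n, 2 * d)))
        c_max = u[:, :d] @ np.diag([3.0, 2.0, 1.0]) @ u[:, :d].T
        c_lim = u[:, d:] @ np.diag([3.0, 2.0, 1.0]) @ u[:, d:].T
        q, _ = sub.fit_exclusive(c_max, c_lim, d=d, seed=0)
        assert sub.alignment_index(q, c_max) >= 0.99
        assert sub.alignment_index(q, c_lim) <= 0.01 + 1e-4

    def test_full_overlap_binds_constraint(self):
        pop = synth.make_unit_population(
            40, geometry=synth.GeometrySpec(5, 1.0), seed=3
        )
        c_t = synth.planted_covariance(pop, "target")
        c_s = synth.planted_covariance(pop, "singleton")
        q, res = sub.fit_exclusive(c_t, c_s, d=5, seed=3)
        assert sub.alignment_index(q, c_s) <= 0.01 + 1e-4
        # identical planted subspaces: excluding one nearly excludes the other
        assert sub.alignment_index(q, c_t) < 0.5

    def test_infeasible_limit_reported(self):
        c = np.eye(6)  # isotropic: every subspace captures the same variance
        with pytest.raises(sub.InfeasibleError, match="minimum achievable"):
            sub.fit_exclusive(c, c, v=0.01, d=2)


class TestShared:
    def _planted(self, overlap, seed):
        pop = synth.make_unit_population(
            40, geometry=synth.GeometrySpec(5, overlap), seed=seed
        )
        return sub.CovariancePair(
            synth.planted_covariance(pop, "target"),
            synth.planted_covariance(pop, "singleton"),
        )

    def test_full_overlap_shared_captures_most_variance(self):
        cov = self._planted(1.0, 4)
        q_et, _ = sub.fit_exclusive(cov.c_target, cov.c_singleton, d=5, seed=4)
        q_es, _ = sub.fit_exclusive(cov.c_singleton, cov.c_target, d=5, seed=4)
        q_sh = sub.fit_shared(cov, q_et, q_es, d=5)
        assert sub.alignment_index(q_sh, cov.c_target) >= 0.8
        assert sub.alignment_index(q_sh, cov.c_singleton) >= 0.8

    def test_orthogonal_planted_geometry_shared_is_empty(self):
        cov = self._planted(0.0, 5)
        q_et, _ = sub.fit_exclusive(cov.c_target, cov.c_singleton, d=5, seed=5)
        q_es, _ = sub.fit_exclusive(cov.c_singleton, cov.c_target, d=5, seed=5)
        q_sh = sub.fit_shared(cov, q_et, q_es, d=5)
        assert sub.alignment_index(q_sh, cov.c_target) <= 0.1
        assert sub.alignment_index(q_sh, cov.c_singleton) <= 0.1

    def test_orthogonality_residual_below_tolerance(self):
        cov = self._planted(0.5, 6)
        q_et, _ = sub.fit_exclusive(cov.c_target, cov.c_singleton, d=5, seed=6)
        q_es, _ = sub.fit_exclusive(cov.c_singleton, cov.c_target, d=5, seed=6)
        q_sh = sub.fit_shared(cov, q_et, q_es, d=5)
        assert np.abs(q_sh.T @ q_et).max() <= 1e-6
        assert np.abs(q_sh.T @ q_es).max() <= 1e-6

    def test_insufficient_complement_rejected(self, rng):
        c = np.eye(8)
        q = stiefel.random_stiefel(8, 3, rng)
        q2 = stiefel.random_stiefel(8, 3, rng)
        with pytest.raises(sub.InputError, match="reduce d"):
            sub.fit_shared(sub.CovariancePair(c, c), q, q2, d=5)


class TestOptimizerOracle:
    def test_matches_exhaustive_grid_n3_d1(self):
        """For N=3, d=1 the orthogonal pair can be found by scanning a fine
        grid of orthonormal vector pairs; the manifold optimizer must reach
        the same objective within 1%."""
        rng = np.random.default_rng(11)
        c_t, *_ = random_covariance(rng, 3)
        c_s, *_ = random_covariance(rng, 3)
        s_t = np.linalg.eigvalsh(c_t)[-1]
        s_s = np.linalg.eigvalsh(c_s)[-1]
        best = -np.inf
        thetas = np.linspace(0, np.pi, 60)
        phis = np.linspace(0, 2 * np.pi, 120)
        psis = np.linspace(0, np.pi, 60)
        for th in thetas:
            for ph in phis:
                q1 = np.array(
                    [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
                )
                # orthonormal frame completing q1
                e1 = np.array([q1[1], -q1[0], 0.0])
                if np.linalg.norm(e1) < 1e-9:
                    e1 = np.array([1.0, 0.0, 0.0])
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(q1, e1)
                f1 = q1 @ c_t @ q1 / s_t
                for ps in psis:
                    q2 = np.cos(ps) * e1 + np.sin(ps) * e2
                    best = max(best, f1 + q2 @ c_s @ q2 / s_s)
        _, _, res = sub.fit_orthogonal_pair(
            sub.CovariancePair(c_t, c_s), d=1, seed=0, restarts=5
        )
        assert res.value >= best * 0.99

    def test_objective_monotone_over_iterations(self, rng):
        c, *_ = random_covariance(rng, 10)
        values = []

        def vg(q):
            f = float(np.trace(q.T @ c @ q))
            values.append(f)
            return f, 2 * c @ q

        stiefel.maximize(vg, stiefel.random_stiefel(10, 3, rng), max_iter=100)
        accepted = np.maximum.accumulate(values)  # line search may probe lower
        assert accepted[-1] >= accepted[0]
        q_final = stiefel.retract(stiefel.random_stiefel(10, 3, rng), np.zeros((10, 3)))
        assert np.allclose(q_final.T @ q_final, np.eye(3), atol=1e-10)


class TestUnitWeights:
    def test_row_norm_identity(self, rng):
        q = stiefel.random_stiefel(30, 5, rng)
        w = sub.unit_weights(q)
        assert np.all(w <= 1.0 + 1e-9)
        assert (w**2).sum() == pytest.approx(5.0)

    def test_absent_unit_has_zero_weight(self, rng):
        q = np.zeros((10, 2))
        q[:2, 0] = [1.0, 0.0]
        q[:2, 1] = [0.0, 1.0]
        w = sub.unit_weights(q)
        assert np.allclose(w[2:], 0.0)

    def test_equal_contribution_anova_usually_flat(self):
        rng = np.random.default_rng(13)
        flagged = 0
        for _ in range(30):
            q = stiefel.random_stiefel(60, 5, rng)
            classes = rng.choice(["target", "singleton", "mixed", "none"], 60)
            _, p = sub.weight_class_anova(sub.unit_weights(q), classes)
            flagged += p < 0.05
        assert flagged <= 4  # ~5% nominal


class TestRecoverySweep:
    def test_cross_projection_monotone_in_overlap(self):
        """Cross-projected alignment increases with the planted subspace
        overlap (coarse 3-point check; the full sweep runs in acceptance)."""
        values = []
        for overlap in (0.0, 0.5, 1.0):
            pop = synth.make_unit_population(
                36, geometry=synth.GeometrySpec(5, overlap), seed=17
            )
            cov = sub.CovariancePair(
                synth.planted_covariance(pop, "target"),
                synth.planted_covariance(pop, "singleton"),
            )
            q_t, _, _ = sub.fit_orthogonal_pair(cov, d=5, seed=17, restarts=3)
            values.append(sub.alignment_index(q_t, cov.c_singleton))
        assert values[0] < values[1] < values[2]


class TestProjection:
    def test_projected_population_shape_and_mismatch(self, rng):
        from popsaliency.decoding import PseudoPopulation

        counts = rng.poisson(4.0, (2, 20, 15, 3)).astype(float)
        pop = PseudoPopulation(counts, np.repeat([0, 1], 10), np.arange(3), np.arange(15))
        q = stiefel.random_stiefel(15, 4, rng)
        proj = sub.project_population(pop, q)
        assert proj.counts.shape == (2, 20, 4, 3)
        with pytest.raises(sub.InputError, match="mismatch"):
            sub.project_population(pop, stiefel.random_stiefel(9, 4, rng))
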