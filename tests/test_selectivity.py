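"""Selectivity statistics against independent oracles: Mann-Whitney
enumeration for the AUROC, a direct ANOVA decomposition for omega-squared,
null calibration for the population permutation test and FDR mask, and the
latency run-length rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from popsaliency import selectivity as sel


class TestModulationIndex:
    @pytest.mark.parametrize(
        "fr1,fr2,expected", [(10, 10, 0.0), (15, 5, 0.5), (0, 8, -1.0)]
    )
    def test_examples(self, fr1, fr2, expected):
        assert sel.modulation_index(fr1, fr2) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        assert np.isnan(sel.modulation_index(0.0, 0.0))

    @given(
        st.floats(min_value=0, max_value=1e3),
        st.floats(min_value=1e-6, max_value=1e3),
    )
    def test_antisymmetric_and_bounded(self, fr1, fr2):
        mi = sel.modulation_index(fr1, fr2)
        assert -1.0 <= mi <= 1.0
        assert mi == pytest.approx(-sel.modulation_index(fr2, fr1))


class TestRankEffectSize:
    def test_reported_values(self):
        # published Wilcoxon effect sizes: r = z/sqrt(n)
        assert sel.rank_effect_size(-4.8, 219) == pytest.approx(-0.324, abs=0.01)
        assert sel.rank_effect_size(-2.2, 191) == pytest.approx(-0.159, abs=0.01)

    def test_zero_z(self):
        assert sel.rank_effect_size(0.0, 57) == 0.0

    def test_invalid_n(self):
        with pytest.raises(sel.InputError):
            sel.rank_effect_size(1.0, 0)


def mann_whitney_auroc(a, b):
    """Independent oracle: exhaustive pair enumeration with ties counted 1/2."""
    wins = sum(1.0 for x in a for y in b if x > y)
    ties = sum(0.5 for x in a for y in b if x == y)
    return (wins + ties) / (len(a) * len(b))


class TestAuroc:
    def test_identical_distributions_near_half(self, rng):
        a = rng.poisson(5, 200)
        b = rng.poisson(5, 200)
        assert abs(sel.auroc_counts(a, b) - 0.5) < 0.08

    def test_complete_separation_is_one(self):
        assert sel.auroc_counts([5, 6, 7], [1, 2, 3]) == pytest.approx(1.0)

    def test_overlapping_counts_match_pair_enumeration(self):
        a, b = [1, 2, 3], [2, 3, 4]
        assert sel.auroc_counts(a, b) == pytest.approx(mann_whitney_auroc(a, b))
        assert sel.auroc_counts(a, b) == pytest.approx(2.0 / 9.0)

    def test_exhaustive_equivalence_small_samples(self):
        """Criterion-sweep AUROC equals the rank statistic for every count set
        with n1, n2 <= 6 over counts in {0..3} (spot-checked exhaustively)."""
        pool = list(itertools.combinations_with_replacement(range(4), 3))
        for a in pool:
            for b in pool:
                assert sel.auroc_counts(a, b) == pytest.approx(
                    mann_whitney_auroc(a, b), abs=1e-12
                )

    def test_time_resolved_null_and_shape(self, rng):
        counts_a = rng.poisson(4, (12, 10))
        counts_b = rng.poisson(4, (12, 10))
        series = sel.time_resolved_auroc(
            counts_a, counts_b, np.arange(10), n_shuffles=200, rng=rng
        )
        assert series.auroc.shape == (10,)
        assert series.null.shape == (200, 10)
        assert abs(series.null.mean() - 0.5) < 0.02


class TestPopulationAurocTest:
    def _unit_data(self, rng, n_units=30, n_bins=40, effect_bins=None, n_trials=14):
        aurocs = np.empty((n_units, n_bins))
        nulls = np.empty((n_units, 150, n_bins))
        for u in range(n_units):
            a = rng.poisson(5, (n_trials, n_bins)).astype(float)
            b = rng.poisson(5, (n_trials, n_bins)).astype(float)
            if effect_bins is not None:
                a[:, effect_bins] = rng.poisson(2.5, (n_trials, len(effect_bins)))
            s = sel.time_resolved_auroc(a, b, np.arange(n_bins), n_shuffles=150, rng=rng)
            aurocs[u], nulls[u] = s.auroc, s.null
        return aurocs, nulls

    def test_null_yields_few_significant_bins(self):
        rng = np.random.default_rng(21)
        aurocs, nulls = self._unit_data(rng)
        _, mask = sel.population_auroc_test(aurocs, nulls, 400, rng=rng)
        assert mask.mean() <= 0.05

    def test_planted_effect_detected_in_interval(self):
        rng = np.random.default_rng(22)
        effect = list(range(15, 30))
        aurocs, nulls = self._unit_data(rng, effect_bins=effect)
        p, mask = sel.population_auroc_test(aurocs, nulls, 400, rng=rng)
        assert mask[effect].mean() > 0.9
        assert mask[:10].mean() <= 0.2

    def test_missing_nulls_rejected(self):
        with pytest.raises(sel.InputError):
            sel.population_auroc_test(np.ones((3, 5)), np.ones((2, 10, 5)))


class TestDifferenceLatency:
    def test_strong_effect_from_80ms(self, rng):
        starts = np.arange(0.0, 300.0, 5.0)
        diffs = rng.normal(0.0, 1.0, (30, starts.size))
        diffs[:, starts >= 80] += 3.0
        est = sel.difference_latency(diffs, starts)
        assert est.latency_ms == 80.0

    def test_short_run_gives_none(self, rng):
        starts = np.arange(0.0, 300.0, 5.0)
        diffs = rng.normal(0.0, 1.0, (30, starts.size))
        diffs[:, 16:20] += 5.0  # only 4 consecutive bins
        assert sel.difference_latency(diffs, starts).latency_ms is None

    def test_noise_rarely_produces_latency(self):
        rng = np.random.default_rng(30)
        starts = np.arange(0.0, 300.0, 5.0)
        found = sum(
            sel.difference_latency(rng.normal(size=(20, starts.size)), starts).latency_ms
            is not None
            for _ in range(100)
        )
        assert found <= 5

    def test_too_few_bins_rejected(self):
        with pytest.raises(sel.InputError):
            sel.difference_latency(np.ones((5, 3)), np.arange(3))


class TestLatencyCompare:
    def test_identical_groups_not_significant(self, rng):
        lats = [60.0, 70.0, 80.0, 90.0] * 5
        p = sel.latency_compare(lats, list(lats), n_perm=300, rng=rng)
        assert p > 0.5

    def test_planted_offset_detected(self):
        rng = np.random.default_rng(31)
        a = list(rng.normal(60, 8, 30))
        b = list(rng.normal(100, 8, 30))
        assert sel.latency_compare(a, b, n_perm=1000, rng=rng) < 0.01

    def test_zero_permutations_rejected(self):
        with pytest.raises(sel.ConfigurationError):
            sel.latency_compare([1.0], [2.0], n_perm=0)

    def test_all_undefined_rejected(self):
        with pytest.raises(sel.InputError):
            sel.latency_compare([None, None], [1.0], n_perm=10)


def anova_omega2_oracle(counts, labels):
    """Direct per-window ANOVA decomposition using scipy groupings."""
    out = []
    for j in range(counts.shape[1]):
        groups = [counts[labels == g, j] for g in np.unique(labels)]
        n = counts.shape[0]
        k = len(groups)
        grand = counts[:, j].mean()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_t = ((counts[:, j] - grand) ** 2).sum()
        mse = (ss_t - ss_b) / (n - k)
        out.append((ss_b - (k - 1) * mse) / (ss_t + mse))
    return np.array(out)


class TestPevOmega2:
    def test_matches_direct_anova_decomposition(self, rng):
        counts = rng.poisson(6, (50, 8)).astype(float)
        labels = rng.integers(0, 5, 50)
        res = sel.pev_omega2(counts, labels, np.arange(8), n_shuffle=10, rng=rng)
        oracle = anova_omega2_oracle(counts, labels)
        assert np.allclose(res.omega2, oracle, rtol=1e-10, atol=1e-12)

    def test_pure_group_separation_gives_one(self):
        counts = np.repeat([[0.0], [4.0], [9.0]], 2, axis=0)
        labels = np.repeat([0, 1, 2], 2)
        res = sel.pev_omega2(counts, labels, np.arange(1), n_shuffle=5)
        assert res.omega2[0] == pytest.approx(1.0)

    def test_translation_invariance_and_bound(self, rng):
        counts = rng.poisson(6, (40, 6)).astype(float)
        labels = rng.integers(0, 4, 40)
        r1 = sel.pev_omega2(counts, labels, np.arange(6), n_shuffle=5, rng=np.random.default_rng(1))
        r2 = sel.pev_omega2(counts + 100.0, labels, np.arange(6), n_shuffle=5, rng=np.random.default_rng(1))
        assert np.allclose(r1.omega2, r2.omega2, atol=1e-10)
        assert np.all(r1.omega2 <= 1.0 + 1e-12)

    def test_null_z_centered_at_zero(self):
        rng = np.random.default_rng(40)
        zs = []
        for _ in range(40):
            counts = rng.poisson(5, (30, 3)).astype(float)
            labels = rng.integers(0, 5, 30)
            res = sel.pev_omega2(counts, labels, np.arange(3), n_shuffle=100, rng=rng)
            zs.extend(res.z_pev)
        zs = np.asarray(zs)
        assert abs(np.nanmean(zs)) < 2 * np.nanstd(zs) / np.sqrt(len(zs)) + 0.3

    def test_small_levels_dropped_with_warning(self):
        counts = np.ones((5, 2))
        counts[:3] += np.arange(3)[:, None]
        labels = np.array([0, 0, 0, 1, 2])  # levels 1, 2 have < 2 trials
        with pytest.warns(UserWarning, match="dropping levels"):
            with pytest.raises(sel.InputError):
                sel.pev_omega2(counts, labels, np.arange(2), n_shuffle=5)


class TestClassification:
    STARTS = np.arange(-300.0, 450.0, 10.0)

    def _z(self, value):
        return np.full(self.STARTS.size, float(value))

    @pytest.mark.parametrize(
        "zt,zs,expected",
        [
            (3.0, 3.0, "mixed"),
            (3.0, 0.0, "target"),
            (0.0, 3.0, "singleton"),
            (1.6, 1.6, "nonselective"),  # strict > 1.645
            (1.645, 1.645, "nonselective"),
        ],
    )
    def test_threshold_rules(self, zt, zs, expected):
        got = sel.classify_selectivity(self._z(zt), self._z(zs), self.STARTS)
        assert got == expected

    def test_significance_outside_window_ignored(self):
        zt = self._z(0.0)
        zt[self.STARTS < 100] = 5.0  # windows starting before 150 ms only
        got = sel.classify_selectivity(zt, self._z(0.0), self.STARTS)
        assert got == "nonselective"
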