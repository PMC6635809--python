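import numpy as np
import pytest
from scipy import stats

from bownet import (
    BOSVector,
    bootstrap_mean_difference,
    consistency,
    cosine_similarity,
    explainable_variance_r2,
    tost_equivalence,
)
from bownet.neurometrics import fisher_z_mean, select_consistent


def vec(values, ids=None):
    values = np.asarray(values, float)
    ids = np.arange(values.size) if ids is None else np.asarray(ids)
    return BOSVector(scene_point_ids=ids, values=values)


class TestConsistency:
    def test_fraction_of_positive_signs(self):
        assert consistency(vec([0.2, 0.1, -0.3, 0.4])) == 0.75
        assert consistency(vec([1.0, 2.0])) == 1.0

    def test_zeros_count_as_inconsistent(self):
        assert consistency(vec([0.0, 0.0, 0.0])) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consistency(vec([]))

    def test_threshold_selection(self):
        idx = select_consistent(np.array([0.9, 0.5, 0.81, 0.8]), threshold=0.8)
        assert list(idx) == [0, 2]


class TestCosineSimilarity:
    def test_identical_opposite_orthogonal(self):
        a = vec([0.3, -0.5, 0.2])
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(a, vec([-0.3, 0.5, -0.2])) == pytest.approx(-1.0)
        assert cosine_similarity(vec([1.0, 0.0]), vec([0.0, 1.0])) == pytest.approx(0.0)

    def test_matches_elementwise_formula_oracle(self, rng):
        a, b = rng.normal(size=(2, 40))
        num = sum(x * y for x, y in zip(a, b))
        den = np.sqrt(sum(x * x for x in a)) * np.sqrt(sum(y * y for y in b))
        assert cosine_similarity(vec(a), vec(b)) == pytest.approx(num / den, abs=1e-12)

    def test_symmetric_and_scale_invariant(self, rng):
        a, b = vec(rng.normal(size=20)), vec(rng.normal(size=20))
        s = cosine_similarity(a, b)
        assert cosine_similarity(b, a) == pytest.approx(s, abs=1e-14)
        assert cosine_similarity(vec(3.7 * a.values), b) == pytest.approx(s, abs=1e-12)

    def test_alignment_on_shared_ids(self):
        a = vec([1.0, 2.0, 3.0], ids=[10, 20, 30])
        b = vec([2.0, 1.0], ids=[20, 10])
        # shared ids {10, 20} align as (1, 2) vs (1, 2)
        assert cosine_similarity(a, b) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity(vec([0.0, 0.0]), vec([1.0, 1.0]))
        with pytest.raises(ValueError, match="shared"):
            cosine_similarity(vec([1.0], ids=[0]), vec([1.0], ids=[1]))


class TestFisherZ:
    def test_mean_of_identical_values_is_that_value(self):
        assert fisher_z_mean(np.array([0.4, 0.4, 0.4])) == pytest.approx(0.4)

    def test_unit_similarity_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            m = fisher_z_mean(np.array([1.0, 0.5]))
        assert np.isfinite(m)


class TestBootstrap:
    def test_identical_groups_are_not_different(self, rng):
        g = rng.uniform(0.2, 0.8, 30)
        p = bootstrap_mean_difference(g, g, n_samples=2000, seed=0)
        assert p > 0.9

    def test_seed_reproducibility(self, rng):
        g1 = rng.uniform(0.1, 0.9, 15)
        g2 = rng.uniform(0.1, 0.9, 40)
        p1 = bootstrap_mean_difference(g1, g2, n_samples=3000, seed=11)
        p2 = bootstrap_mean_difference(g1, g2, n_samples=3000, seed=11)
        assert p1 == p2

    def test_detects_large_shift(self, rng):
        g1 = rng.normal(0.1, 0.05, 40).clip(-0.9, 0.9)
        g2 = rng.normal(0.7, 0.05, 40).clip(-0.9, 0.9)
        assert bootstrap_mean_difference(g1, g2, n_samples=2000, seed=3) < 0.01


class TestTOST:
    def test_same_distribution_is_equivalent(self, rng):
        g1 = rng.normal(0.5, 0.1, 60)
        g2 = rng.normal(0.5, 0.1, 60)
        p, eq = tost_equivalence(g1, g2)
        assert eq and p < 0.05

    def test_offset_outside_zone_not_equivalent(self, rng):
        g1 = rng.normal(0.0, 0.1, 60)
        g2 = rng.normal(0.5, 0.1, 60)
        p, eq = tost_equivalence(g1, g2)
        assert not eq and p > 0.05

    def test_empty_zone_never_equivalent(self, rng):
        g = rng.normal(0.5, 0.01, 50)
        p, eq = tost_equivalence(g, g + 1e-9, zone=(0.0, 0.0))
        assert not eq and p == 1.0

    def test_degenerate_zero_variance_equal_means(self):
        p, eq = tost_equivalence(np.full(5, 0.3), np.full(7, 0.3))
        assert eq and p == 0.0

    def test_equivalence_consistent_with_welch_interval(self, rng):
        # TOST at alpha declares equivalence iff the (1 - 2 alpha) Welch CI of
        # the mean difference lies inside the zone; check the implication on
        # random data so TOST never contradicts the t framework.
        for _ in range(50):
            n1, n2 = rng.integers(5, 30, 2)
            g1 = rng.normal(rng.uniform(-0.3, 0.3), rng.uniform(0.05, 0.4), n1)
            g2 = rng.normal(rng.uniform(-0.3, 0.3), rng.uniform(0.05, 0.4), n2)
            p, eq = tost_equivalence(g1, g2)
            if eq:
                diff = g1.mean() - g2.mean()
                se = np.sqrt(g1.var(ddof=1) / n1 + g2.var(ddof=1) / n2)
                dof = se**4 / (
                    (g1.var(ddof=1) / n1) ** 2 / (n1 - 1)
                    + (g2.var(ddof=1) / n2) ** 2 / (n2 - 1)
                )
                half = stats.t.ppf(0.95, dof) * se
                assert -0.25 < diff - half and diff + half < 0.25


class TestExplainableVariance:
    def test_perfect_noiseless_fit_is_unity(self, rng):
        x = rng.uniform(-1, 1, 20)
        reps = [np.full(5, 3.0 * xi) for xi in x]
        fit = explainable_variance_r2(reps, x)
        assert fit.valid
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.scale == pytest.approx(3.0)
        assert fit.sigma_noise2 == pytest.approx(0.0, abs=1e-20)

    def test_uncorrelated_model_explains_nothing(self, rng):
        x = rng.uniform(-1, 1, 200)
        truth = rng.uniform(-1, 1, 200)
        reps = [2.0 * t + 0.2 * rng.standard_normal(10) for t in truth]
        fit = explainable_variance_r2(reps, x)
        assert abs(fit.r2) < 0.1

    def test_invariant_to_model_rescaling(self, rng):
        x = rng.uniform(-1, 1, 30)
        reps = [2.0 * xi + 0.3 * rng.standard_normal(8) for xi in x]
        r_a = explainable_variance_r2(reps, x).r2
        r_b = explainable_variance_r2(reps, 5.0 * x).r2
        assert r_a == pytest.approx(r_b, abs=1e-12)

    def test_noise_dominated_cell_flagged_invalid(self):
        # identical means, pure within-point noise: explainable variance <= 0
        x = np.array([0.5, -0.2, 0.8, 0.1])
        reps = [np.array([-1.0, 1.0]) for _ in x]
        fit = explainable_variance_r2(reps, x)
        assert not fit.valid
        assert np.isnan(fit.r2)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            explainable_variance_r2([[1.0, 2.0]], np.array([1.0]))  # Ns < 3
        with pytest.raises(ValueError):
            explainable_variance_r2([[1.0]] * 3, np.array([1.0, 2.0, 3.0]))  # 1 repeat
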