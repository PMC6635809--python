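import numpy as np
import pytest
from scipy import special
from scipy.special import expit

from bownet import ModelConfig, grouping_kernel, run_recurrence, winner_take_all
from bownet.frontend import OrientedEdgeVolume
from bownet.recurrence import (
    BorderOwnershipVolume,
    GroupingPyramid,
    banks_for_levels,
    feedback_modulation,
    feedforward_grouping,
)

CFG = ModelConfig(n_orientations=8)


def small_edge_volume(shapes, rng=None, value=0.0):
    """Edge volume of constant (or random nonnegative) activity."""
    levels = []
    for h, w in shapes:
        if rng is None:
            levels.append(np.full((8, 2, h, w), value))
        else:
            levels.append(rng.uniform(0, 1, (8, 2, h, w)))
    return OrientedEdgeVolume(levels=levels, orientations=CFG.undirected_angles())


class TestGroupingKernel:
    def test_matches_literal_formula(self):
        """Oracle: the annular von Mises expression evaluated directly."""
        theta, r0, support = 0.7, 2.0, 10.0
        rad = 10
        dr, dc = np.mgrid[-rad : rad + 1, -rad : rad + 1]
        x, y = dc.astype(float), -dr.astype(float)
        r = np.hypot(x, y)
        kappa = r - r0
        v = np.exp(kappa * np.cos(np.arctan2(y, x) - theta + np.pi / 2))
        v /= 2 * np.pi * special.i0(kappa)  # plain Bessel: fine at this support
        v[r == 0] = 1 / (2 * np.pi)  # angular mean at the undefined origin
        v[r > support] = 0.0
        expected = v / v.max()
        expected[expected < 1e-4] = 0.0
        got = grouping_kernel(theta, r0, support)
        assert np.allclose(got, expected, atol=1e-12)

    def test_uniform_ring_value_at_annulus_radius(self):
        # at r = R0 the concentration is 0: uniform value 1/(2 pi) before
        # max-normalization, identical at every angle
        k = grouping_kernel(1.1, 2.0, 16.0)
        c = k.shape[0] // 2
        ring = [k[c - 2, c], k[c + 2, c], k[c, c - 2], k[c, c + 2]]
        assert np.allclose(ring, ring[0])
        assert k.max() == 1.0

    def test_opposite_angles_are_point_reflections(self):
        # tail_cutoff=0 so the comparison is not confounded by pixels that
        # straddle the truncation threshold under floating-point rounding
        k0 = grouping_kernel(0.3, 2.0, 12.0, tail_cutoff=0.0)
        k1 = grouping_kernel(0.3 + np.pi, 2.0, 12.0, tail_cutoff=0.0)
        assert np.allclose(k0, k1[::-1, ::-1], atol=1e-12)

    def test_lobe_points_toward_theta_minus_half_pi(self):
        k = grouping_kernel(0.0, 2.0, 12.0)
        c = k.shape[0] // 2
        peak = np.unravel_index(k.argmax(), k.shape)
        assert peak[0] > c and peak[1] == c  # downward in array = -pi/2

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            grouping_kernel(0.0, r0=-1.0)
        with pytest.raises(ValueError):
            grouping_kernel(0.0, r0=2.0, support_radius=1.0)


class TestFeedforward:
    def test_zero_b_gives_zero_g(self):
        s = small_edge_volume([(16, 16), (8, 8)])
        banks = banks_for_levels([(16, 16), (8, 8)], CFG)
        b = BorderOwnershipVolume(
            [s.directed(k) for k in range(2)], CFG.directed_angles()
        )
        g = feedforward_grouping(b, banks, first_iteration=True)
        assert all(np.allclose(lvl, 0) for lvl in g.levels)

    def test_single_impulse_reproduces_translated_kernel(self):
        shape = (21, 21)
        banks = banks_for_levels([shape], CFG)
        b_arr = np.zeros((16, 2) + shape)
        d, c = 3, (10, 10)
        b_arr[d, 0, c[0], c[1]] = 1.0
        b = BorderOwnershipVolume([b_arr], CFG.directed_angles())
        g = feedforward_grouping(b, banks, first_iteration=True)
        kern = banks[0].kernels[d]
        kc = kern.shape[0] // 2
        # G(x) = sum_m v(m) B(x+m)  =>  G[c - m] = v(m)
        for dr in (-5, -2, 0, 1, 4):
            for dc in (-4, 0, 3):
                assert np.isclose(
                    g.levels[0][0, c[0] - dr, c[1] - dc],
                    kern[kc + dr, kc + dc],
                    atol=1e-10,
                )

    def test_balanced_pairs_cancel_without_first_iteration_rule(self, rng):
        shape = (16, 16)
        banks = banks_for_levels([shape], CFG)
        b_arr = rng.uniform(0, 1, (16, 2) + shape)
        b_arr[8:] = b_arr[:8]  # each pair identical
        b = BorderOwnershipVolume([b_arr], CFG.directed_angles())
        g = feedforward_grouping(b, banks, first_iteration=False)
        assert np.allclose(g.levels[0], 0, atol=1e-10)


class TestWinnerTakeAll:
    @pytest.mark.parametrize(
        "gl,gd,expected",
        [
            (0.5, 0.3, (0.5, 0.0)),
            (0.3, 0.5, (0.0, 0.5)),
            (0.4, 0.4, (0.0, 0.0)),  # ties silence both polarities
        ],
    )
    def test_pointwise_competition(self, gl, gd, expected):
        g = GroupingPyramid([np.array([[[gl]], [[gd]]])])
        out = winner_take_all(g).levels[0]
        assert (out[0, 0, 0], out[1, 0, 0]) == expected

    def test_exclusivity_on_random_fields(self, rng):
        g = GroupingPyramid([rng.uniform(0, 1, (2, 12, 12))])
        out = winner_take_all(g).levels[0]
        assert np.all(out[0] * out[1] == 0)


class TestFeedback:
    def shapes(self):
        return [(16, 16), (8, 8)]

    def test_zero_grouping_returns_bottom_up_activity(self, rng):
        s = small_edge_volume(self.shapes(), rng=rng)
        banks = banks_for_levels(self.shapes(), CFG)
        g = GroupingPyramid([np.zeros((2, h, w)) for h, w in self.shapes()])
        b = feedback_modulation(s, g, banks)
        for k in range(2):
            assert np.allclose(b.levels[k], s.directed(k), atol=1e-12)

    def test_b_bounded_by_twice_bottom_up(self, rng):
        s = small_edge_volume(self.shapes(), rng=rng)
        banks = banks_for_levels(self.shapes(), CFG)
        g = GroupingPyramid(
            [rng.uniform(0, 5, (2, h, w)) for h, w in self.shapes()]
        )
        b = feedback_modulation(s, g, banks)
        for k in range(2):
            assert np.all(b.levels[k] >= 0)
            assert np.all(b.levels[k] <= 2 * s.directed(k) + 1e-12)

    def test_opposing_pair_activity_is_conserved(self, rng):
        """(theta, L) and (theta+pi, D) share S and receive opposite feedback,
        so their activities sum to exactly 2 S."""
        s = small_edge_volume(self.shapes(), rng=rng)
        banks = banks_for_levels(self.shapes(), CFG)
        g = GroupingPyramid(
            [rng.uniform(0, 3, (2, h, w)) for h, w in self.shapes()]
        )
        b = feedback_modulation(s, g, banks)
        for k in range(2):
            s_dir = s.directed(k)
            pair_sum = b.levels[k][:, 0] + np.roll(b.levels[k], 8, axis=0)[:, 1]
            assert np.allclose(pair_sum, 2 * s_dir[:, 0], atol=1e-9)

    def test_logistic_saturation_limits(self):
        # sigma(+inf) -> B = 2S, sigma(-inf) -> B = 0
        assert expit(50.0) == pytest.approx(1.0)
        assert 2 * 0.7 * expit(-50.0) == pytest.approx(0.0, abs=1e-12)
        assert expit(3.2) + expit(-3.2) == pytest.approx(1.0)


class TestRunRecurrence:
    def test_blank_input_stays_silent(self):
        s = small_edge_volume([(16, 16), (8, 8)], value=0.0)
        b, g, trace = run_recurrence(s, CFG, n_iterations=3)
        assert all(np.allclose(lvl, 0) for lvl in b.levels)
        assert all(np.allclose(lvl, 0) for lvl in g.levels)
        assert all(np.allclose(f.magnitude, 0) for f in trace.fields)

    def test_invalid_iteration_count(self):
        s = small_edge_volume([(16, 16)])
        with pytest.raises(ValueError):
            run_recurrence(s, CFG, n_iterations=0)

    def test_early_stop_satisfies_tolerance(self, rng):
        s = small_edge_volume([(16, 16), (8, 8)], rng=rng)
        _, _, trace = run_recurrence(s, CFG, n_iterations=10, convergence_tol=1e-3)
        assert trace.n_iterations <= 10
        if trace.n_iterations < 10:
            assert trace.deltas[-1] < 1e-3
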