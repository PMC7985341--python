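"""Assessment statistics: nMSE, correlation, Dice, assignment, BBR, ranges."""
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epiwarp import metrics


class TestNmse:
    def test_equal_images_zero(self):
        a = np.arange(12.0).reshape(3, 4)
        assert metrics.nmse(a, a) == 0.0

    def test_zero_versus_nonzero_is_two(self):
        a = np.ones((4, 4))
        assert metrics.nmse(a, np.zeros_like(a)) == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        assert metrics.nmse(np.array([1.0, 2.0]), np.array([2.0, 4.0])) \
            == pytest.approx(0.4)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random((2, 5, 5))
        assert metrics.nmse(a, b) == pytest.approx(metrics.nmse(b, a))

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics.nmse(np.zeros(4), np.zeros(4))


class TestCrossCorrelation:
    def test_identical_is_one(self):
        a = np.arange(10.0)
        assert metrics.cross_correlation(a, a) == pytest.approx(1.0)

    def test_negated_plus_constant_is_minus_one(self):
        a = np.arange(10.0)
        assert metrics.cross_correlation(a, -a + 3.0) == pytest.approx(-1.0)

    def test_closed_form_pearson(self):
        r = metrics.cross_correlation(np.array([1.0, 2.0, 3.0]),
                                      np.array([1.0, 2.0, 4.0]))
        assert round(r, 4) == 0.9820

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(3)
        a, b = rng.random((2, 40))
        r0 = metrics.cross_correlation(a, b)
        assert metrics.cross_correlation(scale * a + offset, b) == pytest.approx(r0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            metrics.cross_correlation(np.ones(5), np.arange(5.0))


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((4, 4), bool)
        m[1:3] = True
        assert metrics.dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros(6, bool); a[:2] = True
        b = np.zeros(6, bool); b[3:] = True
        assert metrics.dice(a, b) == 0.0

    def test_formula_arithmetic(self):
        a = np.zeros(10, bool); a[:3] = True          # |A| = 3
        b = np.zeros(10, bool); b[1:6] = True         # |B| = 5, overlap 2
        assert metrics.dice(a, b) == pytest.approx(0.5)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((2, 7, 7)) > 0.5
        assert metrics.dice(a, b) == metrics.dice(b, a)

    def test_both_empty_warns_zero(self):
        with pytest.warns(UserWarning):
            assert metrics.dice(np.zeros(3, bool), np.zeros(3, bool)) == 0.0


class TestThresholdComponent:
    def test_zero_map_empty(self):
        assert not metrics.threshold_component(np.zeros((3, 3)), 3.0).any()

    def test_minus_inf_threshold_full(self):
        assert metrics.threshold_component(np.zeros((3, 3)), -np.inf).all()

    def test_count_on_fixture(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1, (10, 10))
        z.flat[:7] = 5.0
        assert metrics.threshold_component(z, 3.0).sum() == 7


def brute_force_assignment(d, orders=None):
    """Independent oracle: plain-python greedy over every template order."""
    t, c = d.shape
    best_mean, best_map = -1.0, None
    for order in (orders if orders is not None else permutations(range(t))):
        taken, mapping, total = set(), {}, 0.0
        for ti in order:
            best_ci, best_val = None, -1.0
            for ci in range(c):
                if ci not in taken and d[ti, ci] > best_val:
                    best_ci, best_val = ci, d[ti, ci]
            taken.add(best_ci)
            mapping[ti] = best_ci
            total += best_val
        if total / t > best_mean + 1e-15:
            best_mean, best_map = total / t, mapping
    return best_map, best_mean


class TestAssignRsns:
    def test_single_template_is_argmax(self):
        d = np.array([[0.2, 0.9, 0.4]])
        out = metrics.assign_rsns(d)
        assert out.mapping == {0: 1}
        assert out.mean_dice == pytest.approx(0.9)

    def test_hand_worked_example(self):
        d = np.array([[0.8, 0.7, 0.0],
                      [0.1, 0.6, 0.0],
                      [0.0, 0.0, 0.5]])
        out = metrics.assign_rsns(d)
        assert out.mapping == {0: 0, 1: 1, 2: 2}
        assert out.mean_dice == pytest.approx((0.8 + 0.6 + 0.5) / 3)

    def test_diagonal_dominant_identity(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 0.3, (5, 5)) + np.eye(5) * 0.7
        out = metrics.assign_rsns(d)
        assert out.mapping == {i: i for i in range(5)}

    def test_matches_bruteforce_small(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = int(rng.integers(2, 6))
            d = rng.random((t, t + int(rng.integers(0, 3))))
            out = metrics.assign_rsns(d)
            _, oracle_mean = brute_force_assignment(d)
            assert out.mean_dice == pytest.approx(oracle_mean)

    def test_sampled_mode_deterministic(self):
        rng = np.random.default_rng(3)
        d = rng.random((8, 9))  # 8! > max_orders -> sampling
        a = metrics.assign_rsns(d, max_orders=200, seed=42)
        b = metrics.assign_rsns(d, max_orders=200, seed=42)
        assert a.mapping == b.mapping and a.order_used == b.order_used

    def test_fewer_components_rejected(self):
        with pytest.raises(ValueError):
            metrics.assign_rsns(np.ones((3, 2)) * 0.5)


def sphere_fixture(invert=False):
    """Bright-inside sphere with boundary points and outward normals."""
    shape = (24, 24, 24)
    center = np.array([11.5, 11.5, 11.5])
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"), axis=-1)
    r = np.linalg.norm(grid - center, axis=-1)
    vol = (r <= 8.0).astype(float)
    if invert:
        vol = 1.0 - vol
    theta = np.linspace(0.2, np.pi - 0.2, 12)
    phi = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    tt, pp = np.meshgrid(theta, phi)
    normals = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                        np.cos(tt)], axis=-1).reshape(-1, 3)
    points = center + 8.0 * normals
    return vol, points, normals


class TestBbrCost:
    def test_uniform_image_is_half(self):
        vol, points, normals = sphere_fixture()
        cost = metrics.bbr_cost(np.full_like(vol, 3.0), points, normals, (1, 1, 1))
        assert cost == pytest.approx(0.5)

    def test_bright_inside_low_cost_with_large_slope(self):
        vol, points, normals = sphere_fixture()
        cost = metrics.bbr_cost(vol, points, normals, (1, 1, 1), slope=5.0)
        assert cost < 0.05

    def test_inverted_contrast_high_cost(self):
        vol, points, normals = sphere_fixture(invert=True)
        cost = metrics.bbr_cost(vol, points, normals, (1, 1, 1), slope=5.0)
        assert cost > 0.95

    def test_cost_decreases_with_misalignment_removed(self, truth, clean_pair,
                                                      baseline, spec):
        """Distortion mixes tissues across the WM boundary -> cost toward 0.5."""
        kw = dict(voxel_size=spec.voxel_size, slope=-0.5)  # EPI contrast
        aligned = metrics.bbr_cost(baseline, truth.boundary_points,
                                   truth.boundary_normals, **kw)
        distorted = metrics.bbr_cost(clean_pair[0], truth.boundary_points,
                                     truth.boundary_normals, **kw)
        assert aligned < distorted

    def test_points_outside_grid_rejected(self):
        vol, points, normals = sphere_fixture()
        far = points + 100.0
        with pytest.raises(ValueError):
            metrics.bbr_cost(vol, far, normals, (1, 1, 1))


class TestVsmRoiRange:
    def test_constant(self):
        v = np.full((4, 4), 1.5)
        roi = np.ones((4, 4), bool)
        assert metrics.vsm_roi_range(v, roi) == (1.5, 1.5)

    def test_single_voxel(self):
        v = np.arange(9.0).reshape(3, 3)
        roi = np.zeros((3, 3), bool)
        roi[1, 2] = True
        assert metrics.vsm_roi_range(v, roi) == (5.0, 5.0)

    def test_ramp(self):
        v = np.linspace(0, 10, 11)
        assert metrics.vsm_roi_range(v, np.ones(11, bool)) == (0.0, 10.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            metrics.vsm_roi_range(np.ones(3), np.zeros(3, bool))
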