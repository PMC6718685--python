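import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rromap as rm
from rromap import FeedbackParams, MapParams
from rromap.errors import BracketingError, InvalidParameterError, NoExtremumError

K_RATIO = 1.3811
B = 3.42


class TestActivation:
    @pytest.mark.parametrize(
        "x, gain, expected",
        [
            (0.0, 5.96, 0.0),       # linear branch through the origin
            (2.0, 5.96, 1.0),       # saturated: 2 > 1/5.96
            (-2.0, 5.96, -1.0),
            (0.1, 5.96, 0.596),     # linear branch
        ],
    )
    def test_branches(self, x, gain, expected):
        assert rm.activation(x, gain) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(-10, 10), st.floats(0.01, 50))
    @settings(max_examples=200, deadline=None)
    def test_odd_and_bounded(self, x, gain):
        assert rm.activation(-x, gain) == pytest.approx(-rm.activation(x, gain))
        assert -1.0 <= rm.activation(x, gain) <= 1.0

    @pytest.mark.parametrize("bad_gain", [0.0, -1.0, float("nan"), float("inf")])
    def test_invalid_gain(self, bad_gain):
        with pytest.raises(InvalidParameterError):
            rm.activation(0.1, bad_gain)

    def test_invalid_input(self):
        with pytest.raises(InvalidParameterError):
            rm.activation(float("nan"), 2.0)


class TestMapF:
    def test_origin(self, p596):
        assert rm.map_F(0.0, p596) == 0.0

    def test_double_saturation(self, p596):
        # both activations saturate: F = 1 - k
        assert rm.map_F(2.0, p596) == pytest.approx(1 - K_RATIO)

    def test_kink_value(self, p596):
        # z = 1/a: F_a = 1, F_b = b/a
        assert rm.map_F(1 / 5.96, p596) == pytest.approx(1 - K_RATIO * B / 5.96)

    @given(z=st.floats(-5, 5))
    @settings(max_examples=200, deadline=None)
    def test_odd_and_bounded(self, z, p596):
        assert rm.map_F(-z, p596) == pytest.approx(-rm.map_F(z, p596))
        assert abs(rm.map_F(z, p596)) <= 1 + p596.k


class TestRroU:
    def test_zero_at_merging_point(self, fb0):
        assert rm.rro_u(fb0.z_d, fb0) == 0.0

    @given(st.floats(-2, 2))
    @settings(max_examples=100, deadline=None)
    def test_odd_about_zd(self, x):
        fb = FeedbackParams(K=0.0, z_d=0.25, sigma=0.3)
        assert rm.rro_u(fb.z_d + x, fb) == pytest.approx(-rm.rro_u(fb.z_d - x, fb))

    def test_extremum_magnitude(self, fb0):
        # stationary points of u at z_d +/- sigma with magnitude sigma e^{-1/2}
        assert rm.rro_u(fb0.z_d + fb0.sigma, fb0) == pytest.approx(
            -fb0.sigma * np.exp(-0.5)
        )


class TestFullMap:
    @given(z=st.floats(-3, 3))
    @settings(max_examples=100, deadline=None)
    def test_zero_feedback_reduces_to_F(self, z, p596, fb0):
        assert rm.full_map(z, p596, fb0) == rm.map_F(z, p596)

    def test_negative_feedback_deepens_extrema(self, p596):
        # merging-strength feedback raises the local-max value of the map
        ex0 = rm.find_extrema(p596, FeedbackParams.for_map(p596, K=0.0))
        exn = rm.find_extrema(p596, FeedbackParams.for_map(p596, K=-0.1))
        assert exn.f_max > ex0.f_max
        assert exn.f_min < ex0.f_min


class TestFindExtrema:
    def test_merged_map_signs(self, p603):
        ex = rm.find_extrema(p603, FeedbackParams.for_map(p603))
        assert ex.value_at_max < 0
        assert ex.value_at_min > 0

    def test_separated_map_signs(self, p596, fb0):
        ex = rm.find_extrema(p596, fb0)
        assert ex.value_at_max > 0
        assert ex.value_at_min < 0

    def test_odd_symmetry(self, p596, fb0):
        ex = rm.find_extrema(p596, fb0)
        assert ex.value_at_min == pytest.approx(-ex.value_at_max, abs=1e-9)
        assert ex.z_min == pytest.approx(-ex.z_max, abs=1e-9)

    @pytest.mark.parametrize("K", [0.0, 0.1, -0.1])
    def test_against_dense_grid_oracle(self, p596, K):
        fb = FeedbackParams.for_map(p596, K=K)
        ex = rm.find_extrema(p596, fb)
        L = p596.z_bound
        grid = np.linspace(-L, L, 100_001)
        vals = rm.full_map(grid, p596, fb)
        pos = grid > 0
        neg = grid < 0
        z_max_oracle = grid[pos][np.argmax(vals[pos])]
        z_min_oracle = grid[neg][np.argmin(vals[neg])]
        spacing = grid[1] - grid[0]
        assert abs(ex.z_max - z_max_oracle) <= spacing
        assert abs(ex.z_min - z_min_oracle) <= spacing
        assert ex.f_max >= vals[pos].max() - 1e-12


class TestMergingCondition:
    @pytest.mark.parametrize(
        "a, K, expected",
        [
            (6.03, 0.0, True),    # merged without feedback
            (6.03, 0.1, False),   # positive feedback separates
            (5.96, 0.0, False),   # separated without feedback
            (5.96, -0.1, True),   # negative feedback merges
        ],
    )
    def test_known_cases(self, a, K, expected):
        p = MapParams(a=a)
        assert rm.merging_condition(p, FeedbackParams.for_map(p, K=K)) is expected


def _dense_scan_critical_a(K, lo, hi, step=1e-4):
    a_grid = np.arange(lo, hi + step / 2, step)
    for a in a_grid:
        p = MapParams(a=float(a))
        if rm.merging_condition(p, FeedbackParams.for_map(p, K=K)):
            return float(a)
    raise AssertionError("no flip found")


class TestCriticalParameters:
    def test_critical_a_matches_dense_scan(self):
        val = rm.critical_a(K=0.0, tol=1e-6)
        oracle = _dense_scan_critical_a(0.0, 5.95, 6.05)
        assert abs(val - oracle) <= 2e-4

    def test_critical_a_tolerance_stability(self):
        v1 = rm.critical_a(K=0.0, tol=1e-6)
        v2 = rm.critical_a(K=0.0, tol=1e-8)
        assert round(v1, 2) == round(v2, 2)

    def test_positive_feedback_raises_threshold(self):
        assert rm.critical_a(K=0.1) > rm.critical_a(K=0.0)

    def test_critical_K_matches_dense_scan(self, p596):
        val = rm.critical_K(p596, tol=1e-6)
        step = 1e-4
        k_grid = np.arange(0.0, -0.15, -step)
        oracle = next(
            float(K) for K in k_grid
            if rm.merging_condition(p596, FeedbackParams.for_map(p596, K=float(K)))
        )
        assert abs(val - oracle) <= 2e-4

    def test_critical_K_monotone_in_a(self):
        mags = [abs(rm.critical_K(MapParams(a=a))) for a in (5.95, 5.96, 5.97)]
        assert mags[0] > mags[1] > mags[2]

    def test_bracketing_error(self, p596):
        with pytest.raises(BracketingError):
            rm.critical_K(p596, bracket=(-0.005, 0.0))  # both ends separated


class TestParamValidation:
    def test_weight_constraint_enforced(self):
        with pytest.raises(InvalidParameterError):
            MapParams(a=5.96, w_EE=1.0, w_EI=1.0, w_IE=1.0, w_II=1.3811)

    def test_consistent_weights_accepted(self):
        p = MapParams(a=5.96, w_EE=2.0, w_EI=2 * 1.3811, w_IE=1.0, w_II=1.3811)
        assert p.w_EI / p.w_EE == pytest.approx(p.k)

    @pytest.mark.parametrize("kwargs", [dict(a=-1), dict(a=5.96, b=0), dict(a=5.96, k=-2)])
    def test_bad_gains(self, kwargs):
        with pytest.raises(InvalidParameterError):
            MapParams(**kwargs)

    def test_sigma_positive(self):
        with pytest.raises(InvalidParameterError):
            FeedbackParams(K=0.0, z_d=0.0, sigma=0.0)
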