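"""Geometry of the oblique illumination arrangement: working distances,
angular bounds, effective sheet thickness and illumination path lengths."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lstmsim import (
    ImagingGeometry,
    InfeasibleGeometryError,
    ObjectiveSpec,
    SampleBlock,
    UnsupportedConfigurationError,
    angular_bounds,
    effective_sheet_thickness,
    elongated_working_distance,
    mipl,
    mipl_ratio_map,
)


def _air_objective(wd=29.5, na=0.28, barrel=28.0):
    return ObjectiveSpec(4, na, wd, barrel, 1.0)


class TestElongatedWorkingDistance:
    def test_marginal_ray_into_immersion_oil(self, illumination_objective):
        # the 4x/0.28 air objective focused into n=1.454 oil
        ewd = elongated_working_distance(illumination_objective, 1.454)
        assert ewd == pytest.approx(43.84, abs=5e-3)

    def test_paraxial_limit_is_wd_times_n(self):
        obj = _air_objective(na=1e-6)
        assert elongated_working_distance(obj, 1.454) == pytest.approx(
            29.5 * 1.454, abs=1e-3
        )

    def test_no_refraction_in_air(self):
        assert elongated_working_distance(_air_objective(), 1.0) == 29.5

    def test_rejects_non_air_objective(self, detection_objective):
        with pytest.raises(UnsupportedConfigurationError):
            elongated_working_distance(detection_objective, 1.454)

    def test_rejects_na_at_or_above_medium_index(self):
        with pytest.raises(ValueError):
            elongated_working_distance(_air_objective(na=0.99), 0.95)

    @settings(derandomize=True, max_examples=50)
    @given(n=st.floats(min_value=1.0, max_value=2.0))
    def test_never_shorter_than_air_wd(self, n):
        assert elongated_working_distance(_air_objective(), n) >= 29.5 - 1e-12

    def test_strictly_increasing_in_medium_index(self):
        ns = np.linspace(1.0, 1.6, 25)
        ewds = [elongated_working_distance(_air_objective(), n) for n in ns]
        assert np.all(np.diff(ewds) > 0)


def _geometry(w1=8.0, d1=40.0, wd_ill=29.5, d2=28.0, theta=60.0):
    det = ObjectiveSpec(10, 0.6, w1, d1, 1.454)
    ill = ObjectiveSpec(4, 0.28, wd_ill, d2, 1.0)
    return ImagingGeometry(det, ill, theta=theta, medium_index=1.454)


def _brute_force_bounds(w1, w2, d1, d2, step=1e-4):
    """Independent oracle: scan both constraint residuals over (0, 90) deg."""
    thetas = np.arange(step, 90.0, step)
    t = np.radians(thetas)
    lower_res = w2 * np.sin(t) - d1 / 2 - (d2 / 2) * np.cos(t)
    upper_res = w2 * np.cos(t) - w1 - (d2 / 2) * np.sin(t)
    lower = thetas[np.argmin(np.abs(lower_res))]
    upper = thetas[np.argmin(np.abs(upper_res))]
    return lower, upper


class TestAngularBounds:
    def test_clearance_bound_for_instrument_objectives(self):
        # 43.84 mm elongated WD illumination vs 10x/8 mm WD/40 mm detection
        bounds = angular_bounds(_geometry())
        assert bounds.theta_upper == pytest.approx(62.3, abs=0.05)

    def test_collision_bound_matches_brute_force_scan(self):
        bounds = angular_bounds(_geometry())
        w2 = elongated_working_distance(_air_objective(), 1.454)
        lower, upper = _brute_force_bounds(8.0, w2, 40.0, 28.0)
        assert bounds.theta_lower == pytest.approx(lower, abs=2e-4)
        assert bounds.theta_upper == pytest.approx(upper, abs=2e-4)
        assert bounds.theta_lower == pytest.approx(43.46, abs=0.01)

    def test_zero_barrel_closed_form(self):
        # D2=0 reduces to asin(D1 / 2 W2) and acos(W1 / W2)
        det = ObjectiveSpec(10, 0.6, 8.0, 40.0, 1.454)
        ill = ObjectiveSpec(4, 0.28, 43.84, 1e-12, 1.454)
        bounds = angular_bounds(ImagingGeometry(det, ill, medium_index=1.454))
        assert bounds.theta_lower == pytest.approx(
            math.degrees(math.asin(20 / 43.84)), abs=1e-4
        )
        assert bounds.theta_upper == pytest.approx(
            math.degrees(math.acos(8 / 43.84)), abs=1e-4
        )

    def test_residuals_vanish_at_returned_angles(self):
        geo = _geometry()
        bounds = angular_bounds(geo)
        w2 = elongated_working_distance(geo.illumination, geo.medium_index)
        tl = math.radians(bounds.theta_lower)
        tu = math.radians(bounds.theta_upper)
        assert abs(w2 * math.sin(tl) - 20 - 14 * math.cos(tl)) < 1e-6
        assert abs(w2 * math.cos(tu) - 8 - 14 * math.sin(tu)) < 1e-6

    def test_bound_monotonicity_in_objective_dimensions(self):
        # wider barrels collide earlier; longer detection WD / wider
        # illumination barrel reduce the clearance bound
        lowers_d1 = [angular_bounds(_geometry(d1=d)).theta_lower
                     for d in (30, 35, 40, 45)]
        assert np.all(np.diff(lowers_d1) > 0)
        lowers_d2 = [angular_bounds(_geometry(d2=d)).theta_lower
                     for d in (10, 20, 28, 34)]
        assert np.all(np.diff(lowers_d2) > 0)
        uppers_d2 = [angular_bounds(_geometry(d2=d)).theta_upper
                     for d in (10, 20, 28, 34)]
        assert np.all(np.diff(uppers_d2) < 0)
        uppers_w1 = [angular_bounds(_geometry(w1=w)).theta_upper
                     for w in (4, 8, 12, 16)]
        assert np.all(np.diff(uppers_w1) < 0)

    def test_infeasible_geometry_reports_failing_bound(self):
        # detection barrel too wide for the illumination WD: no collision root
        with pytest.raises(InfeasibleGeometryError, match="collision"):
            angular_bounds(_geometry(d1=200.0))


class TestEffectiveSheetThickness:
    @pytest.mark.parametrize(
        "b, theta, expected",
        [(4.0, 90.0, 4.0), (4.0, 60.0, 4.6188), (4.0, 30.0, 8.0)],
    )
    def test_projection_values(self, b, theta, expected):
        assert effective_sheet_thickness(b, theta) == pytest.approx(
            expected, abs=1e-3
        )

    def test_projection_never_thinner_than_sheet(self):
        thetas = np.linspace(1.0, 90.0, 90)
        eff = np.array([effective_sheet_thickness(4.0, t) for t in thetas])
        assert np.all(eff >= 4.0)
        assert eff[-1] == 4.0
        assert np.all(eff[:-1] > 4.0)

    def test_rejects_nonpositive_angle(self):
        with pytest.raises(ValueError):
            effective_sheet_thickness(4.0, 0.0)


class TestMipl:
    def test_oblique_path_through_thickness(self):
        sample = SampleBlock(14, 10, 5)
        assert mipl(sample, 60.0, "lstm") == pytest.approx(10.0)
        assert mipl(SampleBlock(14, 10, 3), 0.0, "lstm") == pytest.approx(3.0)

    def test_lsm_path_is_width(self):
        sample = SampleBlock(14, 10, 5)
        assert mipl(sample, 60.0, "lsm") == 14.0
        assert mipl(sample, 60.0, "lsm", two_sided=True) == 7.0

    def test_grazing_angle_rejected(self):
        with pytest.raises(ValueError):
            mipl(SampleBlock(14, 10, 5), 90.0, "lstm")


class TestMiplRatioMap:
    def test_strict_inequality_and_boundary(self):
        # t/cos(60)=4 < w=5 favours the oblique path; the w=4 boundary does not
        m = mipl_ratio_map([5.0], [2.0], 60.0)
        assert m[0, 0]
        m = mipl_ratio_map([4.0], [2.0], 60.0)
        assert not m[0, 0]

    @pytest.mark.parametrize("theta", range(0, 81, 10))
    def test_partition_equals_analytic_line(self, theta):
        w = np.arange(1.0, 21.0)
        t = np.arange(1.0, 21.0)
        m = mipl_ratio_map(w, t, theta)
        lstm = t[:, None] / math.cos(math.radians(theta))
        lsm = w[None, :]
        # strictly below the line, boundary cells excluded
        expected = (lstm < lsm) & ~np.isclose(lstm, lsm, rtol=1e-9)
        assert np.array_equal(m, expected)

    def test_partition_line_at_60_degrees_is_w_equals_2t(self):
        w = np.arange(1.0, 21.0)
        t = np.arange(1.0, 21.0)
        m = mipl_ratio_map(w, t, 60.0)
        brute = np.empty_like(m)
        for i, ti in enumerate(t):
            for j, wj in enumerate(w):
                brute[i, j] = 2.0 * ti < wj
        assert np.array_equal(m, brute)


class TestDomainTypes:
    def test_objective_invariants(self):
        with pytest.raises(ValueError):
            ObjectiveSpec(10, 0.0, 8, 40)
        with pytest.raises(ValueError):
            ObjectiveSpec(10, 1.1, 8, 40, design_medium_index=1.0)
        with pytest.raises(ValueError):
            ObjectiveSpec(10, 0.6, -1, 40, design_medium_index=1.454)

    def test_geometry_invariants(self, detection_objective, illumination_objective):
        with pytest.raises(ValueError):
            ImagingGeometry(detection_objective, illumination_objective, theta=95)
        with pytest.raises(ValueError):
            ImagingGeometry(
                detection_objective, illumination_objective, medium_index=0.9
            )

    def test_sample_block_invariants(self):
        with pytest.raises(ValueError):
            SampleBlock(0, 1, 1)
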