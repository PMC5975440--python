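"""Image-formation properties of the rolling-shutter acquisition simulator."""

import numpy as np
import pytest

from lstmsim import (
    BeadPhantom,
    LightSheet,
    field_resolution_profile,
    make_bead_grid,
    measure_axial_fwhm,
    simulate_acquisition,
)


def _centred_bead(extent=(100.0, 10.0, 40.0), diameter=0.5):
    return BeadPhantom(
        np.array([[0.0, 0.0, 0.0]]), np.array([1.0]), diameter, extent
    )


def _centre_loc(stack):
    nz, ny, nx = stack.intensities.shape
    return (nz // 2, ny // 2, nx // 2)


class TestImageFormation:
    def test_empty_phantom_gives_zero_stack(self, geometry, sheet_eff4, camera):
        phantom = BeadPhantom(
            np.empty((0, 3)), np.empty(0), 0.5, (50.0, 10.0, 20.0)
        )
        stack = simulate_acquisition(
            phantom, geometry, sheet_eff4, camera, "2as", 0.1, 1.0
        )
        assert np.all(stack.intensities == 0)

    def test_centred_bead_matches_quadrature_oracle(
        self, geometry, sheet_eff4, camera
    ):
        # oracle: the analytic field profile at s=0 (sheet + detection in
        # quadrature); narrow slit so the shutter window adds nothing
        phantom = _centred_bead()
        stack = simulate_acquisition(
            phantom, geometry, sheet_eff4, camera, "2as", 0.02, 0.5
        )
        measured = measure_axial_fwhm(stack, _centre_loc(stack))
        oracle = field_resolution_profile(
            geometry, sheet_eff4, "2as", 100.0, 11
        ).axial_fwhm[5]
        assert measured == pytest.approx(oracle, rel=0.05)

    def test_edge_bead_lsm_worse_than_2as(self, geometry, camera):
        extent = (1200.0, 6.0, 90.0)
        edge = BeadPhantom(
            np.array([[500.0, 0.0, 0.0]]), np.array([1.0]), 0.5, extent
        )
        lsm = simulate_acquisition(
            edge, geometry, LightSheet.from_effective_thickness(4.0, 90.0),
            camera, "lsm", 0.1, 0.5,
        )
        two_as = simulate_acquisition(
            edge, geometry, LightSheet.from_effective_thickness(4.0, 60.0),
            camera, "2as", 0.1, 0.5,
        )
        xs = lsm.axis_coordinates(2)
        loc = (
            lsm.intensities.shape[0] // 2,
            lsm.intensities.shape[1] // 2,
            int(np.argmin(np.abs(xs - 500.0))),
        )
        f_lsm = measure_axial_fwhm(lsm, loc)
        f_2as = measure_axial_fwhm(two_as, loc)
        assert f_lsm > f_2as

    def test_lsm_limit_matches_orthogonal_sheet_prediction(self, geometry, camera):
        # off-centre bead in LSM mode: the static orthogonal sheet has
        # diverged by exactly the field offset; compare with the analytic
        # profile at that position
        sheet = LightSheet.from_effective_thickness(3.0, 90.0)
        phantom = BeadPhantom(
            np.array([[150.0, 0.0, 0.0]]), np.array([1.0]), 0.5,
            (400.0, 6.0, 80.0),
        )
        stack = simulate_acquisition(
            phantom, geometry, sheet, camera, "lsm", 0.02, 0.5
        )
        xs = stack.axis_coordinates(2)
        loc = (
            stack.intensities.shape[0] // 2,
            stack.intensities.shape[1] // 2,
            int(np.argmin(np.abs(xs - 150.0))),
        )
        measured = measure_axial_fwhm(stack, loc)
        prof = field_resolution_profile(geometry, sheet, "lsm", 400.0, 401)
        oracle = prof.axial_fwhm[np.argmin(np.abs(prof.field_positions - 150.0))]
        assert measured == pytest.approx(oracle, rel=0.05)

    def test_phantom_must_cover_requested_field(self, geometry, sheet_eff4, camera):
        phantom = _centred_bead(extent=(50.0, 10.0, 20.0))
        with pytest.raises(ValueError, match="extent"):
            simulate_acquisition(
                phantom, geometry, sheet_eff4, camera, "2as", 0.1, 1.0,
                fov=200.0,
            )


class TestShutterGating:
    def test_disjoint_windows_sum_to_open_shutter(
        self, geometry, sheet_eff4, camera
    ):
        # image formation is linear in the shutter gate: acquisitions with
        # consecutive disjoint windows add up to the fully open acquisition
        phantom = make_bead_grid((80.0, 8.0, 30.0), 20.0, seed=3, jitter=2.0)
        edges = [-40.0, -10.0, 5.0, 40.0]
        parts = [
            simulate_acquisition(
                phantom, geometry, sheet_eff4, camera, "2as", 1.0, 1.0,
                shutter_window=(lo, hi),
            ).intensities
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        full = simulate_acquisition(
            phantom, geometry, sheet_eff4, camera, "2as", 1.0, 1.0,
            shutter_window=(edges[0], edges[-1]),
        ).intensities
        assert np.allclose(sum(parts), full, rtol=1e-12, atol=1e-15)

    def test_narrowing_never_increases_signal(self, geometry, sheet_eff4, camera):
        phantom = make_bead_grid((80.0, 8.0, 30.0), 20.0, seed=3)
        wide = simulate_acquisition(
            phantom, geometry, sheet_eff4, camera, "2as", 1.0, 1.0
        ).intensities
        narrow = simulate_acquisition(
            phantom, geometry, sheet_eff4, camera, "2as", 0.2, 1.0
        ).intensities
        assert np.all(narrow <= wide + 1e-15)

    def test_wider_slit_degrades_axial_resolution(
        self, geometry, sheet_eff4, camera
    ):
        # the virtual-slit analogue of a confocal pinhole: larger
        # rolling-shutter exposure admits more oblique out-of-plane light
        phantom = _centred_bead(extent=(200.0, 10.0, 80.0))
        fwhm = []
        for exposure in (0.1, 0.5, 1.0):
            stack = simulate_acquisition(
                phantom, geometry, sheet_eff4, camera, "2as", exposure, 0.5
            )
            fwhm.append(measure_axial_fwhm(stack, _centre_loc(stack)))
        assert fwhm[0] < fwhm[1] < fwhm[2]


class TestDeterminism:
    def test_identical_configs_bit_identical(self, geometry, sheet_eff4, camera):
        phantom = make_bead_grid((80.0, 8.0, 30.0), 20.0, seed=5, jitter=3.0)
        a = simulate_acquisition(
            phantom, geometry, sheet_eff4, camera, "2as", 0.5, 1.0
        )
        b = simulate_acquisition(
            phantom, geometry, sheet_eff4, camera, "2as", 0.5, 1.0
        )
        assert np.array_equal(a.intensities, b.intensities)

    def test_poisson_noise_is_seeded(self, geometry, sheet_eff4, camera):
        phantom = _centred_bead()
        kwargs = dict(noise_photons=100.0, seed=11)
        a = simulate_acquisition(
            phantom, geometry, sheet_eff4, camera, "2as", 0.1, 1.0, **kwargs
        )
        b = simulate_acquisition(
            phantom, geometry, sheet_eff4, camera, "2as", 0.1, 1.0, **kwargs
        )
        c = simulate_acquisition(
            phantom, geometry, sheet_eff4, camera, "2as", 0.1, 1.0,
            noise_photons=100.0, seed=12,
        )
        assert np.array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)
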