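"""Gaussian light-sheet propagation and axial-resolution models.

The light sheet is a focused Gaussian beam in its thin axis.  The intensity
FWHM at the waist is ``b``; away from the waist the thickness grows as
``b(x) = b sqrt(1 + (x / zR)^2)`` with Rayleigh range
``zR = pi w0^2 n / lambda`` and 1/e^2 waist half-width
``w0 = b / sqrt(2 ln 2)``.

Because the sheet meets the detection plane at an angle ``theta``, the axial
(detection-axis) footprint of the sheet is its thickness divided by
``sin(theta)``.  The predicted axial resolution at a field position combines
this effective sheet thickness with the detection objective's axial response
in quadrature (independent-Gaussian approximation; the true system response
is a product of the two point spread functions, which this deliberately
over-estimates — see docs/methods.md).

Three scan modes are compared, as in the bead-characterization experiment:

``"2as"``
    default LSTM: the waist is translated both along (tunable lens) and
    perpendicular to (galvo) its propagation axis so the thinnest part always
    sits on the detection plane — the distance from the waist is zero at
    every field position.
``"1as"``
    the sheet is translated only perpendicular to its propagation; the waist
    stays at a fixed propagation distance, so at field position ``s`` the
    detection-plane intersection is ``|s| sin(theta)`` beyond the waist.
``"lsm"``
    conventional orthogonal light sheet (theta = 90) with the waist parked at
    the field centre; the distance from the waist is ``|s|``.

The mode-dependent waist placement is derived from the explicit 3-D scan
trajectory in :mod:`lstmsim.scan` (single source of truth), not from the
closed forms quoted above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FWHM_TO_1E2",
    "SCAN_MODES",
    "LightSheet",
    "FieldResolutionProfile",
    "sheet_thickness_at",
    "detection_axial_fwhm",
    "field_resolution_profile",
]

#: Conversion from intensity FWHM to 1/e^2 half-width of a Gaussian beam.
FWHM_TO_1E2 = 1.0 / math.sqrt(2.0 * math.log(2.0))

SCAN_MODES = ("lsm", "1as", "2as")

#: Default emission wavelength, micrometres (eYFP/GFP band).
DEFAULT_EMISSION_UM = 0.52


@dataclass(frozen=True)
class LightSheet:
    """Gaussian light sheet.

    ``waist_thickness_fwhm`` is the actual intensity FWHM (micrometres) of
    the sheet at its most focused position, measured perpendicular to the
    propagation direction; ``sheet_width`` is the extent perpendicular to
    both the propagation and the thin axis.
    """

    waist_thickness_fwhm: float
    wavelength: float = 0.488
    medium_index: float = 1.454
    sheet_width: float = 1000.0

    def __post_init__(self) -> None:
        if not self.waist_thickness_fwhm > 0:
            raise ValueError("waist_thickness_fwhm must be > 0")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be > 0")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")

    @classmethod
    def from_effective_thickness(
        cls,
        effective_fwhm: float,
        theta: float,
        wavelength: float = 0.488,
        medium_index: float = 1.454,
        sheet_width: float = 1000.0,
    ) -> "LightSheet":
        """Build a sheet whose *axial* footprint at focus is ``effective_fwhm``.

        The instrument is usually specified by its effective thickness
        (``b / sin(theta)``, the number the microscope settings quote, e.g.
        "2 to 5 um effective light sheet thickness"); this inverts the
        projection for a given illumination angle ``theta`` in degrees
        (``theta = 90`` for orthogonal LSM leaves the value unchanged).
        """
        if not 0 < theta <= 90:
            raise ValueError("theta must lie in (0, 90] degrees")
        b = effective_fwhm * math.sin(math.radians(theta))
        return cls(b, wavelength, medium_index, sheet_width)

    @property
    def waist_radius(self) -> float:
        """1/e^2 intensity half-width at focus, micrometres."""
        return self.waist_thickness_fwhm * FWHM_TO_1E2

    @property
    def rayleigh_range(self) -> float:
        """Distance over which the thickness grows by sqrt(2), micrometres."""
        return math.pi * self.waist_radius**2 * self.medium_index / self.wavelength


@dataclass(frozen=True)
class FieldResolutionProfile:
    """Axial FWHM versus signed field position for one scan mode."""

    field_positions: np.ndarray
    axial_fwhm: np.ndarray
    mode: str
    failures: tuple = field(default=())

    def __post_init__(self) -> None:
        pos = np.asarray(self.field_positions, dtype=float)
        fwhm = np.asarray(self.axial_fwhm, dtype=float)
        if pos.shape != fwhm.shape:
            raise ValueError("field_positions and axial_fwhm must have equal length")
        if np.any(fwhm <= 0):
            raise ValueError("all FWHM values must be > 0")
        object.__setattr__(self, "field_positions", pos)
        object.__setattr__(self, "axial_fwhm", fwhm)


def sheet_thickness_at(sheet: LightSheet, distance_from_waist) -> np.ndarray | float:
    """Sheet intensity FWHM at a propagation distance from the waist (um)."""
    x = np.asarray(distance_from_waist, dtype=float)
    zr = sheet.rayleigh_range
    out = sheet.waist_thickness_fwhm * np.sqrt(1.0 + (x / zr) ** 2)
    return float(out) if out.ndim == 0 else out


def detection_axial_fwhm(na: float, medium_index: float, wavelength: float) -> float:
    """Wide-field axial FWHM approximation ``1.77 n lambda / NA^2`` (um).

    ``wavelength`` is the emission wavelength in micrometres.
    """
    if not 0 < na:
        raise ValueError("numerical aperture must be > 0")
    if na >= medium_index:
        raise ValueError("numerical aperture must be smaller than medium_index")
    return 1.77 * medium_index * wavelength / na**2


def field_resolution_profile(
    geometry,
    sheet: LightSheet,
    mode: str,
    fov: float,
    n_points: int = 201,
    emission_wavelength: float = DEFAULT_EMISSION_UM,
) -> FieldResolutionProfile:
    """Predicted axial FWHM across the field of view for one scan mode.

    For each field position ``s`` the distance ``d(s)`` between the sheet
    waist and the detection-plane intersection is taken from the 3-D scan
    trajectory (:func:`lstmsim.scan.scan_trajectory`); the local sheet
    thickness ``b(d)`` is projected onto the detection axis and combined with
    the detection axial response in quadrature:

    ``FWHM(s) = sqrt( (b(d(s)) / sin(theta))^2 + det_axial^2 )``

    with ``theta = 90`` for the orthogonal LSM mode.

    Parameters
    ----------
    geometry : ImagingGeometry
        Supplies ``theta``, the immersion index and the detection NA.
    fov : float
        Field-of-view extent in micrometres (positions span ``+-fov/2``).
    """
    from .scan import scan_trajectory, waist_centers, illumination_axes

    if mode not in SCAN_MODES:
        raise ValueError(f"unknown scan mode {mode!r}; expected one of {SCAN_MODES}")
    if not fov > 0:
        raise ValueError("fov must be > 0")

    traj = scan_trajectory(geometry, mode, fov, n_points)
    theta = 90.0 if mode == "lsm" else geometry.theta
    u_hat, _ = illumination_axes(theta)
    centers = waist_centers(traj)
    # detection-plane point for each row, and its offset from the waist
    pts = np.column_stack(
        [traj.row_positions, np.zeros(n_points), np.zeros(n_points)]
    )
    d = np.abs((pts - centers) @ u_hat)

    b_local = sheet_thickness_at(sheet, d)
    sin_t = math.sin(math.radians(theta))
    det = detection_axial_fwhm(
        geometry.detection.numerical_aperture,
        geometry.medium_index,
        emission_wavelength,
    )
    fwhm = np.sqrt((b_local / sin_t) ** 2 + det**2)
    return FieldResolutionProfile(traj.row_positions, fwhm, mode)
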