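"""Geometry of the oblique (theta) illumination-detection arrangement.

Light sheet theta microscopy (LSTM) places both illumination objectives on the
same side of the sample as the detection objective, at an angle ``theta < 90``
degrees to the detection axis.  This module provides the closed-form and
numerically solved geometry of that arrangement:

* the elongated working distance (EWD) of an air illumination objective whose
  marginal ray refracts into a higher-index immersion medium,
* the feasible range of angular separations, bounded below by objective-barrel
  collision and above by the illumination objective clearing the detection
  objective's working distance,
* the effective (axial) light-sheet thickness ``b / sin(theta)``,
* maximum illumination path lengths (MIPL) for LSTM (``t / cos(theta)``) and
  conventional orthogonal light sheet microscopy (LSM, sample width ``w``).

Angles are degrees at every public interface; radians are internal only.
Lengths follow the unit stated per field (millimetres for objective mechanics
and samples, micrometres for sheet thickness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import bisect

from .errors import InfeasibleGeometryError, UnsupportedConfigurationError

__all__ = [
    "ObjectiveSpec",
    "ImagingGeometry",
    "SampleBlock",
    "AngularRange",
    "elongated_working_distance",
    "angular_bounds",
    "effective_sheet_thickness",
    "mipl",
    "mipl_ratio_map",
]

#: Angular tolerance of the bound solver, in degrees.
ANGLE_TOL_DEG = 1e-6


@dataclass(frozen=True)
class ObjectiveSpec:
    """One objective's optical and mechanical parameters.

    Parameters
    ----------
    nominal_magnification
        Magnification printed on the barrel (for the reference tube lens).
    numerical_aperture
        NA; must satisfy ``0 < NA < design_medium_index``.
    working_distance
        Free working distance in millimetres, in the design medium.
    barrel_diameter
        Outer diameter of the objective barrel in millimetres.
    design_medium_index
        Refractive index of the medium the objective is designed for
        (1.0 for air objectives).
    """

    nominal_magnification: float
    numerical_aperture: float
    working_distance: float
    barrel_diameter: float
    design_medium_index: float = 1.0

    def __post_init__(self) -> None:
        if not self.numerical_aperture > 0:
            raise ValueError("numerical_aperture must be > 0")
        if not self.working_distance > 0:
            raise ValueError("working_distance must be > 0")
        if not self.barrel_diameter > 0:
            raise ValueError("barrel_diameter must be > 0")
        if not self.numerical_aperture < self.design_medium_index:
            raise ValueError(
                "numerical_aperture must be smaller than design_medium_index"
            )


@dataclass(frozen=True)
class ImagingGeometry:
    """Co-arrangement of the detection and illumination arms.

    ``theta`` is the angle (degrees) between the illumination propagation
    axis and the detection axis; ``medium_index`` is the refractive index of
    the immersion medium; ``wavelength`` is the excitation wavelength in
    micrometres.
    """

    detection: ObjectiveSpec
    illumination: ObjectiveSpec
    theta: float = 60.0
    medium_index: float = 1.454
    wavelength: float = 0.488

    def __post_init__(self) -> None:
        if not 0 < self.theta < 90:
            raise ValueError("theta must lie strictly between 0 and 90 degrees")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be > 0")


@dataclass(frozen=True)
class SampleBlock:
    """Cuboid sample: ``width`` (w, along LSM illumination), ``length``,
    and ``thickness`` (t, along the detection axis), all in millimetres."""

    width: float
    length: float
    thickness: float

    def __post_init__(self) -> None:
        for name in ("width", "length", "thickness"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class AngularRange:
    """Feasible angular separations: collision bound ``theta_lower`` and
    clearance bound ``theta_upper``, degrees."""

    theta_lower: float
    theta_upper: float

    def __post_init__(self) -> None:
        if not 0 < self.theta_lower < self.theta_upper < 90:
            raise ValueError(
                "require 0 < theta_lower < theta_upper < 90 degrees, got "
                f"({self.theta_lower}, {self.theta_upper})"
            )


def elongated_working_distance(objective: ObjectiveSpec, medium_index: float) -> float:
    """Working distance of an air objective refracted into an immersion medium.

    The limiting aperture (marginal) ray leaves the front lens at the angle
    ``asin(NA)`` in air and refracts at a flat interface into the medium at
    ``asin(NA / n)``; the focus where it crosses the axis sits at

    ``EWD = WD * tan(asin(NA)) / tan(asin(NA / n))``

    millimetres from the objective.  For ``n = 1`` this is the identity, and
    in the paraxial limit (NA -> 0) it reduces to ``WD * n``.

    Raises
    ------
    UnsupportedConfigurationError
        If the objective is not an air objective.
    ValueError
        If ``NA >= medium_index`` (the marginal ray cannot refract).
    """
    if objective.design_medium_index != 1.0:
        raise UnsupportedConfigurationError(
            "elongated_working_distance models an air objective dipped into an "
            f"immersion medium; got design_medium_index="
            f"{objective.design_medium_index}"
        )
    if medium_index < 1:
        raise ValueError("medium_index must be >= 1")
    na = objective.numerical_aperture
    if na >= medium_index:
        raise ValueError("numerical_aperture must be smaller than medium_index")
    if medium_index == 1.0:
        return objective.working_distance
    air = math.tan(math.asin(na))
    medium = math.tan(math.asin(na / medium_index))
    return objective.working_distance * air / medium


def _illumination_wd_in_medium(geometry: ImagingGeometry) -> float:
    """Illumination working distance expressed in the immersion medium."""
    ill = geometry.illumination
    if ill.design_medium_index == 1.0 and geometry.medium_index > 1.0:
        return elongated_working_distance(ill, geometry.medium_index)
    return ill.working_distance


def angular_bounds(geometry: ImagingGeometry) -> AngularRange:
    """Feasible angular range of the illumination arm.

    The lower bound ``theta_i`` is where the illumination barrel touches the
    detection barrel, ``W2 sin(theta) = D1/2 + (D2/2) cos(theta)``; the upper
    bound ``theta_f`` is where the illumination objective reaches the
    detection working-distance plane, ``W2 cos(theta) = W1 + (D2/2)
    sin(theta)``.  ``W1``/``D1`` are the detection working distance and
    barrel diameter, ``W2``/``D2`` the illumination ones, with ``W2``
    elongated into the immersion medium when the illumination objective is an
    air objective.

    Both equations are solved by bisection on (0, 90) degrees to
    ``ANGLE_TOL_DEG``.

    Raises
    ------
    InfeasibleGeometryError
        If either equation has no root in (0, 90) degrees; the message names
        the failing bound.
    """
    w1 = geometry.detection.working_distance
    d1 = geometry.detection.barrel_diameter
    w2 = _illumination_wd_in_medium(geometry)
    d2 = geometry.illumination.barrel_diameter

    def collision(theta_deg: float) -> float:
        t = math.radians(theta_deg)
        return w2 * math.sin(t) - d1 / 2.0 - (d2 / 2.0) * math.cos(t)

    def clearance(theta_deg: float) -> float:
        t = math.radians(theta_deg)
        return w2 * math.cos(t) - w1 - (d2 / 2.0) * math.sin(t)

    lower = _solve_bound(collision, "collision (lower)")
    upper = _solve_bound(clearance, "clearance (upper)")
    try:
        return AngularRange(theta_lower=lower, theta_upper=upper)
    except ValueError as exc:  # bounds cross: no usable range
        raise InfeasibleGeometryError(str(exc)) from exc


def _solve_bound(residual, label: str) -> float:
    lo, hi = residual(0.0), residual(90.0)
    if lo == 0.0:
        return 0.0
    if hi == 0.0:
        return 90.0
    if lo * hi > 0:
        raise InfeasibleGeometryError(
            f"the {label} bound equation has no root for theta in (0, 90) degrees"
        )
    return float(bisect(residual, 0.0, 90.0, xtol=ANGLE_TOL_DEG))


def effective_sheet_thickness(b: float, theta: float) -> float:
    """Axial projection of the sheet thickness: ``b / sin(theta)``.

    ``b`` is the actual (perpendicular-to-propagation) light sheet thickness
    in micrometres and ``theta`` the illumination angle in degrees; at
    ``theta = 90`` (orthogonal LSM) the projection is the identity.
    """
    if not 0 < theta <= 90:
        raise ValueError("theta must lie in (0, 90] degrees")
    if not b > 0:
        raise ValueError("sheet thickness b must be > 0")
    return b / math.sin(math.radians(theta))


def mipl(
    sample: SampleBlock,
    theta: float,
    mode: Literal["lstm", "lsm"] = "lstm",
    two_sided: bool = False,
) -> float:
    """Maximum illumination path length inside the tissue, millimetres.

    In LSTM the sheet enters through the imaged surface and must traverse the
    full thickness obliquely: ``t / cos(theta)``.  In LSM it must cross the
    sample width ``w`` (or ``w / 2`` with two-sided illumination).  Corner
    wedges are ignored; the value is for the bulk slab.
    """
    mode = mode.lower()
    if mode == "lstm":
        if not 0 <= theta < 90:
            raise ValueError("LSTM mode requires 0 <= theta < 90 degrees")
        return sample.thickness / math.cos(math.radians(theta))
    if mode == "lsm":
        return sample.width / 2.0 if two_sided else sample.width
    raise ValueError(f"unknown mode {mode!r}; expected 'lstm' or 'lsm'")


def mipl_ratio_map(
    widths: Sequence[float],
    thicknesses: Sequence[float],
    theta: float,
    two_sided: bool = False,
) -> np.ndarray:
    """Binary map of where LSTM needs the shorter illumination path.

    Returns a boolean array of shape ``(len(thicknesses), len(widths))`` that
    is ``True`` where ``t / cos(theta) < w`` (strictly; the boundary belongs
    to the equal-or-LSM-favoured class), i.e. where the oblique geometry
    penetrates less tissue than an orthogonal sheet would.
    """
    w = np.asarray(widths, dtype=float)
    t = np.asarray(thicknesses, dtype=float)
    if w.size == 0 or t.size == 0:
        raise ValueError("widths and thicknesses must be non-empty")
    if np.any(w <= 0) or np.any(t <= 0):
        raise ValueError("all sample dimensions must be > 0")
    if not 0 <= theta < 90:
        raise ValueError("theta must lie in [0, 90) degrees")
    lstm = t[:, None] / math.cos(math.radians(theta))
    lsm = (w / 2.0 if two_sided else w)[None, :]
    # strict inequality with a relative guard so analytic boundary points
    # (w = t / cos(theta)) land in the equal-or-LSM-favoured class despite
    # floating-point rounding of the cosine
    return lstm < lsm * (1.0 - 1e-12)
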