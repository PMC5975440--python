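"""Synchronized line-illumination / rolling-shutter acquisition simulator.

Coordinate convention (fixed throughout the package): ``z`` is the detection
axis with the detection focal plane at ``z = 0``; the rolling shutter scans
along ``x``; the illumination propagation unit vector is
``u = (sin(theta), 0, cos(theta))`` and the sheet's thin axis is
``v = (cos(theta), 0, -sin(theta))``.  Physical positions are voxel centres;
voxel indices are 0-based ``(z, y, x)``.

To place the sheet's thinnest line at detection-plane position ``s`` the
displacement ``s x`` is decomposed into the propagation direction and its
in-plane perpendicular, giving the galvo (perpendicular) offset
``g(s) = s cos(theta)`` and the tunable-lens (along-propagation) offset
``e(s) = s sin(theta)``.  The 1-axis mode keeps ``e = 0`` (the waist stays
parked along the propagation axis); the orthogonal LSM mode keeps a static
sheet with its waist at the field centre and ``theta = 90``.

The camera's rolling shutter exposes a band of rows (the "virtual slit")
synchronized with the illumination line; only rows whose band is open while
the line is at ``s`` collect light, which gives confocal-line rejection of
out-of-row illumination.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np

from .beam import (
    DEFAULT_EMISSION_UM,
    SCAN_MODES,
    LightSheet,
    detection_axial_fwhm,
    sheet_thickness_at,
)
from .errors import MeasurementError

__all__ = [
    "CameraSpec",
    "ScanTrajectory",
    "ImageStack",
    "SlitWidths",
    "illumination_axes",
    "waist_centers",
    "rolling_shutter_slit",
    "scan_trajectory",
    "simulate_acquisition",
    "measure_axial_fwhm",
    "fwhm_field_report",
]

_4LN2 = 4.0 * math.log(2.0)

#: Lateral detection FWHM approximation factor (Rayleigh-like): 0.51 lambda / NA.
LATERAL_FWHM_FACTOR = 0.51


@dataclass(frozen=True)
class CameraSpec:
    """sCMOS camera parameters.

    Defaults match a 2048 x 2048, 6.5 um pitch sensor with a 20 ms
    one-direction rolling-shutter full-frame readout at 16 bits.
    ``bidirectional`` flags the split readout mode (10 ms full frame, the two
    halves read toward the centre); it is carried as configuration but the
    simulator always models the one-direction sweep.
    """

    rows: int = 2048
    cols: int = 2048
    pixel_pitch: float = 6.5
    full_frame_time: float = 20.0
    bit_depth: int = 16
    bidirectional: bool = False

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("rows and cols must be > 0")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be > 0")
        if not self.full_frame_time > 0:
            raise ValueError("full_frame_time must be > 0")


@dataclass(frozen=True)
class ScanTrajectory:
    """Per-row sheet placement for one scan mode.

    ``row_positions`` are detection-plane coordinates (um) of each shutter
    row; ``galvo_offsets`` translate the sheet perpendicular to propagation
    and ``etl_offsets`` translate the waist along propagation.
    """

    row_positions: np.ndarray
    galvo_offsets: np.ndarray
    etl_offsets: np.ndarray
    mode: str
    theta: float

    def __post_init__(self) -> None:
        r = np.asarray(self.row_positions, dtype=float)
        g = np.asarray(self.galvo_offsets, dtype=float)
        e = np.asarray(self.etl_offsets, dtype=float)
        if not (r.shape == g.shape == e.shape):
            raise ValueError("row/galvo/etl arrays must have equal length")
        if self.mode == "1as" and np.any(e != 0):
            raise ValueError("1-axis scanning keeps all etl_offsets at 0")
        object.__setattr__(self, "row_positions", r)
        object.__setattr__(self, "galvo_offsets", g)
        object.__setattr__(self, "etl_offsets", e)


@dataclass
class ImageStack:
    """3-D intensity grid ``(z, y, x)`` with voxel size metadata (um)."""

    intensities: np.ndarray
    voxel_size: tuple
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError("intensities must be a 3-D (z, y, x) array")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive numbers (z, y, x)")
        self.intensities = arr
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical centre coordinates along one axis (0=z, 1=y, 2=x), um."""
        n = self.intensities.shape[axis]
        v = self.voxel_size[axis]
        return (np.arange(n) - (n - 1) / 2.0) * v


SlitWidths = namedtuple("SlitWidths", ["sensor_width", "sample_width"])


def illumination_axes(theta: float):
    """Unit vectors ``(u, v)``: propagation and thin-axis directions."""
    t = math.radians(theta)
    u_hat = np.array([math.sin(t), 0.0, math.cos(t)])
    v_hat = np.array([math.cos(t), 0.0, -math.sin(t)])
    return u_hat, v_hat


def waist_centers(traj: ScanTrajectory) -> np.ndarray:
    """3-D waist-line centres per row: ``c(s) = g(s) v + e(s) u``."""
    u_hat, v_hat = illumination_axes(traj.theta)
    return np.outer(traj.galvo_offsets, v_hat) + np.outer(traj.etl_offsets, u_hat)


def rolling_shutter_slit(
    exposure: float, camera: CameraSpec, magnification: float
) -> SlitWidths:
    """Virtual-slit width for a rolling-shutter exposure.

    The band of simultaneously open rows spans
    ``(exposure / full_frame_time) * rows * pixel_pitch`` micrometres on the
    sensor and that divided by the magnification on the sample.
    """
    if not exposure > 0:
        raise ValueError("exposure must be > 0")
    if exposure > camera.full_frame_time:
        raise ValueError(
            "exposure exceeds the full-frame readout time "
            f"({camera.full_frame_time} ms); the shutter is then simply fully open"
        )
    if not magnification > 0:
        raise ValueError("magnification must be > 0")
    sensor = (exposure / camera.full_frame_time) * camera.rows * camera.pixel_pitch
    return SlitWidths(sensor_width=sensor, sample_width=sensor / magnification)


def scan_trajectory(
    geometry, mode: str, fov: float, n_rows: int
) -> ScanTrajectory:
    """Sheet placement per shutter row for a scan mode.

    ``fov`` is the detection-plane extent in micrometres; rows are placed at
    ``n_rows`` evenly spaced positions spanning ``+-fov/2``.
    """
    if mode not in SCAN_MODES:
        raise ValueError(f"unknown scan mode {mode!r}; expected one of {SCAN_MODES}")
    if n_rows < 2:
        raise ValueError("n_rows must be >= 2")
    s = np.linspace(-fov / 2.0, fov / 2.0, n_rows)
    if mode == "lsm":
        theta = 90.0
        g = np.zeros_like(s)
        e = np.zeros_like(s)
    else:
        theta = geometry.theta
        t = math.radians(theta)
        g = s * math.cos(t)
        e = s * math.sin(t) if mode == "2as" else np.zeros_like(s)
    return ScanTrajectory(s, g, e, mode, theta)


def simulate_acquisition(
    phantom,
    geometry,
    sheet: LightSheet,
    camera: CameraSpec,
    mode: str,
    exposure: float,
    z_step: float,
    *,
    lateral_voxel: float = 0.5,
    fov: float | None = None,
    z_extent: float | None = None,
    magnification: float | None = None,
    emission_wavelength: float = DEFAULT_EMISSION_UM,
    shutter_window: tuple | None = None,
    noise_photons: float | None = None,
    seed: int | None = None,
) -> ImageStack:
    """Render a synthetic bead/structure stack for one scan mode.

    Image formation per z-plane and per shutter row: the Gaussian sheet
    (local thickness from :func:`lstmsim.beam.sheet_thickness_at` at the
    emitter's along-propagation distance from the current waist line, waist
    placement from :func:`scan_trajectory`) excites each emitter; the
    detected image is the excited emission blurred by a separable Gaussian
    detection PSF (lateral FWHM ``0.51 lambda / NA``, axial FWHM from
    :func:`lstmsim.beam.detection_axial_fwhm`), summed over the open-shutter
    rows only.  Emitters are rendered as Gaussian blobs of the phantom's bead
    diameter, with the illumination sampled at the bead centre; the axial
    detection response is folded into the per-row sheet profile by
    convolution (quadrature of Gaussian widths), matching the axial model of
    :func:`lstmsim.beam.field_resolution_profile`.

    Deterministic for a given phantom; optional Poisson noise
    (``noise_photons`` = photon count at unit intensity) is seeded.

    Parameters beyond the spec'd core: ``lateral_voxel`` (um) sets the x/y
    sampling, ``fov``/``z_extent`` restrict the rendered extent (defaults:
    the phantom extent), ``shutter_window`` overrides the symmetric slit with
    an explicit half-open offset interval ``(lo, hi)`` in sample micrometres
    relative to the row being read.
    """
    if mode not in SCAN_MODES:
        raise ValueError(f"unknown scan mode {mode!r}; expected one of {SCAN_MODES}")
    if not z_step > 0 or not lateral_voxel > 0:
        raise ValueError("z_step and lateral_voxel must be > 0")

    ext_x, ext_y, ext_z = (float(v) for v in phantom.volume_extent)
    fov = ext_x if fov is None else float(fov)
    z_extent = ext_z if z_extent is None else float(z_extent)
    if fov > ext_x + 1e-9 or z_extent > ext_z + 1e-9:
        raise ValueError(
            "phantom volume does not cover the requested field/z-range: need "
            f"extent >= ({fov}, *, {z_extent}) um, phantom provides "
            f"({ext_x}, {ext_y}, {ext_z}) um"
        )

    if magnification is None:
        # 200 mm tube lens with a 180 mm reference objective, as on the instrument
        magnification = geometry.detection.nominal_magnification * 200.0 / 180.0

    nx = max(2, int(round(fov / lateral_voxel)))
    ny = max(1, int(round(ext_y / lateral_voxel)))
    nz = max(1, int(round(z_extent / z_step)))
    xs = (np.arange(nx) - (nx - 1) / 2.0) * lateral_voxel
    ys = (np.arange(ny) - (ny - 1) / 2.0) * lateral_voxel
    zs = (np.arange(nz) - (nz - 1) / 2.0) * z_step

    traj = scan_trajectory(geometry, mode, fov=xs[-1] - xs[0], n_rows=nx)
    theta = traj.theta
    sin_t = math.sin(math.radians(theta))
    cos_t = math.cos(math.radians(theta))
    centers = waist_centers(traj)  # (nx, 3); rows coincide with x voxel centres

    if shutter_window is None:
        half = rolling_shutter_slit(exposure, camera, magnification).sample_width / 2.0
        lo, hi = -half, half
    else:
        lo, hi = (float(v) for v in shutter_window)
        if not hi > lo:
            raise ValueError("shutter_window must be an increasing (lo, hi) pair")
    # half-open [lo, hi) row-offset interval in voxel units
    o_min = int(np.ceil(lo / lateral_voxel - 1e-9))
    o_max = int(np.ceil(hi / lateral_voxel - 1e-9))
    o_max = max(o_max, o_min + 1)  # at least the synchronized row itself

    det_ax = detection_axial_fwhm(
        geometry.detection.numerical_aperture, geometry.medium_index,
        emission_wavelength,
    )
    lat = LATERAL_FWHM_FACTOR * emission_wavelength / (
        geometry.detection.numerical_aperture
    )
    bead = float(getattr(phantom, "bead_diameter", 0.0))
    lat_fwhm2 = lat**2 + bead**2
    # detection axial + bead blur folded into the sheet profile, expressed in
    # the sheet's thin-axis coordinate (z widths scale by sin(theta))
    extra2 = (det_ax * sin_t) ** 2 + (bead * sin_t) ** 2

    stack = np.zeros((nz, ny, nx))
    positions = np.asarray(phantom.emitter_positions, dtype=float).reshape(-1, 3)
    amplitudes = np.asarray(phantom.emitter_amplitudes, dtype=float).reshape(-1)

    for (ex, ey, ez), amp in zip(positions, amplitudes):
        dx = ex - centers[:, 0]                      # (nx,) per row
        dz0 = ez - centers[:, 2]
        dz = dz0[None, :] - zs[:, None]              # (nz, nx): r_z per plane/row
        delta = dx[None, :] * cos_t - dz * sin_t     # thin-axis offset
        along = dx[None, :] * sin_t + dz * cos_t     # propagation distance
        width2 = sheet_thickness_at(sheet, along) ** 2 + extra2
        k = np.exp(-_4LN2 * delta**2 / width2)
        # gate: sum K over rows s with row-offset in [o_min, o_max)
        csum = np.concatenate(
            [np.zeros((nz, 1)), np.cumsum(k, axis=1)], axis=1
        )
        idx = np.arange(nx)
        lo_i = np.clip(idx + o_min, 0, nx)
        hi_i = np.clip(idx + o_max, 0, nx)
        gated = csum[:, hi_i] - csum[:, lo_i]        # (nz, nx)

        gx = np.exp(-_4LN2 * (xs - ex) ** 2 / lat_fwhm2)
        gy = np.exp(-_4LN2 * (ys - ey) ** 2 / lat_fwhm2)
        stack += amp * np.einsum("kx,y->kyx", gated * gx[None, :], gy)

    if noise_photons is not None:
        rng = np.random.default_rng(0 if seed is None else seed)
        stack = rng.poisson(np.clip(stack, 0, None) * noise_photons) / noise_photons

    meta = {
        "mode": mode,
        "theta": theta,
        "exposure_ms": exposure,
        "z_step_um": z_step,
        "lateral_voxel_um": lateral_voxel,
        "magnification": magnification,
        "emission_wavelength_um": emission_wavelength,
        "seed": seed,
    }
    return ImageStack(stack, (z_step, lateral_voxel, lateral_voxel), meta)


def _interp_crossing(z: np.ndarray, p: np.ndarray, i0: int, i1: int, level: float):
    """Linear interpolation of the position where p crosses `level`."""
    p0, p1 = p[i0], p[i1]
    if p1 == p0:
        return z[i0]
    frac = (level - p0) / (p1 - p0)
    return z[i0] + frac * (z[i1] - z[i0])


def measure_axial_fwhm(stack: ImageStack, bead_location) -> float:
    """Axial FWHM (um) of a bead from its axial line intensity profile.

    Extracts the z line profile through the bead's intensity maximum
    (location refined within a small lateral neighbourhood), subtracts the
    background estimated as the median of the profile tails, and measures
    the separation of the two half-maximum crossings found by linear
    interpolation.

    Raises
    ------
    MeasurementError
        If the profile has no half-maximum crossing on both sides
        (flat/saturated profile or bead at the stack boundary).
    """
    arr = stack.intensities
    nz, ny, nx = arr.shape
    _, yy, xx = (int(v) for v in bead_location)
    if not (0 <= yy < ny and 0 <= xx < nx):
        raise ValueError("bead_location outside stack bounds")
    r = 2
    sub = arr[:, max(0, yy - r): yy + r + 1, max(0, xx - r): xx + r + 1]
    k0, j0, i0 = np.unravel_index(int(np.argmax(sub)), sub.shape)
    yy = max(0, yy - r) + j0
    xx = max(0, xx - r) + i0

    profile = arr[:, yy, xx].astype(float)
    ntail = max(1, nz // 10)
    background = float(np.median(np.concatenate([profile[:ntail], profile[-ntail:]])))
    peak_idx = int(np.argmax(profile))
    peak = profile[peak_idx]
    if peak <= background:
        raise MeasurementError("flat axial profile: no peak above background")
    half = background + (peak - background) / 2.0

    zs = stack.axis_coordinates(0)
    left = None
    for i in range(peak_idx, 0, -1):
        if profile[i - 1] <= half <= profile[i]:
            left = _interp_crossing(zs, profile, i - 1, i, half)
            break
    right = None
    for i in range(peak_idx, nz - 1):
        if profile[i + 1] <= half <= profile[i]:
            right = _interp_crossing(zs, profile, i + 1, i, half)
            break
    if left is None or right is None:
        raise MeasurementError(
            "no half-maximum crossing on "
            + ("both sides" if left is None and right is None
               else "the left side" if left is None else "the right side")
            + " of the peak; profile truncated or saturated"
        )
    return float(right - left)


def fwhm_field_report(stack: ImageStack, bead_locations):
    """Per-bead axial FWHM keyed by field position, sorted by position.

    Measurement failures are collected per bead and reported alongside the
    partial results in ``FieldResolutionProfile.failures``.
    """
    from .beam import FieldResolutionProfile

    if len(bead_locations) < 1:
        raise ValueError("at least one bead location is required")
    xs = stack.axis_coordinates(2)
    results = []
    failures = []
    for loc in bead_locations:
        pos = float(xs[int(loc[2])])
        try:
            results.append((pos, measure_axial_fwhm(stack, loc)))
        except MeasurementError as exc:
            failures.append((tuple(int(v) for v in loc), str(exc)))
    if not results:
        raise MeasurementError(
            "every bead measurement failed: "
            + "; ".join(msg for _, msg in failures)
        )
    results.sort(key=lambda t: t[0])
    positions = np.array([p for p, _ in results])
    fwhm = np.array([f for _, f in results])
    mode = stack.metadata.get("mode", "unknown")
    return FieldResolutionProfile(positions, fwhm, mode, failures=tuple(failures))
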