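"""Total illumination energy load: LSTM voxel accumulation vs analytic LSM.

The oblique geometry re-illuminates out-of-plane tissue on every plane it
images, so the photobleaching burden is assessed by counting, per voxel, how
many sheet exposures it receives over a whole acquisition.

LSTM is simulated by step-wise scanning of the sample through the oblique
sheet: for every imaged plane and every sheet position, each voxel whose
centre lies inside the oblique slab (thickness = the sheet step, oriented at
``theta`` to the detection axis, extending until it leaves the sample volume)
is incremented by one.  The orthogonal-LSM counterpart is analytic: in a row
of tiles along the sample width each voxel is illuminated ``w / f`` times
(``f`` = detection field-of-view size), so the total is ``(w / f) * N``.
The per-line dwell time is identical in both (scanned-sheet implementation),
so the constant factor cancels from the ratio.

Only one row of tiles along the width is simulated; the sample length enters
as a trivially cancelling factor, so the accumulation grid is one voxel deep
along the length axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .optics import SampleBlock

__all__ = [
    "EnergyGrid",
    "EnergyRatioSurface",
    "BleachingTrend",
    "lstm_energy_simulation",
    "lsm_energy_total",
    "energy_ratio_surface",
    "bleaching_trend",
]


@dataclass
class EnergyGrid:
    """Per-voxel accumulated illumination counts, shape ``(nz, 1, nx)``."""

    counts: np.ndarray
    voxel_size: float
    total: int = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 3:
            raise ValueError("counts must be a 3-D (z, y, x) array")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        self.counts = arr
        self.total = int(arr.sum())


@dataclass(frozen=True)
class EnergyRatioSurface:
    """LSTM/LSM total-energy ratios over a (thickness, width) grid."""

    widths: np.ndarray
    thicknesses: np.ndarray
    ratios: np.ndarray  # shape (len(thicknesses), len(widths))
    theta: float
    fov: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.ratios) <= 0):
            raise ValueError("ratios must be > 0")

    def to_frame(self):
        """Long-format (width, thickness, ratio) table."""
        import pandas as pd

        w, t = np.meshgrid(self.widths, self.thicknesses)
        return pd.DataFrame(
            {"width_mm": w.ravel(), "thickness_mm": t.ravel(),
             "ratio": np.asarray(self.ratios).ravel()}
        )


BOUNDARY_EPS = 1e-9  # inclusive slab boundary, robust to rounding


def lstm_energy_simulation(
    sample: SampleBlock,
    theta: float,
    fov: float,
    sheet_step: float | None = None,
    voxel: float | None = None,
) -> EnergyGrid:
    """Accumulate per-voxel illumination counts for an LSTM acquisition.

    The sample cross-section (width ``w`` along x, thickness ``t`` along z)
    is discretized at ``voxel`` millimetres (default ``fov / 100``).  Imaged
    planes are spaced one voxel apart through the thickness; per plane, sheet
    positions step along the width by ``sheet_step`` (default ``voxel``,
    i.e. non-overlapping sheets at the imaged plane).  A voxel is counted for
    a (plane, position) pair when its centre lies within ``sheet_step / 2``
    of the oblique sheet mid-plane.  Tiling along the width does not alter
    the counts (the union of the per-tile sweeps covers the width exactly
    once per plane), so ``fov`` only matters for the LSM comparison.

    ``theta`` may be negative (mirrored arm); ``|theta| < 90`` degrees.
    """
    if not abs(theta) < 90:
        raise ValueError("theta must satisfy |theta| < 90 degrees")
    if voxel is None:
        voxel = fov / 100.0
    if sheet_step is None:
        sheet_step = voxel
    if not 0 < voxel <= sheet_step:
        raise ValueError("require 0 < voxel <= sheet_step")

    if sample.width < voxel or sample.thickness < voxel:
        raise ValueError("sample is smaller than one voxel")
    nx = math.ceil(sample.width / voxel - BOUNDARY_EPS)
    nz = math.ceil(sample.thickness / voxel - BOUNDARY_EPS)

    t_rad = math.radians(theta)
    sin_t, cos_t = math.sin(t_rad), math.cos(t_rad)
    half = sheet_step / 2.0
    eps = BOUNDARY_EPS * voxel

    xs = (np.arange(nx) + 0.5) * voxel               # voxel centres
    planes = (np.arange(nz) + 0.5) * voxel           # imaged plane depths
    n_steps = math.ceil(sample.width / sheet_step - BOUNDARY_EPS)
    steps = (np.arange(n_steps) + 0.5) * sheet_step  # sheet positions

    counts = np.zeros((nz, nx), dtype=np.int64)
    diff = np.zeros((nz + 1, nx), dtype=np.int64)

    if abs(sin_t) < 1e-12:
        # head-on illumination: the slab is a full-depth column |x - s| <= half
        for s in steps:
            cols = np.abs(xs - s) <= half + eps
            counts[:, cols] += nz  # every plane illuminates the same column
        return EnergyGrid(counts[:, None, :], voxel)

    # |(x - s) cos - (z - zp) sin| <= half  =>  z in an interval per column
    for zp in planes:
        for s in steps:
            # columns whose interval can intersect the sample depth
            proj = (xs - s) * cos_t
            lo = zp + (proj - half) / sin_t
            hi = zp + (proj + half) / sin_t
            lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
            k_lo = np.ceil(lo / voxel - 0.5 - BOUNDARY_EPS).astype(int)
            k_hi = np.floor(hi / voxel - 0.5 + BOUNDARY_EPS).astype(int)
            k_lo = np.clip(k_lo, 0, nz)
            k_hi = np.clip(k_hi, -1, nz - 1)
            valid = k_hi >= k_lo
            cols = np.nonzero(valid)[0]
            np.add.at(diff, (k_lo[cols], cols), 1)
            np.add.at(diff, (k_hi[cols] + 1, cols), -1)
    counts += np.cumsum(diff[:-1], axis=0)
    return EnergyGrid(counts[:, None, :], voxel)


def lsm_energy_total(
    sample: SampleBlock,
    fov: float,
    voxel: float,
    integer_tiles: bool = False,
) -> float:
    """Analytic LSM total: each voxel is illuminated ``w / f`` times.

    Fractional tile counts are the default (the stated approximation);
    ``integer_tiles`` rounds the tile count up instead.  The voxel grid uses
    the same round-up rule as the LSTM simulation so totals are comparable.
    """
    if not fov > 0:
        raise ValueError("fov must be > 0")
    nx = math.ceil(sample.width / voxel - BOUNDARY_EPS)
    nz = math.ceil(sample.thickness / voxel - BOUNDARY_EPS)
    n_voxels = nx * nz
    tiles = sample.width / fov
    if integer_tiles:
        tiles = math.ceil(tiles - BOUNDARY_EPS)
    return tiles * n_voxels


def energy_ratio_surface(
    widths,
    thicknesses,
    theta: float,
    fov: float,
    sheet_step: float | None = None,
    voxel: float | None = None,
    length: float = 1.0,
) -> EnergyRatioSurface:
    """LSTM/LSM total-energy ratio over a grid of sample dimensions."""
    widths = np.asarray(widths, dtype=float)
    thicknesses = np.asarray(thicknesses, dtype=float)
    if widths.size == 0 or thicknesses.size == 0:
        raise ValueError("widths and thicknesses must be non-empty")
    if voxel is None:
        voxel = fov / 100.0
    ratios = np.empty((thicknesses.size, widths.size))
    for i, t in enumerate(thicknesses):
        for j, w in enumerate(widths):
            sample = SampleBlock(width=w, length=length, thickness=t)
            lstm = lstm_energy_simulation(sample, theta, fov, sheet_step, voxel)
            lsm = lsm_energy_total(sample, fov, voxel)
            ratios[i, j] = lstm.total / lsm
    return EnergyRatioSurface(widths, thicknesses, ratios, theta, fov)


@dataclass(frozen=True)
class BleachingTrend:
    """Least-squares slope and Kendall rank statistic of tile means."""

    slope: float
    kendall_tau: float


def bleaching_trend(tile_mean_signals) -> BleachingTrend:
    """Photobleaching trend over tiles in acquisition order.

    Returns the least-squares slope of mean tile signal versus acquisition
    index together with the Kendall rank correlation; interpretation (e.g.
    "no significant trend") is left to the caller.
    """
    y = np.asarray(tile_mean_signals, dtype=float)
    if y.size < 3:
        raise ValueError("at least 3 tiles are required for a trend estimate")
    x = np.arange(y.size, dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    if np.all(y == y[0]):
        tau = 0.0  # constant series: no concordant or discordant pairs
    else:
        tau = float(stats.kendalltau(x, y).statistic)
        if math.isnan(tau):
            tau = 0.0
    return BleachingTrend(slope=slope, kendall_tau=tau)
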