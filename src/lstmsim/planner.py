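"""Deterministic acquisition arithmetic: magnification, sampling, tiling,
frame counts and raw data volume for large-sample acquisitions.

All byte figures use decimal (SI) units: 1 GB = 10^9 bytes, 1 TB = 10^12
bytes, which is how acquisition software reports raw-data sizes and the only
convention consistent with published frame-count/volume pairs for a
2048 x 2048 x 16-bit sensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .optics import SampleBlock
from .scan import CameraSpec

__all__ = [
    "AcquisitionPlan",
    "effective_magnification",
    "pixel_sampling",
    "fov_extent",
    "plan_tiles",
    "data_volume",
    "format_bytes",
]

GB = 1e9
TB = 1e12


@dataclass(frozen=True)
class AcquisitionPlan:
    """Tile/plane bookkeeping for a single-channel acquisition."""

    tiles_x: int
    tiles_y: int
    z_planes: int
    total_frames: int
    frame_bytes: int
    total_bytes: int
    pixel_sampling: float  # micrometres
    fov: float  # millimetres

    def __post_init__(self) -> None:
        if self.total_frames != self.tiles_x * self.tiles_y * self.z_planes:
            raise ValueError("total_frames must equal tiles_x * tiles_y * z_planes")
        if self.total_bytes != self.total_frames * self.frame_bytes:
            raise ValueError("total_bytes must equal total_frames * frame_bytes")


def effective_magnification(
    nominal: float,
    tube_focal_length: float,
    reference_tube_focal_length: float = 180.0,
) -> float:
    """Magnification with a non-reference tube lens: ``nominal * f / f_ref``.

    E.g. a 10x objective designed for a 180 mm tube lens used with a 200 mm
    tube lens gives 11.11x.
    """
    if nominal <= 0 or tube_focal_length <= 0 or reference_tube_focal_length <= 0:
        raise ValueError("all focal lengths and the magnification must be > 0")
    return nominal * tube_focal_length / reference_tube_focal_length


def pixel_sampling(camera: CameraSpec, magnification: float) -> float:
    """Object-space pixel size, micrometres: ``pixel_pitch / M``."""
    if not magnification > 0:
        raise ValueError("magnification must be > 0")
    return camera.pixel_pitch / magnification


def fov_extent(camera: CameraSpec, magnification: float) -> float:
    """Detection field of view across the sensor columns, millimetres."""
    if not magnification > 0:
        raise ValueError("magnification must be > 0")
    return camera.cols * camera.pixel_pitch / magnification / 1000.0


def plan_tiles(
    sample: SampleBlock,
    fov: float,
    overlap_fraction: float = 0.1,
    z_step: float = 5.0,
    camera: CameraSpec | None = None,
    channels: int = 1,
) -> AcquisitionPlan:
    """Tile and z-plane counts to cover a sample block.

    Tiles per axis are ``ceil(extent / (fov * (1 - overlap)))`` with ``fov``
    in millimetres; z planes are ``ceil(thickness_um / z_step_um)``.
    ``channels`` multiplies the frame total.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    if not z_step > 0:
        raise ValueError("z_step must be > 0")
    if camera is None:
        camera = CameraSpec()
    sampling = fov * 1000.0 / camera.cols  # um per pixel implied by the FOV
    if sample.width < sampling / 1000.0 or sample.length < sampling / 1000.0:
        raise ValueError("sample is smaller than a single pixel")
    pitch = fov * (1.0 - overlap_fraction)
    tiles_x = math.ceil(sample.width / pitch)
    tiles_y = math.ceil(sample.length / pitch)
    z_planes = math.ceil(sample.thickness * 1000.0 / z_step)
    total_frames = tiles_x * tiles_y * z_planes * channels
    frame_bytes = camera.rows * camera.cols * camera.bit_depth // 8
    return AcquisitionPlan(
        tiles_x=tiles_x,
        tiles_y=tiles_y,
        z_planes=z_planes,
        total_frames=total_frames,
        frame_bytes=frame_bytes,
        total_bytes=total_frames * frame_bytes,
        pixel_sampling=sampling,
        fov=fov,
    )


def data_volume(total_frames: int, camera: CameraSpec | None = None) -> int:
    """Raw data volume in bytes: ``frames * rows * cols * bit_depth / 8``."""
    if total_frames < 0:
        raise ValueError("total_frames must be >= 0")
    if camera is None:
        camera = CameraSpec()
    return total_frames * camera.rows * camera.cols * camera.bit_depth // 8


def format_bytes(n_bytes: float) -> str:
    """Human-readable decimal-unit size string (GB/TB)."""
    if n_bytes >= TB:
        return f"{n_bytes / TB:.2f} TB"
    if n_bytes >= GB:
        return f"{n_bytes / GB:.2f} GB"
    return f"{n_bytes / 1e6:.2f} MB"
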