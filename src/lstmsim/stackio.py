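"""Image stack I/O: multi-page TIFF with voxel-size metadata.

Stacks are written as ImageJ-compatible TIFF so the voxel size survives a
round trip (x/y via the resolution tags, z via the ``spacing`` field).
float64 data is stored as float32; integer data is stored as-is, so a uint16
stack round-trips bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .scan import ImageStack

__all__ = ["write_stack", "read_stack"]


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF with voxel size metadata."""
    if stack.intensities.size == 0:
        raise ValueError("refusing to write an empty stack")
    path = Path(path)
    data = stack.intensities
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    vz, vy, vx = stack.voxel_size
    meta = {
        "spacing": vz,
        "unit": "um",
        "axes": "ZYX",
        "lstmsim": json.dumps(stack.metadata, default=str),
    }
    tifffile.imwrite(
        path,
        data,
        imagej=data.dtype in (np.dtype(np.uint8), np.dtype(np.uint16),
                              np.dtype(np.float32)),
        resolution=(1.0 / vx, 1.0 / vy),
        metadata=meta,
    )


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if data.ndim == 2:
            data = data[None]
        page = tif.pages[0]
        ij = tif.imagej_metadata or {}
        vz = float(ij.get("spacing", 1.0))
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")

        def _res(tag):
            if tag is None:
                return 1.0
            num, den = tag.value
            return den / num if num else 1.0

        vx, vy = _res(xres), _res(yres)
        metadata = {}
        if "lstmsim" in ij:
            try:
                metadata = json.loads(ij["lstmsim"])
            except (TypeError, json.JSONDecodeError):
                metadata = {}
    return ImageStack(np.asarray(data), (vz, vy, vx), metadata)
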