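"""Seeded synthetic samples: bead fields for PSF characterization and sparse
curvilinear structures for qualitative demos.

Phantoms stand in for the fluorescent-microbead and cleared-tissue samples
used to characterize the instrument: micrometre-size emitters embedded in an
index-matched gel.  All generators are pure functions of their parameters and
seed; emitter coordinates are micrometres in a frame centred on the volume,
so every position lies within ``+-extent/2`` per axis.

Beads are rendered at acquisition time as Gaussian blobs whose FWHM equals
``bead_diameter`` (see :func:`lstmsim.scan.simulate_acquisition`), not as
hard spheres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BeadPhantom",
    "make_bead_grid",
    "make_random_beads",
    "make_filament_phantom",
]


@dataclass(frozen=True)
class BeadPhantom:
    """A set of point emitters in a cuboid volume.

    ``emitter_positions`` has shape ``(n, 3)`` ordered ``(x, y, z)`` in
    micrometres, centred coordinates; ``volume_extent`` is the full extent
    per axis.
    """

    emitter_positions: np.ndarray
    emitter_amplitudes: np.ndarray
    bead_diameter: float
    volume_extent: tuple
    seed: int | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.emitter_positions, dtype=float).reshape(-1, 3)
        amp = np.asarray(self.emitter_amplitudes, dtype=float).reshape(-1)
        if pos.shape[0] != amp.shape[0]:
            raise ValueError("positions and amplitudes must have equal length")
        if np.any(amp <= 0):
            raise ValueError("amplitudes must be > 0")
        ext = tuple(float(v) for v in self.volume_extent)
        half = np.asarray(ext) / 2.0
        if pos.size and np.any(np.abs(pos) > half + 1e-9):
            raise ValueError("emitter positions must lie within the volume extent")
        object.__setattr__(self, "emitter_positions", pos)
        object.__setattr__(self, "emitter_amplitudes", amp)
        object.__setattr__(self, "volume_extent", ext)

    @property
    def n_emitters(self) -> int:
        return self.emitter_positions.shape[0]

    def to_csv(self, path) -> None:
        """Write emitters as (x, y, z, amplitude) CSV plus a JSON sidecar."""
        path = Path(path)
        data = np.column_stack([self.emitter_positions, self.emitter_amplitudes])
        np.savetxt(
            path, data, delimiter=",", header="x_um,y_um,z_um,amplitude", comments=""
        )
        sidecar = {
            "bead_diameter": self.bead_diameter,
            "volume_extent": list(self.volume_extent),
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path) -> "BeadPhantom":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1).reshape(-1, 4)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            emitter_positions=data[:, :3],
            emitter_amplitudes=data[:, 3],
            bead_diameter=meta["bead_diameter"],
            volume_extent=tuple(meta["volume_extent"]),
            seed=meta["seed"],
        )


def _as_extent3(extent) -> tuple:
    if np.isscalar(extent):
        return (float(extent),) * 3
    ext = tuple(float(v) for v in extent)
    if len(ext) != 3:
        raise ValueError("extent must be a scalar or a 3-sequence (x, y, z)")
    return ext


def make_bead_grid(
    extent,
    spacing: float,
    bead_diameter: float = 1.0,
    seed: int = 0,
    jitter: float = 0.0,
) -> BeadPhantom:
    """Regular 3-D grid of unit-amplitude beads with optional seeded jitter.

    Per axis the grid holds ``max(1, floor(extent / spacing))`` nodes centred
    in the volume; ``jitter`` displaces each bead uniformly by at most that
    amount per axis (clipped to the volume).
    """
    if not spacing > 0:
        raise ValueError("spacing must be > 0")
    if spacing <= bead_diameter:
        raise ValueError("spacing must exceed the bead diameter")
    ext = _as_extent3(extent)
    axes = []
    for e in ext:
        n = max(1, int(e / spacing))
        axes.append((np.arange(n) - (n - 1) / 2.0) * spacing)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.uniform(-jitter, jitter, size=pos.shape)
        half = np.asarray(ext) / 2.0
        pos = np.clip(pos, -half, half)
    return BeadPhantom(pos, np.ones(len(pos)), bead_diameter, ext, seed)


def make_random_beads(
    extent, n: int, seed: int = 0, bead_diameter: float = 1.0
) -> BeadPhantom:
    """``n`` uniformly placed beads with log-normal(0, 0.25) amplitudes."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ext = _as_extent3(extent)
    rng = np.random.default_rng(seed)
    half = np.asarray(ext) / 2.0
    pos = rng.uniform(-half, half, size=(n, 3))
    amp = rng.lognormal(mean=0.0, sigma=0.25, size=n)
    return BeadPhantom(pos, amp, bead_diameter, ext, seed)


def make_filament_phantom(
    extent,
    n_filaments: int,
    seed: int = 0,
    bead_diameter: float = 1.0,
    n_steps: int = 200,
    wiggle: float = 0.15,
    straight: bool = False,
) -> BeadPhantom:
    """Smooth random-walk chains of emitters (vessel/neurite-like content).

    Each filament is a chain of emitters spaced ``bead_diameter / 2`` apart;
    the direction performs a seeded smooth random walk (``wiggle`` radians
    r.m.s. per step; ``straight=True`` keeps the initial direction), and
    chains reflect off the volume boundary so all emitters stay in bounds.
    """
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    ext = _as_extent3(extent)
    half = np.asarray(ext) / 2.0
    rng = np.random.default_rng(seed)
    step = bead_diameter / 2.0
    points = []
    for _ in range(n_filaments):
        p = rng.uniform(-half * 0.8, half * 0.8)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        for _ in range(n_steps):
            points.append(p.copy())
            if not straight:
                d = d + wiggle * rng.normal(size=3)
                d /= np.linalg.norm(d)
            p = p + step * d
            # reflect at the boundary
            for ax in range(3):
                if p[ax] > half[ax]:
                    p[ax] = 2 * half[ax] - p[ax]
                    d[ax] = -d[ax]
                elif p[ax] < -half[ax]:
                    p[ax] = -2 * half[ax] - p[ax]
                    d[ax] = -d[ax]
            p = np.clip(p, -half, half)
    pos = np.asarray(points)
    return BeadPhantom(pos, np.ones(len(pos)), bead_diameter, ext, seed)
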