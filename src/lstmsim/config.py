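"""Run configuration: schema, defaults, YAML/JSON load and save.

A configuration fully describes one simulated acquisition: the imaging
geometry (both objectives, angle, immersion index, wavelength), the camera,
the light sheet, and the scan settings.  Unknown keys are rejected and every
schema violation is reported in a single error message.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .beam import LightSheet
from .errors import ConfigError
from .optics import ImagingGeometry, ObjectiveSpec
from .scan import CameraSpec

__all__ = ["ScanSettings", "RunConfig", "load_config", "save_config", "default_config"]


@dataclass(frozen=True)
class ScanSettings:
    mode: str = "2as"
    exposure_ms: float = 0.5
    z_step_um: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("lsm", "1as", "2as"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if not self.exposure_ms > 0:
            raise ValueError("exposure_ms must be > 0")
        if not self.z_step_um > 0:
            raise ValueError("z_step_um must be > 0")


@dataclass(frozen=True)
class RunConfig:
    geometry: ImagingGeometry
    camera: CameraSpec
    sheet: LightSheet
    scan: ScanSettings
    seed: int = 0
    output: str | None = None


_DETECTION_DEFAULTS = dict(
    nominal_magnification=10.0,
    numerical_aperture=0.6,
    working_distance=8.0,
    barrel_diameter=40.0,
    design_medium_index=1.454,
)
_ILLUMINATION_DEFAULTS = dict(
    nominal_magnification=4.0,
    numerical_aperture=0.28,
    working_distance=29.5,
    barrel_diameter=28.0,
    design_medium_index=1.0,
)
_GEOMETRY_DEFAULTS = dict(theta=60.0, medium_index=1.454, wavelength=0.488)
_CAMERA_DEFAULTS = dict(
    rows=2048, cols=2048, pixel_pitch=6.5, full_frame_time=20.0, bit_depth=16,
    bidirectional=False,
)
_SHEET_DEFAULTS = dict(
    waist_thickness_fwhm=4.0, wavelength=0.488, medium_index=1.454,
    sheet_width=1000.0,
)
_SCAN_DEFAULTS = dict(mode="2as", exposure_ms=0.5, z_step_um=5.0)


def _merge(section: str, raw: dict, defaults: dict, errors: list) -> dict:
    out = dict(defaults)
    for key, value in raw.items():
        if key not in defaults:
            errors.append(f"{section}: unknown key {key!r}")
        else:
            out[key] = value
    return out


def default_config() -> RunConfig:
    """The instrument defaults: 10x/0.6 detection, 4x/0.28 air illumination,
    theta 60 deg, n 1.454, 488 nm excitation, 2048^2/6.5 um/20 ms camera."""
    return _build({})


def _build(data: dict) -> RunConfig:
    errors: list = []
    known_sections = {
        "geometry", "detection", "illumination", "camera", "sheet", "scan",
        "seed", "output",
    }
    for key in data:
        if key not in known_sections:
            errors.append(f"unknown top-level key {key!r}")

    geo_raw = dict(data.get("geometry", {}) or {})
    det_raw = dict(data.get("detection", geo_raw.pop("detection", {})) or {})
    ill_raw = dict(data.get("illumination", geo_raw.pop("illumination", {})) or {})
    geo_kw = _merge("geometry", geo_raw, _GEOMETRY_DEFAULTS, errors)
    det_kw = _merge("detection", det_raw, _DETECTION_DEFAULTS, errors)
    ill_kw = _merge("illumination", ill_raw, _ILLUMINATION_DEFAULTS, errors)
    cam_kw = _merge("camera", dict(data.get("camera", {}) or {}),
                    _CAMERA_DEFAULTS, errors)
    sheet_kw = _merge("sheet", dict(data.get("sheet", {}) or {}),
                      _SHEET_DEFAULTS, errors)
    scan_kw = _merge("scan", dict(data.get("scan", {}) or {}),
                     _SCAN_DEFAULTS, errors)

    def construct(section, factory, kwargs):
        try:
            return factory(**kwargs)
        except (ValueError, TypeError) as exc:
            errors.append(f"{section}: {exc}")
            return None

    detection = construct("detection", ObjectiveSpec, det_kw)
    illumination = construct("illumination", ObjectiveSpec, ill_kw)
    geometry = None
    if detection is not None and illumination is not None:
        geometry = construct(
            "geometry", ImagingGeometry,
            dict(detection=detection, illumination=illumination, **geo_kw),
        )
    camera = construct("camera", CameraSpec, cam_kw)
    sheet = construct("sheet", LightSheet, sheet_kw)
    scan = construct("scan", ScanSettings, scan_kw)

    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed: expected an integer, got {seed!r}")
    output = data.get("output")

    if errors:
        raise ConfigError(
            "configuration is invalid:\n  - " + "\n  - ".join(str(e) for e in errors)
        )
    return RunConfig(
        geometry=geometry, camera=camera, sheet=sheet, scan=scan,
        seed=seed, output=output,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON configuration file.

    Missing sections and keys fall back to the instrument defaults; unknown
    keys and invalid values are all reported at once.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return _build(data)


def save_config(config: RunConfig, path) -> None:
    """Write a configuration back out (YAML or JSON by extension)."""
    path = Path(path)
    data = {
        "geometry": {
            k: v for k, v in asdict(config.geometry).items()
            if k not in ("detection", "illumination")
        },
        "detection": asdict(config.geometry.detection),
        "illumination": asdict(config.geometry.illumination),
        "camera": asdict(config.camera),
        "sheet": asdict(config.sheet),
        "scan": asdict(config.scan),
        "seed": config.seed,
    }
    if config.output is not None:
        data["output"] = config.output
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
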