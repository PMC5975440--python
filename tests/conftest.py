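import pytest

from lstmsim import CameraSpec, ImagingGeometry, LightSheet, ObjectiveSpec


@pytest.fixture
def illumination_objective():
    """Macro 4x/0.28 NA air objective, 29.5 mm WD, 28 mm barrel."""
    return ObjectiveSpec(
        nominal_magnification=4,
        numerical_aperture=0.28,
        working_distance=29.5,
        barrel_diameter=28.0,
        design_medium_index=1.0,
    )


@pytest.fixture
def detection_objective():
    """10x/0.6 NA detection objective, 8 mm WD, 40 mm barrel, oil-corrected."""
    return ObjectiveSpec(
        nominal_magnification=10,
        numerical_aperture=0.6,
        working_distance=8.0,
        barrel_diameter=40.0,
        design_medium_index=1.454,
    )


@pytest.fixture
def geometry(detection_objective, illumination_objective):
    """The instrument's arrangement: theta 60 deg in n=1.454 immersion oil."""
    return ImagingGeometry(
        detection=detection_objective,
        illumination=illumination_objective,
        theta=60.0,
        medium_index=1.454,
        wavelength=0.488,
    )


@pytest.fixture
def camera():
    return CameraSpec()


@pytest.fixture
def sheet_eff4():
    """Sheet whose axial footprint at focus is 4 um at theta = 60 deg."""
    return LightSheet.from_effective_thickness(4.0, 60.0)
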