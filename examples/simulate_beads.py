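"""Render a bead field in 2-axis-scan and LSM modes and measure the axial
FWHM of every bead from its line profile, reproducing the uniform-vs-edge
resolution contrast on a small field.  Writes the 2-AS stack as TIFF.
"""

import numpy as np

from lstmsim import (
    CameraSpec,
    ImagingGeometry,
    LightSheet,
    ObjectiveSpec,
    fwhm_field_report,
    make_bead_grid,
    simulate_acquisition,
    write_stack,
)

geometry = ImagingGeometry(
    detection=ObjectiveSpec(10, 0.6, 8.0, 40.0, 1.454),
    illumination=ObjectiveSpec(4, 0.28, 29.5, 28.0, 1.0),
    theta=60.0,
)
camera = CameraSpec()
phantom = make_bead_grid((600.0, 4.0, 60.0), 120.0, bead_diameter=1.0)
print(f"Phantom: {phantom.n_emitters} beads across a 600 um field")

for mode in ("2as", "lsm"):
    theta = 60.0 if mode == "2as" else 90.0
    sheet = LightSheet.from_effective_thickness(4.0, theta)
    stack = simulate_acquisition(phantom, geometry, sheet, camera, mode,
                                 exposure=0.1, z_step=0.5)
    xs = stack.axis_coordinates(2)
    nz, ny, _ = stack.intensities.shape
    locs = [(nz // 2, ny // 2, int(np.argmin(np.abs(xs - ex))))
            for ex in sorted(set(phantom.emitter_positions[:, 0]))]
    report = fwhm_field_report(stack, locs)
    values = " ".join(f"{v:5.2f}" for v in report.axial_fwhm)
    print(f"{mode:>4}: axial FWHM (um) by position: {values}")
    if mode == "2as":
        write_stack(stack, "scratch_beads_2as.tif")
        print(f"      wrote stack {stack.intensities.shape} to "
              "scratch_beads_2as.tif")

print("2-AS is uniform across the field; LSM broadens toward the edges as")
print("the parked sheet diverges away from its waist.")
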