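"""Illumination energy load: oblique-scan accumulation versus orthogonal LSM.

The oblique sheet re-illuminates out-of-plane tissue on every plane, so per
acquisition each voxel is hit many times; orthogonal LSM instead re-exposes
the whole width once per tile.  The ratio of the totals shows where each
geometry is gentler, and a synthetic tile series shows the bleaching-trend
statistic on flat data.
"""

import numpy as np

from lstmsim import SampleBlock, bleaching_trend, energy_ratio_surface

FOV = 1.198  # mm, detection field of view at 11.11x

widths = [3.0, 6.0, 12.0, 24.0]
thicknesses = [0.5, 1.0, 2.0]
surface = energy_ratio_surface(widths, thicknesses, theta=60.0, fov=FOV,
                               voxel=0.06)
print("LSTM/LSM total energy ratio (rows: thickness mm, cols: width mm)")
print("        " + " ".join(f"{w:7.1f}" for w in widths))
for t, row in zip(thicknesses, surface.ratios):
    print(f"t={t:4.1f} " + " ".join(f"{r:7.2f}" for r in row))
print("The ratio falls with sample width: the oblique geometry's redundancy")
print("is fixed by the thickness while LSM re-illuminates the whole width")
print("per tile, so for large flat samples the two loads converge.")

print()
rng = np.random.default_rng(0)
tiles = 10.0 + rng.normal(0, 0.3, 60)  # flat mean signal per tile
trend = bleaching_trend(tiles)
print(f"Bleaching trend on a flat 60-tile series: slope {trend.slope:+.4f} "
      f"per tile, Kendall tau {trend.kendall_tau:+.3f}")
print("Both statistics are near zero: no systematic signal loss over the")
print("acquisition order.")
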