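"""Plan a tiled acquisition of a large cleared tissue slab: effective
magnification, pixel sampling, field of view, tile and plane counts, and the
raw data volume implied by the camera format.
"""

from lstmsim import (
    CameraSpec,
    SampleBlock,
    data_volume,
    effective_magnification,
    format_bytes,
    fov_extent,
    pixel_sampling,
    plan_tiles,
)

camera = CameraSpec()
mag = effective_magnification(10, tube_focal_length=200)
fov = fov_extent(camera, mag)
print(f"10x objective with a 200 mm tube lens: {mag:.2f}x effective")
print(f"Pixel sampling: {pixel_sampling(camera, mag):.3f} um")
print(f"Field of view: {fov:.3f} mm")

slab = SampleBlock(width=10.5, length=14.1, thickness=3.0)
plan = plan_tiles(slab, fov=fov, overlap_fraction=0.1, z_step=5.0,
                  camera=camera)
print(f"\n{slab.width:g} x {slab.length:g} x {slab.thickness:g} mm slab, "
      "10% tile overlap, 5 um z-steps:")
print(f"  tiles: {plan.tiles_x} x {plan.tiles_y}, z planes: {plan.z_planes}")
print(f"  total frames: {plan.total_frames:,}")
print(f"  raw data: {format_bytes(plan.total_bytes)}")

print("\nReported frame counts translate directly to raw volume:")
for frames in (23001, 388687):
    print(f"  {frames:,} frames -> {format_bytes(data_volume(frames, camera))}")
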