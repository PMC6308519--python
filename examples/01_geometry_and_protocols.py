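"""Scan geometry arithmetic and acquisition protocols.

The flat-panel system (75 um detector pitch) at SOD 299 mm / SID 325 mm
reconstructs at a 69 um isocenter voxel; moving the object close to the
source (SOD 49 mm, SID 211.1 mm) magnifies to a 17.4 um voxel.  The three
acquisition protocols trade dose for angular coverage: LA takes a quarter
of the projections of DSFC.
"""

from lair.geometry import (
    DSFC,
    LA,
    LSFC,
    ScanGeometry,
    fov_mm,
    isocenter_voxel_size,
    magnification,
    projection_angles,
)

standard = ScanGeometry(sod=299.0, sid=325.0, det_pitch_um=75.0, det_count=864)
high_mag = ScanGeometry(sod=49.0, sid=211.1, det_pitch_um=75.0, det_count=864)

print(f"standard geometry: magnification {magnification(standard):.5f}, "
      f"voxel {isocenter_voxel_size(standard):.2f} um, FOV {fov_mm(standard):.1f} mm")
print(f"high-mag geometry: magnification {magnification(high_mag):.4f}, "
      f"voxel {isocenter_voxel_size(high_mag):.4f} um")

for protocol in (LA, DSFC, LSFC):
    angles = projection_angles(protocol)
    print(f"{protocol.label}: {len(angles)} views, {protocol.step_deg} deg/view, "
          f"{protocol.coverage_deg} deg coverage (dose ~ {len(angles)} projections)")
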