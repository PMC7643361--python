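"""Place the standard stereotactic initial target and report its landmarks.

The standard rule: 11 mm lateral to the third-ventricle wall, a quarter of
the AC-PC length anterior to PC, on the AC-PC plane.
"""

from vimtarget import (
    StereotacticLandmarks,
    StereotacticRule,
    standard_target,
    target_landmark_distances,
)

landmarks = StereotacticLandmarks(
    AC=(0.0, 12.0, 0.0),
    PC=(0.0, -12.0, 0.0),
    third_ventricle_wall_x=-2.5,
    treated_side="left",
)
rule = StereotacticRule()  # 11 mm lateral, 0.25 x AC-PC

target = standard_target(landmarks, rule)
report = target_landmark_distances(target, landmarks)

print(f"standard initial target (mm): ({target[0]:.1f}, {target[1]:.1f}, {target[2]:.1f})")
print(f"distance to midline         : {report.midline_dist:.1f} mm")
print(f"distance to PC along y      : {report.pc_dist_y:.1f} mm")
print(f"position along PC->AC       : {report.acpc_percent:.1f} %")
print(f"distance to AC-PC plane     : {report.acpc_plane_dist_z:.1f} mm")

# With a 24 mm AC-PC distance and the wall 2.5 mm off midline, the target
# lands 13.5 mm lateral to the midline at 25% of the AC-PC length — the
# magnitudes reported for stereotactic Vim targeting.
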