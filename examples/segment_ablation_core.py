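"""Segment an ablation core from a synthetic post-treatment volume.

Builds one thalamic phantom, plants a three-zone FUS ablation (penumbra,
hyperintense core, central hypointensity), then recovers the core with the
scaled-intensity threshold + closing algorithm and compares it with the
planted truth.
"""

import numpy as np

from vimtarget import (
    AblationSpec,
    BinaryMask,
    PhantomSpec,
    dice,
    generate_phantom,
    plant_ablation,
    segment_core,
)

spec = PhantomSpec()
pre, nuclei, landmarks = generate_phantom(spec, rng_seed=0)
thalamus = BinaryMask(nuclei.grid, nuclei.labels > 0)

ablation = AblationSpec(center=spec.efficacious_center)
post, true_core, whole = plant_ablation(pre, ablation, thalamus, rng_seed=0)

seg = segment_core(post, whole, thalamus)
print(f"normal thalamus median / p99 : {seg.thalamus_median:8.1f} / {seg.thalamus_p99:8.1f}")
print(f"whole ablation volume        : {whole.volume_mm3:6.1f} mm3")
print(f"segmented core volume        : {seg.core.volume_mm3:6.1f} mm3")
print(f"planted core volume          : {true_core.volume_mm3:6.1f} mm3")
print(f"Dice(segmented, planted)     : {dice(seg.core, true_core):6.3f}")

# The core is recovered by thresholding intensities re-scaled to the
# normal-appearing thalamus (0 at its median, 1 at its 99th percentile) at
# 1.25, with a connectivity-1 closing that fills the central hypointensity.
# Dice near 1 means the threshold rule recovered the planted core almost
# voxel-for-voxel.
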