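"""Render a short B-mode-like sequence and recover the diameters.

A 10-s paced-breathing diameter series (baseline 2.43 mm, phasic
half-amplitude 0.05 mm) is rendered as speckled 8-bit frames and pushed
through the segmentation pipeline: threshold 70, largest-component cleanup,
moment-based ellipse fit, minor axis x 0.05 mm/pixel.
"""

import numpy as np

import veinmod as vm
from veinmod import segmentation, synthetic

pattern = vm.make_breath_pattern("PB10", duration_s=50)
truth = vm.GroundTruth(d0=2.43, slope=0.0, amp=0.05, noise_sd_diameter=0.0)
series = vm.make_diameter_series(pattern, truth, seed=3)

scene = synthetic.SceneParams(speckle_sd=10.0, seed=11)
frames = vm.render_frames(series, scene)
extracted = segmentation.extract_series(frames)

err = np.abs(extracted.values_mm - series.values_mm)
r = np.corrcoef(extracted.values_mm, series.values_mm)[0, 1]
print(f"frames rendered        : {len(frames)} "
      f"({frames.frame_shape[0]}x{frames.frame_shape[1]} px, "
      f"{frames.pixel_spacing_mm} mm/px)")
print(f"true diameter range    : {series.values_mm.min():.3f}"
      f"-{series.values_mm.max():.3f} mm")
print(f"max extraction error   : {err.max():.4f} mm "
      f"(one pixel = {frames.pixel_spacing_mm} mm)")
print(f"truth correlation      : r = {r:.3f}")
# The extraction error stays below one pixel equivalent even with speckle:
# the ellipse fit averages over the whole lumen cross-section.
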