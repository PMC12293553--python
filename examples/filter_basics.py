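"""Channel-aware 3D filtering of a synthetic fluorescence micrograph.

Builds a small seeded bead scene, applies the 21x21x21 Averaging filter
(treating R,G,B as a third dimension with zero channel padding), and
prints how the background level and a bead's core intensity change.
"""

import numpy as np

from sfmtools import FilterConfig, apply_filter
from sfmtools.synth import SceneSpec, generate_scene

spec = SceneSpec(seed=1, height=512, width=512, n_beads=5, bead_diameter_um=2.0)
image, truth = generate_scene(spec)
filtered = apply_filter(image, FilterConfig(family="average", size_m=21))

r, c = truth.centers[0].astype(int)
print(f"scene: {len(truth.centers)} beads of {spec.bead_diameter_um} um "
      f"({spec.mean_diameter_px:.1f} px) on a {spec.background_level:.0f}-level background")
print(f"bead core at ({r},{c}):  raw {image.green[r, c]:7.2f}  ->  "
      f"filtered {filtered.green[r, c]:6.2f}")
print(f"background median:       raw {np.median(image.green):7.2f}  ->  "
      f"filtered {np.median(filtered.green):6.2f}")
print(f"red+blue after filtering: {filtered.red.max() + filtered.blue.max():.1f} "
      "(false-colored green)")
# The filter attenuates everything by roughly the kernel depth over the
# 3 real channels (3/21), but the background drops proportionally more
# than the bead-to-background contrast, which is what improves CNR.
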