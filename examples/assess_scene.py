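"""Quality assessment (SDNR / Contrast / CNR) on an analytic scene.

The two-level scene plants particles with exactly known intensity
components (core 200, vicinity 50, background 10), so the metric
formulas can be checked against hand arithmetic:
SDNR = (200-50)/10 = 15, Contrast = (200-50)/50 = 3, CNR = 3/10 = 0.3.
"""

from sfmtools import assess_image, two_level_scene

image, centers, config = two_level_scene(n_particles=6)
report = assess_image(image, config)

print(f"planted particles: {len(centers)}, detected: {report.n_particles}")
print(f"image background noise: {report.background_noise:.1f}")
print("per-particle metrics:")
for det, m in report.particles:
    print(f"  ({det.center_row:6.1f},{det.center_col:6.1f})  "
          f"bead {m.bead_intensity:6.1f}  vicinity {m.vicinity_noise:5.1f}  "
          f"SDNR {m.sdnr:5.2f}  Contrast {m.contrast:4.2f}  CNR {m.cnr:4.2f}")
print(f"image means: SDNR {report.mean_sdnr:.2f}, CNR {report.mean_cnr:.2f}")
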