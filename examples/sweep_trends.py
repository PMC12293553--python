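"""Kernel-size sweep: how mean SDNR/CNR respond to filter strength.

Runs both filter families over kernel sizes 3..21 on a few seeded 2 um
bead scenes and prints the seed-averaged image-level means. Expected
pattern: CNR rises steadily with kernel size (background suppression
outpaces signal loss), while the 3x3x3 kernel dips SDNR below the
unfiltered baseline.
"""

from sfmtools import FilterConfig, run_sweep, sweep_to_dataframe
from sfmtools.synth import default_aqafi_config, generate_scene, preset_spec

scenes, cfg = [], None
for seed in (1, 2, 3):
    spec = preset_spec("beads_2um", voltage=4.5, seed=seed,
                       n_beads=6, height=640, width=640)
    image, _ = generate_scene(spec)
    scenes.append((f"seed{seed}", image))
    cfg = default_aqafi_config(spec)

grid = [FilterConfig("average", m) for m in (3, 7, 11, 15, 21)] + [
    FilterConfig("gaussian", m, sigma=5.0) for m in (3, 7, 11, 15, 21)
]
df = sweep_to_dataframe(run_sweep(scenes, grid, cfg))
agg = df.groupby(["filter_family", "size_m"])[["mean_sdnr", "mean_cnr"]].mean()
print(agg.round(3).to_string())
base = agg.loc[("none", 0)]
print(f"\nunfiltered baseline: SDNR {base.mean_sdnr:.3f}, CNR {base.mean_cnr:.3f}")
print("CNR should increase monotonically with kernel size for both families.")
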