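"""Spatial class-distribution heatmaps from a ground-truth oracle.

Each cell of the grid is one sliding-window position; the value is the
class's presence in that window. With the oracle model the heatmap is the
label table rearranged spatially — the bookkeeping identity that trained
models are benchmarked against.
"""

from semssl import SceneSpec, generate_image
from semssl.evaluate import LabelOracle, class_distribution_heatmap, heatmap_table

spec = SceneSpec(width=256, height=256, n_cells=25, n_clusters=4,
                 n_byproduct_blobs=10, byproduct_radius_range=(12, 60),
                 magnification_label=2300.0, scale_um=2.0)
img = generate_image(spec, seed=5)
heatmaps = class_distribution_heatmap(img, LabelOracle(0.01),
                                      kernel=64, stride=32)
for label, hm in heatmaps.items():
    grid = hm.grid.astype(int)
    print(f"{label.name.lower():>10}  grid {grid.shape}, "
          f"present in {grid.sum()}/{grid.size} windows")
    for row in grid:
        print("            " + "".join("#" if v else "." for v in row))
table = heatmap_table(heatmaps)
print(f"long-format table: {len(table)} rows, columns {list(table.columns)}")
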