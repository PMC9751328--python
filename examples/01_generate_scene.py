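"""Render one synthetic SEM biofilm scene with its ground-truth annotation.

Prints the per-class pixel shares; with the default crowded scene the
surface dominates, byproduct crusts cover a sizable minority, and cells a
few percent — the imbalance the downstream classifiers must cope with.
"""

from semssl import SceneSpec, generate_image
from semssl.io import save_annotated_image

spec = SceneSpec(width=512, height=512, n_cells=60, n_clusters=8,
                 cluster_size_range=(4, 10), n_byproduct_blobs=22,
                 byproduct_radius_range=(16, 96), meta_strip_height=40,
                 magnification_label=2300.0, scale_um=2.0)
img = generate_image(spec, seed=7)

total = img.pixels.size
for label, count in img.class_counts().items():
    print(f"{label.name.lower():>10}: {100 * count / total:5.1f}% of pixels")
path = save_annotated_image(img, "scratch/example_scene")
print(f"wrote {path} (+ matching *_annotation.png in blue/pink/green)")
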