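"""Pretrain both self-supervised variants on a small unlabeled patch set.

A two-minute run on one CPU; both loss traces should fall from the first
to the last epoch, showing the encoders learning view-invariant (and, for
the non-contrastive variant, decorrelated) representations.
"""

from semssl import PretrainConfig, SceneSpec, extract_patches, generate_image, pretrain

spec = SceneSpec(width=256, height=256, n_cells=25, n_clusters=4,
                 n_byproduct_blobs=10, byproduct_radius_range=(12, 60),
                 magnification_label=2300.0, scale_um=2.0)
patches = [p for s in range(4)
           for p in extract_patches(generate_image(spec, seed=s), 64, 32)]
print(f"{len(patches)} unlabeled patches")

for variant in ("noncontrastive", "contrastive"):
    cfg = PretrainConfig(epochs=5, batch_size=64, seed=1)
    state, trace = pretrain(patches, variant, cfg)
    print(f"{variant:>15}: epoch-mean loss "
          + " -> ".join(f"{x:.2f}" for x in trace))
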