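"""Clean a raw frame: strip crop, CLAHE, conditional super-resolution.

A 436x / 10 um acquisition qualifies for 4x resolution enhancement; a
2300x / 2 um one does not. The annotation tracks the pixels through every
step, so pixel-level labels stay usable after upscaling.
"""

from semssl import (ImageMeta, SceneSpec, generate_image, preprocess_image,
                    should_super_resolve)

spec = SceneSpec(width=256, height=190, n_cells=20, n_clusters=3,
                 n_byproduct_blobs=8, meta_strip_height=19,
                 magnification_label=436.0, scale_um=10.0)
img = generate_image(spec, seed=1)
print(f"raw frame:       {img.pixels.shape}, strip {img.meta.meta_strip_height} px")
print(f"super-resolve?   {should_super_resolve(img.meta)}   (436x at 10 um)")
print(f"super-resolve?   "
      f"{should_super_resolve(ImageMeta(magnification_label=2300, scale_um=2))}"
      f"   (2300x at 2 um)")

out = preprocess_image(img)
print(f"preprocessed:    {out.pixels.shape}  "
      f"(strip removed, CLAHE, 4x bicubic; annotation upscaled nearest)")
assert out.pixels.shape == out.annotation.shape
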