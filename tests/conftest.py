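import numpy as np
import pytest

from semssl.synthetic import SceneSpec, generate_image
from semssl.types import AnnotatedImage, ClassLabel, ImageMeta


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    """A 160x160 crowded scene that renders in well under a second."""
    return SceneSpec(width=160, height=160, n_cells=12, n_clusters=3,
                     cluster_size_range=(2, 5), n_byproduct_blobs=6,
                     byproduct_radius_range=(6, 30), meta_strip_height=0,
                     magnification_label=2300.0, scale_um=2.0)


@pytest.fixture(scope="session")
def small_image(small_spec) -> AnnotatedImage:
    return generate_image(small_spec, seed=42)


@pytest.fixture(scope="session")
def strip_image() -> AnnotatedImage:
    spec = SceneSpec(width=128, height=96, n_cells=5, n_clusters=1,
                     n_byproduct_blobs=3, meta_strip_height=16,
                     magnification_label=436.0, scale_um=10.0)
    return generate_image(spec, seed=7)


@pytest.fixture()
def flat_image() -> AnnotatedImage:
    """Uniform mid-grey, all-surface annotation."""
    return AnnotatedImage(pixels=np.full((64, 64), 128, np.uint8),
                          annotation=np.zeros((64, 64), np.uint8),
                          meta=ImageMeta())
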