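"""Synthetic SEM biofilm scene generator.

Emulates the salient structure of SEM micrographs of sulfate-reducing
bacteria on mild steel: a dark textured metal background, mid-grey granular
corrosion-byproduct blobs, and bright rod-shaped cells appearing singly and
in crowded clusters, plus an optional black metadata strip along the bottom.
Every scene carries a dense ground-truth class map (topmost object wins),
which makes the full downstream pipeline testable without access-restricted
microscope data.

Intensity layout: cells brightest, byproduct intermediate, surface darkest
and textured — but grey levels, texture grain and speckle vary per frame
and per object, so class identity is carried by morphology and texture
(which survive contrast equalization) rather than by absolute brightness,
and a small labeled sample cannot cover a class's appearance range.

Determinism: every stochastic layer (background, byproducts, each cell,
each cluster) draws from its own child generator derived from ``(seed,
layer, index)``, so regenerating with the same spec and seed is
bit-identical, and increasing an object count only appends objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .types import AnnotatedImage, ClassLabel, ImageMeta

__all__ = ["SceneSpec", "generate_image", "generate_dataset"]

# grey-level anchors (uint8) for the three material classes
_SURFACE_LEVEL = 60.0
_BYPRODUCT_LEVEL = 140.0
_CELL_LEVEL = 205.0


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``height`` is the total image height; when ``meta_strip_height`` > 0 the
    bottom that many rows are a black metadata strip (annotated Surface) and
    the scene content fills the remainder, mirroring how real SEM exports
    embed their info bar in the stated frame size.
    """

    width: int = 1024
    height: int = 758
    n_cells: int = 60
    n_clusters: int = 8
    cluster_size_range: Tuple[int, int] = (3, 8)
    n_byproduct_blobs: int = 14
    cell_axis_range: Tuple[int, int] = (8, 24)      # major-axis length, px
    byproduct_radius_range: Tuple[int, int] = (8, 28)
    background_texture_scale: float = 12.0
    noise_sd: float = 8.0
    overlap_allowed: bool = True
    meta_strip_height: int = 0
    magnification_label: float = 436.0
    scale_um: float = 10.0

    def validate(self) -> None:
        for name in ("width", "height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_cells", "n_clusters", "n_byproduct_blobs",
                     "meta_strip_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cluster_size_range", "cell_axis_range",
                     "byproduct_radius_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy low <= high")
            if lo < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.magnification_label <= 0:
            raise ValueError("magnification_label must be > 0")
        if self.scale_um <= 0:
            raise ValueError("scale_um must be > 0")
        if self.meta_strip_height >= self.height:
            raise ValueError("meta_strip_height must be smaller than height")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


def _background(shape: Tuple[int, int], scale: float,
                rng: np.random.Generator) -> np.ndarray:
    """Low-amplitude smoothed-noise texture around the surface grey level.

    Base level, texture amplitude and correlation length vary per frame,
    as they do across acquisitions of real specimens."""
    level = _SURFACE_LEVEL + rng.uniform(-15.0, 15.0)
    amp = scale * rng.uniform(0.7, 1.5)
    sigma = rng.uniform(4.0, 9.0)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma)
    smooth /= max(smooth.std(), 1e-9)
    fine = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.5)
    fine /= max(fine.std(), 1e-9)
    return level + amp * smooth + 0.25 * amp * fine


def _paint_byproduct(img: np.ndarray, ann: np.ndarray, radius_range,
                     rng: np.random.Generator, overlap: bool = True,
                     center: Optional[Tuple[float, float]] = None) -> None:
    """One granular blob: a noise-perturbed disc with internal texture."""
    h, w = img.shape
    r = rng.uniform(*radius_range)
    cy, cx = center if center is not None else (rng.uniform(0, h),
                                                rng.uniform(0, w))
    y0, y1 = int(max(0, cy - 2 * r)), int(min(h, cy + 2 * r + 1))
    x0, x1 = int(max(0, cx - 2 * r)), int(min(w, cx + 2 * r + 1))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy, xx - cx)
    wobble = ndimage.gaussian_filter(rng.standard_normal(dist.shape), sigma=3.0)
    wobble /= max(np.abs(wobble).max(), 1e-9)
    mask = dist <= r * (0.75 + 0.45 * wobble)
    if not mask.any():
        return
    if not overlap and (ann[y0:y1, x0:x1][mask] != int(ClassLabel.SURFACE)).any():
        return
    # corrosion products are heterogeneous: each deposit gets its own
    # grain scale, granularity strength, speckle density and grey level
    grain = ndimage.gaussian_filter(rng.standard_normal(dist.shape),
                                    sigma=rng.uniform(0.6, 1.6))
    grain /= max(grain.std(), 1e-9)
    speckle = (rng.uniform(size=dist.shape) < rng.uniform(0.03, 0.12)) * 70.0
    level = _BYPRODUCT_LEVEL + rng.uniform(-20.0, 20.0)
    region = img[y0:y1, x0:x1]
    region[mask] = level + rng.uniform(18.0, 38.0) * grain[mask] - speckle[mask]
    ann[y0:y1, x0:x1][mask] = int(ClassLabel.BYPRODUCT)


def _paint_cell(img: np.ndarray, ann: np.ndarray, center: Tuple[float, float],
                axis_range, rng: np.random.Generator,
                overlap: bool = True) -> None:
    """One rod-shaped cell: a randomly oriented bright ellipse."""
    h, w = img.shape
    major = rng.uniform(*axis_range)
    minor = major * rng.uniform(0.35, 0.65)
    theta = rng.uniform(0.0, np.pi)
    rr, cc = draw_ellipse(center[0], center[1], max(minor / 2, 1.0),
                          max(major / 2, 1.0), shape=(h, w), rotation=theta)
    if rr.size == 0:
        return
    if not overlap and (ann[rr, cc] != int(ClassLabel.SURFACE)).any():
        return
    shade = rng.uniform(-25.0, 20.0)
    rim_depth = rng.uniform(35.0, 70.0)
    # smooth interior with a darker rim: distance-from-center shading gives
    # cells the rounded, membrane-bounded look that survives equalization
    dy, dx = rr - center[0], cc - center[1]
    u = np.cos(theta) * dx + np.sin(theta) * dy     # along major axis
    v = -np.sin(theta) * dx + np.cos(theta) * dy    # along minor axis
    radial = np.clip(np.hypot(v / max(minor / 2, 1.0),
                              u / max(major / 2, 1.0)), 0.0, 1.5)
    img[rr, cc] = _CELL_LEVEL + shade - rim_depth * radial ** 3
    ann[rr, cc] = int(ClassLabel.CELL)


def _meta_strip(width: int, height: int,
                rng: np.random.Generator) -> np.ndarray:
    """Black info bar with synthetic white tick/text marks."""
    strip = np.zeros((height, width), dtype=np.float64)
    n_marks = max(3, width // 128)
    for _ in range(n_marks):
        x = int(rng.uniform(4, max(5, width - 24)))
        y = int(rng.uniform(2, max(3, height - 4)))
        mw = int(rng.uniform(6, 20))
        mh = max(1, min(3, height - y - 1))
        strip[y:y + mh, x:x + mw] = 255.0
    return strip


def _object_center(rng: np.random.Generator, hotspots: np.ndarray,
                   shape: Tuple[int, int], p_hotspot: float,
                   spread: float) -> Tuple[float, float]:
    """Colony-structured placement: biofilm constituents aggregate around a
    few hotspots, leaving stretches of bare metal between colonies."""
    if hotspots.size and rng.uniform() < p_hotspot:
        hy, hx = hotspots[rng.integers(len(hotspots))]
        return hy + rng.normal(0.0, spread), hx + rng.normal(0.0, spread)
    return rng.uniform(0, shape[0]), rng.uniform(0, shape[1])


def generate_image(spec: SceneSpec, seed: int) -> AnnotatedImage:
    """Render one annotated scene, bit-identical for equal ``(spec, seed)``.

    Draw order is byproduct blobs, then single cells, then clusters; the
    annotation records the topmost class at each pixel and Surface
    elsewhere, so the class map is always a full partition of the frame.
    Object placement follows a colony structure (a few hotspots per frame)
    so that per-window class coverage is bimodal, as in real crowded
    biofilms: bare surface between colonies, dense occlusion inside them.
    """
    spec.validate()
    content_h = spec.height - spec.meta_strip_height
    shape = (content_h, spec.width)

    img = _background(shape, spec.background_texture_scale, _rng(seed, 0))
    ann = np.full(shape, int(ClassLabel.SURFACE), dtype=np.uint8)

    hs_rng = _rng(seed, 6)
    n_hotspots = max(2, (spec.n_byproduct_blobs + spec.n_clusters) // 6)
    hotspots = np.column_stack([hs_rng.uniform(0, content_h, n_hotspots),
                                hs_rng.uniform(0, spec.width, n_hotspots)])
    spread = 0.12 * min(shape)

    for i in range(spec.n_byproduct_blobs):
        rng = _rng(seed, 1, i)
        center = _object_center(rng, hotspots, shape, 0.75, spread)
        _paint_byproduct(img, ann, spec.byproduct_radius_range, rng,
                         spec.overlap_allowed, center)

    for i in range(spec.n_cells):
        rng = _rng(seed, 2, i)
        center = _object_center(rng, hotspots, shape, 0.5, spread)
        _paint_cell(img, ann, center, spec.cell_axis_range, rng,
                    spec.overlap_allowed)

    for j in range(spec.n_clusters):
        rng = _rng(seed, 3, j)
        cy, cx = _object_center(rng, hotspots, shape, 0.75, spread)
        size = int(rng.integers(spec.cluster_size_range[0],
                                spec.cluster_size_range[1] + 1))
        cluster_spread = 0.9 * spec.cell_axis_range[1]
        for _ in range(size):
            center = (cy + rng.normal(0, cluster_spread),
                      cx + rng.normal(0, cluster_spread))
            _paint_cell(img, ann, center, spec.cell_axis_range, rng,
                        spec.overlap_allowed)

    img += _rng(seed, 4).normal(0.0, spec.noise_sd, shape)

    if spec.meta_strip_height > 0:
        strip = _meta_strip(spec.width, spec.meta_strip_height, _rng(seed, 5))
        img = np.vstack([img, strip])
        ann = np.vstack([ann, np.full((spec.meta_strip_height, spec.width),
                                      int(ClassLabel.SURFACE), dtype=np.uint8)])

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    meta = ImageMeta(magnification_label=spec.magnification_label,
                     scale_um=spec.scale_um,
                     meta_strip_height=spec.meta_strip_height)
    return AnnotatedImage(pixels=pixels, annotation=ann, meta=meta,
                          source_id=f"synthetic_{seed}")


def generate_dataset(n_images: int, spec: SceneSpec, seed: int,
                     out_dir: Optional[str] = None) -> List[AnnotatedImage]:
    """Generate ``n_images`` scenes with per-image derived seeds.

    When ``out_dir`` is given, each image/annotation pair is written as PNG
    alongside a tab-separated metadata table (see :mod:`semssl.io`).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    spec.validate()
    images = []
    for i in range(n_images):
        img = generate_image(spec, seed=(int(seed) * 1000 + i) & 0x7FFFFFFF)
        img.source_id = f"synthetic_{i:03d}"
        images.append(img)
    if out_dir is not None:
        from .io import save_dataset
        save_dataset(images, out_dir)
    return images
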