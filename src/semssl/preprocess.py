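"""Image cleanup: metadata-strip removal, CLAHE, conditional super-resolution.

The pipeline order is crop -> contrast enhancement -> (conditional)
super-resolution. Super-resolution is applied only to low-magnification /
coarse-scale acquisitions (scale >= 10 um and magnification below 1000x by
default) so that object sizes are normalized across magnifications; the
annotation is always resampled alongside the pixels with nearest-neighbor
interpolation so pixel-level labels survive every step.

The learned super-resolution model used on real data is a pluggable
backend: register a callable ``(image_float01, factor) -> image_float01``
under a name and select it via :class:`PreprocessConfig`; the default is
classical bicubic upsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict

import numpy as np
from skimage import exposure, transform

from .types import AnnotatedImage, ClassLabel

__all__ = [
    "PreprocessConfig", "crop_meta_strip", "enhance_contrast",
    "should_super_resolve", "super_resolve", "preprocess_image",
    "register_sr_backend",
]

SRBackend = Callable[[np.ndarray, int], np.ndarray]


def _bicubic(image: np.ndarray, factor: int) -> np.ndarray:
    out_shape = (image.shape[0] * factor, image.shape[1] * factor)
    return transform.resize(image, out_shape, order=3, mode="reflect",
                            anti_aliasing=False, preserve_range=True)


_SR_BACKENDS: Dict[str, SRBackend] = {"classical_bicubic": _bicubic}


def register_sr_backend(name: str, fn: SRBackend) -> None:
    """Make a learned upscaler available as ``sr_backend=name``."""
    _SR_BACKENDS[name] = fn


@dataclass
class PreprocessConfig:
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: int = 8
    sr_factor: int = 4
    sr_backend: str = "classical_bicubic"
    sr_scale_threshold_um: float = 10.0
    sr_magnification_threshold: float = 1000.0

    def validate(self) -> None:
        if self.sr_factor < 1:
            raise ValueError("sr_factor must be >= 1")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be > 0")
        if self.clahe_tile_grid < 1:
            raise ValueError("clahe_tile_grid must be >= 1")
        if self.sr_scale_threshold_um <= 0 or self.sr_magnification_threshold <= 0:
            raise ValueError("thresholds must be > 0")


def crop_meta_strip(img: AnnotatedImage) -> AnnotatedImage:
    """Remove the bottom metadata strip from pixels and annotation alike."""
    strip = img.meta.meta_strip_height
    if strip >= img.pixels.shape[0]:
        raise ValueError(
            f"meta_strip_height {strip} must be smaller than image height "
            f"{img.pixels.shape[0]}")
    if strip == 0:
        return img
    h = img.pixels.shape[0] - strip
    return AnnotatedImage(pixels=img.pixels[:h].copy(),
                          annotation=img.annotation[:h].copy(),
                          meta=replace(img.meta, meta_strip_height=0),
                          source_id=img.source_id)


def enhance_contrast(img: AnnotatedImage,
                     cfg: PreprocessConfig = PreprocessConfig()) -> AnnotatedImage:
    """Contrast-limited adaptive histogram equalization of the pixels only."""
    cfg.validate()
    # skimage expresses the clip limit as a fraction of tile pixel count;
    # divide the OpenCV-style limit by 100 to land in its usual range.
    out = exposure.equalize_adapthist(
        img.pixels,
        kernel_size=(max(1, img.pixels.shape[0] // cfg.clahe_tile_grid),
                     max(1, img.pixels.shape[1] // cfg.clahe_tile_grid)),
        clip_limit=cfg.clahe_clip_limit / 100.0)
    pixels = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return AnnotatedImage(pixels=pixels, annotation=img.annotation.copy(),
                          meta=replace(img.meta), source_id=img.source_id)


def should_super_resolve(meta, cfg: PreprocessConfig = PreprocessConfig()) -> bool:
    """Coarse-scale, low-magnification images get resolution enhancement.

    True iff scale >= ``sr_scale_threshold_um`` micrometers and the
    magnification label is strictly below ``sr_magnification_threshold``.
    """
    if meta is None:
        raise ValueError("image metadata is required to decide on super-resolution")
    cfg.validate()
    return (meta.scale_um >= cfg.sr_scale_threshold_um
            and meta.magnification_label < cfg.sr_magnification_threshold)


def super_resolve(img: AnnotatedImage,
                  cfg: PreprocessConfig = PreprocessConfig()) -> AnnotatedImage:
    """Upscale pixels by ``sr_factor`` via the configured backend.

    The annotation is upscaled nearest-neighbor by the same factor, which
    preserves the class-code set exactly.
    """
    cfg.validate()
    if cfg.sr_backend not in _SR_BACKENDS:
        raise KeyError(
            f"unknown super-resolution backend {cfg.sr_backend!r}; "
            f"registered: {sorted(_SR_BACKENDS)}")
    if cfg.sr_factor == 1:
        return img
    backend = _SR_BACKENDS[cfg.sr_backend]
    up = backend(img.pixels.astype(np.float64) / 255.0, cfg.sr_factor)
    pixels = np.clip(np.rint(up * 255.0), 0, 255).astype(np.uint8)
    ann = transform.resize(img.annotation,
                           (img.annotation.shape[0] * cfg.sr_factor,
                            img.annotation.shape[1] * cfg.sr_factor),
                           order=0, mode="edge", anti_aliasing=False,
                           preserve_range=True).astype(np.uint8)
    return AnnotatedImage(pixels=pixels, annotation=ann,
                          meta=replace(img.meta), source_id=img.source_id)


def preprocess_image(img: AnnotatedImage,
                     cfg: PreprocessConfig = PreprocessConfig()) -> AnnotatedImage:
    """Full cleanup: crop -> CLAHE -> conditional super-resolution."""
    out = crop_meta_strip(img)
    out = enhance_contrast(out, cfg)
    if should_super_resolve(out.meta, cfg):
        out = super_resolve(out, cfg)
    return out
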