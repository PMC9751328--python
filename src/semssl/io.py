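"""Reading and writing images, annotations and metadata tables.

On disk a dataset is a flat directory of 8-bit grayscale PNGs
(``<id>.png``), exact-color RGB annotation PNGs (``<id>_annotation.png``)
and one tab-separated ``metadata.tsv`` with columns
(filename, magnification_label, scale_um, meta_strip_height).
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .types import AnnotatedImage, ImageMeta, annotation_to_rgb, rgb_to_annotation

PathLike = Union[str, Path]

METADATA_COLUMNS = ["filename", "magnification_label", "scale_um", "meta_strip_height"]


def save_annotated_image(img: AnnotatedImage, directory: PathLike) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{img.source_id}.png"
    iio.imwrite(path, img.pixels)
    iio.imwrite(directory / f"{img.source_id}_annotation.png",
                annotation_to_rgb(img.annotation))
    return path


def load_annotated_image(directory: PathLike, source_id: str,
                         meta: ImageMeta) -> AnnotatedImage:
    directory = Path(directory)
    pixels = np.asarray(iio.imread(directory / f"{source_id}.png"))
    if pixels.ndim == 3:  # grayscale saved with redundant channels
        pixels = pixels[..., 0]
    rgb = np.asarray(iio.imread(directory / f"{source_id}_annotation.png"))
    return AnnotatedImage(pixels=pixels, annotation=rgb_to_annotation(rgb),
                          meta=meta, source_id=source_id)


def save_dataset(images: List[AnnotatedImage], directory: PathLike) -> Path:
    """Write all image/annotation pairs plus the metadata table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        save_annotated_image(img, directory)
        rows.append({
            "filename": f"{img.source_id}.png",
            "magnification_label": img.meta.magnification_label,
            "scale_um": img.meta.scale_um,
            "meta_strip_height": img.meta.meta_strip_height,
        })
    table = directory / "metadata.tsv"
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(table, sep="\t", index=False)
    return table


def load_dataset(directory: PathLike) -> List[AnnotatedImage]:
    directory = Path(directory)
    meta_df = pd.read_csv(directory / "metadata.tsv", sep="\t")
    images = []
    for _, row in meta_df.iterrows():
        source_id = Path(str(row["filename"])).stem
        meta = ImageMeta(magnification_label=float(row["magnification_label"]),
                         scale_um=float(row["scale_um"]),
                         meta_strip_height=int(row["meta_strip_height"]))
        images.append(load_annotated_image(directory, source_id, meta))
    return images
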