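"""Raster input and fixed-size tiling (the "image probe" step).

A photographed powder scene is split into equal square tiles, row-major
from the top-left corner; partial tiles at the right and bottom edges
are discarded rather than padded, so every tile has identical pixel
statistics. Tiles inherit the parent image's labels.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image

from .datatypes import LabeledImage, PowderLabels, TileGrid

__all__ = ["read_image", "read_manifest", "tile_image"]

DEFAULT_TILE_SIZE = 400


def read_image(path: str | Path, labels: PowderLabels | None = None) -> LabeledImage:
    """Read an RGB raster (PNG/TIFF/JPEG) as a LabeledImage.

    An alpha channel is dropped; any other non-RGB mode (grayscale,
    palette, CMYK, ...) raises rather than silently converting, since a
    lossy conversion would change the color statistics downstream.
    """
    path = Path(path)
    with Image.open(path) as im:
        mode = im.mode
        if mode == "RGBA":
            arr = np.asarray(im)[..., :3]
        elif mode == "RGB":
            arr = np.asarray(im)
        else:
            raise ValueError(
                f"{path} has mode {mode!r}; only RGB or RGBA input is supported"
            )
    return LabeledImage(pixels=arr.astype(np.uint8), labels=labels, source=str(path))


def read_manifest(manifest_path: str | Path) -> list[LabeledImage]:
    """Load all images listed in a labels manifest CSV.

    The manifest has columns image_path, sample_id, juice_content,
    saccharification; relative paths resolve against the manifest's
    directory.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    images = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            labels = PowderLabels(
                sample_id=int(row["sample_id"]),
                juice_content=int(row["juice_content"]),
                saccharification=row["saccharification"],
            )
            img_path = Path(row["image_path"])
            if not img_path.is_absolute():
                img_path = manifest_path.parent / img_path
            images.append(read_image(img_path, labels=labels))
    return images


def tile_image(raster: LabeledImage, tile_size: int = DEFAULT_TILE_SIZE) -> TileGrid:
    """Cut a raster into tile_size x tile_size tiles.

    Tiles cover the top-left floor(H/ts) x floor(W/ts) region in
    row-major order; remainders are discarded. Each tile carries the
    parent's labels and a ``source`` of the form ``parent#row_col``.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be positive")
    h, w = raster.height, raster.width
    if h < tile_size or w < tile_size:
        raise ValueError(
            f"tile_size {tile_size} exceeds image dimensions {h}x{w}"
        )
    n_rows, n_cols = h // tile_size, w // tile_size
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            block = raster.pixels[
                r * tile_size : (r + 1) * tile_size,
                c * tile_size : (c + 1) * tile_size,
            ]
            tiles.append(
                LabeledImage(
                    pixels=block.copy(),
                    labels=raster.labels,
                    source=f"{raster.source}#{r}_{c}",
                )
            )
    return TileGrid(tile_size=tile_size, n_rows=n_rows, n_cols=n_cols, tiles=tiles)
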