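"""The 46-descriptor color feature vector and feature-table assembly.

Each tile is summarised by order statistics (max, mean, median, min) and
the population standard deviation of nine color channels — R, G, B
(original image), Y, Cb, Cr (BT.601 full-range conversion), S, V (HSV)
and L (HSL) — plus the arithmetic mean hue of chromatic pixels.
That gives 9 channels x 5 statistics + 1 hue mean = 46 descriptors.

Units follow each channel's natural scale: 0-255 for R, G, B, Y, Cb,
Cr; 0-1 for S, V, L; degrees for the hue mean. The mixed scales are
recorded in the CSV header and neutralised by the classifier's input
standardisation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import colorspace
from .datatypes import LabeledImage
from .imaging import tile_image

__all__ = [
    "FEATURE_NAMES",
    "LABEL_COLUMNS",
    "channel_stats",
    "extract_features",
    "build_feature_table",
    "write_feature_table",
    "read_feature_table",
]

_STATS = ("max", "mean", "median", "min", "std")
_PRE_HUE_CHANNELS = ("R", "G", "B", "Y", "Cb", "Cr")
_POST_HUE_CHANNELS = ("S", "V", "L")

#: Canonical descriptor order; fixed so model and report schemas are stable.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"{ch}_{st}" for ch in _PRE_HUE_CHANNELS for st in _STATS)
    + ("H_mean",)
    + tuple(f"{ch}_{st}" for ch in _POST_HUE_CHANNELS for st in _STATS)
)
assert len(FEATURE_NAMES) == 46

LABEL_COLUMNS = ("sample_id", "juice_content", "saccharification")
PROVENANCE_COLUMN = "provenance"


def channel_stats(values) -> tuple[float, float, float, float, float]:
    """(max, mean, median, min, population std) of one channel.

    The standard deviation uses the population denominator N — a tile's
    pixels are the entire population of interest, not a sample. The
    median of an even count is the mean of the two central order
    statistics.
    """
    arr = np.asarray(list(values) if not hasattr(values, "ndim") else values,
                     dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("channel_stats requires a non-empty collection")
    return (
        float(arr.max()),
        float(arr.mean()),
        float(np.median(arr)),
        float(arr.min()),
        float(arr.std()),  # ddof=0
    )


def _stats_block(channel: np.ndarray) -> list[float]:
    return [
        float(channel.max()),
        float(channel.mean()),
        float(np.median(channel)),
        float(channel.min()),
        float(channel.std()),
    ]


def _hist_stats(values: np.ndarray, n_bins: int, scale: float) -> list[float]:
    """Exact 5-stat block for small-integer data via its histogram.

    ``values`` are non-negative integers < n_bins; reported statistics
    are those of values * scale. Two-pass mean/variance over the 256 (or
    511) histogram bins reproduces the direct computation to float64
    precision at a fraction of the cost of sorting the pixels.
    """
    counts = np.bincount(values, minlength=n_bins)
    n = values.size
    levels = np.arange(n_bins, dtype=np.float64)
    mean = float(counts @ levels) / n
    var = float(counts @ (levels - mean) ** 2) / n
    nonzero = np.flatnonzero(counts)
    cum = np.cumsum(counts)
    lo, hi = (n - 1) // 2, n // 2  # central order statistics (0-based)
    median = (np.searchsorted(cum, lo + 1) + np.searchsorted(cum, hi + 1)) / 2.0
    return [
        float(nonzero[-1]) * scale,
        mean * scale,
        float(median) * scale,
        float(nonzero[0]) * scale,
        float(np.sqrt(var)) * scale,
    ]


def extract_features(tile: LabeledImage | np.ndarray, circular_hue: bool = False) -> pd.Series:
    """Compute the 46-descriptor vector of one RGB tile.

    The hue mean is the arithmetic mean over chromatic pixels (s > 0);
    powders occupy a narrow hue arc without wrap-around, so a circular
    mean (``circular_hue=True``) gives the same answer there and is kept
    only as an option. A fully achromatic tile reports H_mean = 0.

    Statistics of the integer-valued channels (R, G, B and, through the
    pixelwise max/min, V and L) are computed exactly from 8-bit
    histograms; Y, Cb, Cr, S and the hue go through the ``colorspace``
    formulas in float.
    """
    pix = tile.pixels if isinstance(tile, LabeledImage) else np.asarray(tile)
    if pix.size == 0:
        raise ValueError("cannot extract features from an empty tile")
    if pix.ndim == 3:
        pix = pix.reshape(-1, 3)
    if pix.shape[-1] != 3:
        raise ValueError(f"expected RGB pixels, got shape {pix.shape}")
    flat = np.ascontiguousarray(pix)
    rgb = flat.astype(np.float64)

    values: list[float] = []
    for ch in range(3):  # R, G, B on 0-255
        values += _hist_stats(flat[:, ch], 256, 1.0)

    ycbcr = colorspace.rgb_to_ycbcr(rgb)
    for ch in range(3):
        values += _stats_block(ycbcr[:, ch])

    # HSV/HSL via shared integer max/min per pixel: V = max/255 and
    # L = (max + min)/510 are exact histogram statistics.
    mx = flat.max(axis=1)
    mn = flat.min(axis=1)
    chroma = (mx - mn).astype(np.float64)
    chromatic = chroma > 0

    if not chromatic.any():
        h_mean = 0.0
    else:
        sub = rgb[chromatic]
        hue = colorspace._hue_degrees(
            sub, mx[chromatic].astype(np.float64), chroma[chromatic]
        )
        if circular_hue:
            rad = np.deg2rad(hue)
            h_mean = float(
                np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0
            )
        else:
            h_mean = float(hue.mean())
    values.append(h_mean)

    mx_f = mx.astype(np.float64)
    sat = np.divide(chroma, mx_f, out=np.zeros_like(chroma), where=mx > 0)
    values += _stats_block(sat)
    values += _hist_stats(mx, 256, 1.0 / 255.0)
    values += _hist_stats(mx.astype(np.int32) + mn, 511, 1.0 / 510.0)
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=np.float64)


def build_feature_table(
    images: Iterable[LabeledImage],
    tile_size: int | None = None,
) -> pd.DataFrame:
    """One feature row per tile, with labels and provenance.

    If ``tile_size`` is given each image is tiled first and every tile
    contributes a row; otherwise each image is treated as a single tile.
    Row order is deterministic: image order, then row-major tile order.
    """
    rows = []
    index = []
    labels = []
    for i, img in enumerate(images):
        if img.labels is None:
            raise ValueError(
                f"image {i} ({img.source or 'unnamed'}) has no labels; "
                "every image must carry the three class labels"
            )
        tiles = tile_image(img, tile_size).tiles if tile_size else [img]
        for tile in tiles:
            rows.append(extract_features(tile))
            index.append(tile.source or f"image_{i}")
            labels.append(
                (img.labels.sample_id, img.labels.juice_content, img.labels.saccharification)
            )
    if not rows:
        raise ValueError("no images supplied")
    table = pd.DataFrame(rows).reset_index(drop=True)
    lab = pd.DataFrame(labels, columns=list(LABEL_COLUMNS))
    table = pd.concat([table, lab], axis=1)
    table[PROVENANCE_COLUMN] = index
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the table as RFC-4180 CSV with '.' decimal separator."""
    table.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table at {path} lacks columns: {missing[:5]} ...")
    return table


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """The n x 46 float matrix in canonical column order."""
    return table.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
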