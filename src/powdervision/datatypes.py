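"""Shared container types for labeled powder imagery.

A powder sample is identified by three categorical labels: the sample
number (1-6), the dry-juice content of the powder (30, 40 or 50 percent,
the rest being maltodextrin carrier) and the saccharification level of
the carrier ("L" = DE 12, "H" = DE 26).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

JUICE_LEVELS = (30, 40, 50)
SACCHARIFICATION_LEVELS = ("L", "H")
SAMPLE_IDS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class PowderLabels:
    """The three categorical labels of one powder sample."""

    sample_id: int
    juice_content: int
    saccharification: str

    def __post_init__(self) -> None:
        if self.sample_id not in SAMPLE_IDS:
            raise ValueError(f"sample_id must be in {SAMPLE_IDS}, got {self.sample_id}")
        if self.juice_content not in JUICE_LEVELS:
            raise ValueError(
                f"juice_content must be in {JUICE_LEVELS}, got {self.juice_content}"
            )
        if self.saccharification not in SACCHARIFICATION_LEVELS:
            raise ValueError(
                "saccharification must be 'L' or 'H', "
                f"got {self.saccharification!r}"
            )


@dataclass
class LabeledImage:
    """An 8-bit RGB raster plus its powder labels.

    ``pixels`` is an H x W x 3 ``uint8`` array in R, G, B channel order.
    ``labels`` may be ``None`` for rasters read before a manifest lookup.
    ``source`` records provenance (file path or generator tag).
    """

    pixels: np.ndarray
    labels: PowderLabels | None = None
    source: str = ""

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if pix.ndim != 3 or pix.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {pix.shape}")
        if pix.dtype != np.uint8:
            if np.issubdtype(pix.dtype, np.integer) and pix.min() >= 0 and pix.max() <= 255:
                pix = pix.astype(np.uint8)
            else:
                raise ValueError(
                    f"pixels must be 8-bit integers in [0, 255], got dtype {pix.dtype}"
                )
        self.pixels = pix

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class TileGrid:
    """Square tiles cut from one parent raster, row-major from top-left."""

    tile_size: int
    n_rows: int
    n_cols: int
    tiles: list[LabeledImage] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tiles)
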