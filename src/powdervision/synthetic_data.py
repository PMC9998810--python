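"""Synthetic powder-tile generator.

The study photographs are not available, so downstream stages are
exercised on synthetic tiles that reproduce the statistical structure
the analysis relies on: six classes spanning the full factorial design
{30, 40, 50}% dry-juice content x {L, H} carrier saccharification, whose
mean color varies monotonically with juice content (the anthocyanin
"dyeing force": more juice means redder, more saturated, darker powder)
and only weakly with saccharification level. Granular powder texture is
emulated with per-channel Gaussian pixel noise plus a sparse
multiplicative dark speckle standing in for grain shadows.

All outputs are pure functions of (spec, dimensions, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .datatypes import (
    JUICE_LEVELS,
    SACCHARIFICATION_LEVELS,
    LabeledImage,
    PowderLabels,
)

__all__ = [
    "PowderClassSpec",
    "default_class_specs",
    "generate_tile",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class PowderClassSpec:
    """Color and texture parameters of one powder class.

    ``base_rgb`` is the mean pixel color; ``channel_sd`` the per-channel
    Gaussian noise scale; ``speckle_fraction`` the share of pixels
    replaced by darker grain pixels, obtained by multiplying all three
    channels by ``speckle_darkening``.
    """

    sample_id: int
    juice_content: int
    saccharification: str
    base_rgb: tuple[float, float, float]
    channel_sd: float = 8.0
    speckle_fraction: float = 0.06
    speckle_darkening: float = 0.75

    def __post_init__(self) -> None:
        if self.juice_content not in JUICE_LEVELS:
            raise ValueError(f"juice_content must be in {JUICE_LEVELS}")
        if self.saccharification not in SACCHARIFICATION_LEVELS:
            raise ValueError("saccharification must be 'L' or 'H'")
        if any(not 0 <= c <= 255 for c in self.base_rgb):
            raise ValueError("base_rgb channels must lie in [0, 255]")
        if self.channel_sd < 0:
            raise ValueError("channel_sd must be non-negative")
        if not 0 <= self.speckle_fraction <= 1:
            raise ValueError("speckle_fraction must lie in [0, 1]")
        if not 0 < self.speckle_darkening <= 1:
            raise ValueError("speckle_darkening must lie in (0, 1]")

    @property
    def labels(self) -> PowderLabels:
        return PowderLabels(self.sample_id, self.juice_content, self.saccharification)


# Mean colors per juice level for the low-saccharification (DE 12) carrier.
# Higher juice content -> more anthocyanin -> redder hue relative to the
# white maltodextrin bulk: the red channel rises while green/blue fall.
_BASE_L = {
    30: (196.0, 150.0, 158.0),
    40: (212.0, 128.0, 143.0),
    50: (228.0, 104.0, 127.0),
}
# High saccharification (DE 26) shifts brightness slightly; the offset is
# deliberately small so L vs H is the hardest of the three distinctions.
_H_OFFSET = (4.0, 7.0, 6.0)


def default_class_specs(
    channel_sd: float = 8.0,
    speckle_fraction: float = 0.06,
    speckle_darkening: float = 0.75,
) -> list[PowderClassSpec]:
    """The six class specs of the full {30,40,50} x {L,H} design.

    Red-channel means increase strictly with juice content at either
    saccharification level; L and H at equal juice content differ by a
    small fixed brightness offset.
    """
    specs = []
    sample_id = 1
    for juice in JUICE_LEVELS:
        for sacch in SACCHARIFICATION_LEVELS:
            base = _BASE_L[juice]
            if sacch == "H":
                base = tuple(
                    min(255.0, c + d) for c, d in zip(base, _H_OFFSET)
                )
            specs.append(
                PowderClassSpec(
                    sample_id=sample_id,
                    juice_content=juice,
                    saccharification=sacch,
                    base_rgb=base,
                    channel_sd=channel_sd,
                    speckle_fraction=speckle_fraction,
                    speckle_darkening=speckle_darkening,
                )
            )
            sample_id += 1
    return specs


def uniform_class_specs(base_rgb=(210.0, 130.0, 140.0), **kwargs) -> list[PowderClassSpec]:
    """Degenerate control: all six classes share one mean color.

    With identical class colors the descriptors carry no label
    information and classifier accuracy should sit at chance level.
    """
    return [replace(s, base_rgb=tuple(base_rgb)) for s in default_class_specs(**kwargs)]


def generate_tile(
    spec: PowderClassSpec, height: int, width: int, seed: int
) -> LabeledImage:
    """Draw one synthetic powder tile.

    Per channel: pixel = clip(round(base + N(0, channel_sd))); a
    Bernoulli(speckle_fraction) mask then multiplies all three channels
    of the selected pixels by speckle_darkening. The same seed always
    reproduces the same raster bit-for-bit.
    """
    if height < 8 or width < 8:
        raise ValueError(f"tile dimensions must be >= 8, got {height}x{width}")
    rng = np.random.default_rng(seed)
    base = np.array(spec.base_rgb, dtype=np.float32)
    noise = rng.standard_normal((height, width, 3), dtype=np.float32)
    pix = base + np.float32(spec.channel_sd) * noise
    pix = np.clip(np.rint(pix), 0, 255)
    if spec.speckle_fraction > 0:
        mask = rng.random((height, width)) < spec.speckle_fraction
        pix[mask] *= spec.speckle_darkening
        pix = np.clip(np.rint(pix), 0, 255)
    return LabeledImage(
        pixels=pix.astype(np.uint8),
        labels=spec.labels,
        source=f"synthetic:s{spec.sample_id}:seed{seed}",
    )


def _tile_seeds(master_seed: int, n: int) -> np.ndarray:
    # One independent 31-bit seed per tile, reproducible from the master.
    return np.random.default_rng(master_seed).integers(0, 2**31, size=n)


def generate_dataset(
    n_tiles_per_class: int,
    height: int = 400,
    width: int = 400,
    seed: int = 0,
    specs: list[PowderClassSpec] | None = None,
) -> list[LabeledImage]:
    """Generate a balanced labeled tile set, class-blocked then index-ordered."""
    if n_tiles_per_class < 1:
        raise ValueError("n_tiles_per_class must be >= 1")
    if specs is None:
        specs = default_class_specs()
    seeds = _tile_seeds(seed, len(specs) * n_tiles_per_class)
    images = []
    k = 0
    for spec in specs:
        for _ in range(n_tiles_per_class):
            images.append(generate_tile(spec, height, width, int(seeds[k])))
            k += 1
    return images


def write_dataset(images: list[LabeledImage], outdir: str | Path) -> Path:
    """Write tiles as 8-bit RGB PNGs plus a labels manifest CSV.

    Returns the manifest path. The manifest columns are image_path,
    sample_id, juice_content, saccharification; paths are relative to
    the manifest's directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "sample_id", "juice_content", "saccharification"])
        for i, img in enumerate(images):
            if img.labels is None:
                raise ValueError(f"image {i} ({img.source!r}) has no labels")
            name = f"tile_{i:05d}_s{img.labels.sample_id}.png"
            Image.fromarray(img.pixels, mode="RGB").save(outdir / name)
            writer.writerow(
                [
                    name,
                    img.labels.sample_id,
                    img.labels.juice_content,
                    img.labels.saccharification,
                ]
            )
    return manifest
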