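"""RGB to YCbCr / HSV / HSL conversions used by the descriptor set.

All functions are vectorised: they accept an array of shape ``(..., 3)``
(or any sequence convertible to one) whose last axis holds R, G, B
channel intensities on the 0-255 scale, and return an array of the same
shape. Conversions are computed in floating point; quantisation happens
only when descriptors are reported.

Conventions
-----------
* YCbCr uses the ITU-R BT.601 full-range matrix (the JPEG convention),
  so white maps to (255, 128, 128) and neutral grays to Cb = Cr = 128.
  The matrix is a module constant; the studio-range variant can be
  swapped in through :func:`rgb_to_ycbcr`'s ``matrix`` argument.
* Hue is reported in degrees in [0, 360) and set to 0 for achromatic
  pixels. HSV and HSL share the same hue.
* Saturation, value (brightness) and lightness live on [0, 1].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rgb_to_ycbcr",
    "rgb_to_hsv",
    "rgb_to_hsl",
    "hsv_to_rgb",
    "YCBCR_MATRICES",
]

# Each entry: (3x3 matrix applied to full-range RGB, offset added afterwards).
YCBCR_MATRICES = {
    "bt601-full": (
        np.array(
            [
                [0.299, 0.587, 0.114],
                [-0.168736, -0.331264, 0.5],
                [0.5, -0.418688, -0.081312],
            ]
        ),
        np.array([0.0, 128.0, 128.0]),
    ),
    # Studio-range BT.601: Y in [16, 235], chroma in [16, 240].
    "bt601-studio": (
        np.array(
            [
                [65.481, 128.553, 24.966],
                [-37.797, -74.203, 112.0],
                [112.0, -93.786, -18.214],
            ]
        )
        / 255.0,
        np.array([16.0, 128.0, 128.0]),
    ),
}


def _as_rgb(rgb) -> np.ndarray:
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected trailing axis of size 3, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    return arr


def rgb_to_ycbcr(rgb, matrix: str = "bt601-full") -> np.ndarray:
    """Convert 0-255 RGB to 0-255 YCbCr (luma, blue- and red-difference).

    Results are clamped to [0, 255]; with the full-range matrix only a
    half-unit excursion at saturated primaries is ever clipped.
    """
    arr = _as_rgb(rgb)
    try:
        mat, offset = YCBCR_MATRICES[matrix]
    except KeyError:
        raise ValueError(
            f"unknown YCbCr matrix {matrix!r}; choose from {sorted(YCBCR_MATRICES)}"
        ) from None
    out = arr @ mat.T + offset
    return np.clip(out, 0.0, 255.0)


def _hue_degrees(arr: np.ndarray, mx: np.ndarray, chroma: np.ndarray) -> np.ndarray:
    """Shared hexcone hue, degrees in [0, 360); 0 where chroma == 0."""
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = np.mod((g - b) / chroma, 6.0)
        hg = (b - r) / chroma + 2.0
        hb = (r - g) / chroma + 4.0
    h = np.where(mx == r, hr, np.where(mx == g, hg, hb))
    h = np.where(chroma == 0, 0.0, h) * 60.0
    return np.mod(h, 360.0)


def rgb_to_hsv(rgb) -> np.ndarray:
    """Convert 0-255 RGB to (hue degrees, saturation 0-1, value 0-1)."""
    arr = _as_rgb(rgb) / 255.0
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    chroma = mx - mn
    h = _hue_degrees(arr, mx, chroma)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(mx == 0, 0.0, chroma / np.where(mx == 0, 1.0, mx))
    return np.stack([h, s, mx], axis=-1)


def rgb_to_hsl(rgb) -> np.ndarray:
    """Convert 0-255 RGB to (hue degrees, saturation 0-1, lightness 0-1).

    Hue is identical to the HSV hue; saturation follows the bi-hexcone
    model, s = chroma / (1 - |2l - 1|), zero for achromatic pixels.
    """
    arr = _as_rgb(rgb) / 255.0
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    chroma = mx - mn
    h = _hue_degrees(arr, mx, chroma)
    l = (mx + mn) / 2.0
    denom = 1.0 - np.abs(2.0 * l - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(chroma == 0, 0.0, chroma / np.where(denom == 0, 1.0, denom))
    return np.stack([h, s, l], axis=-1)


def hsv_to_rgb(hsv) -> np.ndarray:
    """Inverse hexcone transform; returns 0-255 RGB floats."""
    arr = np.asarray(hsv, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected trailing axis of size 3, got shape {arr.shape}")
    h, s, v = arr[..., 0], arr[..., 1], arr[..., 2]
    hp = np.mod(h, 360.0) / 60.0
    c = v * s
    x = c * (1.0 - np.abs(np.mod(hp, 2.0) - 1.0))
    m = v - c
    z = np.zeros_like(c)
    sector = np.floor(hp).astype(int) % 6
    r = np.choose(sector, [c, x, z, z, x, c])
    g = np.choose(sector, [x, c, c, x, z, z])
    b = np.choose(sector, [z, z, x, c, c, x])
    return (np.stack([r, g, b], axis=-1) + m[..., None]) * 255.0
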