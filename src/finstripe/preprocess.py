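"""Image loading, background masking and (optional) color normalization.

The pipeline convention is that background pixels carry a sentinel color
(pure magenta, ``(255, 0, 255)``); every downstream statistic is computed
over the foreground mask only, so the sentinel never leaks into features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import SegmentationError

#: Background sentinel color. Synthetic images never place it on the body.
SENTINEL: tuple[int, int, int] = (255, 0, 255)


@dataclass
class MaskedImage:
    """An RGB raster plus a boolean foreground mask.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    mask : (H, W) bool array, True where the pixel belongs to the subject
    sentinel : RGB triple marking background pixels
    """

    pixels: np.ndarray
    mask: np.ndarray
    sentinel: tuple[int, int, int] = SENTINEL

    def __post_init__(self) -> None:
        self.pixels = np.ascontiguousarray(self.pixels, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) raster")
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape does not match raster shape")

    @classmethod
    def from_raster(cls, pixels: np.ndarray,
                    sentinel: tuple[int, int, int] = SENTINEL,
                    tolerance: int = 0) -> "MaskedImage":
        """Derive the mask from sentinel (in)equality.

        ``tolerance`` is an L-infinity radius around the sentinel within
        which a pixel still counts as background; lossless fixtures use 0,
        JPEG-compressed images need a few intensity units.
        """
        pixels = np.ascontiguousarray(pixels, dtype=np.uint8)
        diff = np.abs(pixels.astype(np.int16) - np.asarray(sentinel, dtype=np.int16))
        mask = diff.max(axis=2) > tolerance
        return cls(pixels=pixels, mask=mask, sentinel=sentinel)

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    @property
    def degenerate(self) -> bool:
        """True when no foreground pixel exists; feature ops will refuse it."""
        return self.n_foreground == 0

    def foreground_pixels(self) -> np.ndarray:
        """(n, 3) uint8 array of foreground pixels in scanline order."""
        return self.pixels[self.mask]

    def save(self, path: str | Path) -> None:
        """Write as PNG; background pixels are forced to the exact sentinel."""
        out = self.pixels.copy()
        out[~self.mask] = self.sentinel
        Image.fromarray(out, mode="RGB").save(Path(path), format="PNG")


def load_image(path: str | Path, tolerance: int | None = None) -> MaskedImage:
    """Load a PNG/JPEG whose background is already the sentinel color.

    ``tolerance`` defaults to 0 for lossless formats and 8 for JPEG, where
    compression perturbs the sentinel slightly.
    """
    path = Path(path)
    img = Image.open(path).convert("RGB")
    if tolerance is None:
        tolerance = 8 if path.suffix.lower() in {".jpg", ".jpeg"} else 0
    masked = MaskedImage.from_raster(np.asarray(img), tolerance=tolerance)
    if masked.degenerate:
        warnings.warn(f"{path.name}: no foreground pixels (all-sentinel image)",
                      stacklevel=2)
    return masked


def _threshold_segmenter(pixels: np.ndarray, rect: tuple[int, int, int, int],
                         color_threshold: float = 30.0) -> np.ndarray:
    """Border-seeded color-distance segmentation.

    The background color is estimated from the one-pixel frame of the image
    (assumed to lie outside the subject); pixels within ``color_threshold``
    Euclidean RGB distance of it are background. Everything outside ``rect``
    is background regardless.
    """
    border = np.concatenate([pixels[0], pixels[-1], pixels[:, 0], pixels[:, -1]])
    bg_color = np.median(border.astype(float), axis=0)
    dist = np.linalg.norm(pixels.astype(float) - bg_color, axis=2)
    mask = dist > color_threshold
    x0, y0, x1, y1 = rect
    keep = np.zeros_like(mask)
    keep[y0:y1, x0:x1] = True
    return mask & keep


SEGMENTERS = {"threshold": _threshold_segmenter}


def remove_background(pixels: np.ndarray,
                      rect: tuple[int, int, int, int] | None = None,
                      method: str = "threshold",
                      sentinel: tuple[int, int, int] = SENTINEL,
                      **kwargs) -> MaskedImage:
    """Estimate the subject mask and replace background with the sentinel.

    The segmentation algorithm is pluggable (register in ``SEGMENTERS``);
    the contract is only that the majority of the true subject is preserved.
    ``rect`` is an (x0, y0, x1, y1) bounding box known to contain the
    subject; it defaults to the full image.
    """
    pixels = np.ascontiguousarray(pixels, dtype=np.uint8)
    h, w = pixels.shape[:2]
    if rect is None:
        rect = (0, 0, w, h)
    x0, y0, x1, y1 = rect
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError("rect outside image bounds")

    # Input already sentinel-masked (some background, all exactly sentinel):
    # identity, which also makes the operation idempotent on its own output.
    already = MaskedImage.from_raster(pixels, sentinel=sentinel)
    if already.n_foreground and not already.mask.all():
        return already

    if method not in SEGMENTERS:
        raise ValueError(f"unknown segmentation method {method!r}")
    mask = SEGMENTERS[method](pixels, rect, **kwargs)
    if not mask.any():
        raise SegmentationError("segmentation failed: empty foreground")
    out = pixels.copy()
    out[~mask] = sentinel
    return MaskedImage(pixels=out, mask=mask, sentinel=sentinel)


def normalize_colors(image: MaskedImage) -> MaskedImage:
    """Per-channel linear stretch of foreground intensities to [0, 255].

    Mirrors ImageMagick's ``-normalize`` in spirit. OFF by default in the
    pipeline: image-wise normalization makes colors inconsistent across
    photographs and measurably hurts classification, so it exists only as
    an explicit opt-in.
    """
    out = image.pixels.copy()
    fg = image.mask
    for ch in range(3):
        vals = image.pixels[..., ch][fg]
        lo, hi = int(vals.min()), int(vals.max())
        if hi == lo:
            warnings.warn(f"channel {ch} constant over foreground; left unchanged",
                          stacklevel=2)
            continue
        stretched = (image.pixels[..., ch].astype(float) - lo) * (255.0 / (hi - lo))
        out[..., ch] = np.where(fg, np.clip(np.round(stretched), 0, 255),
                                out[..., ch]).astype(np.uint8)
    # keep background on the exact sentinel
    out[~fg] = image.sentinel
    return MaskedImage(pixels=out, mask=fg.copy(), sentinel=image.sentinel)
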