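"""The feature extractor: one masked image -> an ordered 48-element summary.

The 48 features are, in fixed order:

* 42 color features — the 7 most frequent quantized colors, each as
  RGB and HSV (all six channels scaled to [0, 1]);
* the color ratio (pixel count of the most frequent color over the second
  most frequent);
* Shannon entropy of the 8-bit grayscale foreground histogram, in bits;
* normalized Canny edge-pixel count (edge pixels / foreground pixels),
  which compensates for larger fish carrying longer edges;
* counts of straight horizontal / diagonal / vertical line segments from a
  probabilistic Hough transform binned at 45° granularity.

Background (sentinel-colored) pixels never contribute to any statistic.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny
from skimage.transform import probabilistic_hough_line
from sklearn.cluster import KMeans

from .errors import DegeneratePaletteError, EmptyForegroundError
from .preprocess import MaskedImage

N_PALETTE = 7
_CHANNELS = ("r", "g", "b", "h", "s", "v")

#: The 48 canonical feature names, in extraction order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"Color_{i}_{ch}" for i in range(N_PALETTE) for ch in _CHANNELS]
    + ["Color_ratio", "Entropy", "Edge_count",
       "X0_deg_lines", "X45_deg_lines", "X90_deg_lines"]
)

COLOR_FEATURE_NAMES: tuple[str, ...] = FEATURE_NAMES[: 6 * N_PALETTE]


@dataclass
class PaletteEntry:
    rgb: tuple[float, float, float]      # 0..255 scale
    hsv: tuple[float, float, float]      # each in [0, 1]
    pixel_count: int


@dataclass
class Palette:
    """Quantized foreground palette, entries descending by pixel count."""

    entries: list[PaletteEntry]

    def __post_init__(self) -> None:
        counts = [e.pixel_count for e in self.entries]
        if counts != sorted(counts, reverse=True):
            raise ValueError("palette entries must be descending by pixel count")

    @property
    def counts(self) -> list[int]:
        return [e.pixel_count for e in self.entries]


@dataclass
class HoughConfig:
    """Parameters of the edge and line stages, at fixture scale."""

    canny_sigma: float = 1.0
    canny_low: float = 50.0
    canny_high: float = 150.0
    threshold: int = 10
    line_length: int = 15
    line_gap: int = 3


@dataclass
class FeatureConfig:
    n_colors: int = N_PALETTE
    hough: HoughConfig = field(default_factory=HoughConfig)


@dataclass
class FeatureVector:
    """The ordered named 48-element summary of one image."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(f"expected {len(self.names)} features, "
                             f"got {self.values.shape}")

    def __len__(self) -> int:
        return len(self.values)

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def _require_foreground(image: MaskedImage) -> None:
    if image.degenerate:
        raise EmptyForegroundError("empty foreground")


def _rgb_to_hsv01(rgb: np.ndarray) -> tuple[float, float, float]:
    r, g, b = (float(c) / 255.0 for c in rgb)
    return colorsys.rgb_to_hsv(r, g, b)


def quantize_palette(image: MaskedImage, k: int = N_PALETTE,
                     seed: int = 0) -> Palette:
    """Quantize foreground pixels into the k best representative colors.

    Optimum-palette-generation style: k-means in RGB space over foreground
    pixels (sorted lexicographically first, so the result depends only on
    the pixel multiset, not on positions). If the image holds fewer than k
    distinct colors, the distinct colors are emitted exactly and the
    remaining slots are padded with the last color at count 0, keeping the
    feature vector length fixed.
    """
    _require_foreground(image)
    fg = image.foreground_pixels().astype(float)
    uniq, counts = np.unique(image.foreground_pixels(), axis=0, return_counts=True)

    if len(uniq) <= k:
        order = np.lexsort((uniq[:, 2], uniq[:, 1], uniq[:, 0], -counts))
        entries = [
            PaletteEntry(rgb=tuple(uniq[i].astype(float)),
                         hsv=_rgb_to_hsv01(uniq[i]),
                         pixel_count=int(counts[i]))
            for i in order
        ]
        while len(entries) < k:
            last = entries[-1]
            entries.append(PaletteEntry(rgb=last.rgb, hsv=last.hsv, pixel_count=0))
        return Palette(entries=entries)

    # position invariance: cluster the sorted pixel multiset
    fg = fg[np.lexsort((fg[:, 2], fg[:, 1], fg[:, 0]))]
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(fg)
    sizes = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    entries = [
        PaletteEntry(rgb=tuple(km.cluster_centers_[i]),
                     hsv=_rgb_to_hsv01(np.clip(km.cluster_centers_[i], 0, 255)),
                     pixel_count=int(sizes[i]))
        for i in order
    ]
    return Palette(entries=entries)


def color_ratio(palette: Palette) -> float:
    """Pixel count of the most frequent color over the second most frequent.

    E.g. 600 brown and 500 blue pixels give 1.2. Intended as a crude
    descriptor of how dominant the base coloration is over the stripes.
    """
    counts = palette.counts
    if len(counts) < 2 or counts[1] == 0:
        raise DegeneratePaletteError("degenerate palette: no second color")
    return counts[0] / counts[1]


def to_grayscale(image: MaskedImage) -> np.ndarray:
    """8-bit grayscale raster via ITU-R BT.601 luma weights."""
    w = np.array([0.299, 0.587, 0.114])
    gray = image.pixels.astype(float) @ w
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def gray_histogram(image: MaskedImage) -> np.ndarray:
    """256 fractions; p[i] = fraction of foreground pixels at intensity i."""
    _require_foreground(image)
    gray = to_grayscale(image)[image.mask]
    counts = np.bincount(gray, minlength=256)
    return counts / counts.sum()


def entropy(image: MaskedImage) -> float:
    """Shannon entropy (bits) of the foreground grayscale histogram.

    A rough measure of image complexity: 0 for a flat single-intensity
    body, up to 8 bits for a uniform spread over all 256 intensities.
    """
    p = gray_histogram(image)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def edge_map(image: MaskedImage, config: HoughConfig | None = None) -> np.ndarray:
    """Boolean Canny edge map of the grayscale image, restricted to foreground.

    Background pixels are replaced by the sentinel's gray level before
    filtering so that whatever sits behind the mask can never leak into
    the edge statistics through the Gaussian smoothing.
    """
    config = config or HoughConfig()
    gray = to_grayscale(image)
    sentinel_gray = np.uint8(round(
        0.299 * image.sentinel[0] + 0.587 * image.sentinel[1]
        + 0.114 * image.sentinel[2]))
    gray[~image.mask] = sentinel_gray
    edges = canny(gray, sigma=config.canny_sigma,
                  low_threshold=config.canny_low, high_threshold=config.canny_high)
    return edges & image.mask


def edge_pixel_count(image: MaskedImage, config: HoughConfig | None = None) -> float:
    """Foreground Canny edge pixels divided by foreground pixel count.

    The normalization compensates for body size: edge length grows
    linearly with scale while area grows quadratically.
    """
    _require_foreground(image)
    return float(edge_map(image, config).sum()) / image.n_foreground


# Hough theta at 45° angular granularity (angles of line normals).
_HOUGH_THETA = np.deg2rad(np.array([-90.0, -45.0, 0.0, 45.0]))


def line_segments(image: MaskedImage, config: HoughConfig | None = None,
                  seed: int = 0) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Straight segments detected on the foreground edge map."""
    config = config or HoughConfig()
    edges = edge_map(image, config)
    return probabilistic_hough_line(
        edges, threshold=config.threshold, line_length=config.line_length,
        line_gap=config.line_gap, theta=_HOUGH_THETA,
        rng=np.random.default_rng(seed))


def line_features(image: MaskedImage, config: HoughConfig | None = None,
                  seed: int = 0) -> tuple[int, int, int]:
    """(n_horizontal, n_diagonal, n_vertical) straight-segment counts.

    Orientation bins at 45° granularity: within 22.5° of 0° is horizontal,
    within 22.5° of 90° is vertical, the rest (45°/135°) is diagonal.
    """
    n_h = n_d = n_v = 0
    for (x0, y0), (x1, y1) in line_segments(image, config, seed):
        ang = np.degrees(np.arctan2(y1 - y0, x1 - x0)) % 180.0
        if ang < 22.5 or ang >= 157.5:
            n_h += 1
        elif 67.5 <= ang < 112.5:
            n_v += 1
        else:
            n_d += 1
    return n_h, n_d, n_v


def extract_features(image: MaskedImage, config: FeatureConfig | None = None,
                     seed: int = 0) -> FeatureVector:
    """Compute the full ordered 48-feature summary of one image.

    A degenerate color ratio (single-color image) is recorded as NaN
    rather than aborting the whole vector.
    """
    _require_foreground(image)
    config = config or FeatureConfig()
    palette = quantize_palette(image, k=config.n_colors, seed=seed)

    values: list[float] = []
    for e in palette.entries:
        values.extend([c / 255.0 for c in e.rgb])
        values.extend(e.hsv)
    try:
        values.append(color_ratio(palette))
    except DegeneratePaletteError:
        values.append(np.nan)
    values.append(entropy(image))
    values.append(edge_pixel_count(image, config.hough))
    n_h, n_d, n_v = line_features(image, config.hough, seed=seed)
    values.extend([n_h, n_d, n_v])
    return FeatureVector(values=np.asarray(values, dtype=float))
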