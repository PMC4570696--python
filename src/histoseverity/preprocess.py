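"""Image loading, illumination normalization, and cutout extraction.

Brightfield histology slides always contain empty white regions (no
tissue), whose pixel values pile up as a peak on the right side of the
intensity histogram.  Illumination differences between slides shift that
peak, so normalization adds a constant intensity bias chosen to align the
white peak of each image with the white peak of a chosen reference image
— the bias maximizes the correlation between the two histograms inside a
window around the reference peak.  Pixels are clipped (not rescaled)
after biasing.

Intensities are handled as floats in [0, 1] regardless of the source bit
depth (8- and 16-bit integer images are divided by their maximal code
value).  Color images are reduced to luminance with Rec. 601 weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "RawImage",
    "Cutout",
    "NoWhitePeakError",
    "load_image",
    "to_grayscale",
    "white_peak",
    "illumination_bias",
    "normalize_illumination",
    "extract_cutout",
]

REC601_WEIGHTS = np.array([0.299, 0.587, 0.114])


class NoWhitePeakError(ValueError):
    """Raised when an image has no detectable white-region histogram peak."""


@dataclass(frozen=True)
class RawImage:
    """A grayscale image with intensities in [0, 1]."""

    pixels: np.ndarray
    source_path: str = ""
    bias: float | None = None  # illumination bias already applied, if any

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("RawImage pixels must be 2-D")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Cutout:
    """A 512x512 block extracted from a RawImage."""

    pixels: np.ndarray
    origin_row: int = 0
    origin_col: int = 0
    bias_applied: float = 0.0
    cutout_id: str = ""

    SIZE = 512

    def __post_init__(self) -> None:
        if self.pixels.shape != (self.SIZE, self.SIZE):
            raise ValueError(f"cutout must be {self.SIZE}x{self.SIZE}, got {self.pixels.shape}")


def to_grayscale(image: np.ndarray, source_path: str = "") -> RawImage:
    """Convert an array (gray or RGB, any common bit depth) to [0, 1] gray.

    Integer inputs are scaled by their dtype's maximal code value; float
    inputs are assumed already in [0, 1] and clipped.  3-channel inputs
    are reduced with the Rec. 601 luminance weighting 0.299 R + 0.587 G +
    0.114 B.
    """
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(float) / scale
    else:
        arr = np.clip(arr.astype(float), 0.0, 1.0)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count {arr.shape[2]}; expected 1 or 3")
        arr = arr @ REC601_WEIGHTS
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    return RawImage(pixels=arr, source_path=source_path)


def load_image(path) -> RawImage:
    """Read a PNG/TIFF image from disk and convert to grayscale [0, 1]."""
    import imageio.v3 as iio

    return to_grayscale(iio.imread(path), source_path=str(path))


def _histogram(pixels: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    counts, edges = np.histogram(pixels, bins=bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def white_peak(image: RawImage, bins: int = 256, min_level: float = 0.25) -> float:
    """Intensity of the rightmost qualifying histogram peak (the white regions).

    A peak qualifies if it is a local maximum of the ``bins``-bin histogram
    over [0, 1], its height exceeds 1% of the modal bin height, and it lies
    at or above ``min_level`` — empty slide regions are bright, so a peak
    found only in the dark range means the image has no white area.
    Returns the peak's bin center.
    """
    if bins < 16:
        raise ValueError("bins must be >= 16")
    pixels = np.asarray(image.pixels if isinstance(image, RawImage) else image)
    if pixels.size == 0:
        raise ValueError("image is empty")
    counts, centers = _histogram(pixels, bins)
    # pad with zeros so peaks in the first/last bins are detectable
    padded = np.concatenate(([0], counts, [0])).astype(float)
    idx, _ = find_peaks(padded, height=0.01 * counts.max())
    idx -= 1
    idx = idx[centers[idx] >= min_level]
    if idx.size == 0:
        raise NoWhitePeakError("no qualifying white-region histogram peak found")
    return float(centers[idx[-1]])


def _bias_grid(search_range: tuple[float, float], step: float) -> np.ndarray:
    lo, hi = search_range
    if step <= 0 or hi < lo:
        raise ValueError(f"invalid search range {search_range} / step {step}")
    ks = np.arange(np.ceil(lo / step - 1e-9), np.floor(hi / step + 1e-9) + 1)
    if ks.size == 0:
        raise ValueError("empty bias search grid")
    return ks * step


def illumination_bias(
    image: RawImage,
    reference: RawImage,
    search_range: tuple[float, float] = (-0.2, 0.2),
    step: float = 1.0 / 512,
    bins: int = 256,
    window: float = 0.1,
    windowed: bool = True,
) -> float:
    """Intensity bias aligning the image's white peak with the reference's.

    Grid-searches biases in ``search_range`` at ``step`` resolution,
    maximizing the Pearson correlation between the histogram of the biased
    image and the reference histogram.  With ``windowed=True`` (default)
    the correlation is restricted to reference-peak +- ``window`` of the
    intensity range; ``windowed=False`` compares full [0, 1] histograms.
    Ties in correlation resolve to the smallest-magnitude bias.
    """
    ref_peak = white_peak(reference, bins=bins)
    white_peak(image, bins=bins)  # raises NoWhitePeakError if absent
    if windowed:
        lo = max(0.0, ref_peak - window)
        hi = min(1.0, ref_peak + window)
    else:
        lo, hi = 0.0, 1.0
    n_bins = max(4, int(round(bins * (hi - lo))))
    edges = np.linspace(lo, hi, n_bins + 1)
    ref_hist, _ = np.histogram(np.asarray(reference.pixels), bins=edges)
    img = np.asarray(image.pixels).ravel()

    grid = _bias_grid(search_range, step)
    order = np.argsort(np.abs(grid), kind="stable")  # prefer small |bias| on ties
    best_corr, best_bias = -np.inf, 0.0
    rh = ref_hist.astype(float)
    for k in order:
        beta = float(grid[k])
        h, _ = np.histogram(img + beta, bins=edges)
        h = h.astype(float)
        if h.std() == 0 or rh.std() == 0:
            corr = -np.inf
        else:
            corr = float(np.corrcoef(h, rh)[0, 1])
        if corr > best_corr + 1e-12:
            best_corr, best_bias = corr, beta
    return best_bias


def normalize_illumination(
    image: RawImage,
    reference: RawImage,
    **kwargs,
) -> RawImage:
    """Add the white-peak-aligning bias to the image and clip to [0, 1]."""
    beta = illumination_bias(image, reference, **kwargs)
    return RawImage(
        pixels=np.clip(image.pixels + beta, 0.0, 1.0),
        source_path=image.source_path,
        bias=beta,
    )


def extract_cutout(
    image: RawImage, origin_row: int, origin_col: int, cutout_id: str = ""
) -> Cutout:
    """Copy the 512x512 block whose top-left corner is (origin_row, origin_col)."""
    size = Cutout.SIZE
    if origin_row < 0 or origin_col < 0:
        raise IndexError("cutout origin must be non-negative")
    if origin_row + size > image.height or origin_col + size > image.width:
        raise IndexError(
            f"cutout at ({origin_row}, {origin_col}) exceeds image "
            f"{image.height}x{image.width}"
        )
    block = np.array(image.pixels[origin_row : origin_row + size, origin_col : origin_col + size])
    return Cutout(
        pixels=block,
        origin_row=origin_row,
        origin_col=origin_col,
        bias_applied=image.bias or 0.0,
        cutout_id=cutout_id,
    )
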