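"""Gabor filter bank construction, convolution, and orientation pooling.

The bank is a Cartesian product over four parameter lists — frequency
bandwidth ``b`` (octaves), cosine wavelength ``lambda`` (pixels), spatial
aspect ratio ``gamma`` and orientation ``theta`` (degrees) — with the phase
offset fixed at 0.  The default grid (6 orientations x 3 aspect ratios x
3 wavelengths x 4 bandwidths = 216 filters) targets the characteristic
scales of colonic histology: crypt-sized elongated structures and small
round inflammatory-cell spots.

A single filter is the real Gabor function

    g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * cos(2 pi x'/lambda + phi)

with x' = x cos(theta) + y sin(theta), y' = -x sin(theta) + y cos(theta).
The Gaussian width ``sigma`` is not free: it is derived from the
half-response spatial-frequency bandwidth via

    sigma/lambda = (1/pi) * (sqrt(ln 2)/2) * (2^b + 1) / (2^b - 1)

After convolving a cutout with every filter, responses are max-pooled
elementwise over the 6 orientations, which makes the downstream statistics
invariant to the arbitrary rotation of tissue in the slide.  The pooled
stack has one map per (b, lambda, gamma) triple — 36 for the default grid.

Kernel ordering is canonical and versioned: bandwidth is the outermost
axis, then wavelength, then aspect ratio, with orientation innermost, so
that feature indices are stable across runs and serializations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterator, Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage
from scipy.signal import fftconvolve

__all__ = [
    "GaborParams",
    "GaborKernel",
    "FilterBank",
    "ResponseStack",
    "DEFAULT_GRID",
    "bandwidth_to_sigma_ratio",
    "sigma_ratio_to_bandwidth",
    "make_kernel",
    "build_bank",
    "convolve_reflect",
    "apply_bank",
    "orientation_max",
    "pooled_response_stack",
]

_HALF_SQRT_LN2 = math.sqrt(math.log(2.0)) / 2.0

#: Ordering/layout version written into serialized banks.
BANK_LAYOUT_VERSION = "b-lambda-gamma-theta/1"

#: The default parameter grid (theta degrees, gamma, lambda pixels, b octaves).
DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "orientations": (0.0, 30.0, 60.0, 90.0, 120.0, 150.0),
    "aspect_ratios": (0.5, 2.0, 4.0),
    "wavelengths": (20.0, 30.0, 40.0),
    "bandwidths": (5.0, 10.0, 15.0, 20.0),
}


def bandwidth_to_sigma_ratio(b: float) -> float:
    """Return sigma/lambda for a half-response bandwidth of ``b`` octaves.

    The ratio decreases monotonically with ``b`` and approaches
    ``sqrt(ln 2) / (2 pi)`` ~ 0.13253 as ``b`` grows.
    """
    if b <= 0:
        raise ValueError(f"bandwidth must be positive, got {b}")
    return (1.0 / math.pi) * _HALF_SQRT_LN2 * (2.0**b + 1.0) / (2.0**b - 1.0)


def sigma_ratio_to_bandwidth(ratio: float) -> float:
    """Invert :func:`bandwidth_to_sigma_ratio`.

    Only ratios strictly above the pole ``sqrt(ln 2) / (2 pi)`` correspond
    to a finite bandwidth.
    """
    x = ratio * math.pi
    if x <= _HALF_SQRT_LN2:
        raise ValueError(
            f"sigma/lambda ratio {ratio} is at or below the pole "
            f"{_HALF_SQRT_LN2 / math.pi:.6f}; no finite bandwidth exists"
        )
    return math.log2((x + _HALF_SQRT_LN2) / (x - _HALF_SQRT_LN2))


@dataclass(frozen=True)
class GaborParams:
    """Parameters of one Gabor filter.

    ``sigma`` is derived from ``bandwidth`` and ``wavelength``; it is a
    property, not a free field.
    """

    wavelength: float  # lambda, pixels
    orientation: float  # theta, degrees in [0, 180)
    aspect_ratio: float  # gamma
    bandwidth: float  # b, octaves
    phase: float = 0.0  # phi, degrees

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.aspect_ratio <= 0:
            raise ValueError("aspect_ratio must be positive")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not 0 <= self.orientation < 180:
            raise ValueError("orientation must lie in [0, 180) degrees")

    @property
    def sigma(self) -> float:
        """Gaussian envelope std along x' (pixels)."""
        return bandwidth_to_sigma_ratio(self.bandwidth) * self.wavelength


@dataclass(frozen=True)
class GaborKernel:
    """A sampled Gabor filter: parameters plus the weight array."""

    params: GaborParams
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.weights.ndim != 2 or self.weights.shape[0] % 2 == 0:
            raise ValueError("kernel must be 2-D with odd side length")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel weights must be finite")


def make_kernel(params: GaborParams) -> GaborKernel:
    """Sample the Gabor function on an integer grid.

    Support extends to +-ceil(3 * max(sigma, sigma/gamma)) from the center:
    sigma/gamma is the envelope std along y', so aspect ratios below one
    widen the kernel.  Rows index y (downward), columns index x.
    """
    sigma = params.sigma
    half = math.ceil(3.0 * max(sigma, sigma / params.aspect_ratio))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    theta = math.radians(params.orientation)
    phi = math.radians(params.phase)
    xp = x * math.cos(theta) + y * math.sin(theta)
    yp = -x * math.sin(theta) + y * math.cos(theta)
    envelope = np.exp(-(xp**2 + params.aspect_ratio**2 * yp**2) / (2.0 * sigma**2))
    carrier = np.cos(2.0 * math.pi * xp / params.wavelength + phi)
    return GaborKernel(params=params, weights=envelope * carrier)


@dataclass(frozen=True)
class FilterBank:
    """An ordered Gabor filter bank over a parameter grid.

    Kernel order is canonical: for b in bandwidths, for lambda in
    wavelengths, for gamma in aspect_ratios, for theta in orientations.
    """

    kernels: tuple[GaborKernel, ...]
    grid: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def n_orientations(self) -> int:
        return len(self.grid["orientations"])

    @property
    def pooled_index(self) -> list[tuple[float, float, float]]:
        """(b, lambda, gamma) triple for each orientation-pooled map."""
        return [
            (b, lam, gam)
            for b in self.grid["bandwidths"]
            for lam in self.grid["wavelengths"]
            for gam in self.grid["aspect_ratios"]
        ]

    def iter_groups(self) -> Iterator[tuple[tuple[float, float, float], tuple[GaborKernel, ...]]]:
        """Yield ((b, lambda, gamma), kernels-over-orientation) groups in order."""
        k = self.n_orientations
        for i, triple in enumerate(self.pooled_index):
            yield triple, self.kernels[i * k : (i + 1) * k]

    def to_json(self) -> str:
        return json.dumps(
            {
                "layout_version": BANK_LAYOUT_VERSION,
                "grid": {key: list(vals) for key, vals in self.grid.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FilterBank":
        payload = json.loads(text)
        if payload.get("layout_version") != BANK_LAYOUT_VERSION:
            raise ValueError(
                f"unsupported bank layout version {payload.get('layout_version')!r}"
            )
        grid = payload["grid"]
        return build_bank(
            orientations=grid["orientations"],
            aspect_ratios=grid["aspect_ratios"],
            wavelengths=grid["wavelengths"],
            bandwidths=grid["bandwidths"],
        )


def build_bank(
    orientations: Sequence[float] | None = None,
    aspect_ratios: Sequence[float] | None = None,
    wavelengths: Sequence[float] | None = None,
    bandwidths: Sequence[float] | None = None,
    phase: float = 0.0,
) -> FilterBank:
    """Build the filter bank as the Cartesian product of the four lists.

    Defaults reproduce the 216-filter reference grid.
    """
    grid = {
        "orientations": tuple(
            float(v) for v in (orientations if orientations is not None else DEFAULT_GRID["orientations"])
        ),
        "aspect_ratios": tuple(
            float(v) for v in (aspect_ratios if aspect_ratios is not None else DEFAULT_GRID["aspect_ratios"])
        ),
        "wavelengths": tuple(
            float(v) for v in (wavelengths if wavelengths is not None else DEFAULT_GRID["wavelengths"])
        ),
        "bandwidths": tuple(
            float(v) for v in (bandwidths if bandwidths is not None else DEFAULT_GRID["bandwidths"])
        ),
    }
    for name, values in grid.items():
        if not values:
            raise ValueError(f"parameter list {name!r} must be nonempty")
    kernels = tuple(
        make_kernel(
            GaborParams(
                wavelength=lam,
                orientation=theta,
                aspect_ratio=gam,
                bandwidth=b,
                phase=phase,
            )
        )
        for b, lam, gam, theta in product(
            grid["bandwidths"], grid["wavelengths"], grid["aspect_ratios"], grid["orientations"]
        )
    )
    return FilterBank(kernels=kernels, grid=grid)


def convolve_reflect(image: np.ndarray, kernel: np.ndarray, method: str = "fft") -> np.ndarray:
    """True 2-D convolution with symmetric (edge-mirroring) boundary handling.

    ``method='fft'`` pads the image, runs an FFT convolution and crops;
    ``method='direct'`` uses spatial-domain convolution.  Both return an
    array the same shape as ``image`` and agree to float tolerance.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if method == "direct":
        return ndimage.convolve(image, kernel, mode="reflect")
    if method != "fft":
        raise ValueError(f"unknown method {method!r}")
    py, px = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((py, py), (px, px)), mode="symmetric")
    out = fftconvolve(padded, kernel, mode="same")
    return out[py : py + image.shape[0], px : px + image.shape[1]]


def _as_pixels(cutout) -> np.ndarray:
    pixels = getattr(cutout, "pixels", cutout)
    return np.asarray(pixels, dtype=float)


def apply_bank(
    cutout,
    bank: FilterBank,
    method: str = "fft",
    require_shape: tuple[int, int] | None = (512, 512),
) -> np.ndarray:
    """Convolve a cutout with every kernel; returns (n_kernels, H, W).

    Responses are signed convolution values.  Pass ``require_shape=None``
    to lift the 512x512 contract (e.g. for probes in analysis scripts).
    """
    pixels = _as_pixels(cutout)
    if require_shape is not None and pixels.shape != require_shape:
        raise ValueError(f"cutout shape {pixels.shape} != required {require_shape}")
    return np.stack([convolve_reflect(pixels, k.weights, method=method) for k in bank.kernels])


@dataclass(frozen=True)
class ResponseStack:
    """Orientation-pooled response maps: one per (b, lambda, gamma) triple."""

    maps: np.ndarray  # (n_triples, H, W)
    index: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.maps.ndim != 3 or self.maps.shape[0] != len(self.index):
            raise ValueError("maps must be (n_triples, H, W) matching index")

    def __len__(self) -> int:
        return self.maps.shape[0]


def orientation_max(responses: np.ndarray, bank: FilterBank) -> ResponseStack:
    """Elementwise max over orientations: signed responses, 6 -> 1 per triple.

    Pooling the signed maxima compensates the arbitrary initial orientation
    of tissue structures in the cutout.
    """
    responses = np.asarray(responses)
    if responses.shape[0] != len(bank):
        raise ValueError(
            f"got {responses.shape[0]} response maps for a bank of {len(bank)} kernels"
        )
    k = bank.n_orientations
    n_triples = len(bank) // k
    pooled = responses.reshape(n_triples, k, *responses.shape[1:]).max(axis=1)
    return ResponseStack(maps=pooled, index=tuple(bank.pooled_index))


class BankConvolver:
    """Reusable FFT convolver for one bank and image shape.

    Precomputes the spectrum of every kernel at a common FFT size, so
    applying the bank to each further image costs one forward transform
    of the image plus one inverse transform per kernel.  Results match
    :func:`convolve_reflect` (symmetric boundary) to float tolerance.
    """

    def __init__(self, bank: FilterBank, shape: tuple[int, int] = (512, 512)):
        self.bank = bank
        self.shape = shape
        self.pad = max(k.weights.shape[0] // 2 for k in bank.kernels)
        padded = (shape[0] + 2 * self.pad, shape[1] + 2 * self.pad)
        kmax = max(k.weights.shape[0] for k in bank.kernels)
        self.fshape = (
            sp_fft.next_fast_len(padded[0] + kmax - 1),
            sp_fft.next_fast_len(padded[1] + kmax - 1),
        )
        self._spectra = [
            sp_fft.rfft2(k.weights, s=self.fshape) for k in bank.kernels
        ]

    def _image_spectrum(self, pixels: np.ndarray) -> np.ndarray:
        padded = np.pad(pixels, self.pad, mode="symmetric")
        return sp_fft.rfft2(padded, s=self.fshape)

    def _one(self, img_f: np.ndarray, i: int) -> np.ndarray:
        full = sp_fft.irfft2(img_f * self._spectra[i], s=self.fshape)
        half = self.bank.kernels[i].weights.shape[0] // 2
        r0 = half + self.pad
        c0 = half + self.pad
        return full[r0 : r0 + self.shape[0], c0 : c0 + self.shape[1]]

    def apply(self, cutout) -> np.ndarray:
        """All per-kernel response maps, shape (n_kernels, H, W)."""
        pixels = _as_pixels(cutout)
        if pixels.shape != self.shape:
            raise ValueError(f"cutout shape {pixels.shape} != convolver shape {self.shape}")
        img_f = self._image_spectrum(pixels)
        return np.stack([self._one(img_f, i) for i in range(len(self.bank))])

    def pooled(self, cutout) -> ResponseStack:
        """Orientation-pooled response stack, streaming one group at a time."""
        pixels = _as_pixels(cutout)
        if pixels.shape != self.shape:
            raise ValueError(f"cutout shape {pixels.shape} != convolver shape {self.shape}")
        img_f = self._image_spectrum(pixels)
        k = self.bank.n_orientations
        pooled = []
        for g in range(len(self.bank) // k):
            group = np.stack([self._one(img_f, g * k + j) for j in range(k)])
            pooled.append(group.max(axis=0))
        return ResponseStack(maps=np.stack(pooled), index=tuple(self.bank.pooled_index))


_CONVOLVER_CACHE: dict[tuple[int, tuple[int, int]], BankConvolver] = {}
_CONVOLVER_CACHE_MAX = 2  # kernel spectra are large; keep at most two banks


def _get_convolver(bank: FilterBank, shape: tuple[int, int]) -> BankConvolver:
    key = (id(bank), shape)
    conv = _CONVOLVER_CACHE.get(key)
    if conv is None or conv.bank is not bank:
        conv = BankConvolver(bank, shape)
        while len(_CONVOLVER_CACHE) >= _CONVOLVER_CACHE_MAX:
            _CONVOLVER_CACHE.pop(next(iter(_CONVOLVER_CACHE)))
        _CONVOLVER_CACHE[key] = conv
    elif key in _CONVOLVER_CACHE:  # refresh LRU position
        _CONVOLVER_CACHE.pop(key)
    _CONVOLVER_CACHE[key] = conv
    return conv


def pooled_response_stack(
    cutout,
    bank: FilterBank,
    method: str = "fft",
    require_shape: tuple[int, int] | None = (512, 512),
) -> ResponseStack:
    """Convolve and orientation-pool, holding one orientation group at a time.

    Equivalent to ``orientation_max(apply_bank(...), bank)``.  The FFT
    path reuses cached kernel spectra across calls with the same bank.
    """
    pixels = _as_pixels(cutout)
    if require_shape is not None and pixels.shape != require_shape:
        raise ValueError(f"cutout shape {pixels.shape} != required {require_shape}")
    if method == "fft":
        return _get_convolver(bank, pixels.shape).pooled(pixels)
    pooled = []
    for _, kernels in bank.iter_groups():
        group = np.stack([convolve_reflect(pixels, k.weights, method=method) for k in kernels])
        pooled.append(group.max(axis=0))
    return ResponseStack(maps=np.stack(pooled), index=tuple(bank.pooled_index))
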