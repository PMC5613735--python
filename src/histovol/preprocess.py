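"""Contrast normalisation, positive-region marking and down-sampling.

The fluorescence signal of interest (a red fluorescent protein) lives in the
red channel, while negatively stained tissue autofluoresces mostly in the
other channels.  Preprocessing therefore: (1) stretches each image's
contrast linearly; (2) converts to grayscale while *marking* red-positive
pixels by adding a fixed intensity boost, so that a single grayscale
threshold later separates positive from negative tissue; (3) optionally
Gaussian-smooths and decimates to cut the working size.

Marking precedes smoothing so the boosted plateau survives blurring; both
precede registration, which resamples with nearest neighbours and never
invents intermediate intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .stack_io import RGBSection

__all__ = [
    "GraySlice",
    "PreprocessParams",
    "auto_contrast",
    "mark_and_grayscale",
    "gaussian_downsample",
    "smooth_float",
]

#: Rec. 601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class GraySlice:
    """Single-channel 8-bit working image after marking/smoothing."""

    pixels: np.ndarray
    slice_index: int
    damaged: bool = False
    marked: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"gray pixels must be 2D, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("gray intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable preprocessing parameters.

    red_threshold
        8-bit red-channel value at or above which a pixel counts as
        positively stained (default 25, midpoint of the 20-30 range used on
        real slices; per-slice overrides via ``red_threshold_overrides``).
    mark_boost
        Additive grayscale intensity for marked pixels (default 100), the
        device that pushes positive pixels above the classification band of
        negative tissue.
    autocontrast_saturation
        Fraction of pixels saturated at each histogram tail before the
        linear stretch (0 = pure min-max).
    gaussian_sigma, downsample_factor
        Smoothing scale (pixels) and integer decimation factor applied to
        the working grayscale images.
    """

    red_threshold: int = 25
    red_threshold_overrides: dict[int, int] = field(default_factory=dict)
    mark_boost: int = 100
    autocontrast_saturation: float = 0.0035
    gaussian_sigma: float = 0.0
    downsample_factor: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.red_threshold <= 255):
            raise ConfigError(f"red_threshold must be in [0, 255], got {self.red_threshold}")
        for k, v in self.red_threshold_overrides.items():
            if not (0 <= v <= 255):
                raise ConfigError(
                    f"red_threshold override for slice {k} must be in [0, 255], got {v}"
                )
        if self.mark_boost < 0:
            raise ConfigError(f"mark_boost must be >= 0, got {self.mark_boost}")
        if not (0 <= self.autocontrast_saturation < 0.5):
            raise ConfigError(
                f"autocontrast_saturation must be in [0, 0.5), got {self.autocontrast_saturation}"
            )
        if self.gaussian_sigma < 0:
            raise ConfigError(f"gaussian_sigma must be >= 0, got {self.gaussian_sigma}")
        if self.downsample_factor < 1:
            raise ConfigError(
                f"downsample_factor must be >= 1, got {self.downsample_factor}"
            )

    def threshold_for(self, slice_index: int) -> int:
        return self.red_threshold_overrides.get(slice_index, self.red_threshold)


def _round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(values + 0.5)


def auto_contrast(section: RGBSection, saturation: float = 0.0035) -> RGBSection:
    """Linear per-image contrast stretch with tail saturation.

    The low and high clip bounds are the intensities at rank
    ``floor(saturation * n)`` from each end of the sorted pooled pixel
    values (all channels jointly, so one transfer function per image and
    hue relations are preserved).  The stretch maps low -> 0 and
    high -> 255 with clipping; constant images are returned unchanged.
    """
    if not (0 <= saturation < 0.5):
        raise ConfigError(f"saturation must be in [0, 0.5), got {saturation}")
    flat = section.pixels.ravel()
    n = flat.size
    k = int(np.floor(saturation * n))
    k = min(k, (n - 1) // 2)
    part = np.partition(flat, [k, n - 1 - k])
    lo = int(part[k])
    hi = int(part[n - 1 - k])
    if hi <= lo:
        return replace(section, pixels=section.pixels.copy())
    scaled = (section.pixels.astype(np.float64) - lo) * (255.0 / (hi - lo))
    out = np.clip(_round_half_up(scaled), 0, 255).astype(np.uint8)
    return replace(section, pixels=out)


def mark_and_grayscale(
    section: RGBSection, red_threshold: int = 25, mark_boost: int = 100
) -> GraySlice:
    """Convert to grayscale, boosting red-positive pixels.

    Grayscale is the rounded Rec. 601 luma; every pixel whose red channel is
    at or above ``red_threshold`` gets ``mark_boost`` added, clipped to 255.
    The returned slice is flagged ``marked`` so it cannot be boosted twice.
    """
    if getattr(section, "marked", False):
        # double boosting would silently corrupt the class bands
        raise ConfigError(
            f"slice {section.slice_index} is already marked; marking is not repeatable"
        )
    px = section.pixels.astype(np.float64)
    gray = _round_half_up(
        LUMA_WEIGHTS[0] * px[:, :, 0]
        + LUMA_WEIGHTS[1] * px[:, :, 1]
        + LUMA_WEIGHTS[2] * px[:, :, 2]
    )
    positive = section.pixels[:, :, 0] >= red_threshold
    gray[positive] += mark_boost
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    return GraySlice(
        pixels=gray,
        slice_index=section.slice_index,
        damaged=section.damaged,
        marked=True,
    )


def smooth_float(pixels: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing in floating point with reflective boundaries.

    The kernel is normalised, so a constant image stays constant and the
    image mean is preserved (up to floating-point error) under reflection.
    """
    if sigma < 0:
        raise ConfigError(f"sigma must be >= 0, got {sigma}")
    arr = np.asarray(pixels, dtype=np.float64)
    if sigma == 0:
        return arr.copy()
    return ndimage.gaussian_filter(arr, sigma=sigma, mode="reflect")


def gaussian_downsample(gray: GraySlice, sigma: float, factor: int) -> GraySlice:
    """Gaussian-smooth then decimate by an integer factor.

    Keeps every ``factor``-th pixel in each dimension starting at index 0,
    so output dims are ``ceil(dim / factor)``.  ``sigma == 0, factor == 1``
    is the identity.
    """
    if factor < 1:
        raise ConfigError(f"downsample factor must be >= 1, got {factor}")
    h, w = gray.pixels.shape
    if factor > h or factor > w:
        raise ConfigError(
            f"downsample factor {factor} exceeds image dims ({h}x{w})"
        )
    smoothed = smooth_float(gray.pixels, sigma)
    decimated = smoothed[::factor, ::factor]
    out = np.clip(_round_half_up(decimated), 0, 255).astype(np.uint8)
    return replace(gray, pixels=out)


def preprocess_section(
    section: RGBSection, params: PreprocessParams
) -> GraySlice:
    """Full per-slice preprocessing: contrast -> mark/grayscale -> smooth/decimate."""
    contrasted = auto_contrast(section, params.autocontrast_saturation)
    gray = mark_and_grayscale(
        contrasted,
        red_threshold=params.threshold_for(section.slice_index),
        mark_boost=params.mark_boost,
    )
    if params.gaussian_sigma > 0 or params.downsample_factor > 1:
        gray = gaussian_downsample(
            gray, params.gaussian_sigma, params.downsample_factor
        )
    return gray
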