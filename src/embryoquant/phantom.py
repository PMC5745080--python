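"""Synthetic embryo phantoms with known ground truth.

Two image classes are emulated, matching the two quantification
workflows downstream:

* A two-channel fluorescence phantom (signal + nuclear counterstain):
  inside a rectangular "embryo" the nuclear channel is flat and the
  signal channel follows ``nuclear_level * ratio_function(x)`` along the
  normalized ventral(0)->dorsal(1) axis, so the true signal/nuclear
  ratio at every axis position is known exactly.

* An RGB brightfield phantom of an oval embryo whose margin carries a
  purple-stained sector of known angular extent — the image class of a
  chromogenic in situ hybridization micrograph.

Both accept additive Gaussian noise (clipped to the valid intensity
range) and are bit-reproducible for a fixed seed.  Optical blur, 3-D
structure and stain chemistry are deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .angular import EllipseROI

__all__ = [
    "GradientPhantomSpec",
    "InSituPhantomSpec",
    "generate_gradient_phantom",
    "generate_insitu_phantom",
    "insitu_stain_mask",
    "sector_extent_fraction",
]

# defaults for the brightfield phantom palette (8-bit RGB)
PURPLE_STAIN = (90, 40, 130)
EMBRYO_BODY = (225, 210, 185)
WHITE_BACKGROUND = (255, 255, 255)


@dataclass(frozen=True)
class GradientPhantomSpec:
    """Parameters of a two-channel gradient phantom.

    ``embryo_bbox`` is (top, left, height, width) in pixels; the
    ventral->dorsal axis runs left (x=0, ventral) to right (x=1, dorsal)
    across the box.  ``ratio_function`` maps normalized axis position
    x in [0, 1] to the true signal/nuclear ratio and must be
    non-negative on the sampled grid.
    """

    image_height: int
    image_width: int
    embryo_bbox: tuple[int, int, int, int]
    ratio_function: Callable[[np.ndarray], np.ndarray]
    nuclear_level: float = 100.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")
        top, left, h, w = self.embryo_bbox
        if h < 1 or w < 2:
            raise ValueError("embryo_bbox must be at least 1 pixel high and 2 wide")
        if top < 0 or left < 0 or top + h > self.image_height or left + w > self.image_width:
            raise ValueError("embryo_bbox must lie within the image")
        if self.nuclear_level <= 0:
            raise ValueError("nuclear_level must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def generate_gradient_phantom(
    spec: GradientPhantomSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a gradient phantom.

    Returns
    -------
    image : (2, H, W) float64 array; channel 0 is the signal channel,
        channel 1 the nuclear channel.  Background is 0.
    true_profile : the ratio_function sampled at the bbox columns'
        normalized axis positions (length = bbox width).
    """
    top, left, h, w = spec.embryo_bbox
    x = np.arange(w) / (w - 1)
    true_profile = np.asarray(spec.ratio_function(x), dtype=float)
    if true_profile.shape != x.shape:
        raise ValueError("ratio_function must map the axis grid elementwise")
    if np.any(true_profile < 0):
        raise ValueError("ratio_function must be non-negative on [0, 1]")

    image = np.zeros((2, spec.image_height, spec.image_width), dtype=np.float64)
    image[1, top : top + h, left : left + w] = spec.nuclear_level
    image[0, top : top + h, left : left + w] = spec.nuclear_level * true_profile
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image += rng.normal(0.0, spec.noise_sigma, size=image.shape)
        np.clip(image, 0.0, None, out=image)
    return image, true_profile


@dataclass(frozen=True)
class InSituPhantomSpec:
    """Parameters of an RGB in situ phantom.

    The embryo is the filled ``ellipse``; a rim band of depth
    ``stain_band_depth`` pixels inward from the boundary, restricted to
    the angular ``stain_sector`` (start, end) in degrees, is painted
    ``stain_color``.  Angles use the image-frame convention of
    :mod:`embryoquant.angular` (0 deg = +x, counter-clockwise); the
    sector is half-open [start, end), with end = 360 meaning the full
    circumference.
    """

    image_height: int
    image_width: int
    ellipse: EllipseROI
    stain_sector: tuple[float, float] = (0.0, 90.0)
    stain_band_depth: float = 25.0
    stain_color: tuple[int, int, int] = PURPLE_STAIN
    background_color: tuple[int, int, int] = WHITE_BACKGROUND
    embryo_color: tuple[int, int, int] = EMBRYO_BODY
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        start, end = self.stain_sector
        if not (0 <= start < 360 and 0 <= end <= 360):
            raise ValueError("sector angles must satisfy 0 <= start < 360, 0 <= end <= 360")
        if self.stain_band_depth < 1:
            raise ValueError("stain_band_depth must be >= 1 pixel")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not self.ellipse.within_image((self.image_height, self.image_width)):
            raise ValueError("ellipse must lie fully inside the image")


def sector_extent_fraction(stain_sector: tuple[float, float]) -> float:
    """True extent fraction of a half-open [start, end) sector."""
    start, end = stain_sector
    span = end - start
    if span < 0:
        span += 360.0
    return span / 360.0


def _sector_contains(phi_deg: np.ndarray, start: float, end: float) -> np.ndarray:
    """Membership of angles (deg, mod 360) in the half-open sector."""
    phi = np.mod(phi_deg, 360.0)
    if end >= start:
        return (phi >= start) & (phi < end)
    return (phi >= start) | (phi < end)


def insitu_stain_mask(spec: InSituPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact (noise-free) pixel masks of the phantom geometry.

    Returns ``(embryo_mask, stain_mask)``.  A pixel belongs to the
    embryo when its elliptical radius is <= 1; it is stained when it
    additionally lies within ``stain_band_depth`` (euclidean pixels,
    measured along its own ray from the center) of the boundary and its
    image-frame angle falls in the stain sector.
    """
    ell = spec.ellipse
    rows, cols = np.mgrid[0 : spec.image_height, 0 : spec.image_width]
    dx = cols - ell.center[1]
    dy = ell.center[0] - rows  # +y is up (toward row 0)
    phi = np.degrees(np.arctan2(dy, dx))
    r = np.hypot(dx, dy)
    theta_geo = np.deg2rad(phi) - np.deg2rad(ell.rotation_deg)
    t_boundary = ell.boundary_distance(theta_geo)
    embryo = r <= t_boundary
    start, end = spec.stain_sector
    stain = embryo & (r >= t_boundary - spec.stain_band_depth) & _sector_contains(phi, start, end)
    return embryo, stain


def generate_insitu_phantom(
    spec: InSituPhantomSpec,
) -> tuple[np.ndarray, float]:
    """Render an in situ phantom.

    Returns
    -------
    image : (H, W, 3) uint8 RGB image.
    true_extent : the ground-truth extent fraction, sector span / 360.
    """
    embryo, stain = insitu_stain_mask(spec)
    image = np.empty((spec.image_height, spec.image_width, 3), dtype=np.float64)
    image[:] = spec.background_color
    image[embryo] = spec.embryo_color
    image[stain] = spec.stain_color
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image += rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, sector_extent_fraction(spec.stain_sector)
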