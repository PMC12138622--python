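"""Micrograph morphology: segmentation, skeletonization and particle sizing.

Implements the image pipeline used on secondary-electron micrographs of
proteinoid microspheres: grayscale conversion, contrast-limited histogram
equalization, adaptive (local-mean) thresholding, topology-preserving
skeletonization with a red overlay, and per-particle measurements
(equivalent diameter, area, circularity) scaled by the pixel size.
Bright-on-dark polarity is assumed, with an inversion flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color, exposure, measure, morphology

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "MicrographImage",
    "Particle",
    "ParticleSet",
    "SkeletonOverlay",
    "preprocess",
    "segment",
    "skeletonize_mask",
    "measure_particles",
    "analyze_micrograph",
]


@dataclass
class MicrographImage:
    pixels: np.ndarray  # 2-D grayscale (or RGB before preprocess)
    pixel_size: float  # nm per pixel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("image intensities must be finite")
        if self.pixel_size <= 0:
            raise DataError("pixel_size must be > 0")


@dataclass
class Particle:
    centroid: tuple[float, float]  # (row, col) pixels
    equivalent_diameter: float  # nm
    area: float  # nm^2
    circularity: float  # 4*pi*A/P^2, <= 1 for a disk
    touches_border: bool = False
    flag: str = ""


@dataclass
class ParticleSet:
    particles: list[Particle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def diameters(self) -> np.ndarray:
        return np.array([p.equivalent_diameter for p in self.particles])


@dataclass
class SkeletonOverlay:
    mask: np.ndarray
    skeleton: np.ndarray
    overlay: np.ndarray  # RGB, skeleton drawn in red


def preprocess(img: MicrographImage) -> MicrographImage:
    """Grayscale conversion + contrast-limited adaptive histogram equalization.

    Output intensities span [0, 1].  A constant image has no contrast to
    enhance and is returned unchanged (logged).
    """
    px = img.pixels
    if px.ndim == 3:  # RGB -> luminance
        px = color.rgb2gray(px)
    if float(np.ptp(px)) == 0.0:
        logger.info("preprocess: constant image, returned unchanged")
        return MicrographImage(pixels=px, pixel_size=img.pixel_size, metadata=dict(img.metadata))
    # rescale to [0,1] before CLAHE, which expects a bounded range
    lo, hi = float(px.min()), float(px.max())
    scaled = (px - lo) / (hi - lo)
    eq = exposure.equalize_adapthist(scaled)
    return MicrographImage(pixels=eq, pixel_size=img.pixel_size, metadata=dict(img.metadata))


def default_window(shape: tuple[int, int]) -> int:
    """Adaptive-threshold window: 1/8 of the smaller image side, rounded odd."""
    w = max(3, min(shape) // 8)
    return w if w % 2 == 1 else w + 1


def segment(
    img: MicrographImage,
    window: int | None = None,
    offset: float = 0.02,
    invert: bool = False,
) -> np.ndarray:
    """Adaptive threshold: foreground where intensity > local mean + offset.

    ``offset`` is in units of the intensity range of the (preprocessed)
    image.  With ``invert=True`` the rule becomes intensity < local mean -
    offset, so an inverted-contrast image segments to the same mask.
    """
    px = img.pixels
    if px.ndim != 2:
        raise DataError("segment expects a 2-D grayscale image; run preprocess first")
    if window is None:
        window = default_window(px.shape)
    if window % 2 == 0 or window < 3:
        raise ParameterError("window must be odd and >= 3")
    if window > min(px.shape):
        raise ParameterError("window larger than image")
    local_mean = ndi.uniform_filter(px, size=window, mode="reflect")
    if invert:
        return px < local_mean - offset
    return px > local_mean + offset


def skeletonize_mask(mask: np.ndarray, image: np.ndarray | None = None) -> SkeletonOverlay:
    """Thin a binary mask to a 1-pixel-wide, topology-preserving skeleton.

    The overlay renders the skeleton in red on the source image (or on the
    mask itself when no image is given).  An empty mask yields an empty
    skeleton.
    """
    mask = np.asarray(mask, dtype=bool)
    skel = morphology.thin(mask)
    base = mask.astype(float) if image is None else np.asarray(image, dtype=float)
    if float(np.ptp(base)) > 0:
        base = (base - base.min()) / np.ptp(base)
    overlay = np.stack([base, base, base], axis=-1)
    overlay[skel] = (1.0, 0.0, 0.0)
    return SkeletonOverlay(mask=mask, skeleton=skel, overlay=overlay)


def measure_particles(mask: np.ndarray, pixel_size: float) -> ParticleSet:
    """Connected-component particle measurements in physical units.

    equivalent diameter = 2*sqrt(area_px/pi) * pixel_size (nm),
    area in nm^2, circularity = 4*pi*area/perimeter^2 (clipped to 1 for
    rasterization overshoot).  Components touching the image border are
    flagged rather than dropped.
    """
    mask = np.asarray(mask, dtype=bool)
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be > 0")
    labeled = measure.label(mask, connectivity=2)
    out = ParticleSet()
    h, w = mask.shape
    for rp in measure.regionprops(labeled):
        area_px = rp.area
        diam = 2.0 * np.sqrt(area_px / np.pi) * pixel_size
        perim = rp.perimeter
        circ = float(min(1.0, 4.0 * np.pi * area_px / perim**2)) if perim > 0 else 1.0
        minr, minc, maxr, maxc = rp.bbox
        border = minr == 0 or minc == 0 or maxr == h or maxc == w
        out.particles.append(
            Particle(
                centroid=tuple(map(float, rp.centroid)),
                equivalent_diameter=float(diam),
                area=float(area_px * pixel_size**2),
                circularity=circ,
                touches_border=border,
            )
        )
    return out


def analyze_micrograph(
    img: MicrographImage,
    window: int | None = None,
    offset: float = 0.02,
    invert: bool = False,
) -> tuple[ParticleSet, SkeletonOverlay]:
    """Full pipeline: preprocess -> segment -> skeletonize -> measure."""
    pre = preprocess(img)
    mask = segment(pre, window=window, offset=offset, invert=invert)
    overlay = skeletonize_mask(mask, image=pre.pixels)
    particles = measure_particles(mask, pre.pixel_size)
    return particles, overlay
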