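"""Lesion segmentation and intensity normalization.

Segmentation follows the classic recipe for semi-automatic tumor
delineation: within a user-supplied rectangular seed region, Otsu's
threshold (maximizing between-class variance on a 256-bin histogram)
binarizes the intensities, morphological operations clean the contour,
and optionally only the largest 8-connected component is kept.

Intensities are z-score normalized (zero mean, unit variance over the
whole image) before feature extraction, which removes acquisition-
dependent offset and scale while preserving pixel rank order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters, morphology, measure

from .core import DegenerateInputError, GrayImage, ROIMask

__all__ = [
    "SegmentationConfig",
    "normalize_intensities",
    "otsu_threshold",
    "refine_mask",
    "segment_lesion",
]


class EmptyMaskError(DegenerateInputError):
    """Segmentation or refinement produced an empty mask."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Morphological refinement settings.

    morphology_sequence
        Ordered operator names from {dilate, erode, open, close}; applied
        left to right with a disk structuring element.
    structuring_element_radius
        Disk radius in pixels (>= 1).
    keep_largest_component
        Retain only the largest 8-connected foreground component.
    bright_foreground
        Treat the brighter Otsu class as lesion (set False for
        dark-lesion contrast).
    """

    morphology_sequence: tuple[str, ...] = ("open", "close")
    structuring_element_radius: int = 1
    keep_largest_component: bool = True
    bright_foreground: bool = True

    _OPS = ("dilate", "erode", "open", "close")

    def __post_init__(self) -> None:
        if self.structuring_element_radius < 1:
            raise ValueError("structuring_element_radius must be >= 1")
        for op in self.morphology_sequence:
            if op not in self._OPS:
                raise ValueError(f"unknown morphology operator {op!r}")


def normalize_intensities(image: GrayImage) -> GrayImage:
    """Z-score the whole image to mean 0, standard deviation 1."""
    px = image.pixels
    sd = px.std()
    if sd == 0:
        raise DegenerateInputError("cannot normalize a constant image (sd = 0)")
    return GrayImage((px - px.mean()) / sd, spacing=image.spacing, id=image.id)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold over a fixed-bin histogram of the values.

    Returns the threshold maximizing between-class variance; binarize as
    ``values > threshold``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise DegenerateInputError("Otsu needs at least 2 distinct values")
    return float(filters.threshold_otsu(values, nbins=nbins))


_MORPH = {
    "dilate": morphology.dilation,
    "erode": morphology.erosion,
    "open": morphology.opening,
    "close": morphology.closing,
}


def refine_mask(mask: ROIMask, config: SegmentationConfig) -> ROIMask:
    """Apply the configured morphology sequence and component filtering."""
    px = mask.pixels.copy()
    footprint = morphology.disk(config.structuring_element_radius)
    for op in config.morphology_sequence:
        px = _MORPH[op](px, footprint)
    if config.keep_largest_component and px.any():
        labels = measure.label(px, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        px = labels == int(np.argmax(counts))
    if not px.any():
        raise EmptyMaskError("morphological refinement emptied the mask")
    return ROIMask(px, provenance="refined")


def segment_lesion(
    image: GrayImage,
    seed_region: tuple[int, int, int, int],
    config: SegmentationConfig | None = None,
) -> ROIMask:
    """Otsu-binarize within a rectangular seed region and refine.

    ``seed_region`` is (row0, col0, row1, col1) with exclusive upper
    bounds.  The returned full-size mask is zero outside the seed region.
    """
    if config is None:
        config = SegmentationConfig()
    r0, c0, r1, c1 = seed_region
    rows, cols = image.shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"seed region {seed_region} outside image bounds {image.shape}")
    patch = image.pixels[r0:r1, c0:c1]
    thr = otsu_threshold(patch)
    fg = patch > thr if config.bright_foreground else patch < thr
    if not fg.any():
        raise EmptyMaskError("Otsu binarization produced an empty foreground")
    full = np.zeros(image.shape, dtype=bool)
    full[r0:r1, c0:c1] = fg
    return refine_mask(ROIMask(full, provenance="otsu"), config)
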