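"""Core data containers shared by every stage of the pipeline.

The unit of analysis is a single 2D grayscale MR slice (:class:`GrayImage`)
paired with a binary lesion mask (:class:`ROIMask`).  Texture features are
computed on the masked pixels only; the gray-level matrix families
additionally require a discretized view (:class:`DiscretizedROI`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrayImage",
    "ROIMask",
    "DiscretizedROI",
    "FeatureVector",
    "FAMILIES",
]

#: Feature family tags, in reporting order.
FAMILIES = ("FOS", "GLCM", "GLDM", "GLRLM", "GLSZM", "NGTDM", "FDTA")


class DegenerateInputError(ValueError):
    """Raised when an input is too degenerate for the requested statistic
    (constant image, empty mask, no valid pixel pairs...)."""


@dataclass(frozen=True)
class GrayImage:
    """A 2D intensity raster with physical pixel spacing.

    Parameters
    ----------
    pixels
        2D float array of intensities; must be finite.
    spacing
        (row, col) pixel size in millimetres.
    id
        Opaque identifier carried through the pipeline.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D raster, got ndim={px.ndim}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"image too small: {px.shape} (need >= 8 per side)")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROIMask:
    """Binary lesion mask aligned to a :class:`GrayImage`.

    ``provenance`` records how the mask was obtained: ``manual-seed``
    (drawn / synthetic), ``otsu`` (raw threshold), or ``refined``
    (after morphological clean-up).
    """

    pixels: np.ndarray
    provenance: str = "manual-seed"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D mask, got ndim={px.ndim}")
        if px.dtype != bool:
            uniq = np.unique(px)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be in {0, 1}")
            px = px.astype(bool)
        if not px.any():
            raise ValueError("mask has no foreground pixels")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class DiscretizedROI:
    """Integer gray levels 1..G on the mask foreground (0 elsewhere)."""

    gray_levels: np.ndarray  # int array, 0 outside mask, 1..G inside
    mask: np.ndarray  # bool
    n_levels: int
    source: str = ""

    def __post_init__(self) -> None:
        gl = np.asarray(self.gray_levels)
        mk = np.asarray(self.mask, dtype=bool)
        if gl.shape != mk.shape:
            raise ValueError("gray_levels and mask shapes differ")
        if self.n_levels < 2:
            raise ValueError("need at least 2 gray levels")
        inside = gl[mk]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("levels outside 1..G on the foreground")
        object.__setattr__(self, "gray_levels", gl.astype(np.int64))
        object.__setattr__(self, "mask", mk)


@dataclass
class FeatureVector:
    """Ordered mapping of feature name -> value, with family tags.

    Names are family-prefixed (``FOS_Mean``, ``GLCM_Contrast``, ...) so that
    the short names that recur across families stay unambiguous.
    """

    values: dict[str, float] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)

    def add(self, family: str, name: str, value: float) -> None:
        if family not in FAMILIES:
            raise ValueError(f"unknown feature family {family!r}")
        key = f"{family}_{name}"
        if key in self.values:
            raise ValueError(f"duplicate feature {key!r}")
        self.values[key] = float(value)
        self.groups[key] = family

    def update(self, other: "FeatureVector") -> None:
        for key, val in other.values.items():
            if key in self.values:
                raise ValueError(f"duplicate feature {key!r}")
            self.values[key] = val
            self.groups[key] = other.groups[key]

    def names(self, family: str | None = None) -> list[str]:
        if family is None:
            return list(self.values)
        return [k for k, fam in self.groups.items() if fam == family]

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)
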