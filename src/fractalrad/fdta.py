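"""Fractal dimension texture analysis (FDTA).

The texture of a tumor ROI is modelled as a fractional Brownian motion
(fBm) surface: the expected absolute intensity difference between pixels a
distance ``k`` apart scales as ``E|ΔI| ∝ k^H`` with Hurst exponent
``H ∈ (0, 1)``.  ``H`` is estimated as the least-squares slope of
``log ID(k)`` versus ``log k``, where ``ID(k)`` is the mean absolute
intensity difference over all horizontal and vertical pixel pairs at
distance ``k`` whose members both lie in the mask.  The fractal dimension
follows as ``FD = 3 − H``: large ``H`` (small FD) means a smooth surface,
small ``H`` (large FD) a rough one.

Three scalar features summarise the fractal structure of an ROI:

``FD``
    3 − H at the native resolution.
``FSVI``
    the least-squares slope of the Hurst exponents computed at
    successively 2× downsampled resolutions against the level index —
    the scale-dependence of roughness (zero for an exactly self-similar
    surface).
``Lacunarity``
    gliding-box "gappiness": variance over squared mean of the occupied
    pixel count in boxes slid across the mask bounding box, averaged over
    a set of box sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import DegenerateInputError, GrayImage, ROIMask, FeatureVector

__all__ = [
    "IDVector",
    "HurstFit",
    "MFVector",
    "FDTAFeatures",
    "intensity_difference",
    "midv",
    "hurst",
    "fractal_dimension",
    "multiresolution_hurst",
    "fsvi",
    "lacunarity",
    "fdta_features",
]

#: Scales with fewer valid pixel pairs than this are dropped from the
#: log–log regression; tiny pair counts make the fit unstable on small ROIs.
MIN_PAIRS_PER_SCALE = 16


class ScaleUnavailableError(DegenerateInputError):
    """No valid pixel pair exists at the requested distance."""


class DegenerateTextureError(DegenerateInputError):
    """Texture too degenerate (e.g. constant) for a Hurst fit."""


@dataclass(frozen=True)
class IDVector:
    """Multiscale intensity difference vector [ID(1) ... ID(s)]."""

    values: np.ndarray  # mean |ΔI| per scale, index 0 ↔ k = 1
    pair_counts: np.ndarray  # valid pairs per scale

    @property
    def max_scale(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class HurstFit:
    """Result of the log–log regression of ID(k) on k.

    ``H`` is the fitted slope; the fBm model constrains it to [0, 1] but
    the estimator does not, so ``out_of_range`` flags estimates outside
    that interval rather than clamping them.
    """

    H: float
    intercept: float
    scales_used: tuple[int, ...]
    r_squared: float

    @property
    def out_of_range(self) -> bool:
        return not (0.0 <= self.H <= 1.0)


@dataclass(frozen=True)
class MFVector:
    """Hurst exponents at successively halved resolutions (level 0 = native)."""

    fits: tuple[HurstFit, ...]

    @property
    def H_by_level(self) -> np.ndarray:
        return np.array([f.H for f in self.fits])

    @property
    def m(self) -> int:
        return len(self.fits)


@dataclass(frozen=True)
class FDTAFeatures:
    FD: float
    Lacunarity: float
    FSVI: float
    diagnostics: dict = field(default_factory=dict, compare=False)

    def as_feature_vector(self) -> FeatureVector:
        fv = FeatureVector()
        fv.add("FDTA", "FD", self.FD)
        fv.add("FDTA", "Lacunarity", self.Lacunarity)
        fv.add("FDTA", "FSVI", self.FSVI)
        return fv


def intensity_difference(
    image: GrayImage, mask: ROIMask, k: int
) -> tuple[float, int]:
    """Mean absolute intensity difference over all pixel pairs at distance k.

    Pairs are taken along rows and columns (both orientations pooled) and
    only counted when both members lie inside the mask.  Returns
    ``(ID(k), pair_count)``.
    """
    if k < 1:
        raise ValueError(f"scale k must be >= 1, got {k}")
    px, mk = image.pixels, mask.pixels
    if px.shape != mk.shape:
        raise ValueError("image and mask shapes differ")
    total = 0.0
    count = 0
    if k < px.shape[1]:
        valid = mk[:, k:] & mk[:, :-k]
        total += np.abs(px[:, k:] - px[:, :-k])[valid].sum()
        count += int(valid.sum())
    if k < px.shape[0]:
        valid = mk[k:, :] & mk[:-k, :]
        total += np.abs(px[k:, :] - px[:-k, :])[valid].sum()
        count += int(valid.sum())
    if count == 0:
        raise ScaleUnavailableError(f"no valid pixel pair at distance k={k}")
    return total / count, count


def midv(image: GrayImage, mask: ROIMask, s: int) -> IDVector:
    """Multiscale intensity difference vector [ID(1) ... ID(s)].

    If some scale k <= s has no valid pair the vector is truncated to the
    largest contiguous prefix of available scales (with a warning).
    """
    if s < 2:
        raise ValueError(f"maximum scale s must be >= 2, got {s}")
    values, counts = [], []
    for k in range(1, s + 1):
        try:
            idk, n = intensity_difference(image, mask, k)
        except ScaleUnavailableError:
            warnings.warn(
                f"scale k={k} unavailable; truncating MIDV to {k - 1} scales",
                stacklevel=2,
            )
            break
        values.append(idk)
        counts.append(n)
    if not values:
        raise ScaleUnavailableError("no scale available for this mask")
    return IDVector(np.array(values), np.array(counts, dtype=int))


def hurst(
    image: GrayImage,
    mask: ROIMask,
    s: int,
    *,
    min_pairs: int = MIN_PAIRS_PER_SCALE,
) -> HurstFit:
    """Estimate the Hurst exponent from the ID(k) ~ k^H scaling law.

    Ordinary least squares of log ID(k) on log k over the usable scales;
    scales with ID(k) = 0 or fewer than ``min_pairs`` valid pairs are
    excluded (with a warning for zero-valued scales).
    """
    idv = midv(image, mask, s)
    return hurst_from_idv(idv, min_pairs=min_pairs)


def hurst_from_idv(idv: IDVector, *, min_pairs: int = MIN_PAIRS_PER_SCALE) -> HurstFit:
    """Fit H from a precomputed intensity-difference vector."""
    ks = np.arange(1, idv.max_scale + 1)
    usable = (idv.values > 0) & (idv.pair_counts >= min_pairs)
    if np.any((idv.values == 0) & (idv.pair_counts >= min_pairs)):
        warnings.warn("zero-valued ID(k) scales excluded from Hurst fit", stacklevel=2)
    if usable.sum() < 2:
        raise DegenerateTextureError(
            "fewer than 2 usable scales for the log-log Hurst regression "
            "(constant or near-constant texture?)"
        )
    x = np.log(ks[usable].astype(float))
    y = np.log(idv.values[usable])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return HurstFit(
        H=float(slope),
        intercept=float(intercept),
        scales_used=tuple(int(k) for k in ks[usable]),
        r_squared=r2,
    )


def fractal_dimension(fit: HurstFit | float) -> float:
    """FD = 3 − H for an fBm surface."""
    h = fit.H if isinstance(fit, HurstFit) else float(fit)
    if not np.isfinite(h):
        raise ValueError("H must be finite")
    return 3.0 - h


def _pool2x2(pixels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One downsampling step: 2×2 mean pooling of intensities, majority
    pooling of the mask (ties count as foreground)."""
    r, c = pixels.shape
    r2, c2 = r - r % 2, c - c % 2
    px = pixels[:r2, :c2].reshape(r2 // 2, 2, c2 // 2, 2)
    mk = mask[:r2, :c2].reshape(r2 // 2, 2, c2 // 2, 2)
    return px.mean(axis=(1, 3)), mk.sum(axis=(1, 3)) >= 2


def multiresolution_hurst(
    image: GrayImage,
    mask: ROIMask,
    m: int,
    s: int,
    *,
    min_pairs: int = MIN_PAIRS_PER_SCALE,
) -> MFVector:
    """Hurst exponents at m resolutions: level i is the image downsampled
    i times by 2×2 mean pooling (level 0 = native resolution)."""
    if m < 1:
        raise ValueError(f"resolution count m must be >= 1, got {m}")
    side = min(image.shape)
    max_m = 1
    while side // (2 ** max_m) >= 8:
        max_m += 1
    if m > max_m:
        raise ValueError(
            f"image side {side} supports at most m={max_m} resolution levels "
            f"(coarsest level must keep >= 8 pixels per side), got m={m}"
        )
    fits = []
    px, mk = image.pixels, mask.pixels
    for level in range(m):
        lvl_img = GrayImage(px, spacing=image.spacing, id=f"{image.id}@L{level}")
        lvl_mask = ROIMask(mk, provenance="refined")
        lvl_s = min(s, max(2, min(px.shape) // 4))
        fits.append(hurst(lvl_img, lvl_mask, lvl_s, min_pairs=min_pairs))
        if level < m - 1:
            px, mk = _pool2x2(px, mk)
    return MFVector(tuple(fits))


def fsvi(mf: MFVector | np.ndarray) -> float:
    """Fractal Scale Variability Index: least-squares slope of H_i on the
    resolution level index i = 0 .. m−1."""
    h = mf.H_by_level if isinstance(mf, MFVector) else np.asarray(mf, dtype=float)
    m = len(h)
    if m < 2:
        raise ValueError(f"FSVI needs at least 2 resolution levels, got {m}")
    i = np.arange(m, dtype=float)
    num = m * np.sum(i * h) - np.sum(i) * np.sum(h)
    den = m * np.sum(i ** 2) - np.sum(i) ** 2
    return float(num / den)


def _occupancy(image: GrayImage, mask: ROIMask, rule: str) -> np.ndarray:
    if rule == "above-mean":
        return mask.pixels & (image.pixels > image.pixels.mean())
    if rule == "mask":
        return mask.pixels.copy()
    raise ValueError(f"unknown occupancy rule {rule!r}")


def lacunarity(
    image: GrayImage,
    mask: ROIMask,
    box_size: int,
    occupancy_rule: str = "above-mean",
) -> float:
    """Gliding-box lacunarity Λ at one box size.

    Boxes of side ``box_size`` slide with stride 1 over the mask bounding
    box; the mass of a box is its count of occupied pixels.  With P(l) the
    empirical distribution of box mass l,

        Λ = [Σ l²P(l) − (Σ lP(l))²] / (Σ lP(l))²

    i.e. variance over squared mean of the box mass.  A uniformly occupied
    region gives Λ = 0; clustered occupancy with gaps gives larger Λ.
    """
    if box_size < 1:
        raise ValueError(f"box_size must be >= 1, got {box_size}")
    occ = _occupancy(image, mask, occupancy_rule)
    rows, cols = np.nonzero(mask.pixels)
    sub = occ[rows.min(): rows.max() + 1, cols.min(): cols.max() + 1]
    if box_size > min(sub.shape):
        raise ValueError(
            f"box_size {box_size} exceeds mask bounding box {sub.shape}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(
        sub.astype(np.int64), (box_size, box_size)
    )
    masses = windows.sum(axis=(2, 3)).ravel()
    mean = masses.mean()
    if mean == 0:
        raise DegenerateInputError("all gliding boxes are empty")
    return float(masses.var() / mean ** 2)


def fdta_features(
    image: GrayImage,
    mask: ROIMask,
    *,
    s: int | None = None,
    m: int = 3,
    box_sizes: tuple[int, ...] = (2, 4, 8),
    occupancy_rule: str = "above-mean",
    min_pairs: int = MIN_PAIRS_PER_SCALE,
) -> FDTAFeatures:
    """The three fractal features of an ROI: FD, Lacunarity, FSVI.

    FD comes from the finest-resolution Hurst fit (H clamped into the fBm
    range [0, 1] so FD lands in [2, 3]); FSVI from the m-level
    multiresolution Hurst vector; Lacunarity is the mean of Λ over the
    configured box sizes (clipped to the ROI bounding box).
    """
    if s is None:
        s = min(8, max(2, min(image.shape) // 4))
    mf = multiresolution_hurst(image, mask, m, s, min_pairs=min_pairs)
    h0 = float(np.clip(mf.fits[0].H, 0.0, 1.0))
    fd = fractal_dimension(h0)
    index = fsvi(mf)

    rows, cols = np.nonzero(mask.pixels)
    bbox_side = min(rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)
    usable_boxes = [b for b in box_sizes if b <= bbox_side]
    if not usable_boxes:
        raise DegenerateInputError(
            f"no configured box size fits the mask bounding box (side {bbox_side})"
        )
    lam_by_box = {
        b: lacunarity(image, mask, b, occupancy_rule) for b in usable_boxes
    }
    lam = float(np.mean(list(lam_by_box.values())))

    diagnostics = {
        "scales_used": [f.scales_used for f in mf.fits],
        "r_squared": [f.r_squared for f in mf.fits],
        "H_by_level": mf.H_by_level.tolist(),
        "lacunarity_by_box": lam_by_box,
    }
    return FDTAFeatures(FD=fd, Lacunarity=lam, FSVI=index, diagnostics=diagnostics)
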