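"""First- and second-order texture features of a masked ROI.

Implements the 90 classical features of the six-family taxonomy —
17 first-order statistics (FOS) plus five gray-level matrix families:
co-occurrence (GLCM, 22), dependence (GLDM, 14), run length (GLRLM, 16),
size zone (GLSZM, 16) and neighboring gray-tone difference (NGTDM, 5) —
using the standard IBSI-consistent definitions of each named feature.
:func:`extract_all` adds the three fractal features for the full
93-feature vector.

Conventions (documented per feature where they matter):

* intensities are z-score normalized and then discretized into a fixed
  number of equal-width bins over the foreground range (default 32);
* GLCM and GLRLM are computed per 2D direction (the 4 unique directions
  at distance 1) and feature values are averaged across directions;
* zones and components use 8-connectivity; matrix neighborhoods are the
  8-neighbors restricted to the mask;
* degenerate cases follow the widely used reference conventions:
  Correlation of a constant ROI is 1, IMC1/IMC2 are 0, NGTDM Coarseness
  is capped at 1e6 when the gray-tone difference sum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    DegenerateInputError,
    DiscretizedROI,
    FeatureVector,
    GrayImage,
    ROIMask,
)
from . import fdta as _fdta
from .preprocessing import normalize_intensities

__all__ = [
    "ExtractionConfig",
    "discretize",
    "fos_features",
    "glcm_features",
    "gldm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "extract_all",
    "ALL_FAMILIES",
    "FAMILY_SIZES",
]

ALL_FAMILIES = ("fos", "glcm", "gldm", "glrlm", "glszm", "ngtdm", "fdta")
FAMILY_SIZES = {
    "fos": 17,
    "glcm": 22,
    "gldm": 14,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
    "fdta": 3,
}

#: The 4 unique 2D directions at distance 1 (row, col offsets).
_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))

_COARSENESS_CAP = 1e6


@dataclass(frozen=True)
class ExtractionConfig:
    """Settings of the full extraction pipeline."""

    n_levels: int = 32
    families: tuple[str, ...] = ALL_FAMILIES
    normalize: bool = True
    fdta_max_scale: int | None = None  # None -> min(8, side // 4)
    fdta_levels: int = 3
    fdta_box_sizes: tuple[int, ...] = (2, 4, 8)
    fdta_occupancy_rule: str = "above-mean"

    def __post_init__(self) -> None:
        for fam in self.families:
            if fam not in ALL_FAMILIES:
                raise ValueError(f"unknown feature family {fam!r}")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


def discretize(image: GrayImage, mask: ROIMask, n_levels: int) -> DiscretizedROI:
    """Equal-width binning of foreground intensities into levels 1..G."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    fg = image.pixels[mask.pixels]
    lo, hi = fg.min(), fg.max()
    if lo == hi:
        raise DegenerateInputError("constant foreground cannot be discretized")
    levels = np.zeros(image.shape, dtype=np.int64)
    scaled = (image.pixels - lo) / (hi - lo) * n_levels
    lv = np.floor(scaled).astype(np.int64) + 1
    np.clip(lv, 1, n_levels, out=lv)
    levels[mask.pixels] = lv[mask.pixels]
    return DiscretizedROI(levels, mask.pixels, n_levels, source=image.id)


# ----------------------------------------------------------------- FOS ---

def fos_features(image: GrayImage, mask: ROIMask, n_bins: int = 32) -> FeatureVector:
    """The 17 first-order statistics of the foreground intensities.

    Entropy and Uniformity use an ``n_bins`` equal-width histogram of the
    foreground; Kurtosis is unadjusted (normal distribution -> 3);
    Skewness is the Fisher–Pearson moment coefficient.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    x = image.pixels[mask.pixels].astype(float)
    if x.size == 0:
        raise DegenerateInputError("empty mask")
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    m3 = np.mean((x - mean) ** 3)
    m4 = np.mean((x - mean) ** 4)
    skew = 0.0 if sd == 0 else m3 / sd ** 3
    kurt = 0.0 if sd == 0 else m4 / var ** 2
    p10, p25, p75, p90 = np.percentile(x, (10, 25, 75, 90))
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / x.size
    fv = FeatureVector()
    add = lambda name, v: fv.add("FOS", name, v)
    add("Mean", mean)
    add("Median", np.median(x))
    add("Skewness", skew)
    add("Kurtosis", kurt)
    add("Energy", np.sum(x ** 2))
    add("Entropy", -np.sum(p * np.log2(p)))
    add("Min", x.min())
    add("Max", x.max())
    add("10th Percentile", p10)
    add("90th Percentile", p90)
    add("IR", p75 - p25)
    add("Range", x.max() - x.min())
    add("MAD", np.abs(x - mean).mean())
    add("rMAD", rmad)
    add("RMS", np.sqrt(np.mean(x ** 2)))
    add("Uniformity", np.sum(p ** 2))
    add("Variance", var)
    return fv


# ---------------------------------------------------------------- GLCM ---

def _glcm_matrix(roi: DiscretizedROI, direction: tuple[int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts at distance 1 along one direction,
    restricted to pairs with both pixels in the mask."""
    G = roi.n_levels
    lv, mk = roi.gray_levels, roi.mask
    dr, dc = direction
    rows, cols = lv.shape
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    a = lv[r0:r1, c0:c1]
    b = lv[r0 + dr: r1 + dr, c0 + dc: c1 + dc]
    valid = mk[r0:r1, c0:c1] & mk[r0 + dr: r1 + dr, c0 + dc: c1 + dc]
    i, j = a[valid] - 1, b[valid] - 1
    mat = np.zeros((G, G), dtype=float)
    np.add.at(mat, (i, j), 1.0)
    np.add.at(mat, (j, i), 1.0)
    return mat


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    G = P.shape[0]
    p = P / P.sum()
    i = np.arange(1, G + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float(np.sum(i * px))
    muy = float(np.sum(i * py))
    sigx = float(np.sqrt(np.sum((i - mux) ** 2 * px)))
    sigy = float(np.sqrt(np.sum((i - muy) ** 2 * py)))

    diff = np.abs(ii - jj)
    pxmy = np.array([p[diff == k].sum() for k in range(G)])  # p_{x-y}
    psum = np.array([p[(ii + jj) == k].sum() for k in range(2, 2 * G + 1)])  # p_{x+y}
    da = float(np.sum(np.arange(G) * pxmy))

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q)))

    hxy = ent(p.ravel())
    outer = np.outer(px, py)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(outer[nz])))
    hxy2 = ent(outer.ravel())
    hx, hy = ent(px), ent(py)

    corr = 1.0 if sigx * sigy == 0 else float(
        (np.sum(ii * jj * p) - mux * muy) / (sigx * sigy)
    )
    if max(hx, hy) == 0:
        imc1 = 0.0
    else:
        imc1 = (hxy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    offdiag = diff > 0
    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "CP": float(np.sum((ii + jj - mux - muy) ** 4 * p)),
        "CS": float(np.sum((ii + jj - mux - muy) ** 3 * p)),
        "CT": float(np.sum((ii + jj - mux - muy) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "DA": da,
        "DE": ent(pxmy),
        "DV": float(np.sum((np.arange(G) - da) ** 2 * pxmy)),
        "ID": float(np.sum(p / (1.0 + diff))),
        "IDN": float(np.sum(p / (1.0 + diff / G))),
        "IMC1": float(imc1),
        "IMC2": imc2,
        "IDM": float(np.sum(p / (1.0 + diff ** 2))),
        "IDMN": float(np.sum(p / (1.0 + diff ** 2 / G ** 2))),
        "JA": mux,
        "JEn": float(np.sum(p ** 2)),
        "JEnt": hxy,
        "IV": float(np.sum(p[offdiag] / diff[offdiag] ** 2)),
        "MP": float(p.max()),
        "SE": ent(psum),
        "SS": float(np.sum((ii - mux) ** 2 * p)),
    }


def glcm_features(roi: DiscretizedROI) -> FeatureVector:
    """22 co-occurrence features, averaged over the 4 directions."""
    per_dir = []
    for d in _DIRECTIONS:
        mat = _glcm_matrix(roi, d)
        if mat.sum() > 0:
            per_dir.append(_glcm_features_single(mat))
    if not per_dir:
        raise DegenerateInputError("no valid co-occurrence pair in any direction")
    fv = FeatureVector()
    for name in per_dir[0]:
        fv.add("GLCM", name, float(np.mean([d[name] for d in per_dir])))
    return fv


# ---------------------------------------------------------------- GLDM ---

def _gldm_matrix(roi: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence matrix: P[i-1, j-1] counts mask pixels of level i whose
    dependence is j = 1 + number of 8-neighbors (in mask) within alpha of
    the center level.  j ranges 1..9 in 2D."""
    lv, mk = roi.gray_levels, roi.mask
    dep = np.zeros(lv.shape, dtype=np.int64)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full(lv.shape, -10**9, dtype=np.int64)
            smk = np.zeros(lv.shape, dtype=bool)
            rows, cols = lv.shape
            r0, r1 = max(0, -dr), min(rows, rows - dr)
            c0, c1 = max(0, -dc), min(cols, cols - dc)
            shifted[r0:r1, c0:c1] = lv[r0 + dr: r1 + dr, c0 + dc: c1 + dc]
            smk[r0:r1, c0:c1] = mk[r0 + dr: r1 + dr, c0 + dc: c1 + dc]
            dep += (np.abs(shifted - lv) <= alpha) & smk & mk
    P = np.zeros((roi.n_levels, 9), dtype=float)
    i = lv[mk] - 1
    j = dep[mk]  # 0..8 dependent neighbors -> j+1 including the center
    np.add.at(P, (i, j), 1.0)
    return P


def _sizezone_style_features(
    P: np.ndarray, n_pixels: int, names: dict[str, str]
) -> dict[str, float]:
    """Shared feature formulas of the GLDM/GLRLM/GLSZM families: matrices
    indexed (gray level i, size/length/dependence j)."""
    Nz = P.sum()
    p = P / Nz
    G, J = P.shape
    i = np.arange(1, G + 1)[:, None]
    j = np.arange(1, J + 1)[None, :]
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(np.arange(1, G + 1) * pi))
    mu_j = float(np.sum(np.arange(1, J + 1) * pj))
    pnz = p[p > 0]
    out = {
        names["small"]: float(np.sum(p / j ** 2)),
        names["large"]: float(np.sum(p * j ** 2.0)),
        names["gln"]: float(np.sum(P.sum(axis=1) ** 2) / Nz),
        names["sizen"]: float(np.sum(P.sum(axis=0) ** 2) / Nz),
        names["glv"]: float(np.sum(p * (i - mu_i) ** 2)),
        names["sizev"]: float(np.sum(p * (j - mu_j) ** 2)),
        names["entropy"]: float(-np.sum(pnz * np.log2(pnz))),
        names["lgl"]: float(np.sum(p / i ** 2)),
        names["hgl"]: float(np.sum(p * i ** 2.0)),
        names["slgl"]: float(np.sum(p / (i ** 2 * j ** 2))),
        names["shgl"]: float(np.sum(p * i ** 2.0 / j ** 2)),
        names["llgl"]: float(np.sum(p * j ** 2.0 / i ** 2)),
        names["lhgl"]: float(np.sum(p * i ** 2.0 * j ** 2.0)),
    }
    if "glnn" in names:
        out[names["glnn"]] = float(np.sum(P.sum(axis=1) ** 2) / Nz ** 2)
    if "sizenn" in names:
        out[names["sizenn"]] = float(np.sum(P.sum(axis=0) ** 2) / Nz ** 2)
    if "percentage" in names:
        out[names["percentage"]] = float(Nz / n_pixels)
    return out


def gldm_features(roi: DiscretizedROI, alpha: int = 0) -> FeatureVector:
    """14 gray-level dependence features (distance 1, similarity alpha)."""
    P = _gldm_matrix(roi, alpha)
    if P.sum() == 0:
        raise DegenerateInputError("empty dependence matrix")
    n_px = int(roi.mask.sum())
    names = {
        "small": "SDE", "large": "LDE", "gln": "GLN", "sizen": "DN",
        "sizenn": "DNN", "glv": "GLV", "sizev": "DV", "entropy": "DE",
        "lgl": "LGLE", "hgl": "HGLE", "slgl": "SDLGLE", "shgl": "SDHGLE",
        "llgl": "LDLGLE", "lhgl": "LDHGLE",
    }
    feats = _sizezone_style_features(P, n_px, names)
    fv = FeatureVector()
    for name, val in feats.items():
        fv.add("GLDM", name, val)
    return fv


# --------------------------------------------------------------- GLRLM ---

def _runs_along(levels: np.ndarray, mask: np.ndarray, direction: tuple[int, int]):
    """Yield (level, run_length) for maximal constant-level runs along all
    lines of one direction, runs broken by off-mask pixels."""
    rows, cols = levels.shape
    dr, dc = direction
    if (dr, dc) == (0, 1):
        lines = [(r, 0) for r in range(rows)]
    elif (dr, dc) == (1, 0):
        lines = [(0, c) for c in range(cols)]
    elif (dr, dc) == (1, 1):
        lines = [(0, c) for c in range(cols)] + [(r, 0) for r in range(1, rows)]
    elif (dr, dc) == (1, -1):
        lines = [(0, c) for c in range(cols)] + [(r, cols - 1) for r in range(1, rows)]
    else:  # pragma: no cover
        raise ValueError(f"unsupported direction {direction}")
    for r, c in lines:
        cur_level, cur_len = None, 0
        while 0 <= r < rows and 0 <= c < cols:
            if mask[r, c]:
                lv = levels[r, c]
                if lv == cur_level:
                    cur_len += 1
                else:
                    if cur_level is not None:
                        yield cur_level, cur_len
                    cur_level, cur_len = lv, 1
            else:
                if cur_level is not None:
                    yield cur_level, cur_len
                cur_level, cur_len = None, 0
            r, c = r + dr, c + dc
        if cur_level is not None:
            yield cur_level, cur_len


def _glrlm_matrix(roi: DiscretizedROI, direction: tuple[int, int]) -> np.ndarray:
    max_len = max(roi.gray_levels.shape)
    P = np.zeros((roi.n_levels, max_len), dtype=float)
    for level, length in _runs_along(roi.gray_levels, roi.mask, direction):
        P[level - 1, length - 1] += 1
    return P


_GLRLM_NAMES = {
    "small": "SRE", "large": "LRE", "gln": "GLN", "glnn": "GLNN",
    "sizen": "RLN", "sizenn": "RLNN", "percentage": "RP", "glv": "GLV",
    "sizev": "RV", "entropy": "RE", "lgl": "LGLRE", "hgl": "HGLRE",
    "slgl": "SRLGLE", "shgl": "SRHGLE", "llgl": "LRLGLE", "lhgl": "LRHGLE",
}


def glrlm_features(roi: DiscretizedROI) -> FeatureVector:
    """16 run-length features, averaged over the 4 directions."""
    n_px = int(roi.mask.sum())
    per_dir = []
    for d in _DIRECTIONS:
        P = _glrlm_matrix(roi, d)
        if P.sum() > 0:
            per_dir.append(_sizezone_style_features(P, n_px, _GLRLM_NAMES))
    if not per_dir:
        raise DegenerateInputError("no run in any direction")
    fv = FeatureVector()
    for name in per_dir[0]:
        fv.add("GLRLM", name, float(np.mean([d[name] for d in per_dir])))
    return fv


# --------------------------------------------------------------- GLSZM ---

_GLSZM_NAMES = {
    "small": "SAE", "large": "LAE", "gln": "GLN", "glnn": "GLNN",
    "sizen": "SZN", "sizenn": "SZNN", "percentage": "ZP", "glv": "GLV",
    "sizev": "ZV", "entropy": "ZE", "lgl": "LGLZE", "hgl": "HGLZE",
    "slgl": "SALGLE", "shgl": "SAHGLE", "llgl": "LALGLE", "lhgl": "LAHGLE",
}


def _glszm_matrix(roi: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix: zones are 8-connected components of equal level."""
    n_px = int(roi.mask.sum())
    P = np.zeros((roi.n_levels, n_px), dtype=float)
    eight = np.ones((3, 3), dtype=int)
    for level in np.unique(roi.gray_levels[roi.mask]):
        blob = (roi.gray_levels == level) & roi.mask
        labels, n_comp = ndimage.label(blob, structure=eight)
        if n_comp == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for sz in sizes:
            P[level - 1, sz - 1] += 1
    return P


def glszm_features(roi: DiscretizedROI) -> FeatureVector:
    """16 size-zone features (direction-free by construction)."""
    P = _glszm_matrix(roi)
    if P.sum() == 0:
        raise DegenerateInputError("empty size-zone matrix")
    feats = _sizezone_style_features(P, int(roi.mask.sum()), _GLSZM_NAMES)
    fv = FeatureVector()
    for name, val in feats.items():
        fv.add("GLSZM", name, val)
    return fv


# --------------------------------------------------------------- NGTDM ---

def _ngtdm_accumulate(roi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level gray-tone difference sums s_i and pixel counts n_i.

    A pixel contributes when it has at least one in-mask 8-neighbor; its
    difference is |level − mean(neighboring levels in mask)|.
    """
    lv = roi.gray_levels.astype(float)
    mk = roi.mask.astype(float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    nbr_sum = ndimage.convolve(lv * mk, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(mk, kernel, mode="constant", cval=0.0)
    valid = roi.mask & (nbr_cnt > 0)
    diffs = np.abs(lv[valid] - nbr_sum[valid] / nbr_cnt[valid])
    levels = roi.gray_levels[valid]
    G = roi.n_levels
    s = np.zeros(G)
    n = np.zeros(G, dtype=int)
    np.add.at(s, levels - 1, diffs)
    np.add.at(n, levels - 1, 1)
    return s, n, int(valid.sum())


def ngtdm_features(roi: DiscretizedROI) -> FeatureVector:
    """The 5 neighboring gray-tone difference features."""
    s, n, Nv = _ngtdm_accumulate(roi)
    if Nv == 0:
        raise DegenerateInputError("no pixel with an in-mask neighbor")
    p = n / Nv
    G = roi.n_levels
    i_vals = np.arange(1, G + 1, dtype=float)
    nz = p > 0
    Ngp = int(nz.sum())
    iv, pv, sv = i_vals[nz], p[nz], s[nz]

    sum_ps = float(np.sum(pv * sv))
    coarseness = _COARSENESS_CAP if sum_ps == 0 else min(1.0 / sum_ps, _COARSENESS_CAP)

    if Ngp > 1:
        di = iv[:, None] - iv[None, :]
        pp = pv[:, None] * pv[None, :]
        contrast = float(np.sum(pp * di ** 2) / (Ngp * (Ngp - 1)) * s.sum() / Nv)
        denom = float(np.sum(np.abs(iv[:, None] * pv[:, None] - iv[None, :] * pv[None, :])))
        busyness = 0.0 if denom == 0 else sum_ps / denom
        num = np.abs(di) * (
            (pv[:, None] * sv[:, None] + pv[None, :] * sv[None, :])
            / (pv[:, None] + pv[None, :])
        )
        complexity = float(num.sum() / Nv)
        strength_num = float(np.sum((pv[:, None] + pv[None, :]) * di ** 2))
        strength = 0.0 if s.sum() == 0 else strength_num / s.sum()
    else:
        contrast = busyness = complexity = strength = 0.0

    fv = FeatureVector()
    fv.add("NGTDM", "Busyness", busyness)
    fv.add("NGTDM", "Coarseness", coarseness)
    fv.add("NGTDM", "Complexity", complexity)
    fv.add("NGTDM", "Contrast", contrast)
    fv.add("NGTDM", "Strength", strength)
    return fv


# ------------------------------------------------------------ pipeline ---

def extract_all(
    image: GrayImage,
    mask: ROIMask,
    config: ExtractionConfig | None = None,
) -> FeatureVector:
    """Normalize, discretize and run every configured feature family.

    With all families enabled the result has exactly 93 named features
    (17 FOS + 73 second-order + 3 FDTA); with the fractal family disabled,
    90.
    """
    if config is None:
        config = ExtractionConfig()
    img = normalize_intensities(image) if config.normalize else image
    fv = FeatureVector()
    need_roi = set(config.families) & {"glcm", "gldm", "glrlm", "glszm", "ngtdm"}
    roi = discretize(img, mask, config.n_levels) if need_roi else None
    for fam in config.families:
        if fam == "fos":
            fv.update(fos_features(img, mask, n_bins=config.n_levels))
        elif fam == "glcm":
            fv.update(glcm_features(roi))
        elif fam == "gldm":
            fv.update(gldm_features(roi))
        elif fam == "glrlm":
            fv.update(glrlm_features(roi))
        elif fam == "glszm":
            fv.update(glszm_features(roi))
        elif fam == "ngtdm":
            fv.update(ngtdm_features(roi))
        elif fam == "fdta":
            feats = _fdta.fdta_features(
                img,
                mask,
                s=config.fdta_max_scale,
                m=config.fdta_levels,
                box_sizes=config.fdta_box_sizes,
                occupancy_rule=config.fdta_occupancy_rule,
            )
            fv.update(feats.as_feature_vector())
    return fv
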