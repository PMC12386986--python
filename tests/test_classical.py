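"""Gray-level matrix features against brute-force enumeration oracles."""

import numpy as np
import pytest

from fractalrad.classical import (
    ExtractionConfig,
    FAMILY_SIZES,
    _DIRECTIONS,
    _glcm_matrix,
    _gldm_matrix,
    _glrlm_matrix,
    _glszm_matrix,
    _ngtdm_accumulate,
    discretize,
    extract_all,
    fos_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from fractalrad.core import DegenerateInputError, GrayImage, ROIMask
from conftest import make_roi


# ------------------------------------------------------------- oracles ---

def oracle_glcm(roi, direction):
    """Pure-loop symmetric co-occurrence counts."""
    G = roi.n_levels
    mat = np.zeros((G, G))
    rows, cols = roi.gray_levels.shape
    dr, dc = direction
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                if roi.mask[r, c] and roi.mask[r2, c2]:
                    i, j = roi.gray_levels[r, c] - 1, roi.gray_levels[r2, c2] - 1
                    mat[i, j] += 1
                    mat[j, i] += 1
    return mat


def oracle_gldm(roi):
    """Pure-loop dependence counts (center included, alpha = 0)."""
    G = roi.n_levels
    P = np.zeros((G, 9))
    rows, cols = roi.gray_levels.shape
    for r in range(rows):
        for c in range(cols):
            if not roi.mask[r, c]:
                continue
            dep = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < rows and 0 <= c2 < cols and roi.mask[r2, c2]:
                        if roi.gray_levels[r2, c2] == roi.gray_levels[r, c]:
                            dep += 1
            P[roi.gray_levels[r, c] - 1, dep] += 1
    return P


def oracle_runs(roi, direction):
    """Pure-loop run enumeration along one direction."""
    rows, cols = roi.gray_levels.shape
    dr, dc = direction
    starts = set()
    for r in range(rows):
        for c in range(cols):
            prev = (r - dr, c - dc)
            if not (0 <= prev[0] < rows and 0 <= prev[1] < cols):
                starts.add((r, c))
    runs = []
    for r0, c0 in sorted(starts):
        seq = []
        r, c = r0, c0
        while 0 <= r < rows and 0 <= c < cols:
            seq.append(roi.gray_levels[r, c] if roi.mask[r, c] else None)
            r, c = r + dr, c + dc
        cur, n = None, 0
        for v in seq + [None]:
            if v is not None and v == cur:
                n += 1
            else:
                if cur is not None:
                    runs.append((cur, n))
                cur, n = v, 1
    return runs


def oracle_glszm(roi):
    """Flood-fill zone enumeration (8-connectivity)."""
    rows, cols = roi.gray_levels.shape
    seen = np.zeros((rows, cols), dtype=bool)
    n_px = int(roi.mask.sum())
    P = np.zeros((roi.n_levels, n_px))
    for r in range(rows):
        for c in range(cols):
            if not roi.mask[r, c] or seen[r, c]:
                continue
            level = roi.gray_levels[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                y, x = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        y2, x2 = y + dy, x + dx
                        if (
                            0 <= y2 < rows and 0 <= x2 < cols
                            and not seen[y2, x2] and roi.mask[y2, x2]
                            and roi.gray_levels[y2, x2] == level
                        ):
                            seen[y2, x2] = True
                            stack.append((y2, x2))
            P[level - 1, size - 1] += 1
    return P


def oracle_ngtdm(roi):
    """Pure-loop s_i / n_i accumulation."""
    rows, cols = roi.gray_levels.shape
    s = np.zeros(roi.n_levels)
    n = np.zeros(roi.n_levels, dtype=int)
    for r in range(rows):
        for c in range(cols):
            if not roi.mask[r, c]:
                continue
            nbrs = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < rows and 0 <= c2 < cols and roi.mask[r2, c2]:
                        nbrs.append(roi.gray_levels[r2, c2])
            if nbrs:
                i = roi.gray_levels[r, c]
                s[i - 1] += abs(i - np.mean(nbrs))
                n[i - 1] += 1
    return s, n


# --------------------------------------------------------------- tests ---

class TestDiscretize:
    def test_equally_spaced_values_map_to_all_levels(self):
        img = GrayImage(np.tile(np.array([0.0, 1.0, 2.0, 3.0]), (8, 2)))
        roi = discretize(img, ROIMask(np.ones((8, 8), bool)), 4)
        assert set(roi.gray_levels[roi.mask]) == {1, 2, 3, 4}

    def test_extremes_map_to_1_and_G(self):
        rng = np.random.default_rng(0)
        img = GrayImage(rng.normal(size=(8, 8)))
        roi = discretize(img, ROIMask(np.ones((8, 8), bool)), 7)
        fg = roi.gray_levels[roi.mask]
        assert fg[np.argmin(img.pixels)] == 1
        assert fg[np.argmax(img.pixels)] == 7
        assert fg.min() >= 1 and fg.max() <= 7

    def test_two_values_two_levels(self):
        px = np.zeros((8, 8))
        px[:, 4:] = 10.0
        roi = discretize(GrayImage(px), ROIMask(np.ones((8, 8), bool)), 2)
        assert set(roi.gray_levels[roi.mask]) == {1, 2}

    def test_constant_foreground_rejected(self):
        img = GrayImage(np.outer(np.arange(8.0), np.ones(8)))
        mask = np.zeros((8, 8), bool)
        mask[3, :] = True  # constant row
        with pytest.raises(DegenerateInputError):
            discretize(img, ROIMask(mask), 4)


class TestFOS:
    def test_hand_arithmetic_on_four_values(self):
        px = np.zeros((8, 8))
        mask = np.zeros((8, 8), bool)
        px[0, :4] = [1, 2, 3, 4]
        mask[0, :4] = True
        fv = fos_features(GrayImage(px), ROIMask(mask))
        assert fv["FOS_Mean"] == pytest.approx(2.5)
        assert fv["FOS_Min"] == 1 and fv["FOS_Max"] == 4
        assert fv["FOS_Range"] == 3
        assert fv["FOS_Median"] == pytest.approx(2.5)
        assert fv["FOS_Variance"] == pytest.approx(1.25)
        assert fv["FOS_RMS"] == pytest.approx(np.sqrt(7.5))
        assert fv["FOS_Energy"] == pytest.approx(30.0)
        assert fv["FOS_MAD"] == pytest.approx(1.0)

    def test_constant_foreground_dispersion_is_zero(self):
        px = np.full((8, 8), 5.0)
        fv = fos_features(GrayImage(px), ROIMask(np.ones((8, 8), bool)))
        for name in ("Variance", "Range", "MAD", "IR"):
            assert fv[f"FOS_{name}"] == 0.0

    def test_kurtosis_unadjusted_convention(self):
        # normal sample -> Pearson kurtosis near 3 (not excess 0)
        rng = np.random.default_rng(0)
        px = rng.normal(size=(64, 64))
        fv = fos_features(GrayImage(px), ROIMask(np.ones((64, 64), bool)))
        assert fv["FOS_Kurtosis"] == pytest.approx(3.0, abs=0.3)

    def test_count(self):
        rng = np.random.default_rng(1)
        fv = fos_features(GrayImage(rng.normal(size=(8, 8))), ROIMask(np.ones((8, 8), bool)))
        assert len(fv) == FAMILY_SIZES["fos"]


class TestGLCM:
    def test_two_by_two_pair_counts(self, roi_factory):
        roi = roi_factory([[1, 1], [2, 2]], np.ones((2, 2), bool), 2)
        horiz = _glcm_matrix(roi, (0, 1))
        np.testing.assert_array_equal(horiz, [[2, 0], [0, 2]])
        vert = _glcm_matrix(roi, (1, 0))
        np.testing.assert_array_equal(vert, [[0, 2], [2, 0]])

    @pytest.mark.parametrize("seed", range(8))
    def test_matrix_matches_enumeration(self, random_roi_factory, seed):
        roi = random_roi_factory(seed)
        for d in _DIRECTIONS:
            np.testing.assert_array_equal(_glcm_matrix(roi, d), oracle_glcm(roi, d))

    @pytest.mark.parametrize("seed", range(4))
    def test_features_from_oracle_matrix(self, random_roi_factory, seed):
        """Loop-computed Autocorrelation/Contrast/MP per direction, averaged."""
        roi = random_roi_factory(seed)
        G = roi.n_levels
        per_dir = {"Autocorrelation": [], "Contrast": [], "MP": []}
        for d in _DIRECTIONS:
            mat = oracle_glcm(roi, d)
            if mat.sum() == 0:
                continue
            p = mat / mat.sum()
            auto = contrast = 0.0
            for i in range(G):
                for j in range(G):
                    auto += (i + 1) * (j + 1) * p[i, j]
                    contrast += (i - j) ** 2 * p[i, j]
            per_dir["Autocorrelation"].append(auto)
            per_dir["Contrast"].append(contrast)
            per_dir["MP"].append(p.max())
        fv = glcm_features(roi)
        for name, vals in per_dir.items():
            assert fv[f"GLCM_{name}"] == pytest.approx(np.mean(vals))

    def test_constant_roi_correlation_convention(self, roi_factory):
        roi = roi_factory(np.ones((4, 4), int), np.ones((4, 4), bool), 2)
        assert glcm_features(roi)["GLCM_Correlation"] == 1.0

    def test_count(self, random_roi_factory):
        assert len(glcm_features(random_roi_factory(0))) == FAMILY_SIZES["glcm"]


class TestGLDM:
    @pytest.mark.parametrize("seed", range(8))
    def test_matrix_matches_enumeration(self, random_roi_factory, seed):
        roi = random_roi_factory(seed)
        np.testing.assert_array_equal(_gldm_matrix(roi), oracle_gldm(roi))

    def test_uniform_roi_concentrates_on_max_dependence(self, roi_factory):
        roi = roi_factory(np.ones((6, 6), int), np.ones((6, 6), bool), 2)
        P = _gldm_matrix(roi)
        # 16 interior pixels with all 8 neighbors dependent, 16 edge pixels
        # with 5, 4 corners with 3; everything on the single level row
        np.testing.assert_array_equal(P[0], [0, 0, 0, 4, 0, 16, 0, 0, 16])
        np.testing.assert_array_equal(P[1], np.zeros(9))

    def test_checkerboard_dependence_counts(self, roi_factory):
        cb = (np.indices((3, 3)).sum(axis=0) % 2) + 1
        roi = roi_factory(cb, np.ones((3, 3), bool), 2)
        np.testing.assert_array_equal(_gldm_matrix(roi), oracle_gldm(roi))
        # same-level neighbors exist only along diagonals: the center
        # (level 1) sees its 4 diagonal corners
        P = _gldm_matrix(roi)
        assert P[0, 4] == 1

    def test_count(self, random_roi_factory):
        assert len(gldm_features(random_roi_factory(1))) == FAMILY_SIZES["gldm"]


class TestGLRLM:
    def test_single_row_runs(self, roi_factory):
        mask = np.zeros((2, 4), bool)
        mask[0] = True
        roi = roi_factory([[1, 1, 1, 2], [0, 0, 0, 0]], mask, 2)
        P = _glrlm_matrix(roi, (0, 1))
        assert P[0, 2] == 1 and P[1, 0] == 1 and P.sum() == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_runs_match_enumeration(self, random_roi_factory, seed):
        roi = random_roi_factory(seed)
        for d in _DIRECTIONS:
            expected = np.zeros_like(_glrlm_matrix(roi, d))
            for level, length in oracle_runs(roi, d):
                expected[level - 1, length - 1] += 1
            np.testing.assert_array_equal(_glrlm_matrix(roi, d), expected)

    def test_constant_roi_minimizes_sre(self, roi_factory):
        rng = np.random.default_rng(0)
        const = roi_factory(np.ones((6, 6), int), np.ones((6, 6), bool), 4)
        noisy = roi_factory(rng.integers(1, 5, (6, 6)), np.ones((6, 6), bool), 4)
        assert (
            glrlm_features(const)["GLRLM_SRE"] < glrlm_features(noisy)["GLRLM_SRE"]
        )

    def test_count(self, random_roi_factory):
        assert len(glrlm_features(random_roi_factory(2))) == FAMILY_SIZES["glrlm"]


class TestGLSZM:
    def test_two_blobs_zone_rows(self):
        lv = np.zeros((6, 6), int)
        lv[0, 0:3] = 1  # zone of 3
        lv[3:5, 3] = 1
        lv[3:5, 4] = 1  # zone of 4... make it 5
        lv[5, 4] = 1
        mask = lv > 0
        roi = make_roi(lv, mask, 2)
        P = _glszm_matrix(roi)
        assert P[0, 2] == 1 and P[0, 4] == 1 and P.sum() == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_zones_match_flood_fill(self, random_roi_factory, seed):
        roi = random_roi_factory(seed)
        np.testing.assert_array_equal(_glszm_matrix(roi), oracle_glszm(roi))

    def test_constant_roi_single_zone(self, roi_factory):
        roi = roi_factory(np.ones((5, 5), int), np.ones((5, 5), bool), 2)
        assert _glszm_matrix(roi).sum() == 1

    def test_count(self, random_roi_factory):
        assert len(glszm_features(random_roi_factory(3))) == FAMILY_SIZES["glszm"]


class TestNGTDM:
    def test_deviant_center_hand_accumulation(self, roi_factory):
        lv = np.ones((3, 3), int)
        lv[1, 1] = 3
        roi = roi_factory(lv, np.ones((3, 3), bool), 3)
        s, n = oracle_ngtdm(roi)
        s_impl, n_impl, nv = _ngtdm_accumulate(roi)
        np.testing.assert_allclose(s_impl, s)
        np.testing.assert_array_equal(n_impl, n)
        # hand values: center |3 - 1| = 2; each corner |1 - mean([1,1,3])|
        # = 2/3; each edge |1 - mean([1,1,1,1,3])| = 2/5
        assert s_impl[2] == pytest.approx(2.0)
        assert s_impl[0] == pytest.approx(4 * 2 / 3 + 4 * 2 / 5)

    @pytest.mark.parametrize("seed", range(8))
    def test_accumulation_matches_enumeration(self, random_roi_factory, seed):
        roi = random_roi_factory(seed)
        s, n = oracle_ngtdm(roi)
        s_impl, n_impl, _ = _ngtdm_accumulate(roi)
        np.testing.assert_allclose(s_impl, s)
        np.testing.assert_array_equal(n_impl, n)

    def test_constant_roi_coarseness_cap(self, roi_factory):
        roi = roi_factory(np.ones((5, 5), int), np.ones((5, 5), bool), 2)
        assert ngtdm_features(roi)["NGTDM_Coarseness"] == 1e6

    def test_count(self, random_roi_factory):
        assert len(ngtdm_features(random_roi_factory(4))) == FAMILY_SIZES["ngtdm"]


class TestExtractAll:
    @pytest.fixture(scope="class")
    def sample(self):
        from fractalrad.synthetic import CohortSpec, generate_cohort

        return generate_cohort(
            CohortSpec(n_patients_per_class=1, images_per_patient=1, seed=3)
        )[0]

    def test_full_vector_has_93_features(self, sample):
        fv = extract_all(sample.image, sample.mask)
        assert len(fv) == 93
        by_family = {f: len(fv.names(f.upper())) for f in FAMILY_SIZES}
        assert by_family == FAMILY_SIZES

    def test_without_fdta_90_features(self, sample):
        cfg = ExtractionConfig(families=("fos", "glcm", "gldm", "glrlm", "glszm", "ngtdm"))
        assert len(extract_all(sample.image, sample.mask, cfg)) == 90

    def test_deterministic(self, sample):
        a = extract_all(sample.image, sample.mask).as_dict()
        b = extract_all(sample.image, sample.mask).as_dict()
        assert a == b

    def test_translation_invariance(self, sample):
        # shift by multiples of the 2x2^(m-1) pooling period so the
        # multiresolution grid realigns exactly
        px = sample.image.pixels
        mk = sample.mask.pixels
        shifted_px = np.roll(np.roll(px, 4, axis=0), -4, axis=1)
        shifted_mk = np.roll(np.roll(mk, 4, axis=0), -4, axis=1)
        a = extract_all(sample.image, sample.mask).as_dict()
        b = extract_all(GrayImage(shifted_px), ROIMask(shifted_mk)).as_dict()
        for name in a:
            assert a[name] == pytest.approx(b[name]), name

    def test_all_values_finite(self, sample):
        fv = extract_all(sample.image, sample.mask)
        assert all(np.isfinite(v) for v in fv.values.values())
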