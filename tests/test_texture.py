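"""Texture matrices and parameters against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from trabtex.texture import (DIRECTIONS, GLCM_FEATURE_NAMES,
                             GLRLM_FEATURE_NAMES, DegenerateInputError,
                             QuantizedImage, compute_glcm, compute_glrlm,
                             directional_table, glcm_features, glrlm_features,
                             quantize)

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(pixels, levels, distance, direction):
    """Exhaustive pair counting, both orders, normalized."""
    dr, dc = OFFSETS[direction]
    dr, dc = dr * distance, dc * distance
    nrow, ncol = pixels.shape
    counts = np.zeros((levels, levels))
    for r in range(nrow):
        for c in range(ncol):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nrow and 0 <= c2 < ncol:
                counts[pixels[r, c], pixels[r2, c2]] += 1
                counts[pixels[r2, c2], pixels[r, c]] += 1
    return counts / counts.sum()


def brute_haralick(P):
    """Literal double-loop summation over matrix cells."""
    G = P.shape[0]
    px = P.sum(axis=1)
    mu = sum(i * px[i] for i in range(G))
    sigma2 = sum((i - mu) ** 2 * px[i] for i in range(G))
    p_sum = np.zeros(2 * G - 1)
    p_diff = np.zeros(G)
    for i in range(G):
        for j in range(G):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def ent(v):
        return -sum(x * np.log(x) for x in v if x > 0)

    out = {}
    out["angular_second_moment"] = (P ** 2).sum()
    out["contrast"] = sum(k ** 2 * p_diff[k] for k in range(G))
    out["correlation"] = (
        (sum(i * j * P[i, j] for i in range(G) for j in range(G)) - mu * mu)
        / sigma2) if sigma2 > 0 else float("nan")
    out["variance"] = sum((i - mu) ** 2 * P[i, j]
                          for i in range(G) for j in range(G))
    out["mean_sum"] = sum(k * p_sum[k] for k in range(2 * G - 1))
    out["sum_of_variance"] = sum((k - out["mean_sum"]) ** 2 * p_sum[k]
                                 for k in range(2 * G - 1))
    out["entropy"] = ent(P.ravel())
    out["sum_entropy"] = ent(p_sum)
    out["entropy_difference"] = ent(p_diff)
    mu_d = sum(k * p_diff[k] for k in range(G))
    out["residual_variance"] = sum((k - mu_d) ** 2 * p_diff[k]
                                   for k in range(G))
    out["inverse_difference_moment"] = sum(
        P[i, j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))
    return out


class TestQuantize:
    def test_constant_image_maps_to_single_level(self):
        q = quantize(np.full((5, 5), 128), levels=16)
        assert np.unique(q.pixels).size == 1

    def test_extremes_map_to_extreme_bins(self):
        q = quantize(np.array([[0, 255]]), levels=2)
        assert q.pixels.tolist() == [[0, 1]]

    def test_ramp_bins_uniformly(self):
        q = quantize(np.arange(256).reshape(16, 16), levels=4)
        assert np.bincount(q.pixels.ravel()).tolist() == [64, 64, 64, 64]

    def test_rejects_too_few_levels(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((3, 3)), levels=1)


class TestGlcm:
    def test_constant_image_single_cell(self):
        q = QuantizedImage(np.full((8, 8), 5), levels=8)
        m = compute_glcm(q, distance=3, direction=45)
        assert m.counts[5, 5] == pytest.approx(1.0)
        assert m.counts.sum() == pytest.approx(1.0)

    def test_checkerboard_horizontal_pairs_all_differ(self, checkerboard):
        q = QuantizedImage(checkerboard, levels=2)
        m = compute_glcm(q, distance=1, direction=0)
        assert m.counts[0, 1] == pytest.approx(0.5)
        assert m.counts[1, 0] == pytest.approx(0.5)
        assert m.counts[0, 0] == m.counts[1, 1] == 0

    @pytest.mark.parametrize("direction", DIRECTIONS)
    @pytest.mark.parametrize("distance", [1, 2])
    def test_matches_brute_force_enumeration(self, toy_qimage, direction,
                                             distance):
        ours = compute_glcm(toy_qimage, distance, direction).counts
        ref = brute_glcm(toy_qimage.pixels, 3, distance, direction)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_matches_skimage_on_random_images(self):
        """Independent library cross-check; the row axis points down here,
        so this package's 45deg (up-right) is skimage's 3pi/4 angle.
        Distance 1 only: skimage rounds sin/cos offsets, so diagonal
        offsets at larger distances are not (d, d) there."""
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(11)
        angle_of = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2,
                    135: np.pi / 4}
        for _ in range(5):
            img = rng.integers(0, 6, (12, 9)).astype(np.uint8)
            q = QuantizedImage(img, levels=6)
            for d in DIRECTIONS:
                ours = compute_glcm(q, 1, d).counts
                ref = graycomatrix(img, [1], [angle_of[d]], levels=6,
                                   symmetric=True, normed=True)[:, :, 0, 0]
                np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_mask_excludes_boundary_pairs(self):
        px = np.array([[0, 1, 0, 1], [0, 0, 0, 0]])
        mask = np.array([[True, True, False, True],
                         [False, False, False, False]])
        q = QuantizedImage(px, levels=2, mask=mask)
        m = compute_glcm(q, distance=1, direction=0)
        # only the leading (0,1) pair lies fully inside the mask
        assert m.counts[0, 1] == pytest.approx(0.5)
        assert m.counts[1, 0] == pytest.approx(0.5)
        assert m.counts[0, 0] == 0

    def test_empty_mask_is_degenerate(self):
        q = QuantizedImage(np.zeros((4, 4), int), levels=2,
                           mask=np.zeros((4, 4), bool))
        with pytest.raises(DegenerateInputError):
            compute_glcm(q, distance=1, direction=0)

    @settings(max_examples=40, deadline=None)
    @given(arrays(np.int64, (7, 9), elements=st.integers(0, 4)))
    def test_normalized_and_symmetric(self, img):
        q = QuantizedImage(img, levels=5)
        for d in DIRECTIONS:
            m = compute_glcm(q, 1, d).counts
            assert abs(m.sum() - 1.0) < 1e-12
            np.testing.assert_allclose(m, m.T, atol=1e-15)

    def test_rotation_permutes_directions_exactly(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 4, (10, 10))
        q = QuantizedImage(img, levels=4)
        q_rot = QuantizedImage(np.rot90(img), levels=4)
        perm = {0: 90, 90: 0, 45: 135, 135: 45}
        for d, d_rot in perm.items():
            a = compute_glcm(q, 2, d).counts
            b = compute_glcm(q_rot, 2, d_rot).counts
            np.testing.assert_allclose(a, b, atol=1e-15)


class TestGlcmFeatures:
    def test_constant_image_limits(self):
        q = QuantizedImage(np.full((8, 8), 2), levels=4)
        with pytest.warns(RuntimeWarning, match="correlation undefined"):
            f = glcm_features(compute_glcm(q, 1, 0))
        assert f["angular_second_moment"] == pytest.approx(1.0)
        assert f["contrast"] == 0
        assert f["entropy"] == 0
        assert f["inverse_difference_moment"] == pytest.approx(1.0)
        assert np.isnan(f["correlation"])

    def test_checkerboard_unit_contrast(self, checkerboard):
        q = QuantizedImage(checkerboard, levels=2)
        f = glcm_features(compute_glcm(q, 1, 0))
        assert f["contrast"] == pytest.approx(1.0)
        assert f["inverse_difference_moment"] == pytest.approx(0.5)

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_matches_summation_oracle(self, toy_qimage, direction):
        glcm = compute_glcm(toy_qimage, 1, direction)
        ours = glcm_features(glcm)
        ref = brute_haralick(glcm.counts)
        for name in GLCM_FEATURE_NAMES:
            assert ours[name] == pytest.approx(ref[name], abs=1e-12), name


class TestGlrlm:
    def test_constant_rows_one_run_each(self):
        q = QuantizedImage(np.full((8, 8), 1), levels=4)
        rlm = compute_glrlm(q, 0)
        assert rlm.n_runs == 8
        assert rlm.counts[1, 7] == 8

    def test_checkerboard_all_singleton_runs(self, checkerboard):
        q = QuantizedImage(checkerboard, levels=2)
        rlm = compute_glrlm(q, 0)
        assert rlm.n_runs == 64
        assert rlm.counts.shape[1] == 1

    def test_hand_run_length_encoding(self):
        q = QuantizedImage(np.array([[1, 1, 2, 2, 2, 1]]), levels=3)
        rlm = compute_glrlm(q, 0)
        assert rlm.counts[1, 1] == 1  # level 1, length 2
        assert rlm.counts[2, 2] == 1  # level 2, length 3
        assert rlm.counts[1, 0] == 1  # level 1, length 1
        assert rlm.n_runs == 3

    def test_masked_pixels_break_runs(self):
        px = np.array([[1, 1, 1, 1]])
        mask = np.array([[True, True, False, True]])
        q = QuantizedImage(px, levels=2, mask=mask)
        rlm = compute_glrlm(q, 0)
        assert rlm.counts[1, 1] == 1 and rlm.counts[1, 0] == 1

    @settings(max_examples=25, deadline=None)
    @given(arrays(np.int64, (6, 8), elements=st.integers(0, 3)))
    def test_every_pixel_in_exactly_one_run(self, img):
        q = QuantizedImage(img, levels=4)
        for d in DIRECTIONS:
            rlm = compute_glrlm(q, d)
            r = np.arange(1, rlm.counts.shape[1] + 1)
            assert (rlm.counts * r).sum() == img.size

    def test_rotation_permutes_directions(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 3, (9, 9))
        q = QuantizedImage(img, levels=3)
        q_rot = QuantizedImage(np.rot90(img), levels=3)
        for d, d_rot in {0: 90, 45: 135}.items():
            a = glrlm_features(compute_glrlm(q, d))
            b = glrlm_features(compute_glrlm(q_rot, d_rot))
            assert a == pytest.approx(b)


class TestGlrlmFeatures:
    def test_singleton_runs_unit_emphases(self, checkerboard):
        q = QuantizedImage(checkerboard, levels=2)
        f = glrlm_features(compute_glrlm(q, 0))
        assert f["short_run_emphasis"] == 1.0
        assert f["long_run_emphasis"] == 1.0

    def test_constant_image_closed_form(self):
        q = QuantizedImage(np.full((8, 8), 0), levels=2)
        f = glrlm_features(compute_glrlm(q, 0))
        assert f["short_run_emphasis"] == pytest.approx(1 / 64)
        assert f["long_run_emphasis"] == pytest.approx(64)
        assert f["grey_level_nonuniformity"] == pytest.approx(8)
        assert f["run_length_nonuniformity"] == pytest.approx(8)

    def test_hand_arithmetic_three_runs(self):
        q = QuantizedImage(np.array([[1, 1, 2, 2, 2, 1]]), levels=3)
        f = glrlm_features(compute_glrlm(q, 0))
        assert f["long_run_emphasis"] == pytest.approx(14 / 3)


class TestDirectionalTable:
    def test_isotropic_input_gives_identical_directions(self):
        """Constant image: GLCM parameters cannot depend on direction.
        GLRLM values match in axis-aligned and in diagonal pairs (a square
        grid's diagonal scan lines vary in length, so diagonals only match
        each other)."""
        q = QuantizedImage(np.full((10, 10), 3), levels=8)
        with pytest.warns(RuntimeWarning):
            table = directional_table(q, distance=2)
        for name in GLCM_FEATURE_NAMES:
            vals = table[name]
            if name == "correlation":
                assert all(np.isnan(v) for v in vals.values())
            else:
                assert len(set(vals.values())) == 1, name
        for name in GLRLM_FEATURE_NAMES:
            vals = table[name]
            assert vals[0] == vals[90] and vals[45] == vals[135], name

    def test_stripes_register_anisotropy(self):
        img = np.tile(np.array([[0], [3]]), (5, 10))
        q = QuantizedImage(img, levels=4)
        table = directional_table(q, distance=1)
        contrast = table["contrast"]
        assert contrast[0] != contrast[90]

    def test_cardinality_fifteen_by_four(self, toy_qimage):
        table = directional_table(toy_qimage, distance=1)
        assert len(table) == 15
        assert all(len(v) == 4 for v in table.values())
        assert set(table) == set(GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES)
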