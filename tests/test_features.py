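"""Texture matrices, wavelet subbands and the 730-feature panel."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from conftest import qpatch
from usradiomics.features import (
    compute_glcm,
    compute_glrlm,
    extract_all_features,
    first_order_features,
    glcm_features,
    glrlm_features,
    wavelet_decompose,
)
from usradiomics.imaging import RoiPatch, normalize_patch
from usradiomics.registry import DEFAULT_REGISTRY, FeatureRegistry

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


# ---------------------------------------------------------------- oracles
def glcm_oracle(q, distance, angle):
    """Exhaustive pair enumeration, independent of the vectorized builder."""
    dr, dc = OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = q.pixels.shape
    counts = np.zeros((q.levels, q.levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = q.pixels[r, c], q.pixels[r2, c2]
                if a != 0 and b != 0:
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    s = counts.sum()
    return counts / s if s else counts


def glrlm_oracle(q, angle):
    """Run-length encoding by explicit line walking."""
    dr, dc = OFFSETS[angle]
    h, w = q.pixels.shape
    # start cells: those whose predecessor along (dr,dc) is out of bounds
    runs = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if 0 <= pr < h and 0 <= pc < w:
                continue
            line = []
            rr, cc = r, c
            while 0 <= rr < h and 0 <= cc < w:
                line.append(q.pixels[rr, cc])
                rr += dr
                cc += dc
            # split at masked-out sentinels
            cur, n = None, 0
            for v in line + [0]:
                if v == cur:
                    n += 1
                else:
                    if cur not in (None, 0):
                        runs.append((cur, n))
                    cur, n = v, 1
    R = max((l for _, l in runs), default=1)
    mat = np.zeros((q.levels, R), dtype=int)
    for lvl, length in runs:
        mat[lvl - 1, length - 1] += 1
    return mat


# ------------------------------------------------------------- first order
class TestFirstOrder:
    def test_hand_arithmetic(self):
        p = RoiPatch(np.array([[1.0, 2.0], [3.0, 4.0]]), np.ones((2, 2), bool), normalized=True)
        f = first_order_features(p)
        assert f["mean"] == 2.5
        assert f["variance"] == 1.25
        assert f["energy"] == 30.0
        assert f["range"] == 3.0
        assert f["median"] == 2.5
        assert f["rms"] == pytest.approx(np.sqrt(7.5))
        assert f["mad"] == 1.0

    def test_constant_patch_degenerate_values(self):
        p = RoiPatch(np.full((4, 4), 2.0), np.ones((4, 4), bool), normalized=True)
        f = first_order_features(p)
        assert f["variance"] == 0.0
        assert f["entropy"] == 0.0
        assert f["uniformity"] == 1.0
        assert f["range"] == 0.0
        assert f["skewness"] == 0.0

    def test_two_equal_mass_bins_give_one_bit(self):
        pix = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 0.0, 1.0)
        f = first_order_features(RoiPatch(pix, np.ones((8, 8), bool), normalized=True))
        assert f["entropy"] == pytest.approx(1.0)
        assert f["uniformity"] == pytest.approx(0.5)

    def test_masked_pixels_only(self):
        pix = np.zeros((4, 4))
        pix[0, 0] = 1000.0  # outside the mask
        mask = np.zeros((4, 4), bool)
        mask[1:, 1:] = True
        pix[mask] = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        f = first_order_features(RoiPatch(pix, mask))
        assert f["maximum"] == 9.0
        assert f["mean"] == 5.0


# -------------------------------------------------------------------- GLCM
class TestGlcm:
    def test_two_column_patch(self):
        g = compute_glcm(qpatch([[1, 2], [1, 2]]), distance=1, angle=0)
        assert np.allclose(g.matrix, [[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(g)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(0.5)
        assert f["dissimilarity"] == pytest.approx(1.0)

    def test_constant_patch_point_mass(self):
        g = compute_glcm(qpatch(np.ones((3, 3), int), levels=2), 1, 0)
        assert g.matrix[0, 0] == 1.0
        f = glcm_features(g)
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["contrast"] == 0.0
        assert f["max_probability"] == 1.0

    def test_checkerboard_contrast(self):
        pix = 1 + (np.indices((6, 6)).sum(axis=0) % 2)
        f = glcm_features(compute_glcm(qpatch(pix, levels=2), 1, 0))
        assert f["contrast"] == pytest.approx(1.0)  # every pair differs by 1 level

    def test_symmetric_unit_sum(self, rng):
        q = qpatch(rng.integers(1, 9, (12, 12)), levels=8)
        for ang in (0, 45, 90, 135):
            g = compute_glcm(q, 1, ang)
            assert np.allclose(g.matrix, g.matrix.T)
            assert g.matrix.sum() == pytest.approx(1.0)

    def test_mask_breaks_pairs(self):
        arr = np.array([[1, 0, 2]])
        g = compute_glcm(qpatch(arr, levels=2), distance=1, angle=0)
        assert g.degenerate  # the gap kills the only horizontal pairs

    def test_matches_skimage_on_full_mask(self, rng):
        """Cross-check against scikit-image's graycomatrix (mask-free case)."""
        from skimage.feature import graycomatrix

        img = rng.integers(0, 6, (15, 17))
        q = qpatch(img + 1, levels=6)
        # skimage angles are measured with rows downward; 45 deg there
        # pairs (r+d, c+d) which is our 135 convention
        sk = graycomatrix(img.astype(np.uint8), [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                          levels=6, symmetric=True, normed=True)
        for ours, theirs in [(0, 0), (135, 1), (90, 2), (45, 3)]:
            g = compute_glcm(q, 1, ours)
            assert np.allclose(g.matrix, sk[:, :, 0, theirs], atol=1e-12)

    @given(arrays(np.int64, (4, 4), elements=st.integers(0, 2)))
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_masked(self, arr):
        if (arr > 0).sum() < 2:
            return
        q = qpatch(arr, levels=2)
        for ang in (0, 45, 90, 135):
            ours = compute_glcm(q, 1, ang)
            assert np.allclose(ours.matrix, glcm_oracle(q, 1, ang), atol=1e-12)


# ------------------------------------------------------------------- GLRLM
class TestGlrlm:
    def test_constant_rows(self):
        m = compute_glrlm(qpatch(np.ones((4, 4), int), levels=2), angle=0)
        assert m.n_runs == 4
        assert m.matrix[0, 3] == 4
        f = glrlm_features(m)
        assert f["rp"] == 0.25
        assert f["sre"] == pytest.approx(1 / 16)
        assert f["rln"] == pytest.approx(4.0)
        assert f["lre"] == pytest.approx(16.0)

    def test_hand_run_length_encoding(self):
        m = compute_glrlm(qpatch([[1, 1, 2, 2, 2, 1]], levels=2), angle=0)
        assert m.matrix[0, 1] == 1   # run of 1s, length 2
        assert m.matrix[1, 2] == 1   # run of 2s, length 3
        assert m.matrix[0, 0] == 1   # trailing single 1
        assert m.n_runs == 3

    def test_all_single_runs(self):
        pix = 1 + (np.indices((5, 5)).sum(axis=0) % 2)
        f = glrlm_features(compute_glrlm(qpatch(pix, levels=2), angle=0))
        assert f["sre"] == 1.0
        assert f["lre"] == 1.0
        assert f["rp"] == 1.0

    def test_gln_equals_runs_for_single_level(self):
        m = compute_glrlm(qpatch(np.ones((4, 6), int), levels=3), angle=90)
        f = glrlm_features(m)
        assert f["gln"] == pytest.approx(m.n_runs)

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_pixel_count_conservation(self, rng, angle):
        arr = rng.integers(0, 4, (9, 11))
        if (arr > 0).sum() == 0:
            arr[0, 0] = 1
        m = compute_glrlm(qpatch(arr, levels=3), angle=angle)
        j = np.arange(1, m.matrix.shape[1] + 1)
        assert (m.matrix * j).sum() == (arr > 0).sum()

    @given(arrays(np.int64, (4, 4), elements=st.integers(0, 2)))
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_masked(self, arr):
        if (arr > 0).sum() < 1:
            return
        q = qpatch(arr, levels=2)
        for ang in (0, 45, 90, 135):
            ours = compute_glrlm(q, ang).matrix
            theirs = glrlm_oracle(q, ang)
            # pad to common width before comparing
            w = max(ours.shape[1], theirs.shape[1])
            o = np.zeros((2, w), int); o[:, :ours.shape[1]] = ours
            t = np.zeros((2, w), int); t[:, :theirs.shape[1]] = theirs
            assert np.array_equal(o, t)


# ----------------------------------------------------------------- wavelet
class TestWavelet:
    def test_constant_patch_has_no_detail(self):
        p = RoiPatch(np.full((8, 8), 3.0), np.ones((8, 8), bool), normalized=True)
        sb = wavelet_decompose(p)
        assert np.allclose(sb.LH, 0) and np.allclose(sb.HL, 0) and np.allclose(sb.HH, 0)
        assert np.allclose(sb.LL, sb.LL[0, 0])

    def test_perfect_reconstruction(self, speckle_patch):
        sb = wavelet_decompose(speckle_patch)
        rec = pywt.idwt2((sb.LL, (sb.LH, sb.HL, sb.HH)), "haar", mode="symmetric")
        filled = np.where(speckle_patch.mask, speckle_patch.pixels, 0.0)
        h, w = filled.shape
        assert np.allclose(rec[:h, :w], filled, atol=1e-6)

    def test_horizontal_edge_energizes_vertical_detail(self):
        pix = np.zeros((8, 8))
        pix[3:, :] = 1.0  # horizontal step edge, astride a haar block
        sb = wavelet_decompose(RoiPatch(pix, np.ones((8, 8), bool), normalized=True))
        e = {k: float((getattr(sb, k) ** 2).sum()) for k in ("LH", "HL", "HH")}
        # vertical-variation detail dominates; haar stores it in HL for
        # pywt's (LH=horizontal, HL=vertical) labelling convention
        assert max(e["LH"], e["HL"]) > 10 * e["HH"]
        assert e["LH"] + e["HL"] > 0

    def test_mask_downsampling_block_any(self):
        mask = np.zeros((6, 6), bool)
        mask[0:3, 0:4] = True
        mask[3:6, 1:5] = True
        p = RoiPatch(np.random.default_rng(0).normal(size=(6, 6)), mask, normalized=True)
        sb = wavelet_decompose(p)
        expect = mask.reshape(3, 2, 3, 2).any(axis=(1, 3))
        assert np.array_equal(sb.mask, expect)


# -------------------------------------------------------------- full panel
class TestExtractAll:
    def test_registry_length_is_730(self):
        assert len(DEFAULT_REGISTRY) == 730
        assert len(set(DEFAULT_REGISTRY.names)) == 730

    def test_vector_length_and_order(self, speckle_patch):
        fv = extract_all_features(speckle_patch, patient_id="p1")
        assert len(fv) == 730
        assert fv.names == DEFAULT_REGISTRY.names
        assert np.all(np.isfinite(fv.values))

    def test_deterministic(self, speckle_patch):
        a = extract_all_features(speckle_patch)
        b = extract_all_features(speckle_patch)
        assert np.array_equal(a.values, b.values)

    def test_constant_patch_survives(self):
        p = RoiPatch(np.zeros((10, 10)), np.ones((10, 10), bool),
                     normalized=True, degenerate=True)
        fv = extract_all_features(p)
        assert len(fv) == 730
        assert np.all(np.isfinite(fv.values))
        d = fv.as_dict()
        assert d["orig_firstorder_variance"] == 0.0
        assert d["orig_firstorder_uniformity"] == 1.0
        assert d["orig_glcm_energy_0"] == 1.0

    def test_requires_normalized_patch(self):
        p = RoiPatch(np.random.default_rng(0).normal(size=(8, 8)), np.ones((8, 8), bool))
        with pytest.raises(ValueError, match="normalized"):
            extract_all_features(p)

    def test_rotation_permutes_angle_blocks(self, speckle_patch):
        """Rotating the patch 90 deg swaps the 0/90 and 45/135 texture blocks."""
        fv = extract_all_features(speckle_patch).as_dict()
        rot = RoiPatch(np.rot90(speckle_patch.pixels), np.rot90(speckle_patch.mask),
                       normalized=True)
        fr = extract_all_features(rot).as_dict()
        swap = {0: 90, 90: 0, 45: 135, 135: 45}
        for stat in ("glcm_contrast", "glcm_entropy", "glrlm_sre", "glrlm_rln"):
            for a, b in swap.items():
                assert fv[f"orig_{stat}_{a}"] == pytest.approx(
                    fr[f"orig_{stat}_{b}"], abs=1e-9
                )
        for stat in ("mean", "variance", "entropy", "median"):
            assert fv[f"orig_firstorder_{stat}"] == pytest.approx(
                fr[f"orig_firstorder_{stat}"], abs=1e-9
            )

    def test_intensity_rescaling_invariance(self, rng):
        """Normalization first makes features blind to affine intensity maps."""
        from usradiomics.imaging import GrayImage, RoiMask, extract_roi

        pix = rng.normal(120, 15, (40, 40)).clip(0, 255)
        mask = np.zeros((40, 40), bool)
        mask[8:30, 6:32] = True
        img1 = GrayImage(pix)
        img2 = GrayImage((pix * 0.5 + 40).clip(0, 255))
        f1 = extract_all_features(normalize_patch(extract_roi(img1, RoiMask(mask))))
        f2 = extract_all_features(normalize_patch(extract_roi(img2, RoiMask(mask))))
        assert np.allclose(f1.values, f2.values, atol=1e-6)

    def test_custom_registry_scales_count(self):
        reg = FeatureRegistry(channels=("orig",), angles=(0, 90))
        assert len(reg) == 14 + 22 * 2 + 11 * 2
        fv = extract_all_features(
            RoiPatch(np.random.default_rng(1).normal(size=(12, 12)),
                     np.ones((12, 12), bool), normalized=True),
            registry=reg,
        )
        assert len(fv) == len(reg)
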