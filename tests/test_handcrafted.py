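"""Texture-feature families checked against brute-force enumeration oracles,
closed forms on degenerate images, and invariance properties."""

import numpy as np
import pytest
from conftest import as_proi, sample_gmrf

from mammofuse import handcrafted as hc
from mammofuse.preprocess import pad_resize


def quantized(arr, levels=4):
    return hc.quantize_gray(as_proi(np.asarray(arr, dtype=float)), levels=levels)


from helpers_oracles import glcm_pairs_oracle, runs_oracle  # noqa: E402


def checkerboard(n=4):
    i, j = np.mgrid[0:n, 0:n]
    return ((i + j) % 2).astype(float)


# ---------------------------------------------------------------------------


class TestQuantize:
    def test_bin_edges(self):
        q = quantized([[0.0, 0.5, 1.0]], levels=2)
        np.testing.assert_array_equal(q.pixels, [[0, 1, 1]])

    def test_constant_all_zero(self):
        q = quantized(np.full((4, 4), 0.3), levels=16)
        assert (q.pixels == 0).all()

    def test_max_code_bound_and_monotone(self, rng):
        a = rng.random((20, 20))
        q = hc.quantize_gray(as_proi(a), levels=64)
        assert q.pixels.max() <= 63
        flat_a, flat_q = a.ravel(), q.pixels.ravel()
        order = np.argsort(flat_a)
        assert (np.diff(flat_q[order]) >= 0).all()

    def test_levels_validation(self, gradient_roi):
        with pytest.raises(ValueError):
            hc.quantize_gray(gradient_roi, levels=1)


class TestHistogram:
    def test_constant_closed_form(self):
        f = hc.histogram_features(as_proi(np.full((8, 8), 0.25)))
        mean, var, skew, kurt, energy, entropy, mn, mx, med = f
        assert mean == 0.25 and var == 0 and skew == 0 and kurt == 0
        assert energy == 1.0 and entropy == 0.0
        assert mn == mx == med == 0.25

    def test_two_point_distribution(self):
        a = np.zeros((4, 4))
        a[:, 2:] = 1.0
        f = hc.histogram_features(as_proi(a))
        assert f[0] == pytest.approx(0.5)  # mean
        assert f[5] == pytest.approx(1.0)  # entropy, one bit
        assert f[4] == pytest.approx(0.5)  # energy of the two-point histogram

    def test_symmetric_distribution_zero_skew(self, rng):
        a = np.linspace(0.1, 0.9, 101)
        f = hc.histogram_features(as_proi(a.reshape(1, -1)))
        assert abs(f[2]) < 1e-9


class TestGLCM:
    def test_checkerboard_direction0(self):
        q = quantized(checkerboard(4), levels=2)
        feats = hc.glcm_features(q).reshape(4, 14)
        d0 = feats[0]
        assert d0[0] == pytest.approx(0.5)  # energy: P = [[0,.5],[.5,0]]
        assert d0[1] == pytest.approx(1.0)  # contrast
        # independent oracle on the same fixture
        M = glcm_pairs_oracle(q.pixels, (0, 1), 2)
        P = M / M.sum()
        np.testing.assert_allclose(P, [[0, 0.5], [0.5, 0]])

    def test_constant_image(self):
        q = quantized(np.full((6, 6), 0.4), levels=8)
        feats = hc.glcm_features(q).reshape(4, 14)
        for d in feats:
            assert d[0] == pytest.approx(1.0)  # energy
            assert d[1] == pytest.approx(0.0)  # contrast
            assert d[8] == pytest.approx(0.0)  # entropy

    @pytest.mark.parametrize("direction,offset", list(hc._DIRECTIONS.items()))
    def test_pair_counts_match_oracle(self, rng, direction, offset):
        for _ in range(5):
            a = rng.integers(0, 5, size=(6, 6))
            q = quantized(a / 4.0, levels=5)
            got = hc._pair_counts(q, offset)
            want = glcm_pairs_oracle(q.pixels, offset, 5)
            np.testing.assert_array_equal(got, want)

    def test_matrix_normalized_symmetric(self, gradient_roi):
        q = hc.quantize_gray(gradient_roi, levels=16)
        for offset in hc._DIRECTIONS.values():
            M = hc._pair_counts(q, offset)
            P = M / M.sum()
            assert P.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(P, P.T)

    def test_masked_padding_excluded(self):
        """Padding zeros must not contribute pairs."""
        a = np.random.default_rng(0).random((50, 100)) * 0.9 + 0.1
        roi = pad_resize(a)
        q = hc.quantize_gray(roi)
        M = hc._pair_counts(q, (0, 1))
        content_pairs = 2 * roi.content_shape[0] * (roi.content_shape[1] - 1)
        assert M.sum() == content_pairs


class TestGLGCM:
    def test_constant_image(self):
        f = hc.glgcm_features(as_proi(np.full((8, 8), 0.6)))
        small_grad, joint_entropy = f[0], f[12]
        assert small_grad == pytest.approx(1.0)  # all mass at the smallest gradient bin
        assert joint_entropy == pytest.approx(0.0)

    def test_step_edge_concentration(self):
        """A vertical step edge puts nearly all joint mass in two cells:
        (flat gray, zero gradient) and (edge gray, max gradient)."""
        a = np.zeros((5, 5))
        a[:, 3:] = 1.0
        f = hc.glgcm_features(as_proi(a), q_levels=2, g_levels=2)
        energy = f[4]
        # direct Sobel evaluation: 15 zero-gradient px, 10 max-gradient px
        assert energy == pytest.approx((15 / 25) ** 2 * 0 + (10 / 25) ** 2 + (5 / 25) ** 2 * 2 + 0.0, abs=0.2)
        assert f[12] < 2.0  # joint entropy far below the 2-bit maximum of a 2x2 grid...

    def test_joint_histogram_normalized(self, gradient_roi):
        # descriptors bounded as normalized-histogram functionals
        f = hc.glgcm_features(gradient_roi)
        assert 0 < f[4] <= 1.0  # energy
        assert f[12] >= 0


class TestGLDS:
    def test_constant(self):
        q = quantized(np.full((5, 5), 0.2), levels=8)
        mean, contrast, asm, entropy = hc.glds_features(q)
        assert mean == 0 and contrast == 0 and asm == 1.0 and entropy == 0

    def test_checkerboard_enumeration(self):
        q = quantized(checkerboard(4), levels=2)
        mean, contrast, asm, entropy = hc.glds_features(q)
        # oracle: enumerate |differences| over the four displacements on 4x4
        diffs = []
        a = q.pixels
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            for i in range(4):
                for j in range(4):
                    ii, jj = i + dr, j + dc
                    if 0 <= ii < 4 and 0 <= jj < 4:
                        diffs.append(abs(int(a[i, j]) - int(a[ii, jj])))
        diffs = np.array(diffs)
        assert mean == pytest.approx(diffs.mean())
        assert contrast == pytest.approx((diffs**2).mean())

    def test_histogram_normalized(self, gradient_roi):
        q = hc.quantize_gray(gradient_roi)
        _, _, asm, entropy = hc.glds_features(q)
        assert 0 < asm <= 1 and entropy >= 0


class TestGLRLM:
    def test_single_row_runs(self):
        q = quantized(np.array([[1, 1, 1, 2]]) / 2.0, levels=3)
        feats = hc.glrlm_features(q).reshape(4, 11)
        rp_d0 = feats[0][4]
        assert rp_d0 == pytest.approx(2 / 4)  # two runs, four pixels

    def test_constant_square_lre(self):
        n = 6
        q = quantized(np.full((n, n), 0.7), levels=4)
        feats = hc.glrlm_features(q).reshape(4, 11)
        lre_d0 = feats[0][1]
        assert lre_d0 == pytest.approx(n**2)  # each row is one run of length n

    @pytest.mark.parametrize("direction", list(hc._DIRECTIONS))
    def test_run_matrix_matches_oracle(self, rng, direction):
        for _ in range(5):
            a = rng.integers(0, 3, size=(5, 6))
            q = quantized(a / 2.0, levels=3)
            lines = hc._lines_for_direction(q.pixels, q.content_mask, direction)
            R = hc._run_length_matrix(lines, 3, max_len=6)
            want = np.zeros((3, 6))
            for val, length in runs_oracle(q.pixels, direction):
                want[val, length - 1] += 1
            np.testing.assert_array_equal(R, want)

    @pytest.mark.parametrize("direction", list(hc._DIRECTIONS))
    def test_pixel_conservation(self, rng, direction):
        """Sum over runs of (length x count) equals the number of scanned pixels."""
        a = rng.random((14, 9))
        q = hc.quantize_gray(as_proi(a), levels=8)
        lines = hc._lines_for_direction(q.pixels, q.content_mask, direction)
        R = hc._run_length_matrix(lines, 8, max_len=14)
        j = np.arange(1, 15)
        assert (R * j).sum() == a.size


class TestLBP:
    def test_constant_codes_255(self):
        f = hc.lbp_features(as_proi(np.full((6, 6), 0.5)))
        assert f[255] == 1.0 and f.sum() == pytest.approx(1.0)

    def test_bright_center_codes(self):
        """Direct code computation: the bright pixel reads 0 (all neighbors
        below), dark interior pixels read 255 (ties and the bright neighbor
        all count as >=)."""
        a = np.zeros((5, 5))
        a[2, 2] = 1.0
        f = hc.lbp_features(as_proi(a))
        assert f[0] == pytest.approx(1 / 9)
        assert f[255] == pytest.approx(8 / 9)

    def test_single_gradient_code(self):
        """3x3 fixture, oracle by hand: center 0.5, top-left neighbor 1.0,
        rest 0.0 -> only the MSB fires -> code 128."""
        a = np.zeros((3, 3))
        a[1, 1] = 0.5
        a[0, 0] = 1.0
        f = hc.lbp_features(as_proi(a))
        assert f[128] == 1.0

    def test_histogram_sums_to_one(self, gradient_roi):
        assert hc.lbp_features(gradient_roi).sum() == pytest.approx(1.0, abs=1e-9)


class TestGMRF:
    def test_white_noise_near_zero(self, rng):
        theta = hc.gmrf_features(as_proi(rng.standard_normal((128, 128))))
        np.testing.assert_allclose(theta, 0.0, atol=0.02)

    def test_horizontal_recovery(self):
        field = sample_gmrf((0.4, 0.0, 0.0, 0.0), shape=(128, 128), sweeps=80, seed=11)
        theta = hc.gmrf_features(as_proi(field))
        assert theta[0] == pytest.approx(0.4, abs=0.05)
        np.testing.assert_allclose(theta[1:], 0.0, atol=0.05)

    def test_constant_regularized_path(self):
        with pytest.warns(RuntimeWarning, match="regularized"):
            theta = hc.gmrf_features(as_proi(np.full((8, 8), 0.3)))
        assert np.isfinite(theta).all()


class TestHuMoments:
    def _shape(self, n=128, cy=40, cx=50):
        """An asymmetric two-lobe pattern so all 7 invariants are well away
        from zero (near-zero invariants are meaningless after the log map)."""
        i, j = np.mgrid[0:n, 0:n].astype(float)
        lobe1 = np.exp(-(((i - cy) / 9.0) ** 2 + ((j - cx) / 5.0) ** 2))
        lobe2 = 0.6 * np.exp(-(((i - cy - 14) / 4.0) ** 2 + ((j - cx - 7) / 12.0) ** 2))
        p = lobe1 + lobe2
        return np.where(p > 1e-8, p, 0.0)  # compact support: integer shifts permute exactly

    def test_translation_invariance(self):
        ha = hc.hu_moments(as_proi(self._shape(cy=45, cx=45)))
        hb = hc.hu_moments(as_proi(self._shape(cy=55, cx=62)))  # shifted (10, 17)
        np.testing.assert_allclose(ha, hb, rtol=1e-6)

    def test_rotation_invariance(self):
        a = self._shape()
        ha = hc.hu_moments(as_proi(a))
        hb = hc.hu_moments(as_proi(np.rot90(a)))
        np.testing.assert_allclose(ha, hb, rtol=1e-6)

    def test_scale_invariance(self):
        from skimage.transform import rescale

        a = self._shape(n=64, cy=20, cx=26)
        b = rescale(a, 2.0, order=1, anti_aliasing=False)
        np.testing.assert_allclose(hc.hu_moments(as_proi(a)), hc.hu_moments(as_proi(b)), rtol=1e-2)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError):
            hc.hu_moments(as_proi(np.zeros((10, 10))))


class TestGabor:
    def test_constant_zero_std(self):
        roi = pad_resize(np.full((224, 224), 0.8))
        f = hc.gabor_features(roi).reshape(20, 3)
        np.testing.assert_allclose(f[:, 1], 0.0, atol=1e-9)

    def test_grating_matches_tuned_filter(self):
        j = np.mgrid[0:224, 0:224][1].astype(float)
        grating = 0.5 + 0.5 * np.sin(2 * np.pi * j / 8.0)  # vertical stripes, wavelength 8
        roi = pad_resize(grating)
        means = hc.gabor_features(roi).reshape(20, 3)[:, 0]
        best = int(np.argmax(means))
        lam_idx, ori_idx = divmod(best, 5)
        assert hc.GABOR_WAVELENGTHS[lam_idx] == 8
        assert hc.GABOR_ORIENTATIONS_DEG[ori_idx] == 0

    def test_bank_cardinality(self, gradient_roi):
        assert hc.gabor_features(gradient_roi).shape == (60,)


class TestExtract:
    def test_total_and_family_slices(self, gradient_roi):
        fv = hc.extract_handcrafted(gradient_roi)
        assert fv.values.shape == (455,)
        assert np.isfinite(fv.values).all()
        dims = [d for _, d in hc.FAMILY_DIMS]
        assert dims == [9, 7, 56, 15, 4, 44, 256, 4, 60]
        assert len(fv.family("lbp")) == 256

    def test_deterministic(self, gradient_roi):
        a = hc.extract_handcrafted(gradient_roi).values
        b = hc.extract_handcrafted(gradient_roi).values
        np.testing.assert_array_equal(a, b)

    def test_names_stable_and_unique(self):
        names = hc.feature_names()
        assert len(names) == 455 and len(set(names)) == 455
        assert names == hc.FEATURE_NAMES

    def test_family_error_identified(self):
        tiny = as_proi(np.full((2, 2), 0.5))  # too small for 3x3 families
        with pytest.raises(hc.FeatureExtractionError, match="glgcm"):
            hc.extract_handcrafted(tiny)
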