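"""ROI spectra, spectral cropping, SPA selection and 2-D wavelet features."""

import itertools

import numpy as np
import pytest

from teafuse.containers import SpectralCube
from teafuse.hsi import (
    RoiSpectrum,
    crop_spectrum,
    extract_hsi_features,
    extract_roi_spectrum,
    hsi_feature_names,
    spa_chain,
    spa_select,
    wavelet_subband_features,
)


def _cube(data):
    b = data.shape[2]
    return SpectralCube(data, 908.0 + 2.0 * np.arange(b))


class TestRoiSpectrum:
    def test_uniform_cube(self):
        cube = _cube(np.full((60, 60, 5), 0.4))
        spec = extract_roi_spectrum(cube, roi_size=50)
        np.testing.assert_allclose(spec.reflectance, 0.4)

    def test_border_excluded(self):
        data = np.zeros((60, 60, 3))
        data[5:55, 5:55, :] = 1.0  # exactly the centered 50x50 window
        spec = extract_roi_spectrum(_cube(data), roi_size=50)
        np.testing.assert_allclose(spec.reflectance, 1.0)

    def test_matches_double_loop(self, rng):
        data = rng.random((12, 14, 4))
        cube = _cube(data)
        spec = extract_roi_spectrum(cube, roi_size=6)
        r0, c0 = (12 - 6) // 2, (14 - 6) // 2
        for b in range(4):
            acc = 0.0
            for i in range(6):
                for j in range(6):
                    acc += data[r0 + i, c0 + j, b]
            assert spec.reflectance[b] == pytest.approx(acc / 36, rel=1e-12)

    def test_roi_too_large(self):
        with pytest.raises(ValueError):
            extract_roi_spectrum(_cube(np.ones((10, 10, 2))), roi_size=50)


class TestCrop:
    def _spec(self, n=397):
        wl = 908.0 + 2.0 * np.arange(n)
        return RoiSpectrum(wl, np.linspace(0.3, 0.6, n))

    def test_study_crop_retains_interval(self):
        out = crop_spectrum(self._spec(), 944.0, 1688.0)
        assert out.wavelengths.min() >= 944 and out.wavelengths.max() <= 1688
        assert len(out.wavelengths) == 373  # (1688-944)/2 + 1 on the 2-nm grid

    def test_full_range_is_identity(self):
        s = self._spec()
        out = crop_spectrum(s, 908.0, 1700.0)
        np.testing.assert_array_equal(out.wavelengths, s.wavelengths)

    def test_empty_crop_rejected(self):
        with pytest.raises(ValueError):
            crop_spectrum(self._spec(), 1.0, 2.0)


# ---- exhaustive SPA oracle (literal projection chains) ----


def oracle_spa(X, y, wavelengths, k):
    n = X.shape[0]
    val = np.zeros(n, dtype=bool)
    val[3::4] = True
    best = None
    for start in range(X.shape[1]):
        chain = [start]
        for _ in range(k - 1):
            # explicit Gram-Schmidt against all selected columns
            best_norm, best_j = -1.0, None
            for j in range(X.shape[1]):
                if j in chain:
                    continue
                v = X[:, j].astype(float).copy()
                Q, _ = np.linalg.qr(X[:, chain])
                v = v - Q @ (Q.T @ v)
                norm = float(v @ v)
                if norm > best_norm + 1e-30:
                    best_norm, best_j = norm, j
            chain.append(best_j)
        A = np.column_stack([np.ones(n), X[:, chain]])
        coef, *_ = np.linalg.lstsq(A[~val], y[~val], rcond=None)
        rmse = float(np.sqrt(np.mean((y[val] - A[val] @ coef) ** 2)))
        key = (rmse, tuple(sorted(chain)))
        if best is None or key < best[0]:
            best = (key, chain)
    return wavelengths[sorted(best[1])]


class TestSpa:
    def test_orthogonal_columns_chain_picks_largest_norms(self, rng):
        # orthogonal design: the chain from the largest-norm start adds
        # the second-largest column
        Q, _ = np.linalg.qr(rng.standard_normal((20, 6)))
        scales = np.array([5.0, 1.0, 3.0, 0.5, 2.0, 4.0])
        X = Q * scales
        chain = spa_chain(X, start=0, k=2)
        assert chain == [0, 5]  # next-largest norm among the rest

    def test_duplicate_column_never_selected_twice(self, rng):
        X = rng.standard_normal((15, 4))
        X[:, 3] = X[:, 1]  # duplicate
        chain = spa_chain(X, start=1, k=3)
        assert 3 not in chain

    @pytest.mark.parametrize("n_bands,k", [(5, 2), (8, 2), (8, 3)])
    def test_agrees_with_exhaustive_oracle(self, rng, n_bands, k):
        for _ in range(5):
            X = rng.standard_normal((24, n_bands))
            beta = rng.standard_normal(n_bands)
            y = X @ beta + 0.1 * rng.standard_normal(24)
            wl = 1000.0 + 10.0 * np.arange(n_bands)
            got = spa_select(X, y, wl, k=k)
            want = oracle_spa(X, y, wl, k=k)
            np.testing.assert_array_equal(got, want)

    def test_k_exceeding_bands_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            spa_select(X, rng.standard_normal(10), np.arange(3.0), k=4)


class TestWaveletSubbands:
    def test_constant_image_zero_details(self):
        out = wavelet_subband_features(np.full((50, 50), 0.7))
        for key, val in out.items():
            assert val == pytest.approx(0.0, abs=1e-20), key

    def test_energy_scales_quadratically_entropy_invariant(self, rng):
        img = rng.random((50, 50))
        f1 = wavelet_subband_features(img)
        f2 = wavelet_subband_features(3.0 * img)
        for key in f1:
            if key.endswith("_WE"):
                assert f2[key] == pytest.approx(9.0 * f1[key], rel=1e-9)
            else:
                assert f2[key] == pytest.approx(f1[key], rel=1e-9)

    def test_single_coefficient_energy_has_zero_entropy(self):
        # an image whose level-1 HH band has exactly one nonzero coefficient
        import pywt

        coeffs = pywt.wavedec2(np.zeros((32, 32)), "db4", mode="periodization", level=2)
        cH1, cV1, cD1 = (np.zeros_like(c) for c in coeffs[-1])
        cD1[3, 3] = 2.5
        coeffs = [coeffs[0], tuple(coeffs[1]), (cH1, cV1, cD1)]
        img = pywt.waverec2(coeffs, "db4", mode="periodization")
        out = wavelet_subband_features(img)
        assert out["HH1_WE"] > 0
        assert out["HH1_WEN"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("size", [48, 64])
    def test_parseval_energy_conservation(self, rng, size):
        # sizes divisible by 2^levels: no odd-length padding is involved
        # and the periodized transform is exactly orthonormal
        import pywt

        img = rng.standard_normal((size, size))
        coeffs = pywt.wavedec2(img, "db4", mode="periodization", level=2)
        total = np.sum(coeffs[0] ** 2) + sum(
            np.sum(c**2) for det in coeffs[1:] for c in det
        )
        assert total == pytest.approx(np.sum(img**2), rel=1e-9)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            wavelet_subband_features(np.ones((3, 3)))


class TestExtractHsiFeatures:
    def test_24_named_features(self, rng):
        cube = _cube(rng.random((60, 60, 397)).astype(np.float32))
        out = extract_hsi_features(cube, (1106.0, 1375.0))
        assert len(out) == 24
        assert set(out) == set(hsi_feature_names())
        assert "B1_HL1_WE" in out and "B2_HL2_WE" in out
        assert all(np.isfinite(v) for v in out.values())
        assert all(v >= 0 for k, v in out.items() if k.endswith("_WE"))

    def test_locality_only_feature_bands_matter(self, rng):
        data = rng.random((60, 60, 397)).astype(np.float64)
        cube1 = _cube(data)
        data2 = data.copy()
        i1 = cube1.band_index(1106.0)
        i2 = cube1.band_index(1375.0)
        mask = np.ones(397, bool)
        mask[[i1, i2]] = False
        data2[:, :, mask] = rng.random((60, 60, mask.sum()))
        out1 = extract_hsi_features(cube1, (1106.0, 1375.0))
        out2 = extract_hsi_features(_cube(data2), (1106.0, 1375.0))
        assert out1 == out2

    def test_wavelength_outside_crop_rejected(self, rng):
        cube = _cube(rng.random((60, 60, 397)))
        with pytest.raises(ValueError, match="outside"):
            extract_hsi_features(cube, (920.0, 1375.0))
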