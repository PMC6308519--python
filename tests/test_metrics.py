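import numpy as np
import pytest
from scipy import stats

from lair.metrics import (
    ProfileLine,
    ROISpec,
    cnr,
    fwhm,
    linearity,
    mse,
    psnr,
    roi_pixels,
    rtv,
    sample_profile,
    snr,
    ssim,
    uiqi,
)

RNG = np.random.default_rng(123)
GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


class TestPSNR:
    def test_identical_images_give_inf_sentinel(self):
        f = RNG.random((8, 8))
        assert psnr(f, f) == float("inf")

    def test_hand_case_20db(self):
        # peak 1, MSE 0.01 -> exactly 20 dB
        f1 = np.array([1.0, 0.0])
        f2 = np.array([1.0, np.sqrt(0.02)])
        assert psnr(f1, f2) == pytest.approx(20.0, abs=1e-10)

    def test_hand_case_two_pixels(self):
        f1 = np.array([0.0, 1.0])
        f2 = np.array([0.0, 0.9])
        assert mse(f1, f2) == pytest.approx(0.005)
        assert psnr(f1, f2) == pytest.approx(23.0103, abs=1e-4)

    def test_symmetric_and_uses_joint_peak(self):
        f1 = RNG.random((16, 16))
        f2 = RNG.random((16, 16)) * 2.0  # peak carried by f2 only
        assert psnr(f1, f2) == pytest.approx(psnr(f2, f1), rel=1e-12)


class TestUIQI:
    def test_identity(self):
        f = RNG.random((10, 10))
        assert uiqi(f, f) == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_reduces_to_luminance_term(self):
        f1 = RNG.random((10, 10)) + 1.0
        c = 0.5
        f2 = f1 + c
        mu1, mu2 = f1.mean(), f2.mean()
        assert uiqi(f1, f2) == pytest.approx(
            2 * mu1 * mu2 / (mu1**2 + mu2**2), rel=1e-10
        )
        assert uiqi(f1, f2) < 1.0

    def test_sign_inversion_zero_mean(self):
        f = RNG.random((10, 10))
        f -= f.mean()
        assert uiqi(f, -f) == pytest.approx(-1.0, abs=1e-12)

    def test_never_exceeds_one(self):
        for _ in range(20):
            a = RNG.random((6, 6)) * RNG.uniform(0.1, 5)
            b = RNG.random((6, 6)) * RNG.uniform(0.1, 5)
            assert uiqi(a, b) <= 1.0 + 1e-12


class TestSSIM:
    def test_identity(self):
        f = RNG.random((32, 32))
        assert ssim(f, f, dynamic_range=1.0) == pytest.approx(1.0, abs=1e-9)
        assert ssim(f, f, dynamic_range=1.0, mode="global") == pytest.approx(1.0, abs=1e-9)

    def test_constants_for_unit_range(self):
        # c1 = (0.01 L)^2, c2 = (0.03 L)^2 with L = 1: verify through the
        # closed form for two constant images differing by d
        mu1, mu2 = 0.4, 0.6
        f1 = np.full((16, 16), mu1)
        f2 = np.full((16, 16), mu2)
        c1, c2 = 1e-4, 9e-4
        expected = (2 * mu1 * mu2 + c1) / (mu1**2 + mu2**2 + c1)
        assert ssim(f1, f2, dynamic_range=1.0, mode="global") == pytest.approx(
            expected, rel=1e-12
        )
        assert ssim(f1, f2, dynamic_range=1.0) == pytest.approx(expected, rel=1e-6)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.ones((4, 4)), np.ones((4, 4)), dynamic_range=0.0)


class TestRTV:
    def test_identity_and_homogeneity(self):
        f = RNG.random((12, 12))
        assert rtv(f, f) == pytest.approx(1.0, rel=1e-12)
        assert rtv(2 * f, f) == pytest.approx(2.0, rel=1e-12)

    def test_smoothing_reduces_rtv(self):
        from scipy.ndimage import uniform_filter

        f = RNG.random((32, 32))
        assert rtv(uniform_filter(f, 3), f) < 1.0

    def test_asymmetric_ratio(self):
        f = RNG.random((8, 8))
        g = f + RNG.random((8, 8))
        assert rtv(f, g) != pytest.approx(rtv(g, f))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            rtv(RNG.random((4, 4)), np.ones((4, 4)))


def _fill_roi(img: np.ndarray, roi: ROISpec, vox: float, mean: float, std: float, seed: int) -> None:
    """Fill exactly the ROI's pixels with values of prescribed mean/std."""
    idx = roi_pixels(np.arange(img.size, dtype=float).reshape(img.shape), roi, vox)
    sel = idx.astype(int)
    a = np.random.default_rng(seed).standard_normal(sel.size)
    a = (a - a.mean()) / a.std() * std + mean
    img.flat[sel] = a


class TestRoiStatistics:
    def test_cnr_hand_case(self):
        # mu_sig 10, mu_bg 4, sigma_sig 3, sigma_bg 4 -> CNR 6/5 = 1.2
        img = np.zeros((64, 64))
        sig = ROISpec((-10.0, 0.0)); bg = ROISpec((10.0, 0.0))
        _fill_roi(img, sig, 1.0, mean=10.0, std=3.0, seed=0)
        _fill_roi(img, bg, 1.0, mean=4.0, std=4.0, seed=1)
        assert cnr(img, sig, bg, 1.0) == pytest.approx(1.2, rel=1e-10)

    def test_snr_hand_case(self):
        img = np.zeros((64, 64))
        roi = ROISpec((0.0, 0.0))
        _fill_roi(img, roi, 1.0, mean=10.0, std=2.0, seed=2)
        assert snr(img, roi, 1.0) == pytest.approx(5.0, rel=1e-10)

    def test_identical_rois_give_zero_cnr(self):
        img = RNG.random((64, 64))
        roi = ROISpec((0.0, 0.0))
        assert cnr(img, roi, roi, 1.0) == 0.0

    def test_out_of_bounds_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_pixels(np.zeros((16, 16)), ROISpec((100.0, 0.0)), 1.0)


class TestFWHM:
    def test_noiseless_gaussian_sigma_10px(self):
        x = np.arange(200, dtype=float)
        y = 3.0 * np.exp(-0.5 * ((x - 90.0) / 10.0) ** 2) + 0.2
        assert fwhm(x, y) == pytest.approx(GAUSS_FWHM * 10.0, rel=1e-3)

    def test_amplitude_invariance(self):
        x = np.linspace(-50, 50, 301)
        y = np.exp(-0.5 * (x / 7.0) ** 2)
        assert fwhm(x, 5.0 * y) == pytest.approx(fwhm(x, y), rel=1e-9)

    def test_micro_ct_wire_sigma(self):
        # sigma = 21.739 um -> FWHM = 2 sqrt(2 ln 2) sigma = 51.19 um
        x = np.linspace(-200, 200, 801)
        y = np.exp(-0.5 * (x / 21.739) ** 2)
        assert fwhm(x, y) == pytest.approx(51.19, abs=0.01)

    def test_profile_sampling_through_image(self):
        img = np.zeros((64, 64))
        xs, ys = np.meshgrid(np.arange(64) - 31.5, np.arange(64) - 31.5)
        img += np.exp(-0.5 * ((xs**2 + ys**2) / 4.0**2))
        line = ProfileLine((-20.0, 0.0), (20.0, 0.0), n_samples=400)
        s, v = sample_profile(img, line, voxel_mm=1.0)
        assert fwhm(s, v) == pytest.approx(GAUSS_FWHM * 4.0, rel=0.02)


class TestLinearity:
    def test_proportional_means_give_unit_correlation(self):
        img = np.zeros((64, 64))
        densities = [0.0, 100.0, 200.0, 400.0, 800.0]
        centers = [(-20.0, 0.0), (-10.0, 0.0), (0.0, 0.0), (10.0, 0.0), (20.0, 0.0)]
        inserts = []
        for (cx, cy), d in zip(centers, densities):
            roi = ROISpec((cx, cy))
            j = int(cx + 32)
            img[31:34, j - 1 : j + 2] = 0.01 + 2e-5 * d
            inserts.append((roi, d))
        assert linearity(img, inserts, 1.0) == pytest.approx(1.0, abs=1e-12)
        neg = [(roi, -d) for roi, d in inserts]
        assert linearity(img, neg, 1.0) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pearson_formula(self):
        img = RNG.random((64, 64))
        inserts = [
            (ROISpec((x, 0.0)), float(d))
            for x, d in zip((-20.0, -10.0, 0.0, 10.0, 20.0), RNG.random(5) * 100)
        ]
        means = [roi_pixels(img, roi, 1.0).mean() for roi, _ in inserts]
        expected = stats.pearsonr(means, [d for _, d in inserts])[0]
        assert linearity(img, inserts, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_too_few_inserts_rejected(self):
        with pytest.raises(ValueError):
            linearity(np.ones((8, 8)), [(ROISpec((0, 0)), 1.0)], 1.0)
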