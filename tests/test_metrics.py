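import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cspd.metrics import (VesselProfile, count_profile_peaks, extract_profile,
                          fourier_resolution, fwhm, mse_nip, normalize01,
                          psnr, ssim, upsample_image)

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _profile(values, spacing_um=1.0):
    v = np.asarray(values, dtype=float)
    return VesselProfile(positions_um=np.arange(v.size) * spacing_um,
                         intensities=v)


def test_psnr_uniform_offset():
    a = np.zeros((16, 16))
    assert psnr(a, a + 0.1) == pytest.approx(20.0, abs=1e-9)


def test_psnr_identical_is_infinite():
    a = np.random.default_rng(0).random((8, 8))
    assert np.isinf(psnr(a, a))


def test_ssim_self_is_one(rng):
    a = rng.random((32, 32))
    assert ssim(a, a) == pytest.approx(1.0, abs=1e-9)


def test_ssim_decreases_with_noise(rng):
    a = rng.random((32, 32))
    b = np.clip(a + 0.3 * rng.standard_normal(a.shape), 0, 1)
    assert ssim(a, b) < ssim(a, a)


def test_fwhm_gaussian_closed_form():
    sigma_um = 12.0
    x = np.linspace(-60, 60, 241)
    prof = VesselProfile(positions_um=x, intensities=np.exp(-x ** 2 / (2 * sigma_um ** 2)))
    assert fwhm(prof) == pytest.approx(FWHM_PER_SIGMA * sigma_um, rel=0.02)


def test_fwhm_flat_profile_raises():
    with pytest.raises(ValueError):
        fwhm(_profile(np.ones(32)))


def test_fwhm_truncated_profile_raises():
    x = np.linspace(0, 30, 31)
    with pytest.raises(ValueError):
        fwhm(VesselProfile(positions_um=x,
                           intensities=np.exp(-(x - 30.0) ** 2 / 50.0)))


def test_mse_nip_analytic():
    a = _profile([1.0, 0.5, 1.0, 0.5, 1.0, 0.5])
    b = _profile([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    assert mse_nip(a, b) == pytest.approx(0.125, abs=1e-12)


def test_mse_nip_peak_normalization_invariance():
    a = _profile([2.0, 1.0, 2.0, 1.0, 2.0, 1.0])
    b = _profile([5.0, 0.0, 5.0, 0.0, 5.0, 0.0])
    assert mse_nip(a, b) == pytest.approx(0.125, abs=1e-12)


def test_count_profile_peaks():
    x = np.linspace(-30, 30, 121)
    two = np.exp(-(x - 10) ** 2 / 18.0) + np.exp(-(x + 10) ** 2 / 18.0)
    one = np.exp(-x ** 2 / 200.0)
    assert count_profile_peaks(VesselProfile(x, two)) == 2
    assert count_profile_peaks(VesselProfile(x, one)) == 1


def test_extract_profile_geometry(rng):
    img = np.zeros((64, 64))
    img[:, 32] = 1.0  # vertical line at x = 32 px
    pitch = 0.025
    line = ((32 * pitch - 0.2, 32 * pitch), (32 * pitch + 0.2, 32 * pitch))
    prof = extract_profile(img, pitch, line, n_samples=81)
    assert prof.intensities.max() == pytest.approx(1.0, abs=1e-6)
    peak_um = prof.positions_um[np.argmax(prof.intensities)]
    assert abs(peak_um - 200.0) < 10.0  # peak at line center


def test_extract_profile_band_average(rng):
    img = rng.random((64, 64))
    pitch = 0.025
    line = ((0.2, 0.8), (1.4, 0.8))
    plain = extract_profile(img, pitch, line)
    banded = extract_profile(img, pitch, line, average_half_width_mm=0.1)
    assert plain.intensities.shape == banded.intensities.shape
    assert np.std(banded.intensities) < np.std(plain.intensities)


def test_fourier_resolution_self_consistency(rng):
    pd = gaussian_filter(rng.random((128, 128)), 2.0)
    wavelength_um = 77.0
    r = fourier_resolution(pd, pd, wavelength_um, 25.0)
    assert r == pytest.approx(wavelength_um, rel=0.05)


def test_fourier_resolution_blur_is_coarser(rng):
    pd = gaussian_filter(rng.random((128, 128)), 1.0)
    blurred = gaussian_filter(pd, 3.0)
    r_sharp = fourier_resolution(pd, pd, 77.0, 25.0)
    r_blur = fourier_resolution(pd, blurred, 77.0, 25.0)
    assert r_blur > r_sharp


def test_normalize01():
    img = np.array([[1.0, 3.0], [5.0, 2.0]])
    out = normalize01(img)  # max-scaling of a nonnegative image
    assert out.max() == 1.0 and out.min() == pytest.approx(0.2)
    assert np.array_equal(normalize01(np.zeros((3, 3))), np.zeros((3, 3)))


def test_upsample_image_shape_and_range(rng):
    img = rng.random((16, 16))
    up = upsample_image(img, 4)
    assert up.shape == (64, 64)
    assert up.min() >= img.min() - 1e-9 and up.max() <= img.max() + 1e-9
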