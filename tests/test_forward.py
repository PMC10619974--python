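import numpy as np
import pytest

from cspd.forward import (SpatiotemporalBlock, make_gaussian_psf,
                          synthesize_block)
from cspd.vasculature import ScattererTrajectorySet


def _static_traj(x_mm, z_mm, n_frames=4, amp=1.0, dt=1e-3):
    pos = np.tile(np.array([[x_mm, z_mm]], dtype=float), (n_frames, 1))[None]
    return ScattererTrajectorySet(
        positions=pos, amplitudes=np.array([amp]),
        alive_mask=np.ones((1, n_frames), dtype=bool), frame_interval=dt,
        segment_index=np.zeros(1, dtype=int))


def test_psf_properties():
    psf = make_gaussian_psf(0.077, 1.0, 0.005)
    k = psf.kernel
    assert k.shape[0] % 2 == 1 and k.shape[1] % 2 == 1
    assert abs(np.sum(k ** 2) - 1.0) < 1e-9
    assert np.count_nonzero(k == k.max()) == 1
    # lateral FWHM = wavelength * f_number, measured on the center row
    row = k[k.shape[0] // 2]
    half = row.max() / 2.0
    width_px = np.sum(row >= half)
    assert abs(width_px * 0.005 - 0.077) < 2 * 0.005


def test_psf_invalid_arguments():
    for bad in ((0.0, 1.0, 0.005), (0.077, -1.0, 0.005), (0.077, 1.0, 0.0)):
        with pytest.raises(ValueError):
            make_gaussian_psf(*bad)


def test_psf_undersampling_warns():
    with pytest.warns(RuntimeWarning):
        make_gaussian_psf(0.077, 1.0, 0.025)


def test_single_scatterer_on_pixel_is_kernel():
    psf = make_gaussian_psf(0.077, 1.0, 0.005)
    traj = _static_traj(32 * 0.005, 32 * 0.005, n_frames=2, amp=2.0)
    blk = synthesize_block(traj, psf, (64, 64), 0.0, 0.0, seed=0)
    frame = blk.data[:, :, 0]
    iz, ix = np.unravel_index(np.argmax(frame), frame.shape)
    assert (iz, ix) == (32, 32)
    kz, kx = psf.kernel.shape
    sub = frame[32 - kz // 2:32 + kz // 2 + 1, 32 - kx // 2:32 + kx // 2 + 1]
    np.testing.assert_allclose(sub, 2.0 * psf.kernel, atol=1e-12)


def test_subpixel_centroid_preserved():
    """Bilinear deposition preserves the echo centroid for subpixel shifts."""
    psf = make_gaussian_psf(0.077, 1.0, 0.005)
    x_mm, z_mm = 31.3 * 0.005, 32.6 * 0.005
    blk = synthesize_block(_static_traj(x_mm, z_mm), psf, (64, 64), 0.0, 0.0,
                           seed=0)
    frame = blk.data[:, :, 0]
    zz, xx = np.mgrid[0:64, 0:64]
    cx = np.sum(xx * frame) / np.sum(frame)
    cz = np.sum(zz * frame) / np.sum(frame)
    assert abs(cx * 0.005 - x_mm) < 1e-9
    assert abs(cz * 0.005 - z_mm) < 1e-9


def test_clutter_rank_at_most_two():
    psf = make_gaussian_psf(0.077, 1.0, 0.005)
    traj = _static_traj(0.1, 0.1, n_frames=32, amp=0.0)
    blk = synthesize_block(traj, psf, (32, 32), 10.0, 0.0, seed=5)
    C = blk.data.reshape(-1, 32)
    s = np.linalg.svd(C, compute_uv=False)
    assert s[2] / s[0] < 1e-10


def test_noise_statistics():
    psf = make_gaussian_psf(0.077, 1.0, 0.005)
    traj = _static_traj(0.1, 0.1, n_frames=16, amp=0.0)
    blk = synthesize_block(traj, psf, (32, 32), 0.0, 0.5, seed=2)
    assert abs(np.std(blk.data) - 0.5) < 0.02


def test_synthesis_determinism():
    psf = make_gaussian_psf(0.077, 1.0, 0.005)
    traj = _static_traj(0.05, 0.07, n_frames=8)
    a = synthesize_block(traj, psf, (32, 32), 5.0, 0.1, seed=9)
    b = synthesize_block(traj, psf, (32, 32), 5.0, 0.1, seed=9)
    np.testing.assert_array_equal(a.data, b.data)


def test_negative_noise_rejected():
    psf = make_gaussian_psf(0.077, 1.0, 0.005)
    with pytest.raises(ValueError):
        synthesize_block(_static_traj(0.1, 0.1), psf, (32, 32), 0.0, -0.1)


def test_block_validation():
    with pytest.raises(ValueError):
        SpatiotemporalBlock(data=np.zeros((4, 4)), pixel_pitch=0.025,
                            frame_rate=1000.0)
    with pytest.raises(ValueError):
        SpatiotemporalBlock(data=np.full((4, 4, 2), np.nan),
                            pixel_pitch=0.025, frame_rate=1000.0)
    with pytest.raises(ValueError):
        SpatiotemporalBlock(data=np.zeros((4, 4, 2)), pixel_pitch=0.025,
                            frame_rate=0.0)


def test_complex_mode_block():
    psf = make_gaussian_psf(0.077, 1.0, 0.005)
    blk = synthesize_block(_static_traj(0.1, 0.1, n_frames=4), psf, (32, 32),
                           1.0, 0.01, seed=3, complex_mode=True)
    assert np.iscomplexobj(blk.data)
    assert np.all(np.isfinite(blk.data.real))
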