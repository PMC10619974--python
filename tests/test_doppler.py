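import numpy as np
import pytest

from cspd.doppler import (SvdFilterSpec, adaptive_cutoff, casorati_svd,
                          flow_separation_augment, power_doppler,
                          sliding_window_series, svd_clutter_filter, to_db,
                          truncate_and_interpolate)
from cspd.forward import SpatiotemporalBlock


def _block(data, kind="raw"):
    return SpatiotemporalBlock(data=np.asarray(data, dtype=float),
                               pixel_pitch=0.025, frame_rate=1000.0, kind=kind)


def _random_block(rng, shape=(8, 8, 16), kind="raw"):
    return _block(rng.standard_normal(shape), kind=kind)


def test_casorati_reconstruction(rng):
    blk = _random_block(rng)
    U, s, Vh = casorati_svd(blk)
    np.testing.assert_allclose((U * s) @ Vh,
                               blk.data.reshape(-1, blk.n_frames), atol=1e-10)


def test_filter_requires_raw(rng):
    blk = _random_block(rng, kind="clutter_filtered")
    with pytest.raises(ValueError):
        svd_clutter_filter(blk, SvdFilterSpec(low_cutoff=1))


def test_filter_energy_never_grows(rng):
    blk = _random_block(rng)
    filt = svd_clutter_filter(blk, SvdFilterSpec(low_cutoff=3))
    assert filt.energy() <= blk.energy() + 1e-9
    assert filt.kind == "clutter_filtered"


def test_filter_zero_cutoff_identity(rng):
    blk = _random_block(rng)
    filt = svd_clutter_filter(blk, SvdFilterSpec(low_cutoff=0))
    np.testing.assert_allclose(filt.data, blk.data, atol=1e-10)


def test_filter_removes_rank_one_component(rng):
    f = rng.standard_normal((8, 8))
    clutter = np.repeat(f[:, :, None], 16, axis=2)
    blk = _block(100.0 * clutter + 0.01 * rng.standard_normal((8, 8, 16)))
    filt = svd_clutter_filter(blk, SvdFilterSpec(low_cutoff=1))
    assert filt.energy() / blk.energy() < 1e-4


def test_spec_validation():
    with pytest.raises(ValueError):
        SvdFilterSpec(low_cutoff=16).validate(16)
    with pytest.raises(ValueError):
        SvdFilterSpec(low_cutoff=2, high_cutoff=14).validate(16)


def test_power_doppler_brute_force(rng):
    blk = _random_block(rng, kind="clutter_filtered")
    pd = power_doppler(blk)
    np.testing.assert_allclose(pd.intensity,
                               np.mean(np.abs(blk.data) ** 2, axis=2),
                               atol=1e-12)
    with pytest.raises(ValueError):
        power_doppler(_random_block(rng, kind="raw"))


def test_flow_band_partition(rng):
    blk = _random_block(rng, kind="clutter_filtered")
    for n_bands in (2, 3, 5):
        bands = flow_separation_augment(blk, n_bands)
        assert len(bands) == n_bands
        total = sum(b.data for b in bands)
        np.testing.assert_allclose(total, blk.data, atol=1e-9)


def test_truncate_and_interpolate_identity(rng):
    blk = _random_block(rng, kind="clutter_filtered")
    out = truncate_and_interpolate(blk, keep_every=1)
    np.testing.assert_allclose(out.data, blk.data, atol=1e-12)


def test_truncate_and_interpolate_linear_exact():
    t = np.arange(16, dtype=float)
    data = np.broadcast_to(2.0 * t + 1.0, (4, 4, 16)).copy()
    blk = _block(data, kind="clutter_filtered")
    out = truncate_and_interpolate(blk, keep_every=4)
    assert out.n_frames == blk.n_frames
    # exact between kept samples; the tail beyond the last kept frame is
    # edge-clamped
    np.testing.assert_allclose(out.data[:, :, :13], blk.data[:, :, :13],
                               atol=1e-9)
    np.testing.assert_allclose(
        out.data[:, :, 13:],
        np.broadcast_to(blk.data[:, :, 12:13], (4, 4, 3)), atol=1e-9)


def test_sliding_window_counts(rng):
    blk = _random_block(rng, shape=(4, 4, 400))
    imgs, times = sliding_window_series(
        blk, 200, 50, lambda b: np.mean(b.data ** 2, axis=2))
    assert len(imgs) == 5
    np.testing.assert_allclose(np.diff(times), 0.05)


def test_sliding_window_full_equals_whole(rng):
    blk = _random_block(rng, shape=(4, 4, 64), kind="clutter_filtered")
    imgs, _ = sliding_window_series(blk, 64, 16,
                                    lambda b: power_doppler(b).intensity)
    assert len(imgs) == 1
    np.testing.assert_allclose(imgs[0], power_doppler(blk).intensity)


def test_adaptive_cutoff_detects_knee(rng):
    f1 = rng.standard_normal((8, 8))
    clutter = 1000.0 * np.repeat(f1[:, :, None], 32, axis=2)
    blk = _block(clutter + rng.standard_normal((8, 8, 32)))
    k = adaptive_cutoff(blk)
    assert 1 <= k <= 3


def test_to_db_range(rng):
    img = np.abs(rng.standard_normal((8, 8))) + 1e-6
    db = to_db(img, dynamic_range_db=40.0)
    assert db.max() <= 1.0 + 1e-9 and db.min() >= 0.0
    assert db.flat[np.argmax(img)] == pytest.approx(1.0)
    assert np.array_equal(to_db(np.zeros((4, 4))), np.zeros((4, 4)))
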