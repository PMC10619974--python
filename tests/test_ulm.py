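import numpy as np
import pytest

from cspd.forward import make_gaussian_psf, synthesize_block
from cspd.ulm import (LocalizationSet, TrainingPairConfig, UlmImage,
                      accumulate_ulm, localize_block, localize_frame,
                      make_training_pair)
from cspd.vasculature import ScattererTrajectorySet, make_parallel_pair_tree

PITCH = 0.005


@pytest.fixture(scope="module")
def fine_psf():
    return make_gaussian_psf(0.077, 1.0, PITCH)


def _frame_with_scatterer(psf, x_px, z_px, amp=1.0, grid=(64, 64)):
    pos = np.array([[[x_px * PITCH, z_px * PITCH]]], dtype=float)
    traj = ScattererTrajectorySet(
        positions=pos, amplitudes=np.array([amp]),
        alive_mask=np.ones((1, 1), dtype=bool), frame_interval=1e-3,
        segment_index=np.zeros(1, dtype=int))
    return synthesize_block(traj, psf, grid, 0.0, 0.0, seed=0).data[:, :, 0]


def test_localize_single_scatterer_subpixel(fine_psf):
    frame = _frame_with_scatterer(fine_psf, 30.27, 33.61)
    dets = localize_frame(frame, fine_psf)
    assert len(dets) == 1
    x, z, amp = dets[0]
    assert abs(x / PITCH - 30.27) < 0.05
    assert abs(z / PITCH - 33.61) < 0.05
    assert amp > 0


def test_localize_blank_frame(fine_psf):
    assert localize_frame(np.zeros((32, 32)), fine_psf) == []


def test_localize_threshold_suppresses_weak(fine_psf):
    strong = _frame_with_scatterer(fine_psf, 20.0, 20.0, amp=1.0)
    weak = _frame_with_scatterer(fine_psf, 45.0, 45.0, amp=0.1)
    dets = localize_frame(strong + weak, fine_psf, detection_threshold=0.3)
    assert len(dets) == 1


def test_ulm_count_conservation(fine_psf):
    events = np.array([[0.0, 0.1, 0.1, 1.0],
                       [0.0, 0.2, 0.15, 2.0],
                       [1.0, 0.02, 0.31, 1.0]])
    locs = LocalizationSet(events=events)
    ulm = accumulate_ulm(locs, (64, 64), 4, PITCH)
    assert int(ulm.counts.sum()) == locs.n_events


def test_ulm_rendered_range(fine_psf):
    events = np.array([[0.0, 0.1, 0.1, 1.0], [1.0, 0.1, 0.1, 1.0]])
    ulm = accumulate_ulm(LocalizationSet(events=events), (64, 64), 4, PITCH)
    img = ulm.rendered(1.0)
    assert img.min() >= 0.0 and img.max() <= 1.0
    assert img.max() > 0


def test_localize_block_ids(fine_psf):
    frame = _frame_with_scatterer(fine_psf, 30.0, 30.0)
    data = np.repeat(frame[:, :, None], 3, axis=2)
    from cspd.forward import SpatiotemporalBlock
    blk = SpatiotemporalBlock(data=data, pixel_pitch=PITCH, frame_rate=1000.0,
                              kind="clutter_filtered")
    locs = localize_block(blk, fine_psf, 0.3)
    assert locs.n_events == 3
    assert set(locs.events[:, 0].astype(int)) == {0, 1, 2}


def test_training_pair_structure():
    cfg = TrainingPairConfig(block_frames=16, n_blocks=2, n_contrast_free=2,
                             ulm_frames=100, ulm_chunk=50)
    tree = make_parallel_pair_tree(4)
    blocks, ulm = make_training_pair(tree, cfg, seed=3)
    assert len(blocks) == 2
    for b in blocks:
        assert b.kind == "raw"
        assert b.n_frames == 16
        assert b.grid_shape == tuple(cfg.grid)
    assert isinstance(ulm, UlmImage)
    assert ulm.counts.shape == (cfg.grid[0] * 4, cfg.grid[1] * 4)
    assert ulm.counts.sum() > 0


def test_training_pair_determinism():
    cfg = TrainingPairConfig(block_frames=16, n_blocks=1, n_contrast_free=1,
                             ulm_frames=50, ulm_chunk=50)
    tree = make_parallel_pair_tree(4)
    a_blocks, a_ulm = make_training_pair(tree, cfg, seed=9)
    b_blocks, b_ulm = make_training_pair(tree, cfg, seed=9)
    np.testing.assert_array_equal(a_blocks[0].data, b_blocks[0].data)
    np.testing.assert_array_equal(a_ulm.counts, b_ulm.counts)


def test_training_pair_frame_budget_validation():
    cfg = TrainingPairConfig(block_frames=64, ulm_frames=32)
    tree = make_parallel_pair_tree(4)
    with pytest.raises(ValueError):
        make_training_pair(tree, cfg, seed=0)


def test_grid_fov():
    cfg = TrainingPairConfig(grid=(64, 32), pixel_pitch=0.025)
    assert cfg.grid_fov() == (32 * 0.025, 64 * 0.025)
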