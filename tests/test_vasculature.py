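import numpy as np
import pytest

from cspd.vasculature import (PulsatilityProfile, cross_section_line,
                              make_parallel_pair_tree, make_vessel_tree,
                              sample_trajectories)

FOV = (1.6, 1.6)


def test_tree_determinism():
    a = make_vessel_tree(3, FOV, 2, 2)
    b = make_vessel_tree(3, FOV, 2, 2)
    assert len(a.segments) == len(b.segments)
    for pa, pb in zip(a.segments, b.segments):
        np.testing.assert_array_equal(pa, pb)


def test_tree_zero_roots():
    tree = make_vessel_tree(0, FOV, 0, 2)
    assert tree.n_segments == 0


def test_tree_containment():
    tree = make_vessel_tree(1, FOV, 2, 3)
    for seg in tree.segments:
        assert np.all(seg[:, 0] >= 0) and np.all(seg[:, 0] <= FOV[0])
        assert np.all(seg[:, 1] >= 0) and np.all(seg[:, 1] <= FOV[1])


def test_tree_invalid_fov():
    with pytest.raises(ValueError):
        make_vessel_tree(1, (0.0, 1.0), 2, 2)


def test_parallel_pair_spacing():
    spacing = 0.0385
    tree = make_vessel_tree(7, FOV, 2, 2, parallel_pair_spacing=spacing)
    assert tree.parallel_pair is not None
    i, j = tree.parallel_pair["segments"]
    a, b = tree.segments[i], tree.segments[j]
    n = min(len(a), len(b))
    gaps = np.hypot(*(a[:n] - b[:n]).T)
    assert np.allclose(gaps, spacing, rtol=0.05)


def test_child_radius_not_larger_than_parent():
    tree = make_vessel_tree(5, FOV, 2, 3)
    for k, parent in enumerate(tree.parents):
        if parent >= 0:
            assert tree.radii[k] <= tree.radii[parent] + 1e-12


def test_trajectories_zero_density():
    tree = make_parallel_pair_tree(1)
    traj = sample_trajectories(tree, 0.0, 8, 1e-3, seed=0)
    assert traj.n_scatterers == 0


def test_trajectories_negative_density():
    tree = make_parallel_pair_tree(1)
    with pytest.raises(ValueError):
        sample_trajectories(tree, -1.0, 8, 1e-3, seed=0)


def test_trajectory_advection_speed():
    """Per-frame displacement equals local speed x frame interval (m=0)."""
    tree = make_parallel_pair_tree(2)
    dt = 1e-3
    traj = sample_trajectories(tree, 5.0, 32, dt, seed=4)
    d = np.diff(traj.positions, axis=1)
    step = np.hypot(d[..., 0], d[..., 1])
    both = traj.alive_mask[:, :-1] & traj.alive_mask[:, 1:]
    speeds = tree.mean_speeds[traj.segment_index]
    expected = speeds[:, None] * dt
    ratio = step[both] / np.broadcast_to(expected, step.shape)[both]
    # curvature tolerance: chord is never longer than the arc
    assert np.all(ratio < 1.0 + 1e-6)
    assert np.median(ratio) > 0.9


def test_trajectory_containment():
    tree = make_vessel_tree(9, FOV, 2, 2)
    traj = sample_trajectories(tree, 10.0, 16, 1e-3, seed=2)
    for s in range(traj.n_scatterers):
        seg = tree.segments[traj.segment_index[s]]
        r = tree.radii[traj.segment_index[s]]
        for t in range(traj.n_frames):
            if not traj.alive_mask[s, t]:
                continue
            p = traj.positions[s, t]
            dmin = np.min(np.hypot(seg[:, 0] - p[0], seg[:, 1] - p[1]))
            # polyline vertices only -> allow half a typical vertex spacing
            assert dmin <= r + 0.03


def test_trajectory_determinism():
    tree = make_parallel_pair_tree(3)
    a = sample_trajectories(tree, 5.0, 16, 1e-3, seed=11)
    b = sample_trajectories(tree, 5.0, 16, 1e-3, seed=11)
    np.testing.assert_array_equal(a.positions, b.positions)
    np.testing.assert_array_equal(a.alive_mask, b.alive_mask)


def test_pulsatility_waveform_unit_mean():
    p = PulsatilityProfile.cardiac(0.5, 0.2)
    t = np.linspace(0.0, 0.2, 20001)[:-1]
    assert abs(np.mean(p.scale_at(t)) - 1.0) < 1e-3
    assert np.all(p.scale_at(t) > 0)


def test_pulsatility_modulates_speed():
    tree = make_parallel_pair_tree(5)
    dt = 1e-3
    period = 0.2
    puls = PulsatilityProfile.cardiac(0.5, period)
    traj = sample_trajectories(tree, 5.0, 400, dt, seed=6, pulsatility=puls)
    d = np.diff(traj.positions, axis=1)
    step = np.hypot(d[..., 0], d[..., 1])
    both = traj.alive_mask[:, :-1] & traj.alive_mask[:, 1:]
    step = np.where(both, step, np.nan)
    mean_step = np.nanmean(step, axis=0)
    w = puls.scale_at((np.arange(399) + 0.5) * dt)
    mask = ~np.isnan(mean_step)
    c = np.corrcoef(mean_step[mask], w[mask])[0, 1]
    assert c > 0.8


def test_cross_section_line_perpendicular():
    tree = make_parallel_pair_tree(1)
    (x0, z0), (x1, z1) = cross_section_line(tree, 0, 0.5, 0.1)
    seg = tree.segments[0]
    mid = len(seg) // 2
    tangent = seg[mid + 1] - seg[mid - 1]
    line = np.array([x1 - x0, z1 - z0])
    cosang = abs(np.dot(tangent, line) /
                 (np.linalg.norm(tangent) * np.linalg.norm(line)))
    assert cosang < 0.2
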