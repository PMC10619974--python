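"""Synthetic 2-D microvasculature and scatterer kinematics.

This module generates the latent ground truth that the rest of the pipeline
images: tortuous branching vessel trees in a lateral (x) / axial (z) field of
view, and populations of blood scatterers (red-blood-cell-like or
microbubble-like) advected along the vessel centerlines at the local flow
speed, optionally modulated by a cardiac pulsatility waveform.

Units: positions and radii in mm, speeds in mm/s, times in s.  The axial
coordinate z increases downward, lateral x to the right.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VesselTree",
    "PulsatilityProfile",
    "ScattererTrajectorySet",
    "make_vessel_tree",
    "make_parallel_pair_tree",
    "sample_trajectories",
    "cross_section_line",
]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass
class VesselTree:
    """A set of vessel segments (smoothed centerline polylines) with per-segment
    radius, mean flow speed and flow direction.

    ``segments[i]`` is an (P_i, 2) array of (x, z) points in mm.  ``parents[i]``
    is the index of the parent segment (-1 for roots); a child's radius never
    exceeds its parent's.  ``parallel_pair`` optionally records a deliberately
    placed pair of closely spaced parallel vessels used for resolution studies:
    a dict with keys ``segments`` (two indices), ``spacing_mm`` and
    ``cross_line`` (two (x, z) endpoints of a profile line crossing both).
    """

    segments: list = field(default_factory=list)
    radii: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mean_speeds: np.ndarray = field(default_factory=lambda: np.zeros(0))
    flow_directions: np.ndarray = field(default_factory=lambda: np.zeros(0))
    field_of_view: tuple = (1.6, 1.6)  # (x extent, z extent) in mm
    parents: list = field(default_factory=list)
    parallel_pair: Optional[dict] = None

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_length(self, i: int) -> float:
        pts = self.segments[i]
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))

    def total_length(self) -> float:
        return sum(self.segment_length(i) for i in range(self.n_segments))

    def validate(self) -> None:
        fx, fz = self.field_of_view
        if fx <= 0 or fz <= 0:
            raise ValueError("field of view must be positive")
        if np.any(np.asarray(self.radii) <= 0) and self.n_segments:
            raise ValueError("all radii must be positive")
        for i, pts in enumerate(self.segments):
            if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > fx) or \
               np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > fz):
                raise ValueError(f"segment {i} leaves the field of view")
            p = self.parents[i]
            if p >= 0 and self.radii[i] > self.radii[p] + 1e-12:
                raise ValueError(f"segment {i} radius exceeds parent radius")


@dataclass
class PulsatilityProfile:
    """Cardiac modulation of flow speed.

    The instantaneous speed scale is ``base_speed_scale * (1 + m * (w(t) - 1))``
    where ``w`` is a stored periodic waveform with unit mean and ``m`` the
    modulation depth.  With ``m = 0`` the scale is constant.
    """

    base_speed_scale: float = 1.0
    modulation_depth: float = 0.0
    cardiac_period: float = 0.2
    waveform: np.ndarray = field(
        default_factory=lambda: np.ones(256))  # one period, unit mean

    def __post_init__(self):
        w = np.asarray(self.waveform, dtype=float)
        if abs(w.mean() - 1.0) > 1e-6:
            raise ValueError("waveform must have unit mean")
        if not (0.0 <= self.modulation_depth < 1.0):
            raise ValueError("modulation depth must lie in [0, 1)")
        if np.any(1.0 + self.modulation_depth * (w - 1.0) <= 0):
            raise ValueError("instantaneous speed scale must stay positive")
        self.waveform = w

    @classmethod
    def cardiac(cls, modulation_depth: float = 0.5, cardiac_period: float = 0.2,
                systolic_fraction: float = 0.35, peak: float = 3.0,
                n_samples: int = 512) -> "PulsatilityProfile":
        """Rectified-cosine systolic bump over a flat diastole, unit mean."""
        phase = np.arange(n_samples) / n_samples
        w = np.ones(n_samples)
        sys = phase < systolic_fraction
        w[sys] += peak * 0.5 * (1.0 - np.cos(2 * np.pi * phase[sys] / systolic_fraction))
        w /= w.mean()
        return cls(modulation_depth=modulation_depth,
                   cardiac_period=cardiac_period, waveform=w)

    def scale_at(self, t) -> np.ndarray:
        """Instantaneous speed scale at time(s) ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        phase = np.mod(t / self.cardiac_period, 1.0)
        w = np.interp(phase, np.arange(self.waveform.size) / self.waveform.size,
                      self.waveform, period=1.0)
        return self.base_speed_scale * (1.0 + self.modulation_depth * (w - 1.0))


@dataclass
class ScattererTrajectorySet:
    """Per-scatterer positions over slow time; the simulator's latent truth.

    ``positions`` is (n, T, 2) in mm with columns (x, z); ``amplitudes`` (n,)
    holds the time-invariant echogenicity of each scatterer; ``alive_mask``
    (n, T) flags frames in which a scatterer contributes (a recycling transit
    frame is marked dead).
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    alive_mask: np.ndarray
    frame_interval: float
    segment_index: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def alive_count(self) -> np.ndarray:
        """N(t): number of contributing scatterers per frame."""
        return self.alive_mask.sum(axis=0)


# --------------------------------------------------------------------------- #
# vessel tree generation
# --------------------------------------------------------------------------- #

def _smooth_polyline(pts: np.ndarray, passes: int = 2) -> np.ndarray:
    """Light moving-average smoothing, endpoints pinned."""
    out = pts.copy()
    for _ in range(passes):
        if len(out) < 3:
            break
        out[1:-1] = 0.25 * out[:-2] + 0.5 * out[1:-1] + 0.25 * out[2:]
    return out


def _grow_polyline(rng, start, heading, length, step, tortuosity, fov, margin):
    """Random-walk growth of a centerline; heading is steered back toward the
    interior when the walk approaches the field-of-view margin."""
    fx, fz = fov
    n_steps = max(2, int(round(length / step)))
    pts = [np.asarray(start, float)]
    th = float(heading)
    for _ in range(n_steps):
        th += rng.normal(0.0, tortuosity)
        d = np.array([np.sin(th), np.cos(th)])  # heading measured from +z
        nxt = pts[-1] + step * d
        # steer toward the center if the margin box would be violated
        if not (margin <= nxt[0] <= fx - margin and margin <= nxt[1] <= fz - margin):
            center = np.array([fx / 2, fz / 2])
            to_c = center - pts[-1]
            th = float(np.arctan2(to_c[0], to_c[1]))
            nxt = pts[-1] + step * np.array([np.sin(th), np.cos(th)])
        nxt[0] = np.clip(nxt[0], margin, fx - margin)
        nxt[1] = np.clip(nxt[1], margin, fz - margin)
        pts.append(nxt)
    return _smooth_polyline(np.array(pts))


def make_vessel_tree(seed: int, field_of_view=(1.6, 1.6), n_roots: int = 2,
                     branching_depth: int = 2, *, tortuosity: float = 0.25,
                     step_mm: float = 0.05, root_radius: float = 0.025,
                     radius_decay: float = 0.8, speed_median: float = 2.5,
                     speed_sigma: float = 0.4,
                     parallel_pair_spacing: float = 0.0385) -> VesselTree:
    """Generate a random binary branching vessel tree.

    Roots descend from near the top of the field of view; each tip spawns two
    children of reduced radius and length until ``branching_depth`` is reached.
    When ``branching_depth >= 2`` (and ``n_roots > 0``) a pair of straight,
    parallel, sub-diffraction-spaced vessels separated by
    ``parallel_pair_spacing`` mm is added and recorded in ``parallel_pair``;
    this pair is the standard resolution phantom for the rest of the pipeline.
    Deterministic for a fixed seed.
    """
    fx, fz = field_of_view
    if fx <= 0 or fz <= 0:
        raise ValueError("field of view must be positive")
    if n_roots < 0:
        raise ValueError("n_roots must be >= 0")

    rng = np.random.default_rng(seed)
    tree = VesselTree(field_of_view=(float(fx), float(fz)))
    margin = max(2 * root_radius, 0.04)

    def add_segment(pts, radius, speed, parent):
        tree.segments.append(pts)
        tree.parents.append(parent)
        return len(tree.segments) - 1

    radii, speeds, dirs = [], [], []

    def grow(start, heading, depth, radius, parent, length):
        pts = _grow_polyline(rng, start, heading, length, step_mm,
                             tortuosity, (fx, fz), margin)
        speed = speed_median * np.exp(rng.normal(0.0, speed_sigma)) * \
            (radius / root_radius) ** 0.5
        idx = add_segment(pts, radius, speed, parent)
        radii.append(radius)
        speeds.append(speed)
        dirs.append(1.0)
        if depth > 0:
            tip = pts[-1]
            base_heading = np.arctan2(*(pts[-1] - pts[-2]))
            for sgn in (-1.0, 1.0):
                child_heading = base_heading + sgn * rng.uniform(0.35, 0.8)
                child_radius = radius * radius_decay * rng.uniform(0.85, 1.0)
                grow(tip, child_heading, depth - 1, child_radius, idx,
                     length * 0.65)

    for _ in range(n_roots):
        x0 = rng.uniform(0.18 * fx, 0.82 * fx)
        start = np.array([x0, margin])
        heading = rng.normal(0.0, 0.2)  # mostly downward
        grow(start, heading, branching_depth, root_radius, -1,
             rng.uniform(0.30, 0.45) * fz)

    # deliberate sub-diffraction parallel pair for resolution studies
    if n_roots > 0 and branching_depth >= 2:
        pair = _append_parallel_pair(tree, radii, speeds, dirs, rng,
                                     parallel_pair_spacing)
        tree.parallel_pair = pair

    tree.radii = np.array(radii)
    tree.mean_speeds = np.array(speeds)
    tree.flow_directions = np.array(dirs)
    tree.validate()
    return tree


def _append_parallel_pair(tree, radii, speeds, dirs, rng, spacing,
                          pair_radius=None, pair_speeds=(1.5, 3.0)):
    fx, fz = tree.field_of_view
    if pair_radius is None:
        pair_radius = min(0.010, spacing / 3.5)
    z_lo, z_hi = 0.30 * fz, 0.75 * fz
    # The phantom must stay measurable: place it where its measurement
    # corridor keeps the largest clearance from the random tree, as a crossing
    # vessel would corrupt both the ULM target and the cross profile (the
    # in vivo analogue is manually selecting an isolated vessel pair).
    candidates = rng.uniform(0.18 * fx, 0.82 * fx, size=64)
    x0 = float(candidates[0])
    if tree.segments:
        pts = np.concatenate(tree.segments)
        z_mid = 0.5 * (z_lo + z_hi)
        near = pts[np.abs(pts[:, 1] - z_mid) <= 0.35]
        if near.size:
            clearance = [np.min(np.abs(near[:, 0] - c)) for c in candidates]
            x0 = float(candidates[int(np.argmax(clearance))])
    n_pts = 24
    z = np.linspace(z_lo, z_hi, n_pts)
    idx = []
    for k, dx in enumerate((-spacing / 2, spacing / 2)):
        pts = np.column_stack([np.full(n_pts, x0 + dx), z])
        tree.segments.append(pts)
        tree.parents.append(-1)
        radii.append(pair_radius)
        speeds.append(pair_speeds[k])
        dirs.append(1.0)
        idx.append(len(tree.segments) - 1)
    z_mid = 0.5 * (z_lo + z_hi)
    half = 3.0 * spacing
    cross = ((max(x0 - half, 0.0), z_mid), (min(x0 + half, fx), z_mid))
    return {"segments": tuple(idx), "spacing_mm": float(spacing),
            "cross_line": cross}


def make_parallel_pair_tree(seed: int, field_of_view=(1.6, 1.6),
                            spacing: float = 0.0385,
                            pair_speeds=(1.5, 3.0)) -> VesselTree:
    """A tree containing only the two-parallel-vessel resolution phantom."""
    rng = np.random.default_rng(seed)
    tree = VesselTree(field_of_view=tuple(map(float, field_of_view)))
    radii, speeds, dirs = [], [], []
    tree.parallel_pair = _append_parallel_pair(
        tree, radii, speeds, dirs, rng, spacing, pair_speeds=pair_speeds)
    tree.radii = np.array(radii)
    tree.mean_speeds = np.array(speeds)
    tree.flow_directions = np.array(dirs)
    tree.validate()
    return tree


def cross_section_line(tree: VesselTree, segment: int, frac: float = 0.5,
                       half_length_mm: float = 0.15) -> tuple:
    """Endpoints of a profile line perpendicular to a segment at fractional
    arc length ``frac``, clipped to the field of view."""
    pts = tree.segments[segment]
    seglen = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    target = frac * s[-1]
    j = int(np.searchsorted(s, target, side="right") - 1)
    j = min(max(j, 0), len(pts) - 2)
    t = (target - s[j]) / max(s[j + 1] - s[j], 1e-12)
    p = (1 - t) * pts[j] + t * pts[j + 1]
    tang = pts[j + 1] - pts[j]
    tang = tang / max(np.hypot(*tang), 1e-12)
    normal = np.array([-tang[1], tang[0]])
    fx, fz = tree.field_of_view
    a = np.clip(p - half_length_mm * normal, [0, 0], [fx, fz])
    b = np.clip(p + half_length_mm * normal, [0, 0], [fx, fz])
    return (tuple(a), tuple(b))


# --------------------------------------------------------------------------- #
# scatterer trajectories
# --------------------------------------------------------------------------- #

def _arclength_param(pts: np.ndarray):
    d = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(d)])
    return s, s[-1]


def _eval_centerline(pts, s_cum, s):
    """Position and unit normal of the polyline at arc lengths ``s``."""
    x = np.interp(s, s_cum, pts[:, 0])
    z = np.interp(s, s_cum, pts[:, 1])
    # tangent from finite differences of the interpolant
    eps = max(s_cum[-1] * 1e-4, 1e-6)
    xp = np.interp(np.minimum(s + eps, s_cum[-1]), s_cum, pts[:, 0])
    zp = np.interp(np.minimum(s + eps, s_cum[-1]), s_cum, pts[:, 1])
    xm = np.interp(np.maximum(s - eps, 0.0), s_cum, pts[:, 0])
    zm = np.interp(np.maximum(s - eps, 0.0), s_cum, pts[:, 1])
    tx, tz = xp - xm, zp - zm
    norm = np.hypot(tx, tz)
    norm[norm < 1e-12] = 1.0
    nx, nz = -tz / norm, tx / norm
    return np.column_stack([x, z]), np.column_stack([nx, nz])


def sample_trajectories(tree: VesselTree, density: float, n_frames: int,
                        frame_interval: float,
                        pulsatility: Optional[PulsatilityProfile] = None,
                        seed: int = 0, *, amplitude_median: float = 1.0,
                        amplitude_sigma: float = 0.3) -> ScattererTrajectorySet:
    """Advect scatterers along vessel centerlines.

    ``density`` is the expected number of scatterers per mm of vessel length
    (per-segment counts are Poisson distributed).  Each scatterer keeps a
    fixed perpendicular offset within the lumen and moves along the arc length
    at the segment's mean speed scaled by the pulsatility profile.  A scatterer
    reaching the end of its segment is recycled at the entrance, with the
    transit frame marked dead in ``alive_mask``.  Deterministic per seed;
    amplitudes are log-normal with the given median.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    if pulsatility is None:
        pulsatility = PulsatilityProfile()

    t = np.arange(n_frames) * frame_interval
    scale = pulsatility.scale_at(t)            # (T,)
    # cumulative advected arc length shared by all scatterers of a segment,
    # per unit mean speed: integral of scale dt with left samples
    adv_unit = np.concatenate([[0.0], np.cumsum(scale[:-1]) * frame_interval])

    all_pos, all_amp, all_alive, all_seg = [], [], [], []
    for si in range(tree.n_segments):
        pts = tree.segments[si]
        s_cum, length = _arclength_param(pts)
        n_s = int(rng.poisson(density * length)) if density > 0 else 0
        if n_s == 0 or length <= 0:
            continue
        s0 = rng.uniform(0.0, length, n_s)
        offs = rng.uniform(-1.0, 1.0, n_s) * tree.radii[si]
        amp = amplitude_median * np.exp(rng.normal(0.0, amplitude_sigma, n_s))
        v = tree.mean_speeds[si] * tree.flow_directions[si]
        s_t = s0[:, None] + v * adv_unit[None, :]          # (n, T) signed
        wrapped = np.floor_divide(s_t, length)
        s_mod = s_t - wrapped * length
        # transit (recycling) frames: the wrap count changes between frames
        alive = np.ones((n_s, n_frames), dtype=bool)
        if n_frames > 1:
            alive[:, 1:] = wrapped[:, 1:] == wrapped[:, :-1]
        flat = s_mod.ravel()
        c, nrm = _eval_centerline(pts, s_cum, flat)
        pos = c + offs.repeat(n_frames)[:, None] * nrm
        all_pos.append(pos.reshape(n_s, n_frames, 2))
        all_amp.append(amp)
        all_alive.append(alive)
        all_seg.append(np.full(n_s, si, dtype=int))

    if not all_pos:
        return ScattererTrajectorySet(
            positions=np.zeros((0, n_frames, 2)), amplitudes=np.zeros(0),
            alive_mask=np.zeros((0, n_frames), bool),
            frame_interval=float(frame_interval))
    return ScattererTrajectorySet(
        positions=np.concatenate(all_pos, axis=0),
        amplitudes=np.concatenate(all_amp),
        alive_mask=np.concatenate(all_alive, axis=0),
        frame_interval=float(frame_interval),
        segment_index=np.concatenate(all_seg))
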