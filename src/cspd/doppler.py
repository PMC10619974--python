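"""SVD clutter filtering and power Doppler processing.

The Casorati matrix of a (Z, X, T) block is its reshaping to (Z*X, T); tissue
clutter occupies the leading singular components (large, slowly varying),
while blood signal is spread across the remainder.  Removing the first k
components and (optionally) a trailing noise band is the standard ultrafast
Doppler clutter filter.  Power Doppler is the per-pixel mean squared magnitude
of the filtered slow-time samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .forward import SpatiotemporalBlock

__all__ = [
    "PowerDopplerImage",
    "SvdFilterSpec",
    "svd_clutter_filter",
    "casorati_svd",
    "adaptive_cutoff",
    "power_doppler",
    "flow_separation_augment",
    "truncate_and_interpolate",
    "sliding_window_series",
    "to_db",
]


@dataclass
class PowerDopplerImage:
    """Blood signal power map (nonnegative, linear scale)."""

    intensity: np.ndarray   # (Z, X), >= 0
    pixel_pitch: float      # mm
    n_frames_used: int

    def __post_init__(self):
        v = np.asarray(self.intensity, dtype=float)
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("power Doppler intensity must be finite and >= 0")
        self.intensity = v

    def normalized(self) -> np.ndarray:
        m = self.intensity.max()
        return self.intensity / m if m > 0 else self.intensity.copy()


@dataclass
class SvdFilterSpec:
    """Cutoffs for the SVD clutter filter: remove the leading ``low_cutoff``
    singular components (tissue) and optionally the trailing ``high_cutoff``
    components (noise)."""

    low_cutoff: int = 2
    high_cutoff: Optional[int] = None

    def validate(self, rank_bound: int) -> None:
        if not (0 <= self.low_cutoff < rank_bound):
            raise ValueError(
                f"low_cutoff must be in [0, {rank_bound}), got {self.low_cutoff}")
        if self.high_cutoff is not None and not (
                0 <= self.high_cutoff < rank_bound - self.low_cutoff):
            raise ValueError("high_cutoff leaves no singular components")


def casorati_svd(block: SpatiotemporalBlock):
    """SVD of the (Z*X, T) Casorati matrix; returns (U, s, Vh)."""
    Z, X, T = block.data.shape
    C = block.data.reshape(Z * X, T)
    return np.linalg.svd(C, full_matrices=False)


def adaptive_cutoff(block: SpatiotemporalBlock, max_k: Optional[int] = None) -> int:
    """Knee detection on the log singular-value curve: the index of maximum
    distance to the chord between the first and last values.  Offered as an
    alternative to a fixed low cutoff."""
    _, s, _ = casorati_svd(block)
    s = np.log10(np.maximum(s, s.max() * 1e-12))
    n = len(s) if max_k is None else min(len(s), max_k)
    i = np.arange(n)
    chord = s[0] + (s[n - 1] - s[0]) * i / max(n - 1, 1)
    return int(np.argmax(chord - s[:n]))


def svd_clutter_filter(block: SpatiotemporalBlock,
                       spec: SvdFilterSpec) -> SpatiotemporalBlock:
    """Zero singular components [0, low_cutoff) and, if requested, the trailing
    ``high_cutoff`` components of the Casorati matrix; output kind is
    ``clutter_filtered``.  Output energy never exceeds input energy."""
    if block.kind != "raw":
        raise ValueError("svd_clutter_filter expects a raw block")
    Z, X, T = block.data.shape
    spec.validate(min(Z * X, T))
    U, s, Vh = casorati_svd(block)
    s = s.copy()
    s[:spec.low_cutoff] = 0.0
    if spec.high_cutoff:
        s[len(s) - spec.high_cutoff:] = 0.0
    filt = (U * s) @ Vh
    return block.with_data(filt.reshape(Z, X, T), kind="clutter_filtered")


def clutter_projection_basis(block: SpatiotemporalBlock, k: int) -> np.ndarray:
    """Temporal singular vectors (T, k) of the leading k components; the filter
    is the projection of each pixel's slow-time signal onto their orthogonal
    complement.  Useful for analyzing what the filter does to signal
    components synthesized separately."""
    _, _, Vh = casorati_svd(block)
    return Vh[:k].conj().T


def project_out(data: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Remove the temporal subspace spanned by ``basis`` (T, k) from a
    (Z, X, T) array."""
    Z, X, T = data.shape
    C = data.reshape(Z * X, T)
    coeff = C @ basis
    return (C - coeff @ basis.conj().T).reshape(Z, X, T)


def power_doppler(block: SpatiotemporalBlock) -> PowerDopplerImage:
    """Mean over slow time of the squared signal magnitude.  The mean (rather
    than the sum) keeps images from different ensemble lengths comparable."""
    if block.kind != "clutter_filtered":
        raise ValueError("power_doppler expects a clutter-filtered block")
    if block.n_frames == 0:
        raise ValueError("empty block")
    intensity = np.mean(np.abs(block.data) ** 2, axis=2)
    return PowerDopplerImage(intensity=intensity, pixel_pitch=block.pixel_pitch,
                             n_frames_used=block.n_frames)


def flow_separation_augment(block: SpatiotemporalBlock,
                            n_bands: int) -> list:
    """Partition the slow-time spectrum into ``n_bands`` contiguous bands and
    return one band-filtered block per band; the elementwise sum of the outputs
    reconstructs the input.

    For complex data the bands tile the signed (fftshifted) frequency axis and
    are direction-resolved; for real data the one-sided spectrum is used, so
    negative frequencies fold onto positive ones and direction information is
    lost.
    """
    if block.kind != "clutter_filtered":
        raise ValueError("flow_separation_augment expects a clutter-filtered block")
    T = block.n_frames
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if n_bands > T // 2:
        raise ValueError(f"n_bands must be <= T/2 = {T // 2}")
    data = block.data
    if np.iscomplexobj(data):
        spec = np.fft.fftshift(np.fft.fft(data, axis=2), axes=2)
        groups = np.array_split(np.arange(T), n_bands)
        out = []
        for g in groups:
            band = np.zeros_like(spec)
            band[:, :, g] = spec[:, :, g]
            out.append(block.with_data(
                np.fft.ifft(np.fft.ifftshift(band, axes=2), axis=2)))
        return out
    spec = np.fft.rfft(data, axis=2)
    nb = spec.shape[2]
    groups = np.array_split(np.arange(nb), n_bands)
    out = []
    for g in groups:
        band = np.zeros_like(spec)
        band[:, :, g] = spec[:, :, g]
        out.append(block.with_data(np.fft.irfft(band, n=T, axis=2)))
    return out


def truncate_and_interpolate(block: SpatiotemporalBlock,
                             keep_every: int) -> SpatiotemporalBlock:
    """Decimate the slow-time axis by ``keep_every`` and linearly interpolate
    back to the original frame count (the frame-count mismatch protocol for
    testing a network trained on full ensembles)."""
    T = block.n_frames
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if keep_every >= T or T // keep_every < 2:
        raise ValueError("keep_every leaves fewer than two frames")
    if keep_every == 1:
        return block.with_data(block.data.copy())
    kept = np.arange(0, T, keep_every)
    t_full = np.arange(T, dtype=float)
    # vectorized piecewise-linear interpolation with edge clamping
    j = np.clip(np.searchsorted(kept, t_full, side="right") - 1, 0, len(kept) - 2)
    t0, t1 = kept[j], kept[j + 1]
    w = np.clip((t_full - t0) / (t1 - t0), 0.0, 1.0)
    d = block.data
    out = d[:, :, kept[j]] * (1.0 - w) + d[:, :, kept[j + 1]] * w
    return block.with_data(out)


def sliding_window_series(block: SpatiotemporalBlock, window: int, step: int,
                          reconstructor: Callable[[SpatiotemporalBlock], object]):
    """Apply ``reconstructor`` to successive slow-time windows.

    Returns ``(images, start_times)`` with ``floor((T - window)/step) + 1``
    entries; each image is reconstructed from its window only.  The
    reconstructor receives a block of the same kind as the input; for raw
    input it would typically compose the SVD filter with power Doppler (the
    filter is then window-local, which is what makes slow diastolic flow
    drop out and the series track the cardiac cycle).
    """
    T = block.n_frames
    if window > T:
        raise ValueError("window longer than block")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = np.arange(0, T - window + 1, step)
    images = []
    for s0 in starts:
        sub = block.with_data(block.data[:, :, s0:s0 + window])
        images.append(reconstructor(sub))
    return images, starts / block.frame_rate


def to_db(image: np.ndarray, dynamic_range_db: float = 70.0) -> np.ndarray:
    """Display-only log compression of a nonnegative linear-scale image to
    [0, 1] over the given dynamic range (default 70 dB)."""
    img = np.asarray(image, dtype=float)
    peak = img.max()
    if peak <= 0:
        return np.zeros_like(img)
    db = 10.0 * np.log10(np.maximum(img / peak, 10 ** (-dynamic_range_db / 10 - 2)))
    return np.clip(1.0 + db / dynamic_range_db, 0.0, 1.0)
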