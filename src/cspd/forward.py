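"""Forward ultrasound signal model.

Synthesizes spatiotemporal blocks U(z, x, t) as a sum of PSF-shaped echoes at
the scatterer positions plus a quasi-static tissue clutter field and additive
electronic noise.  The PSF is a parametric anisotropic Gaussian standing in
for the beamformed system response; echoes are deposited with bilinear
subpixel weighting, which is exact for isolated scatterers and preserves the
first moment (centroid) of each echo.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

logger = logging.getLogger(__name__)

__all__ = ["Psf", "SpatiotemporalBlock", "make_gaussian_psf", "synthesize_block"]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

# tissue-motion time constant governing the clutter gains' drift
_CLUTTER_TIME_CONSTANT_S = 0.1


@dataclass
class Psf:
    """Imaging point spread function sampled on the pixel grid.

    ``kernel`` is indexed [z, x], has odd extent along both axes, a single
    global maximum and unit energy (sum of squares).
    """

    kernel: np.ndarray
    pixel_pitch: float  # mm per pixel, isotropic
    wavelength: float   # mm

    def __post_init__(self):
        k = np.asarray(self.kernel, dtype=float)
        if k.shape[0] % 2 == 0 or k.shape[1] % 2 == 0:
            raise ValueError("PSF kernel extent must be odd along both axes")
        if np.count_nonzero(k == k.max()) != 1:
            raise ValueError("PSF kernel must have a single global maximum")
        self.kernel = k

    @property
    def lateral_fwhm_mm(self) -> float:
        return _measure_fwhm_1d(self.kernel[self.kernel.shape[0] // 2, :]) * self.pixel_pitch

    @property
    def axial_fwhm_mm(self) -> float:
        return _measure_fwhm_1d(self.kernel[:, self.kernel.shape[1] // 2]) * self.pixel_pitch


def _measure_fwhm_1d(profile: np.ndarray) -> float:
    """FWHM of a sampled unimodal profile in samples, half-max crossings by
    linear interpolation."""
    p = np.asarray(profile, dtype=float)
    p = p - p.min()
    imax = int(np.argmax(p))
    half = p[imax] / 2.0
    # left crossing
    left = None
    for i in range(imax, 0, -1):
        if p[i - 1] <= half <= p[i]:
            left = (i - 1) + (half - p[i - 1]) / (p[i] - p[i - 1] + 1e-300)
            break
    right = None
    for i in range(imax, len(p) - 1):
        if p[i + 1] <= half <= p[i]:
            right = i + (p[i] - half) / (p[i] - p[i + 1] + 1e-300)
            break
    if left is None or right is None:
        raise ValueError("profile truncated before reaching half maximum")
    return float(right - left)


def make_gaussian_psf(wavelength: float, f_number: float,
                      pixel_pitch: float) -> Psf:
    """Anisotropic Gaussian PSF: lateral FWHM = wavelength * f_number, axial
    FWHM = wavelength / 2 (pulse-length proxy), unit energy."""
    if wavelength <= 0 or f_number <= 0 or pixel_pitch <= 0:
        raise ValueError("wavelength, f_number and pixel_pitch must be > 0")
    fwhm_x = wavelength * f_number
    fwhm_z = wavelength / 2.0
    if pixel_pitch > min(fwhm_x, fwhm_z) / 2.0:
        warnings.warn("pixel pitch coarser than PSF FWHM/2: PSF is undersampled",
                      RuntimeWarning, stacklevel=2)
    sx = fwhm_x / _FWHM_PER_SIGMA / pixel_pitch
    sz = fwhm_z / _FWHM_PER_SIGMA / pixel_pitch
    hx = max(int(np.ceil(3.0 * sx)), 1)
    hz = max(int(np.ceil(3.0 * sz)), 1)
    x = np.arange(-hx, hx + 1)
    z = np.arange(-hz, hz + 1)
    kern = np.exp(-0.5 * (z[:, None] ** 2 / sz ** 2 + x[None, :] ** 2 / sx ** 2))
    kern /= np.sqrt(np.sum(kern ** 2))
    return Psf(kernel=kern, pixel_pitch=float(pixel_pitch),
               wavelength=float(wavelength))


@dataclass
class SpatiotemporalBlock:
    """Spatiotemporal ensemble, ``data`` indexed [z, x, t] (real magnitude or
    complex), with acquisition metadata."""

    data: np.ndarray
    pixel_pitch: float  # mm
    frame_rate: float   # Hz
    kind: str = "raw"   # "raw" | "clutter_filtered"

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.ndim != 3 or d.shape[2] < 1:
            raise ValueError("block data must be (Z, X, T) with T >= 1")
        if not np.all(np.isfinite(d if not np.iscomplexobj(d) else d.view(float))):
            raise ValueError("block contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if self.kind not in ("raw", "clutter_filtered"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        self.data = d

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:2]

    def energy(self) -> float:
        return float(np.sum(np.abs(self.data) ** 2))

    def with_data(self, data, kind=None) -> "SpatiotemporalBlock":
        return SpatiotemporalBlock(data=data, pixel_pitch=self.pixel_pitch,
                                   frame_rate=self.frame_rate,
                                   kind=kind or self.kind)


def _clutter_field(rng, grid, smooth_px=8.0):
    f = gaussian_filter(rng.standard_normal(grid), smooth_px, mode="reflect")
    rms = np.sqrt(np.mean(f ** 2))
    return f / max(rms, 1e-300)


def _slow_gain(rng, n_frames, smooth_frames):
    """Unit-RMS band-limited temporal drift (tissue motion is slow; white or
    random-walk gains would put clutter energy inside the flow band, where no
    subspace filter could separate it)."""
    g = gaussian_filter1d(rng.standard_normal(n_frames), smooth_frames,
                          mode="reflect")
    rms = np.sqrt(np.mean(g ** 2))
    return g / max(rms, 1e-300)


def synthesize_block(traj, psf: Psf, grid, clutter_amplitude: float = 0.0,
                     noise_sigma: float = 0.0, seed: int = 0, *,
                     frame_rate: float | None = None,
                     complex_mode: bool = False) -> SpatiotemporalBlock:
    """Render a ScattererTrajectorySet into a spatiotemporal block.

    Every alive scatterer deposits ``amplitude x kernel`` centered at its
    subpixel position via bilinear weighting over the four neighboring integer
    shifts.  Tissue clutter is a fixed pair of smooth random fields, each with
    a strong near-constant gain drifting on a slow (band-limited, ~0.1 s)
    time scale — a rank-<=2 quasi-static subspace whose components stay above
    the flow singular values on any analysis window — scaled by
    ``clutter_amplitude``.  I.i.d. Gaussian electronic
    noise of ``noise_sigma`` is added last.  Scatterers whose center falls
    outside the grid are skipped and counted via the module logger.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    Z, X = grid
    T = traj.n_frames
    rng = np.random.default_rng(seed)
    dtype = np.complex128 if complex_mode else np.float64
    out = np.zeros((Z, X, T), dtype=dtype)

    kern = psf.kernel
    kz, kx = kern.shape
    hz, hx = kz // 2, kx // 2
    pitch = psf.pixel_pitch

    amps = traj.amplitudes.astype(np.complex128 if complex_mode else float)
    if complex_mode and traj.n_scatterers:
        amps = amps * np.exp(2j * np.pi * rng.random(traj.n_scatterers))

    n_skipped = 0
    for t in range(T):
        alive = np.flatnonzero(traj.alive_mask[:, t])
        if alive.size == 0:
            continue
        x = traj.positions[alive, t, 0] / pitch
        z = traj.positions[alive, t, 1] / pitch
        inside = (x >= 0) & (x <= X - 1) & (z >= 0) & (z <= Z - 1)
        n_skipped += int(np.sum(~inside))
        idx = alive[inside]
        if idx.size == 0:
            continue
        x, z = x[inside], z[inside]
        ix0 = np.floor(x).astype(int)
        iz0 = np.floor(z).astype(int)
        fx_, fz_ = x - ix0, z - iz0
        a = amps[idx]
        frame = out[:, :, t]
        for dz_ in (0, 1):
            wz = (1 - fz_) if dz_ == 0 else fz_
            for dx_ in (0, 1):
                wx = (1 - fx_) if dx_ == 0 else fx_
                w = a * wz * wx
                zi = iz0 + dz_
                xi = ix0 + dx_
                for s in range(len(w)):
                    z0 = zi[s] - hz
                    x0 = xi[s] - hx
                    zs0, zs1 = max(z0, 0), min(z0 + kz, Z)
                    xs0, xs1 = max(x0, 0), min(x0 + kx, X)
                    if zs0 >= zs1 or xs0 >= xs1:
                        continue
                    frame[zs0:zs1, xs0:xs1] += (
                        w[s] * kern[zs0 - z0:zs1 - z0, xs0 - x0:xs1 - x0])
    if n_skipped:
        logger.info("synthesize_block: skipped %d out-of-grid scatterer frames",
                    n_skipped)

    if clutter_amplitude > 0:
        f1 = _clutter_field(rng, (Z, X))
        f2 = _clutter_field(rng, (Z, X))
        fr = frame_rate if frame_rate is not None else 1.0 / traj.frame_interval
        smooth = _CLUTTER_TIME_CONSTANT_S * fr
        g1 = 1.0 + 0.01 * _slow_gain(rng, T, smooth)
        g2 = 0.3 + 0.05 * _slow_gain(rng, T, smooth)
        clut = (f1[:, :, None] * g1[None, None, :] +
                f2[:, :, None] * g2[None, None, :])
        if complex_mode:
            phase = np.exp(2j * np.pi * rng.random((Z, X)))
            clut = clut * phase[:, :, None]
        out += clutter_amplitude * clut

    if noise_sigma > 0:
        if complex_mode:
            out += noise_sigma * (rng.standard_normal((Z, X, T)) +
                                  1j * rng.standard_normal((Z, X, T))) / np.sqrt(2)
        else:
            out += noise_sigma * rng.standard_normal((Z, X, T))

    fr = frame_rate if frame_rate is not None else 1.0 / traj.frame_interval
    return SpatiotemporalBlock(data=out, pixel_pitch=pitch, frame_rate=fr,
                               kind="raw")
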