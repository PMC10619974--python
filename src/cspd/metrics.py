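"""Image-quality and resolution metrics for Doppler / super-resolution images.

Pixelwise agreement is measured by PSNR = -10 log10(MSE) and by SSIM with a
3x3 Gaussian window.  Per-vessel resolution uses the full width at half
maximum (FWHM) of cross-sectional intensity profiles; per-vessel fidelity
uses the mean squared error of min-max normalized longitudinal intensity
profiles (MSE-NIP).  A global, image-wide resolution estimate comes from the
Fourier domain: the radially averaged spectral magnitude (iso-frequency
curve) is fitted with an exponential, the reference amplitude is the power
Doppler curve at the one-wavelength spatial frequency, and the resolution of
another image is the inverse of the frequency where its fitted curve reaches
that amplitude.  All metrics operate on linear-scale intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import correlate, map_coordinates, zoom
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "VesselProfile", "MetricsReport", "psnr", "ssim", "fwhm", "mse_nip",
    "fourier_resolution", "evaluate_pair", "extract_profile",
    "upsample_image", "normalize01", "count_profile_peaks",
]


# --------------------------------------------------------------------------- #
# helpers
# --------------------------------------------------------------------------- #

def normalize01(image: np.ndarray) -> np.ndarray:
    """Scale a nonnegative image to [0, 1] by its maximum."""
    img = np.asarray(image, dtype=float)
    m = img.max()
    return img / m if m > 0 else img.copy()


def upsample_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Bilinear upsampling used to reconcile a native-grid power Doppler image
    with the R-times super-resolved grid before pixelwise comparison."""
    return zoom(np.asarray(image, dtype=float), factor, order=1,
                grid_mode=True, mode="nearest")


@dataclass
class VesselProfile:
    """Intensity samples along a line across (cross-sectional) or along
    (longitudinal) a vessel; positions in micrometers, linear intensities."""

    positions_um: np.ndarray
    intensities: np.ndarray
    orientation: str = "cross_sectional"  # or "longitudinal"

    def __post_init__(self):
        p = np.asarray(self.positions_um, dtype=float)
        v = np.asarray(self.intensities, dtype=float)
        if p.size != v.size or p.size < 5:
            raise ValueError("profile needs >= 5 matched samples")
        if np.any(v < 0):
            raise ValueError("profile intensities must be nonnegative")
        self.positions_um, self.intensities = p, v


def extract_profile(image: np.ndarray, pixel_pitch_mm: float, line,
                    n_samples: int = 101,
                    orientation: str = "cross_sectional",
                    average_half_width_mm: float = 0.0) -> VesselProfile:
    """Sample an image along a line given by two (x, z) endpoints in mm,
    bilinear interpolation, positions returned in micrometers along the line.

    With ``average_half_width_mm`` > 0 the profile is the mean over parallel
    lines offset perpendicularly by up to that half-width (band averaging,
    standard for sparse accumulation maps such as localization counts)."""
    (x0, z0), (x1, z1) = line
    length_mm = np.hypot(x1 - x0, z1 - z0)
    nx, nz = ((z0 - z1) / max(length_mm, 1e-12),
              (x1 - x0) / max(length_mm, 1e-12))
    if average_half_width_mm > 0:
        n_off = 2 * max(1, int(round(average_half_width_mm /
                                     pixel_pitch_mm))) + 1
        offsets = np.linspace(-average_half_width_mm,
                              average_half_width_mm, n_off)
    else:
        offsets = np.array([0.0])
    img = np.asarray(image, dtype=float)
    acc = np.zeros(n_samples)
    for off in offsets:
        xs = (np.linspace(x0, x1, n_samples) + off * nx) / pixel_pitch_mm
        zs = (np.linspace(z0, z1, n_samples) + off * nz) / pixel_pitch_mm
        acc += map_coordinates(img, [zs, xs], order=1, mode="nearest")
    vals = acc / offsets.size
    pos = np.linspace(0.0, length_mm * 1000.0, n_samples)
    return VesselProfile(pos, np.maximum(vals, 0.0), orientation)


def count_profile_peaks(profile: VesselProfile,
                        min_prominence: float = 0.2) -> int:
    """Number of local maxima of a min-max normalized profile with at least
    the given prominence — the bimodality test for whether a vessel pair is
    resolved (2 peaks) or blurred into one (1 peak)."""
    v = profile.intensities.astype(float)
    vmin, vmax = v.min(), v.max()
    if vmax <= vmin:
        return 0
    v = (v - vmin) / (vmax - vmin)
    peaks, _ = find_peaks(v, prominence=min_prominence)
    return int(len(peaks))


# --------------------------------------------------------------------------- #
# pixelwise metrics
# --------------------------------------------------------------------------- #

def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio -10 log10(MSE) in dB for images normalized
    to [0, 1]; returns +inf when the images are identical."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(-10.0 * np.log10(mse))


def _gaussian_window3(sigma: float = 1.0) -> np.ndarray:
    x = np.arange(-1, 2, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    w = np.outer(k, k)
    return w / w.sum()


def ssim(a: np.ndarray, b: np.ndarray, *, sigma: float = 1.0,
         c1: float = 0.01 ** 2, c2: float = 0.03 ** 2,
         return_map: bool = False):
    """Structural similarity with local statistics from a 3x3 Gaussian window.

    ``c1 = (0.01 L)^2`` and ``c2 = (0.03 L)^2`` with dynamic range L = 1 on
    normalized images.  The local SSIM map is averaged to a scalar.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    w = _gaussian_window3(sigma)
    mu_a = correlate(a, w, mode="reflect")
    mu_b = correlate(b, w, mode="reflect")
    var_a = correlate(a * a, w, mode="reflect") - mu_a ** 2
    var_b = correlate(b * b, w, mode="reflect") - mu_b ** 2
    cov = correlate(a * b, w, mode="reflect") - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    smap = num / den
    return smap if return_map else float(smap.mean())


# --------------------------------------------------------------------------- #
# per-vessel metrics
# --------------------------------------------------------------------------- #

def fwhm(profile: VesselProfile) -> float:
    """Full width at half maximum (micrometers) of a min-max normalized
    profile; half-max crossings located by linear interpolation on each side
    of the global maximum.  Raises if the profile is truncated before falling
    to half maximum on either side."""
    pos = profile.positions_um
    v = profile.intensities.astype(float)
    vmin, vmax = v.min(), v.max()
    if vmax <= vmin:
        raise ValueError("flat profile: no half-maximum crossing")
    v = (v - vmin) / (vmax - vmin)
    imax = int(np.argmax(v))
    half = 0.5
    left = None
    for i in range(imax, 0, -1):
        if v[i - 1] <= half <= v[i]:
            t = (half - v[i - 1]) / (v[i] - v[i - 1])
            left = pos[i - 1] + t * (pos[i] - pos[i - 1])
            break
    right = None
    for i in range(imax, len(v) - 1):
        if v[i + 1] <= half <= v[i]:
            t = (v[i] - half) / (v[i] - v[i + 1])
            right = pos[i] + t * (pos[i + 1] - pos[i])
            break
    if left is None or right is None:
        raise ValueError("profile truncated before reaching half maximum")
    return float(right - left)


def mse_nip(profile_a: VesselProfile, profile_b: VesselProfile) -> float:
    """MSE of normalized intensity profiles: both profiles are linearly
    resampled to common positions, peak-normalized to [0, 1], and compared by
    mean squared difference."""
    lo = max(profile_a.positions_um.min(), profile_b.positions_um.min())
    hi = min(profile_a.positions_um.max(), profile_b.positions_um.max())
    if hi <= lo:
        raise ValueError("profiles do not overlap")
    n = max(profile_a.positions_um.size, profile_b.positions_um.size)
    x = np.linspace(lo, hi, n)
    out = []
    for p in (profile_a, profile_b):
        v = np.interp(x, p.positions_um, p.intensities)
        out.append(v / v.max() if v.max() > 0 else np.zeros_like(v))
    return float(np.mean((out[0] - out[1]) ** 2))


# --------------------------------------------------------------------------- #
# Fourier-domain resolution
# --------------------------------------------------------------------------- #

def _iso_frequency_curve(image: np.ndarray, pixel_pitch_um: float,
                         ring_width_px: float = 1.0):
    """Radially averaged 2-D spectral magnitude.  Returns (frequencies in
    cycles/um, mean magnitude per ring), DC excluded."""
    img = normalize01(image)
    spec = np.abs(np.fft.fftshift(np.fft.fft2(img)))
    Z, X = img.shape
    fz = np.fft.fftshift(np.fft.fftfreq(Z, d=pixel_pitch_um))
    fx = np.fft.fftshift(np.fft.fftfreq(X, d=pixel_pitch_um))
    fr = np.hypot(fz[:, None], fx[None, :])
    df = ring_width_px / (min(Z, X) * pixel_pitch_um)
    ring = np.round(fr / df).astype(int)
    n_rings = ring.max() + 1
    sums = np.bincount(ring.ravel(), weights=spec.ravel(), minlength=n_rings)
    cnts = np.bincount(ring.ravel(), minlength=n_rings)
    curve = sums / np.maximum(cnts, 1)
    freqs = np.arange(n_rings) * df
    f_nyq = 0.5 / pixel_pitch_um
    keep = (freqs > 0) & (freqs <= f_nyq)
    return freqs[keep], curve[keep]


def _fit_exponential(freqs, curve):
    def model(f, a, b, c):
        return a * np.exp(-b * f) + c
    a0 = max(curve[0] - curve[-1], 1e-12)
    b0 = 1.0 / max(freqs[-1] / 3.0, 1e-12)
    c0 = max(curve[-1], 0.0)
    popt, _ = curve_fit(model, freqs, curve, p0=(a0, b0, c0),
                        bounds=([0.0, 0.0, 0.0],
                                [np.inf, np.inf, np.inf]), maxfev=20000)
    return popt


def fourier_resolution(image_ref_pd: np.ndarray, image_test: np.ndarray,
                       wavelength_um: float, pixel_pitch_um: float,
                       ring_width_px: float = 1.0) -> float:
    """Global resolution (micrometers) of ``image_test`` relative to a power
    Doppler reference assumed to resolve one wavelength.

    Both images must share the grid.  The reference spectral amplitude is the
    exponential fit of the PD iso-frequency curve evaluated at 1/wavelength;
    the test image's resolution is the inverse of the frequency where its own
    fitted curve decays to that amplitude.  By construction the PD image
    evaluates to the wavelength itself.
    """
    if np.asarray(image_ref_pd).shape != np.asarray(image_test).shape:
        raise ValueError("reference and test images must share the grid")
    if wavelength_um <= 0 or pixel_pitch_um <= 0:
        raise ValueError("wavelength and pixel pitch must be positive")
    f_ref, c_ref = _iso_frequency_curve(image_ref_pd, pixel_pitch_um,
                                        ring_width_px)
    a1, b1, c1 = _fit_exponential(f_ref, c_ref)
    if b1 <= 0:
        raise RuntimeError("non-decreasing reference iso-frequency curve")
    amp_ref = a1 * np.exp(-b1 / wavelength_um) + c1
    f_t, c_t = _iso_frequency_curve(image_test, pixel_pitch_um, ring_width_px)
    a2, b2, c2 = _fit_exponential(f_t, c_t)
    if b2 <= 0 or amp_ref <= c2 or amp_ref >= a2 + c2:
        raise RuntimeError(
            "iso-frequency fit cannot be inverted at the reference amplitude")
    f_star = -np.log((amp_ref - c2) / a2) / b2
    return float(1.0 / f_star)


# --------------------------------------------------------------------------- #
# aggregate report
# --------------------------------------------------------------------------- #

@dataclass
class MetricsReport:
    """Aggregate comparison of a generated image against ULM and PD.

    Per-vessel lists hold one entry per supplied vessel line; ``mean_std``
    summarizes them as (mean, standard deviation) pairs.
    """

    psnr_db: float
    ssim: float
    fwhm_generated_um: list = field(default_factory=list)
    fwhm_pd_um: list = field(default_factory=list)
    fwhm_ratio: list = field(default_factory=list)
    mse_nip: list = field(default_factory=list)
    fourier_resolution_um: Optional[float] = None

    def mean_std(self, name: str) -> tuple:
        vals = np.asarray(getattr(self, name), dtype=float)
        if vals.size == 0:
            return (float("nan"), float("nan"))
        return (float(vals.mean()), float(vals.std()))

    def to_dict(self) -> dict:
        d = {"psnr_db": self.psnr_db, "ssim": self.ssim,
             "fourier_resolution_um": self.fourier_resolution_um}
        for name in ("fwhm_generated_um", "fwhm_pd_um", "fwhm_ratio",
                     "mse_nip"):
            d[name] = list(getattr(self, name))
            m, s = self.mean_std(name)
            d[name + "_mean"] = m
            d[name + "_std"] = s
        return d


def evaluate_pair(generated: np.ndarray, ulm, pd, *,
                  vessel_lines: Sequence[dict] = (),
                  wavelength_um: Optional[float] = None) -> MetricsReport:
    """Full metric suite for one (generated, ULM target, power Doppler) triplet.

    ``generated`` lives on the R-times grid; the PD image is bilinearly
    upsampled to that grid for the pixelwise metrics.  ``vessel_lines`` are
    dicts with keys ``kind`` ('cross_sectional' or 'longitudinal') and
    ``line`` (two (x, z) endpoints in mm).  Cross-sectional lines yield FWHM
    and the PD/generated FWHM ratio; longitudinal lines yield MSE-NIP between
    generated and ULM.  With a wavelength, the Fourier-domain resolution of
    the generated image relative to PD is added.
    """
    gen = normalize01(np.asarray(generated, dtype=float))
    target = normalize01(ulm.normalized() if hasattr(ulm, "normalized")
                         else np.asarray(ulm, dtype=float))
    if gen.shape != target.shape:
        raise ValueError("generated image and ULM target must share the grid")
    R = round(gen.shape[0] / pd.intensity.shape[0])
    pd_up = normalize01(upsample_image(pd.intensity, R))
    if pd_up.shape != gen.shape:
        raise ValueError("PD grid is not an integer factor of the output grid")
    pitch_sr = pd.pixel_pitch / R

    report = MetricsReport(psnr_db=psnr(gen, target), ssim=ssim(gen, target))
    for vl in vessel_lines:
        if vl["kind"] == "cross_sectional":
            p_gen = extract_profile(gen, pitch_sr, vl["line"])
            p_pd = extract_profile(pd_up, pitch_sr, vl["line"])
            # a degenerate (flat / boundary-truncated) profile on one vessel
            # line is recorded as NaN so the rest of the report survives
            try:
                w_gen = fwhm(p_gen)
            except ValueError as err:
                logger.warning("generated-image FWHM on %s: %s", vl["line"],
                               err)
                w_gen = np.nan
            try:
                w_pd = fwhm(p_pd)
            except ValueError as err:
                logger.warning("PD FWHM on %s: %s", vl["line"], err)
                w_pd = np.nan
            report.fwhm_generated_um.append(w_gen)
            report.fwhm_pd_um.append(w_pd)
            report.fwhm_ratio.append(w_pd / w_gen)
        elif vl["kind"] == "longitudinal":
            p_gen = extract_profile(gen, pitch_sr, vl["line"],
                                    orientation="longitudinal")
            p_ulm = extract_profile(target, pitch_sr, vl["line"],
                                    orientation="longitudinal")
            report.mse_nip.append(mse_nip(p_gen, p_ulm))
        else:
            raise ValueError(f"unknown vessel line kind {vl['kind']!r}")
    if wavelength_um is not None:
        report.fourier_resolution_um = fourier_resolution(
            pd_up, gen, wavelength_um, pitch_sr * 1000.0)
    return report
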