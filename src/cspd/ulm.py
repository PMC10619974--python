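"""Ultrasound localization microscopy (ULM) reconstruction.

Sparse bright scatterers (microbubble-like) are localized frame by frame via
normalized cross-correlation with the PSF and intensity-weighted centroid
refinement, then accumulated on an R-times upsampled grid: each localization
event increments the nearest super-resolved pixel, realizing the Dirac-delta
accumulation of localization-based super-resolution.  The accumulation map is
the training target for the learned contrast-free reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template, peak_local_max

from .doppler import SvdFilterSpec, svd_clutter_filter
from .forward import Psf, SpatiotemporalBlock, make_gaussian_psf, synthesize_block
from .vasculature import PulsatilityProfile, VesselTree, sample_trajectories

logger = logging.getLogger(__name__)

__all__ = [
    "LocalizationSet",
    "UlmImage",
    "localize_frame",
    "localize_block",
    "accumulate_ulm",
    "make_training_pair",
    "TrainingPairConfig",
]


@dataclass
class LocalizationSet:
    """Localization events as an (M, 4) array of rows
    (frame index, x mm, z mm, peak amplitude)."""

    events: np.ndarray
    source_block_id: str = ""

    def __post_init__(self):
        ev = np.asarray(self.events, dtype=float).reshape(-1, 4)
        self.events = ev

    @property
    def n_events(self) -> int:
        return self.events.shape[0]


@dataclass
class UlmImage:
    """Super-resolved accumulation map on an R-times upsampled grid.

    ``counts`` holds raw event counts; total counts equal the number of
    accumulated (in-grid) events.  ``normalized()`` applies the saturation
    used for network targets.
    """

    counts: np.ndarray
    upsampling: int
    pixel_pitch: float  # mm per super-resolved pixel

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if np.any(c < 0):
            raise ValueError("ULM counts must be >= 0")
        self.counts = c

    def normalized(self, saturate_percentile: float = 99.0) -> np.ndarray:
        """Saturate at the given percentile of nonzero counts, scale to [0, 1]."""
        nz = self.counts[self.counts > 0]
        if nz.size == 0:
            return np.zeros_like(self.counts)
        cap = np.percentile(nz, saturate_percentile)
        cap = max(cap, 1.0)
        return np.clip(self.counts / cap, 0.0, 1.0)

    def rendered(self, sigma_px: float = 1.0,
                 saturate_percentile: float = 99.0) -> np.ndarray:
        """Accumulation map rendered with a Gaussian spot per event (the
        usual display/comparison form of a localization map, and the network
        target at event counts where the raw Dirac map is too sparse),
        saturated and scaled to [0, 1] like :meth:`normalized`."""
        from scipy.ndimage import gaussian_filter
        if sigma_px <= 0:
            return self.normalized(saturate_percentile)
        sm = gaussian_filter(self.counts, sigma_px, mode="constant")
        nz = sm[sm > 0]
        if nz.size == 0:
            return np.zeros_like(sm)
        cap = max(np.percentile(nz, saturate_percentile), 1e-12)
        return np.clip(sm / cap, 0.0, 1.0)


def localize_frame(frame: np.ndarray, psf: Psf,
                   detection_threshold: float = 0.3, *,
                   ncc_min: float = 0.5, noise_floor_k: float = 10.0) -> list:
    """Localize isolated scatterers in a single frame.

    Normalized cross-correlation of |frame| with the PSF kernel; regional
    maxima with NCC >= ``ncc_min`` whose image amplitude exceeds both
    ``detection_threshold`` x frame max and ``noise_floor_k`` x a robust (MAD)
    noise floor are kept.  Subpixel position comes from a separable
    three-point log-parabola fit through the peak (exact for a Gaussian PSF,
    and local enough not to be pulled by neighboring sources closer than the
    diffraction limit), falling back to a background-subtracted
    intensity-weighted centroid over a PSF-FWHM window when the fit is not
    applicable.  Returns a list of (x mm, z mm, amplitude); empty on blank
    frames.
    """
    if not (0.0 < detection_threshold < 1.0):
        raise ValueError("detection_threshold must be in (0, 1)")
    img = np.abs(np.asarray(frame, dtype=float))
    fmax = img.max()
    if fmax <= 0:
        return []
    mad = np.median(np.abs(img - np.median(img)))
    floor = noise_floor_k * 1.4826 * mad
    ncc = np.nan_to_num(match_template(img, psf.kernel, pad_input=True))
    kz, kx = psf.kernel.shape
    min_dist = max(1, int(round(min(kz, kx) / 2)))
    peaks = peak_local_max(ncc, min_distance=min_dist, threshold_abs=ncc_min,
                           exclude_border=False)
    hz = max(1, int(np.ceil(0.5 * psf.axial_fwhm_mm / psf.pixel_pitch)))
    hx = max(1, int(np.ceil(0.5 * psf.lateral_fwhm_mm / psf.pixel_pitch)))
    Z, X = img.shape
    out = []
    for iz, ix in peaks:
        amp = img[iz, ix]
        if amp < detection_threshold * fmax or amp < floor:
            continue
        dz = _log_parabola_offset(img[:, ix], iz)
        dx = _log_parabola_offset(img[iz, :], ix)
        if dz is not None and dx is not None:
            zc, xc = iz + dz, ix + dx
        else:
            z0, z1 = max(iz - hz, 0), min(iz + hz + 1, Z)
            x0, x1 = max(ix - hx, 0), min(ix + hx + 1, X)
            win = img[z0:z1, x0:x1]
            win = win - win.min()
            tot = win.sum()
            if tot <= 0:
                continue
            zz, xx = np.mgrid[z0:z1, x0:x1]
            zc = float((zz * win).sum() / tot)
            xc = float((xx * win).sum() / tot)
        out.append((xc * psf.pixel_pitch, zc * psf.pixel_pitch, float(amp)))
    return out


def _log_parabola_offset(line: np.ndarray, i: int):
    """Subpixel offset of a peak at index ``i`` from a parabola through the
    log of the three surrounding samples; None when not applicable (border,
    nonpositive samples, or not a local maximum)."""
    if i <= 0 or i >= line.size - 1:
        return None
    lo, mid, hi = line[i - 1], line[i], line[i + 1]
    if min(lo, mid, hi) <= 0 or mid < lo or mid < hi:
        return None
    la, lb, lc = np.log(lo), np.log(mid), np.log(hi)
    denom = la - 2.0 * lb + lc
    if denom >= 0:
        return None
    return float(np.clip(0.5 * (la - lc) / denom, -1.0, 1.0))


def localize_block(block: SpatiotemporalBlock, psf: Psf,
                   detection_threshold: float = 0.3,
                   block_id: str = "") -> LocalizationSet:
    """Frame-by-frame localization over a (filtered) block."""
    rows = []
    for t in range(block.n_frames):
        for x, z, a in localize_frame(block.data[:, :, t], psf,
                                      detection_threshold):
            rows.append((t, x, z, a))
    events = np.array(rows, dtype=float).reshape(-1, 4)
    return LocalizationSet(events=events, source_block_id=block_id)


def accumulate_ulm(locs: LocalizationSet, grid, upsampling: int,
                   pixel_pitch: float) -> UlmImage:
    """Accumulate localization events on the super-resolved grid: each event
    increments the nearest super-resolved pixel by one.  Events outside the
    grid are dropped with a logged count; total counts are conserved for
    in-grid events."""
    if upsampling < 1 or int(upsampling) != upsampling:
        raise ValueError("upsampling factor must be a positive integer")
    Z, X = grid
    R = int(upsampling)
    pitch_sr = pixel_pitch / R
    counts = np.zeros((R * Z, R * X))
    if locs.n_events:
        iz = np.round(locs.events[:, 2] / pitch_sr).astype(int)
        ix = np.round(locs.events[:, 1] / pitch_sr).astype(int)
        ok = (iz >= 0) & (iz < R * Z) & (ix >= 0) & (ix < R * X)
        dropped = int(np.sum(~ok))
        if dropped:
            logger.info("accumulate_ulm: dropped %d out-of-grid events", dropped)
        np.add.at(counts, (iz[ok], ix[ok]), 1.0)
    return UlmImage(counts=counts, upsampling=R, pixel_pitch=pitch_sr)


# --------------------------------------------------------------------------- #
# paired dataset synthesis for one imaging plane
# --------------------------------------------------------------------------- #

@dataclass
class TrainingPairConfig:
    """Synthesis settings for one imaging plane.

    Short raw blocks are contrast-free ensembles (dense, weak scatterers) by
    default, matching the regime the trained network sees at inference; the
    ULM target is built from a much longer contrast-enhanced synthesis
    (sparse, strong, microbubble-like) of the same vessel tree.  Setting
    ``n_contrast_free`` below ``n_blocks`` mixes contrast-enhanced blocks
    into the short-ensemble set.
    """

    grid: tuple = (64, 64)
    pixel_pitch: float = 0.025      # mm
    wavelength: float = 0.077       # mm (20 MHz regime)
    f_number: float = 1.0
    frame_rate: float = 1000.0      # Hz
    n_blocks: int = 4
    n_contrast_free: int = 4        # of n_blocks
    block_frames: int = 16
    ulm_frames: int = 2000
    ulm_chunk: int = 200            # SVD-filtered chunk length for ULM
    upsampling: int = 4
    cf_density: float = 25.0        # scatterers / mm vessel length
    ce_density: float = 0.6
    cf_amplitude: float = 1.0
    ce_amplitude: float = 5.0
    clutter_amplitude: float = 50.0
    noise_sigma: float = 0.02
    svd_low_cutoff: int = 2
    detection_threshold: float = 0.3
    pulsatility: PulsatilityProfile = field(default_factory=PulsatilityProfile)

    def make_psf(self) -> Psf:
        return make_gaussian_psf(self.wavelength, self.f_number,
                                 self.pixel_pitch)

    def grid_fov(self) -> tuple:
        """Field of view in mm as (x extent, z extent); grid is (Z, X)."""
        return (self.grid[1] * self.pixel_pitch,
                self.grid[0] * self.pixel_pitch)


def make_training_pair(tree: VesselTree, config: TrainingPairConfig,
                       seed: int = 0):
    """Emit the per-plane training unit: ``n_blocks`` short raw blocks
    (contrast-free by default, see :class:`TrainingPairConfig`) plus one ULM
    target accumulated from a long contrast-enhanced synthesis of the same
    tree.

    Returns ``(blocks, ulm_image)`` where blocks carry kind ``raw`` (clutter
    filtering is the caller's processing step).  The ULM synthesis is filtered
    and localized in chunks of ``ulm_chunk`` frames.
    """
    cfg = config
    if cfg.ulm_frames < cfg.block_frames:
        raise ValueError("ULM frame budget must be >= block length")
    psf = cfg.make_psf()
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 * cfg.n_blocks + 2 *
                              max(1, cfg.ulm_frames // cfg.ulm_chunk) + 4) % (2 ** 31)
    ci = iter(child.tolist())

    blocks = []
    dt = 1.0 / cfg.frame_rate
    for b in range(cfg.n_blocks):
        contrast_free = b < cfg.n_contrast_free
        density = cfg.cf_density if contrast_free else cfg.ce_density
        amp = cfg.cf_amplitude if contrast_free else cfg.ce_amplitude
        traj = sample_trajectories(tree, density, cfg.block_frames, dt,
                                   pulsatility=cfg.pulsatility, seed=next(ci),
                                   amplitude_median=amp)
        blocks.append(synthesize_block(traj, psf, cfg.grid,
                                       cfg.clutter_amplitude, cfg.noise_sigma,
                                       seed=next(ci)))

    # long contrast-enhanced synthesis for the ULM target, chunked
    spec = SvdFilterSpec(low_cutoff=cfg.svd_low_cutoff)
    all_events = []
    n_chunks = max(1, cfg.ulm_frames // cfg.ulm_chunk)
    for c in range(n_chunks):
        frames = cfg.ulm_chunk if c < n_chunks - 1 else \
            cfg.ulm_frames - cfg.ulm_chunk * (n_chunks - 1)
        traj = sample_trajectories(tree, cfg.ce_density, frames, dt,
                                   pulsatility=cfg.pulsatility, seed=next(ci),
                                   amplitude_median=cfg.ce_amplitude)
        raw = synthesize_block(traj, psf, cfg.grid, cfg.clutter_amplitude,
                               cfg.noise_sigma, seed=next(ci))
        if tree.n_segments == 0:
            continue
        filt = svd_clutter_filter(raw, spec)
        locs = localize_block(filt, psf, cfg.detection_threshold,
                              block_id=f"ulm_chunk_{c}")
        if locs.n_events:
            all_events.append(locs.events)
    events = (np.concatenate(all_events, axis=0) if all_events
              else np.zeros((0, 4)))
    ulm = accumulate_ulm(LocalizationSet(events=events, source_block_id="ulm"),
                         cfg.grid, cfg.upsampling, cfg.pixel_pitch)
    return blocks, ulm
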