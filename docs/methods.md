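# Methods

This document records the models, assumptions, parameter choices, and
numerical decisions behind the `cspd` package, which implements a
contrast-free super-resolution power Doppler (CS-PD) study at desk scale:
a synthetic microvasculature and ultrafast-Doppler simulator, a
deep-learning reconstruction that maps short clutter-filtered slow-time
ensembles to a super-resolved vessel map, and the evaluation and ablation
protocols around it.

## 1. Synthetic vasculature (`cspd.vasculature`)

**Vessel tree.** A 2-D binary branching tree inside a rectangular field of
view. Root vessels start on the boundary and grow inward; each child
branches at a random angle with radius reduced by a factor drawn around
Murray-law-like scaling, down to `branching_depth` levels. Segments are
polylines with per-segment radius and mean flow speed (faster in larger
vessels). A deterministic seed fully determines the geometry.

**Parallel-pair phantom.** Each tree can embed two straight parallel
vessels separated by `pair_spacing_mm = 0.0385` mm — half the lateral PSF
FWHM (see §3) — with speeds 1.5 and 3.0 mm/s. This is the resolution
phantom: diffraction-limited power Doppler cannot separate the pair, a
super-resolved method can. The tree also records the perpendicular
`cross_line` through the pair midpoint used for profile measurements.

**Scatterer flow.** Scatterers are seeded along vessel centerlines with a
linear density (per mm of vessel length), given a random radial offset
within the lumen, and advected along the polyline at the segment speed.
Scatterers leaving a segment are recycled at its entrance so density is
stationary. Two regimes share the same machinery:

- *contrast-free (CF)*: dense (25 /mm), unit-amplitude scatterers — the
  blood speckle regime the method takes as input;
- *contrast-enhanced (CE)*: sparse (0.6 /mm), bright (5×, Rayleigh-spread)
  scatterers — the microbubble regime used only to build ULM targets.

**Pulsatility.** A `PulsatilityProfile` multiplies all speeds by a
periodic cardiac waveform (period 0.2 s, modulation depth `m`, a fast
systolic peak at 35% of the cycle). `m = 0.5` in the pulsatility study;
`m = 0` elsewhere.

## 2. Forward model (`cspd.forward`)

Each frame is the sum of Gaussian point-spread functions centered at the
scatterer positions (sub-pixel, by evaluating the separable Gaussian at
the exact offset), plus tissue clutter and white Gaussian noise:

- **PSF**: separable Gaussian with lateral FWHM = wavelength × f-number
  (0.077 mm × 1 = 77 µm, i.e. ~3.1 pixels at 25 µm pitch) and axial FWHM
  = wavelength/2. The axial width is under-sampled at this pitch; the
  simulator warns once per PSF construction and the study accepts the
  aliasing as part of the fixture.
- **Clutter**: two smooth random spatial fields (Gaussian-filtered white
  noise, σ = 8 px), amplitudes 50 and 15 relative to the unit flow
  scatterer, each multiplied by a slow temporal gain. The gains are
  band-limited: unit-RMS white noise smoothed over a 0.1 s time constant,
  scaled to 1% and ~17% relative drift. Tissue moves on cardiac/breathing
  time scales, so its slow-time spectrum must stay below the flow band;
  white or random-walk gains would leak broadband energy into the flow
  band and make clutter fundamentally inseparable, which is neither
  physical nor what SVD filtering assumes.
- **Noise**: i.i.d. Gaussian, σ = 0.02.

A `SpatiotemporalBlock` (nz × nx × T plus pitch, frame rate, and a
`kind` tag `raw`/`clutter_filtered`) is the unit of data. Frame rate is
1000 Hz throughout.

## 3. Doppler processing (`cspd.doppler`)

**SVD clutter filtering.** The Casorati matrix (pixels × frames) is
decomposed by SVD and the first `k` components are removed
(`svd_low_cutoff = 2`, matching the rank-2 clutter model). An
`adaptive_cutoff` utility finds the singular-value knee but the fixed
cutoff is the study default. Filtering requires `kind == "raw"` and tags
its output, so double filtering is a type error.

**Power Doppler (PD).** Per-pixel mean power of the filtered slow-time
signal.

**Flow-separation augmentation.** The filtered slow-time signal is
partitioned into `n` spectral bands (FFT bins, conjugate-symmetric so the
bands are real and sum exactly to the input). Used as a data augmentation;
at this fixture's speeds (≤3 mm/s at 1000 Hz) the transit-time bandwidths
of both pair vessels fall inside the lowest band, so band partitioning
cannot by itself separate the pair — it is an augmentation, not a
resolution mechanism.

**Truncate-and-interpolate.** Keeps every n-th frame and linearly
re-interpolates to the original length (edge-clamped past the last kept
frame): the test-time-only frame-reduction protocol of the ablation.

**Sliding windows.** `sliding_window_series` applies a reconstruction to
overlapping windows (window 64, step 16 at fixture scale) for the
pulsatility series.

## 4. ULM targets (`cspd.ulm`)

Per CE frame, after SVD filtering in 200-frame chunks, local maxima above
`detection_threshold = 0.3` (relative to the frame maximum) are localized
with a 3×3 center-of-mass refinement — sub-0.05 px accurate noiselessly.
Events accumulate on an R = 4× grid (nearest super-resolved pixel; counts
conserved for in-grid events, out-of-grid drops are logged). The target
presented to the network is the count map convolved with a Gaussian spot
(`target_sigma_px = 1.0` on the super-resolved grid) and peak-normalized:
rendering with the localization uncertainty scale makes the regression
target piecewise-smooth instead of near-singular while preserving the
pair separation of ~6 super-resolved pixels.

`make_training_pair` builds one imaging plane: 4 raw 64-frame blocks (all
CF by default) plus a 2000-frame CE synthesis for the ULM target.
Training inputs are all contrast-free: mixing CE blocks into the input
set makes the network hedge between two input statistics that map to the
same target and measurably floors the L1 loss.

## 5. Network and training (`cspd.network`, `cspd.nn`)

**Framework.** A small, self-contained float32 NumPy autodiff layer set
(im2col convolutions, batch norm, max-pool, exact-adjoint bilinear
upsampling, Adam) — no GPU framework dependency.

**Generator.** A U-Net encoder-decoder (2 levels, base 12 channels,
skip connections) over the native 64×64 grid with the T = 64 slow-time
frames as input channels, followed by an upsampling tail that refines
after every bilinear 2× stage (conv-BN-ReLU at each intermediate scale)
and a 1×1 head with LeakyReLU(0.1) at the finest 256×256 grid. Refining
at the output resolution matters: a bilinear-only tail cannot synthesize
structure finer than the native grid, and in ablation probes it failed to
reproduce the two-vessel separation even on training data. At inference
the output is clamped non-negative. ~75k parameters.

**Input normalization.** Magnitudes of the filtered block divided by the
block's 99th percentile (`block_to_input`). For sliding-window inference
(pulsatility) a fixed global scale replaces the per-block scale so window
amplitudes remain comparable.

**Losses.** `l1`; `l1+feature` (L1 plus λ₁ = 0.001 times an L1 distance
in the feature space of a fixed random-convolution extractor — a
VGG-perceptual-loss stand-in that needs no pretrained weights);
`l1+adversarial` (Wasserstein critic, weight clipping 0.01, 5 critic
steps per generator step, λ₂ = 0.01). The acceptance study uses `l1`.

**Optimization.** Adam, lr 1e-3, batch 1, 10% validation split,
plateau decay ×0.5 with patience 10 down to 1e-5, up to 75 epochs,
best-validation weights restored. The decay factor, batch size, and epoch
budget were set from training diagnostics: with a ×0.1 decay the rate
collapsed to the floor mid-training while validation was still improving,
and the underfit model failed to reproduce the pair phantom even on
training planes whose targets are cleanly bimodal; batch 1 doubles
updates per epoch at equal wall time, and best validation lands near
epoch 40–50.

**Flip augmentation** (random horizontal/vertical flips of input and
target together) is implemented and exactly physics-valid — the separable
axis-symmetric PSF makes each reflection an invariance of the task, while
90° rotations would not be (lateral 77 µm vs axial 38.5 µm widths) — but
is off by default: at this dataset size and epoch budget it slows
convergence on fine two-vessel structure more than it improves
generalization (flip-trained models kept the pair lobes merged on planes
they had seen). The option remains for larger-data regimes.

## 6. Metrics (`cspd.metrics`)

- **PSNR** with max = 1 on normalized images; infinite for identical
  inputs.
- **SSIM**: Gaussian-windowed (3×3, σ = 1), c₁ = (0.01 L)², c₂ = (0.03 L)²
  with L = 1.
- **FWHM** on a `VesselProfile` (positions µm, intensities): min-max
  normalized, half-crossings by linear interpolation; boundary-truncated
  profiles raise.
- **MSE-NIP**: profiles linearly resampled to common positions, each
  min-max normalized, mean squared difference.
- **Fourier iso-frequency resolution**: radial spectrum averages, an
  `A·exp(−b f) + c` fit, reference amplitude from the PD curve at 1/λ;
  the test image's resolution is where its fitted curve reaches that
  amplitude. Self-consistency: `fourier_resolution(PD, PD) = λ`.
- **Profile peak counting** uses half-max prominence on the normalized
  profile, so the bimodal/unimodal decision is scale-free.
- Vessel lines for profiles come from the latent tree geometry
  (`default_vessel_lines`): the designated FWHM vessel is the fastest
  vessel whose measurement corridor stays farthest from all other
  vessels, so neighbors do not contaminate the profile.

## 7. Study orchestration (`cspd.pipeline`)

**Seeding.** A master seed fans out via CRC32-hashed labels through
`numpy.random.SeedSequence`, all child seeds < 2³¹, so any subset of the
study is reproducible in isolation and manifests are bitwise-reproducible.

**Dataset.** 6 training + 1 held-out plane, each a fresh vessel tree with
the embedded pair phantom, 4×64-frame CF blocks and a 2000-frame CE ULM
target; optional flow-separation augmentation multiplies the block list.

**Evaluation.** On the held-out plane the CS-PD map is compared to the
rendered ULM target (SSIM, PSNR) against bilinearly upsampled PD as the
baseline, plus FWHM ratio (PD/CS-PD) on the designated vessel, MSE-NIP on
a longitudinal pair line, pair-profile modality, and Fourier resolution.
Pixelwise quality metrics (SSIM, PSNR) are computed per contrast-free
ensemble and averaged across the plane's blocks — the ensemble-averaged
estimate standard for such studies. Image-geometry measurements
(profiles, FWHM, pair modality, Fourier resolution) are taken on the
full-acquisition compound images — the mean of per-block CS-PD
reconstructions and of per-block PD images — because those questions
address the final accumulated map, just as the ULM reference itself only
exists as a full-acquisition accumulation. The distinction matters:
per-block CS-PD reconstructions carry small vessel-position jitter, so
the compound image scores a lower SSIM than any individual block even
though it is the more complete map.

**Frame-count ablation.** For each frame count c, both arms see the same
physical data — every T/c-th frame of each held-out block, preserving
the full observation span — and differ only in how the model consumes
it: *matched* (retrained and tested on c-sample inputs) vs
*interpolated* (full-frame model fed the decimated block linearly
re-interpolated back to T). Truncating one arm to the first c frames
instead would confound the protocol comparison with a c/T-times shorter
observation of the flow. A *collapsed* control trains on single
accumulated PD images (no temporal information).

**Pulsatility.** A 400-frame CF synthesis with cardiac modulation
(m = 0.5, period 0.2 s); sliding-window (64/16) PD and CS-PD with
window-local SVD filtering (filtering the whole series globally removes
the slow-time mean per window and with it the speed sensitivity of PD).
Each CS-PD window is reconstructed *on-manifold*: the window's central
`in_frames` frames are normalized by their own 99th-percentile magnitude
(the training-time normalization), and the peak-normalized output is
multiplied by the squared normalization scale. The network is trained
scale-invariantly, so its raw amplitude is uncalibrated; the window's
measured Doppler scale is the only calibrated intensity in the data and
carries the modulation, while the network supplies the super-resolved
structure. ROI-mean series over the whole vasculature (see
`_vasculature_roi_mask`: the modulation is tree-wide, and a
single-vessel ROI is dominated by scatterer shot noise at fixture scale)
are correlated with the imposed waveform and with each other.

## 8. Numerical choices

- float32 network arithmetic; float64 elsewhere.
- Exact adjoints for all layers (gradient-checked in the test suite).
- FFT band partition is conjugate-symmetric by construction; the bands
  sum to the input to machine precision.
- SVD on the tall Casorati matrix uses `full_matrices=False`.
- All I/O is standard formats: HDF5 blocks, TIFF images, CSV vessel
  lines, JSON manifests/reports, YAML configs.

## 9. Limitations

- 2-D scalar intensity model: no RF phase, beamforming, speckle
  interference, or aberration; SVD filtering operates on real-valued
  envelope-like data.
- The clutter model is rank-2 by construction, which flatters a fixed
  rank-2 SVD cutoff; real tissue needs the adaptive cutoff.
- Fixture scale (64×64, 7 planes, ~75k parameters) is far below any
  in vivo deployment of such methods; absolute metric values are not
  comparable to in vivo numbers, only orderings and trends.
- At 1000 Hz and ≤3 mm/s, slow-time spectral bands cannot distinguish the
  pair speeds, so flow separation functions purely as augmentation here.
- Global SSIM at fixture scale is insensitive to the temporal channel:
  the synthetic tree is almost entirely diffraction-resolvable, so a
  model trained on collapsed single accumulated-PD inputs reaches
  validation L1 within 0.5% of the spatiotemporal model and slightly
  *higher* held-out SSIM, despite being unable to resolve the
  sub-diffraction pair (its pair profile stays unimodal). The
  spatiotemporal advantage at this scale appears in pair resolution, not
  in global image-quality metrics; the frame-count orderings at 16
  frames are within block-to-block noise (±0.002 SSIM).
- ULM targets from 2000 CE frames are themselves sparse; on some tree
  seeds a crossing vessel contaminates the pair cross-line and the target
  profile is unimodal. These planes stay in the dataset (dataset
  variance), and the held-out evaluation line comes from the latent
  geometry, not the target.
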