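# Methods

`cellmech` quantifies three readouts of cellular mechanotransduction from
2D fluorescence micrographs: the nuclear-to-cytoplasmic (N/C) distribution
of a transcription factor such as YAP, the sensitized-emission FRET index
of a molecular tension sensor inside focal adhesions, and cell-generated
substrate stresses by traction force microscopy. This note records the
models, the tunable parameters with their defaults, and the design choices
made where the procedure was genuinely open.

## Channel pre-correction

Every quantitative channel passes through the same chain, in order:
illumination correction, inter-channel registration, background
subtraction, 3x3 mean smoothing.

**Illumination.** With a measured flat-field the channel is divided by the
flat-field normalized to unit mean (mean intensity is preserved). Without
one, `correct_illumination` can divide by a 2nd-degree bivariate
polynomial surface fit to the image itself; higher orders would begin
absorbing cell signal, and even at degree 2 the self-fit is only
appropriate for fields much larger than a cell. For this reason the
`correct_channel` chain *skips* the illumination step by default when no
flat-field is given (`fit_illumination=True` restores the polynomial
fallback): on sparse scenes the self-fit surface measurably biases
downstream ratios.

**Registration.** Only translation is modelled. The shift is estimated by
phase correlation with upsampled-DFT subpixel refinement and applied by
bilinear resampling. Two failure guards return a zero shift with a
warning: an indistinct correlation peak (peak-to-runner-up ratio below
1.05) and an estimated shift above a quarter of the image size.

**Background.** A scalar level is subtracted and negatives are clipped to
zero. The level is the mean over a user-supplied cell-free ROI (at least
100 px), or the image's 5th percentile when no ROI is given. The
percentile fallback is robust to sparse bright cells but underestimates
the offset when the noise scale is comparable to it; pipelines that have a
cell mask available therefore build the ROI as the complement of the
dilated cell mask.

**Smoothing.** "Three-point" smoothing is interpreted as one pass of a
3x3 uniform mean filter with replicated borders — the closest 2D analogue
of a 3-tap moving average. Constants map to themselves; output extrema are
bounded by input extrema; total intensity is preserved to well under 0.5%
at 64x64 and above. A 1D 3-tap or median variant would also be defensible;
the choice is configurable at the call site by composing filters directly.

## Segmentation

**Nuclei** (DAPI): Canny edges (sigma 2 px; hysteresis thresholds at 10%
and 30% of the peak smoothed-gradient magnitude, making the result
invariant to intensity scaling), morphological closing (disk radius 3),
hole filling, then refinement of the filled region to the half-amplitude
intensity contour. The refinement matters: the filled Canny band straddles
the true boundary and inflates area by roughly half the perimeter (~7% for
a 20x12 px ellipse); the midpoint criterion — also scale-invariant —
brings the error below 1%. Objects smaller than `min_area_um2` (default
50 um^2, a lower bound for fibroblast nuclei) or touching the image border
are removed; a border-touching nucleus cannot carry an untruncated
cytoplasmic ring. Touching nuclei are not split (no watershed).

**Cytoplasmic rings**: for each nucleus, the pixels whose Euclidean
distance to that nucleus lies in `(guard, guard + width]`, with width 5 px
by default. Pixels reachable from two nuclei go to the nearer one
(distance-transform assignment), so rings never overlap. `guard_px = 0`
reproduces the literal "dilate and subtract" ring; the N/C pipeline uses
`guard_px = 1` to keep partial-volume pixels at the blurred nuclear edge
out of the cytoplasmic estimate (see below).

**Cells** (F-actin): Otsu threshold (fixed value configurable), hole
filling, minimum area 100 um^2. **Focal adhesions** (acceptor channel): a
white top-hat with a 10 px disk removes diffuse cytoplasmic sensor signal,
Otsu over cell pixels thresholds the residue, detections outside the cell
mask are dropped, and each adhesion inherits the majority cell label under
it.

## N/C ratio

Per nucleus: mean signal over the nuclear mask divided by mean signal over
the matching ring. The ring samples a similar-thickness strip of cytoplasm
next to the nucleus rather than the whole cytoplasm — that locality is the
method. The ratio is invariant to multiplicative intensity changes; an
additive offset b moves it to (mu_n + b)/(mu_c + b), i.e. toward 1, which
is why the pipeline subtracts background measured on a cell-free ROI
first.

Two partial-volume guards, both 1 px by default in `nc_ratio_pipeline` and
both off in the raw operations: the ring starts 1 px away from the nuclear
boundary, and the nuclear mean is read over the mask eroded by 1 px (areas
are still reported on the full mask). Without the guards, pixels that
straddle the blurred nucleus edge contaminate both means and bias a true
ratio of 4 about 8% toward 1 on synthetic scenes; with them the recovered
median is within 0.5% of truth across ratios 0.5–4.

## Three-cube FRET index

Channels: donor excitation/donor emission (I_d), acceptor
excitation/acceptor emission (I_a), donor excitation/acceptor emission
(I_f). The FRET channel contains donor bleed-through and directly excited
acceptor signal, both linear in the pure channels, with fractions dL and
aL measured as ordinary least-squares slopes of I_f against the
single-fluorophore channel on donor-only / acceptor-only samples. The
regression keeps an intercept (absorbing residual background) and discards
it; a through-origin variant would differ only if background subtraction
were imperfect. Fits with negative slope or r^2 < 0.5 are rejected as
invalid calibration samples, as are samples with fewer than 500 usable
pixels. Calibration pixels are restricted to an intensity floor so that
empty pixels do not dominate.

The pixelwise index is (I_f − dL·I_d − aL·I_a) / I_a = F_c / I_a, defined
where I_a exceeds a floor (recommended: ~5x the background standard
deviation of the acceptor channel) and NaN elsewhere. The index is a
relative proxy for FRET efficiency — no instrument G-factor is applied, so
no absolute efficiency or force in piconewtons is reported. For the
tension sensor, higher force means lower index; the C-terminal control
construct bears no force and its group mean defines the normalization
scale in `normalize_to_control`.

Per-cell averages are taken over focal-adhesion pixels only, as the
pixel-area-weighted mean over the union of a cell's valid adhesion pixels
(the literal reading of adhesion-area normalization). A mean-of-adhesion-
means alternative is available via `per_adhesion_mean=True`; the two
differ when the index varies across adhesions of unequal size.

## Traction force microscopy

**Displacements.** PIV-style windowed cross-correlation between the loaded
(cell attached) and relaxed (post-lysis) bead images: 32 px windows, 50%
overlap, mean subtraction, FFT correlation, three-point Gaussian subpixel
peak fit per axis. A second pass re-correlates each window against the
relaxed window cropped at the first-pass integer displacement, which makes
the residual peak symmetric and removes the loss-of-pairs bias of one-pass
correlation (~0.1 px on uniform shifts; ≤0.02 px after). Windows whose
matching content falls outside the frame, or that fail a peak-quality
check, are invalidated; the universal normalized-median test (3x3
neighbourhood, threshold 2, eps 0.1 px) flags outliers, and invalid
vectors are replaced by the median of valid neighbours and marked in
`validity`. More than 50% invalid windows is an error. An optional Hann
taper exists but is off by default — with mean subtraction alone the
estimator is exact on integer shifts, and the taper costs that exactness.

**Drift.** Stage drift between the pre- and post-lysis acquisitions is the
median displacement over grid nodes outside the cell mask dilated by a
margin (default 20 px); it is subtracted from every vector. At least 20
far-field vectors are required, otherwise no correction is applied (with a
warning).

**Forward model.** The substrate is a semi-infinite, linear-elastic,
incompressible half-space (Poisson ratio 0.5 by default; the kernel is
implemented for nu in [0, 0.5]). In Fourier space the surface displacement
is u(k) = G(k) t(k) with

    G(k) = 2(1+nu) / (E k^3) * [ (1-nu)k^2 + nu ky^2,   -nu kx ky
                                 -nu kx ky,    (1-nu)k^2 + nu kx^2 ]

k in rad/um, G in um/Pa. The k = 0 mode is zeroed (no rigid motion). The
~50 um thickness of a real spin-coated gel layer is not modelled; the
finite-thickness correction is omitted to match the half-space assumption.

**Inverse.** Zeroth-order Tikhonov per wavevector:
t(k) = (G^T G + lambda^2 I)^{-1} G^T u(k). `lambda` is applied to the
kernel in its physical units (um/Pa), the convention of the classical FTTC
codes; at E = 10 kPa and micron-scale grids, lambda = 1e-4 attenuates the
noisiest (highest-k) modes by a factor ~0.7–0.9 while leaving the signal
band untouched. A convention that rescales G by its largest singular value
(which lives at the lowest wavevector) was considered and rejected: it
renders lambda = 1e-4 inert on realistic grids. No automatic
lambda selection (L-curve, Bayesian) is performed; lambda is a fixed input.
Because the k = 0 mode is zeroed in both directions, recovered fields are
force-balanced to machine precision whenever the input displacement field
derives from a balanced traction.

**Per-cell stress** is the mean traction magnitude over the cell's mask
sampled at the grid nodes. Note that the mean of |t| is biased upward by
noise (rectification); for recovery-versus-truth comparisons inside a
patch of uniform direction, the magnitude of the mean traction vector is
the unbiased reading and is what the verification scripts report. The
per-cell readout keeps the plain mean-of-magnitudes definition.

## Synthetic scenes

The generator is a pure function of its `SceneConfig` (seed included):
re-rendering is bit-identical. Noise is Poisson shot noise on the
noiseless render plus additive Gaussian read noise plus a constant camera
offset, each optional.

* **Cell scenes**: anti-aliased filled ellipses (4x4 supersampled
  coverage) for nuclei (DAPI) and cell silhouettes (F-actin); the YAP
  channel realizes the configured N/C ratio exactly (nucleus =
  ratio x cytoplasm intensity). Truth masks threshold coverage at 0.5.
  With `antialias=False` rendering is binary at pixel centres and
  measuring the truth masks reproduces configured ratios exactly; with
  anti-aliasing, edge pixels introduce the same partial-volume effects as
  a real point-spread function, which is what the measurement guards are
  for. Defaults (0.325 um/px, 45x35 px cell and 20x12 px nucleus
  semi-axes, cytoplasm 150 counts) sketch a spread fibroblast at moderate
  magnification.
* **FRET scenes**: per pixel with sensor concentration c and efficiency E,
  I_d = k_d c (1−E), I_a = k_a c, I_f = k_f c E + dL I_d + aL I_a. This is
  the minimal three-gain linear model under which the index equation is
  exact, recovering k_f E / k_a wherever c > 0 — instrument spectra are
  deliberately not modelled, since the artifact tests the analysis, not
  the microscope. Concentration carries smooth lognormal heterogeneity
  (sigma 0.4, correlation length 8 px) emulating expression variability;
  adhesions are bright elliptical puncta (concentration 2000 vs cytoplasm
  500). Donor-only and acceptor-only calibration scenes zero the other
  fluorophore and set E = 0.
* **TFM scenes**: traction patches (uniform disks or Gaussians, 100 Pa
  scale) are force-balanced by construction — any residual net force is
  absorbed by a broad compensating Gaussian patch, then spread exactly.
  Truth displacement is the Boussinesq forward response at pixel
  resolution. Beads (default 0.03 per px^2, Gaussian PSF sigma 1.2 px,
  the diffraction-limited size of a 100 nm bead at 63x/1.4 NA) are placed
  uniformly at random and rendered analytically at subpixel positions;
  the loaded image renders each bead displaced by the truth field at its
  rest position, plus optional uniform drift. Defaults: 0.103 um/px
  (63x objective, 6.5 um camera pixels), E = 10 kPa, nu = 0.5.

What passing on these scenes does *not* show: robustness to uneven
illumination beyond a smooth polynomial, chromatic aberration beyond
translation, out-of-focus light, touching nuclei, bead detachment or
focus drift between TFM frames, and any absolute comparability of
traction magnitudes across lambda conventions.

## Problem sizes and verification

The test suite and the verification script (`scripts/acceptance.py`)
regenerate all inputs at run time: 512x512 scenes with 3 cells for N/C
recovery (6 scenes per ratio), 256x256 donor-only scenes for calibration
(50 seeds), 64x64 traction grids for the inversion studies (10 noise
seeds), and 512x512 bead pairs for PIV. These sizes give stable medians
and worst-case statistics while keeping a full run in the tens of
seconds. Known limitations are listed above per section; the headline
per-cell distributions of any particular biological experiment depend on
its microscopy data and are outside what synthetic verification can
reproduce.
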