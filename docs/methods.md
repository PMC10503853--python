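# Methods

This note documents the models, the synthetic data, the numerical choices and
the limitations of the package, in the order data flows through it.

## Ground-truth temperature fields (`fieldgen`)

All synthetic scenes are exact or numerically converged solutions of the
steady-state heat equation, because spatial smoothness dictated by heat
diffusion is the structure the recurrent models exploit.

* **Pipe cross-section** (`pipe_cross_section`): the logarithmic annulus
  profile T(r) = T_i + (T_o − T_i)·ln(r/r_i)/ln(r_o/r_i), constant inside the
  inner wall and outside the outer wall. Radii are in pixels, wall
  temperatures in kelvin.
* **Plate** (`plate_dirichlet`): the bilinear blend of four corner
  temperatures, a + bx + cy + dxy, which is harmonic.
* **Finite-difference** (`fd_poisson`): the 5-point-stencil Laplace equation
  with Dirichlet edges, insulated ("mirror") edges, and interior
  fixed-temperature heater lines, solved with a sparse direct factorization.
  The discrete interior residual |4T − ΣT_nb| is asserted below a tolerance
  (default 1e−6 K) on every solution; a direct solve reaches ~1e−12 K, so the
  tolerance is a contract, not a convergence knob.

An optional sinusoidal modulation A·sin(2πx/λ)·exp(−2πd/λ) can be added near
the top and bottom edges (defaults A = 1 K, λ = 16 px). This term is itself
harmonic, so perturbed fields remain heat-equation solutions; it recreates
the short-wavelength periodic edge features that are the hardest part of a
scene to reconstruct. Pixel pitch defaults to 1 μm so gradient maps read in
K/μm. The coordinate convention is row-major, 0-based, (row, col) = (y, x).

Temperature noise is pixelwise i.i.d. Gaussian, σ = 0.1 K by default, applied
to the *temperature field* before any intensity conversion — the noisy copy
is rendered, the clean field remains the regression target. Under this
ordering, "reconstruction below 0.1 K RMSE" is a statement about recovering
ground truth through the noise, which is the de-noising property the patch
networks are designed to show.

## Photophysics and calibration (`photophysics`, `presets`)

Quantum-dot emission is a Gaussian line parameterized by a reference peak
(620 nm), linear red-shift (0.1 nm/K), reference FWHM (30 nm), linear
broadening (0.05 nm/K) and linear quenching (0.5 %/K), all relative to
298 K. These defaults are a surrogate for measured CdSe/ZnS spectra of 620 nm
dots and are config-overridable; the qualitative behaviour that matters is
that every filter channel's integrated intensity varies smoothly and
monotonically-enough with temperature.

Two filter banks are provided:

* the **five-band** bank: contiguous sharp-edged band-passes tiling
  585–660 nm (edge softness 0), used with fields in the 298–308 K regime;
* the **filter-wheel** bank: 550 nm long-pass, 650 ± 20, 660 ± 5, 650 ± 5,
  640 ± 5, 620 ± 5 nm FWHM, with logistic roll-offs (3 nm scale) producing
  overlapping pass-bands, used for chip scenes in the 290–380 K regime. The
  620 ± 5 channel adds little information and is dropped by default for
  training (five of six channels), controlled by a flag.

Calibration integrates the emission line over the bank at a ladder of
temperatures, pins the *global* minimum and maximum raw intensity of that set
to grayscale 0 and 65,535 (the anchors are frozen and reused verbatim for
later data; later data may clip, and the clipped fraction is logged), and
fits one least-squares quadratic in T per channel. Channels whose quadratic
is not strictly monotone over the validity range are flagged and excluded
from closed-form inversion (two of the six filter-wheel channels flag
non-monotone with the default quench; the remaining four carry the
inversion). The five-band calibration is fitted over 296–314 K — wider than
the 298–308 K training fields — so that extrapolation scenes up to 312 K and
noise excursions stay inside the rendering domain.

Rendering evaluates the quadratics per pixel, clips to [0, 65535], and by
default quantizes with round-half-even (16-bit camera realism; the flag
exists because unquantized rendering makes the render→invert round trip an
exact identity, used as an oracle). Pointwise inversion solves each monotone
channel's quadratic in closed form (root selected inside the validity range)
and combines channels weighted by squared mean sensitivity |d counts/dT| —
the least-squares combination in count space under a local linearization.
Camera binning averages factor×factor blocks and re-quantizes; a trailing
remainder is cropped and logged.

## Patches (`patches`)

Training and inference operate on 1×5 horizontal pixel sequences or 5×5
tiles, extracted densely (stride 1) — a deliberate choice: small patches
multiply the number of unique training examples from few images, and stride-1
reconstruction lets every pixel be predicted by up to 5 (sequences) or 25
(tiles) overlapping patches whose mean suppresses seams. Intensities are
divided by 65,535 before entering a network. No padding is used: patches
exist only where fully inside the image, which still covers every pixel.
Stitching raises on any uncovered pixel rather than inventing values.
Batches can carry per-pixel loss weights; chip training uses the channel mask
as weights so that pixels with no fluorophore (zero counts, no information)
do not contribute to the fit.

## Architectures (`models`)

The three recurrent variants and their fusion rules are described in the
README. Implementation decisions that were genuinely open:

* Directional cores (forward/backward; row/column) have **independent
  weights** by default — the most expressive reading of "separate" cores. A
  `tie_weights` flag shares parameters across directions (and orientations),
  which makes palindrome symmetry (BFTLSTM) and transpose equivariance
  (MFTLSTM) exact; the symmetry tests rely on it.
* Bidirectional fusion aligns the reverse scan **by source position** (the
  reverse core's output is re-reversed before the pointwise sum), the only
  arrangement in which adding features is semantically coherent.
* The MFTLSTM's row/column fusion likewise aligns by source pixel: the fused
  feature at (i, j) is row-scan(row i, step j) + column-scan(column j, step
  i).
* The fully connected head maps each position's hidden2-dim feature to one
  kelvin value with weights **shared across positions**; a `flattened_head`
  flag provides the 25·hidden2 → 25 alternative (parameter-heavy, off by
  default, and it breaks transpose equivariance).
* Dropout (0.2) acts on the feature entering the head and is active only in
  training; evaluation-mode forward passes are deterministic and
  batch-order invariant.

The numpy implementation keeps parameters in float32 (float64 available via
config, used by the finite-difference gradient checks); a two-layer LSTM with
fused gate matrices costs 4·(in+hidden+1)·hidden parameters per layer, which
the tests assert for arbitrary sizes (8,226,869 total for the
publication-scale 5-channel FTLSTM).

Baselines: MVPF is an ordinary least-squares polynomial of total degree 2 in
the C channel intensities (all cross terms; C(C+2, 2) monomials — 21 at
C = 5), applied per pixel. The random forest uses 200 trees, unlimited depth,
√C feature subsampling and a fixed seed by default.

## Training (`harness`)

Loss is MSE on kelvin targets; the optimizer is Adam. The method itself
prescribes none of this, so everything is config-exposed: defaults are
lr 1e−3, batch 256, early stopping on validation RMSE (patience 10), with an
optional cosine learning-rate schedule. The head bias is initialized to the
mean training target so optimization starts at the best constant predictor
(equivalently, target centering — also available explicitly — without moving
the targets). Train/validation splits are at the whole-image level, never the
patch level, because stride-1 patches from one image overlap heavily and
would leak. Both patch-level validation RMSE and stitched full-image
reconstruction RMSE are reported, since they answer different questions.

## The two synthetic regimes and the experiments

**Five-band benchmark** (`run_benchmark_experiment`): random pipe/plate
fields in 298–308 K (σ = 0.1 K noise, quantized rendering), fixed evaluation
scenes (two pipe cross-sections with periodic edge perturbations and one
plate), and a second evaluation set spanning 298–312 K for extrapolation.
Desk-scale problem sizes, chosen once: 40 training + 8 validation images of
32×32 px; 12,000 training sequences / 6,000 tiles subsampled from the dense
extraction; hidden sizes 48/24; batch 32 with a cosine schedule from 3e−3;
40 epochs (50 for the cheapest, one-directional model). At these sizes the
qualitative results of the full-scale method reproduce: reconstruction RMSE
orders MFTLSTM ≤ BFTLSTM ≤ FTLSTM < MVPF, the MFTLSTM validates below the
0.1 K injected noise, and every model degrades when extrapolating beyond its
training range. The absolute RMSE values are naturally higher than
publication-scale training would give.

**Chip range sweep** (`run_chip_sweep`): a serpentine-channel chip scene
(48×48 px, 4 passes, 7 px channel width) with fixed ambient walls at 293 K
and two vertical heater lines stepped over offsets chosen once
(+1, +5, +12, +25, +50 K), giving scene spans from ~1 K to ~50 K inside the
290–380 K regime — the multiphysics-simulation ground truth a real chip
would require is replaced by the finite-difference solver, which shares the
governing equation. Rendering
uses the filter-wheel bank (620 ± 5 dropped), masked to the channel;
calibration-from-probe mirrors the single-thermocouple protocol (quadratics
fitted only from the probe pixel across the series). A tile network
(hidden 64/32) is trained on mask-weighted tiles pooled across four noise
replicates of the series — fresh exposures of the same steady states, since
a single realization of five small images overfits — and evaluated on
further replicates with mask-aware RMSE per scene (per-scene squared errors
averaged over three evaluation exposures). This experiment trains without
dropout: head-feature dropout in a small regression network shrinks
predictions toward the target mean, which biases the coldest (smallest-span)
scenes upward by a few hundredths of a kelvin — comparable to the spacing
between the smallest spans' errors — while the replicate augmentation
already provides the regularization dropout would. Expected behaviour: RMSE
grows with scene span, and |error| rank-correlates positively with the L2
gradient-norm map (K/μm) — steep regions near the heater lines are where
reconstruction fails first. The error–gradient statistic is a Spearman
correlation (the association is monotone, not linear); a constant error map
is reported as "correlation undefined" rather than NaN.

## What the generator does and does not emulate

The synthetic data reproduce: heat-diffusion spatial statistics, the
temperature sensitivity of band intensities, 16-bit quantization, band
overlap, channel masking, single-point calibration, and pixelwise
temperature noise. They do **not** reproduce: real CdSe/ZnS spectral shapes
(tabulated spectra can be supplied via the photophysics API), shot/read
camera noise (an intensity-domain noise toggle exists but is off by default,
matching the stated pipeline of temperature-domain noise only), optical
blur/PSF, photobleaching, fluid flow, or 3-D heat conduction. Passing tests
therefore demonstrate the *mechanism* — recurrent spatial context denoises
pixelwise inversion — under the stated noise model, not performance on any
particular instrument.

## Numerical choices and degenerate inputs

* Quadratic inversion guards a numerically negative discriminant at machine
  precision by flooring it at zero; root selection picks the root nearest
  the validity interval; results clamp to the interval.
* Round-half-even everywhere quantization happens (rendering, binning).
* Degenerate sequences (all-identical pixels) are ordinary inputs; no
  special-casing.
* A globally constant calibration set is rejected (no scale); a constant
  single channel is flagged non-monotone but still fitted.
* `stitch` divides by the coverage count, which is asserted positive
  everywhere first.
* Weighted training guards empty-weight minibatches with an epsilon
  denominator.

## Configuration

Every experiment knob above is a field of `ExperimentSpec`, `ChipSweepSpec`,
`TrainConfig` or `NetConfig`; the CLI accepts the same keys from a YAML file.
An annotated example for `fluorotherm evaluate --config bench.yaml`:

```yaml
train_t_range: [298.0, 308.0]   # kelvin range of the training fields
test_t_range: [298.0, 312.0]    # wider range for the extrapolation scenes
image_shape: [32, 32]           # pixels per synthetic image
n_train_images: 40              # image-level split: train side
n_val_images: 8                 #                    validation side
noise_sigma_k: 0.1              # pixelwise temperature noise (K)
stride: 1                       # dense patch extraction
hidden1: 48                     # first LSTM layer width
hidden2: 24                     # second LSTM layer width
dropout: 0.2                    # head-feature dropout during training
epochs: 40
batch_size: 32
lr: 3.0e-3                      # cosine-annealed to 1e-4
lr_schedule: cosine
max_train_sequences: 12000      # subsampling caps for the dense extraction
max_train_tiles: 6000
```

and for `fluorotherm sweep --config chip.yaml`:

```yaml
heater_offsets_k: [1, 5, 12, 25, 50]  # heater temperature above 293 K ambient
shape: [48, 48]
n_passes: 4                     # serpentine runs
channel_width_px: 7
noise_sigma_k: 0.1
n_noise_reps: 4                 # training exposures per heater setting
n_eval_reps: 3                  # evaluation exposures averaged per scene
drop_channel: true              # use five of the six filter channels
hidden1: 64
hidden2: 32
dropout: 0.0                    # see the chip-sweep rationale above
epochs: 50
```

## Known limitations

* The sequence length/tile side is fixed at 5; other sizes would require
  retraining and minor plumbing.
* The numpy training loop is single-threaded and CPU-bound; publication-size
  hidden dimensions (1024/612) are supported but impractically slow to
  train here — the architecture is exercised at reduced hidden sizes.
* The chip surrogate's natural-convection boundary is a fixed-temperature
  wall; absolute gradient magnitudes near walls differ from a conjugate
  heat-transfer model.
* Predictions at the extreme ends of the training target distribution carry
  a small shrinkage bias (hundredths of a kelvin at these scales) that grows
  with any training-time output regularization; the chip sweep disables
  dropout for this reason, but the two smallest-span scenes' RMSEs remain
  within ~0.01 K of each other at desk-scale training budgets.
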