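# Methods

This note documents the models and procedures implemented in `chipstain`,
the assumptions behind them, the parameters that matter, and what the
synthetic benchmark does and does not establish.

## The assay being modelled

Tumour cells are embedded in a hydrogel inside the ~500 µm-wide gel channel
of a microfluidic organ chip, cultured for several days, dosed with a drug
for 48 h, and imaged: bright-field (BF) for label-free morphology, a DAPI
band for a Hoechst all-nuclei stain and a TRITC band for an ethidium
dead-cell stain. Chip-level viability metrics are computed from the two
stain masks, ranked for assay quality across control chips with the
Z'-factor, and summarized as 4PL dose-response curves. An in-silico
staining model trained on endpoint (BF, stain) pairs then replaces physical
staining at earlier timepoints, enabling baseline-subtracted longitudinal
readouts.

## Synthetic data generator (`simulate`)

No public raw data exists for this assay, so the package ships a forward
model with complete ground truth.

**Population model.** A chip seeds `seeding_density` cells (default 300;
the emulated devices are seeded with 300–5000 cells per chip) placed
uniformly in the channel ROI. Per-cell radii are lognormal around
`base_radius_px` = 4 px (≈7 µm at 1.7 µm/px, a 4x objective scale) with
CV 0.25. Radii grow by `growth_rate` = 1.12 per day — a deliberate,
exactly multiplicative growth law (mean radius ratio between days is
`growth_rate^Δday` by construction), giving ≈2.5× radius and ≈6× area over
8 days, consistent with visible aggregate growth over a week of culture.
Each day a growing fraction (`aggregate_fraction_per_day` = 0.06/day,
capped at 0.8) of cells is recruited into clusters packed sunflower-style
around anchor cells, emulating aggregate formation; only formation and
growth are modelled, not fusion/fission or migration. A fixed 2% of cells
is dead at baseline regardless of treatment.

**Drug action.** Expected viability follows a 4PL curve
`v(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill)` with defaults
bottom 0.05, top 1.0, IC50 1 µM, hill 1.5 (dose range 0.01–100 µM, vehicle
dose 0). Each live cell dies independently with probability `1 − v(d)`, so
the realized live fraction is binomial around `v(d)` and deaths only
accumulate. In multi-day datasets the drug acts between day 6 and the
day-8 endpoint (dose after a baseline culture period, endpoint 48 h later).

**Rendering.** Cells are rendered in 2D (the analysis surface is a
Z-projection; Z-stacks are simulated only as shifted-blur slices for
projection tests):

- *Fluorescence*: soft-edged disks (logistic edge, 0.35 px) at each cell,
  DAPI for all cells, TRITC only for dead cells plus a faint broad halo of
  leaked stain. The steep edge keeps the Otsu-thresholded mask area within
  a few percent of the true disk area; the TRITC halo provides the real
  mid-intensity class that 3-class thresholding separates from background
  and positive signal.
- *Bright-field*: a deterministic function of the cell layout — dark
  membrane rims, interior shading that differs between live (brighter) and
  dead (darker) cells, a per-cell "optical density" that darkens the BF
  interior and proportionally brightens that cell's stains, and mild
  deterministic texture. This guarantees the BF→fluorescence mapping is
  well-posed and learnable while remaining far from pixel-identical to the
  stains.
- *Artifacts*: a smooth multiplicative uneven-staining field (sum of three
  random low-frequency cosines, amplitude `stain_unevenness_amplitude`)
  multiplies the fluorescence channels only — BF is unaffected, exactly as
  a staining artifact behaves; Gaussian detector noise (`noise_sd`, DN) is
  added last to every channel; output is quantized to 8/16-bit.

All randomness derives from `(seed, chip_id, day, purpose)` streams, so a
fixed config is byte-reproducible and changing one artifact (e.g. the
unevenness amplitude) leaves every other channel's draw untouched.

**What the generator does not emulate:** real BF contrast physics
(defocus, phase effects), staining chemistry variation beyond the smooth
multiplicative field, cell migration, 3D structure, debris and
out-of-focus artifacts. Passing the benchmark therefore shows the
*pipeline* is correct and the *method* works on well-posed image pairs; it
does not certify performance on real microscope data.

## Pre-analytical processing (`imagecore`)

"2D projection" is maximum-intensity projection (mean projection is an
option). Stitching assumes a horizontal row of equal tiles with fixed
fractional overlap and blends the overlap with a linear ramp (exact on
constants; reconstructs crops of a single source exactly). Background
subtraction is a grayscale opening with a disk (default radius 50 px —
large relative to cells, so structures survive and smooth offsets map to
zero); smoothing is Gaussian, reflective boundary, default σ = 1 px.
Vendor-specific steps from the emulated acquisition software ("digital
phase contrast", "kinetic frame registration") have no published
algorithms; an optional plain percentile contrast normalization is the
only stand-in, off by default.

## Segmentation and viability (`segment`)

Foregrounds come from Otsu thresholds on 256-bin histograms: 2-class for
DAPI, 3-class for TRITC with the **top** class counted positive (dead-cell
signal is the brightest population; the middle class absorbs haze). The
2-class implementation resolves objective ties (empty histogram gaps) to
the plateau midpoint, so two well-separated modes threshold strictly
between them. Objects are 8-connected components (connectivity is a
choice; nothing hinges on it at these densities) with components below
`min_area_px` = 20 removed as artifacts; objects with area ≥ 200 px count
as aggregates (ties inclusive). Both cutoffs are exposed in the config.
Viability arithmetic is integer-exact on masks:
`viable = |DAPI| − |TRITC ∩ DAPI|`, `viability% = 100·viable/|DAPI|`, and
dead pixels outside the DAPI mask never count. A chip with an empty DAPI
mask yields flagged, undefined metrics rather than silent NaNs.

## Assay statistics (`assaystats`)

Z'-factor: `1 − 3(σ₊+σ₋)/|μ₊−μ₋|`, undefined at zero dynamic range
(raised as an error), computed per metric over labelled control chips and
sorted descending with alphabetical tie-break.

4PL fitting uses log₁₀-dose with the sign convention hill > 0 ⇒ falling
viability, bounds bottom ≥ 0, top ≤ 120 (% of vehicle), and multi-start
least squares (3 hill × 4 log-IC50 starts) via `scipy.optimize.curve_fit`.
The vehicle (dose 0) anchors normalization to 100% but is excluded from
the log-dose fit. A fit is **converged** only if the optimizer succeeded
and the fitted dynamic range (top − bottom) is at least 5 percentage
points — below that the response is indistinguishable from flat and the
IC50 is reported "n.d." rather than a meaningless number. Standard errors
come from the curve_fit covariance. AUC is the trapezoidal integral of the
normalized response over log₁₀-dose divided by the log-dose span, making a
flat 100% curve score 100 and complete inhibition 0, comparable across
drugs with different dose ranges.

## In-silico staining (`staining` + `_nn`)

One model per fluorescence channel; the DAPI and TRITC artifacts are fully
independent. The network is a compact U-net-style encoder-decoder written
directly in NumPy (shift-and-GEMM convolutions with hand-written backward
passes): double 3×3 conv + ReLU blocks, 2×2 average pooling, nearest-
neighbour upsampling with skip concatenation, and a 1×1 linear head;
default base width 16 filters and 2 pooling levels (configurable; at
desk-scale image sizes, extra depth costs optimizer steps without a
measurable accuracy gain).
Inputs are z-scored per dataset (BF statistics from the training split);
targets are scaled to [0, 1] by the bit-depth maximum. Training minimizes
MSE with Adam, batch size 8, on overlapping patches whose union covers
every pixel (border-anchored grid); the weights with the best validation
loss across epochs are retained, and an optional early-stopping mode
(patience 15) exists alongside the default fixed-epoch mode. The learning
rate is constant by default with an optional cosine decay (to 1/20 of the
initial rate) for short desk-scale runs. Initial weights (He-scaled) and
data order derive from the run seed, so training and inference are
deterministic on one platform. Inference runs patch-wise with overlap
blending (equal-weight averaging by default, linear-ramp feathering as an
option), pads internally to the pooling divisor, and clips to the declared
bit depth; an optional deterministic test-time ensemble averages
predictions over the four axis flips of the input, damping
orientation-dependent errors at object edges.

Evaluation: SSIM (standard 11×11 Gaussian window, σ 1.5) and PSNR
(`10·log₁₀(MAX²/MSE)`, MAX from the bit depth, capped at 100 dB for exact
matches) per image pair, and — the biologically relevant level — Pearson
correlations across test chips of chip-level sum intensity and sum area
extracted from predicted vs. true stains through the standard
post-processing. Correlations are computed across chips, not patches, to
match how the features are used downstream.

## Longitudinal analysis (`longitudinal`)

Predictions (or true stains) are post-processed identically: Gaussian
smoothing → Otsu mask (2-class DAPI / 3-class TRITC top class) → removal
of components < 20 px. "Artifact removal" is small-component removal
only; border-touching objects are retained because chip ROIs are crops and
real objects commonly touch the edge. Live features are exact set
arithmetic: `live_area = |DAPI mask| − |TRITC mask ∩ DAPI mask|`, with
intensities measured on the DAPI image inside the live mask. The
endpoint-trained models are applied unchanged to earlier-day BF images (no
per-day fine-tuning). The baseline change is day 8 − day 6 per chip, which
cancels additive per-chip offsets exactly.

Three readout strategies are compared on the same chips: endpoint live
area alone, Δ(total DAPI area), and Δ(live area). Each is normalized to
vehicle, fitted with the 4PL model, and summarized by a **sensitivity**
statistic defined here as the dynamic range in vehicle-SD units
(vehicle mean − top-dose mean, divided by the vehicle SD). The claim that
Δlive is the most sensitive readout is tested on simulations constructed
to match its mechanism (drug acting only in the treatment window on top of
strong chip-to-chip seeding variability); the statistic itself is this
package's choice, since "sensitivity" admits several definitions.

## Benchmark problem sizes

The acceptance benchmark (`scripts/acceptance.py`,
`chipstain.benchmarks`) runs entirely on one CPU, with sizes chosen so a
full from-scratch run (simulation, two model trainings, evaluation) takes
roughly 15 minutes:

- 60 chips of 128×96 px at 48 cells per chip (≈ the area density of a
  well-seeded chip), doses cycled over {0, 0.01, 0.1, 1, 10, 100} µM,
  day-8 endpoint, mild detector noise (SD 300 DN at 16 bit). The
  uneven-staining pathology is off in this benchmark: the pixel-level
  quality floors presume clean staining — uneven staining is precisely the
  artifact that degrades SSIM/PSNR on real data — while the artifact
  itself is exercised by the simulator tests and the pipeline demo;
- 7:2:1 chip-level train/validation/test split;
- per-channel training: 30 epochs, batch 8, MSE, Adam at 2×10⁻³ with
  cosine decay, base 16 filters, depth 2, 48-px patches at stride 32,
  linear-ramp blending and flip-ensembled inference. The learning rate
  scales the production recipe (10⁻⁴ over 150 epochs × ~500 images) to
  the desk-scale step count so the total optimizer movement is
  comparable; epochs, batch size, loss and optimizer follow the recipe
  unchanged.

Dose-response recovery runs 50 independent simulated assays (5 doses ×
4 replicate chips, 5% response noise) in a few seconds. The demo pipeline
(12 chips × 5 days, tiny 3-epoch models) exists to prove end-to-end
reproducibility — identical checksums at a fixed seed — not prediction
quality.

## Numerical choices and degenerate inputs

- Otsu on a constant (or near-constant) image raises a degenerate-
  histogram error; pipeline post-processing converts it to a flagged
  zero-feature record (a blank TRITC chip is data, not a crash).
- `stitch_tiles` requires overlap fraction in [0, 0.5); `max_project`
  requires uniform slice shapes; background-subtraction radius must be
  positive; σ = 0 smoothing is the identity.
- Aggregate/single-cell ties (area exactly at the cutoff) count as
  aggregates.
- Pearson correlation on a zero-variance readout raises instead of
  returning NaN.
- 4PL fits never raise on poor data; they return non-converged results
  with IC50 "n.d.".
- Float32 is used throughout the network; gradients were verified against
  finite differences and convolutions against an independent
  `scipy.signal.correlate2d` oracle.

## Known limitations

- The translation benchmark is synthetic; transfer to real microscopes is
  out of scope (no real data ships with the package).
- The NumPy network is single-threaded BLAS-bound; it is sized for
  ~100-chip desk experiments, not for the image volumes a GPU framework
  would handle.
- The 60-metric feature catalogue of a commercial analysis suite is not
  reproduced exactly; the object table ships a documented superset basis
  (area, intensity sums/means, eccentricity, solidity, perimeter) without
  claiming one-to-one correspondence.
- Tracking individual cells across days, 3D segmentation, and
  machine-learned segmentation are out of scope.
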