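# Methods

## Scope and data model

The package implements a complete patch-based tumor-classification
pipeline for hyperspectral (HS) microscopy of H&E slides. All arrays
follow one axis convention — `lines × samples × bands` (0-based), the
natural order of a push-broom scan — fixed in `hsipath.io` and consumed
unchanged everywhere else. Cubes carry a processing-stage tag
(`radiance` → `transmittance` → `reduced`) and operations check the
stage they require, so a cube cannot silently skip flat-field
correction or be band-reduced twice.

Labels are *weak*: one class per cube, inherited by every patch. This
mirrors how such datasets are annotated (region-level pathologist
marks) and is why the classifier is patch-based rather than
fully-convolutional per-pixel.

On-disk format is an ENVI-style text header plus raw raster (BIL
interleave by default, BSQ/BIP accepted on read). The reader/writer is
deliberately minimal and self-contained; round-trips are bit-exact,
wavelengths are serialized at full precision.

## Synthetic slides

The generator's job is to produce data with exactly the statistical
structure the pipeline exploits, not photorealistic histology.

* **Stain optics.** Beer–Lambert: `T(λ) = exp(−Σ_s c_s A_s(λ))` with
  two Gaussian absorbance lobes per stain. Defaults put the
  hematoxylin-like peak at 590 nm and the eosin-like peak at 525 nm so
  nucleus and background spectra differ visibly in 400–700 nm and both
  are flat and bright in the near-infrared tail. These are tunable
  configuration, not asserted stain chemistry.
* **Geometry.** Nuclei are filled ellipses from a seeded uniform point
  process with radius jitter. Class defaults: tumor 40 nuclei per
  100×100 px with radius sd 3.0 px; non-tumor 12 per 100×100 px with
  sd 1.5 px (nuclear density and pleomorphism are the discriminating
  spatial properties). At the 87 px patch size this yields ≈ 30 vs ≈ 9
  expected nuclei per patch — a strong but overlapping signal.
  *Caveat discovered during testing:* if the patch side is scaled down
  (e.g. 21 px in unit tests) the per-patch nucleus count drops to ~2
  and Poisson fluctuations cap the achievable patch AUC near 0.8;
  scaled test fixtures therefore scale the nuclear geometry too.
* **Illumination and noise.** A smooth halogen-like lamp curve
  (rising into the NIR), jittered ±20 % per slide and shared with that
  slide's blank reference; additive white Gaussian noise on radiance
  (`noise_sd`, default 0.01 against a lamp peak of ~1), clipped at 0.
* **Patients.** Per-patient multiplicative stain factors, lognormal
  with σ = 0.2, drawn once per patient — so between-patient spectral
  variance dominates within-patient variance, which the fold design is
  meant to respect.
* **Blank regions** are smooth random blobs occupying a target
  fraction of pixels (default 0.15), carrying illumination only.
* **Determinism.** All randomness flows from integer seeds through
  `numpy.random.SeedSequence([seed, …])` splitting; cohorts regenerate
  bit-identically, file by file.

What the generator does **not** emulate: chromatic aberration and
defocus, scattering, stain co-localization, nuclear texture, tissue
architecture (vessels, necrosis), or realistic class imbalance at the
patch level. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that the classifier can exploit
density/spectral signals across patients — not that it would reach any
particular accuracy on clinical slides.

## Preprocessing choices

* **Flat field.** The blank reference is averaged over its scan lines
  to one spectrum per sensor sample before division — the standard
  reading for push-broom geometry, where each sample column has its own
  fixed-pattern response; averaging also suppresses reference noise.
  Transmittance is clamped to [0, 1] (noise can push the ratio above 1,
  which would break downstream invariants).
* **Band reduction.** 826 = 3·275 + 1; consecutive groups of three are
  averaged and the lone final band dropped (`drop_last`, recorded in
  the plan; `fold_into_last` is available). Output wavelengths are
  group means. On white noise the per-band variance falls by the group
  size — asserted in tests.
* **RGB synthesis** uses fixed piecewise-Gaussian analytic fits of the
  human-eye color-matching functions, resampled to the cube's
  wavelength grid and normalized per channel so an all-ones spectrum
  maps to white. RGB is synthesized from the transmittance cube
  (before/after reduction both work — the reduced grid still spans the
  visible range).

## Patch rejection

The hue channel of the 8-bit RGB rendering is thresholded: blank light
renders as neutral white (hue 0 after quantization) while H&E tissue
sits in the pink/purple range (hue ≈ 0.7–0.9 on synthetic slides). The
default threshold 0.35 is the midpoint between the blank mode and the
lower edge of the tissue mode, configured empirically on synthetic
data and exposed in `RejectionRule`. A patch is rejected when its light
fraction *exceeds* 0.5 — exactly half light is retained. Decisions are
local to the patch footprint, so tiling is order-independent and
translation-consistent.

## Fold design

Constraints implemented: every patient tests exactly once; test sizes
differ by at most one (13 patients → 3/3/3/4, oversized folds last);
one validation patient per fold, chosen from both-class patients
outside the test set; every test set contains at least one both-class
patient. Assignment is randomized under a seed with rejection sampling
over the constraint predicate; an optional `size_aware` policy
additionally forces the smallest tumor-only patients into the oversized
fold's test set and keeps the largest patient in its training set.
Default is pure constrained randomization.

## Classifier

Architecture as described in the README. Numerical/engineering notes:

* Convolutions are "valid" 3×3, computed as nine shifted-slice
  accumulations, each one a large BLAS matmul over a contiguous scratch
  buffer — measured ~2.5× faster than per-sample im2col at these
  shapes. The first layer skips its (unused) input gradient.
* This architecture is sometimes tabulated with a 73 × 73 pooling
  input and a 25 × 25 pool "kernel"; that arithmetic is inconsistent
  with eight unpadded 3×3 convolutions on an 87 px input
  (87 − 2·8 = 71). This implementation applies the eight convolutions
  literally and pools globally over the resulting 71 × 71 map; the
  layer table exposes the consistent successive-input sides
  (87, 85, …, 73) and a 71 × 71 pool input.
* Dropout (rate 0.10) follows every convolution and the first dense
  layer, disabled at inference; He initialization; float32 throughout.
* Optimizer: SGD with learning rate 10⁻³ and momentum 0.9 (momentum,
  batch size 16–32, epoch budget and model selection are this
  package's choices, recorded in `TrainConfig`). The returned model is
  the epoch with the best validation ROC-AUC — early-stopping-by-
  selection, so extra epochs never degrade the selected model.
* Determinism: weights, shuffling and dropout masks all derive from
  the config seed; two runs with the same seed produce identical
  losses.
* Class balancing duplicates each minority-class training patch once,
  rotated 180° (90°/270° available); rotation is a pixel permutation,
  so patch statistics are preserved exactly. The minority class is
  detected from the data rather than hard-coded.

## Desk-scale experiment

`ExperimentConfig` fixes the synthetic study conditions: 10 patients
(4 tumor-only), one cube per ROI, cubes 261 × 348 × 826 (3 × 4 patch
grid) reduced to 275 bands, blank fraction 0.15, noise sd 0.005, width
scale 0.0625 (widths 16…64, full depth), batch 16, ≤ 8 epochs with
best-validation selection. These sizes keep a full run — cohort
generation through evaluation — in the tens of minutes on one CPU while
preserving the real architecture depth, the 87 px patch size and the
full spectral chain. The evaluation fold is the last (oversized) one,
whose three test patients give the largest held-out patch count.
The label-shuffled control permutes training and validation labels and
trains briefly (2 epochs); its held-out AUC should land in the chance
band, confirming the pipeline cannot leak labels through any side
channel.

## Evaluation conventions

Tumor is the positive class. Decision threshold 0.5, ties predicted
positive. Metrics with empty denominators propagate as `N.A.` (NaN)
rather than raising; aggregates are unweighted means over defined
per-patient entries with sample sd (single entry → sd 0). Display
rounding is half-away-from-zero, applied last; machine-readable outputs
keep full precision. A reference worked example
(`hsipath.worked_example`) — a 13-patient cohort with five tumor-only
patients, before and after defective-image exclusion — pins down these
aggregation semantics in tests.

## Known limitations

* The NumPy CNN is CPU-bound; full-scale (scale = 1.0) training is out
  of reach here by design — the full-scale model is built and
  shape-checked but trained only at reduced widths.
* The hue-threshold default is calibrated on the synthetic stain
  model; real slides would need the threshold re-examined.
* The generator's spectra are qualitative stand-ins; no claim of
  radiometric realism.
* Heat-map edge margins replicate the nearest covered pixel for
  rendering; the probability grid itself never extrapolates.

## Addendum: the label-shuffled control

Shuffling only the *training* labels does not produce a chance-level
held-out AUC for an under-trained CNN: the scores still rank patches by
the initialization's projection of their features (which genuinely
separate the classes), AUC is invariant under monotone transforms, and
so the magnitude stays extreme with a random sign. The implemented
control is therefore a full permutation null — the labels of training,
validation and evaluation patches are all permuted, and the model's
scores are scored against the permuted labels, pooled over every
held-out patient. Under this null the AUC is centred at 0.5 with the
Mann–Whitney standard error for the held-out patch count.

Relatedly, the desk-scale model's *probabilities* are under-calibrated:
after a few epochs they cluster just below 0.5, so threshold-based
metrics (accuracy, sensitivity at 0.5) can look degenerate even when
the ranking is nearly perfect (AUC ≈ 0.96). AUC is the reliable
desk-scale metric; threshold metrics become meaningful only with longer
training.
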