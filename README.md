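# hsipath

Patch-based CNN classification of hyperspectral microscopy images of
H&E-stained brain tissue: discriminating glioblastoma (GB) from
non-tumor tissue, with a synthetic-slide simulator so the entire
pipeline can be exercised and validated without clinical data.

## The problem

A push-broom hyperspectral (HS) microscope images stained pathology
slides over 400–1000 nm, producing cubes of 800 lines × 1004 samples ×
826 spectral bands. Ground truth is weak: a pathologist labels whole
regions of interest, so every cube — not every pixel — carries a single
`tumor` / `non_tumor` label. The classification strategy is therefore
patch-based:

1. **Flat-field correction** — each radiance cube is divided by the
   line-averaged spectrum of a blank-area reference cube, giving
   normalized transmittance `T = I / I_blank ∈ [0, 1]`.
2. **Band reduction** — neighbouring bands are highly correlated;
   averaging groups of 3 maps 826 → 275 bands and attenuates white
   sensor noise (variance ÷ 3).
3. **Patching** — the cube is tiled into non-overlapping 87 × 87
   patches (99 per full cube). Patches that are *more than 50 %*
   background light are rejected; light pixels are found by binarizing
   the hue channel of the synthesized RGB rendering.
4. **Patient-disjoint cross-validation** — patients are split into 4
   folds (for 13 patients: three folds with 3 test patients, one with
   4); each patient is tested exactly once, each fold holds out a
   single both-class validation patient, and train/validation/test
   never share a patient.
5. **CNN** — eight unpadded 3×3 convolutions (widths
   256, 256, 512, 512, 1024, 1024, 1024, 1024) with ReLU and 10 %
   dropout, global average pooling, a 256-unit dense layer, and a
   2-class softmax, trained with SGD at learning rate 10⁻³. The
   minority class is balanced by appending one spatially rotated copy
   of each of its training patches. A `scale` factor shrinks channel
   widths for CPU-scale runs. The network is implemented directly in
   NumPy (BLAS-backed shifted-slice convolutions with full backprop).
6. **Evaluation** — per-patient sensitivity `TP/(TP+FN)`, specificity
   `TN/(TN+FP)`, accuracy `(TP+TN)/total`, and ROC-AUC (Mann–Whitney,
   ties ½). Patients with only tumor patches get `N.A.` specificity and
   AUC; aggregate rows are unweighted means over the defined entries.
   Manifest exclusion flags (ink, unfocused, artifact, blood, necrosis)
   remove cubes from the *test* evaluation only — never retraining.
7. **Heat maps** — an 87 px window slides at a 23 px stride
   (32 × 40 = 1280 windows on a full cube); per-pixel tumor probability
   is the mean over covering windows.

The synthetic generator (`hsipath.synth`) emulates the data this
pipeline assumes: Beer–Lambert stain optics with hematoxylin-like
(~590 nm) and eosin-like (~525 nm) absorbance bands, nuclei from a
seeded elliptical point process (tumor = denser, more pleomorphic),
blank-light regions, per-patient stain factors, halogen-like
illumination, Gaussian sensor noise, and a paired blank reference cube.

## Worked example

```python
import hsipath as hp

# one synthetic tumor slide + blank reference
spec = hp.SceneSpec(lines=261, samples=348, bands=826, label="tumor", seed=7)
cube, reference, nucleus_mask = hp.generate_slide(spec)

trans = hp.flat_field_correct(cube, reference)   # radiance -> transmittance
reduced = hp.reduce_bands(trans)                 # 826 -> 275 bands
patches = hp.extract_patches(reduced)            # 87x87 tiles, light-filtered
print(reduced.bands, len(patches), patches.n_rejected)
```

prints

```
275 11 1
```

— the cube reduces to 275 bands and tiles into a 3 × 4 grid of twelve
87 px patches, one of which falls in a blank-light area and is rejected.
The full cross-validated experiment is one call:

```python
result = hp.run_synthetic_experiment(seed=1, fold_index=3)
print(result.summary())
```

which generates a 10-patient cohort (four tumor-only), trains the
desk-scale CNN (`scale=0.0625`) on one fold and reports per-patient test
metrics plus the pooled held-out AUC.

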