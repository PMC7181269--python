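"""Synthetic H&E-like hyperspectral slide generator.

Emulates the statistical structure the patch classifier relies on:

* three spectral populations — stained cell nuclei (hematoxylin-dominant),
  background tissue (eosin-dominant) and blank illumination — with
  distinct transmittance signatures under a Beer-Lambert stain model;
* two tissue classes that differ in nuclear density and in nuclear
  morphology variance (a pleomorphism proxy for the tumor class);
* per-patient multiplicative stain-concentration factors (staining
  variability between slides of different patients);
* additive white Gaussian sensor noise on the radiance, and a paired
  blank-field reference cube sharing the slide's illumination.

Everything is driven by integer seeds through ``numpy.random.SeedSequence``
so cohorts regenerate bit-identically, piecewise.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import io as hio
from .errors import ValidationError
from .io import HSCube, Label, Manifest, Stage

__all__ = [
    "AbsorbanceBand",
    "StainModel",
    "SceneSpec",
    "default_stain_model",
    "halogen_illumination",
    "stain_transmittance",
    "generate_slide",
    "generate_cohort",
]

STAINS = ("hematoxylin", "eosin")


@dataclass(frozen=True)
class AbsorbanceBand:
    """One Gaussian absorbance band: peak position, width (sd) and amplitude."""

    peak_nm: float
    width_nm: float
    amplitude: float


@dataclass(frozen=True)
class StainModel:
    """Beer-Lambert stain optics: absorbance bands per stain + illumination.

    Defaults place the hematoxylin-like absorbance around 590 nm and the
    eosin-like absorbance around 525 nm, so nucleus and background spectra
    are visibly distinct across 400-700 nm and both are flat and bright in
    the 700-1000 nm near-infrared tail.  These are tunable configuration,
    not asserted stain chemistry.
    """

    hematoxylin: tuple[AbsorbanceBand, ...] = (
        AbsorbanceBand(590.0, 70.0, 1.10),
        AbsorbanceBand(445.0, 55.0, 0.25),
    )
    eosin: tuple[AbsorbanceBand, ...] = (
        AbsorbanceBand(525.0, 40.0, 0.90),
        AbsorbanceBand(560.0, 55.0, 0.30),
    )

    def absorbance(self, stain: str, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Total absorbance curve of ``stain`` on the given wavelength grid."""
        bands = getattr(self, stain)
        wl = np.asarray(wavelengths_nm, dtype=float)
        out = np.zeros_like(wl)
        for b in bands:
            if b.amplitude < 0:
                raise ValidationError("absorbance amplitudes must be >= 0")
            out += b.amplitude * np.exp(-0.5 * ((wl - b.peak_nm) / b.width_nm) ** 2)
        return out


def default_stain_model() -> StainModel:
    return StainModel()


def halogen_illumination(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Smooth positive halogen-like lamp spectrum, rising into the NIR."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return 0.25 + 0.75 * np.exp(-(((wl - 850.0) / 350.0) ** 2))


def stain_transmittance(wavelengths_nm, concentrations, model: StainModel | None = None):
    """Beer-Lambert transmittance ``exp(-sum_s c_s A_s(lambda))`` in (0, 1].

    ``concentrations`` maps stain name -> non-negative scalar (or is a
    sequence ordered as :data:`STAINS`).  Strictly decreasing in each
    concentration wherever that stain absorbs.
    """
    model = model or default_stain_model()
    if not isinstance(concentrations, dict):
        concentrations = dict(zip(STAINS, concentrations))
    wl = np.asarray(wavelengths_nm, dtype=float)
    absorbance = np.zeros_like(wl)
    for stain, conc in concentrations.items():
        if conc < 0:
            raise ValidationError(f"negative concentration for {stain!r}: {conc}")
        absorbance += conc * model.absorbance(stain, wl)
    return np.exp(-absorbance)


# ---------------------------------------------------------------------------
# Scene specification and slide synthesis
# ---------------------------------------------------------------------------

#: Default nuclei per 100x100 px; the tumor class is denser — nuclear
#: density is the spatial property that separates the classes.
TUMOR_DENSITY = 40.0
NON_TUMOR_DENSITY = 12.0


@dataclass
class SceneSpec:
    """Everything needed to synthesize one slide deterministically."""

    lines: int = hio.NOMINAL_LINES
    samples: int = hio.NOMINAL_SAMPLES
    bands: int = hio.NOMINAL_BANDS
    label: Label = Label.TUMOR
    nuclear_density: float | None = None  # nuclei per 100x100 px; None -> class default
    nucleus_radius_mean: float = 6.0
    nucleus_radius_sd: float | None = None  # None -> 1.5 non-tumor, 3.0 tumor
    blank_fraction: float = 0.15
    patient_effects: dict = field(
        default_factory=lambda: {"hematoxylin": 1.0, "eosin": 1.0}
    )
    noise_sd: float = 0.01  # additive Gaussian sd, radiance units (lamp peak ~ 1)
    seed: int = 0
    reference_lines: int = 64
    dtype: type = np.float32

    def __post_init__(self) -> None:
        self.label = Label(self.label)
        if self.label is Label.UNKNOWN:
            raise ValidationError("scene label must be tumor or non_tumor")
        if not (0.0 <= self.blank_fraction < 1.0):
            raise ValidationError("blank_fraction must lie in [0, 1)")
        if self.nuclear_density is None:
            self.nuclear_density = (
                TUMOR_DENSITY if self.label is Label.TUMOR else NON_TUMOR_DENSITY
            )
        if self.nucleus_radius_sd is None:
            self.nucleus_radius_sd = 3.0 if self.label is Label.TUMOR else 1.5


def _blank_mask(rng, lines, samples, fraction):
    if fraction <= 0:
        return np.zeros((lines, samples), dtype=bool)
    field_ = gaussian_filter(
        rng.standard_normal((lines, samples)), sigma=max(4.0, min(lines, samples) / 8.0)
    )
    thresh = np.quantile(field_, fraction)
    return field_ < thresh


def _rasterize_nuclei(rng, spec: SceneSpec):
    """Seeded elliptical point process; returns (mask, per-pixel conc jitter)."""
    lines, samples = spec.lines, spec.samples
    n = rng.poisson(spec.nuclear_density * lines * samples / 1e4)
    mask = np.zeros((lines, samples), dtype=bool)
    jitter = np.ones((lines, samples), dtype=np.float32)
    for _ in range(n):
        cy = rng.uniform(0, lines)
        cx = rng.uniform(0, samples)
        r = max(1.5, rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd))
        ecc = rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        stain_jit = np.float32(max(0.2, rng.normal(1.0, 0.15)))
        ry, rx = r, r * ecc
        half = int(np.ceil(r)) + 1
        y0, y1 = max(0, int(cy) - half), min(lines, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(samples, int(cx) + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        inside = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        mask[y0:y1, x0:x1] |= inside
        region = jitter[y0:y1, x0:x1]
        region[inside] = stain_jit
    return mask, jitter


# Baseline stain concentrations for the three pixel populations.
_NUCLEUS_H, _NUCLEUS_E = 1.6, 0.25
_TISSUE_H, _TISSUE_E = 0.12, 0.65


def generate_slide(spec: SceneSpec, model: StainModel | None = None):
    """Synthesize one slide: (radiance cube, blank reference cube, nucleus mask).

    Nuclei come from a seeded elliptical point process with radius jitter;
    nucleus pixels are hematoxylin-dominant, tissue background is
    eosin-dominant with a smooth concentration texture, blank regions carry
    the illumination spectrum only.  Radiance = illumination x transmittance
    + Gaussian noise, clipped at zero.  Identical seeds give bit-identical
    outputs.
    """
    model = model or default_stain_model()
    if spec.blank_fraction >= 0.5:
        warnings.warn(
            f"blank_fraction={spec.blank_fraction:g} >= 0.5: patches may all be "
            "rejected by the light rule",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed)]))
    wl = hio.nominal_wavelengths(spec.bands)
    dtype = np.dtype(spec.dtype)

    blank = _blank_mask(rng, spec.lines, spec.samples, spec.blank_fraction)
    nucleus, stain_jit = _rasterize_nuclei(rng, spec)
    nucleus &= ~blank

    texture = gaussian_filter(rng.standard_normal((spec.lines, spec.samples)), sigma=12.0)
    sd = texture.std()
    texture = 1.0 + (0.15 / sd) * texture if sd > 0 else np.ones_like(texture)

    f_h = float(spec.patient_effects.get("hematoxylin", 1.0))
    f_e = float(spec.patient_effects.get("eosin", 1.0))
    conc_h = np.where(nucleus, _NUCLEUS_H * stain_jit, _TISSUE_H).astype(dtype) * dtype.type(f_h)
    conc_e = np.where(nucleus, _NUCLEUS_E, _TISSUE_E * texture).astype(dtype) * dtype.type(f_e)
    conc_h[blank] = 0
    conc_e[blank] = 0

    abs_h = model.absorbance("hematoxylin", wl).astype(dtype)
    abs_e = model.absorbance("eosin", wl).astype(dtype)
    # absorbance volume built in place: conc_h x A_h + conc_e x A_e
    vol = np.multiply.outer(conc_h, abs_h)
    vol += np.multiply.outer(conc_e, abs_e)
    np.exp(-vol, out=vol)  # now transmittance in (0, 1]

    jitter = rng.uniform(0.8, 1.2)  # per-slide lamp intensity, shared with reference
    illum = (halogen_illumination(wl) * jitter).astype(dtype)
    vol *= illum  # now radiance
    if spec.noise_sd > 0:
        vol += spec.noise_sd * rng.standard_normal(vol.shape, dtype=np.float32).astype(
            dtype, copy=False
        )
        np.clip(vol, 0, None, out=vol)

    ref = np.broadcast_to(illum, (spec.reference_lines, spec.samples, spec.bands)).copy()
    if spec.noise_sd > 0:
        ref += spec.noise_sd * rng.standard_normal(ref.shape, dtype=np.float32).astype(
            dtype, copy=False
        )
        np.clip(ref, 0, None, out=ref)

    cube = HSCube(data=vol, wavelengths_nm=wl, stage=Stage.RADIANCE, label=spec.label)
    reference = HSCube(data=ref, wavelengths_nm=wl, stage=Stage.RADIANCE)
    return cube, reference, nucleus


def scene_transmittance(spec: SceneSpec, model: StainModel | None = None) -> np.ndarray:
    """The noise-free transmittance volume of a scene (pipeline oracle).

    Regenerates the same scene geometry as :func:`generate_slide` for the
    same seed and returns illumination-free transmittance; with
    ``noise_sd=0`` flat-field correction of the generated slide must
    recover exactly this volume.
    """
    noiseless = SceneSpec(**{**spec.__dict__, "noise_sd": 0.0})
    cube, reference, _ = generate_slide(noiseless, model)
    profile = reference.data.mean(axis=0)
    return cube.data / profile[None, :, :]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _child_seed(*key: int) -> int:
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] % (2**31))


def generate_cohort(
    n_patients: int,
    n_cubes_per_roi: int = 1,
    tumor_only_patients: int = 0,
    seed: int = 0,
    out_dir: str = ".",
    lines: int = hio.NOMINAL_LINES,
    samples: int = hio.NOMINAL_SAMPLES,
    bands: int = hio.NOMINAL_BANDS,
    blank_fraction: float = 0.15,
    noise_sd: float = 0.01,
    model: StainModel | None = None,
    write_masks: bool = True,
) -> Manifest:
    """Write a cohort of synthetic slides + references to disk; return its manifest.

    Mirrors the clinical dataset's shape: the last ``tumor_only_patients``
    patients contribute tumor ROIs only, the rest contribute one tumor and
    one non-tumor ROI each.  Per-patient stain factors are drawn once per
    patient (lognormal, sigma 0.2).  Deterministic per (seed, patient, roi,
    cube) so regeneration is reproducible piecewise.
    """
    if n_patients < 4:
        raise ValidationError("need at least 4 patients for a 4-fold patient-disjoint design")
    if tumor_only_patients > n_patients:
        raise ValidationError("tumor_only_patients cannot exceed n_patients")
    os.makedirs(out_dir, exist_ok=True)
    model = model or default_stain_model()

    rows = []
    for p_idx in range(n_patients):
        pid = f"P{p_idx + 1:02d}"
        p_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1000, p_idx]))
        effects = {
            "hematoxylin": float(np.exp(p_rng.normal(0.0, 0.2))),
            "eosin": float(np.exp(p_rng.normal(0.0, 0.2))),
        }
        tumor_only = p_idx >= n_patients - tumor_only_patients
        rois = [("R1", Label.TUMOR)] if tumor_only else [
            ("R1", Label.TUMOR), ("R2", Label.NON_TUMOR)
        ]
        pdir = os.path.join(out_dir, pid)
        os.makedirs(pdir, exist_ok=True)
        for r_idx, (rid, label) in enumerate(rois):
            for c_idx in range(n_cubes_per_roi):
                spec = SceneSpec(
                    lines=lines, samples=samples, bands=bands, label=label,
                    blank_fraction=blank_fraction, noise_sd=noise_sd,
                    patient_effects=effects,
                    seed=_child_seed(seed, p_idx, r_idx, c_idx),
                )
                cube, reference, mask = generate_slide(spec, model)
                cube.patient_id = pid
                cube.roi_id = rid
                reference.patient_id = pid
                reference.roi_id = rid
                stem = f"{rid}_C{c_idx}"
                cube_rel = os.path.join(pid, stem + ".hdr")
                ref_rel = os.path.join(pid, stem + "_ref.hdr")
                hio.write_cube(cube, os.path.join(out_dir, cube_rel))
                hio.write_cube(reference, os.path.join(out_dir, ref_rel))
                if write_masks:
                    import imageio.v3 as iio

                    iio.imwrite(
                        os.path.join(pdir, stem + "_mask.png"),
                        (mask * np.uint8(255)),
                    )
                rows.append(
                    {
                        "patient_id": pid,
                        "roi_id": rid,
                        "cube_path": cube_rel,
                        "reference_path": ref_rel,
                        "label": label.value,
                        "excluded": False,
                        "exclusion_reason": "none",
                    }
                )

    import pandas as pd

    manifest = Manifest(frame=pd.DataFrame(rows), root=out_dir)
    hio.save_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest
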