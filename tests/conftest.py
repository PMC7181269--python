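import numpy as np
import pandas as pd
import pytest

from hsipath.io import Label, Manifest
from hsipath.partition import balance_by_rotation
from hsipath.patching import PatchSet, RejectionRule, extract_patches
from hsipath.preprocess import BandReductionPlan, flat_field_correct, reduce_bands
from hsipath.synth import SceneSpec, generate_slide


def manifest_13_patients(cubes_both=(4, 6), cubes_tumor_only=3) -> Manifest:
    """In-memory manifest shaped like a 13-patient cohort, 5 tumor-only."""
    rows = []
    for i in range(13):
        pid = f"P{i + 1}"
        tumor_only = i >= 8
        n_t, n_nt = (cubes_tumor_only, 0) if tumor_only else cubes_both
        for label, count in ((Label.TUMOR, n_t), (Label.NON_TUMOR, n_nt)):
            for c in range(count):
                rows.append(
                    {
                        "patient_id": pid,
                        "roi_id": f"R_{label.value}",
                        "cube_path": f"{pid}/{label.value}_{c}.hdr",
                        "reference_path": f"{pid}/ref_{c}.hdr",
                        "label": label.value,
                        "excluded": False,
                        "exclusion_reason": "none",
                    }
                )
    return Manifest(frame=pd.DataFrame(rows))


def tiny_cohort_patches(
    n_patients=4,
    lines=63,
    samples=84,
    bands=36,
    patch=21,
    noise_sd=0.003,
    blank_fraction=0.0,
    seed=0,
):
    """Small slide-based patch sets: full generator -> flat-field -> reduce -> patch.

    Returns one pooled PatchSet whose patients are P1..Pn, each with one
    tumor and one non-tumor slide.  Nuclear geometry is scaled to the 21 px
    patch (smaller, denser nuclei) so each patch holds about as many nuclei
    as a full-size 87 px patch does at the default densities — otherwise
    per-patch nucleus-count noise caps the achievable patch-level AUC.
    """
    sets = []
    rule = RejectionRule()
    plan = BandReductionPlan(group_size=3)
    class_geometry = {
        Label.TUMOR: dict(nuclear_density=250.0, nucleus_radius_sd=1.2),
        Label.NON_TUMOR: dict(nuclear_density=70.0, nucleus_radius_sd=0.6),
    }
    for p in range(n_patients):
        factors = {
            "hematoxylin": float(np.exp(np.random.default_rng(100 + p).normal(0, 0.15))),
            "eosin": float(np.exp(np.random.default_rng(200 + p).normal(0, 0.15))),
        }
        for k, label in enumerate((Label.TUMOR, Label.NON_TUMOR)):
            spec = SceneSpec(
                lines=lines, samples=samples, bands=bands, label=label,
                nucleus_radius_mean=2.5, **class_geometry[label],
                blank_fraction=blank_fraction, noise_sd=noise_sd,
                patient_effects=factors, seed=seed * 1000 + p * 10 + k,
            )
            cube, ref, _ = generate_slide(spec)
            cube.patient_id = f"P{p + 1}"
            cube.roi_id = f"R{k}"
            reduced = reduce_bands(flat_field_correct(cube, ref), plan)
            sets.append(extract_patches(reduced, rule, patch=patch))
    return PatchSet.concatenate(sets)


@pytest.fixture(scope="session")
def tiny_patches():
    return tiny_cohort_patches()


@pytest.fixture(scope="session")
def tiny_trained(tiny_patches):
    """A small CNN fitted on the tiny synthetic cohort (patients P1-P3 train,
    P4 validation); reused by model and heat-map tests."""
    from hsipath.cnn import ModelSpec, PatchClassifier, TrainConfig

    train = balance_by_rotation(tiny_patches.for_patients(["P1", "P2", "P3"]))
    val = tiny_patches.for_patients(["P4"])
    spec = ModelSpec(input_side=train.side, input_bands=train.bands, scale=0.0625)
    model = PatchClassifier(spec, seed=0)
    results = model.fit(train, val, TrainConfig(epochs=20, batch_size=16, seed=0))
    return results
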