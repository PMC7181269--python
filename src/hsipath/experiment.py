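"""End-to-end synthetic experiment: cohort -> preprocessing -> folds -> CNN -> report.

This is the desk-scale rehearsal of the full pipeline: generate a
synthetic cohort, flat-field and band-reduce every cube, extract and
light-filter patches, build patient-disjoint folds, balance the training
classes by rotation, fit the patch CNN at a reduced width scale, and
evaluate on the held-out test patients.  The defaults here are the
package's fixed desk-scale study conditions (10 patients, four of them
tumor-only, 261 x 348 x 826 cubes reduced to 275 bands, width scale
0.0625); see docs/methods.md for the rationale.
"""

from __future__ import annotations

import os
import shutil
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as hio
from .cnn import DESK_SCALE, ModelSpec, PatchClassifier, TrainConfig
from .evaluate import MetricsReport, per_patient_report, roc_auc
from .io import Manifest
from .partition import FoldPlan, balance_by_rotation, make_folds
from .patching import PatchSet, RejectionRule, extract_patches
from .preprocess import BandReductionPlan, flat_field_correct, reduce_bands, synthesize_rgb
from .synth import generate_cohort

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "build_patchset",
    "prepare_cohort_patches",
    "run_fold",
    "run_synthetic_experiment",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Fixed desk-scale study conditions for the synthetic experiment."""

    n_patients: int = 10
    tumor_only_patients: int = 4
    n_cubes_per_roi: int = 1
    lines: int = 261
    samples: int = 348
    bands: int = 826
    blank_fraction: float = 0.15
    noise_sd: float = 0.005
    patch: int = 87
    scale: float = DESK_SCALE
    epochs: int = 8
    batch_size: int = 16
    learning_rate: float = 1e-3
    momentum: float = 0.9
    modality: str = "hsi"  # or "rgb"


def build_patchset(
    manifest: Manifest,
    rule: RejectionRule | None = None,
    patch: int = 87,
    plan: BandReductionPlan | None = None,
    modality: str = "hsi",
) -> tuple[PatchSet, np.ndarray]:
    """Read, flat-field, band-reduce and patch every cube of a manifest.

    Returns the pooled patch set plus a per-patch ``excluded`` mask taken
    from the manifest flags (applied downstream at evaluation time only).
    For the RGB baseline the same retained patch footprints carry the
    3-channel rendering instead of the reduced spectra.
    """
    rule = rule or RejectionRule()
    plan = plan or BandReductionPlan()
    sets: list[PatchSet] = []
    excluded_flags: list[np.ndarray] = []
    for idx, row in manifest.frame.iterrows():
        cube = hio.read_cube(manifest.resolve(str(row["cube_path"])))
        reference = hio.read_cube(manifest.resolve(str(row["reference_path"])))
        cube.patient_id = str(row["patient_id"])
        cube.roi_id = str(row["roi_id"])
        cube.label = hio.Label(row["label"])
        reduced = reduce_bands(flat_field_correct(cube, reference), plan)
        cube_id = f"{row['patient_id']}/{row['roi_id']}/{os.path.basename(str(row['cube_path']))}"
        ps = extract_patches(reduced, rule, patch=patch, cube_id=cube_id)
        if modality == "rgb":
            rgb = synthesize_rgb(reduced).astype(np.float32)
            ps.data = np.stack(
                [
                    rgb[r * patch : (r + 1) * patch, c * patch : (c + 1) * patch, :]
                    for r, c in zip(ps.grid_rows, ps.grid_cols)
                ]
            ) if len(ps) else np.empty((0, patch, patch, 3), dtype=np.float32)
        sets.append(ps)
        excluded_flags.append(np.full(len(ps), bool(row["excluded"])))
    pooled = PatchSet.concatenate(sets)
    return pooled, np.concatenate(excluded_flags)


@dataclass
class ExperimentResult:
    """Everything the desk-scale experiment measured on one fold."""

    fold_plan: FoldPlan
    fold_index: int
    config: ExperimentConfig
    seed: int
    shuffled: bool
    n_patches: dict
    fit_history: pd.DataFrame
    best_epoch: int
    best_val_auc: float
    test_auc: float
    report: MetricsReport
    results_obj: object = None

    def summary(self) -> str:
        fold = self.fold_plan.folds[self.fold_index]
        lines = [
            "Synthetic end-to-end experiment",
            "===============================",
            f"modality: {self.config.modality}   seed: {self.seed}"
            f"   labels shuffled: {self.shuffled}",
            f"fold {self.fold_index}: train={list(fold.train)}"
            f" val={list(fold.validation)} test={list(fold.test)}",
            f"patches: {self.n_patches}",
            f"best epoch {self.best_epoch} (validation AUC {self.best_val_auc:.3f})",
            f"held-out test AUC (pooled over test patients): {self.test_auc:.3f}",
            "",
            "Per-patient test report:",
            self.report.summary(),
        ]
        return "\n".join(lines)


def prepare_cohort_patches(
    seed: int,
    config: ExperimentConfig | None = None,
    work_dir: str | None = None,
    keep_files: bool = False,
) -> tuple[Manifest, PatchSet, np.ndarray]:
    """Generate the synthetic cohort and run it through preprocessing/patching."""
    cfg = config or ExperimentConfig()
    tmp = work_dir or tempfile.mkdtemp(prefix="hsipath_cohort_")
    try:
        manifest = generate_cohort(
            n_patients=cfg.n_patients,
            n_cubes_per_roi=cfg.n_cubes_per_roi,
            tumor_only_patients=cfg.tumor_only_patients,
            seed=seed,
            out_dir=tmp,
            lines=cfg.lines,
            samples=cfg.samples,
            bands=cfg.bands,
            blank_fraction=cfg.blank_fraction,
            noise_sd=cfg.noise_sd,
            write_masks=False,
        )
        patches, excluded = build_patchset(manifest, patch=cfg.patch, modality=cfg.modality)
    finally:
        if not keep_files and work_dir is None:
            shutil.rmtree(tmp, ignore_errors=True)
    return manifest, patches, excluded


def run_fold(
    manifest: Manifest,
    patches: PatchSet,
    excluded: np.ndarray,
    seed: int,
    config: ExperimentConfig | None = None,
    fold_index: int = 0,
    shuffle_labels: bool = False,
    epochs: int | None = None,
    verbose: bool = False,
) -> ExperimentResult:
    """Train and evaluate one fold on an already-built patch set."""
    cfg = config or ExperimentConfig()
    plan = make_folds(manifest, n_folds=4, seed=seed)
    fold = plan.folds[fold_index]

    def pick(patients):
        return patches.for_patients(patients)

    train_set = pick(fold.train)
    val_set = pick(fold.validation)
    test_set = pick(fold.test)
    test_excluded = excluded[np.isin(patches.patient_ids, list(fold.test))]

    if shuffle_labels:
        # Global label-permutation null: scramble the labels of every subset
        # (training, validation AND the labels the test AUC is scored
        # against).  Note an under-trained CNN's scores still rank patches
        # by their init-projected features, so shuffling only the training
        # labels does not drive the test AUC to chance; scoring against
        # permuted labels is the actual permutation null.
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 999]))
        train_set.labels = rng.permutation(train_set.labels)
        val_set.labels = rng.permutation(val_set.labels)
        test_set.labels = rng.permutation(test_set.labels)

    train_set = balance_by_rotation(train_set)
    spec = ModelSpec(
        input_side=cfg.patch,
        input_bands=train_set.bands,
        scale=cfg.scale,
    )
    model = PatchClassifier(spec, seed=seed)
    fit = model.fit(
        train_set,
        val_set,
        TrainConfig(
            learning_rate=cfg.learning_rate,
            momentum=cfg.momentum,
            epochs=cfg.epochs if epochs is None else epochs,
            batch_size=cfg.batch_size,
            seed=seed,
        ),
        verbose=verbose,
    )

    scores = fit.predict_tumor_probability(test_set)
    keep = ~test_excluded
    if shuffle_labels:
        # pool every held-out patient (validation + test) for a stable null
        val_scores = fit.predict_tumor_probability(val_set)
        test_auc = roc_auc(
            np.concatenate([scores[keep], val_scores]),
            np.concatenate([test_set.labels[keep], val_set.labels]),
        )
    else:
        test_auc = roc_auc(scores[keep], test_set.labels[keep])
    report = per_patient_report(
        scores, test_set.labels, test_set.patient_ids, excluded=test_excluded
    )
    n_neg, n_pos = train_set.class_counts()
    return ExperimentResult(
        fold_plan=plan,
        fold_index=fold_index,
        config=cfg,
        seed=seed,
        shuffled=shuffle_labels,
        n_patches={
            "train_non_tumor": n_neg,
            "train_tumor": n_pos,
            "validation": len(val_set),
            "test": len(test_set),
            "rejected": patches.n_rejected,
            "tiled": patches.n_rejected + len(patches),
        },
        fit_history=fit.history,
        best_epoch=fit.best_epoch,
        best_val_auc=fit.best_val_auc,
        test_auc=float(test_auc),
        report=report,
        results_obj=fit,
    )


def run_synthetic_experiment(
    seed: int = 0,
    config: ExperimentConfig | None = None,
    fold_index: int = 0,
    shuffle_labels: bool = False,
    work_dir: str | None = None,
    keep_files: bool = False,
    epochs: int | None = None,
    verbose: bool = False,
) -> ExperimentResult:
    """Run the full pipeline on one fold of a fresh synthetic cohort."""
    manifest, patches, excluded = prepare_cohort_patches(
        seed, config, work_dir=work_dir, keep_files=keep_files
    )
    return run_fold(
        manifest, patches, excluded, seed, config,
        fold_index=fold_index, shuffle_labels=shuffle_labels,
        epochs=epochs, verbose=verbose,
    )
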