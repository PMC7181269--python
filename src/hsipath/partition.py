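"""Patient-disjoint cross-validation folds and rotation class balancing.

The fold design mirrors a 13-patient cohort where five patients carry
tumor tissue only: every patient appears in exactly one test set, each
fold holds out a single validation patient that has both classes, and
train/validation/test patients never overlap within a fold, so no patient
ever leaks between roles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleError, ValidationError
from .io import Manifest
from .patching import PatchSet

__all__ = ["Fold", "FoldPlan", "make_folds", "balance_by_rotation"]


@dataclass(frozen=True)
class Fold:
    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]


@dataclass
class FoldPlan:
    folds: list[Fold]
    seed: int

    def __len__(self) -> int:
        return len(self.folds)

    def assert_no_leakage(self) -> None:
        """Raise unless the plan is patient-disjoint and covers each patient once."""
        all_test: list[str] = []
        for k, f in enumerate(self.folds):
            tr, va, te = set(f.train), set(f.validation), set(f.test)
            if tr & va or tr & te or va & te:
                raise ValidationError(f"fold {k}: train/validation/test overlap")
            if len(f.validation) != 1:
                raise ValidationError(f"fold {k}: expected exactly one validation patient")
            all_test.extend(f.test)
        if len(all_test) != len(set(all_test)):
            raise ValidationError("a patient appears in more than one test set")

    def test_sizes(self) -> list[int]:
        return [len(f.test) for f in self.folds]

    def all_patients(self) -> set[str]:
        out: set[str] = set()
        for f in self.folds:
            out |= set(f.train) | set(f.validation) | set(f.test)
        return out

    # -- serialization ----------------------------------------------
    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "folds": [
                    {"train": list(f.train), "validation": list(f.validation),
                     "test": list(f.test)}
                    for f in self.folds
                ],
            },
            indent=2,
        )
        if path:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str) -> "FoldPlan":
        try:
            obj = json.loads(text_or_path)
        except json.JSONDecodeError:
            with open(text_or_path, "r", encoding="utf-8") as fh:
                obj = json.load(fh)
        return cls(
            folds=[
                Fold(tuple(f["train"]), tuple(f["validation"]), tuple(f["test"]))
                for f in obj["folds"]
            ],
            seed=int(obj["seed"]),
        )


def _check_plan(plan: FoldPlan, patients: set[str], both: set[str]) -> None:
    plan.assert_no_leakage()
    if plan.all_patients() != patients:
        raise ValidationError("fold plan does not cover every patient")
    for k, f in enumerate(plan.folds):
        if f.validation[0] not in both:
            raise ValidationError(f"fold {k}: validation patient lacks one class")
        if not set(f.test) & both:
            raise ValidationError(f"fold {k}: test set has no both-class patient")


def make_folds(
    manifest: Manifest,
    n_folds: int = 4,
    seed: int = 0,
    policy: str = "random",
    max_attempts: int = 500,
) -> FoldPlan:
    """Constrained random patient partition into ``n_folds`` folds.

    Constraints: each patient is tested exactly once; test-set sizes differ
    by at most one (for 13 patients and 4 folds: three folds of 3 plus one
    of 4, the larger folds last); exactly one validation patient per fold,
    drawn from the both-class patients outside that fold's test set; every
    test set contains at least one both-class patient.  ``policy``
    ``"size_aware"`` additionally forces, in the oversized fold, the
    smallest tumor-only patients (fewest cubes) into test and the largest
    patient into training.
    """
    patients = manifest.patients()
    both = set(manifest.patients_with_both())
    if len(patients) < n_folds:
        raise InfeasibleError(
            f"{len(patients)} patients cannot fill {n_folds} test sets"
        )
    if len(both) < n_folds:
        raise InfeasibleError(
            f"only {len(both)} patients have both classes; need at least "
            f"{n_folds} to provide one validation patient per fold"
        )
    if policy not in ("random", "size_aware"):
        raise ValidationError(f"unknown policy {policy!r}")

    n = len(patients)
    q, r = divmod(n, n_folds)
    sizes = [q] * (n_folds - r) + [q + 1] * r  # oversized folds last

    cube_counts = manifest.frame.groupby("patient_id").size().to_dict()
    tumor_only = sorted(set(patients) - both)

    largest = max(patients, key=lambda p: cube_counts.get(p, 0))
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        order = list(rng.permutation(patients))

        if policy == "size_aware" and r and tumor_only:
            # Oversized fold(s) sit last: steer the smallest tumor-only
            # patients (two per extra fold, as its extra test slots) to the
            # end of the order so they land in the oversized test sets.
            extra = sorted(tumor_only, key=lambda p: cube_counts.get(p, 0))[: 2 * r]
            for p in extra:
                order.remove(p)
                order.append(p)

        groups, start = [], 0
        for s in sizes:
            groups.append(order[start : start + s])
            start += s

        folds, ok = [], True
        for k, test in enumerate(groups):
            test_set = set(test)
            oversized = sizes[k] > q
            if not test_set & both:
                ok = False
                break
            val_candidates = sorted(both - test_set)
            if policy == "size_aware" and oversized:
                # the largest patient bolsters the oversized fold's training
                if largest in test_set:
                    ok = False
                    break
                val_candidates = [p for p in val_candidates if p != largest]
            if not val_candidates:
                ok = False
                break
            validation = str(rng.choice(val_candidates))
            train = [p for p in patients if p not in test_set and p != validation]
            folds.append(Fold(tuple(sorted(train)), (validation,), tuple(sorted(test))))
        if not ok:
            continue

        plan = FoldPlan(folds=folds, seed=seed)
        try:
            _check_plan(plan, set(patients), both)
        except ValidationError:
            continue
        return plan

    raise InfeasibleError(
        f"no valid {n_folds}-fold plan found in {max_attempts} attempts; "
        "constraints may be infeasible for this cohort"
    )


def balance_by_rotation(train: PatchSet, angle: int = 180) -> PatchSet:
    """Double the minority class by appending spatially rotated copies.

    Each minority-class patch is duplicated once, rotated in the spatial
    plane by ``angle`` degrees (the spectral axis is untouched), and
    flagged ``augmented``.  The majority class is left as-is.  Only square
    rotations (90/180/270) are allowed — no interpolation.
    """
    if angle not in (90, 180, 270):
        raise ValidationError(f"rotation angle must be one of 90/180/270, got {angle}")
    n_neg, n_pos = train.class_counts()
    if n_neg == 0 or n_pos == 0:
        raise ValidationError("training set must contain both classes to balance")
    minority_code = 1 if n_pos < n_neg else 0
    idx = np.flatnonzero(train.labels == minority_code)
    rotated = train.subset(idx)
    rotated.data = np.ascontiguousarray(np.rot90(rotated.data, k=angle // 90, axes=(1, 2)))
    rotated.augmented = np.ones(len(rotated), dtype=bool)
    return PatchSet.concatenate([train, rotated])
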