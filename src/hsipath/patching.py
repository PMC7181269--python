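"""Tile cubes into labeled square patches and reject light-dominated ones.

A patch is rejected when *more than* half of its pixels are background
light (a patch at exactly 50% light is retained).  Light pixels are found
on the 8-bit RGB rendering of the patch footprint: the image is converted
to hue-saturation-value and the hue channel is binarized — blank
illumination renders as neutral white (hue at 0) while H&E-stained tissue
sits in the pink/purple hue range, so a single hue threshold separates
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .errors import ValidationError
from .io import HSCube, Label, Stage
from .preprocess import synthesize_rgb

__all__ = [
    "PATCH_SIZE",
    "RejectionRule",
    "PatchSet",
    "tile_grid",
    "light_fraction",
    "extract_patches",
]

#: Default spatial patch side, px.
PATCH_SIZE = 87

#: Hue midpoint between the blank-light mode (0.0 for neutral white pixels)
#: and the lower edge of the stained-tissue hue mode (~0.7 on synthetic
#: slides); configured empirically on synthetic data.
DEFAULT_HUE_THRESHOLD = 0.35


@dataclass(frozen=True)
class RejectionRule:
    """Hue binarization threshold + maximum tolerated light fraction."""

    hue_threshold: float = DEFAULT_HUE_THRESHOLD
    max_light_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_threshold <= 1.0):
            raise ValidationError("hue_threshold must lie in [0, 1]")
        if not (0.0 < self.max_light_fraction < 1.0):
            raise ValidationError("max_light_fraction must lie in (0, 1)")


def tile_grid(lines: int, samples: int, patch: int = PATCH_SIZE) -> list[tuple[int, int]]:
    """Non-overlapping tile anchors (row0, col0), row-major, top-left anchored.

    Residual margins that do not fit a whole patch are discarded; a
    nominal 800 x 1004 cube yields a 9 x 11 grid of 99 tiles.
    """
    if patch < 1:
        raise ValidationError(f"patch size must be >= 1, got {patch}")
    return [
        (i * patch, j * patch)
        for i in range(lines // patch)
        for j in range(samples // patch)
    ]


def _quantize(rgb: np.ndarray) -> np.ndarray:
    return (np.clip(rgb, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def light_mask(rgb_region: np.ndarray, rule: RejectionRule | None = None) -> np.ndarray:
    """Boolean per-pixel background-light mask of an RGB region in [0, 1]."""
    rule = rule or RejectionRule()
    hsv = rgb2hsv(_quantize(rgb_region))
    return hsv[..., 0] < rule.hue_threshold


def light_fraction(rgb_region: np.ndarray, rule: RejectionRule | None = None) -> float:
    """Fraction of a patch's pixels binarized as background light."""
    return float(light_mask(rgb_region, rule).mean())


# ---------------------------------------------------------------------------
# Patch container
# ---------------------------------------------------------------------------

LABEL_CODES = {Label.NON_TUMOR: 0, Label.TUMOR: 1}


@dataclass
class PatchSet:
    """Labeled patch tensors with grid provenance.

    ``labels`` is an int8 vector (1 = tumor, 0 = non-tumor); ``augmented``
    flags rotation copies added by class balancing.
    """

    data: np.ndarray  # (n, side, side, bands)
    labels: np.ndarray
    patient_ids: np.ndarray
    cube_ids: np.ndarray
    grid_rows: np.ndarray
    grid_cols: np.ndarray
    light_fractions: np.ndarray
    augmented: np.ndarray | None = None
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.augmented is None:
            self.augmented = np.zeros(len(self.labels), dtype=bool)

    def __len__(self) -> int:
        return int(self.data.shape[0])

    @property
    def side(self) -> int:
        return int(self.data.shape[1])

    @property
    def bands(self) -> int:
        return int(self.data.shape[3])

    def class_counts(self) -> tuple[int, int]:
        """(non_tumor, tumor) patch counts."""
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def subset(self, index: np.ndarray) -> "PatchSet":
        return PatchSet(
            data=self.data[index],
            labels=self.labels[index],
            patient_ids=self.patient_ids[index],
            cube_ids=self.cube_ids[index],
            grid_rows=self.grid_rows[index],
            grid_cols=self.grid_cols[index],
            light_fractions=self.light_fractions[index],
            augmented=self.augmented[index],
        )

    def for_patients(self, patients) -> "PatchSet":
        mask = np.isin(self.patient_ids, list(patients))
        return self.subset(mask)

    @classmethod
    def concatenate(cls, sets: list["PatchSet"]) -> "PatchSet":
        if not sets:
            raise ValidationError("cannot concatenate zero patch sets")
        return cls(
            data=np.concatenate([s.data for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            patient_ids=np.concatenate([s.patient_ids for s in sets]),
            cube_ids=np.concatenate([s.cube_ids for s in sets]),
            grid_rows=np.concatenate([s.grid_rows for s in sets]),
            grid_cols=np.concatenate([s.grid_cols for s in sets]),
            light_fractions=np.concatenate([s.light_fractions for s in sets]),
            augmented=np.concatenate([s.augmented for s in sets]),
            n_rejected=sum(s.n_rejected for s in sets),
        )

    # -- persistence (HDF5 container + per-patch metadata) -----------
    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip", compression_opts=1)
            f.create_dataset("labels", data=self.labels)
            str_dt = h5py.string_dtype()
            f.create_dataset("patient_ids", data=self.patient_ids.astype(object), dtype=str_dt)
            f.create_dataset("cube_ids", data=self.cube_ids.astype(object), dtype=str_dt)
            f.create_dataset("grid_rows", data=self.grid_rows)
            f.create_dataset("grid_cols", data=self.grid_cols)
            f.create_dataset("light_fractions", data=self.light_fractions)
            f.create_dataset("augmented", data=self.augmented)
            f.attrs["n_rejected"] = self.n_rejected

    @classmethod
    def load(cls, path: str) -> "PatchSet":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][:],
                labels=f["labels"][:],
                patient_ids=f["patient_ids"].asstr()[:],
                cube_ids=f["cube_ids"].asstr()[:],
                grid_rows=f["grid_rows"][:],
                grid_cols=f["grid_cols"][:],
                light_fractions=f["light_fractions"][:],
                augmented=f["augmented"][:].astype(bool),
                n_rejected=int(f.attrs.get("n_rejected", 0)),
            )


def extract_patches(
    cube: HSCube,
    rule: RejectionRule | None = None,
    patch: int = PATCH_SIZE,
    cube_id: str | None = None,
) -> PatchSet:
    """Tile a reduced cube into patches, rejecting light-dominated ones.

    Every retained patch inherits the cube's (weak) label.  A patch is
    retained iff its light fraction is <= the rule's maximum (ties kept).
    ``n_rejected`` on the returned set preserves retained+rejected = tiled.
    """
    rule = rule or RejectionRule()
    if cube.stage is not Stage.REDUCED:
        raise ValidationError(
            f"extract_patches expects a reduced cube, got stage {cube.stage.value}"
        )
    if cube.label is Label.UNKNOWN:
        raise ValidationError("cannot extract labeled patches from an unlabeled cube")
    if cube_id is None:
        cube_id = f"{cube.patient_id}/{cube.roi_id}" if cube.patient_id else "cube"

    offsets = tile_grid(cube.lines, cube.samples, patch)
    rgb = synthesize_rgb(cube)
    lightm = light_mask(rgb, rule)

    tensors, rows, cols, fracs = [], [], [], []
    n_rejected = 0
    for r0, c0 in offsets:
        frac = float(lightm[r0 : r0 + patch, c0 : c0 + patch].mean())
        if frac > rule.max_light_fraction:
            n_rejected += 1
            continue
        tensors.append(cube.data[r0 : r0 + patch, c0 : c0 + patch, :].astype(np.float32))
        rows.append(r0 // patch)
        cols.append(c0 // patch)
        fracs.append(frac)

    n = len(tensors)
    data = (
        np.stack(tensors)
        if n
        else np.empty((0, patch, patch, cube.bands), dtype=np.float32)
    )
    label_code = LABEL_CODES[cube.label]
    return PatchSet(
        data=data,
        labels=np.full(n, label_code, dtype=np.int8),
        patient_ids=np.array([cube.patient_id] * n, dtype=object),
        cube_ids=np.array([cube_id] * n, dtype=object),
        grid_rows=np.array(rows, dtype=np.int32),
        grid_cols=np.array(cols, dtype=np.int32),
        light_fractions=np.array(fracs, dtype=np.float64),
        n_rejected=n_rejected,
    )
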