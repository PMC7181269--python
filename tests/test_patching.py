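"""Patch tiling, background-light rejection and the PatchSet container."""

import numpy as np
import pytest

from hsipath.errors import ValidationError
from hsipath.io import HSCube, Label, Stage, nominal_wavelengths
from hsipath.patching import (
    PatchSet,
    RejectionRule,
    extract_patches,
    light_fraction,
    light_mask,
    tile_grid,
)
from hsipath.preprocess import BandReductionPlan, flat_field_correct, reduce_bands
from hsipath.synth import SceneSpec, generate_slide

TISSUE_RGB = (0.70, 0.35, 0.65)  # eosin-pink; hue well above the threshold


class TestTileGrid:
    def test_nominal_cube_gives_99_tiles(self):
        offsets = tile_grid(800, 1004, 87)
        assert len(offsets) == 99
        rows = {r for r, _ in offsets}
        cols = {c for _, c in offsets}
        assert len(rows) == 9 and len(cols) == 11
        assert offsets[0] == (0, 0) and offsets[-1] == (8 * 87, 10 * 87)

    def test_exact_fit_single_tile(self):
        assert tile_grid(87, 87, 87) == [(0, 0)]

    def test_too_small_image_empty(self):
        assert tile_grid(86, 1004, 87) == []

    def test_row_major_order(self):
        assert tile_grid(4, 6, 2) == [(0, 0), (0, 2), (0, 4), (2, 0), (2, 2), (2, 4)]


class TestLightFraction:
    def test_all_blank_patch(self):
        rgb = np.ones((87, 87, 3))
        assert light_fraction(rgb) == 1.0

    def test_all_tissue_patch(self):
        rgb = np.broadcast_to(TISSUE_RGB, (87, 87, 3)).copy()
        assert light_fraction(rgb) == 0.0

    def test_half_split_counts_exact_pixels(self):
        """A patch split at column 43 gives exactly 43/87 light fraction."""
        rgb = np.broadcast_to(TISSUE_RGB, (87, 87, 3)).copy()
        rgb[:, :43, :] = 1.0
        assert light_fraction(rgb) == pytest.approx(43 / 87)
        rgb2 = np.broadcast_to(TISSUE_RGB, (87, 87, 3)).copy()
        rgb2[:, :44, :] = 1.0
        assert light_fraction(rgb2) == pytest.approx(44 / 87)


def _reduced_cube(trans, label=Label.TUMOR):
    """Wrap a transmittance array as a reduced-stage cube for patching."""
    return HSCube(data=np.asarray(trans, np.float32),
                  wavelengths_nm=nominal_wavelengths(trans.shape[2]),
                  stage=Stage.REDUCED, patient_id="P1", roi_id="R1", label=label)


def _tissue_spectrum(bands):
    """A spectrum whose RGB rendering lands in the pink tissue hue range."""
    from hsipath.synth import stain_transmittance
    from hsipath.io import nominal_wavelengths as nwl

    return stain_transmittance(nwl(bands), {"hematoxylin": 0.6, "eosin": 0.5}).astype(
        np.float32
    )


class TestExtractPatches:
    def synth_reduced(self, blank_fraction, seed=0, lines=63, samples=84, bands=36):
        spec = SceneSpec(lines=lines, samples=samples, bands=bands, label=Label.TUMOR,
                         blank_fraction=blank_fraction, noise_sd=0.003, seed=seed)
        cube, ref, _ = generate_slide(spec)
        return reduce_bands(flat_field_correct(cube, ref), BandReductionPlan(3))

    def test_no_blank_keeps_every_tile(self):
        reduced = self.synth_reduced(blank_fraction=0.0)
        ps = extract_patches(reduced, patch=21)
        assert len(ps) == len(tile_grid(63, 84, 21))
        assert ps.n_rejected == 0
        assert np.all(ps.labels == 1)

    def test_retained_plus_rejected_equals_tiled(self):
        for seed in (1, 2, 3):
            reduced = self.synth_reduced(blank_fraction=0.3, seed=seed)
            ps = extract_patches(reduced, patch=21)
            assert len(ps) + ps.n_rejected == len(tile_grid(63, 84, 21))

    def test_rejection_matches_brute_force_mask_count(self):
        """Blank right columns: retention equals a per-patch mask tally."""
        bands = 12
        patch = 10
        trans = np.tile(_tissue_spectrum(bands), (30, 50, 1))
        trans[:, 30:, :] = 1.0  # right 40% of columns are blank light
        cube = _reduced_cube(trans)
        ps = extract_patches(cube, patch=patch)
        blank_cols = np.zeros((30, 50), dtype=bool)
        blank_cols[:, 30:] = True
        expected_keep = sum(
            blank_cols[r : r + patch, c : c + patch].mean() <= 0.5
            for r, c in tile_grid(30, 50, patch)
        )
        assert len(ps) == expected_keep
        assert ps.n_rejected == len(tile_grid(30, 50, patch)) - expected_keep

    def test_exact_half_light_is_retained(self):
        bands = 12
        trans = np.tile(_tissue_spectrum(bands), (10, 10, 1))
        trans[:, :5, :] = 1.0  # exactly 50% light
        ps = extract_patches(_reduced_cube(trans), patch=10)
        assert len(ps) == 1 and ps.n_rejected == 0
        assert ps.light_fractions[0] == pytest.approx(0.5)
        trans[:, 5, :] = 1.0  # now 60% -> "more than 50%" rejects
        ps2 = extract_patches(_reduced_cube(trans), patch=10)
        assert len(ps2) == 0 and ps2.n_rejected == 1

    def test_monotone_in_blank_fraction(self):
        counts = [
            len(extract_patches(self.synth_reduced(bf, seed=5), patch=21))
            for bf in (0.0, 0.2, 0.4)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_translation_consistency_at_tile_boundary(self):
        """Cropping whole tile rows/cols off yields the matching patch subset."""
        reduced = self.synth_reduced(blank_fraction=0.0, seed=9)
        patch = 21
        full = extract_patches(reduced, patch=patch)
        cropped = extract_patches(
            reduced.with_data(reduced.data[patch:, patch:]), patch=patch
        )
        keep = (full.grid_rows >= 1) & (full.grid_cols >= 1)
        np.testing.assert_array_equal(cropped.data, full.data[keep])

    def test_unlabeled_cube_rejected(self):
        cube = _reduced_cube(np.tile(_tissue_spectrum(6), (10, 10, 1)))
        cube.label = Label.UNKNOWN
        with pytest.raises(ValidationError, match="unlabeled"):
            extract_patches(cube, patch=10)

    def test_requires_reduced_stage(self):
        cube = HSCube(data=np.ones((10, 10, 6)) * 0.5,
                      wavelengths_nm=nominal_wavelengths(6),
                      stage=Stage.TRANSMITTANCE, label=Label.TUMOR)
        with pytest.raises(ValidationError, match="reduced"):
            extract_patches(cube, patch=10)


class TestPatchSetContainer:
    def test_hdf5_roundtrip(self, tmp_path, tiny_patches):
        sub = tiny_patches.subset(np.arange(min(6, len(tiny_patches))))
        path = str(tmp_path / "patches.h5")
        sub.save(path)
        back = PatchSet.load(path)
        np.testing.assert_array_equal(back.data, sub.data)
        np.testing.assert_array_equal(back.labels, sub.labels)
        assert list(back.patient_ids) == list(sub.patient_ids)

    def test_class_counts_and_patient_selection(self, tiny_patches):
        n_neg, n_pos = tiny_patches.class_counts()
        assert n_neg + n_pos == len(tiny_patches)
        one = tiny_patches.for_patients(["P1"])
        assert set(one.patient_ids) == {"P1"}
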