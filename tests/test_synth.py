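"""Synthetic slide generator: stain optics, determinism, cohort structure."""

import hashlib

import numpy as np
import pytest

from hsipath.errors import ValidationError
from hsipath.io import Label, nominal_wavelengths
from hsipath.preprocess import flat_field_correct
from hsipath.synth import (
    SceneSpec,
    default_stain_model,
    generate_cohort,
    generate_slide,
    scene_transmittance,
    stain_transmittance,
)

WL = nominal_wavelengths(120)


def test_zero_concentration_gives_unit_transmittance():
    t = stain_transmittance(WL, {"hematoxylin": 0.0, "eosin": 0.0})
    np.testing.assert_array_equal(t, np.ones_like(WL))


def test_doubling_concentration_squares_transmittance():
    t1 = stain_transmittance(WL, {"hematoxylin": 0.8})
    t2 = stain_transmittance(WL, {"hematoxylin": 1.6})
    np.testing.assert_allclose(t2, t1**2, rtol=1e-12)


def test_concentration_recovered_by_log_linear_least_squares():
    """Closed-form inversion: c = -<A, log T> / <A, A> on a noiseless spectrum."""
    model = default_stain_model()
    c_true = 1.37
    t = stain_transmittance(WL, {"hematoxylin": c_true}, model)
    a = model.absorbance("hematoxylin", WL)
    c_hat = -(a @ np.log(t)) / (a @ a)
    assert abs(c_hat - c_true) / c_true < 1e-6


def test_negative_concentration_rejected():
    with pytest.raises(ValidationError, match="negative"):
        stain_transmittance(WL, {"eosin": -0.1})


def test_transmittance_monotone_in_concentration():
    model = default_stain_model()
    absorbing = model.absorbance("eosin", WL) > 1e-6
    t_lo = stain_transmittance(WL, {"eosin": 0.5}, model)
    t_hi = stain_transmittance(WL, {"eosin": 0.9}, model)
    assert np.all(t_hi[absorbing] < t_lo[absorbing])


# ---------------------------------------------------------------------------
# Slide generation
# ---------------------------------------------------------------------------


def _spec(**kw):
    base = dict(lines=60, samples=80, bands=40, label=Label.TUMOR, seed=7,
                noise_sd=0.005, blank_fraction=0.1, reference_lines=12)
    base.update(kw)
    return SceneSpec(**base)


def test_same_seed_bit_identical():
    c1, r1, m1 = generate_slide(_spec())
    c2, r2, m2 = generate_slide(_spec())
    np.testing.assert_array_equal(c1.data, c2.data)
    np.testing.assert_array_equal(r1.data, r2.data)
    np.testing.assert_array_equal(m1, m2)
    c3, _, _ = generate_slide(_spec(seed=8))
    assert not np.array_equal(c1.data, c3.data)


def test_beer_lambert_ratio_bound():
    """Noise-free, no blanks: radiance / illumination profile lies in (0, 1]."""
    cube, ref, _ = generate_slide(_spec(blank_fraction=0.0, noise_sd=0.0))
    profile = ref.data.mean(axis=0)
    ratio = cube.data / profile[None]
    assert ratio.min() > 0 and ratio.max() <= 1 + 1e-6


def test_tumor_class_has_denser_nucleus_mask():
    """Tumor nuclear coverage beats non-tumor in >= 95% of seeded trials."""
    wins = 0
    trials = 30
    for s in range(trials):
        _, _, m_t = generate_slide(_spec(label=Label.TUMOR, seed=s, noise_sd=0.0))
        _, _, m_n = generate_slide(_spec(label=Label.NON_TUMOR, seed=s, noise_sd=0.0))
        wins += m_t.mean() > m_n.mean()
    assert wins / trials >= 0.95


def test_blank_fraction_warning():
    with pytest.warns(UserWarning, match="blank_fraction"):
        generate_slide(_spec(blank_fraction=0.7))


def test_flat_field_recovers_scene_transmittance_exactly():
    """Noiseless pipeline-consistency oracle, float64: max abs error <= 1e-12."""
    spec = _spec(noise_sd=0.0, dtype=np.float64)
    cube, ref, _ = generate_slide(spec)
    recovered = flat_field_correct(cube, ref)
    expected = scene_transmittance(spec)
    assert np.max(np.abs(recovered.data - np.clip(expected, 0, 1))) <= 1e-12


def test_nucleus_vs_blank_pixels_linearly_separable_noise_free():
    """At zero noise a threshold on mean transmittance separates the
    nucleus and blank-light pixel populations perfectly."""
    spec = _spec(noise_sd=0.0, blank_fraction=0.2)
    cube, ref, mask = generate_slide(spec)
    trans = flat_field_correct(cube, ref).data
    mean_t = trans.mean(axis=2)
    blank = mean_t > 0.999  # blank pixels transmit everything (up to fp rounding)
    nucleus_vals = mean_t[mask]
    assert nucleus_vals.size and blank.any()
    assert not np.any(mask & blank)
    # any threshold between the two population extremes separates perfectly
    assert nucleus_vals.max() < mean_t[blank].min()


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def _cohort(tmp_path, **kw):
    base = dict(n_patients=5, n_cubes_per_roi=1, tumor_only_patients=2, seed=3,
                out_dir=str(tmp_path), lines=40, samples=50, bands=30,
                noise_sd=0.005, write_masks=False)
    base.update(kw)
    return generate_cohort(**base)


def test_cohort_tumor_only_structure(tmp_path):
    man = _cohort(tmp_path)
    assert len(man.tumor_only_patients()) == 2
    assert len(man.patients_with_both()) == 3
    man.check_paths()  # every referenced file exists


def test_cohort_all_both_class(tmp_path):
    man = _cohort(tmp_path, n_patients=4, tumor_only_patients=0)
    assert man.patients_with_both() == man.patients()


def test_cohort_deterministic_files(tmp_path):
    man1 = _cohort(tmp_path / "a")
    man2 = _cohort(tmp_path / "b")
    assert man1.frame.equals(man2.frame)
    for rel in man1.frame["cube_path"][:3]:
        h1 = hashlib.sha256(open(man1.resolve(rel)[:-4] + ".img", "rb").read()).hexdigest()
        h2 = hashlib.sha256(open(man2.resolve(rel)[:-4] + ".img", "rb").read()).hexdigest()
        assert h1 == h2


def test_cohort_too_few_patients(tmp_path):
    with pytest.raises(ValidationError, match="4 patients"):
        _cohort(tmp_path, n_patients=3)


def test_patient_stain_variability_dominates_within_patient(tmp_path):
    """Variance decomposition at default settings: per-patient stain factors
    make the between-patient variance of the background-tissue spectrum
    exceed the within-patient (slide-to-slide) variance."""
    import imageio.v3 as iio

    from hsipath import io as hio

    man = _cohort(tmp_path, n_patients=6, tumor_only_patients=0, n_cubes_per_roi=2,
                  lines=64, samples=64, write_masks=True)
    means: dict[str, list[float]] = {}
    tumor_rows = man.frame[man.frame["label"] == "tumor"]
    for _, row in tumor_rows.iterrows():
        cube = hio.read_cube(man.resolve(row["cube_path"]))
        ref = hio.read_cube(man.resolve(row["reference_path"]))
        nucleus = iio.imread(man.resolve(row["cube_path"]).replace(".hdr", "_mask.png")) > 0
        trans = flat_field_correct(cube, ref).data
        mean_t = trans.mean(axis=2)
        tissue = (~nucleus) & (mean_t < 0.98)  # background tissue, not blank light
        means.setdefault(row["patient_id"], []).append(float(mean_t[tissue].mean()))
    patient_means = np.array([np.mean(v) for v in means.values()])
    within = np.mean([np.var(v) for v in means.values()])
    assert patient_means.var() > within
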