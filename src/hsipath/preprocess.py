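"""Radiance -> transmittance -> reduced-band processing, and RGB baselines.

All three operations are deterministic and involve no randomness.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import HSCube, Stage

__all__ = [
    "BandReductionPlan",
    "TailPolicy",
    "flat_field_correct",
    "reduce_bands",
    "synthesize_rgb",
    "color_matching_weights",
]


# ---------------------------------------------------------------------------
# Flat-field correction
# ---------------------------------------------------------------------------


def flat_field_correct(cube: HSCube, reference: HSCube) -> HSCube:
    """Normalize radiance to transmittance against a blank-slide reference.

    The reference is first averaged over its scan lines to a single
    spectrum per sensor sample (the push-broom fixed-pattern profile);
    the cube is then divided by that profile and clamped to [0, 1].
    Scale-invariant: multiplying cube and reference by the same positive
    constant leaves the output unchanged.
    """
    if cube.stage is not Stage.RADIANCE or reference.stage is not Stage.RADIANCE:
        raise ValidationError(
            f"flat-field correction needs radiance cubes, got {cube.stage.value} "
            f"and {reference.stage.value}"
        )
    if cube.samples != reference.samples or cube.bands != reference.bands:
        raise ValidationError(
            f"cube ({cube.samples} samples x {cube.bands} bands) and reference "
            f"({reference.samples} x {reference.bands}) must agree on samples and bands"
        )
    profile = reference.data.mean(axis=0)  # (samples, bands)
    bad = np.argwhere(profile <= 0)
    if bad.size:
        shown = ", ".join(f"(sample={s}, band={b})" for s, b in bad[:5])
        raise ValidationError(
            f"reference profile not strictly positive at {bad.shape[0]} entries: {shown}"
        )
    trans = cube.data / profile[None, :, :]
    np.clip(trans, 0.0, 1.0, out=trans)
    return cube.with_data(trans, stage=Stage.TRANSMITTANCE)


# ---------------------------------------------------------------------------
# Spectral band reduction
# ---------------------------------------------------------------------------


class TailPolicy(str, enum.Enum):
    DROP_LAST = "drop_last"
    FOLD_INTO_LAST = "fold_into_last"


@dataclass(frozen=True)
class BandReductionPlan:
    """Average consecutive non-overlapping groups of spectral neighbours.

    With the defaults (group of 3, drop the residual band) the camera's
    826 bands reduce to 275, averaging down the white sensor noise.
    """

    group_size: int = 3
    tail_policy: TailPolicy = TailPolicy.DROP_LAST

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValidationError(f"group_size must be >= 1, got {self.group_size}")

    def output_bands(self, input_bands: int) -> int:
        return input_bands // self.group_size


def reduce_bands(cube: HSCube, plan: BandReductionPlan | None = None) -> HSCube:
    """Reduce a transmittance cube spectrally; output wavelengths are group means."""
    plan = plan or BandReductionPlan()
    if cube.stage is not Stage.TRANSMITTANCE:
        raise ValidationError(
            f"band reduction expects a transmittance cube, got stage {cube.stage.value}"
        )
    g = plan.group_size
    n_groups = cube.bands // g
    if n_groups < 1:
        raise ValidationError(f"cube has {cube.bands} bands, fewer than group_size {g}")
    used = n_groups * g
    lines, samples = cube.lines, cube.samples
    data = cube.data[:, :, :used].reshape(lines, samples, n_groups, g).mean(axis=3)
    wl = cube.wavelengths_nm[:used].reshape(n_groups, g).mean(axis=1)
    if plan.tail_policy is TailPolicy.FOLD_INTO_LAST and used < cube.bands:
        tail = cube.data[:, :, used:]
        k = cube.bands - used
        data[:, :, -1] = (data[:, :, -1] * g + tail.sum(axis=2)) / (g + k)
        wl = wl.copy()
        wl[-1] = (cube.wavelengths_nm[used - g:used].sum() + cube.wavelengths_nm[used:].sum()) / (g + k)
    return cube.with_data(
        data.astype(cube.data.dtype, copy=False), stage=Stage.REDUCED, wavelengths_nm=wl
    )


# ---------------------------------------------------------------------------
# Synthetic RGB baseline
# ---------------------------------------------------------------------------

# Piecewise-Gaussian analytic fit of the CIE 1931 2-degree standard observer
# (one asymmetric Gaussian lobe per term).  Fixed coefficients make the RGB
# rendering bit-stable across runs and platforms.
_CMF_TERMS = {
    "x": ((1.056, 599.8, 37.9, 31.0), (0.362, 442.0, 16.0, 26.7), (-0.065, 501.1, 20.4, 26.2)),
    "y": ((0.821, 568.8, 46.9, 40.5), (0.286, 530.9, 16.3, 31.1)),
    "z": ((1.217, 437.0, 11.8, 36.0), (0.681, 459.0, 26.0, 13.8)),
}


def _observer_curve(name: str, wl: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wl, dtype=float)
    for amp, mu, s_left, s_right in _CMF_TERMS[name]:
        sigma = np.where(wl < mu, s_left, s_right)
        out += amp * np.exp(-0.5 * ((wl - mu) / sigma) ** 2)
    return out


def color_matching_weights(wavelengths_nm: np.ndarray) -> np.ndarray:
    """(bands, 3) channel weights, each column normalized to unit sum.

    Normalization makes a unit (all-ones) spectrum map to (1, 1, 1): each
    channel is a weighted mean of the spectrum under its observer curve.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    cols = []
    for name in ("x", "y", "z"):
        w = _observer_curve(name, wl)
        total = w.sum()
        if total <= 0:
            raise ValidationError("wavelength grid does not overlap the visible range")
        cols.append(w / total)
    return np.stack(cols, axis=1)


def synthesize_rgb(cube: HSCube) -> np.ndarray:
    """Collapse a transmittance (or reduced) cube to a 3-channel image in [0, 1].

    Each channel is the normalized inner product of the pixel spectrum with
    a fixed human-eye color-matching weight curve; an all-ones spectrum
    maps to white.
    """
    if cube.stage is Stage.RADIANCE:
        raise ValidationError("synthesize_rgb expects a transmittance or reduced cube")
    wl = cube.wavelengths_nm
    if wl[0] > 450.0 or wl[-1] < 650.0:
        raise ValidationError(
            f"wavelength coverage [{wl[0]:g}, {wl[-1]:g}] nm misses the visible range"
        )
    weights = color_matching_weights(wl)
    rgb = np.tensordot(cube.data.astype(np.float64, copy=False), weights, axes=([2], [0]))
    return np.clip(rgb, 0.0, 1.0)
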