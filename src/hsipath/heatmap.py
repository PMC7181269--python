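"""Sliding-window tumor-probability heat maps over whole cubes.

An 87 px window slides with a 23 px stride (defaults), each window is
scored by the patch classifier, and the per-pixel overlay value is the
unweighted mean of every window covering the pixel — a convex combination,
so overlay values stay in [0, 1].  With stride equal to the window the
grid reduces exactly to the non-overlapping tile grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import HSCube, Stage
from .patching import PATCH_SIZE

__all__ = ["DEFAULT_STRIDE", "HeatMap", "sliding_offsets", "render_heatmap"]

DEFAULT_STRIDE = 23


def sliding_offsets(
    lines: int, samples: int, patch: int = PATCH_SIZE, stride: int = DEFAULT_STRIDE
) -> list[tuple[int, int]]:
    """Window anchors (row0, col0) on the stride grid, row-major.

    Only fully contained windows are scored; an image smaller than the
    window yields an empty list.  A nominal 800 x 1004 cube gives a
    32 x 40 grid (1280 windows).
    """
    if patch < 1 or stride < 1:
        raise ValidationError("patch and stride must be >= 1")
    if lines < patch or samples < patch:
        return []
    rows = (lines - patch) // stride + 1
    cols = (samples - patch) // stride + 1
    return [(i * stride, j * stride) for i in range(rows) for j in range(cols)]


@dataclass
class HeatMap:
    """Window-probability grid plus its per-pixel overlay field."""

    grid: np.ndarray  # (rows, cols) window tumor probabilities
    overlay: np.ndarray  # (lines, samples) per-pixel mean probability
    stride: int
    patch: int
    cube_id: str = ""

    def render(self, rgb: np.ndarray | None = None, alpha: float = 0.55) -> np.ndarray:
        """Blue-to-red rendering of the overlay, optionally blended over RGB."""
        import matplotlib.cm as cm

        colored = cm.coolwarm(np.clip(self.overlay, 0.0, 1.0))[..., :3]
        if rgb is None:
            return colored
        return (1 - alpha) * np.clip(rgb, 0, 1) + alpha * colored


def render_heatmap(
    model,
    cube: HSCube,
    stride: int = DEFAULT_STRIDE,
    patch: int | None = None,
    batch_size: int = 16,
) -> HeatMap:
    """Score every sliding window of a reduced cube with the classifier.

    ``model`` is anything with ``predict_tumor_probability`` (a
    :class:`~hsipath.cnn.PatchClassifier`, its results object, or a stub).
    Edge margins not covered by any full window inherit the nearest
    covered pixel's value in the overlay only; the grid itself contains no
    extrapolated cells.
    """
    if cube.stage is not Stage.REDUCED:
        raise ValidationError(f"heat maps need a reduced cube, got {cube.stage.value}")
    spec = getattr(model, "spec", None) or getattr(getattr(model, "model", None), "spec", None)
    if patch is None:
        patch = spec.input_side if spec is not None else PATCH_SIZE
    if spec is not None and spec.input_bands != cube.bands:
        raise ValidationError(
            f"band mismatch: model expects {spec.input_bands}, cube has {cube.bands}"
        )
    offsets = sliding_offsets(cube.lines, cube.samples, patch, stride)
    if not offsets:
        raise ValidationError("cube is smaller than the sliding window")
    rows = (cube.lines - patch) // stride + 1
    cols = (cube.samples - patch) // stride + 1

    probs = np.empty(len(offsets), dtype=np.float64)
    for s in range(0, len(offsets), batch_size):
        chunk = offsets[s : s + batch_size]
        windows = np.stack(
            [cube.data[r : r + patch, c : c + patch, :] for r, c in chunk]
        ).astype(np.float32)
        probs[s : s + len(chunk)] = np.asarray(
            model.predict_tumor_probability(windows), dtype=np.float64
        )
    grid = probs.reshape(rows, cols)

    acc = np.zeros((cube.lines, cube.samples), dtype=np.float64)
    cover = np.zeros((cube.lines, cube.samples), dtype=np.int32)
    for p, (r, c) in zip(probs, offsets):
        acc[r : r + patch, c : c + patch] += p
        cover[r : r + patch, c : c + patch] += 1
    covered = cover > 0
    overlay = np.zeros_like(acc)
    overlay[covered] = acc[covered] / cover[covered]
    # replicate the last covered row/column into the uncovered far margins
    last_r = (rows - 1) * stride + patch
    last_c = (cols - 1) * stride + patch
    overlay[last_r:, :last_c] = overlay[last_r - 1, :last_c]
    overlay[:, last_c:] = overlay[:, last_c - 1][:, None]

    return HeatMap(
        grid=grid,
        overlay=overlay,
        stride=stride,
        patch=patch,
        cube_id=f"{cube.patient_id}/{cube.roi_id}",
    )
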