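"""Patch classifier: an all-convolutional 2-D CNN implemented in NumPy.

Architecture (full scale): eight unpadded 3x3 convolutions with ReLU and
10% dropout — channel widths 256, 256, 512, 512, 1024, 1024, 1024, 1024 —
followed by global average pooling, a 256-unit ReLU dense layer with
dropout, a 2-unit logits layer and softmax.  Each unpadded convolution
shrinks the spatial side by 2, so an 87 x 87 input passes through sides
85, 83, 81, 79, 77, 75, 73 and reaches the pool at 71 x 71.  A ``scale``
multiplier on the channel widths gives desk-scale variants with the same
depth and spatial arithmetic.

Training is plain mini-batch stochastic gradient descent (learning rate
1e-3 by default) with optional momentum; the model kept is the epoch with
the best validation ROC-AUC.  Forward, backward and the optimizer are
written directly on NumPy (shifted-slice convolutions backed by BLAS
matmuls), so training is deterministic for a fixed seed.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .patching import PatchSet

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "PatchClassifier",
    "PatchClassifierResults",
    "build_model",
    "train",
    "predict_patches",
]

FULL_CONV_WIDTHS = (256, 256, 512, 512, 1024, 1024, 1024, 1024)
#: Desk-scale default width multiplier (widths 16..64, full depth).
DESK_SCALE = 0.0625


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the patch CNN."""

    input_side: int = 87
    input_bands: int = 275  # 3 for the RGB baseline
    conv_widths: tuple[int, ...] = FULL_CONV_WIDTHS
    dense_units: int = 256
    classes: int = 2
    dropout_rate: float = 0.10
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.scale <= 0:
            raise ValidationError("scale must be positive")
        min_side = 2 * len(self.conv_widths) + 1
        if self.input_side < min_side:
            raise ValidationError(
                f"input_side {self.input_side} too small for "
                f"{len(self.conv_widths)} unpadded 3x3 convolutions (needs >= {min_side})"
            )

    def scaled_widths(self) -> tuple[int, ...]:
        return tuple(max(1, round(w * self.scale)) for w in self.conv_widths)

    def spatial_sides(self) -> tuple[int, ...]:
        """Input spatial side of every conv layer plus the pooled side."""
        return tuple(self.input_side - 2 * k for k in range(len(self.conv_widths) + 1))

    def shape_table(self) -> pd.DataFrame:
        """Layer table: name, kernel, input size of every layer."""
        widths = self.scaled_widths()
        sides = self.spatial_sides()
        rows = []
        in_ch = self.input_bands
        for k, w in enumerate(widths):
            rows.append(
                {"layer": "Conv2D", "kernel": "3 x 3",
                 "input": f"{sides[k]} x {sides[k]} x {in_ch}"}
            )
            in_ch = w
        rows.append(
            {"layer": "GlobalAvgPool", "kernel": f"{sides[-1]} x {sides[-1]}",
             "input": f"{sides[-1]} x {sides[-1]} x {widths[-1]}"}
        )
        rows.append({"layer": "Dense", "kernel": f"{self.dense_units} neurons",
                     "input": f"1 x {widths[-1]}"})
        rows.append({"layer": "Dense", "kernel": "logits",
                     "input": f"1 x {self.dense_units}"})
        rows.append({"layer": "Softmax", "kernel": "classifier",
                     "input": f"1 x {self.classes}"})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; every unstated choice lives here explicitly."""

    learning_rate: float = 1e-3
    momentum: float = 0.9
    epochs: int = 25
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")


# ---------------------------------------------------------------------------
# Conv primitives
# ---------------------------------------------------------------------------


class _Conv3x3:
    """Valid 3x3 convolution layer on NHWC batches.

    Implemented as nine shifted-slice accumulations, each a single BLAS
    matmul over a contiguous scratch copy of the shifted input — much
    cheaper than materializing a full im2col matrix per sample.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in = 9 * in_ch
        self.w = (
            rng.standard_normal((3, 3, in_ch, out_ch)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.in_ch = in_ch
        self.out_ch = out_ch

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w_, c = x.shape
        oh, ow = h - 2, w_ - 2
        out = np.broadcast_to(self.b, (n * oh * ow, self.out_ch)).copy()
        buf = np.empty((n, oh, ow, c), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                np.copyto(buf, x[:, i : i + oh, j : j + ow, :])
                out += buf.reshape(-1, c) @ self.w[i, j]
        return out.reshape(n, oh, ow, self.out_ch)

    def backward(self, x: np.ndarray, dout: np.ndarray, need_dx: bool = True):
        n, h, w_, c = x.shape
        oh, ow = h - 2, w_ - 2
        dflat = np.ascontiguousarray(dout.reshape(n * oh * ow, self.out_ch))
        db = dflat.sum(axis=0)
        dw = np.empty_like(self.w)
        dx = np.zeros_like(x) if need_dx else None
        buf = np.empty((n, oh, ow, c), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                np.copyto(buf, x[:, i : i + oh, j : j + ow, :])
                dw[i, j] = buf.reshape(-1, c).T @ dflat
                if need_dx:
                    dx[:, i : i + oh, j : j + ow, :] += (
                        dflat @ self.w[i, j].T
                    ).reshape(n, oh, ow, c)
        return dx, dw, db


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(
            np.float32
        )
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.w + self.b

    def backward(self, x: np.ndarray, dout: np.ndarray):
        return dout @ self.w.T, x.T @ dout, dout.sum(axis=0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class PatchClassifier:
    """The patch CNN as a fittable model object.

    Construct from a :class:`ModelSpec` (weights are initialized from
    ``seed``), call :meth:`fit` with training and validation patch sets to
    obtain a :class:`PatchClassifierResults`, or :meth:`predict_proba`
    directly for forward passes.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
        widths = spec.scaled_widths()
        self.convs: list[_Conv3x3] = []
        in_ch = spec.input_bands
        for w in widths:
            self.convs.append(_Conv3x3(in_ch, w, rng))
            in_ch = w
        self.dense1 = _Dense(in_ch, spec.dense_units, rng)
        self.dense2 = _Dense(spec.dense_units, spec.classes, rng)

    # -- parameter plumbing ------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        params: list[np.ndarray] = []
        for layer in [*self.convs, self.dense1, self.dense2]:
            params.extend([layer.w, layer.b])
        return params

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- forward / backward ------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.spec.input_side or x.shape[2] != self.spec.input_side:
            raise ValidationError(
                f"expected {self.spec.input_side}x{self.spec.input_side} patches, "
                f"got {x.shape[1]}x{x.shape[2]}"
            )
        if x.shape[3] != self.spec.input_bands:
            raise ValidationError(
                f"band mismatch: model expects {self.spec.input_bands} bands, "
                f"got {x.shape[3]}"
            )
        return x

    def _forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None):
        """Returns (probs, cache); dropout is active only when training."""
        p_drop = self.spec.dropout_rate if training else 0.0
        keep = 1.0 - p_drop
        cache = {"inputs": [], "relu": [], "drop": []}
        h = x
        for conv in self.convs:
            cache["inputs"].append(h)
            z = conv.forward(h)
            relu_mask = z > 0
            h = z * relu_mask
            cache["relu"].append(relu_mask)
            if p_drop > 0:
                mask = (rng.random(h.shape, dtype=np.float32) < keep).astype(np.float32) / keep
                h = h * mask
                cache["drop"].append(mask)
            else:
                cache["drop"].append(None)
        pooled = h.mean(axis=(1, 2))  # global average pooling
        cache["pre_pool_shape"] = h.shape
        cache["pooled_in"] = pooled
        z1 = self.dense1.forward(pooled)
        relu1 = z1 > 0
        h1 = z1 * relu1
        cache["relu1"] = relu1
        if p_drop > 0:
            mask1 = (rng.random(h1.shape, dtype=np.float32) < keep).astype(np.float32) / keep
            h1 = h1 * mask1
            cache["drop1"] = mask1
        else:
            cache["drop1"] = None
        cache["dense1_out"] = h1
        logits = self.dense2.forward(h1)
        return _softmax(logits), cache

    def predict_proba(self, patches, batch_size: int = 32) -> np.ndarray:
        """Per-patch class probabilities (columns: non-tumor, tumor).

        Dropout is disabled at inference, so predictions are deterministic
        and duplicated patches score identically.
        """
        x = patches.data if isinstance(patches, PatchSet) else patches
        x = self._check_input(np.asarray(x, dtype=np.float32))
        out = np.empty((x.shape[0], self.spec.classes), dtype=np.float64)
        for s in range(0, x.shape[0], batch_size):
            probs, _ = self._forward(x[s : s + batch_size], training=False, rng=None)
            out[s : s + batch_size] = probs
        return out

    def predict_tumor_probability(self, patches, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(patches, batch_size)[:, 1]

    def _backward(self, x, probs, onehot, cache):
        """Gradients of mean cross-entropy wrt every parameter."""
        n = x.shape[0]
        grads: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        dlogits = ((probs - onehot) / n).astype(np.float32)
        dh1, dw2, db2 = self.dense2.backward(cache["dense1_out"], dlogits)
        if cache["drop1"] is not None:
            dh1 = dh1 * cache["drop1"]
        dz1 = dh1 * cache["relu1"]
        dpooled, dw1, db1 = self.dense1.backward(cache["pooled_in"], dz1)
        _, ph, pw, pc = cache["pre_pool_shape"]
        dh = np.broadcast_to(
            dpooled[:, None, None, :] / np.float32(ph * pw), cache["pre_pool_shape"]
        ).astype(np.float32)
        conv_grads = []
        for k in range(len(self.convs) - 1, -1, -1):
            if cache["drop"][k] is not None:
                dh = dh * cache["drop"][k]
            dz = dh * cache["relu"][k]
            dh, dwk, dbk = self.convs[k].backward(
                cache["inputs"][k], dz, need_dx=(k > 0)
            )
            conv_grads.append((dwk, dbk))
        conv_grads.reverse()
        flat: list[np.ndarray] = []
        for dwk, dbk in conv_grads:
            flat.extend([dwk, dbk])
        flat.extend([dw1, db1, dw2, db2])
        return flat

    # -- training ----------------------------------------------------
    def fit(
        self,
        train_set: PatchSet,
        val_set: PatchSet,
        config: TrainConfig | None = None,
        verbose: bool = False,
    ) -> "PatchClassifierResults":
        """Mini-batch SGD; returns results carrying the best-validation model.

        Training and validation sets must be patient-disjoint; the epoch
        with the highest validation ROC-AUC is kept.
        """
        from .evaluate import roc_auc

        cfg = config or TrainConfig()
        overlap = set(train_set.patient_ids) & set(val_set.patient_ids)
        if overlap:
            raise ValidationError(f"train/validation patient leakage: {sorted(overlap)}")
        n_neg, n_pos = train_set.class_counts()
        if n_neg == 0 or n_pos == 0:
            raise ValidationError("training set must contain both classes")

        x = self._check_input(train_set.data)
        y = train_set.labels.astype(np.int64)
        onehot_all = np.eye(self.spec.classes, dtype=np.float32)[y]
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 11]))

        velocity = [np.zeros_like(p) for p in self.parameters()]
        history = []
        best_auc, best_state, best_epoch = -np.inf, self.get_state(), -1
        val_y = val_set.labels

        for epoch in range(cfg.epochs):
            order = rng.permutation(len(y))
            losses = []
            for s in range(0, len(order), cfg.batch_size):
                idx = order[s : s + cfg.batch_size]
                xb, ob = x[idx], onehot_all[idx]
                probs, cache = self._forward(xb, training=True, rng=rng)
                loss = float(-np.mean(np.log(np.sum(probs * ob, axis=1) + 1e-12)))
                losses.append(loss)
                grads = self._backward(xb, probs, ob, cache)
                for p, v, g in zip(self.parameters(), velocity, grads):
                    v *= np.float32(cfg.momentum)
                    v -= np.float32(cfg.learning_rate) * g
                    p += v
            val_scores = self.predict_tumor_probability(val_set)
            auc = roc_auc(val_scores, val_y)
            auc_val = float(auc) if auc == auc else 0.5  # single-class validation
            history.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auc": auc_val}
            )
            if verbose:
                print(f"epoch {epoch}: loss={np.mean(losses):.4f} val_auc={auc_val:.4f}")
            if auc_val > best_auc:
                best_auc, best_state, best_epoch = auc_val, self.get_state(), epoch

        self.set_state(best_state)
        return PatchClassifierResults(
            model=self,
            config=cfg,
            history=pd.DataFrame(history),
            best_epoch=best_epoch,
            best_val_auc=best_auc,
        )


@dataclass
class PatchClassifierResults:
    """Fit outcome: the selected model, its config and per-epoch history."""

    model: PatchClassifier
    config: TrainConfig
    history: pd.DataFrame
    best_epoch: int
    best_val_auc: float

    def predict_proba(self, patches) -> np.ndarray:
        return self.model.predict_proba(patches)

    def predict_tumor_probability(self, patches) -> np.ndarray:
        return self.model.predict_tumor_probability(patches)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Patch CNN fit summary",
            "=====================",
            f"input: {spec.input_side} x {spec.input_side} x {spec.input_bands}"
            f"   scale: {spec.scale:g}   widths: {spec.scaled_widths()}",
            f"optimizer: SGD(lr={self.config.learning_rate:g}, "
            f"momentum={self.config.momentum:g})   batch={self.config.batch_size}"
            f"   epochs={self.config.epochs}   seed={self.config.seed}",
            f"selected epoch: {self.best_epoch}   validation AUC: {self.best_val_auc:.4f}",
            "",
            self.history.to_string(index=False),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def build_model(spec: ModelSpec, seed: int = 0) -> tuple[PatchClassifier, pd.DataFrame]:
    """Construct the classifier; returns (model, layer shape table)."""
    return PatchClassifier(spec, seed=seed), spec.shape_table()


def train(
    model: PatchClassifier,
    train_set: PatchSet,
    val_set: PatchSet,
    config: TrainConfig | None = None,
    verbose: bool = False,
) -> PatchClassifierResults:
    return model.fit(train_set, val_set, config, verbose=verbose)


def predict_patches(model, patches) -> np.ndarray:
    """Per-patch tumor probability from a model or fit results object."""
    return model.predict_tumor_probability(patches)
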