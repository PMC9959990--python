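"""Hybrid CNN-GRU classifier for three-class nodule slices.

Architecture (fixed structural counts): four valid-padding 3x3 stride-1
convolution layers with rectified-linear activations — the first with 128
feature maps, taking 50x50x3 inputs to 48x48 — with 2x2 max pooling after
the first three conv layers and dropout after the first pooled block;
flatten;
two fully connected layers of 512 units (heavy dropout); the 512-vector
reshaped to an (8, 64) sequence feeding a 512-unit GRU; and a final fully
connected softmax head over the three classes.  The recurrent axis of the
flattened representation is a convention of this package and is
configurable via ``gru_time_steps``.

The reset/update gate equations are exposed as standalone operations
(:func:`gru_reset_gate`, :func:`gru_update_gate`) so they can be verified
against an explicit-loop oracle independently of the trained network.

Training is plain stochastic gradient descent (momentum 0) with softmax
cross-entropy, fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import _nn
from . import imageio as sio


@dataclass(frozen=True)
class GruGateParams:
    """Weights of the two GRU gates (input, hidden, bias per gate)."""

    KXR: np.ndarray
    KXU: np.ndarray
    WhR: np.ndarray
    WhU: np.ndarray
    CR: np.ndarray
    CU: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.KXR.shape[1]


def _gate(u_t, r_prev, kx, wh, bias) -> np.ndarray:
    u_t = np.atleast_2d(np.asarray(u_t, dtype=np.float64))
    r_prev = np.atleast_2d(np.asarray(r_prev, dtype=np.float64))
    kx, wh = np.atleast_2d(kx), np.atleast_2d(wh)
    if u_t.shape[1] != kx.shape[0] or r_prev.shape[1] != wh.shape[0] \
            or kx.shape[1] != wh.shape[1]:
        raise ValueError(
            f"inconsistent gate shapes: input {u_t.shape} x {kx.shape}, "
            f"hidden {r_prev.shape} x {wh.shape}"
        )
    pre = u_t @ kx + r_prev @ wh + np.asarray(bias, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-pre))


def gru_reset_gate(u_t, r_prev, w: GruGateParams) -> np.ndarray:
    """Reset gate: logistic(U_t . KXR + R_{t-1} . WhR + CR), values in (0, 1)."""
    return _gate(u_t, r_prev, w.KXR, w.WhR, w.CR)


def gru_update_gate(u_t, r_prev, w: GruGateParams) -> np.ndarray:
    """Update gate: logistic(U_t . KXU + R_{t-1} . WhU + CU), values in (0, 1)."""
    return _gate(u_t, r_prev, w.KXU, w.WhU, w.CU)


@dataclass(frozen=True)
class CnnGruConfig:
    input_shape: tuple[int, int, int] = (50, 50, 3)
    conv_channels: tuple[int, ...] = (128, 64, 64, 32)
    kernel: int = 3
    stride: int = 1
    n_pool: int = 3
    conv_dropout: float = 0.3
    fc_dropout: float = 0.9
    fc_units: int = 512
    gru_units: int = 512
    gru_time_steps: int = 8
    n_classes: int = 3

    def validate(self) -> None:
        if len(self.conv_channels) != 4:
            raise ValueError("architecture requires exactly 4 conv layers")
        if self.conv_channels[0] != 128:
            raise ValueError("first conv layer is fixed at 128 feature maps")
        if self.n_pool != 3:
            raise ValueError("architecture requires exactly 3 max-pool layers")
        if self.kernel != 3 or self.stride != 1:
            raise ValueError("kernel 3x3 with stride 1 is fixed")
        if self.gru_units != 512:
            raise ValueError("GRU width is fixed at 512 units")
        if self.fc_units % self.gru_time_steps != 0:
            raise ValueError("fc_units must be divisible by gru_time_steps")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.05
    epochs: int = 15
    batch_size: int = 64
    drop_rate: float | None = None  # None -> architecture's printed 0.3/0.9
    clip_norm: float | None = 2.0   # global gradient-norm clip (stability)
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if self.drop_rate is not None and not 0.0 <= self.drop_rate < 1.0:
            raise ValueError("drop_rate must lie in [0, 1)")
        if self.clip_norm is not None and self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")


class CnnGruModel:
    """Model handle: layer stack plus an auditable summary."""

    def __init__(self, cfg: CnnGruConfig, seed: int = 0,
                 drop_rate: float | None = None):
        cfg.validate()
        self.cfg = cfg
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        conv_do = drop_rate if drop_rate is not None else cfg.conv_dropout
        fc_do = drop_rate if drop_rate is not None else cfg.fc_dropout

        h, w, c = cfg.input_shape
        layers: list[_nn.Layer] = []
        desc: list[str] = []
        c_in = c
        for li, c_out in enumerate(cfg.conv_channels):
            layers.append(_nn.Conv2D(c_in, c_out, cfg.kernel, rng))
            h, w = h - cfg.kernel + 1, w - cfg.kernel + 1
            desc.append(f"conv{li + 1}: {c_out} maps, 3x3, stride 1 -> ({h}, {w})")
            layers.append(_nn.ReLU())
            if li < cfg.n_pool:
                layers.append(_nn.MaxPool2())
                h, w = h // 2, w // 2
                desc.append(f"maxpool{li + 1}: 2x2 -> ({h}, {w})")
            if li == 0:  # the conv-path dropout follows the first pooled block
                layers.append(_nn.Dropout(conv_do))
                desc.append(f"dropout: rate {conv_do}")
            c_in = c_out
        layers.append(_nn.Flatten())
        flat = c_in * h * w
        desc.append(f"flatten -> {flat}")
        for fi in range(2):
            n_in = flat if fi == 0 else cfg.fc_units
            layers.append(_nn.Dense(n_in, cfg.fc_units, rng))
            desc.append(f"fc{fi + 1}: {n_in} -> {cfg.fc_units}")
            layers.append(_nn.ReLU())
            layers.append(_nn.Dropout(fc_do))
            desc.append(f"dropout: rate {fc_do}")
        t, f = cfg.gru_time_steps, cfg.fc_units // cfg.gru_time_steps
        layers.append(_nn.Reshape((t, f)))
        desc.append(f"reshape -> ({t}, {f}) sequence")
        layers.append(_nn.GRU(f, cfg.gru_units, rng))
        desc.append(f"gru: {cfg.gru_units} units")
        layers.append(_nn.Dense(cfg.gru_units, cfg.n_classes, rng))
        desc.append(f"fc3: {cfg.gru_units} -> {cfg.n_classes} (softmax)")

        self.net = _nn.Sequential(layers)
        self._desc = desc

    # -- audit -------------------------------------------------------------
    def summary(self) -> dict:
        counts = {
            "n_conv": sum(isinstance(l, _nn.Conv2D) for l in self.net.layers),
            "n_pool": sum(isinstance(l, _nn.MaxPool2) for l in self.net.layers),
            "n_fc": sum(isinstance(l, _nn.Dense) for l in self.net.layers),
            "n_gru": sum(isinstance(l, _nn.GRU) for l in self.net.layers),
        }
        first_conv = next(l for l in self.net.layers if isinstance(l, _nn.Conv2D))
        gru = next(l for l in self.net.layers if isinstance(l, _nn.GRU))
        return {
            **counts,
            "first_conv_maps": first_conv.c_out,
            "first_conv_output": (self.cfg.input_shape[0] - self.cfg.kernel + 1,) * 2,
            "kernel": (self.cfg.kernel, self.cfg.kernel),
            "stride": self.cfg.stride,
            "gru_units": gru.hidden,
            "n_parameters": self.net.n_parameters(),
            "layers": list(self._desc),
        }

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        return self.net.forward(x.astype(_nn.DTYPE), train=train, rng=rng)


def build_model(cfg: CnnGruConfig | None = None, seed: int = 0,
                drop_rate: float | None = None) -> CnnGruModel:
    """Construct the CNN-GRU with seeded initialization."""
    return CnnGruModel(cfg or CnnGruConfig(), seed=seed, drop_rate=drop_rate)


# ---------------------------------------------------------------------------
# data preparation, training, prediction


def prepare_images(images, size: int = 50) -> np.ndarray:
    """Resize grayscale images to (size, size), scale to [-0.5, 0.5]
    (zero-centred for SGD conditioning), and replicate to 3 channels;
    returns (N, 3, size, size) float32."""
    out = np.empty((len(images), 3, size, size), dtype=_nn.DTYPE)
    for i, img in enumerate(images):
        small = resize(np.asarray(img, dtype=np.float64) / 255.0, (size, size),
                       anti_aliasing=True, preserve_range=True)
        out[i] = (small[None] - 0.5).astype(_nn.DTYPE)
    return out


def labels_to_int(labels) -> np.ndarray:
    lookup = {name: k for k, name in enumerate(sio.CLASS_LABELS)}
    try:
        return np.array([lookup[str(l)] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc}") from exc


def _load_from_manifest(manifest) -> tuple[np.ndarray, np.ndarray]:
    import pandas as pd

    if not isinstance(manifest, pd.DataFrame):
        manifest = sio.load_manifest(manifest)
    images = [sio.load_image(p) for p in manifest["path"]]
    return prepare_images(images), labels_to_int(manifest["label"])


def train(model: CnnGruModel, data, tc: TrainConfig | None = None
          ) -> dict[str, list[float]]:
    """Train in place; ``data`` is a manifest (path/DataFrame) or (X, y).

    Returns per-epoch ``loss`` and ``accuracy`` histories.  Requires at
    least two classes in the training labels.
    """
    tc = tc or TrainConfig()
    tc.validate()
    if isinstance(data, tuple):
        X, y = data
        X = np.asarray(X, dtype=_nn.DTYPE)
        y = np.asarray(y, dtype=np.int64)
    else:
        X, y = _load_from_manifest(data)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least two classes")

    rng = np.random.default_rng(tc.seed)
    n = len(X)
    history = {"loss": [], "accuracy": []}
    for _epoch in range(tc.epochs):
        order = rng.permutation(n)
        total_loss, correct = 0.0, 0
        for start in range(0, n, tc.batch_size):
            idx = order[start: start + tc.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.net.forward(xb, train=True, rng=rng)
            loss, dlogits = _nn.softmax_cross_entropy(logits, yb)
            model.net.backward(dlogits)
            model.net.sgd_step(tc.learning_rate, clip_norm=tc.clip_norm)
            total_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history["loss"].append(total_loss / n)
        history["accuracy"].append(correct / n)
    return history


def predict(model: CnnGruModel, images: np.ndarray,
            batch_size: int = 64) -> tuple[np.ndarray, list[str]]:
    """Class probabilities (rows on the simplex) and argmax labels."""
    images = np.asarray(images, dtype=_nn.DTYPE)
    if images.ndim == 3:  # single image (C, H, W)
        images = images[None]
    probs = np.vstack([
        _nn.softmax(model.net.forward(images[s: s + batch_size]).astype(np.float64))
        for s in range(0, len(images), batch_size)
    ])
    labels = [sio.CLASS_LABELS[k] for k in probs.argmax(axis=1)]
    return probs, labels


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: CnnGruModel, path: str | Path) -> None:
    cfg = {k: getattr(model.cfg, k) for k in model.cfg.__dataclass_fields__}
    arrays = {f"p{i}": p for i, p in enumerate(model.net.parameters())}
    np.savez(path, config=json.dumps(cfg, default=list), seed=model.seed, **arrays)


def load_checkpoint(path: str | Path) -> CnnGruModel:
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["config"]))
        for key in ("input_shape", "conv_channels"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = build_model(CnnGruConfig(**cfg_dict), seed=int(data["seed"]))
        for i, p in enumerate(model.net.parameters()):
            p[...] = data[f"p{i}"]
    return model
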