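"""The 29-level inception CNN: declarative architecture, shape tracing,
construction and the training protocol.

The default architecture is a GoogLeNet-style network sized for the
120 x 344 x 1 spectrogram epoch: three stand-alone convolutions (valid
padding), five max-pooling levels (ceil-mode), nine inception blocks
(same padding, canonical GoogLeNet branch allocations, 6 convolutions each),
one 7 x 7 average pooling, 40% dropout and a 2-way fully connected softmax
head. Every convolution is followed by batch normalization and ReLU.

Training uses SGD with momentum 0.9, learning rate 0.01, 30 epochs, a
stratified 20% hold-out validation split evaluated every 50 iterations, and
scalar zero-centering of the input epochs estimated from the training set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import _nn
from .features import SEIZURE_ACTIVE, SEIZURE_FREE, SpectrogramEpoch
from .io import Recording, SeizureAnnotation

__all__ = [
    "LayerSpec",
    "InceptionSpec",
    "ArchitectureSpec",
    "TrainConfig",
    "TrainedModel",
    "default_architecture",
    "shape_trace",
    "count_convolutions",
    "build_model",
    "extract_training_segments",
    "loso_folds",
    "train",
    "predict_epoch",
    "save_model",
    "load_model",
]

CLASS_NAMES = (SEIZURE_FREE, SEIZURE_ACTIVE)  # class index 0, 1

#: Canonical GoogLeNet inception branch allocations (1x1, 1x1->3x3, 1x1->5x5,
#: pool->1x1); their totals reproduce the nine printed output widths
#: 256, 480, 512, 512, 512, 528, 832, 832, 1024.
CANONICAL_INCEPTIONS: tuple[tuple[int, tuple[int, int], tuple[int, int], int], ...] = (
    (64, (96, 128), (16, 32), 32),
    (128, (128, 192), (32, 96), 64),
    (192, (96, 208), (16, 48), 64),
    (160, (112, 224), (24, 64), 64),
    (128, (128, 256), (24, 64), 64),
    (112, (144, 288), (32, 64), 64),
    (256, (160, 320), (32, 128), 128),
    (256, (160, 320), (32, 128), 128),
    (384, (192, 384), (48, 128), 128),
)


@dataclass(frozen=True)
class InceptionSpec:
    """Branch allocation of one inception block."""

    b1: int
    b2: tuple[int, int]
    b3: tuple[int, int]
    b4: int

    @property
    def out_channels(self) -> int:
        return self.b1 + self.b2[1] + self.b3[1] + self.b4

    @property
    def n_convolutions(self) -> int:
        return 6


@dataclass(frozen=True)
class LayerSpec:
    """One level of the architecture table."""

    kind: str  # input | conv | maxpool | avgpool | inception | dropout | fc | softmax
    level: int | None = None
    kernel: tuple[int, int] | None = None
    stride: tuple[int, int] | None = None
    channels: int | None = None
    rate: float | None = None
    inception: InceptionSpec | None = None


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer table plus input geometry."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (120, 344, 1)
    n_classes: int = 2

    @property
    def n_levels(self) -> int:
        """Highest level number in the table (inceptions span two levels)."""
        return max(l.level for l in self.layers if l.level is not None)

    def count(self, kind: str) -> int:
        return sum(1 for l in self.layers if l.kind == kind)


def _scale(c: int, width: float) -> int:
    return max(1, int(round(c * width)))


def default_architecture(width: float = 1.0) -> ArchitectureSpec:
    """The default 29-level architecture for 120 x 344 x 1 epochs.

    ``width`` < 1 shrinks every convolution's channel count proportionally
    (minimum 1 per branch) while preserving the topology; inception output
    widths become the sum of their scaled branches. The default ``width=1``
    reproduces the reference layer table exactly.
    """
    inceptions = [
        InceptionSpec(_scale(b1, width), (_scale(b2[0], width), _scale(b2[1], width)),
                      (_scale(b3[0], width), _scale(b3[1], width)), _scale(b4, width))
        for (b1, b2, b3, b4) in CANONICAL_INCEPTIONS
    ]
    ls: list[LayerSpec] = [LayerSpec(kind="input")]

    def conv(level, kernel, channels):
        ls.append(LayerSpec(kind="conv", level=level, kernel=kernel, stride=(1, 1),
                            channels=_scale(channels, width)))

    def pool(level, kernel, stride, kind="maxpool"):
        ls.append(LayerSpec(kind=kind, level=level, kernel=kernel, stride=stride))

    def inception(level, idx):
        spec = inceptions[idx]
        ls.append(LayerSpec(kind="inception", level=level, channels=spec.out_channels,
                            inception=spec))

    conv(1, (5, 3), 64)
    pool(2, (1, 3), (1, 3))
    conv(3, (5, 3), 64)
    pool(4, (3, 3), (2, 2))
    conv(5, (1, 1), 192)
    pool(6, (2, 2), (2, 2))
    inception(7, 0)
    inception(9, 1)
    pool(11, (3, 3), (2, 2))
    inception(12, 2)
    inception(14, 3)
    inception(16, 4)
    inception(18, 5)
    inception(20, 6)
    pool(22, (3, 3), (2, 2))
    inception(23, 7)
    inception(25, 8)
    pool(27, (7, 7), (1, 1), kind="avgpool")
    ls.append(LayerSpec(kind="dropout", level=28, rate=0.4))
    ls.append(LayerSpec(kind="fc", level=29, channels=2))
    ls.append(LayerSpec(kind="softmax"))
    return ArchitectureSpec(layers=tuple(ls))


def shape_trace(spec: ArchitectureSpec) -> list[tuple[LayerSpec, tuple, tuple]]:
    """Per-level (input_shape, output_shape) trace in (H, W, C) form.

    Stand-alone convolutions use valid padding, inception convolutions same
    padding (spatial size preserved), max pooling ceil-mode, average pooling
    an exact fit. Raises :class:`ValueError` naming the level when any shape
    becomes inconsistent.
    """
    shape = spec.input_shape
    out: list[tuple[LayerSpec, tuple, tuple]] = []
    for layer in spec.layers:
        h, w, c = shape
        name = f"level {layer.level}" if layer.level is not None else layer.kind
        if layer.kind == "input":
            new = shape
        elif layer.kind == "conv":
            kh, kw = layer.kernel
            sh, sw = layer.stride
            nh, nw = (h - kh) // sh + 1, (w - kw) // sw + 1
            if h < kh or w < kw:
                raise ValueError(f"{name}: kernel {layer.kernel} exceeds input {h}x{w}")
            new = (nh, nw, layer.channels)
        elif layer.kind == "maxpool":
            ph, pw = layer.kernel
            sh, sw = layer.stride
            try:
                new = (_nn.MaxPool.ceil_out(h, ph, sh), _nn.MaxPool.ceil_out(w, pw, sw), c)
            except ValueError as exc:
                raise ValueError(f"{name}: {exc}") from None
        elif layer.kind == "avgpool":
            ph, pw = layer.kernel
            sh, sw = layer.stride
            if h < ph or w < pw or (h - ph) % sh or (w - pw) % sw:
                raise ValueError(f"{name}: average pool {layer.kernel} does not fit {h}x{w}")
            new = ((h - ph) // sh + 1, (w - pw) // sw + 1, c)
        elif layer.kind == "inception":
            new = (h, w, layer.inception.out_channels)
        elif layer.kind == "dropout":
            new = shape
        elif layer.kind == "fc":
            new = (1, 1, layer.channels)
        elif layer.kind == "softmax":
            new = shape
        else:
            raise ValueError(f"{name}: unknown layer kind {layer.kind!r}")
        out.append((layer, shape, new))
        shape = new
    return out


def count_convolutions(spec: ArchitectureSpec) -> tuple[int, int]:
    """(stand-alone convolutions, convolutions inside inception blocks)."""
    standalone = spec.count("conv")
    inception_internal = sum(
        l.inception.n_convolutions for l in spec.layers if l.kind == "inception"
    )
    return standalone, inception_internal


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (defaults are the reference protocol)."""

    learning_rate: float = 0.01
    epochs: int = 30
    val_fraction: float = 0.20
    val_frequency: int = 50
    batch_size: int = 32
    momentum: float = 0.9
    seed: int = 0
    class_weighting: bool = False
    early_stop_train_acc: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainedModel:
    """An (optionally trained) network plus its normalization and history."""

    spec: ArchitectureSpec
    net: _nn.Sequential
    mean_offset: float = 0.0
    history: dict = field(default_factory=dict)

    def predict_proba(self, epochs: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch of epochs (n, H, W) or one (H, W)."""
        x = np.asarray(epochs, dtype=np.float32)
        single = x.ndim == 2
        if single:
            x = x[None]
        h, w, _ = self.spec.input_shape
        if x.shape[1:] != (h, w):
            raise ValueError(f"epoch shape {x.shape[1:]} != model input {(h, w)}")
        x = (x - np.float32(self.mean_offset))[..., None]
        logits = self.net.forward(x, train=False)
        probs = _nn.softmax(logits)
        return probs[0] if single else probs


def build_model(spec: ArchitectureSpec, seed: int = 0) -> TrainedModel:
    """Construct the network from a (shape-consistent) architecture spec.

    Every convolution is followed by batch normalization and ReLU; weights
    are drawn reproducibly from ``seed``.
    """
    trace = shape_trace(spec)  # validates shape consistency
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    for layer, in_shape, out_shape in trace:
        if layer.kind in ("input", "softmax"):
            continue
        if layer.kind == "conv":
            layers.extend(
                _nn.conv_bn_relu(in_shape[2], layer.channels, layer.kernel,
                                 stride=layer.stride, padding="valid", rng=rng)
            )
        elif layer.kind == "maxpool":
            layers.append(_nn.MaxPool(layer.kernel, stride=layer.stride, mode="ceil"))
        elif layer.kind == "avgpool":
            layers.append(_nn.AvgPool(layer.kernel, stride=layer.stride))
        elif layer.kind == "inception":
            s = layer.inception
            layers.append(_nn.Inception(in_shape[2], s.b1, s.b2, s.b3, s.b4, rng=rng))
        elif layer.kind == "dropout":
            layers.append(_nn.Dropout(layer.rate))
        elif layer.kind == "fc":
            layers.append(_nn.Flatten())
            layers.append(_nn.Dense(in_shape[0] * in_shape[1] * in_shape[2],
                                    layer.channels, rng=rng))
    return TrainedModel(spec=spec, net=_nn.Sequential(layers))


# ---------------------------------------------------------------------------
# Training protocol
# ---------------------------------------------------------------------------

def extract_training_segments(
    rec: Recording,
    ann: SeizureAnnotation,
    pre_min: float = 10.0,
    post_min: float = 5.0,
) -> list[tuple[float, float]]:
    """Per-seizure training spans: [onset - pre, onset + post], clipped and merged.

    Defaults take 10 minutes before and 5 minutes after each seizure onset;
    overlapping spans are merged.
    """
    spans = []
    for onset, _ in ann.intervals:
        lo = max(0.0, onset - pre_min * 60.0)
        hi = min(rec.duration_s, onset + post_min * 60.0)
        if hi > lo:
            spans.append((lo, hi))
    spans.sort()
    merged: list[tuple[float, float]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def loso_folds(dataset: Mapping[str, object]) -> list[tuple[list[str], str]]:
    """Leave-one-subject-out folds: one per subject, each subject tested once."""
    subjects = sorted(dataset)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out requires at least 2 subjects")
    return [([s for s in subjects if s != test], test) for test in subjects]


def _stratified_split(
    y: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train(
    model: TrainedModel,
    epochs_data: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
) -> TrainedModel:
    """Train in place with seeded SGD + momentum and hold-out validation.

    ``epochs_data`` is (n, H, W) of dB values; ``labels`` holds class indices
    (0 seizure-free, 1 seizure-active). The scalar mean of the training split
    is stored on the model and subtracted from every input. History records
    (iteration, loss, batch accuracy) per iteration and validation accuracy
    every ``cfg.val_frequency`` iterations and at the end of training.
    """
    x = np.asarray(epochs_data, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    for layer in model.net.all_layers():
        if isinstance(layer, _nn.Dropout):
            layer.rng = rng

    tr_idx, val_idx = _stratified_split(y, cfg.val_fraction, rng)
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    model.mean_offset = float(x_tr.mean())
    off = np.float32(model.mean_offset)

    class_weights = None
    if cfg.class_weighting:
        counts = np.bincount(y_tr, minlength=model.spec.n_classes).astype(np.float64)
        class_weights = counts.sum() / np.maximum(counts, 1) / model.spec.n_classes

    opt = _nn.SGDMomentum([model.net], lr=cfg.learning_rate, momentum=cfg.momentum)
    history = {
        "iteration": [], "loss": [], "train_acc": [],
        "val_iteration": [], "val_acc": [],
        "n_train": int(len(tr_idx)), "n_val": int(len(val_idx)),
    }

    def val_accuracy() -> float:
        if len(y_val) == 0:
            return float("nan")
        preds = []
        for i in range(0, len(x_val), cfg.batch_size):
            xb = (x_val[i : i + cfg.batch_size] - off)[..., None]
            preds.append(model.net.forward(xb, train=False).argmax(axis=-1))
        return 100.0 * float(np.mean(np.concatenate(preds) == y_val))

    it = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        epoch_correct = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb = (x_tr[batch] - off)[..., None]
            yb = y_tr[batch]
            logits = model.net.forward(xb, train=True)
            loss, probs, grad = _nn.softmax_cross_entropy(logits, yb, class_weights)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at iteration {it} (epoch {epoch}); "
                    "check input scaling or lower the learning rate"
                )
            model.net.backward(grad)
            opt.step()
            it += 1
            batch_correct = int((probs.argmax(axis=-1) == yb).sum())
            epoch_correct += batch_correct
            history["iteration"].append(it)
            history["loss"].append(loss)
            history["train_acc"].append(100.0 * batch_correct / len(yb))
            if it % cfg.val_frequency == 0:
                history["val_iteration"].append(it)
                history["val_acc"].append(val_accuracy())
        train_acc = 100.0 * epoch_correct / len(x_tr)
        if cfg.early_stop_train_acc is not None and train_acc >= cfg.early_stop_train_acc:
            break
    if not history["val_iteration"] or history["val_iteration"][-1] != it:
        history["val_iteration"].append(it)
        history["val_acc"].append(val_accuracy())
    model.history = history
    return model


def predict_epoch(
    model: TrainedModel, epoch: SpectrogramEpoch | np.ndarray
) -> tuple[str, float]:
    """Classify one epoch; returns (label, probability of seizure-active)."""
    values = epoch.values if isinstance(epoch, SpectrogramEpoch) else epoch
    probs = model.predict_proba(values)
    label = CLASS_NAMES[int(probs.argmax())]
    return label, float(probs[1])


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: ArchitectureSpec) -> dict:
    layers = []
    for l in spec.layers:
        d = {"kind": l.kind, "level": l.level, "kernel": l.kernel, "stride": l.stride,
             "channels": l.channels, "rate": l.rate}
        if l.inception is not None:
            d["inception"] = [l.inception.b1, list(l.inception.b2),
                              list(l.inception.b3), l.inception.b4]
        layers.append(d)
    return {"layers": layers, "input_shape": list(spec.input_shape),
            "n_classes": spec.n_classes}


def _spec_from_dict(d: dict) -> ArchitectureSpec:
    layers = []
    for ld in d["layers"]:
        inc = None
        if "inception" in ld:
            b1, b2, b3, b4 = ld["inception"]
            inc = InceptionSpec(b1, tuple(b2), tuple(b3), b4)
        layers.append(
            LayerSpec(
                kind=ld["kind"], level=ld["level"],
                kernel=tuple(ld["kernel"]) if ld["kernel"] else None,
                stride=tuple(ld["stride"]) if ld["stride"] else None,
                channels=ld["channels"], rate=ld["rate"], inception=inc,
            )
        )
    return ArchitectureSpec(tuple(layers), tuple(d["input_shape"]), d["n_classes"])


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Save weights, batch-norm statistics, spec and normalization to .npz."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.net.all_layers()):
        for j, p in enumerate(layer.params):
            arrays[f"p_{i}_{j}"] = p
        if isinstance(layer, _nn.BatchNorm):
            arrays[f"rm_{i}"] = layer.running_mean
            arrays[f"rv_{i}"] = layer.running_var
    meta = {"spec": _spec_to_dict(model.spec), "mean_offset": model.mean_offset}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    return path


def load_model(path: str | Path) -> TrainedModel:
    """Load a checkpoint written by :func:`save_model`."""
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    model = build_model(_spec_from_dict(meta["spec"]), seed=0)
    model.mean_offset = float(meta["mean_offset"])
    for i, layer in enumerate(model.net.all_layers()):
        for j, p in enumerate(layer.params):
            p[...] = data[f"p_{i}_{j}"]
        if isinstance(layer, _nn.BatchNorm):
            layer.running_mean[...] = data[f"rm_{i}"]
            layer.running_var[...] = data[f"rv_{i}"]
    return model
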