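"""Convolutional-recurrent word classifier and its training protocol.

The architecture: a stem (conv + batch norm + ReLU) adapts the single-plane
256 × 256 input tensor; a residual convolutional trunk (basic blocks, no
final fully-connected/softmax of its own) extracts a feature map; the map's
columns are read as a left-to-right sequence and fed to a 2-layer GRU with
1024 hidden units; the GRU's last hidden state is average-pooled with width
2 down to 512 values, passed through a fully connected layer with ReLU, and
projected to class probabilities with softmax.

Training follows a fixed protocol: Adam, mini-batches of 16, learning rate
0.01 divided by 10 after steps 500 and 1000, up to 2500 steps, with a
stratified 70/20/10 train/validation/test split plus optional out-of-sample
subjects held out entirely.  A "lite" preset (2 residual stages, width 16,
GRU hidden 64, 64 × 64 input) keeps desk-scale experiments on one CPU core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import GRU, Adam, BatchNorm2d, Conv2d, Linear, Module, Tensor
from .nn.autograd import add, avg_pool1d, cross_entropy, relu, reshape, softmax
from .tensorize import InputTensor

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "Splits",
    "EvalReport",
    "WordClassifier",
    "TrainingDivergedError",
    "build_model",
    "split_dataset",
    "train",
    "evaluate",
    "save_model",
    "load_model",
    "prepare_inputs",
]

log = logging.getLogger(__name__)

#: stage widths / block counts / input size per trunk preset
_PRESETS: dict = {
    "lite": dict(widths=(16, 32), blocks=(1, 1), strides=(1, 2), input_size=64, stem_k=3),
    18: dict(widths=(64, 128, 256, 512), blocks=(2, 2, 2, 2), strides=(2, 2, 2, 2),
             input_size=256, stem_k=7),
    50: dict(widths=(64, 128, 256, 512), blocks=(3, 4, 6, 3), strides=(2, 2, 2, 2),
             input_size=256, stem_k=7),
    101: dict(widths=(64, 128, 256, 512), blocks=(3, 4, 23, 3), strides=(2, 2, 2, 2),
              input_size=256, stem_k=7),
}


class TrainingDivergedError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs; the defaults reproduce the full-size network."""

    trunk_depth: int | str = 18  # 18 | 50 | 101 | "lite" (depth/width knob)
    stem: bool = True
    gru_layers: int = 2
    gru_hidden: int = 1024
    pool_width: int = 2
    n_classes: int = 9

    def __post_init__(self) -> None:
        if self.trunk_depth not in _PRESETS:
            raise ValueError(f"unknown trunk preset {self.trunk_depth!r}")
        if self.gru_hidden % self.pool_width:
            raise ValueError("gru_hidden must be divisible by pool_width")

    @property
    def fc_input(self) -> int:
        """Width of the fully connected layer's input after pooling."""
        return self.gru_hidden // self.pool_width

    @property
    def input_size(self) -> int:
        return _PRESETS[self.trunk_depth]["input_size"]

    @classmethod
    def lite(cls, n_classes: int = 9) -> "ModelConfig":
        return cls(trunk_depth="lite", gru_hidden=64, n_classes=n_classes)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol and data split."""

    batch_size: int = 16
    lr0: float = 0.01
    lr_boundaries: tuple[int, ...] = (500, 1000)
    max_iter: int = 2500
    split: tuple[float, float, float] = (0.7, 0.2, 0.1)
    out_of_sample_subjects: tuple[str, ...] = ()
    seed: int = 0
    eval_every: int = 50

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


class _BasicBlock(Module):
    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride=stride, padding=0, rng=rng)
            self.proj_bn = BatchNorm2d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        y = relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        skip = x if self.proj is None else self.proj_bn(self.proj(x))
        return relu(add(y, skip))


class WordClassifier(Module):
    """Residual CNN trunk + stacked GRU + pooled fully-connected head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        preset = _PRESETS[cfg.trunk_depth]
        widths, blocks, strides = preset["widths"], preset["blocks"], preset["strides"]
        self.cfg = cfg

        self.stem_conv = Conv2d(1, widths[0], preset["stem_k"], stride=2,
                                padding=preset["stem_k"] // 2, rng=rng)
        self.stem_bn = BatchNorm2d(widths[0]) if cfg.stem else None

        stages: list[_BasicBlock] = []
        cin = widths[0]
        for w, nb, s in zip(widths, blocks, strides):
            for b in range(nb):
                stages.append(_BasicBlock(cin, w, s if b == 0 else 1, rng))
                cin = w
        self.stages = stages

        spatial = cfg.input_size // 2
        for s in strides:
            spatial //= s
        self.final_height = spatial
        self.seq_len = spatial
        self.gru_in = widths[-1] * spatial
        self.gru = GRU(self.gru_in, cfg.gru_hidden, cfg.gru_layers, rng=rng)
        self.fc = Linear(cfg.fc_input, cfg.fc_input, rng=rng, bias_init=0.01)
        self.out = Linear(cfg.fc_input, cfg.n_classes, rng=rng)

    @property
    def fc_in_features(self) -> int:
        return self.cfg.fc_input

    def logits(self, x: np.ndarray) -> Tensor:
        """Forward pass returning the pre-softmax class scores.

        ``x`` is (N, 1, S, S) with S the preset's input size.
        """
        t = Tensor(np.asarray(x, dtype=float))
        y = self.stem_conv(t)
        if self.stem_bn is not None:
            y = relu(self.stem_bn(y))
        for block in self.stages:
            y = block(y)
        n, c, h, w = y.data.shape
        # feature-map columns become the GRU's time axis
        seq = _transpose_seq(reshape(y, (n, c * h, w)))
        h_last = self.gru(seq)
        pooled = avg_pool1d(h_last, self.cfg.pool_width)
        hidden = relu(self.fc(pooled))
        return self.out(hidden)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        was_training = self.training
        self.eval()
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.logits(x[i:i + batch_size]).data))
        if was_training:
            self.train()
        return np.concatenate(out)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def _transpose_seq(x: Tensor) -> Tensor:
    """(N, F, T) → (N, T, F) inside the graph."""
    from .nn.autograd import _node

    def backward(g):
        if x.requires_grad:
            x.accumulate(g.transpose(0, 2, 1))
    return _node(x.data.transpose(0, 2, 1), (x,), backward)


def build_model(cfg: ModelConfig, seed: int = 0) -> WordClassifier:
    """Construct the classifier with seed-controlled initialization."""
    return WordClassifier(cfg, rng=np.random.default_rng(seed))


# --- data handling ----------------------------------------------------------

@dataclass(eq=False)
class Splits:
    """Train/validation/test partitions plus held-out subjects."""

    train: list[InputTensor]
    val: list[InputTensor]
    test: list[InputTensor]
    out_of_sample: list[InputTensor]
    classes: list[str]

    def arrays(self, which: str, input_size: int) -> tuple[np.ndarray, np.ndarray]:
        tensors = getattr(self, which)
        return prepare_inputs(tensors, input_size, self.classes)


def prepare_inputs(
    tensors: list[InputTensor], input_size: int, classes: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack tensors into a model-ready array plus integer labels.

    Tensors are reduced to the preset's input size by index-mask striding
    (keeping raw sample values rather than smoothing them away) and
    standardized per tensor.
    """
    if not tensors:
        return np.zeros((0, 1, input_size, input_size)), np.zeros(0, dtype=int)
    label_to_idx = {c: i for i, c in enumerate(classes)}
    step = tensors[0].data.shape[0] // input_size
    xs, ys = [], []
    for t in tensors:
        img = t.data[::step, ::step][:input_size, :input_size]
        mu, sd = img.mean(), img.std()
        xs.append((img - mu) / (sd if sd > 1e-12 else 1.0))
        ys.append(label_to_idx[t.label])
    return np.stack(xs)[:, None, :, :], np.array(ys, dtype=int)


def split_dataset(tensors: list[InputTensor], cfg: TrainConfig) -> Splits:
    """Stratified 70/20/10 split at the *epoch* level.

    Both Sample 01 and Sample 02 tensors of one epoch always land in the
    same partition (no within-trial leakage), splits are stratified by
    word, and out-of-sample subjects are excluded from all three partitions.
    """
    oos = [t for t in tensors if t.subject_id in cfg.out_of_sample_subjects]
    pool = [t for t in tensors if t.subject_id not in cfg.out_of_sample_subjects]
    for s in cfg.out_of_sample_subjects:
        if not any(t.subject_id == s for t in tensors):
            log.warning("out-of-sample subject %r not present in the data", s)

    groups: dict[tuple, list[InputTensor]] = {}
    for t in pool:
        groups.setdefault((t.subject_id, t.session_id, t.epoch_id), []).append(t)
    by_class: dict[str, list[list[InputTensor]]] = {}
    for key in sorted(groups):
        grp = groups[key]
        by_class.setdefault(grp[0].label, []).append(grp)

    rng = np.random.default_rng(cfg.seed)
    f_train, f_val, _ = cfg.split
    train, val, test = [], [], []
    for label in sorted(by_class):
        grps = by_class[label]
        rng.shuffle(grps)
        n = len(grps)
        n_tr = int(round(f_train * n))
        n_val = int(round(f_val * n))
        for i, g in enumerate(grps):
            dest = train if i < n_tr else val if i < n_tr + n_val else test
            dest.extend(g)
    classes = sorted({t.label for t in tensors})
    return Splits(train=train, val=val, test=test, out_of_sample=oos, classes=classes)


# --- training & evaluation --------------------------------------------------

def train(
    model: WordClassifier, splits: Splits, cfg: TrainConfig
) -> tuple[WordClassifier, pd.DataFrame]:
    """Cross-entropy training with the fixed Adam protocol.

    Deterministic given ``cfg.seed`` (batch order) and the model's init
    seed.  The validation set is only ever measured, never used to adjust
    weights.  Raises :class:`TrainingDivergedError` on non-finite loss.
    """
    size = model.cfg.input_size
    x_train, y_train = splits.arrays("train", size)
    x_val, y_val = splits.arrays("val", size)
    if x_train.shape[0] == 0:
        raise ValueError("empty training split")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr0)
    model.train()
    history: list[dict] = []
    order = rng.permutation(x_train.shape[0])
    cursor = 0
    for it in range(1, cfg.max_iter + 1):
        if cursor + cfg.batch_size > order.size:
            order = rng.permutation(x_train.shape[0])
            cursor = 0
        idx = order[cursor:cursor + cfg.batch_size]
        cursor += cfg.batch_size
        opt.lr = Adam.scheduled_lr(cfg.lr0, it, cfg.lr_boundaries)
        opt.zero_grad()
        loss = cross_entropy(model.logits(x_train[idx]), y_train[idx])
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise TrainingDivergedError(f"loss became {loss_val} at iteration {it}")
        loss.backward()
        opt.step()
        rec = dict(iteration=it, lr=opt.lr, train_loss=loss_val, val_accuracy=np.nan)
        if x_val.shape[0] and (it % cfg.eval_every == 0 or it == cfg.max_iter):
            rec["val_accuracy"] = float(
                (model.predict(x_val) == y_val).mean() * 100.0
            )
            model.train()
        history.append(rec)
    return model, pd.DataFrame(history)


@dataclass(eq=False)
class EvalReport:
    """Per-split accuracy (%) and loss, plus the test confusion matrix."""

    accuracy: dict[str, float | None]
    loss: dict[str, float | None]
    confusion: np.ndarray
    classes: list[str]

    def as_dict(self) -> dict:
        return dict(
            accuracy=self.accuracy, loss=self.loss,
            confusion=self.confusion.tolist(), classes=self.classes,
        )


def save_model(model: WordClassifier, path) -> None:
    """Serialize parameters, normalization statistics and config to .npz."""
    import json
    from dataclasses import asdict

    arrays = model.state_arrays()
    np.savez(
        path,
        cfg=json.dumps(asdict(model.cfg)),
        **{f"arr_{i}": a for i, a in enumerate(arrays)},
    )


def load_model(path) -> WordClassifier:
    import json

    with np.load(path, allow_pickle=False) as f:
        cfg_d = json.loads(str(f["cfg"]))
        depth = cfg_d.pop("trunk_depth")
        cfg = ModelConfig(trunk_depth=depth if depth == "lite" else int(depth), **cfg_d)
        model = build_model(cfg)
        for i, target in enumerate(model.state_arrays()):
            target[...] = f[f"arr_{i}"]
    return model


def evaluate(model: WordClassifier, splits: Splits) -> EvalReport:
    """Accuracy and cross-entropy loss on all four partitions.

    Empty partitions are reported as None; the confusion matrix is over the
    test partition (rows = true class, columns = predicted).
    """
    size = model.cfg.input_size
    accuracy: dict[str, float | None] = {}
    loss: dict[str, float | None] = {}
    n_classes = model.cfg.n_classes
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for part in ("train", "val", "test", "out_of_sample"):
        x, y = splits.arrays(part, size)
        if x.shape[0] == 0:
            accuracy[part] = None
            loss[part] = None
            continue
        p = model.predict_proba(x)
        pred = p.argmax(axis=1)
        accuracy[part] = float((pred == y).mean() * 100.0)
        eps = np.finfo(float).tiny
        loss[part] = float(-np.mean(np.log(p[np.arange(y.size), y] + eps)))
        if part == "test":
            for yi, pi in zip(y, pred):
                confusion[yi, pi] += 1
    return EvalReport(accuracy=accuracy, loss=loss, confusion=confusion,
                      classes=splits.classes)
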