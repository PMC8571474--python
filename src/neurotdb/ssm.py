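"""The three-module tracing-difficulty classifier.

* SFE (structure feature extraction): a volumetric residual network over
  32×64×64 image blocks and a 3-layer fully connected network over the
  32 morphometrics of the automatic reconstruction; each emits a 2-vector.
* SIE (sequence information extraction): two 2-layer, 10-hidden-unit LSTMs
  consuming, per step, the one-hot label context concatenated with the SFE
  output of that step's block.  The target step's label context is a zero
  vector; earlier steps carry previously predicted labels at inference and,
  during training, either the frozen SFE branch's predictions (default,
  matching the inference distribution) or ground truth (teacher forcing) —
  see ``TrainConfig.context_source``.
* MF (model fusion): concatenation of the two SIE outputs followed by a
  2-layer fully connected network with softmax.

Training is staged: SFE branches alone, then SIE with SFE frozen, then all
modules jointly through MF.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .blocks import Block
from .labeling import HIGH, LABELS, LOW
from .metrics import lmeasure_features
from .nn import (
    LSTM,
    Adam,
    AvgPool3d,
    BatchNorm3d,
    Conv3d,
    Dropout,
    Linear,
    MaxPool3d,
    Module,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)
from .sequences import ORDER_INDEX_STEP, are_adjacent

__all__ = [
    "SfeImageConfig",
    "SfeAutoConfig",
    "SieConfig",
    "MfConfig",
    "TrainConfig",
    "SfeImageNet",
    "SfeAutoNet",
    "SieNet",
    "MfNet",
    "SsmModel",
    "sfe_image_forward",
    "sfe_auto_forward",
    "sie_forward",
    "mf_forward",
    "augment_rotations",
    "normalize_image",
    "train_stagewise",
    "evaluate",
    "accuracy_f1",
]

BLOCK_SHAPE = (32, 64, 64)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class SfeImageConfig:
    """Image-branch residual network.

    ``base_channels=64`` reproduces the reference architecture; smaller
    values keep the identical stage/stride layout for CPU-scale training.
    """

    base_channels: int = 64
    dropout: float = 0.2
    n_classes: int = 2


@dataclass
class SfeAutoConfig:
    input_width: int = 32
    widths: Tuple[int, ...] = (100, 50, 2)


@dataclass
class SieConfig:
    hidden_size: int = 10
    num_layers: int = 2
    input_size: int = 4  # one-hot label context (2) ⊕ SFE output (2)
    output_size: int = 2


@dataclass
class MfConfig:
    widths: Tuple[int, ...] = (30, 2)
    input_size: int = 4  # cat(O_Is, O_As)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    betas: Tuple[float, float] = (0.9, 0.99)
    batch_size: int = 30
    weight_decay: float = 0.01
    epochs_sfe: int = 30
    epochs_sie: int = 20
    epochs_mf_warmup: int = 30  # fusion head alone, on frozen branch outputs
    epochs_joint: int = 20
    sequence_length: int = 3
    augment: bool = True
    # label context fed to the recurrent stage for steps 1..s−1 during
    # training: "predicted" uses the frozen SFE branch's own predictions
    # (matches the inference-time context distribution), "truth" is strict
    # teacher forcing
    context_source: str = "predicted"
    seed: int = 0
    runs: int = 5
    base_channels: int = 64


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class _ResidualUnit(Module):
    """Basic two-convolution residual unit.

    Unit A keeps the spatial size (identity skip); unit B halves it
    (stride-2 first convolution with a 1×1×1 stride-2 projection skip).
    """

    def __init__(self, in_channels: int, channels: int, stride: int, rng):
        super().__init__()
        self.conv1 = self.register(
            "conv1", Conv3d(in_channels, channels, 3, stride=stride, padding=1, rng=rng)
        )
        self.bn1 = self.register("bn1", BatchNorm3d(channels))
        self.relu1 = self.register("relu1", ReLU())
        self.conv2 = self.register(
            "conv2", Conv3d(channels, channels, 3, stride=1, padding=1, rng=rng)
        )
        self.bn2 = self.register("bn2", BatchNorm3d(channels))
        self.relu_out = self.register("relu_out", ReLU())
        if stride != 1 or in_channels != channels:
            self.proj = self.register(
                "proj", Conv3d(in_channels, channels, 1, stride=stride, rng=rng)
            )
            self.proj_bn = self.register("proj_bn", BatchNorm3d(channels))
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x, train: bool = False):
        main = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, train), train), train
        )
        main = self.bn2.forward(self.conv2.forward(main, train), train)
        skip = x
        if self.proj is not None:
            skip = self.proj_bn.forward(self.proj.forward(x, train), train)
        return self.relu_out.forward(main + skip, train)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        dmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(grad))))
        )
        if self.proj is not None:
            dskip = self.proj.backward(self.proj_bn.backward(grad))
        else:
            dskip = grad
        return dmain + dskip


class SfeImageNet(Module):
    """Volumetric residual classifier over (N, 1, 32, 64, 64) inputs.

    Stage layout (output spatial sizes for the reference input):
    conv 3³/64 stride (1,2,2) → 32³; max-pool 3³ stride 2 → 16³; four
    residual layers (dropout 0.2 at entry, units [A,A], [B,A], [B,A],
    [B,A]) → 16³, 8³, 4³, 2³; average-pool 2³ → 1³; fully connected → 2.
    """

    STAGES = ("conv", "maxpool", "layer1", "layer2", "layer3", "layer4", "avgpool", "fc")

    def __init__(self, config: SfeImageConfig = SfeImageConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        self.conv1 = self.register(
            "conv1", Conv3d(1, c, 3, stride=(1, 2, 2), padding=1, rng=rng)
        )
        self.bn1 = self.register("bn1", BatchNorm3d(c))
        self.relu1 = self.register("relu1", ReLU())
        self.maxpool = self.register("maxpool", MaxPool3d(3, stride=2, padding=1))
        specs = [(c, c, 1), (c, 2 * c, 2), (2 * c, 4 * c, 2), (4 * c, 8 * c, 2)]
        self.layers: List[Sequential] = []
        for i, (cin, cout, stride) in enumerate(specs, start=1):
            layer = Sequential(
                Dropout(config.dropout, rng),
                _ResidualUnit(cin, cout, stride, rng),
                _ResidualUnit(cout, cout, 1, rng),
            )
            self.register(f"layer{i}", layer)
            self.layers.append(layer)
        self.avgpool = self.register("avgpool", AvgPool3d(2))
        self.fc = self.register("fc", Linear(8 * c, config.n_classes, rng))
        self._flat_shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != 1 or x.shape[2:] != BLOCK_SHAPE:
            raise ValueError(
                f"expected input of shape (N, 1, {BLOCK_SHAPE[0]}, {BLOCK_SHAPE[1]},"
                f" {BLOCK_SHAPE[2]}), got {x.shape}"
            )
        for _, out in self._staged_forward(x, train):
            pass
        return out

    def _staged_forward(self, x, train: bool):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        yield "conv", out
        out = self.maxpool.forward(out, train)
        yield "maxpool", out
        for i, layer in enumerate(self.layers, start=1):
            out = layer.forward(out, train)
            yield f"layer{i}", out
        out = self.avgpool.forward(out, train)
        yield "avgpool", out
        self._flat_shape = out.shape
        out = self.fc.forward(out.reshape(out.shape[0], -1), train)
        yield "fc", out

    def stage_output_shapes(self, x: np.ndarray) -> Dict[str, Tuple[int, ...]]:
        """Spatial/feature sizes of every stage for one forward pass."""
        shapes: Dict[str, Tuple[int, ...]] = {}
        for name, out in self._staged_forward(x, train=False):
            shapes[name] = tuple(out.shape[2:]) if out.ndim == 5 else (out.shape[1],)
        return shapes

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.fc.backward(grad).reshape(self._flat_shape)
        grad = self.avgpool.backward(grad)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        grad = self.maxpool.backward(grad)
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(grad)))


class SfeAutoNet(Module):
    """3-layer fully connected network over the 32 morphometrics."""

    def __init__(self, config: SfeAutoConfig = SfeAutoConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        layers = []
        prev = config.input_width
        for i, width in enumerate(config.widths):
            layers.append(Linear(prev, width, rng))
            if i < len(config.widths) - 1:
                layers.append(ReLU())
            prev = width
        self.net = self.register("net", Sequential(*layers))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.atleast_2d(x)
        if x.shape[-1] != self.config.input_width:
            raise ValueError(
                f"expected width {self.config.input_width}, got {x.shape[-1]}"
            )
        return self.net.forward(x, train)

    def backward(self, grad):
        return self.net.backward(grad)


class SieNet(Module):
    """Label-conditioned recurrent network emitting 2-way logits."""

    def __init__(self, config: SieConfig = SieConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.lstm = self.register(
            "lstm", LSTM(config.input_size, config.hidden_size, config.num_layers, rng)
        )
        self.head = self.register("head", Linear(config.hidden_size, config.output_size, rng))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.lstm.forward(x, train), train)

    def backward(self, grad):
        return self.lstm.backward(self.head.backward(grad))


class MfNet(Module):
    """Fusion head: 2-layer fully connected network over cat(O_Is, O_As)."""

    def __init__(self, config: MfConfig = MfConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        layers = []
        prev = config.input_size
        for i, width in enumerate(config.widths):
            layers.append(Linear(prev, width, rng))
            if i < len(config.widths) - 1:
                layers.append(ReLU())
            prev = width
        self.net = self.register("net", Sequential(*layers))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train)

    def backward(self, grad):
        return self.net.backward(grad)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-block min-max normalization to [0, 1]."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi > lo:
        return (img - lo) / (hi - lo)
    return np.zeros_like(img)


def sfe_image_forward(net: SfeImageNet, block_image: np.ndarray) -> np.ndarray:
    """Evaluation-mode logits (length 2) for one 32×64×64 block image."""
    img = np.asarray(block_image, dtype=float)
    if img.shape != BLOCK_SHAPE:
        raise ValueError(f"expected image of shape {BLOCK_SHAPE}, got {img.shape}")
    return net.forward(img[None, None], train=False)[0]


def sfe_auto_forward(net: SfeAutoNet, morphometrics: np.ndarray) -> np.ndarray:
    """Evaluation-mode logits (length 2) for one 32-vector."""
    vec = np.asarray(morphometrics, dtype=float)
    if vec.shape != (net.config.input_width,):
        raise ValueError(f"expected width {net.config.input_width}, got {vec.shape}")
    return net.forward(vec[None], train=False)[0]


def sie_forward(
    net: SieNet,
    sfe_outputs: Sequence[np.ndarray],
    label_context: Sequence[np.ndarray],
) -> np.ndarray:
    """Logits for one sequence: per-step input is label context ⊕ SFE output.

    The last step's context must be the zero vector (the label being
    predicted is unknown); earlier steps carry one-hot labels.
    """
    steps = []
    if len(sfe_outputs) != len(label_context):
        raise ValueError("sfe_outputs and label_context lengths differ")
    for ctx, out in zip(label_context, sfe_outputs):
        ctx = np.asarray(ctx, dtype=float)
        out = np.asarray(out, dtype=float)
        if ctx.shape != (2,) or out.shape != (2,):
            raise ValueError("per-step context and SFE output must be 2-vectors")
        steps.append(np.concatenate([ctx, out]))
    return net.forward(np.asarray(steps)[None], train=False)[0]


def mf_forward(net: MfNet, o_is: np.ndarray, o_as: np.ndarray) -> np.ndarray:
    """Softmax fusion output for one (O_Is, O_As) pair."""
    o_is = np.asarray(o_is, dtype=float)
    o_as = np.asarray(o_as, dtype=float)
    if o_is.shape != (2,) or o_as.shape != (2,):
        raise ValueError("fusion inputs must be 2-vectors")
    logits = net.forward(np.concatenate([o_is, o_as])[None], train=False)[0]
    return softmax(logits)


def augment_rotations(blocks: Sequence[Block]) -> List[Block]:
    """Three rotated copies (90°, 180°, 270° in the 64×64 plane) per block."""
    out: List[Block] = []
    for blk in blocks:
        for k in (1, 2, 3):
            out.append(
                dataclasses.replace(blk, image=np.ascontiguousarray(np.rot90(blk.image, k, axes=(1, 2))))
            )
    return out


# ---------------------------------------------------------------------------
# the assembled model
# ---------------------------------------------------------------------------

def _one_hot(index: int) -> np.ndarray:
    v = np.zeros(2)
    v[index] = 1.0
    return v


def _label_index(label: Optional[str]) -> int:
    if label not in LABELS:
        raise ValueError(f"block has no valid label: {label!r}")
    return LABELS.index(label)


class SsmModel:
    """SFE + SIE + MF with morphometric standardization statistics."""

    def __init__(
        self,
        image_config: SfeImageConfig = SfeImageConfig(),
        auto_config: SfeAutoConfig = SfeAutoConfig(),
        sie_config: SieConfig = SieConfig(),
        mf_config: MfConfig = MfConfig(),
        seed: int = 0,
    ):
        self.sfe_image = SfeImageNet(image_config, seed=seed)
        self.sfe_auto = SfeAutoNet(auto_config, seed=seed + 1)
        self.sie_image = SieNet(sie_config, seed=seed + 2)
        self.sie_auto = SieNet(sie_config, seed=seed + 3)
        self.mf = MfNet(mf_config, seed=seed + 4)
        self.morpho_mean: Optional[np.ndarray] = None
        self.morpho_std: Optional[np.ndarray] = None
        self.seed = seed

    # -- feature preparation --------------------------------------------------
    def fit_standardization(self, morpho: np.ndarray) -> None:
        self.morpho_mean = morpho.mean(axis=0)
        std = morpho.std(axis=0)
        self.morpho_std = np.where(std > 0, std, 1.0)

    def standardize(self, morpho: np.ndarray) -> np.ndarray:
        if self.morpho_mean is None:
            raise RuntimeError("standardization statistics not fitted")
        return (morpho - self.morpho_mean) / self.morpho_std

    def module_groups(self) -> Dict[str, Module]:
        return {
            "sfe_image": self.sfe_image,
            "sfe_auto": self.sfe_auto,
            "sie_image": self.sie_image,
            "sie_auto": self.sie_auto,
            "mf": self.mf,
        }

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {}
        for group, module in self.module_groups().items():
            for name, arr in module.state_dict().items():
                state[f"{group}.{name}"] = arr
        if self.morpho_mean is not None:
            state["morpho_mean"] = self.morpho_mean.copy()
            state["morpho_std"] = self.morpho_std.copy()
        return state

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        data = np.load(path)
        groups = self.module_groups()
        for key in data.files:
            if key == "morpho_mean":
                self.morpho_mean = data[key]
            elif key == "morpho_std":
                self.morpho_std = data[key]
            else:
                group, rest = key.split(".", 1)
                groups[group].load_state_dict({rest: data[key]})


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def accuracy_f1(pred: np.ndarray, truth: np.ndarray) -> Tuple[float, float]:
    """Accuracy and F1 with the high-difficulty class positive."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    acc = float((pred == truth).mean())
    tp = int(((pred == HIGH) & (truth == HIGH)).sum())
    fp = int(((pred == HIGH) & (truth == LOW)).sum())
    fn = int(((pred == LOW) & (truth == HIGH)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return acc, f1


@dataclass
class _Prepared:
    """Per-block tensors keyed by list position."""

    blocks: List[Block]
    images: np.ndarray  # (n, 1, 32, 64, 64), min-max normalized
    morpho: np.ndarray  # (n, 32), raw (standardized lazily by the model)
    labels: np.ndarray  # (n,), int

    @classmethod
    def from_blocks(cls, blocks: Sequence[Block]) -> "_Prepared":
        blocks = list(blocks)
        images = np.stack([normalize_image(b.image) for b in blocks])[:, None]
        morpho = np.stack([lmeasure_features(b.auto) for b in blocks])
        labels = np.array([_label_index(b.label) for b in blocks], dtype=int)
        return cls(blocks, images, morpho, labels)


def _train_classifier(
    net: Module,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    epochs: int,
    rng: np.random.Generator,
    history: Optional[List[float]] = None,
) -> None:
    opt = Adam(net.parameters(), lr=cfg.learning_rate, betas=cfg.betas, weight_decay=cfg.weight_decay)
    n = len(x)
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(x[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            total += loss * len(idx)
        if history is not None:
            history.append(total / n)


def _sequence_windows(prepared: _Prepared, s: int) -> List[List[int]]:
    """Index windows of length ≤ s ending at every block (fallback to shorter
    runs so each block keeps a prediction path)."""
    index_of = {id(b): i for i, b in enumerate(prepared.blocks)}
    by_neuron: Dict[str, List[Block]] = {}
    for b in prepared.blocks:
        by_neuron.setdefault(b.neuron_id, []).append(b)
    windows: List[List[int]] = []
    for neuron_blocks in by_neuron.values():
        neuron_blocks = sorted(neuron_blocks, key=lambda b: (b.anchor_order_index, b.block_index))
        for b in neuron_blocks:
            window = [b]
            cur = b
            while len(window) < s:
                prevs = [
                    p
                    for p in neuron_blocks
                    if p.anchor_order_index == cur.anchor_order_index - ORDER_INDEX_STEP
                    and are_adjacent(p, cur)
                ]
                if not prevs:
                    break
                prev = min(
                    prevs,
                    key=lambda p: (
                        float(np.linalg.norm(np.subtract(p.anchor, cur.anchor))),
                        p.block_index,
                    ),
                )
                window.insert(0, prev)
                cur = prev
            windows.append([index_of[id(w)] for w in window])
    return windows


def _sie_inputs(
    sfe_logits: np.ndarray,
    labels: Sequence[int],
    windows: Sequence[Sequence[int]],
    target_pos: int = -1,
) -> List[np.ndarray]:
    """Per-window (T, 4) input arrays; the last step's context is zero."""
    out = []
    for window in windows:
        steps = []
        for j, idx in enumerate(window):
            if j == len(window) - 1:
                ctx = np.zeros(2)
            else:
                ctx = _one_hot(labels[idx])
            steps.append(np.concatenate([ctx, sfe_logits[idx]]))
        out.append(np.asarray(steps))
    return out


def _group_by_length(windows: List[List[int]]) -> Dict[int, List[int]]:
    groups: Dict[int, List[int]] = {}
    for wi, w in enumerate(windows):
        groups.setdefault(len(w), []).append(wi)
    return groups


def train_stagewise(
    train_blocks: Sequence[Block],
    cfg: TrainConfig,
    checkpoint_dir=None,
) -> Tuple[SsmModel, Dict]:
    """Stage 1: SFE branches; stage 2: SIE with SFE frozen; stage 3: joint.

    Returns the trained model and a report with per-stage loss histories.
    """
    train_blocks = list(train_blocks)
    if not train_blocks:
        raise ValueError("empty training corpus")
    for b in train_blocks:
        _label_index(b.label)

    rng = np.random.default_rng(cfg.seed)
    model = SsmModel(
        image_config=SfeImageConfig(base_channels=cfg.base_channels),
        seed=cfg.seed,
    )
    prepared = _Prepared.from_blocks(train_blocks)
    model.fit_standardization(prepared.morpho)
    morpho_std = model.standardize(prepared.morpho)

    report: Dict = {"seed": cfg.seed, "n_train_blocks": len(train_blocks)}

    # ---- stage 1: SFE image + SFE auto -------------------------------------
    if cfg.augment:
        augmented = augment_rotations(train_blocks)
        aug_images = np.stack([normalize_image(b.image) for b in augmented])[:, None]
        images = np.concatenate([prepared.images, aug_images])
        image_labels = np.concatenate(
            [prepared.labels, np.array([_label_index(b.label) for b in augmented])]
        )
        report["n_augmented"] = len(augmented)
    else:
        images, image_labels = prepared.images, prepared.labels
        report["n_augmented"] = 0

    hist_img: List[float] = []
    hist_auto: List[float] = []
    _train_classifier(model.sfe_image, images, image_labels, cfg, cfg.epochs_sfe, rng, hist_img)
    _recalibrate_batchnorm(model.sfe_image, images, cfg.batch_size)
    _train_classifier(model.sfe_auto, morpho_std, prepared.labels, cfg, cfg.epochs_sfe, rng, hist_auto)
    report["stage1_loss_image"] = hist_img
    report["stage1_loss_auto"] = hist_auto
    if checkpoint_dir is not None:
        Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
        model.save(Path(checkpoint_dir) / "stage1.npz")

    # ---- stage 2: SIE with SFE frozen --------------------------------------
    windows = _sequence_windows(prepared, cfg.sequence_length)
    img_logits = _forward_in_batches(model.sfe_image, prepared.images, cfg.batch_size)
    auto_logits = model.sfe_auto.forward(morpho_std, train=False)
    targets = np.array([prepared.labels[w[-1]] for w in windows], dtype=int)

    hist_sie: List[float] = []
    opt_sie = Adam(
        model.sie_image.parameters() + model.sie_auto.parameters(),
        lr=cfg.learning_rate,
        betas=cfg.betas,
        weight_decay=cfg.weight_decay,
    )
    if cfg.context_source == "predicted":
        img_ctx_labels = img_logits.argmax(axis=1)
        auto_ctx_labels = auto_logits.argmax(axis=1)
    elif cfg.context_source == "truth":
        img_ctx_labels = auto_ctx_labels = prepared.labels
    else:
        raise ValueError(f"unknown context_source {cfg.context_source!r}")
    img_inputs = _sie_inputs(img_logits, img_ctx_labels, windows)
    auto_inputs = _sie_inputs(auto_logits, auto_ctx_labels, windows)
    groups = _group_by_length(windows)
    for _ in range(cfg.epochs_sie):
        total = 0.0
        for length, wis in sorted(groups.items()):
            order = rng.permutation(len(wis))
            for start in range(0, len(wis), cfg.batch_size):
                sel = [wis[i] for i in order[start : start + cfg.batch_size]]
                xi = np.stack([img_inputs[i] for i in sel])
                xa = np.stack([auto_inputs[i] for i in sel])
                yb = targets[sel]
                li = model.sie_image.forward(xi, train=True)
                la = model.sie_auto.forward(xa, train=True)
                loss_i, di = softmax_cross_entropy(li, yb)
                loss_a, da = softmax_cross_entropy(la, yb)
                opt_sie.zero_grad()
                model.sie_image.backward(di)
                model.sie_auto.backward(da)
                opt_sie.step()
                total += (loss_i + loss_a) * len(sel)
        hist_sie.append(total / (2 * len(windows)))
    report["stage2_loss"] = hist_sie
    if checkpoint_dir is not None:
        model.save(Path(checkpoint_dir) / "stage2.npz")

    # ---- stage 3: joint training through MF --------------------------------
    # warm the fusion head on frozen branch outputs first; a cold random head
    # would back-propagate noise into the pretrained branches
    if cfg.epochs_mf_warmup > 0:
        o_is_all, o_as_all = [], []
        for length, wis in sorted(groups.items()):
            xi = np.stack([img_inputs[i] for i in wis])
            xa = np.stack([auto_inputs[i] for i in wis])
            o_is_all.append((wis, model.sie_image.forward(xi, train=False)))
            o_as_all.append(model.sie_auto.forward(xa, train=False))
        warm_x = np.zeros((len(windows), 4), dtype=img_logits.dtype)
        for (wis, o_is), o_as in zip(o_is_all, o_as_all):
            warm_x[wis] = np.concatenate([o_is, o_as], axis=1)
        _train_classifier(model.mf, warm_x, targets, cfg, cfg.epochs_mf_warmup, rng)

    hist_joint: List[float] = []
    all_params = []
    for module in model.module_groups().values():
        all_params.extend(module.parameters())
    opt_joint = Adam(
        all_params, lr=cfg.learning_rate, betas=cfg.betas, weight_decay=cfg.weight_decay
    )
    joint_batch = max(1, cfg.batch_size // max(1, cfg.sequence_length))
    for _ in range(cfg.epochs_joint):
        total = 0.0
        for length, wis in sorted(groups.items()):
            order = rng.permutation(len(wis))
            for start in range(0, len(wis), joint_batch):
                sel = [wis[i] for i in order[start : start + joint_batch]]
                loss = _joint_step(
                    model, prepared, morpho_std, windows, sel, targets, opt_joint,
                    img_ctx_labels, auto_ctx_labels,
                )
                total += loss * len(sel)
        hist_joint.append(total / len(windows))
    _recalibrate_batchnorm(model.sfe_image, prepared.images, cfg.batch_size)
    report["stage3_loss"] = hist_joint
    if checkpoint_dir is not None:
        model.save(Path(checkpoint_dir) / "stage3.npz")
    return model, report


def _recalibrate_batchnorm(net: Module, x: np.ndarray, batch_size: int) -> None:
    """Replace batch-norm running statistics with the cumulative average of
    batch statistics over ``x`` (dropout disabled).

    Necessary at desk scale: few, small batches leave the exponential
    running averages far from the activations' true moments, collapsing
    evaluation-mode accuracy.
    """
    bns = [m for m in net.modules() if isinstance(m, BatchNorm3d)]
    drops = [m for m in net.modules() if isinstance(m, Dropout)]
    saved_p = [d.p for d in drops]
    saved_momentum = [bn.momentum for bn in bns]
    for d in drops:
        d.p = 0.0
    try:
        for i, start in enumerate(range(0, len(x), batch_size)):
            for bn in bns:
                bn.momentum = 1.0 / (i + 1)
            net.forward(x[start : start + batch_size], train=True)
    finally:
        for d, p in zip(drops, saved_p):
            d.p = p
        for bn, m in zip(bns, saved_momentum):
            bn.momentum = m


def _forward_in_batches(net: SfeImageNet, images: np.ndarray, batch: int) -> np.ndarray:
    out = []
    for start in range(0, len(images), batch):
        out.append(net.forward(images[start : start + batch], train=False))
    return np.concatenate(out) if out else np.zeros((0, 2))


def _joint_step(
    model: SsmModel,
    prepared: _Prepared,
    morpho_std: np.ndarray,
    windows: List[List[int]],
    sel: List[int],
    targets: np.ndarray,
    opt: Adam,
    img_ctx_labels: np.ndarray,
    auto_ctx_labels: np.ndarray,
) -> float:
    length = len(windows[sel[0]])
    n = len(sel)
    flat_idx = np.array([i for wi in sel for i in windows[wi]], dtype=int)
    img_batch = prepared.images[flat_idx]
    morpho_batch = morpho_std[flat_idx]
    img_logits = model.sfe_image.forward(img_batch, train=True)
    auto_logits = model.sfe_auto.forward(morpho_batch, train=True)

    ctx_i = np.zeros((n, length, 2))
    ctx_a = np.zeros((n, length, 2))
    for r, wi in enumerate(sel):
        for j, idx in enumerate(windows[wi][:-1]):
            ctx_i[r, j] = _one_hot(int(img_ctx_labels[idx]))
            ctx_a[r, j] = _one_hot(int(auto_ctx_labels[idx]))
    xi = np.concatenate([ctx_i, img_logits.reshape(n, length, 2)], axis=2)
    xa = np.concatenate([ctx_a, auto_logits.reshape(n, length, 2)], axis=2)

    o_is = model.sie_image.forward(xi, train=True)
    o_as = model.sie_auto.forward(xa, train=True)
    fused = model.mf.forward(np.concatenate([o_is, o_as], axis=1), train=True)
    yb = targets[sel]
    loss, dfused = softmax_cross_entropy(fused, yb)

    opt.zero_grad()
    dcat = model.mf.backward(dfused)
    d_xi = model.sie_image.backward(dcat[:, :2])
    d_xa = model.sie_auto.backward(dcat[:, 2:])
    model.sfe_image.backward(d_xi[:, :, 2:].reshape(n * length, 2))
    model.sfe_auto.backward(d_xa[:, :, 2:].reshape(n * length, 2))
    opt.step()
    return loss


def predict_blocks(
    model: SsmModel,
    blocks: Sequence[Block],
    sequence_length: int,
    batch_size: int = 30,
    mode: str = "mf",
) -> np.ndarray:
    """Predicted label indices, in the order of ``blocks``.

    ``mode`` selects the read-out: ``"mf"`` (full fusion), ``"sie_image"``,
    ``"sie_auto"``, ``"sfe_image"`` or ``"sfe_auto"``.  Label context for
    earlier sequence steps uses the model's own previous predictions.
    """
    prepared_blocks = list(blocks)
    images = np.stack([normalize_image(b.image) for b in prepared_blocks])[:, None]
    morpho = model.standardize(
        np.stack([lmeasure_features(b.auto) for b in prepared_blocks])
    )
    img_logits = _forward_in_batches(model.sfe_image, images, batch_size)
    auto_logits = model.sfe_auto.forward(morpho, train=False)

    if mode == "sfe_image":
        return img_logits.argmax(axis=1)
    if mode == "sfe_auto":
        return auto_logits.argmax(axis=1)

    labels_dummy = np.zeros(len(prepared_blocks), dtype=int)
    fake = _Prepared(prepared_blocks, images, morpho, labels_dummy)
    windows = _sequence_windows(fake, sequence_length)
    # windows come out per-neuron in ascending order index: predictions for
    # earlier blocks are available when later windows need them.
    target_order = [w[-1] for w in windows]
    preds = np.full(len(prepared_blocks), -1, dtype=int)
    for w in windows:
        tgt = w[-1]
        ctx_rows = []
        for j, idx in enumerate(w):
            if j == len(w) - 1:
                ctx_rows.append(np.zeros(2))
            else:
                prior = preds[idx] if preds[idx] >= 0 else int(img_logits[idx].argmax())
                ctx_rows.append(_one_hot(prior))
        ctx = np.asarray(ctx_rows)
        xi = np.concatenate([ctx, img_logits[w]], axis=1)[None]
        xa = np.concatenate([ctx, auto_logits[w]], axis=1)[None]
        o_is = model.sie_image.forward(xi, train=False)
        o_as = model.sie_auto.forward(xa, train=False)
        if mode == "sie_image":
            preds[tgt] = int(o_is[0].argmax())
        elif mode == "sie_auto":
            preds[tgt] = int(o_as[0].argmax())
        elif mode == "mf":
            fused = model.mf.forward(np.concatenate([o_is, o_as], axis=1), train=False)
            preds[tgt] = int(fused[0].argmax())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return preds


def evaluate(
    train_blocks: Sequence[Block],
    test_blocks: Sequence[Block],
    cfg: TrainConfig,
    runs: Optional[int] = None,
    mode: str = "mf",
) -> Dict:
    """Train ``runs`` times (seeds cfg.seed..cfg.seed+runs−1) and report
    mean ± std of accuracy and F1 on both splits.

    Raises if any neuron contributes to both splits.
    """
    runs = cfg.runs if runs is None else runs
    train_ids = {b.neuron_id for b in train_blocks}
    test_ids = {b.neuron_id for b in test_blocks}
    shared = train_ids & test_ids
    if shared:
        raise ValueError(f"split leakage: neurons {sorted(shared)} in both splits")

    y_train = np.array([_label_index(b.label) for b in train_blocks], dtype=int)
    y_test = np.array([_label_index(b.label) for b in test_blocks], dtype=int)
    per_run = []
    for run in range(runs):
        run_cfg = dataclasses.replace(cfg, seed=cfg.seed + run)
        model, _ = train_stagewise(train_blocks, run_cfg)
        pred_train = predict_blocks(model, train_blocks, cfg.sequence_length, cfg.batch_size, mode)
        pred_test = predict_blocks(model, test_blocks, cfg.sequence_length, cfg.batch_size, mode)
        tr = accuracy_f1(pred_train, y_train)
        te = accuracy_f1(pred_test, y_test)
        per_run.append({"seed": run_cfg.seed, "train": tr, "test": te})

    def agg(split: str, idx: int) -> Tuple[float, float]:
        vals = np.array([r[split][idx] for r in per_run])
        return float(vals.mean()), float(vals.std())

    return {
        "runs": runs,
        "mode": mode,
        "sequence_length": cfg.sequence_length,
        "train_accuracy": agg("train", 0),
        "train_f1": agg("train", 1),
        "test_accuracy": agg("test", 0),
        "test_f1": agg("test", 1),
        "per_run": per_run,
    }
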