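"""Automatic difficulty labeling from similarity features.

A 4-layer fully connected classifier (widths 50, 30, 20, 2 on a 10-wide
input) maps gold/auto agreement features to a low/high tracing-difficulty
label.  It is trained on a manually labeled subset and then applied to the
remaining blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .metrics import SimilarityFeatures
from .nn import Adam, Linear, ReLU, Sequential, softmax, softmax_cross_entropy

__all__ = [
    "DifficultyLabel",
    "LabelerSpec",
    "AutoLabeler",
    "train_auto_labeler",
    "predict_difficulty",
]

LABELS = ("low", "high")
LOW, HIGH = 0, 1


@dataclass(frozen=True)
class DifficultyLabel:
    value: str  # "low" | "high"

    def __post_init__(self) -> None:
        if self.value not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.value!r}")

    @property
    def index(self) -> int:
        return LABELS.index(self.value)

    @property
    def one_hot(self) -> np.ndarray:
        v = np.zeros(2)
        v[self.index] = 1.0
        return v


@dataclass
class LabelerSpec:
    input_width: int = 10
    layer_widths: Tuple[int, ...] = (50, 30, 20, 2)
    epochs: int = 150
    batch_size: int = 30
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layer_widths[-1] != 2:
            raise ValueError("final layer width must be 2")


def _as_matrix(features, width: int) -> np.ndarray:
    rows = []
    for f in features:
        arr = f.as_array() if isinstance(f, SimilarityFeatures) else np.asarray(f, dtype=float)
        if arr.shape != (width,):
            raise ValueError(f"feature vector must have width {width}, got {arr.shape}")
        rows.append(arr)
    return np.array(rows, dtype=float)


class AutoLabeler:
    """Trained difficulty classifier: z-scoring + FCNN.

    Standardization statistics are fit on the training split only and are
    part of the model.
    """

    FORMAT_VERSION = 1

    def __init__(self, spec: LabelerSpec):
        self.spec = spec
        self.mean: Optional[np.ndarray] = None
        self.std: Optional[np.ndarray] = None
        rng = np.random.default_rng(spec.seed)
        layers = []
        prev = spec.input_width
        for i, width in enumerate(spec.layer_widths):
            layers.append(Linear(prev, width, rng))
            if i < len(spec.layer_widths) - 1:
                layers.append(ReLU())
            prev = width
        self.net = Sequential(*layers)
        self.trained = False

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std

    def predict_proba(self, features) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("labeler has not been trained")
        if isinstance(features, SimilarityFeatures):
            x = features.as_array()[None, :]
        elif isinstance(features, np.ndarray) and features.ndim == 2:
            x = features
        else:
            x = _as_matrix(features, self.spec.input_width)
        return softmax(self.net.forward(self._standardize(x)))

    def predict(self, features) -> List[DifficultyLabel]:
        probs = self.predict_proba(features)
        return [DifficultyLabel(LABELS[int(i)]) for i in probs.argmax(axis=1)]

    # -- serialization (versioned JSON container) ------------------------------
    def save(self, path) -> None:
        state = {
            "format_version": self.FORMAT_VERSION,
            "spec": {
                "input_width": self.spec.input_width,
                "layer_widths": list(self.spec.layer_widths),
                "seed": self.spec.seed,
            },
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "weights": {
                name: p.data.tolist() for name, p in self.net.named_parameters()
            },
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path) -> "AutoLabeler":
        state = json.loads(Path(path).read_text())
        if state.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported labeler format {state.get('format_version')}")
        spec = LabelerSpec(
            input_width=state["spec"]["input_width"],
            layer_widths=tuple(state["spec"]["layer_widths"]),
            seed=state["spec"]["seed"],
        )
        model = cls(spec)
        model.mean = np.asarray(state["mean"], dtype=float)
        model.std = np.asarray(state["std"], dtype=float)
        params = dict(model.net.named_parameters())
        for name, value in state["weights"].items():
            params[name].data[...] = np.asarray(value, dtype=float)
        model.trained = True
        return model


def _accuracy_f1(pred: np.ndarray, truth: np.ndarray) -> Tuple[float, float]:
    acc = float((pred == truth).mean())
    tp = int(((pred == HIGH) & (truth == HIGH)).sum())
    fp = int(((pred == HIGH) & (truth == LOW)).sum())
    fn = int(((pred == LOW) & (truth == HIGH)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return acc, f1


def train_auto_labeler(
    features: Sequence,
    labels: Sequence[Union[DifficultyLabel, str]],
    spec: LabelerSpec = LabelerSpec(),
) -> Tuple[AutoLabeler, Dict]:
    """Train the labeler on a 70/30 random split; returns (model, report)."""
    x = _as_matrix(features, spec.input_width)
    y = np.array(
        [
            (lab.index if isinstance(lab, DifficultyLabel) else DifficultyLabel(lab).index)
            for lab in labels
        ],
        dtype=int,
    )
    if len(x) != len(y):
        raise ValueError("features and labels differ in length")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")

    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(x))
    n_test = max(1, int(round(spec.test_fraction * len(x))))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("training split must contain both classes")

    model = AutoLabeler(spec)
    model.mean = x[train_idx].mean(axis=0)
    std = x[train_idx].std(axis=0)
    model.std = np.where(std > 0, std, 1.0)

    xt = model._standardize(x[train_idx])
    yt = y[train_idx]
    opt = Adam(
        model.net.parameters(),
        lr=spec.learning_rate,
        weight_decay=spec.weight_decay,
    )
    losses = []
    for _ in range(spec.epochs):
        order = rng.permutation(len(xt))
        epoch_loss = 0.0
        for start in range(0, len(xt), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            logits = model.net.forward(xt[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, yt[idx])
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / len(xt))
    model.trained = True

    pred_train = np.argmax(model.predict_proba(x[train_idx]), axis=1)
    pred_test = np.argmax(model.predict_proba(x[test_idx]), axis=1)
    train_acc, train_f1 = _accuracy_f1(pred_train, y[train_idx])
    test_acc, test_f1 = _accuracy_f1(pred_test, y[test_idx])
    report = {
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "train_accuracy": train_acc,
        "train_f1": train_f1,
        "test_accuracy": test_acc,
        "test_f1": test_f1,
        "final_loss": losses[-1],
        "epochs": spec.epochs,
        "seed": spec.seed,
    }
    return model, report


def predict_difficulty(labeler: AutoLabeler, features) -> DifficultyLabel:
    """Argmax label for one feature vector."""
    if isinstance(features, SimilarityFeatures):
        features = features.as_array()
    return labeler.predict([np.asarray(features, dtype=float)])[0]
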