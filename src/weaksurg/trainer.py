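"""Two-stage frame-classifier training harness.

The benchmark's training protocol is deliberately plain: a frame-level
classifier is (optionally) pre-trained on a weak dataset-label pair, its
classification head is swapped for the target vocabulary, and the whole
network — no layers frozen — is fine-tuned on the scarce step-labeled data.
Class imbalance is handled by weighted sampling (each class contributes
equally in expectation), the loss is cross-entropy, and early stopping
returns the checkpoint with the best validation loss.

The backbone is a small fully connected network over flattened frames,
trained with Adam entirely in numpy. At desk scale (32x32x3 inputs, tens of
videos) this trains in seconds per job and is bit-reproducible given the
seed, which the head-swap and determinism contracts rely on. Larger
backbones register under their own ids; nothing in the harness assumes a
particular architecture beyond "backbone features -> linear head".

An epoch under weighted sampling is N_labeled draws with replacement
(without-replacement epochs are incompatible with a non-uniform sampler);
validation loss is the unweighted mean cross-entropy so that model selection
reflects the natural class distribution, not the balanced sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .random_utils import substream

__all__ = [
    "TrainConfig",
    "ModelRef",
    "BACKBONES",
    "parameter_count",
    "init_model",
    "weighted_sampler",
    "train_stage",
    "predict",
    "TrainingError",
]


class TrainingError(ValueError):
    """Raised for invalid training inputs (empty or single-class sets)."""


#: backbone id -> hidden layer widths of the fully connected trunk
BACKBONES: dict[str, tuple[int, ...]] = {
    "mlp-64": (64,),
    "mlp-128-64": (128, 64),
    "linear": (),
}


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of one training stage.

    Defaults follow the benchmark protocol: batch 64, learning rate 1e-3,
    early stopping on validation loss. ``max_epochs``/``patience`` bound the
    desk-scale run; both are ordinary config surface.
    """

    batch_size: int = 64
    learning_rate: float = 1e-3
    max_epochs: int = 30
    patience: int = 5
    weight_decay: float = 1e-4
    backbone: str = "mlp-64"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class _MLP:
    """Weights of the trunk + head. ``trunk`` is what transfers across stages."""

    trunk: list[tuple[np.ndarray, np.ndarray]]   # (W, b) per hidden layer
    head: tuple[np.ndarray, np.ndarray]          # (W, b) onto n_classes

    def copy(self) -> "_MLP":
        return _MLP(
            trunk=[(W.copy(), b.copy()) for W, b in self.trunk],
            head=(self.head[0].copy(), self.head[1].copy()),
        )


@dataclass
class ModelRef:
    """Handle to trained weights plus an append-only provenance chain.

    ``provenance`` fully specifies how to regenerate the model: the init
    event and one event per completed training stage, each carrying the
    label vocabulary and seeds involved.
    """

    backbone_id: str
    input_dim: int
    classes: list[str]
    model: _MLP
    provenance: list[dict] = field(default_factory=list)


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int):
    W = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
    b = np.zeros(fan_out)
    return W, b


def parameter_count(backbone_id: str, input_dim: int, n_classes: int) -> int:
    """Total trainable parameter count for a registered backbone."""
    if backbone_id not in BACKBONES:
        raise ValueError(f"unknown backbone {backbone_id!r}; known: {sorted(BACKBONES)}")
    widths = (input_dim, *BACKBONES[backbone_id], n_classes)
    return sum(a * b + b for a, b in zip(widths, widths[1:]))


def init_model(
    backbone_id: str, input_dim: int, classes: Sequence[str], seed: int
) -> ModelRef:
    """Deterministically initialize a model with a head over ``classes``."""
    if backbone_id not in BACKBONES:
        raise ValueError(f"unknown backbone {backbone_id!r}; known: {sorted(BACKBONES)}")
    classes = list(classes)
    if len(classes) < 2:
        raise TrainingError(f"need >= 2 classes, got {classes}")
    rng = substream(seed, "init", backbone_id)
    trunk = []
    fan_in = input_dim
    for width in BACKBONES[backbone_id]:
        trunk.append(_he_init(rng, fan_in, width))
        fan_in = width
    head = _he_init(rng, fan_in, len(classes))
    return ModelRef(
        backbone_id=backbone_id,
        input_dim=input_dim,
        classes=classes,
        model=_MLP(trunk=trunk, head=head),
        provenance=[{"event": "init", "backbone": backbone_id, "seed": seed,
                     "classes": classes}],
    )


def _forward(model: _MLP, X: np.ndarray):
    """Return (activations per layer, softmax probabilities)."""
    acts = [X]
    h = X
    for W, b in model.trunk:
        h = np.maximum(h @ W + b, 0.0)
        acts.append(h)
    logits = h @ model.head[0] + model.head[1]
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    return acts, probs


def _cross_entropy(probs: np.ndarray, y_idx: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y_idx)), y_idx], 1e-12, None)
    return float(-np.log(p).mean())


def weighted_sampler(labels: Sequence[str]) -> np.ndarray:
    """Per-frame sampling weights inverse to class frequency, summing to 1.

    Under these weights the expected class distribution of a draw is
    uniform, which is how the protocol addresses class imbalance.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise TrainingError("no labeled frames to sample from")
    classes, counts = np.unique(labels, return_counts=True)
    freq = dict(zip(classes.tolist(), counts.tolist()))
    w = np.array([1.0 / freq[lab] for lab in labels.tolist()])
    return w / w.sum()


class _Adam:
    """Adam with decoupled weight decay (AdamW-style, decay on weights only)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd and p.ndim > 1:  # decay matrices, not biases
                p -= self.lr * self.wd * p


def _flat_params(model: _MLP) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for W, b in model.trunk:
        out += [W, b]
    out += [model.head[0], model.head[1]]
    return out


def _backward(model: _MLP, acts: list[np.ndarray], probs: np.ndarray,
              y_idx: np.ndarray) -> list[np.ndarray]:
    n = len(y_idx)
    delta = probs.copy()
    delta[np.arange(n), y_idx] -= 1.0
    delta /= n
    grads: list[np.ndarray] = []
    # head
    gW = acts[-1].T @ delta
    gb = delta.sum(axis=0)
    grads = [gW, gb]
    back = delta @ model.head[0].T
    # trunk, in reverse
    for layer in range(len(model.trunk) - 1, -1, -1):
        back = back * (acts[layer + 1] > 0)
        gW = acts[layer].T @ back
        gb = back.sum(axis=0)
        grads = [gW, gb] + grads
        if layer > 0:
            back = back @ model.trunk[layer][0].T
    return grads


def train_stage(
    ref: ModelRef,
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_val: np.ndarray,
    y_val: Sequence[str],
    config: TrainConfig,
    stage: str = "train",
) -> tuple[ModelRef, list[dict]]:
    """Run one training stage; return the best-val-loss checkpoint and log.

    If the training vocabulary differs from the model's current head, the
    head is re-initialized (seeded) while the trunk is carried over
    bit-identically — the head-swap contract of two-stage transfer. All
    weights are then updated; nothing is frozen.
    """
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if y_train.size == 0:
        raise TrainingError("empty training set after exclusions")
    vocab = sorted(np.unique(y_train).tolist())
    if len(vocab) < 2:
        raise TrainingError(f"single-class training set ({vocab}); cannot train")
    if X_train.shape[1] != ref.input_dim:
        raise TrainingError(
            f"input dim {X_train.shape[1]} != model dim {ref.input_dim}"
        )

    model = ref.model.copy()
    if vocab != ref.classes:
        rng = substream(config.seed, "head", stage)
        fan_in = BACKBONES[ref.backbone_id][-1] if model.trunk else ref.input_dim
        model.head = _he_init(rng, fan_in, len(vocab))

    idx_of = {lab: i for i, lab in enumerate(vocab)}
    y_tr = np.array([idx_of[lab] for lab in y_train.tolist()])
    known_val = np.array([lab in idx_of for lab in y_val.tolist()])
    Xv = X_val[known_val]
    yv = np.array([idx_of[lab] for lab in y_val[known_val].tolist()])
    if yv.size == 0:
        raise TrainingError("validation set shares no classes with training set")

    weights = weighted_sampler(y_train)
    rng_sample = substream(config.seed, "sampling", stage)
    opt = _Adam(_flat_params(model), config.learning_rate, config.weight_decay)

    best = model.copy()
    best_val = np.inf
    since_best = 0
    log: list[dict] = []
    n = len(y_tr)
    for epoch in range(config.max_epochs):
        draw = rng_sample.choice(n, size=n, replace=True, p=weights)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            batch = draw[lo:lo + config.batch_size]
            acts, probs = _forward(model, X_train[batch])
            epoch_loss += _cross_entropy(probs, y_tr[batch]) * len(batch)
            grads = _backward(model, acts, probs, y_tr[batch])
            opt.step(_flat_params(model), grads)
        train_loss = epoch_loss / n
        _, pv = _forward(model, Xv)
        val_loss = _cross_entropy(pv, yv)
        log.append({"epoch": epoch, "train_loss": train_loss,
                    "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best = model.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    out = ModelRef(
        backbone_id=ref.backbone_id,
        input_dim=ref.input_dim,
        classes=vocab,
        model=best,
        provenance=ref.provenance + [{
            "event": stage,
            "classes": vocab,
            "seed": config.seed,
            "epochs_run": len(log),
            "best_val_loss": best_val,
        }],
    )
    return out, log


def predict(ref: ModelRef, X: np.ndarray):
    """Predicted labels and per-frame class probabilities (rows sum to 1)."""
    _, probs = _forward(ref.model, X)
    labels = np.asarray(ref.classes)[probs.argmax(axis=1)]
    return labels, probs
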