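"""Training, evaluation and prediction for the classifier family.

The optimisation recipe follows the published configuration: soft-label
cross-entropy (so MixUp/CutMix targets work unchanged), Adam at 1e-3,
batch 64, input 224, 150 epochs.  Desk-scale runs override batch size,
epochs and image size; a single seed drives shuffling, mixing and weight
initialisation so histories replay exactly.
"""

from __future__ import annotations

import json
import math
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import augment as aug
from .metrics import MetricsReport, confusion_matrix, scores
from .models import ClassifierNet, ModelConfig
from .nn import Adam, Module, Tensor, F

__all__ = ["TrainConfig", "TrainHistory", "train", "evaluate", "predict",
           "save_checkpoint", "load_checkpoint", "soft_cross_entropy"]


@dataclass
class TrainConfig:
    """Optimisation hyperparameters; defaults are the published recipe."""

    input_size: int = 224
    batch_size: int = 64
    epochs: int = 150
    learning_rate: float = 0.001
    loss: str = "cross_entropy"
    optimizer: str = "adam"
    seed: int = 0
    mix_method: str = "none"        # none | mixup | cutmix
    mix_alpha: float = 1.0

    def __post_init__(self):
        for name in ("input_size", "batch_size", "learning_rate", "mix_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.mix_method not in ("none", "mixup", "cutmix"):
            raise ValueError(f"unknown mix_method {self.mix_method!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_accuracy(self) -> float:
        return self.val_accuracy[self.best_epoch] if self.val_accuracy else float("nan")


def soft_cross_entropy(logits: Tensor, soft_labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, K) logits against soft targets."""
    n = logits.shape[0]
    logp = F.log_softmax(logits)
    return F.sum_(logp * Tensor(-soft_labels / n))


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], k), dtype=np.float32)
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train(model: ClassifierNet, train_x: np.ndarray, train_y: np.ndarray,
          val_x: np.ndarray, val_y: np.ndarray, cfg: TrainConfig,
          checkpoint_path: str | Path | None = None,
          log=None) -> TrainHistory:
    """Optimise ``model`` in place; returns the per-epoch history.

    ``train_x``/``val_x`` are (N, 3, H, W) float arrays in [0, 1];
    labels are integer class indices.  When a checkpoint path is given the
    best-validation-accuracy weights are saved there (with the configs
    needed to rebuild the model).  Raises on a non-finite training loss.
    """
    if train_x.shape[0] == 0 or val_x.shape[0] == 0:
        raise ValueError("datasets must be non-empty")
    k = model.config.num_classes
    if train_y.max() >= k:
        raise ValueError(f"labels exceed the model's {k}-class head")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    best_acc, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        model.train()
        losses = []
        for idx in _batches(train_x.shape[0], cfg.batch_size, rng):
            xb, yb = train_x[idx], _one_hot(train_y[idx], k)
            mixed = aug.mix_batch(xb, yb, cfg.mix_method, cfg.mix_alpha, rng)
            logits = model(Tensor(mixed.images))
            loss = soft_cross_entropy(logits, mixed.soft_labels)
            if not math.isfinite(loss.item()):
                raise ArithmeticError(
                    f"non-finite training loss at epoch {epoch}: {loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        vl, va = _validate(model, val_x, val_y, cfg.batch_size)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(vl)
        history.val_accuracy.append(va)
        if va > best_acc:
            best_acc, best_state = va, model.state_dict()
            history.best_epoch = epoch
        if log is not None:
            log(f"epoch {epoch + 1}/{cfg.epochs} "
                f"train_loss={history.train_loss[-1]:.4f} "
                f"val_loss={vl:.4f} val_acc={va:.4f}")
    if best_state is not None:
        model.load_state_dict(best_state)
        if checkpoint_path is not None:
            save_checkpoint(model, checkpoint_path, train_config=cfg,
                            history=history)
    return history


def _forward_in_batches(model: Module, x: np.ndarray, batch_size: int) -> np.ndarray:
    outs = []
    for i in range(0, x.shape[0], batch_size):
        outs.append(model(Tensor(x[i:i + batch_size])).data)
    return np.concatenate(outs, axis=0)


def _validate(model: ClassifierNet, x, y, batch_size) -> tuple[float, float]:
    model.eval()
    logits = _forward_in_batches(model, x, batch_size)
    k = logits.shape[1]
    loss = soft_cross_entropy(Tensor(logits), _one_hot(y, k)).item()
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def evaluate(model: ClassifierNet, x: np.ndarray, y: np.ndarray,
             class_names: list[str] | None = None,
             batch_size: int = 64) -> MetricsReport:
    """Deterministic eval-mode pass: argmax predictions, full metrics report."""
    model.eval()
    logits = _forward_in_batches(model, x, batch_size)
    preds = logits.argmax(axis=1)
    cm = confusion_matrix(y, preds, model.config.num_classes, class_names)
    return scores(cm)


def predict(model: ClassifierNet, image: np.ndarray,
            class_names: list[str] | None = None) -> list[tuple[str, float]]:
    """Softmax class ranking for one (3, H, W) image, most probable first."""
    model.eval()
    if image.ndim != 3:
        raise ValueError(f"expected one (3, H, W) image, got shape {image.shape}")
    logits = model(Tensor(image[None]))
    logp = F.log_softmax(logits).data[0]
    probs = np.exp(logp)
    names = class_names or [str(i) for i in range(probs.shape[0])]
    ranking = sorted(zip(names, probs.tolist()), key=lambda t: -t[1])
    return [(n, float(p)) for n, p in ranking]


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(model: ClassifierNet, path: str | Path,
                    train_config: TrainConfig | None = None,
                    history: TrainHistory | None = None) -> None:
    """Weights + the model config that built them, as an npz-in-zip archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"model_config": model.config.to_dict()}
    if train_config is not None:
        meta["train_config"] = train_config.to_dict()
    if history is not None:
        meta["history"] = {"train_loss": history.train_loss,
                           "val_loss": history.val_loss,
                           "val_accuracy": history.val_accuracy,
                           "best_epoch": history.best_epoch}
    state = model.state_dict()
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        import io
        buf = io.BytesIO()
        np.savez(buf, **state)
        zf.writestr("state.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[ClassifierNet, dict]:
    """Rebuild the network from a checkpoint; returns (model, metadata)."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        import io
        state = dict(np.load(io.BytesIO(zf.read("state.npz"))))
    model = ClassifierNet(ModelConfig.from_dict(meta["model_config"]))
    model.load_state_dict(state)
    return model, meta
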