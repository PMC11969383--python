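"""Training and evaluation for the CNN classifier/regressor.

The training recipe: batch size 4, Adam with learning rate 1e-5 and weight
decay 1e-1, binary cross-entropy on logits (classification) or mean
squared error in degrees (regression), optional random Z-rotation
augmentation on training samples only, and checkpoint selection by highest
validation accuracy (classification, probability threshold 0.5, earlier
epoch wins ties) or lowest validation RMSE (regression). Runs are
deterministic for a fixed seed: shuffle order, augmentation angles and
dropout masks are all derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .nn.layers import Adam, bce_with_logits, mse_loss, sigmoid
from .nn.models import Network
from .preprocess import rotate_z


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    lr: float = 1e-5
    weight_decay: float = 1e-1
    epochs: int = 800
    seed: int = 0
    augment: bool = False
    threshold: float = 0.5   # probability threshold for accuracy/checkpointing

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")


@dataclass
class TrainingResult:
    """Selected checkpoint plus the full training trace."""

    model: Network
    best_epoch: int
    best_metric: float
    metric_name: str
    history: pd.DataFrame      # epoch, train_loss, val_metric
    config: TrainConfig
    state: dict = field(repr=False, default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"{self.model.arch} network, {self.model.mode} head",
            f"  epochs run: {len(self.history)}  (batch {self.config.batch_size}, "
            f"lr {self.config.lr:g}, weight decay {self.config.weight_decay:g})",
            f"  selected epoch {self.best_epoch}: "
            f"{self.metric_name} = {self.best_metric:.4f}",
            f"  final train loss = {self.history['train_loss'].iloc[-1]:.4f}",
        ]
        return "\n".join(lines)


def predict(model: Network, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Deterministic forward pass (dropout off); one scalar per item."""
    outs = []
    for i in range(0, len(x), batch_size):
        outs.append(model.forward(x[i:i + batch_size], train=False).ravel())
    return np.concatenate(outs) if outs else np.empty(0)


def _val_metric(model: Network, x: np.ndarray, y: np.ndarray,
                threshold: float) -> float:
    out = predict(model, x)
    if model.mode == "classification":
        return metrics.accuracy_at(y, sigmoid(out), threshold)
    return float(np.sqrt(np.mean((out - y) ** 2)))


def train(model: Network, train_data: tuple[np.ndarray, np.ndarray],
          val_data: tuple[np.ndarray, np.ndarray],
          cfg: TrainConfig = TrainConfig()) -> TrainingResult:
    """Train ``model`` and return the best checkpoint by validation metric.

    ``train_data``/``val_data`` are (volumes, targets): volumes shaped
    (N, 1, Z, Y, X) (or (N, 1, Y, X) for the 2D variant), targets in {0, 1}
    with 1 = S/G2 for classification or theta in degrees for regression.
    """
    x_train, y_train = train_data
    x_val, y_val = val_data
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty train or validation set")
    loss_fn = bce_with_logits if model.mode == "classification" else mse_loss
    higher_better = model.mode == "classification"
    metric_name = "val_accuracy" if higher_better else "val_rmse"
    model.reseed_dropout(cfg.seed)
    opt = Adam(model, lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = len(x_train)
    best_metric = -np.inf if higher_better else np.inf
    best_state: dict = {}
    best_epoch = -1
    history = []
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, epoch)))
        order = rng.permutation(n)
        angles = rng.uniform(0.0, 359.0, size=n)  # per original index
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x_train[idx].astype(np.float32)
            if cfg.augment:
                xb = np.stack([
                    rotate_z(xb[j, 0], float(angles[i]))[None]
                    for j, i in enumerate(idx)])
            out = model.forward(xb, train=True)
            loss, dout = loss_fn(out, y_train[idx])
            model.backward(dout)
            opt.step()
            losses.append(loss)
        val = _val_metric(model, x_val, y_val, cfg.threshold)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        metric_name: val})
        improved = val > best_metric if higher_better else val < best_metric
        if improved:  # strict: earlier epoch wins ties
            best_metric = val
            best_epoch = epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return TrainingResult(model=model, best_epoch=best_epoch,
                          best_metric=float(best_metric),
                          metric_name=metric_name,
                          history=pd.DataFrame(history), config=cfg,
                          state=best_state)


# -------------------------------------------------------------------------
# evaluation

@dataclass
class EvalReport:
    """Held-out evaluation of a classifier or regressor."""

    auroc: float
    roc: tuple | None = None
    accuracy: float | None = None
    confusion: dict | None = None
    rmse: float | None = None
    pearson_r: float | None = None
    spearman_r: float | None = None
    n: int = 0
    scores: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [f"evaluation on n = {self.n}"]
        if self.accuracy is not None:
            lines += [f"  AUROC    = {self.auroc:.4f}",
                      f"  accuracy = {self.accuracy:.4f}",
                      f"  confusion = {self.confusion}"]
        else:
            lines += [f"  RMSE (deg) = {self.rmse:.2f}",
                      f"  Pearson r  = {self.pearson_r:.3f}",
                      f"  Spearman r = {self.spearman_r:.3f}",
                      f"  AUROC (45 deg binarized) = {self.auroc:.4f}"]
        return "\n".join(lines)


def evaluate_classifier(model: Network, x: np.ndarray, y: np.ndarray,
                        threshold: float = 0.5) -> EvalReport:
    """ROC/AUROC over all score thresholds + accuracy at ``threshold``."""
    if model.mode != "classification":
        raise ValueError("model does not have a classification head")
    y = np.asarray(y).astype(int)
    probs = sigmoid(predict(model, x))
    return EvalReport(
        auroc=metrics.auroc(y, probs),
        roc=metrics.roc_points(y, probs),
        accuracy=metrics.accuracy_at(y, probs, threshold),
        confusion=metrics.confusion(y, probs, threshold),
        n=len(y), scores=probs)


def evaluate_regressor(model: Network, x: np.ndarray, theta: np.ndarray,
                       boundary: float = 45.0) -> EvalReport:
    """RMSE/Pearson/Spearman in degrees + AUROC after boundary binarization."""
    if model.mode != "regression":
        raise ValueError("model does not have a regression head")
    preds = predict(model, x)
    m = metrics.regression_metrics(theta, preds, boundary=boundary)
    return EvalReport(auroc=m["auroc_binarized"], rmse=m["rmse"],
                      pearson_r=m["pearson_r"], spearman_r=m["spearman_r"],
                      n=len(preds), scores=preds)


# -------------------------------------------------------------------------
# combined-platform training support

def merge_datasets(manifests: list[dict]) -> dict:
    """Concatenate per-platform manifests preserving each source's split.

    Every manifest keeps its own normalization constant (items are already
    normalized per source); final shapes must agree; ids must be globally
    unique. Each item in the combined manifest records its source, so a
    combined-trained model can be evaluated per platform.
    """
    if not manifests:
        raise ValueError("no manifests to merge")
    final_shape = manifests[0]["final_shape"]
    items = []
    seen: set = set()
    for man in manifests:
        if man["final_shape"] != final_shape:
            raise ValueError(
                f"final_shape mismatch: {man['final_shape']} != {final_shape}")
        for part in ("train", "val", "test"):
            for item_id in man["split"][part]:
                if item_id in seen:
                    raise ValueError(f"duplicate id across manifests: {item_id!r}")
                seen.add(item_id)
                items.append({"id": item_id, "source": man["source"],
                              "split": part})
    split = {part: [it["id"] for it in items if it["split"] == part]
             for part in ("train", "val", "test")}
    return {
        "source": "+".join(m["source"] for m in manifests),
        "final_shape": final_shape,
        "norm_constants": {m["source"]: m["norm_constant"] for m in manifests},
        "items": items,
        "split": split,
    }


# -------------------------------------------------------------------------
# model-object surface

class CellCycleCNN:
    """statsmodels-style wrapper: data in, ``fit()`` out a TrainingResult."""

    def __init__(self, model: Network, train_data, val_data,
                 config: TrainConfig = TrainConfig()) -> None:
        self.model = model
        self.train_data = train_data
        self.val_data = val_data
        self.config = config

    def fit(self) -> TrainingResult:
        return train(self.model, self.train_data, self.val_data, self.config)


__all__ = ["TrainConfig", "TrainingResult", "train", "predict",
           "evaluate_classifier", "evaluate_regressor", "EvalReport",
           "merge_datasets", "CellCycleCNN"]
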