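"""Training loop, LR schedule, evaluation driver and structured logging.

The schedule follows the published protocol: AdamW (lr 1e-4, weight decay
1e-4), up to 100 epochs, dropout 0.3 in the head, early stopping with
patience 20, and a plateau rule that multiplies the learning rate by 0.8
after every 10 consecutive epochs without improvement of the monitored
metric (validation Top-1; ties resolve toward the earlier epoch, and an LR
decay does not reset the early-stop counter).  The schedule logic is a pure
function of the metric sequence so it can be unit-tested without a model.
"""

from __future__ import annotations

import copy
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import MetricReport, RocResult, compute_report, roc_auc_ovr
from .model import WheatStageNet
from .nn import Tensor, cross_entropy, no_grad, seed_dropout, softmax
from .nn.optim import AdamW


class DivergenceError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    max_epochs: int = 100
    batch_size: int = 32
    early_stop_patience: int = 20
    plateau_patience: int = 10
    lr_decay_factor: float = 0.8
    monitor: str = "val_top1"
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.max_epochs, self.batch_size,
               self.early_stop_patience, self.plateau_patience) <= 0:
            raise ValueError("all training quantities must be positive")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr_decay_factor must be in (0,1)")
        if self.plateau_patience > self.early_stop_patience:
            raise ValueError("plateau_patience must not exceed early_stop_patience")

    def to_dict(self) -> dict:
        import dataclasses
        return dataclasses.asdict(self)


class PlateauSchedule:
    """Plateau LR decay + early stopping as a pure metric-sequence machine.

    ``update(value)`` returns ``(improved, decay, stop)`` for the epoch that
    just ended.  Improvement is strict (>), so a tie keeps the earlier best.
    The LR decays at the end of every completed ``plateau_patience``-length
    non-improving stretch; training stops once ``early_stop_patience``
    epochs have passed without improvement.  Decays never reset the
    early-stop counter.
    """

    def __init__(self, plateau_patience: int, early_stop_patience: int):
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.best: float | None = None
        self.best_epoch = -1
        self.epoch = -1
        self.since_improve = 0

    def update(self, value: float) -> tuple[bool, bool, bool]:
        self.epoch += 1
        if self.best is None or value > self.best:
            self.best = value
            self.best_epoch = self.epoch
            self.since_improve = 0
            return True, False, False
        self.since_improve += 1
        decay = self.since_improve % self.plateau_patience == 0
        stop = self.since_improve >= self.early_stop_patience
        return False, decay, stop


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = "max_epochs"

    def lr_sequence(self) -> list[float]:
        return [e["lr"] for e in self.epochs]

    def to_dict(self) -> dict:
        return {"epochs": self.epochs, "best_epoch": self.best_epoch,
                "stop_reason": self.stop_reason}


def stratified_val_carve(x: np.ndarray, y: np.ndarray, frac: float = 0.1,
                         seed: int = 0):
    """Carve a stratified validation slice out of a training array pair."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    val_idx = []
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        n_val = max(int(round(frac * idx.size)), 1)
        val_idx.append(rng.permutation(idx)[:n_val])
    val_idx = np.concatenate(val_idx)
    mask = np.zeros(y.size, dtype=bool)
    mask[val_idx] = True
    return (x[~mask], y[~mask]), (x[mask], y[mask])


def _forward_in_batches(model: WheatStageNet, x: np.ndarray,
                        batch_size: int = 64) -> np.ndarray:
    """Inference-mode class probabilities for an array of images."""
    model.eval()
    probs = []
    with no_grad():
        for i in range(0, len(x), batch_size):
            logits = model(Tensor(x[i:i + batch_size]))
            probs.append(softmax(logits, axis=1).data)
    return np.concatenate(probs)


def _validation_stats(model: WheatStageNet, x: np.ndarray, y: np.ndarray,
                      batch_size: int) -> tuple[float, float]:
    probs = _forward_in_batches(model, x, batch_size)
    logp = np.log(np.clip(probs, 1e-12, 1.0))
    loss = float(-logp[np.arange(len(y)), y].mean())
    top1 = float((probs.argmax(axis=1) == y).mean())
    return loss, top1


def train(model: WheatStageNet, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray] | None,
          cfg: TrainConfig, augment_fn=None,
          log_path: str | Path | None = None,
          ) -> tuple[dict[str, np.ndarray], TrainingHistory]:
    """Train with cross-entropy under the plateau/early-stop schedule.

    Returns the best checkpoint (a ``state_dict``) and the history.  If
    ``val_set`` is None, a stratified 10% slice of the training data is
    carved out for monitoring.  ``augment_fn(images, epoch) -> images`` may
    inject stochastic augmentation per epoch.
    """
    x_train, y_train = train_set
    if val_set is None:
        (x_train, y_train), val_set = stratified_val_carve(
            x_train, y_train, 0.1, cfg.seed)
    x_val, y_val = val_set
    if not len(x_train) or not len(x_val):
        raise ValueError("training and validation sets must be nonempty")

    seed_dropout(model, cfg.seed)
    optimizer = AdamW(model.parameters(), lr=cfg.learning_rate,
                      weight_decay=cfg.weight_decay)
    schedule = PlateauSchedule(cfg.plateau_patience, cfg.early_stop_patience)
    history = TrainingHistory()
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 88]))
    best_state = model.state_dict()
    log_fh = open(log_path, "a") if log_path else None
    if log_fh:
        log_fh.write(json.dumps({"event": "config", "train": cfg.to_dict(),
                                 "model": model.cfg.to_dict()}) + "\n")
    try:
        for epoch in range(cfg.max_epochs):
            t0 = time.time()
            model.train()
            order = shuffle_rng.permutation(len(x_train))
            xs = augment_fn(x_train, epoch) if augment_fn else x_train
            losses, wfa_means = [], []
            for i in range(0, len(order), cfg.batch_size):
                idx = order[i:i + cfg.batch_size]
                logits = model(Tensor(xs[idx]))
                loss = cross_entropy(logits, y_train[idx])
                if not np.isfinite(loss.item()):
                    raise DivergenceError(
                        f"non-finite training loss {loss.item()} at epoch "
                        f"{epoch}, batch {i // cfg.batch_size}")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(loss.item())
                if model.last_fusion_weights is not None:
                    wfa_means.append(model.last_fusion_weights.mean(axis=0))

            val_loss, val_top1 = _validation_stats(model, x_val, y_val,
                                                   cfg.batch_size)
            improved, decay, stop = schedule.update(val_top1)
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": val_loss, "val_top1": val_top1,
                     "lr": optimizer.lr, "wall_time": time.time() - t0}
            if wfa_means:
                entry["wfa_weights"] = np.mean(wfa_means, axis=0).tolist()
            history.epochs.append(entry)
            if log_fh:
                log_fh.write(json.dumps({"event": "epoch", **entry}) + "\n")
            if improved:
                best_state = model.state_dict()
                history.best_epoch = epoch
            if decay:
                optimizer.lr *= cfg.lr_decay_factor
            if stop:
                history.stop_reason = "early_stop"
                break
        else:
            history.stop_reason = "max_epochs"
    finally:
        if log_fh:
            log_fh.write(json.dumps({
                "event": "done", "best_epoch": history.best_epoch,
                "stop_reason": history.stop_reason}) + "\n")
            log_fh.close()
    model.load_state_dict(best_state)
    return best_state, history


def evaluate(model: WheatStageNet, test_set: tuple[np.ndarray, np.ndarray],
             batch_size: int = 64,
             class_names: tuple[str, ...] | None = None,
             ) -> tuple[MetricReport, RocResult]:
    """Inference-mode evaluation: full metric report plus ROC curves."""
    x, y = test_set
    k = model.cfg.num_classes
    if y.max() >= k:
        raise ValueError(f"labels reach {y.max()} but model has {k} classes")
    probs = _forward_in_batches(model, x, batch_size)
    preds = probs.argmax(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = compute_report(y, preds, probs, class_names=class_names)
        roc = roc_auc_ovr(y, probs)
    return report, roc
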