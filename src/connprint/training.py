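"""Training recipe: Adam, gradient clipping, recurrent L2, plateau LR schedule.

The objective is mean cross-entropy over the minibatch plus
``recurrent_l2 * sum(recurrent_kernel ** 2)`` (the penalty is added
un-normalized, the usual framework convention, so the coefficient is
interpreted per-sum rather than per-sample).  Gradients are clipped by
their *global* norm across all trainable tensors.  After every epoch the
model is scored on the validation clips and checkpointed only on strict
improvement; the learning rate is halved when validation accuracy
plateaus, and training stops early after a longer plateau.

Internally the optimizer works on a float32 copy of the weights for
throughput; the returned checkpoint is cast back to float64.  With a
fixed seed the whole procedure is deterministic on a single-threaded
BLAS; with threaded BLAS reductions it is reproducible statistically.
"""

from __future__ import annotations

import copy
import sys
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas_io import CohortSplit, TimeSeriesClip
from .convrnn import (
    ConvRnnModel,
    ModelConfig,
    _model_backward,
    _model_forward,
    initialize_weights,
    predict_proba,
)
from .errors import ValidationError


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 128
    initial_lr: float = 0.001
    clip_norm: float = 1.0
    recurrent_l2_grid: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001)
    max_epochs: int = 100
    lr_reduce_factor: float = 0.5
    lr_patience: int = 3
    early_stop_patience: int = 10
    seed: int = 0
    verbose: bool = True
    #: stop once validation accuracy is perfect: the checkpoint can no
    #: longer change, since saving requires a strict improvement
    stop_at_perfect_validation: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if not self.initial_lr > 0 or not self.clip_norm > 0:
            raise ValidationError("initial_lr and clip_norm must be positive")
        if not self.recurrent_l2_grid:
            raise ValidationError("recurrent_l2_grid must be non-empty")
        if not 0.0 < self.lr_reduce_factor < 1.0:
            raise ValidationError("lr_reduce_factor must be in (0, 1)")


@dataclass
class TrainingHistory:
    """Per-epoch log plus the per-step diagnostics the recipe guarantees."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_validation_accuracy: float = float("-inf")
    step_grad_norms: list[float] = field(default_factory=list)
    checkpoint_epochs: list[int] = field(default_factory=list)
    checkpoint_val_accuracies: list[float] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


def _clips_to_arrays(
    clips: list[TimeSeriesClip], label_map: dict[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    if not clips:
        raise ValidationError("clip list is empty")
    windows = {c.window for c in clips}
    if len(windows) != 1:
        raise ValidationError(f"clips have mixed window lengths: {sorted(windows)}")
    x = np.stack([c.values for c in clips]).astype(np.float32)
    y = np.array([label_map[c.subject_id] for c in clips], dtype=np.int64)
    return x, y


class _Adam:
    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        correction = np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= (lr * correction) * m / (np.sqrt(v) + self.eps)


def _clip_global_norm(grads: list[np.ndarray], clip_norm: float) -> float:
    """Scale gradients to a global norm of at most ``clip_norm``.

    Returns the post-clip global norm.
    """
    total = float(np.sqrt(sum(float(np.sum(np.square(g, dtype=np.float64))) for g in grads)))
    if total > clip_norm:
        scale = clip_norm / total
        for g in grads:
            g *= scale
        return clip_norm
    return total


def _accuracy(model: ConvRnnModel, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    pred = predict_proba(model, x, batch_size=batch_size).argmax(axis=1)
    return float((pred == y).mean())


def train(
    model: ConvRnnModel,
    split: CohortSplit,
    cfg: TrainingConfig,
    log=sys.stderr,
) -> tuple[ConvRnnModel, TrainingHistory]:
    """Fit the network on a cohort split; return the checkpointed best model.

    The returned model is the one saved at the best validation epoch
    (never the final-epoch weights) with the split's label map attached.
    """
    config = model.config
    label_map = split.label_map
    if config.n_classes != len(label_map):
        raise ValidationError(
            f"model has {config.n_classes} classes but split labels {len(label_map)} subjects"
        )
    x_train, y_train = _clips_to_arrays(split.train, label_map)
    x_val, y_val = _clips_to_arrays(split.validation, label_map)
    if x_train.shape[1] != x_val.shape[1]:
        raise ValidationError("train and validation clips have different window lengths")

    weights32 = model.weights.astype(np.float32)
    work = ConvRnnModel(config=config, weights=weights32, label_map=label_map)
    params = [arr for _, arr in weights32.trainable_arrays()]
    names = [name for name, _ in weights32.trainable_arrays()]
    adam = _Adam(params)
    shuffle_ss, dropout_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    dropout_rng = np.random.default_rng(dropout_ss)

    history = TrainingHistory()
    best_weights = None
    lr = cfg.initial_lr
    epochs_since_improvement = 0
    n_train = x_train.shape[0]
    l2 = config.recurrent_l2

    for epoch in range(cfg.max_epochs):
        t0 = time.time()
        perm = shuffle_rng.permutation(n_train)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n_train, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            out = _model_forward(
                weights32, config, xb, training=True, dropout_rng=dropout_rng, keep_cache=True
            )
            probs = out["probs"]
            ce = float(-np.log(np.maximum(probs[np.arange(len(yb)), yb], 1e-30)).mean())
            penalty = l2 * sum(
                float(np.sum(np.square(lw.recurrent_kernel, dtype=np.float64)))
                for lw in weights32.layers
            )
            loss = ce + penalty
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {start // cfg.batch_size}: "
                    f"ce={ce}, l2 penalty={penalty}, lr={lr}"
                )
            grad_dict = _model_backward(weights32, config, out, yb, recurrent_l2=l2)
            grads = [grad_dict[name] for name in names]
            history.step_grad_norms.append(_clip_global_norm(grads, cfg.clip_norm))
            adam.step(params, grads, lr)
            epoch_loss += ce * len(yb)
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
        train_loss = epoch_loss / n_train
        train_acc = epoch_correct / n_train
        val_acc = _accuracy(work, x_val, y_val, cfg.batch_size)
        history.epochs.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_accuracy": train_acc,
                "validation_accuracy": val_acc,
                "learning_rate": lr,
            }
        )
        if val_acc > history.best_validation_accuracy:
            history.best_validation_accuracy = val_acc
            history.best_epoch = epoch
            history.checkpoint_epochs.append(epoch)
            history.checkpoint_val_accuracies.append(val_acc)
            best_weights = copy.deepcopy(weights32)
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
            if epochs_since_improvement % cfg.lr_patience == 0:
                lr *= cfg.lr_reduce_factor
        if cfg.verbose and log is not None:
            print(
                f"epoch {epoch:3d}  loss {train_loss:.4f}  train_acc {train_acc:.4f}  "
                f"val_acc {val_acc:.4f}  lr {lr:.2e}  ({time.time() - t0:.1f}s)",
                file=log,
            )
        if epochs_since_improvement >= cfg.early_stop_patience:
            break
        if cfg.stop_at_perfect_validation and history.best_validation_accuracy >= 1.0:
            break
    assert best_weights is not None
    best = ConvRnnModel(
        config=config, weights=best_weights.astype(np.float64), label_map=dict(label_map)
    )
    return best, history


def grid_search_l2(
    split: CohortSplit,
    cfg: TrainingConfig,
    model_config: ModelConfig | None = None,
    log=sys.stderr,
) -> tuple[pd.DataFrame, ConvRnnModel]:
    """Train one model per L2 value on the grid; pick the best by validation.

    Every candidate starts from the same seeded initialization and sees
    the same shuffles.  Ties in best validation accuracy are broken
    toward the smaller L2 value.
    """
    if model_config is None:
        model_config = ModelConfig(n_classes=len(split.label_map))
    results = []
    best: tuple[float, float, ConvRnnModel] | None = None
    for l2 in cfg.recurrent_l2_grid:
        candidate_cfg = replace(model_config, recurrent_l2=float(l2))
        model = ConvRnnModel(
            config=candidate_cfg,
            weights=initialize_weights(candidate_cfg, seed=cfg.seed),
        )
        fitted, history = train(model, split, cfg, log=log)
        acc = history.best_validation_accuracy
        results.append({"l2": float(l2), "best_validation_accuracy": acc})
        if best is None or acc > best[0] or (acc == best[0] and l2 < best[1]):
            best = (acc, float(l2), fitted)
    assert best is not None
    return pd.DataFrame(results), best[2]
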