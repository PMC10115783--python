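"""Regenerate-then-update training.

Each step discards any previously generated weight matrix, rolls out fresh
weights from the current wiring rules, evaluates the batch loss through them,
and updates the *rules* with Adam. Evaluation runs on a hold-out set at a
fixed batch cadence; the reported figure for a run is the best hold-out
accuracy seen. Early stopping follows the improvement-threshold protocol:
after the second evaluation, stop as soon as an evaluation fails to beat the
best so far by more than ``early_stop_delta``.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Adam, cross_entropy, grad, no_grad, softmax_accuracy
from .genome_core import ParamBudget

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "PRESETS",
    "train_step",
    "evaluate",
    "fit",
    "compression_report",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    max_batches: int = 30_000
    eval_every: int = 1_000
    early_stop_delta: float = 0.005
    learning_rate: float = 1e-3
    seed: int = 0
    patience: int = 1  # evaluations below threshold before stopping
    max_epochs: int | None = None  # when set, max_batches/eval_every derive from it


#: Published training schedules, named by experiment.
PRESETS: dict[str, TrainConfig] = {
    # digit benchmarks: batches of 64, cap 30k, eval each 1k, stop at ≤0.005 gain
    "mnist-slp": TrainConfig(batch_size=64, max_batches=30_000, eval_every=1_000,
                             early_stop_delta=0.005, learning_rate=1e-3),
    "mnist-mlp": TrainConfig(batch_size=64, max_batches=30_000, eval_every=1_000,
                             early_stop_delta=0.005, learning_rate=1e-3),
    # LeNet-5 runs: batches of 128 for 200 epochs, evaluated every epoch
    "lenet5": TrainConfig(batch_size=128, max_epochs=200, max_batches=0,
                          eval_every=0, early_stop_delta=0.0, learning_rate=1e-3),
    "cifar-lenet5": TrainConfig(batch_size=128, max_epochs=200, max_batches=0,
                                eval_every=0, early_stop_delta=0.0, learning_rate=1e-3),
}


@dataclass
class TrainHistory:
    records: list = field(default_factory=list)  # (batch, split, loss, accuracy)
    best_accuracy: float = 0.0
    stopped_early: bool = False
    budget: ParamBudget | None = None

    def holdout_curve(self):
        return [(b, a) for b, s, _, a in self.records if s == "holdout"]


def train_step(model, batch, optimizer: Adam, loss_fn=cross_entropy):
    """One regenerate-forward-backward-update cycle on the rule parameters."""
    x, y = batch
    logits = model.forward(x)
    loss = loss_fn(logits, y)
    if not np.isfinite(loss.data):
        norms = {k: float(np.linalg.norm(v.data)) for k, v in model.params.items()}
        raise FloatingPointError(f"non-finite training loss; rule-parameter norms: {norms}")
    names = list(model.params)
    grads = grad(loss, [model.params[k] for k in names])
    optimizer.step(dict(zip(names, grads)))
    return float(loss.data)


def evaluate(model, dataset) -> float:
    """Argmax accuracy on a labeled set; no parameter updates."""
    x, y = dataset
    with no_grad():
        logits = model.forward(x)
    return softmax_accuracy(logits, y)


def _resolve_epochs(config: TrainConfig, batches_per_epoch: int) -> TrainConfig:
    if config.max_epochs is None:
        return config
    return replace(
        config,
        max_batches=config.max_epochs * batches_per_epoch,
        eval_every=batches_per_epoch,
        max_epochs=None,
    )


def fit(model, task, config: TrainConfig, eval_fn=None, stop_at: float | None = None,
        log=False) -> TrainHistory:
    """Run the full training protocol and return its history.

    ``task`` provides ``train_x/train_y`` and ``holdout_x/holdout_y`` plus a
    flat input dimension. ``eval_fn(model, batch_index) -> accuracy`` replaces
    hold-out evaluation when given (protocol tests use this). ``stop_at``
    optionally ends the run once the hold-out accuracy reaches a level —
    useful for capability probes where only "reached within N batches"
    matters.
    """
    if task is None or len(task.train_x) == 0:
        raise ValueError("task provides no training examples")
    config = _resolve_epochs(config, max(1, len(task.train_x) // config.batch_size))
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    history = TrainHistory(budget=model.budget())
    holdout = (task.holdout_x, task.holdout_y)

    best = 0.0
    n_evals = 0
    misses = 0
    loss_acc, loss_n = 0.0, 0
    t0 = time.time()
    for b in range(1, config.max_batches + 1):
        idx = rng.integers(0, len(task.train_x), config.batch_size)
        loss = train_step(model, (task.train_x[idx], task.train_y[idx]), opt)
        loss_acc += loss
        loss_n += 1
        if b % config.eval_every == 0:
            acc = eval_fn(model, b) if eval_fn is not None else evaluate(model, holdout)
            history.records.append((b, "train", loss_acc / loss_n, float("nan")))
            history.records.append((b, "holdout", float("nan"), acc))
            loss_acc, loss_n = 0.0, 0
            n_evals += 1
            if log:
                print(f"[{time.time() - t0:8.1f}s] batch {b}: holdout acc {acc:.4f}",
                      file=sys.stderr)
            improved = acc > best + config.early_stop_delta
            best = max(best, acc)
            history.best_accuracy = best
            if stop_at is not None and best >= stop_at:
                break
            if n_evals >= 2 and not improved:
                misses += 1
                if misses >= config.patience:
                    history.stopped_early = True
                    break
            else:
                misses = 0
    return history


def compression_report(model) -> dict:
    """Encoded vs direct parameter counts for one model."""
    budget = model.budget()
    direct = model.direct_parameter_count()
    return {
        "encoded_total": budget.total,
        "encoded_learned": budget.learned_total,
        "direct_total": direct,
        "percent_of_direct": 100.0 * budget.total / direct,
        "fold_compression": direct / budget.total,
    }
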