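"""MAML few-shot training of encoded models.

The outer "evolution" loop maintains wiring rules; for each episode the inner
"learning" loop takes a few gradient steps on the rules using the support
examples, and the meta-objective is the query loss after adaptation. Because
the forward pass regenerates weights from rules, adaptation edits the
developmental program rather than a weight matrix. Each named parameter
tensor carries its own learned inner-loop learning rate, trained in the outer
loop alongside the rules. Meta-gradients flow through the unrolled inner
steps (second order) by default; a first-order switch cuts the graph at the
inner gradients.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, cross_entropy, grad, no_grad, softmax_accuracy
from .training import TrainHistory

__all__ = [
    "Episode",
    "MetaConfig",
    "sample_episode",
    "make_lr_params",
    "inner_adapt",
    "maml_meta_step",
    "evaluate_episodes",
    "meta_fit",
]


@dataclass
class Episode:
    support_x: np.ndarray
    support_y: np.ndarray
    query_x: np.ndarray
    query_y: np.ndarray
    ways: int
    shots: int


@dataclass(frozen=True)
class MetaConfig:
    """Few-shot schedule; defaults are the published Omniglot protocol:
    5-way 1-shot, 2 inner steps, meta-batches of 32 episodes, Adam at 1e-3
    for up to 50,000 meta-batches, hold-out evaluation every 250 meta-batches
    averaged over 10 batches of 64 query predictions."""

    ways: int = 5
    shots: int = 1
    query_shots: int = 1
    inner_steps: int = 2
    meta_batch: int = 32
    meta_lr: float = 1e-3
    max_meta_batches: int = 50_000
    eval_every: int = 250
    eval_batches: int = 10
    eval_batch_size: int = 64
    inner_lr_init: float = 1e-3
    second_order: bool = True
    seed: int = 0


def sample_episode(pool: dict, ways: int, shots: int, query_shots: int,
                   rng: np.random.Generator) -> Episode:
    """Draw an N-way K-shot episode; labels remapped to 0..ways−1."""
    classes = sorted(pool)
    if len(classes) < ways:
        raise ValueError(f"pool has {len(classes)} classes, need {ways}")
    chosen = rng.choice(len(classes), size=ways, replace=False)
    sx, sy, qx, qy = [], [], [], []
    for new_label, ci in enumerate(chosen):
        ex = pool[classes[ci]]
        need = shots + query_shots
        if len(ex) < need:
            raise ValueError(
                f"class {classes[ci]} has {len(ex)} examples, need {need}"
            )
        pick = rng.choice(len(ex), size=need, replace=False)
        sx.append(ex[pick[:shots]])
        sy.extend([new_label] * shots)
        qx.append(ex[pick[shots:]])
        qy.extend([new_label] * query_shots)
    return Episode(
        support_x=np.concatenate(sx),
        support_y=np.asarray(sy),
        query_x=np.concatenate(qx),
        query_y=np.asarray(qy),
        ways=ways,
        shots=shots,
    )


def make_lr_params(model, init: float = 1e-3) -> dict:
    """One learned inner-loop learning-rate scalar per named parameter tensor."""
    return {f"lr.{k}": Tensor(np.asarray(init), requires_grad=True) for k in model.params}


def inner_adapt(model, params: dict, support, steps: int, lr_params: dict,
                second_order: bool = True) -> dict:
    """Functionally adapt rule parameters on the support set.

    Returns a fresh name → Tensor dict; the passed parameters are never
    mutated. With ``second_order`` the adapted parameters remain
    differentiable w.r.t. both the originals and the learning rates.
    """
    sx, sy = support
    current = dict(params)
    names = list(params)
    for _ in range(steps):
        loss = cross_entropy(model.forward(sx, current), sy)
        gs = grad(loss, [current[k] for k in names], create_graph=second_order)
        if not second_order:
            gs = [g.detach() for g in gs]
        current = {
            k: current[k] - lr_params[f"lr.{k}"] * g for k, g in zip(names, gs)
        }
    return current


def maml_meta_step(model, episodes, optimizer: Adam, lr_params: dict,
                   config: MetaConfig) -> float:
    """One outer step: mean post-adaptation query loss over a meta-batch."""
    meta_loss = None
    for ep in episodes:
        adapted = inner_adapt(
            model, model.params, (ep.support_x, ep.support_y),
            config.inner_steps, lr_params, config.second_order,
        )
        ql = cross_entropy(model.forward(ep.query_x, adapted), ep.query_y)
        meta_loss = ql if meta_loss is None else meta_loss + ql
    meta_loss = meta_loss * (1.0 / len(episodes))
    if not np.isfinite(meta_loss.data):
        norms = {k: float(np.linalg.norm(v.data)) for k, v in model.params.items()}
        raise FloatingPointError(f"non-finite meta-loss; rule-parameter norms: {norms}")
    all_params = dict(model.params)
    all_params.update(lr_params)
    names = list(all_params)
    gs = grad(meta_loss, [all_params[k] for k in names])
    optimizer.step(dict(zip(names, gs)))
    return float(meta_loss.data)


def evaluate_episodes(model, pool: dict, config: MetaConfig,
                      rng: np.random.Generator, lr_params: dict) -> float:
    """Post-adaptation query accuracy, averaged over the evaluation schedule.

    Runs ``eval_batches`` batches; each batch accumulates episodes until
    ``eval_batch_size`` query predictions have been made, and the reported
    figure is the mean accuracy over batches.
    """
    per_episode = config.ways * config.query_shots
    episodes_per_batch = max(1, config.eval_batch_size // per_episode)
    accs = []
    for _ in range(config.eval_batches):
        correct, total = 0.0, 0
        for _ in range(episodes_per_batch):
            ep = sample_episode(pool, config.ways, config.shots, config.query_shots, rng)
            adapted = inner_adapt(
                model, model.params, (ep.support_x, ep.support_y),
                config.inner_steps, lr_params, second_order=False,
            )
            with no_grad():
                logits = model.forward(ep.query_x, adapted)
            correct += softmax_accuracy(logits, ep.query_y) * len(ep.query_y)
            total += len(ep.query_y)
        accs.append(correct / total)
    return float(np.mean(accs))


def meta_fit(model, train_pool: dict, test_pool: dict, config: MetaConfig,
             lr_params: dict | None = None, eval_fn=None,
             stop_at: float | None = None, log=False) -> TrainHistory:
    """Full MAML run over disjoint train/test class pools."""
    overlap = set(train_pool) & set(test_pool)
    if overlap:
        raise ValueError(f"train and test class pools overlap: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(config.seed)
    eval_rng = np.random.default_rng(config.seed + 1)
    if lr_params is None:
        lr_params = make_lr_params(model, config.inner_lr_init)
    all_params = dict(model.params)
    all_params.update(lr_params)
    opt = Adam(all_params, lr=config.meta_lr)
    history = TrainHistory(budget=model.budget())
    t0 = time.time()
    loss_acc, loss_n = 0.0, 0
    for mb in range(1, config.max_meta_batches + 1):
        episodes = [
            sample_episode(train_pool, config.ways, config.shots, config.query_shots, rng)
            for _ in range(config.meta_batch)
        ]
        loss_acc += maml_meta_step(model, episodes, opt, lr_params, config)
        loss_n += 1
        if mb % config.eval_every == 0:
            if eval_fn is not None:
                acc = eval_fn(model, mb)
            else:
                acc = evaluate_episodes(model, test_pool, config, eval_rng, lr_params)
            history.records.append((mb, "train", loss_acc / loss_n, float("nan")))
            history.records.append((mb, "holdout", float("nan"), acc))
            loss_acc, loss_n = 0.0, 0
            history.best_accuracy = max(history.best_accuracy, acc)
            if log:
                print(f"[{time.time() - t0:8.1f}s] meta-batch {mb}: "
                      f"holdout acc {acc:.4f}", file=sys.stderr)
            if stop_at is not None and history.best_accuracy >= stop_at:
                break
    return history
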