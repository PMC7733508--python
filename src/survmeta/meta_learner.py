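"""First-order gradient-based meta-learning for few-shot survival prediction.

One meta-round: sample ``m`` tasks from the multi-task pool, adapt a copy of
the shared initialisation ``theta`` to each task with ``k`` plain-SGD steps
(one minibatch per step), then move theta toward the mean adapted solution,

    theta <- theta + gamma * (1/m) * sum_tau (theta_tau^k - theta).

The mean displacement can equivalently be handed to an adaptive first/second
moment optimizer (Adam) as a negative gradient — the default, matching the
selected hyper-parameters (inner SGD at 0.01, 5 steps, batch 100; meta-level
Adam at 1e-4, 10 tasks per update, L2 scale 0.1). The epoch counter advances
by m per round, so ``meta_epochs`` counts tasks consumed, not data passes.

After meta-training, :func:`final_learn` fine-tunes all parameters on the
few-shot target data with ordinary minibatch SGD — the same procedure as a
single inner loop, without an outer loop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cox_network import (
    ModelParams,
    NetworkConfig,
    cox_loss,
    init_params,
    loss_gradient,
)
from .data_model import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "MetaConfig",
    "TaskBatch",
    "AdamState",
    "sample_tasks",
    "inner_adapt",
    "meta_update",
    "meta_train",
    "final_learn",
    "sgd_train",
]


@dataclass
class MetaConfig:
    """Meta-learning stage hyper-parameters (defaults = selected values)."""

    inner_lr: float = 0.01          # task-level learning rate (alpha)
    inner_steps: int = 5            # task-level gradient steps (k)
    inner_batch: int = 100          # task-level batch size
    meta_lr: float = 0.0001        # meta-level learning rate (gamma)
    tasks_per_update: int = 10      # meta-level tasks batch size (m)
    meta_epochs: int = 3000         # total tasks consumed (Algorithm counter n)
    task_mode: str = "per_task"     # per_task | mixed
    meta_optimizer: str = "adam"    # adam | sgd (plain Eq.-style step)
    l2_scale: float = 0.1
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tasks_per_update < 1 or self.inner_steps < 1:
            raise ValueError("m and k must be >= 1")
        if self.inner_lr <= 0 or self.meta_lr < 0:
            # meta_lr = 0 is allowed: it freezes theta (a useful fixed-point
            # contract), while inner_lr = 0 would make adaptation a no-op
            raise ValueError("inner_lr must be positive and meta_lr nonnegative")
        if self.task_mode not in ("per_task", "mixed"):
            raise ValueError(f"unknown task_mode {self.task_mode!r}")
        if self.meta_optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown meta_optimizer {self.meta_optimizer!r}")


@dataclass
class TaskBatch:
    """The k ordered minibatches one inner loop will consume for one task."""

    task_id: str
    minibatches: list[SurvivalDataset]

    def __post_init__(self) -> None:
        if not self.minibatches or any(len(b) == 0 for b in self.minibatches):
            raise ValueError("each task needs at least one nonempty minibatch")


def _minibatch_indices(
    pool_size: int, batch: int, k: int, rng: np.random.Generator, label: str
) -> list[np.ndarray]:
    """k index sets of size ``batch``; without replacement within a pass."""
    if pool_size < batch:
        warnings.warn(
            f"task {label!r} has {pool_size} samples < batch {batch}; "
            "sampling with replacement"
        )
        return [rng.choice(pool_size, size=batch, replace=True) for _ in range(k)]
    order: list[int] = []
    while len(order) < batch * k:
        order.extend(rng.permutation(pool_size))
    order_arr = np.array(order[: batch * k])
    return [order_arr[s * batch : (s + 1) * batch] for s in range(k)]


def _take(dataset: SurvivalDataset, indices: np.ndarray) -> SurvivalDataset:
    """Subset that tolerates repeated rows (with-replacement minibatches).

    Repeated draws get a ``#r<k>`` suffix on their sample id so the
    uniqueness invariant holds; the Cox loss is id-agnostic.
    """
    idx = np.asarray(indices, dtype=int)
    if np.unique(idx).size == idx.size:
        return dataset.subset(idx)
    from dataclasses import replace as _replace
    from .data_model import ExpressionMatrix

    counts: dict[int, int] = {}
    ids, recs = [], []
    for i in idx:
        k = counts.get(i, 0)
        counts[i] = k + 1
        rec = dataset.records[i]
        sid = rec.sample_id if k == 0 else f"{rec.sample_id}#r{k}"
        ids.append(sid)
        recs.append(rec if k == 0 else _replace(rec, sample_id=sid))
    mat = ExpressionMatrix(ids, dataset.gene_ids, dataset.x[idx])
    return SurvivalDataset(mat, recs)


def sample_tasks(
    multitask: SurvivalDataset,
    config: MetaConfig,
    rng: np.random.Generator,
) -> list[TaskBatch]:
    """Draw the m TaskBatches for one meta-update.

    per_task mode: each batch's pool is one task label (cancer type), labels
    drawn without replacement within the round when enough exist. mixed
    mode: each pool is a uniform draw of ``inner_batch * inner_steps``
    samples across all labels, so successive minibatches can span cancers.
    """
    m, k, batch = config.tasks_per_update, config.inner_steps, config.inner_batch
    batches: list[TaskBatch] = []
    if config.task_mode == "per_task":
        labels = sorted(set(multitask.task_labels))
        if m <= len(labels):
            chosen = rng.choice(len(labels), size=m, replace=False)
        else:
            chosen = rng.choice(len(labels), size=m, replace=True)
        label_idx: dict[str, np.ndarray] = {
            lab: np.flatnonzero(multitask.task_labels == lab) for lab in labels
        }
        for c in chosen:
            lab = labels[c]
            pool = label_idx[lab]
            idx_sets = _minibatch_indices(pool.size, batch, k, rng, lab)
            batches.append(
                TaskBatch(lab, [_take(multitask, pool[s]) for s in idx_sets])
            )
    else:  # mixed
        n = len(multitask)
        pool_size = min(batch * k, n)
        for t in range(m):
            pool = rng.choice(n, size=pool_size, replace=False)
            idx_sets = _minibatch_indices(pool.size, batch, k, rng, f"mixed-{t}")
            batches.append(
                TaskBatch(f"mixed-{t}", [_take(multitask, pool[s]) for s in idx_sets])
            )
    return batches


def inner_adapt(
    theta: ModelParams,
    task: TaskBatch,
    inner_lr: float,
    inner_steps: Optional[int] = None,
    l2_scale: float = 0.0,
    activation: str = "relu",
) -> ModelParams:
    """k steps of plain SGD from theta, one minibatch per step; theta untouched."""
    k = len(task.minibatches) if inner_steps is None else inner_steps
    if k > len(task.minibatches):
        raise ValueError(f"{k} steps requested but only {len(task.minibatches)} minibatches")
    adapted = theta.copy()
    for s in range(k):
        grad = loss_gradient(
            adapted, task.minibatches[s], l2_scale=l2_scale, activation=activation
        )
        for p, g in zip(adapted.arrays(), grad.arrays()):
            p -= inner_lr * g
    adapted.check_finite()
    return adapted


@dataclass
class AdamState:
    """Per-parameter first/second moment accumulators for the meta-learner."""

    step: int = 0
    m: Optional[list[np.ndarray]] = None
    v: Optional[list[np.ndarray]] = None
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


def meta_update(
    theta: ModelParams,
    adapted: Sequence[ModelParams],
    meta_lr: float,
    optimizer_state: Optional[AdamState] = None,
) -> tuple[ModelParams, Optional[AdamState]]:
    """One meta-learner step from the m adapted parameter sets.

    Plain mode (``optimizer_state is None``): theta + gamma * mean
    displacement. Adaptive mode: the negative mean displacement is fed to
    Adam as a gradient, with per-parameter moment state carried across
    rounds.
    """
    if not adapted:
        raise ValueError("need at least one adapted parameter set")
    m = len(adapted)
    theta_arrays = theta.arrays()
    deltas = []
    for i, base in enumerate(theta_arrays):
        acc = np.zeros_like(base)
        for a in adapted:
            arr = a.arrays()[i]
            if arr.shape != base.shape:
                raise ValueError("adapted parameter shape mismatch")
            acc += arr - base
        deltas.append(acc / m)

    new = theta.copy()
    if optimizer_state is None:
        for p, d in zip(new.arrays(), deltas):
            p += meta_lr * d
        return new, None

    st = optimizer_state
    if st.m is None:
        st.m = [np.zeros_like(d) for d in deltas]
        st.v = [np.zeros_like(d) for d in deltas]
    st.step += 1
    t = st.step
    for p, d, m1, v1 in zip(new.arrays(), deltas, st.m, st.v):
        g = -d  # descent displacement enters the optimizer as a gradient
        m1 *= st.beta1
        m1 += (1 - st.beta1) * g
        v1 *= st.beta2
        v1 += (1 - st.beta2) * g * g
        mhat = m1 / (1 - st.beta1**t)
        vhat = v1 / (1 - st.beta2**t)
        p -= meta_lr * mhat / (np.sqrt(vhat) + st.eps)
    return new, st


def meta_train(
    multitask: SurvivalDataset,
    net_config: NetworkConfig,
    config: MetaConfig,
    theta: Optional[ModelParams] = None,
    loss_log: Optional[list] = None,
) -> ModelParams:
    """Full meta-learning loop; deterministic given config.seed.

    Repeats {sample m tasks -> inner-adapt each from the current theta ->
    meta-update} until ``meta_epochs`` tasks have been consumed (the counter
    advances by m per round). Appends (round, mean final inner loss,
    displacement norm) tuples to ``loss_log`` when given.
    """
    rng = np.random.default_rng(config.seed)
    if theta is None:
        theta = init_params(net_config)
    state = AdamState() if config.meta_optimizer == "adam" else None
    consumed = 0
    rounds = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        while consumed < config.meta_epochs:
            tasks = sample_tasks(multitask, config, rng)
            adapted = [
                inner_adapt(
                    theta,
                    task,
                    inner_lr=config.inner_lr,
                    l2_scale=config.l2_scale,
                    activation=config.activation,
                )
                for task in tasks
            ]
            new_theta, state = meta_update(theta, adapted, config.meta_lr, state)
            if loss_log is not None or logger.isEnabledFor(logging.INFO):
                mean_loss = float(
                    np.mean(
                        [
                            cox_loss(a, t.minibatches[-1], activation=config.activation)
                            for a, t in zip(adapted, tasks)
                        ]
                    )
                )
                delta_norm = float(
                    np.sqrt(
                        sum(
                            np.sum((n_ - o_) ** 2)
                            for n_, o_ in zip(new_theta.arrays(), theta.arrays())
                        )
                    )
                )
                if loss_log is not None:
                    loss_log.append((rounds, mean_loss, delta_norm))
                logger.info(
                    "meta-round %d: mean inner loss %.4f, |delta| %.3e",
                    rounds, mean_loss, delta_norm,
                )
            theta = new_theta
            theta.check_finite()
            consumed += config.tasks_per_update
            rounds += 1
    return theta


def sgd_train(
    theta: ModelParams,
    dataset: SurvivalDataset,
    lr: float,
    batch_size: int,
    epochs: int,
    l2_scale: float = 0.1,
    activation: str = "relu",
    seed: int = 0,
    loss_log: Optional[list] = None,
) -> ModelParams:
    """Plain minibatch SGD on the Cox loss; epochs shuffle, batches partition."""
    rng = np.random.default_rng(seed)
    params = theta.copy()
    n = len(dataset)
    batch_size = min(batch_size, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for epoch in range(epochs):
            perm = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = perm[start : start + batch_size]
                if idx.size < 2:
                    continue  # a singleton batch carries no partial-likelihood signal
                batch = dataset.subset(idx)
                grad = loss_gradient(params, batch, l2_scale=l2_scale,
                                     activation=activation)
                for p, g in zip(params.arrays(), grad.arrays()):
                    p -= lr * g
            if loss_log is not None:
                loss_log.append(
                    cox_loss(params, dataset, l2_scale=l2_scale, activation=activation)
                )
    params.check_finite()
    return params


def final_learn(
    theta: ModelParams,
    target_train: SurvivalDataset,
    lr: float = 0.001,
    batch_size: int = 20,
    epochs: int = 100,
    l2_scale: float = 0.1,
    activation: str = "relu",
    seed: int = 0,
    loss_log: Optional[list] = None,
) -> ModelParams:
    """Fine-tune all of theta on few-shot target data (the final learning stage).

    Defaults follow the fine-tune stage: SGD at 0.001, batch 20, L2 0.1; the
    epoch count defaults to 100 so a 20-sample target consumes ~100 gradient
    steps.
    """
    if epochs == 0:
        return theta.copy()
    return sgd_train(
        theta, target_train, lr=lr, batch_size=batch_size, epochs=epochs,
        l2_scale=l2_scale, activation=activation, seed=seed, loss_log=loss_log,
    )
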