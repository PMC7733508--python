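"""Benchmark comparators sharing the neural Cox core.

Four alternatives to meta-learning, all trained on the same information
within a trial:

* direct learning — target-task samples only, from random init; batch size
  is half the training-set size (floored, minimum 2);
* combined learning — one-stage training on the multi-task pool plus the
  few-shot target samples concatenated;
* regular pre-training — stage 1 on the multi-task pool, stage 2 fine-tunes
  all parameters on the target samples;
* linear Cox baseline — no hidden layers, risk = x @ beta, trained on the
  combined pool by the same SGD machinery (the p >> n regime makes the L2
  penalty mandatory).

Shared defaults mirror the selected hyper-parameters: SGD at 0.001, batch
800 for pooled stages, batch 20 for fine-tuning, L2 scale 0.1. Epoch counts
are open config values with logged defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .cox_network import ModelParams, NetworkConfig, init_params
from .data_model import SurvivalDataset
from .meta_learner import final_learn, sgd_train

logger = logging.getLogger(__name__)

__all__ = [
    "SchemeSpec",
    "PretrainResult",
    "train_direct",
    "train_combined",
    "pretrain_then_finetune",
    "train_linear_baseline",
]

SCHEME_NAMES = ("direct", "combined", "pretrain", "meta", "linear_baseline")


def _fresh_init(net_config: NetworkConfig, seed: int) -> ModelParams:
    """Random init tied to the training seed, so repeated trials re-draw it."""
    d = dict(net_config.__dict__)
    d["init_seed"] = seed
    return init_params(NetworkConfig(**d))


@dataclass
class SchemeSpec:
    """Optimizer settings for one training scheme."""

    name: str = "direct"
    target_train_size: int = 20
    rate: float = 0.001
    batch: Optional[int] = None     # None = scheme-specific rule
    epochs: int = 100
    finetune_epochs: int = 100
    l2_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme {self.name!r}")
        if self.target_train_size < 1:
            raise ValueError("target_train_size must be positive")


def _direct_batch(n: int, spec: SchemeSpec) -> int:
    if spec.batch is not None:
        return spec.batch
    return max(2, n // 2)  # half-of-training-size rule, floored, min 2


def train_direct(
    target_train: SurvivalDataset, net_config: NetworkConfig, spec: SchemeSpec
) -> ModelParams:
    """Train from random init on the target task only."""
    if target_train.n_events == 0:
        raise ValueError("direct learning requires at least one event in training data")
    batch = _direct_batch(len(target_train), spec)
    logger.info("direct learning: n=%d, batch=%d, epochs=%d",
                len(target_train), batch, spec.epochs)
    theta = _fresh_init(net_config, spec.seed)
    return sgd_train(
        theta, target_train, lr=spec.rate, batch_size=batch, epochs=spec.epochs,
        l2_scale=spec.l2_scale, activation=net_config.activation, seed=spec.seed,
    )


def train_combined(
    multitask: Optional[SurvivalDataset],
    target_train: SurvivalDataset,
    net_config: NetworkConfig,
    spec: SchemeSpec,
) -> ModelParams:
    """Single-stage training on the multi-task + target pool."""
    pool = target_train if multitask is None or len(multitask) == 0 \
        else multitask.concat(target_train)
    batch = spec.batch if spec.batch is not None else 800
    logger.info("combined learning: pool=%d, batch=%d, epochs=%d",
                len(pool), batch, spec.epochs)
    theta = _fresh_init(net_config, spec.seed)
    return sgd_train(
        theta, pool, lr=spec.rate, batch_size=batch, epochs=spec.epochs,
        l2_scale=spec.l2_scale, activation=net_config.activation, seed=spec.seed,
    )


class PretrainResult(NamedTuple):
    final: ModelParams
    stage1: ModelParams


def pretrain_stage1(
    multitask: SurvivalDataset, net_config: NetworkConfig, spec: SchemeSpec
) -> ModelParams:
    """Stage-1 pre-training on the multi-task pool alone."""
    batch = spec.batch if spec.batch is not None else 800
    theta = init_params(net_config)  # stage 1 is shared across trials; keep its init fixed
    return sgd_train(
        theta, multitask, lr=spec.rate, batch_size=batch, epochs=spec.epochs,
        l2_scale=spec.l2_scale, activation=net_config.activation, seed=spec.seed,
    )


def pretrain_then_finetune(
    multitask: SurvivalDataset,
    target_train: SurvivalDataset,
    net_config: NetworkConfig,
    spec: SchemeSpec,
    stage1: Optional[ModelParams] = None,
) -> PretrainResult:
    """Two-stage regular pre-training; both stage checkpoints returned.

    A precomputed ``stage1`` model may be supplied so the expensive pooled
    stage is shared across trials that differ only in the target draw.
    """
    if stage1 is None:
        stage1 = pretrain_stage1(multitask, net_config, spec)
    final = final_learn(
        stage1, target_train, lr=spec.rate, batch_size=20,
        epochs=spec.finetune_epochs, l2_scale=spec.l2_scale,
        activation=net_config.activation, seed=spec.seed + 1,
    )
    return PretrainResult(final=final, stage1=stage1)


def train_linear_baseline(
    multitask: Optional[SurvivalDataset],
    target_train: SurvivalDataset,
    spec: SchemeSpec,
    init_seed: int = 0,
) -> ModelParams:
    """Penalized linear Cox model (risk = x @ beta) on the combined pool."""
    pool = target_train if multitask is None or len(multitask) == 0 \
        else multitask.concat(target_train)
    net_config = NetworkConfig(
        n_genes=pool.matrix.n_genes, linear=True, hidden_sizes=[],
        feature_size=pool.matrix.n_genes, activation="identity",
        l2_scale=spec.l2_scale, init_seed=init_seed,
    )
    batch = spec.batch if spec.batch is not None else 800
    theta = init_params(net_config)
    theta.beta[:] = 0.0  # start the linear score at the null model
    return sgd_train(
        theta, pool, lr=spec.rate, batch_size=batch, epochs=spec.epochs,
        l2_scale=spec.l2_scale, activation="identity", seed=spec.seed,
    )
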