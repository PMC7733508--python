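"""Shared fixtures: tiny hand-built datasets and small simulated cohorts."""

import numpy as np
import pytest

from survmeta import (
    ExpressionMatrix,
    GeneratorConfig,
    NetworkConfig,
    SurvivalDataset,
    SurvivalRecord,
    generate_multitask_cohort,
    init_params,
)


def make_dataset(values, times, events, task="T", gene_ids=None, subtypes=None):
    """Build a SurvivalDataset from plain arrays (one row per sample)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    gene_ids = gene_ids or [f"g{j}" for j in range(p)]
    sample_ids = [f"s{i}" for i in range(n)]
    records = [
        SurvivalRecord(
            sample_id=sample_ids[i],
            time=float(times[i]),
            event=int(events[i]),
            task_label=task,
            subtype=None if subtypes is None else subtypes[i],
        )
        for i in range(n)
    ]
    return SurvivalDataset(ExpressionMatrix(sample_ids, gene_ids, values), records)


def risk_dataset(risks, times, events):
    """1-gene dataset whose single column equals the desired risk scores."""
    return make_dataset(np.asarray(risks, dtype=float)[:, None], times, events,
                        gene_ids=["g"])


@pytest.fixture(scope="session")
def small_cohort():
    """5 tasks x 60 samples, 20 genes, linear hazard, moderate censoring."""
    cfg = GeneratorConfig(
        n_tasks=5, samples_per_task=(60, 60), n_genes=20, n_signal=5,
        target_censoring_fraction=0.5, seed=42,
    )
    return generate_multitask_cohort(cfg)


@pytest.fixture()
def toy_net():
    """A small network config + params acting on 6 genes."""
    config = NetworkConfig(
        n_genes=6, hidden_sizes=[5, 4], feature_size=3, init_seed=3
    )
    return config, init_params(config)


@pytest.fixture()
def random_batch(toy_net):
    """8-sample, 6-gene batch with mixed censoring."""
    rng = np.random.default_rng(7)
    x = rng.standard_normal((8, 6))
    times = rng.exponential(10.0, 8) + 0.5
    events = np.array([1, 0, 1, 1, 0, 1, 0, 1])
    return make_dataset(x, times, events)
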