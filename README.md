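# survmeta

Few-shot survival prediction on genomic data with meta-learned neural Cox
models.

## The problem

Predicting patient survival from gene expression in a rare cancer is a
few-shot problem: tens of labelled samples, tens of thousands of genes,
and most follow-up times right-censored. Abundant data from *other* cancer
types exists, but naive pooling or pre-training transfers it poorly.
`survmeta` treats each cancer type as a learning task and meta-learns a
neural Cox model initialisation that adapts quickly to a new cancer from as
few as 20 samples.

## The model

A feed-forward extractor z = f_φ(x) feeds a Cox proportional-hazards head
r = zβ, trained by minimising the negative partial log-likelihood

    L(θ) = − Σ_{i:event} [ z_iβ − log Σ_{y_j ≥ y_i} exp(z_jβ) ],   θ = {φ, β}.

The initialisation is meta-learned first-order (Reptile-style): per
meta-round, m tasks are each adapted from the shared θ with k steps of
minibatch SGD (rate α), and the meta-learner moves θ toward the mean
adapted solution,

    θ ← θ + γ · (1/m) Σ_τ (θ_τ^k − θ),

optionally through Adam by treating the negative mean displacement as a
gradient (the default). A final learning stage fine-tunes θ on the
few-shot target data with plain SGD. Benchmarks against direct learning,
combined learning, regular pre-training, and a penalized linear Cox
baseline share the same core, and models are scored by Harrell's
concordance index (C-index) and the IPCW integrated Brier score (IBS) with
Breslow-baseline survival curves. Trained models are interpreted by
risk-score backpropagation (mean ∂risk/∂gene), hypergeometric
over-representation, and pre-ranked running-sum enrichment over GMT gene
sets. A synthetic multi-task cohort generator with known ground truth
makes every pipeline testable offline.

Everything is numpy with hand-written exact backpropagation (verified
against finite differences); no deep-learning framework is required.

## Worked example

Simulate 10 related tasks of 200 samples (100 genes, 78% censored, full
transfer affinity), hold out one task, and compare meta-learning against
direct learning from 20 target samples over 10 trials:

```python
from survmeta import (GeneratorConfig, MetaConfig, NetworkConfig, SchemeSpec,
                      generate_multitask_cohort, run_benchmark)

cohort, truth = generate_multitask_cohort(GeneratorConfig(
    n_tasks=10, samples_per_task=(200, 200), n_genes=100,
    transfer_affinity=1.0, seed=11))

net = NetworkConfig(n_genes=100, hidden_sizes=[64, 32], feature_size=16)
results = run_benchmark(
    cohort, target_label="task00",
    schemes=[SchemeSpec(name="meta"),
             SchemeSpec(name="direct", target_train_size=20)],
    net_config=net, meta_config=MetaConfig(seed=5),
    n_trials=10, test_fraction=0.5, seed=7)

for name, res in results.items():
    s = res.summary()
    print(f"{name:8s} C-index {s['c_index_mean']:.3f} "
          f"(95% CI {s['c_index_ci'][0]:.3f}-{s['c_index_ci'][1]:.3f})  "
          f"IBS {s['ibs_mean']:.3f}")
```

Output (about 10 s on one CPU):

```
meta     C-index 0.753 (95% CI 0.737-0.769)  IBS 0.103
direct   C-index 0.572 (95% CI 0.513-0.630)  IBS 0.105
```

The meta-learned initialisation, fine-tuned on the same 20 samples each
trial, orders three quarters of comparable patient pairs correctly —
approaching the generator's oracle ceiling (ranking by the true log-hazard
gives ≈ 0.75 on this test set) — while direct learning from 20 samples
stays near chance. Setting `transfer_affinity=0` removes the shared signal
and the gap closes: the advantage comes from transferable structure, not
from the architecture.

The same pipeline is scriptable from the shell:

```
survmeta simulate --seed 3 --out-expression X.tsv --out-clinical C.tsv
survmeta meta-train --expression X.tsv --clinical C.tsv \
    --exclude-task task00 --config cfg.yaml --out model.npz
survmeta benchmark --expression X.tsv --clinical C.tsv \
    --target-task task00 --schemes meta,direct --trials 25 --out bench.tsv
survmeta interpret --model model.npz --expression X.tsv \
    --gmt sets.gmt --fraction 0.10 --out enrichment.tsv
```

Each run writes a JSON manifest (config snapshot, seeds, input digests)
beside its outputs.

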