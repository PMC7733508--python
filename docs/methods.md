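# Methods

## Model

The prediction model couples a feed-forward feature extractor to a Cox
proportional-hazards head. For a patient with (preprocessed) expression
vector x, the extractor computes features z = f_φ(x) through fully
connected layers with ReLU activations, and the head scores the log
relative hazard r = zβ. Training minimises the negative Cox partial
log-likelihood over a batch,

    L(θ) = − Σ_{i: event} [ r_i − log Σ_{j: y_j ≥ y_i} exp(r_j) ],

with θ = {φ, β}. The risk set {j : y_j ≥ y_i} is taken literally, ties
included, which coincides with the Breslow convention for tied event times;
no Efron correction is offered. Censored patients contribute no event term
but appear in other patients' risk sets. The log-sum-exp is always
max-stabilised. An optional L2 penalty 0.5·λ·(‖φ_W‖² + ‖β‖²) applies to
weights and β but not biases. A batch with zero events has loss 0 (and a
warning): random few-shot draws from heavily censored cohorts can produce
such batches, and training simply skips them.

All gradients are closed-form backpropagation in numpy; the architecture is
a small fixed MLP, so hand-written chain rule is exact, fast on one CPU, and
is verified against central finite differences (relative 1e-4) in the test
suite. During minibatch SGD the risk set spans the minibatch only —
full-dataset risk sets would make per-minibatch losses ill-defined — while
evaluation-time likelihoods can use the full batch.

## Meta-learning

The initialisation is meta-learned with a first-order (Reptile-style)
scheme. One meta-round: sample m tasks; from the current θ, adapt each with
k steps of plain SGD (one fresh minibatch per step, rate α); then update

    θ ← θ + γ · (1/m) Σ_τ (θ_τ^k − θ).

The mean displacement may instead be handed, negated, to an Adam optimizer
as a gradient — the default meta-optimizer. Defaults follow the selected
hyper-parameters of the full-scale study: α = 0.01, k = 5, inner batch 100,
Adam meta-optimizer at γ = 1e-4, m = 10, L2 scale 0.1. The epoch counter
advances by m per round, so `meta_epochs` counts tasks consumed rather than
passes over data. The number of meta-epochs is open; the default of 3000
tasks (300 meta-rounds at m = 10) was chosen by watching the mean inner-loss
trajectory flatten on desk-scale synthetic cohorts — at the Adam rate of
1e-4 substantially fewer rounds leave the initialisation near its random
start.

Two task-sampling modes exist: `per_task` draws each task's minibatches from
a single task label (a cancer type), labels without replacement within a
round when enough exist; `mixed` builds each pool as a uniform draw of
k × batch samples across labels, so successive minibatches can span
cancers. Tasks smaller than the inner batch are sampled with replacement
(warned); duplicated rows get suffixed sample ids since the loss is
id-agnostic.

After meta-training, `final_learn` fine-tunes all parameters on the
few-shot target data with ordinary minibatch SGD (rate 0.001, batch 20, L2
0.1 — the fine-tune-stage settings), defaulting to 100 epochs so a
20-sample target consumes about 100 gradient steps.

## Benchmark schemes

Direct learning trains from random init on target samples only; its batch
size is half the training size (floored, minimum 2). Combined learning
trains one stage on the multi-task pool plus the target samples (SGD 0.001,
batch 800, L2 0.1). Regular pre-training runs that same pooled stage, then
fine-tunes on the target. The linear baseline drops the extractor entirely
(risk = xβ) and reuses the same SGD machinery on the combined pool — in the
p ≫ n regime the L2 penalty is what keeps it identified. Within a
benchmark trial every scheme operating at the shot size trains on exactly
the same drawn sample ids; direct/combined/linear re-draw their random
initialisation per trial, while the meta and pre-trained stage-1 models are
computed once from the multi-task pool and shared across trials (trials
differ in the target draw, matching the study design). Pooled-stage and
fine-tune epoch counts are open config values; defaults (100) are logged.

## Evaluation

Harrell's concordance index counts pairs (i, j) with y_i < y_j and
event_i = 1 as comparable; pairs whose earlier time is censored, both-
censored pairs, and tied-time both-event pairs are excluded; tied predicted
risks credit 0.5. The implementation is exact against an O(n²)
pair-enumeration oracle and agrees with scikit-survival on distinct-time
data.

Survival curves for Brier scoring come from the Breslow baseline cumulative
hazard H0 estimated on the scheme's final training data (a larger reference
set can be requested, because 20-sample baselines are unstable):
S_i(t) = exp(−H0(t)·exp(r_i)). The Brier score at horizon t is IPCW-
weighted: events by t contribute S_i(t)²/G(y_i⁻), survivors
(1 − S_i(t))²/G(t), earlier-censored subjects 0, averaged over all test
subjects; G is the Kaplan–Meier censoring-survival estimate on the test
cohort. Zero weights are capped at G's smallest positive value with a
warning. The integrated Brier score is the trapezoidal integral of the
Brier curve over the unique observed test times up to the largest observed
event time, normalised by the span of that grid, which keeps the IBS in
[0, 1] and reduces to the time-average in the equal-spacing case.

Benchmark summaries report per-trial metric vectors with mean ± 1.96·SE
normal-approximation 95% intervals (a t-quantile option exists).

## Interpretation

Risk-score backpropagation assigns gene j the sample-average of ∂r_i/∂x_ij
— for a linear model this is exactly β_j. Genes rank most-positive first
(high risk). "Top 10%" selection applies, by default, to the positively
scored (resp. negatively scored) subpopulation, with a flag for
10%-of-all-genes. Over-representation uses the one-sided hypergeometric
tail P(X ≥ k) with the 2×2 odds ratio as statistic and Benjamini–Hochberg
adjustment across the set family; the universe is the genes surviving
preprocessing, not the full annotation. Pre-ranked enrichment is the
weighted Kolmogorov–Smirnov running sum (hits weighted |score|^p, default
exponent 1; misses −1/(N−K)); ES is the signed extremum, the null comes
from label permutations (default 1000, seeded), NES divides ES by the mean
|null ES| of the same sign, and the empirical p-value carries an add-one
correction, so it cannot drop below 1/(B+1).

## Preprocessing

Genes containing any missing value are dropped; remaining values are
log-transformed as log2(x + pseudocount) (pseudocount 1, base and
pseudocount configurable) and z-scored per gene with sample (ddof = 1)
standard deviations. Statistics computed on training data are frozen and
re-applied to test data to avoid leakage. Zero-variance genes are dropped
with a warning.

## Synthetic cohorts

The generator emulates the structure the method assumes: n_tasks tasks
(default 33) of 100–500 samples, standard-normal features per gene (the
model consumes z-scored expression, so Gaussian features match the
post-preprocessing scale — no count-level realism is attempted), a sparse
shared log-hazard direction w0 (10 signal genes, normalised to unit scale),
task coefficients w_τ = a·w0 + ε_τ with per-coordinate perturbation sd 0.05
and transfer affinity a ∈ [0, 1], exponential event times with rate
0.01·exp(x·w_τ) per month (median survival ≈ 70 months at baseline), and
independent censoring calibrated by bisection so the realized censored
fraction hits the target (default 0.78). At a = 1 every task shares the
latent direction and multi-task methods have something to transfer; at
a = 0 tasks are mutually unrelated and the few-shot advantage disappears —
the two ends of the transferability spectrum. Quadratic and interaction
links are available to exercise the nonlinear extractor. Ground truth
(per-task coefficients, true log-hazards, latent event/censor times) is
returned for recovery tests; ranking by the true log-hazard bounds any
model's achievable concordance.

What the generator does not emulate: count-level RNA-seq noise, library
size and batch effects, covariate-dependent censoring, correlated gene
modules. Passing tests therefore demonstrate algorithmic correctness and
the existence of the transfer effect under proportional hazards with
independent censoring — not performance on real transcriptomes.

## Problem sizes and numerical choices

Test and acceptance workloads run at desk scale by design: cohorts of 5–10
tasks × 40–500 samples, 20–100 genes, networks of hidden sizes [8] to
[64, 32] with 4–16 features. The full-scale architecture (hidden 6000 and
2000, 200 features, 17k genes) is a configuration choice, not a code path
difference. The linear-baseline convergence settings used in recovery
experiments (full-batch gradient descent, rate 0.002, a few hundred epochs)
were chosen for stability of the sum-form loss — step sizes above ~1/L for
the partial-likelihood curvature L oscillate, which the descent tests would
catch. Degenerate inputs are contracts, not crashes: zero-event batches
(loss 0, warning), singleton strata (assigned to train, warning), empty
signed gene subsets (empty selection, warning), censoring-survival zeros
(capped weight, warning).

## Known limitations

Stage-1 models are shared across benchmark trials, so trial-to-trial
variation reflects only the target draw and fine-tuning stochasticity, as
in the study design; fully independent replicates would need per-trial
meta-training. The IBS depends on the Breslow-baseline construction of
survival probabilities, which is a documented assumption rather than a
specified part of the evaluation protocol. Harrell's C with the
tied-time/tie-credit conventions above can differ from other packages'
defaults on data with ties.
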