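"""Neural Cox proportional-hazards model.

The model is a feed-forward feature extractor ``z = f_phi(x)`` joined to a
Cox partial-likelihood head ``risk = z @ beta``. The negative partial
log-likelihood over a batch with risk scores ``r`` is

    L = - sum_{i: event_i = 1} [ r_i - log sum_{j: y_j >= y_i} exp(r_j) ],

where the inner sum runs over the batch-local risk set (everyone still under
observation at ``y_i``, ties included — Breslow convention). Censored
subjects contribute no event term but appear in others' risk sets.

Everything is plain numpy with closed-form backpropagation: the architecture
is a small fixed MLP, so exact gradients are cheap and are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_model import SurvivalDataset

__all__ = [
    "NetworkConfig",
    "ModelParams",
    "RiskPrediction",
    "init_params",
    "forward_features",
    "cox_loss",
    "loss_gradient",
    "predict_risk",
    "partial_likelihood",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture and regularisation settings.

    ``hidden_sizes=[]`` with ``linear=True`` gives the linear Cox baseline
    (risk = x @ beta, no extractor). The default architecture mirrors the
    full-scale model (hidden layers 6000 and 2000, feature layer 200, ReLU
    throughout); tests and desk-scale experiments pass smaller sizes.
    """

    n_genes: int = 0
    hidden_sizes: Sequence[int] = (6000, 2000)
    feature_size: int = 200
    activation: str = "relu"
    l2_scale: float = 0.1
    init_seed: int = 0
    linear: bool = False

    def __post_init__(self) -> None:
        self.hidden_sizes = list(self.hidden_sizes)
        if self.linear:
            self.hidden_sizes = []
        elif not self.hidden_sizes and self.feature_size != self.n_genes:
            # extractor-free nonlinear model only makes sense as identity
            pass
        if self.feature_size < 1 and not self.linear:
            raise ValueError("feature_size must be >= 1")
        if self.l2_scale < 0:
            raise ValueError("l2_scale must be nonnegative")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def layer_sizes(self) -> list[int]:
        """Input width of each extractor layer followed by its output width."""
        if self.linear:
            return [self.n_genes]
        return [self.n_genes, *self.hidden_sizes, self.feature_size]


@dataclass
class ModelParams:
    """theta = {phi: extractor weights/biases, beta: Cox coefficients}."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    beta: np.ndarray

    def copy(self) -> "ModelParams":
        return ModelParams(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.beta.copy(),
        )

    def arrays(self) -> list[np.ndarray]:
        """All parameter arrays in a fixed order (weights, biases, beta)."""
        return [*self.weights, *self.biases, self.beta]

    def check_finite(self) -> None:
        for a in self.arrays():
            if not np.all(np.isfinite(a)):
                raise FloatingPointError("non-finite model parameters")

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0] if self.weights else self.beta.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelParams):
            return NotImplemented
        return all(
            a.shape == b.shape and np.array_equal(a, b)
            for a, b in zip(self.arrays(), other.arrays())
        ) and len(self.arrays()) == len(other.arrays())


def init_params(config: NetworkConfig) -> ModelParams:
    """Random initialisation: weights ~ U(-1/sqrt(fan_in), 1/sqrt(fan_in)), biases 0."""
    rng = np.random.default_rng(config.init_seed)
    sizes = config.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    feat = sizes[-1]
    beta = rng.uniform(-1.0 / np.sqrt(feat), 1.0 / np.sqrt(feat), size=feat)
    return ModelParams(weights, biases, beta)


def _activate(a: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(a, 0.0)
    return a


def _forward_cached(params: ModelParams, x: np.ndarray, activation: str):
    """Forward pass keeping pre-activations for backprop."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.n_inputs:
        raise ValueError(
            f"input width {x.shape[1]} does not match model input {params.n_inputs}"
        )
    hs = [x]          # post-activation outputs, hs[0] = input
    pre = []          # pre-activation values per layer
    h = x
    for w, b in zip(params.weights, params.biases):
        a = h @ w + b
        pre.append(a)
        h = _activate(a, activation)
        hs.append(h)
    return hs, pre


def forward_features(
    params: ModelParams, x: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """Extracted features z_i = f_phi(x_i), one row per sample."""
    hs, _ = _forward_cached(params, x, activation)
    return hs[-1]


def predict_risk(
    params: ModelParams, dataset: SurvivalDataset | np.ndarray, activation: str = "relu"
) -> "RiskPrediction":
    """Log relative hazard risk_i = f_phi(x_i) @ beta."""
    if isinstance(dataset, SurvivalDataset):
        x, ids = dataset.x, dataset.sample_ids
    else:
        x = np.atleast_2d(np.asarray(dataset, dtype=float))
        ids = [str(i) for i in range(x.shape[0])]
    z = forward_features(params, x, activation)
    risk = z @ params.beta
    if not np.all(np.isfinite(risk)):
        raise FloatingPointError("non-finite risk predictions")
    return RiskPrediction(sample_ids=list(ids), risk=risk)


@dataclass
class RiskPrediction:
    sample_ids: list[str]
    risk: np.ndarray


# ---------------------------------------------------------------------------
# partial likelihood
# ---------------------------------------------------------------------------

def partial_likelihood(
    risk: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative Cox partial log-likelihood and its gradient w.r.t. the risks.

    Uses max-subtraction stabilised log-sum-exp over each batch-local risk
    set {j : y_j >= y_i}. Returns (loss, dloss/drisk). A batch with no
    events has loss 0 and zero gradient (warned about by callers that care).
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    n = risk.size
    if not np.all(np.isfinite(risk)):
        raise FloatingPointError("non-finite risk scores in partial likelihood")
    ev_idx = np.flatnonzero(events == 1)
    if ev_idx.size == 0:
        return 0.0, np.zeros(n)

    # in_set[k, j] = 1 iff j is in the risk set of event k  (y_j >= y_{ev_k})
    in_set = times[None, :] >= times[ev_idx, None]
    masked = np.where(in_set, risk[None, :], -np.inf)
    m = masked.max(axis=1)
    expterm = np.exp(masked - m[:, None])
    denom = expterm.sum(axis=1)
    lse = m + np.log(denom)
    loss = float(np.sum(lse - risk[ev_idx]))

    grad = (expterm / denom[:, None]).sum(axis=0)
    grad[ev_idx] -= 1.0
    return loss, grad


def _l2_penalty(params: ModelParams, l2_scale: float) -> float:
    # weights and beta only; biases left unpenalised
    sq = sum(float(np.sum(w**2)) for w in params.weights) + float(
        np.sum(params.beta**2)
    )
    return 0.5 * l2_scale * sq


def cox_loss(
    params: ModelParams,
    dataset: SurvivalDataset,
    l2_scale: float = 0.0,
    activation: str = "relu",
) -> float:
    """Negative partial log-likelihood of the batch, optional L2 penalty."""
    risk = predict_risk(params, dataset, activation).risk
    if dataset.n_events == 0:
        warnings.warn("batch contains no events; Cox loss is 0")
        base = 0.0
    else:
        base, _ = partial_likelihood(risk, dataset.times, dataset.events)
    return base + (_l2_penalty(params, l2_scale) if l2_scale > 0 else 0.0)


def loss_gradient(
    params: ModelParams,
    dataset: SurvivalDataset,
    l2_scale: float = 0.0,
    activation: str = "relu",
    return_input_grad: bool = False,
):
    """Exact gradient of :func:`cox_loss` with respect to all of theta.

    Backpropagates the partial-likelihood gradient through the extractor.
    With ``return_input_grad`` the per-sample gradient w.r.t. the inputs is
    returned as well (used by risk-score backpropagation when weighted by
    d loss / d risk = 1 per sample — see interpretation module for the pure
    risk gradient).
    """
    x = dataset.x
    hs, pre = _forward_cached(params, x, activation)
    z = hs[-1]
    risk = z @ params.beta
    _, dl_drisk = partial_likelihood(risk, dataset.times, dataset.events)

    grad = _backprop(params, hs, pre, dl_drisk, activation,
                     return_input_grad=return_input_grad)
    g_params, g_x = grad
    if l2_scale > 0:
        for gw, w in zip(g_params.weights, params.weights):
            gw += l2_scale * w
        g_params.beta += l2_scale * params.beta
    if return_input_grad:
        return g_params, g_x
    return g_params


def _backprop(
    params: ModelParams,
    hs: list[np.ndarray],
    pre: list[np.ndarray],
    dl_drisk: np.ndarray,
    activation: str,
    return_input_grad: bool = False,
):
    """Chain-rule pass given d loss / d risk per sample."""
    z = hs[-1]
    g_beta = z.T @ dl_drisk
    delta = np.outer(dl_drisk, params.beta)  # d loss / d z
    g_w = [np.empty_like(w) for w in params.weights]
    g_b = [np.empty_like(b) for b in params.biases]
    for layer in range(len(params.weights) - 1, -1, -1):
        if activation == "relu":
            delta = delta * (pre[layer] > 0)
        g_w[layer] = hs[layer].T @ delta
        g_b[layer] = delta.sum(axis=0)
        delta = delta @ params.weights[layer].T
    g_x = delta if return_input_grad else None
    return ModelParams(g_w, g_b, g_beta), g_x


def risk_input_gradients(
    params: ModelParams, x: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """Per-sample gradient of risk_i w.r.t. x_i (samples x genes)."""
    hs, pre = _forward_cached(params, x, activation)
    ones = np.ones(hs[0].shape[0])
    _, g_x = _backprop(params, hs, pre, ones, activation, return_input_grad=True)
    return g_x


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: ModelParams, config: NetworkConfig,
                    stats=None) -> None:
    """Single-archive checkpoint: named parameter arrays + JSON metadata."""
    meta = {
        "n_genes": config.n_genes,
        "hidden_sizes": list(config.hidden_sizes),
        "feature_size": config.feature_size,
        "activation": config.activation,
        "l2_scale": config.l2_scale,
        "init_seed": config.init_seed,
        "linear": config.linear,
        "n_layers": len(params.weights),
    }
    arrays = {"beta": params.beta, "meta_json": np.array(json.dumps(meta))}
    if stats is not None:
        arrays["stats_mean"] = stats.mean
        arrays["stats_std"] = stats.std
        arrays["stats_genes"] = np.array(stats.gene_ids)
        meta["log_pseudocount"] = stats.log_pseudocount
        meta["log_base"] = stats.log_base
        arrays["meta_json"] = np.array(json.dumps(meta))
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Returns (ModelParams, NetworkConfig, PreprocessStats | None)."""
    from .data_model import PreprocessStats

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        n_layers = meta.pop("n_layers")
        weights = [data[f"w{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
        params = ModelParams(weights, biases, data["beta"])
        stats = None
        if "stats_mean" in data:
            stats = PreprocessStats(
                gene_ids=[str(g) for g in data["stats_genes"]],
                mean=data["stats_mean"],
                std=data["stats_std"],
                log_pseudocount=meta.pop("log_pseudocount", 1.0),
                log_base=meta.pop("log_base", 2.0),
            )
    config = NetworkConfig(**meta)
    return params, config, stats
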