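"""Survival-model evaluation: concordance index, IPCW Brier scores, and the
multi-trial benchmark harness.

The concordance index is the fraction of comparable subject pairs whose
predicted risk ordering matches their survival ordering. A pair (i, j) with
y_i < y_j is comparable iff subject i's event was observed; pairs whose
earlier time is censored, or with both members censored, cannot be ordered.
Tied-time pairs with both events observed are not well ordered and are
skipped; tied predicted risks on a comparable pair credit 0.5.

The Brier score at horizon t is the censoring-weighted mean squared
difference between the observed status and the predicted survival
probability; its time integral (trapezoidal, normalised by the grid span) is
the integrated Brier score. Predicted survival curves come from the Breslow
baseline cumulative hazard, S_i(t) = exp(-H0(t) * exp(risk_i)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cox_network import ModelParams, NetworkConfig, init_params, predict_risk
from .data_model import SurvivalDataset, draw_target_subset, stratified_split
from .meta_learner import MetaConfig, final_learn, meta_train
from .training_schemes import (
    SchemeSpec,
    pretrain_stage1,
    pretrain_then_finetune,
    train_combined,
    train_direct,
    train_linear_baseline,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StepFunction",
    "SurvivalCurve",
    "EvalResult",
    "concordance_index",
    "km_censoring_estimator",
    "breslow_baseline",
    "brier_score_at",
    "integrated_brier_score",
    "evaluate_model",
    "run_benchmark",
]


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance_index(
    times: np.ndarray, events: np.ndarray, risks: np.ndarray
) -> float:
    """Harrell's C: concordant fraction over comparable pairs."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risks = np.asarray(risks, dtype=float)
    if not (times.size == events.size == risks.size):
        raise ValueError("times, events, risks must have equal length")
    # comparable[i, j]: y_i < y_j and event_i observed
    comparable = (times[:, None] < times[None, :]) & (events[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs: concordance index undefined")
    higher = risks[:, None] > risks[None, :]
    tied = risks[:, None] == risks[None, :]
    concordant = float((higher & comparable).sum()) + 0.5 * float(
        (tied & comparable).sum()
    )
    return concordant / n_pairs


# ---------------------------------------------------------------------------
# step functions / censoring KM / Breslow baseline
# ---------------------------------------------------------------------------

class StepFunction:
    """Right-continuous step function with a left-limit accessor."""

    def __init__(self, times: np.ndarray, values: np.ndarray, start_value: float):
        order = np.argsort(times, kind="stable")
        self.times = np.asarray(times, dtype=float)[order]
        self.values = np.asarray(values, dtype=float)[order]
        self.start_value = float(start_value)

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.start_value)
        return out if out.ndim else float(out)

    def left_limit(self, t) -> np.ndarray | float:
        """Value just before t (G(t-)), for IPCW weighting at event times."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.start_value)
        return out if out.ndim else float(out)


def km_censoring_estimator(times: np.ndarray, events: np.ndarray) -> StepFunction:
    """Kaplan-Meier estimate of the censoring survival function G(t).

    The product-limit estimator with the roles of event and censoring
    exchanged: a drop occurs at each censoring time.
    """
    times = np.asarray(times, dtype=float)
    censored = 1 - np.asarray(events, dtype=int)
    uniq = np.unique(times)
    at_risk = np.array([(times >= t).sum() for t in uniq], dtype=float)
    drops = np.array([censored[times == t].sum() for t in uniq], dtype=float)
    surv = np.cumprod(1.0 - drops / at_risk)
    return StepFunction(uniq, surv, start_value=1.0)


def breslow_baseline(
    train_times: np.ndarray, train_events: np.ndarray, train_risks: np.ndarray
) -> StepFunction:
    """Breslow estimator of the baseline cumulative hazard H0(t).

    H0(t) = sum over event times t_i <= t of d_i / sum_{y_j >= t_i} exp(risk_j).
    Risks are centred before exponentiation for numerical stability; the
    shift cancels when the same centred risks are used in S_i(t).
    """
    times = np.asarray(train_times, dtype=float)
    events = np.asarray(train_events, dtype=int)
    risks = np.asarray(train_risks, dtype=float)
    if events.sum() == 0:
        raise ValueError("Breslow baseline requires at least one event")
    shift = risks.max()
    e = np.exp(risks - shift)
    ev_times = np.unique(times[events == 1])
    increments = np.empty(ev_times.size)
    for i, t in enumerate(ev_times):
        d = int(((times == t) & (events == 1)).sum())
        denom = e[times >= t].sum()
        increments[i] = d / denom
    cumhaz = np.cumsum(increments) * np.exp(-shift)
    return StepFunction(ev_times, cumhaz, start_value=0.0)


@dataclass
class SurvivalCurve:
    """Per-sample survival functions S_i(t) = exp(-H0(t) exp(risk_i))."""

    baseline_cumhaz: StepFunction
    risks: np.ndarray

    @property
    def time_grid(self) -> np.ndarray:
        return self.baseline_cumhaz.times

    def survival_at(self, t) -> np.ndarray:
        """Matrix of S_i(t): rows = samples, columns = horizons."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        h0 = np.atleast_1d(self.baseline_cumhaz(t))
        return np.exp(-np.outer(np.exp(self.risks), h0))


# ---------------------------------------------------------------------------
# Brier / IBS
# ---------------------------------------------------------------------------

def brier_score_at(
    t: float,
    test_times: np.ndarray,
    test_events: np.ndarray,
    surv_at_t: np.ndarray,
    censor_surv: StepFunction,
) -> float:
    """IPCW Brier score at horizon t.

    Subjects with an observed event at or before t contribute
    S_i(t)^2 / G(y_i-); subjects still under observation past t contribute
    (1 - S_i(t))^2 / G(t); subjects censored at or before t contribute 0.
    The mean runs over all test subjects. Zero censoring-survival weights are
    capped at the smallest positive value of G with a warning.
    """
    times = np.asarray(test_times, dtype=float)
    events = np.asarray(test_events, dtype=int)
    s = np.asarray(surv_at_t, dtype=float)
    g_event = np.asarray(censor_surv.left_limit(times), dtype=float)
    g_t = float(censor_surv(t))
    floor = _positive_floor(censor_surv)
    if g_t <= 0 or np.any((g_event <= 0) & (times <= t) & (events == 1)):
        warnings.warn("censoring survival hit 0; IPCW weight capped")
        g_t = max(g_t, floor)
        g_event = np.maximum(g_event, floor)
    contrib = np.zeros(times.size)
    died = (times <= t) & (events == 1)
    alive = times > t
    contrib[died] = s[died] ** 2 / g_event[died]
    contrib[alive] = (1.0 - s[alive]) ** 2 / g_t
    return float(contrib.mean())


def _positive_floor(g: StepFunction) -> float:
    pos = g.values[g.values > 0]
    return float(pos.min()) if pos.size else 1.0


def integrated_brier_score(
    curves: SurvivalCurve | np.ndarray,
    test_times: np.ndarray,
    test_events: np.ndarray,
    censor_surv: Optional[StepFunction] = None,
    time_grid: Optional[np.ndarray] = None,
) -> float:
    """Trapezoidal time-average of the IPCW Brier score.

    The grid defaults to the unique observed test times up to the largest
    observed event time; the integral is normalised by the grid span. Either
    a :class:`SurvivalCurve` or an explicit samples x grid matrix of
    survival probabilities may be supplied.
    """
    times = np.asarray(test_times, dtype=float)
    events = np.asarray(test_events, dtype=int)
    if censor_surv is None:
        censor_surv = km_censoring_estimator(times, events)
    if time_grid is None:
        if events.sum() == 0:
            raise ValueError("IBS undefined: no observed events define t_max")
        t_max = times[events == 1].max()
        time_grid = np.unique(times[times <= t_max])
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size < 2:
        raise ValueError("IBS needs at least two grid points")

    if isinstance(curves, SurvivalCurve):
        surv = curves.survival_at(time_grid)
    else:
        surv = np.asarray(curves, dtype=float)
        if surv.shape != (times.size, time_grid.size):
            raise ValueError("survival matrix must be n_test x n_grid")
    bs = np.array(
        [
            brier_score_at(t, times, events, surv[:, j], censor_surv)
            for j, t in enumerate(time_grid)
        ]
    )
    span = time_grid[-1] - time_grid[0]
    return float(np.trapezoid(bs, time_grid) / span)


# ---------------------------------------------------------------------------
# model-level evaluation and the benchmark harness
# ---------------------------------------------------------------------------

def evaluate_model(
    params: ModelParams,
    test: SurvivalDataset,
    baseline_train: SurvivalDataset,
    activation: str = "relu",
) -> tuple[float, float]:
    """(C-index, IBS) of a trained model on a held-out test set.

    The Breslow baseline hazard is estimated on ``baseline_train`` (by
    default the scheme's final training data; a larger reference set can be
    passed because 20-sample baselines are unstable). The IPCW censoring
    distribution is estimated on the test cohort.
    """
    risk_test = predict_risk(params, test, activation).risk
    cidx = concordance_index(test.times, test.events, risk_test)
    risk_train = predict_risk(params, baseline_train, activation).risk
    if baseline_train.n_events == 0:
        raise ValueError("baseline training data has no events")
    h0 = breslow_baseline(baseline_train.times, baseline_train.events, risk_train)
    curves = SurvivalCurve(baseline_cumhaz=h0, risks=risk_test)
    ibs = integrated_brier_score(curves, test.times, test.events)
    return cidx, ibs


@dataclass
class EvalResult:
    """Per-scheme benchmark outcome over trials."""

    scheme: str
    c_index: np.ndarray
    ibs: np.ndarray
    n_test: int
    failed_trials: list[int] = field(default_factory=list)

    def _ci(self, v: np.ndarray, use_t: bool) -> tuple[float, float]:
        m = float(np.mean(v))
        if v.size < 2:
            return m, m
        se = float(np.std(v, ddof=1) / np.sqrt(v.size))
        q = sps.t.ppf(0.975, v.size - 1) if use_t else 1.959963984540054
        return m - q * se, m + q * se

    def summary(self, use_t: bool = False) -> dict:
        lo_c, hi_c = self._ci(self.c_index, use_t)
        lo_b, hi_b = self._ci(self.ibs, use_t)
        return {
            "scheme": self.scheme,
            "n_trials": int(self.c_index.size),
            "c_index_mean": float(np.mean(self.c_index)),
            "c_index_ci": (lo_c, hi_c),
            "ibs_mean": float(np.mean(self.ibs)),
            "ibs_ci": (lo_b, hi_b),
            "n_test": self.n_test,
        }


def run_benchmark(
    full_data: SurvivalDataset,
    target_label: str,
    schemes: Sequence[SchemeSpec],
    net_config: NetworkConfig,
    meta_config: Optional[MetaConfig] = None,
    n_trials: int = 25,
    test_fraction: float = 0.2,
    seed: int = 0,
    baseline_reference: bool = False,
    strata: Sequence[str] = ("subtype", "event"),
) -> dict[str, EvalResult]:
    """Multi-trial benchmark on one held-out target task.

    The target task is split once (stratified) into train and test; per
    trial a few-shot target training subset is drawn and every scheme that
    uses the shot-sized subset trains on exactly the same sample ids.
    Stage-1 models (meta-learning, pre-training) are computed once from the
    multi-task pool and shared across trials; only the final/fine-tune stage
    is repeated. All randomness derives from ``seed`` by fixed offsets, so
    adding a scheme does not perturb the others.
    """
    target_data = full_data.select_task(target_label)
    multitask = full_data.exclude_task(target_label)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        train_pool, test = stratified_split(
            target_data, test_fraction, strata=strata, seed=seed
        )
    logger.info("target %s: %d train pool, %d test, %d multitask",
                target_label, len(train_pool), len(test), len(multitask))

    names = [s.name for s in schemes]
    theta_meta = None
    if "meta" in names:
        mc = meta_config if meta_config is not None else MetaConfig()
        mc_seeded = MetaConfig(**{**mc.__dict__, "seed": seed + 101})
        theta_meta = meta_train(multitask, net_config, mc_seeded)
    stage1 = None
    if "pretrain" in names:
        spec = next(s for s in schemes if s.name == "pretrain")
        spec_seeded = _reseed(spec, seed + 202)
        stage1 = pretrain_stage1(multitask, net_config, spec_seeded)

    results = {
        s.name if names.count(s.name) == 1 else f"{s.name}{s.target_train_size}": {
            "spec": s, "c": [], "ibs": [], "failed": [],
        }
        for s in schemes
    }
    shot_size = min(s.target_train_size for s in schemes)

    for trial in range(n_trials):
        trial_seed = seed + 1000 * (trial + 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            shot = draw_target_subset(train_pool, shot_size, seed=trial_seed)
        subsets: dict[int, SurvivalDataset] = {shot_size: shot}
        for key, slot in results.items():
            spec: SchemeSpec = slot["spec"]
            size = spec.target_train_size
            if size not in subsets:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    subsets[size] = draw_target_subset(
                        train_pool, size, seed=trial_seed + size
                    )
            sub = subsets[size]
            spec_t = _reseed(spec, trial_seed + 7)
            try:
                params, baseline_train, activation = _train_one(
                    spec_t, sub, multitask, net_config, theta_meta, stage1
                )
                if baseline_reference:
                    baseline_train = train_pool
                cidx, ibs = evaluate_model(params, test, baseline_train, activation)
                slot["c"].append(cidx)
                slot["ibs"].append(ibs)
            except (ValueError, FloatingPointError) as exc:
                logger.warning("trial %d scheme %s failed: %s", trial, key, exc)
                slot["failed"].append(trial)

    return {
        key: EvalResult(
            scheme=key,
            c_index=np.array(slot["c"]),
            ibs=np.array(slot["ibs"]),
            n_test=len(test),
            failed_trials=slot["failed"],
        )
        for key, slot in results.items()
    }


def _reseed(spec: SchemeSpec, seed: int) -> SchemeSpec:
    d = dict(spec.__dict__)
    d["seed"] = seed
    return SchemeSpec(**d)


def _train_one(
    spec: SchemeSpec,
    subset: SurvivalDataset,
    multitask: SurvivalDataset,
    net_config: NetworkConfig,
    theta_meta: Optional[ModelParams],
    stage1: Optional[ModelParams],
):
    """Dispatch one scheme; returns (params, baseline-train data, activation)."""
    if spec.name == "direct":
        params = train_direct(subset, net_config, spec)
        return params, subset, net_config.activation
    if spec.name == "combined":
        params = train_combined(multitask, subset, net_config, spec)
        return params, multitask.concat(subset), net_config.activation
    if spec.name == "pretrain":
        res = pretrain_then_finetune(
            multitask, subset, net_config, spec, stage1=stage1
        )
        return res.final, subset, net_config.activation
    if spec.name == "meta":
        if theta_meta is None:
            raise ValueError("meta scheme requires a meta-trained initialization")
        params = final_learn(
            theta_meta, subset, lr=spec.rate, batch_size=20,
            epochs=spec.finetune_epochs, l2_scale=spec.l2_scale,
            activation=net_config.activation, seed=spec.seed,
        )
        return params, subset, net_config.activation
    if spec.name == "linear_baseline":
        params = train_linear_baseline(multitask, subset, spec)
        return params, multitask.concat(subset), "identity"
    raise ValueError(f"unknown scheme {spec.name!r}")
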