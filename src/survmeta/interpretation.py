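"""Gene prioritisation and gene-set statistics.

Risk-score backpropagation attributes the model's predicted risk to input
genes: each gene's score is the partial derivative of the risk with respect
to that gene's (z-scored) expression, averaged across samples. A large
positive score marks a gene whose higher expression drives the model toward
poor prognosis; large negative, toward good prognosis.

Downstream, the top high-/low-risk genes feed a hypergeometric
over-representation test, and the full ranked list feeds a pre-ranked
running-sum enrichment statistic with a permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cox_network import ModelParams, risk_input_gradients
from .data_model import SurvivalDataset

__all__ = [
    "GeneRiskScore",
    "GeneSet",
    "EnrichmentResult",
    "risk_backprop_scores",
    "select_top_fraction",
    "overrepresentation_test",
    "preranked_enrichment",
    "adjust_pvalues",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneRiskScore:
    gene_id: str
    score: float
    rank: int  # 1 = most positive (highest risk)


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        if len(set(self.members)) != len(self.members):
            self.members = list(dict.fromkeys(self.members))


@dataclass
class EnrichmentResult:
    set_id: str
    statistic: float          # odds ratio (ORA) or normalized ES (pre-ranked)
    p_value: float
    direction: str            # high_risk | low_risk | signed
    overlap: int
    es: Optional[float] = None
    adjusted_p: Optional[float] = None


def risk_backprop_scores(
    params: ModelParams,
    dataset: SurvivalDataset | np.ndarray,
    activation: str = "relu",
) -> list[GeneRiskScore]:
    """Mean d(risk)/d(gene) per gene, ranked most-positive first."""
    if isinstance(dataset, SurvivalDataset):
        x, gene_ids = dataset.x, dataset.gene_ids
    else:
        x = np.atleast_2d(np.asarray(dataset, dtype=float))
        gene_ids = [f"g{j}" for j in range(x.shape[1])]
    grads = risk_input_gradients(params, x, activation)
    mean_scores = grads.mean(axis=0)
    order = np.argsort(-mean_scores, kind="stable")
    ranks = np.empty(mean_scores.size, dtype=int)
    ranks[order] = np.arange(1, mean_scores.size + 1)
    return [
        GeneRiskScore(gene_id=g, score=float(s), rank=int(r))
        for g, s, r in zip(gene_ids, mean_scores, ranks)
    ]


def select_top_fraction(
    scores: Sequence[GeneRiskScore], fraction: float = 0.10,
    of_all_genes: bool = False,
) -> tuple[list[str], list[str]]:
    """Top high-risk and top low-risk gene ids.

    By default the fraction applies to the positively-scored (resp.
    negatively-scored) subpopulation; ``of_all_genes`` switches the
    denominator to the full gene list. Counts are floored with a minimum of
    one when the signed subpopulation is nonempty.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    pos = sorted((s for s in scores if s.score > 0), key=lambda s: -s.score)
    neg = sorted((s for s in scores if s.score < 0), key=lambda s: s.score)
    denom_pos = len(scores) if of_all_genes else len(pos)
    denom_neg = len(scores) if of_all_genes else len(neg)
    n_hi = min(len(pos), max(1, int(denom_pos * fraction))) if pos else 0
    n_lo = min(len(neg), max(1, int(denom_neg * fraction))) if neg else 0
    if not pos:
        warnings.warn("no genes with positive risk score; high-risk set empty")
    if not neg:
        warnings.warn("no genes with negative risk score; low-risk set empty")
    return [s.gene_id for s in pos[:n_hi]], [s.gene_id for s in neg[:n_lo]]


def overrepresentation_test(
    selected: Sequence[str],
    gene_set: GeneSet,
    universe: Sequence[str],
    direction: str = "high_risk",
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test.

    With N universe genes, K of them in the set, n selected, and overlap k,
    the p-value is P(X >= k) under the hypergeometric distribution; the
    statistic is the odds ratio of the 2x2 table (inf when the off-diagonal
    vanishes).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    sel = set(selected) & uni
    members = set(gene_set.members) & uni
    if not members:
        raise ValueError(f"gene set {gene_set.set_id!r} disjoint from universe")
    if set(selected) - uni:
        raise ValueError("selected genes must be a subset of the universe")
    N, K, n = len(uni), len(members), len(sel)
    k = len(sel & members)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    a, b, c, d = k, K - k, n - k, N - K - n + k
    odds = float(a * d / (b * c)) if b * c > 0 else float("inf")
    return EnrichmentResult(
        set_id=gene_set.set_id, statistic=odds, p_value=min(p, 1.0),
        direction=direction, overlap=k,
    )


def adjust_pvalues(results: Sequence[EnrichmentResult]) -> None:
    """Benjamini-Hochberg adjustment in place across a family of sets."""
    p = np.array([r.p_value for r in results])
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        i = m - rank_from_last  # 1-based rank of this p-value
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)


def preranked_enrichment(
    scores: Sequence[GeneRiskScore],
    gene_set: GeneSet,
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Pre-ranked running-sum (weighted Kolmogorov-Smirnov) enrichment.

    Genes are walked in rank order (most positive risk score first); hits
    increment the running sum by |score|^p normalised over in-set genes,
    misses decrement by 1/(N-K). The enrichment score ES is the signed
    extremum of the walk. The null is built by permuting gene labels;
    NES = ES / mean |null ES| of the same sign, and the empirical p-value
    carries an add-one correction, so it lies in [1/(B+1), 1].
    """
    ordered = sorted(scores, key=lambda s: s.rank)
    gene_ids = [s.gene_id for s in ordered]
    vals = np.array([s.score for s in ordered], dtype=float)
    in_set = np.array([g in set(gene_set.members) for g in gene_ids])
    K = int(in_set.sum())
    N = in_set.size
    if K == 0:
        raise ValueError(f"gene set {gene_set.set_id!r} disjoint from ranked list")
    if K == N:
        warnings.warn("gene set covers the entire ranked list; ES degenerate")
        return EnrichmentResult(
            set_id=gene_set.set_id, statistic=0.0, p_value=1.0,
            direction="signed", overlap=K, es=0.0,
        )

    es = _running_sum_es(vals, in_set, weight_exponent)
    rng = np.random.default_rng(seed)
    null_es = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(N)
        null_es[b] = _running_sum_es(vals, in_set[perm], weight_exponent)
    same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    if same_sign.size and np.mean(np.abs(same_sign)) > 0:
        nes = es / float(np.mean(np.abs(same_sign)))
    else:
        nes = float("nan")
    n_extreme = int(np.sum(np.abs(same_sign) >= abs(es)))
    p = (n_extreme + 1) / (same_sign.size + 1)
    return EnrichmentResult(
        set_id=gene_set.set_id, statistic=float(nes), p_value=float(p),
        direction="signed", overlap=K, es=float(es),
    )


def _running_sum_es(vals: np.ndarray, in_set: np.ndarray, p: float) -> float:
    N = vals.size
    K = int(in_set.sum())
    w = np.abs(vals) ** p
    hit_total = w[in_set].sum()
    if hit_total == 0:
        # all in-set weights zero (e.g. exponent>0 with zero scores): fall
        # back to unweighted hits so the walk stays defined
        steps = np.where(in_set, 1.0 / K, -1.0 / (N - K))
    else:
        steps = np.where(in_set, w / hit_total, -1.0 / (N - K))
    walk = np.cumsum(steps)
    i_max = int(np.argmax(np.abs(walk)))
    return float(walk[i_max])


# ---------------------------------------------------------------------------
# GMT format
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    """GMT: one set per line — id <tab> description <tab> member genes..."""
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs id, description, members")
            sets.append(GeneSet(parts[0], parts[1], [g for g in parts[2:] if g]))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *s.members]) + "\n")
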