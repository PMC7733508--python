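"""Domain containers and I/O for expression + clinical survival data.

The in-memory convention throughout the package is samples x genes: one row
per patient, one column per gene. Clinical records carry a survival time in
months, an event indicator (1 = death/event observed, 0 = right-censored), a
task label (cancer type or synthetic task id) and an optional subtype used as
a stratification key.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalRecord",
    "ExpressionMatrix",
    "SurvivalDataset",
    "PreprocessStats",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "preprocess",
    "stratified_split",
    "draw_target_subset",
]

#: tokens accepted as missing values in expression tables
NA_TOKENS = ("NA", "NaN", "nan", "null", "")


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's outcome: time in months, event status, task membership."""

    sample_id: str
    time: float
    event: int
    task_label: str
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: survival time must be positive, got {self.time}"
            )
        if self.event not in (0, 1):
            raise ValueError(
                f"sample {self.sample_id!r}: event must be 0 or 1, got {self.event}"
            )


class ExpressionMatrix:
    """Samples x genes real-valued matrix with aligned id vectors."""

    def __init__(
        self,
        sample_ids: Sequence[str],
        gene_ids: Sequence[str],
        values: np.ndarray,
    ) -> None:
        values = np.asarray(values, dtype=float)
        sample_ids = [str(s) for s in sample_ids]
        gene_ids = [str(g) for g in gene_ids]
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if values.shape != (len(sample_ids), len(gene_ids)):
            raise ValueError(
                f"shape {values.shape} does not match {len(sample_ids)} samples "
                f"x {len(gene_ids)} genes"
            )
        _check_unique(sample_ids, "sample id")
        _check_unique(gene_ids, "gene id")
        self.sample_ids = list(sample_ids)
        self.gene_ids = list(gene_ids)
        self.values = values

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            [self.sample_ids[i] for i in idx], self.gene_ids, self.values[idx]
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.n_samples} samples x {self.n_genes} genes)"


@dataclass
class SurvivalDataset:
    """Expression matrix aligned, row for row, with survival records."""

    matrix: ExpressionMatrix
    records: list[SurvivalRecord]

    def __post_init__(self) -> None:
        if len(self.records) != self.matrix.n_samples:
            raise ValueError(
                f"{len(self.records)} records for {self.matrix.n_samples} matrix rows"
            )
        for rec, sid in zip(self.records, self.matrix.sample_ids):
            if rec.sample_id != sid:
                raise ValueError(
                    f"record order mismatch: record {rec.sample_id!r} vs row {sid!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.matrix.gene_ids

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=int)

    @property
    def task_labels(self) -> np.ndarray:
        return np.array([r.task_label for r in self.records])

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def x(self) -> np.ndarray:
        return self.matrix.values

    def subset(self, indices: Sequence[int]) -> "SurvivalDataset":
        idx = list(np.asarray(indices, dtype=int))
        return SurvivalDataset(
            self.matrix.subset_samples(idx), [self.records[i] for i in idx]
        )

    def select_task(self, task_label: str) -> "SurvivalDataset":
        idx = [i for i, r in enumerate(self.records) if r.task_label == task_label]
        if not idx:
            raise KeyError(f"no samples with task label {task_label!r}")
        return self.subset(idx)

    def exclude_task(self, task_label: str) -> "SurvivalDataset":
        idx = [i for i, r in enumerate(self.records) if r.task_label != task_label]
        if not idx:
            raise KeyError(f"all samples carry task label {task_label!r}")
        return self.subset(idx)

    def concat(self, other: "SurvivalDataset") -> "SurvivalDataset":
        overlap = set(self.sample_ids) & set(other.sample_ids)
        if overlap:
            raise ValueError(f"sample id collision on concat: {sorted(overlap)[:5]}")
        if self.gene_ids != other.gene_ids:
            raise ValueError("gene id mismatch on concat")
        mat = ExpressionMatrix(
            self.sample_ids + other.sample_ids,
            self.gene_ids,
            np.vstack([self.x, other.x]),
        )
        return SurvivalDataset(mat, self.records + other.records)


@dataclass
class PreprocessStats:
    """Per-gene training statistics frozen for test-time application."""

    gene_ids: list[str]
    mean: np.ndarray
    std: np.ndarray
    log_pseudocount: float = 1.0
    log_base: float = 2.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if not (len(self.gene_ids) == self.mean.size == self.std.size):
            raise ValueError("stats vectors must align with gene_ids")
        if np.any(self.std <= 0):
            raise ValueError("standard deviations must be positive for retained genes")
        if self.log_pseudocount < 0:
            raise ValueError("log pseudocount must be nonnegative")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, orientation: str = "samples_by_genes") -> ExpressionMatrix:
    """Read a tab-separated expression table.

    The file must have one header row and one leading id column. Cells equal
    to one of the NA tokens become NaN (removed later by :func:`preprocess`);
    any other non-numeric cell is a parse error naming the offending
    row/column.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):  # pandas would silently mangle these
        dup = [h for h in set(header) if header.count(h) > 1]
        raise ValueError(f"{path}: duplicate ids {sorted(dup)[:5]}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(NA_TOKENS),
        keep_default_na=False, dtype=str,
    )
    if df.columns.size == 0:
        raise ValueError(f"{path}: no data columns found (missing header?)")
    if df.index.has_duplicates or df.columns.has_duplicates:
        dup = (list(df.index[df.index.duplicated()]) +
               list(df.columns[df.columns.duplicated()]))
        raise ValueError(f"{path}: duplicate ids {dup[:5]}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            ) from None
    mat = ExpressionMatrix(list(df.index), list(df.columns), values)
    if orientation == "genes_by_samples":
        mat = ExpressionMatrix(mat.gene_ids, mat.sample_ids, mat.values.T)
    return mat


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_clinical(path) -> list[SurvivalRecord]:
    """Read a tab-separated clinical table (sample_id, time, event, task_label[, subtype])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "task_label": str})
    required = {"sample_id", "time", "event", "task_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    has_subtype = "subtype" in df.columns
    records = []
    for row in df.itertuples(index=False):
        subtype = getattr(row, "subtype", None) if has_subtype else None
        if subtype is not None and (pd.isna(subtype) or subtype == ""):
            subtype = None
        records.append(
            SurvivalRecord(
                sample_id=str(row.sample_id),
                time=float(row.time),
                event=int(row.event),
                task_label=str(row.task_label),
                subtype=subtype,
            )
        )
    _check_unique([r.sample_id for r in records], "sample id")
    return records


def write_clinical(records: Iterable[SurvivalRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "time": r.time,
            "event": r.event,
            "task_label": r.task_label,
            "subtype": "" if r.subtype is None else r.subtype,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_dataset(expression_path, clinical_path,
                 orientation: str = "samples_by_genes") -> SurvivalDataset:
    """Read and align an expression table with its clinical table."""
    matrix = read_expression(expression_path, orientation=orientation)
    records = {r.sample_id: r for r in read_clinical(clinical_path)}
    missing = [s for s in matrix.sample_ids if s not in records]
    if missing:
        raise ValueError(f"samples without clinical records: {missing[:5]}")
    return SurvivalDataset(matrix, [records[s] for s in matrix.sample_ids])


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    matrix: ExpressionMatrix,
    stats: Optional[PreprocessStats] = None,
    log_pseudocount: float = 1.0,
    log_base: float = 2.0,
    log_transform: bool = True,
) -> tuple[ExpressionMatrix, PreprocessStats]:
    """Drop genes with missing values, log-transform, z-score per gene.

    When ``stats`` is supplied (test-time), its gene list, pseudocount and
    frozen training means/SDs are applied instead of recomputing, so test
    data is normalised on the training scale. Zero-variance genes are dropped
    with a warning when computing fresh stats.
    """
    values = matrix.values
    if stats is None:
        keep = ~np.any(np.isnan(values), axis=0)
        if not keep.any():
            raise ValueError("preprocessing dropped all genes (all contain NA)")
        kept_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
        v = values[:, keep]
        if log_transform:
            if np.any(v + log_pseudocount <= 0):
                raise ValueError("log transform undefined: values + pseudocount <= 0")
            v = np.log(v + log_pseudocount) / np.log(log_base)
        mean = v.mean(axis=0)
        # sample SD (ddof=1) when more than one sample; lone samples cannot
        # be scaled and every gene would be zero-variance anyway
        std = v.std(axis=0, ddof=1) if v.shape[0] > 1 else v.std(axis=0)
        nonconst = std > 0
        if not np.all(nonconst):
            dropped = [g for g, ok in zip(kept_ids, nonconst) if not ok]
            warnings.warn(
                f"dropping {len(dropped)} zero-variance gene(s): {dropped[:5]}"
            )
            kept_ids = [g for g, ok in zip(kept_ids, nonconst) if ok]
            v, mean, std = v[:, nonconst], mean[nonconst], std[nonconst]
        if not kept_ids:
            raise ValueError("preprocessing dropped all genes")
        out = (v - mean) / std
        stats = PreprocessStats(
            gene_ids=kept_ids, mean=mean, std=std,
            log_pseudocount=log_pseudocount if log_transform else 0.0,
            log_base=log_base,
        )
    else:
        col = {g: j for j, g in enumerate(matrix.gene_ids)}
        missing = [g for g in stats.gene_ids if g not in col]
        if missing:
            raise ValueError(f"matrix lacks genes required by stats: {missing[:5]}")
        idx = [col[g] for g in stats.gene_ids]
        v = values[:, idx]
        if np.any(np.isnan(v)):
            raise ValueError("NA values present in genes retained by training stats")
        if stats.log_pseudocount > 0 or log_transform:
            v = np.log(v + stats.log_pseudocount) / np.log(stats.log_base)
        out = (v - stats.mean) / stats.std
    return ExpressionMatrix(matrix.sample_ids, list(stats.gene_ids), out), stats


# ---------------------------------------------------------------------------
# splitting / subsampling
# ---------------------------------------------------------------------------

def _stratum_key(record: SurvivalRecord, strata: Sequence[str]) -> tuple:
    key = []
    for s in strata:
        if s == "subtype":
            key.append(record.subtype)
        elif s == "event":
            key.append(record.event)
        elif s == "task_label":
            key.append(record.task_label)
        else:
            raise ValueError(f"unknown stratification key {s!r}")
    return tuple(key)


def stratified_split(
    dataset: SurvivalDataset,
    test_fraction: float,
    strata: Sequence[str] = ("subtype", "event"),
    seed: int = 0,
) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Deterministic stratified train/test split.

    Per-stratum test counts are floor(stratum size x fraction); the remaining
    test slots (to reach round(total x fraction)) go to the largest strata
    first, largest fractional remainder breaking ties — a fixed, stated
    rounding rule. Strata of size 1 go entirely to train with a warning.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[int]] = {}
    for i, rec in enumerate(dataset.records):
        groups.setdefault(_stratum_key(rec, strata), []).append(i)

    total_target = int(round(len(dataset) * test_fraction))
    order = sorted(groups, key=lambda k: (-len(groups[k]), str(k)))
    base = {k: int(np.floor(len(groups[k]) * test_fraction)) for k in order}
    for k in order:
        if len(groups[k]) == 1 and base[k] > 0:
            base[k] = 0
    remainder = total_target - sum(base.values())
    frac = {k: len(groups[k]) * test_fraction - base[k] for k in order}
    for k in sorted(order, key=lambda k: (-frac[k], -len(groups[k]), str(k))):
        if remainder <= 0:
            break
        if base[k] < len(groups[k]) - (1 if len(groups[k]) == 1 else 0) and len(groups[k]) > 1:
            base[k] += 1
            remainder -= 1

    test_idx: list[int] = []
    for k in order:
        members = groups[k]
        if len(members) == 1:
            warnings.warn(f"stratum {k!r} has a single sample; assigned to train")
            continue
        chosen = rng.choice(len(members), size=base[k], replace=False)
        test_idx.extend(members[c] for c in chosen)
    test_set = set(test_idx)
    train_idx = [i for i in range(len(dataset)) if i not in test_set]
    return dataset.subset(train_idx), dataset.subset(sorted(test_idx))


def draw_target_subset(train: SurvivalDataset, n: int, seed: int = 0) -> SurvivalDataset:
    """Uniform subsample without replacement (the few-shot target draw)."""
    if n > len(train):
        raise ValueError(f"requested {n} samples from a pool of {len(train)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(train), size=n, replace=False)
    subset = train.subset(sorted(idx))
    if subset.n_events == 0:
        warnings.warn("drawn target subset contains zero events")
    return subset
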