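"""Rank aggregation over the all-against-all performance matrix.

The performance matrix holds one row per experiment (ChIP-seq, HT-SELEX at
top-10% or top-50%, PBM) and one column per candidate matrix; entries are
AUC ROC values or Pearson correlations, with missing values allowed.  Within
each row the values are converted to ranks (rank 1 = best performance,
average ranks for ties, unevaluated matrices excluded).  A matrix's
*aggregate rank score* for a gene is the geometric mean of its ranks over
all experiments attributed to that gene (within an assay group, or over all
assays); lower is better, with 1 the best attainable.  The best matrix per
gene minimizes this score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ASSAYS = ("chipseq", "selex10", "selex50", "pbm")
#: pseudo-group meaning "pool every assay type" for globally-best selection
ALL_ASSAYS = "all"


@dataclass
class PerformanceMatrix:
    """values: experiments x matrices table (NaN = not evaluated);
    experiments: per-row metadata with columns gene_symbol, assay."""

    values: pd.DataFrame
    experiments: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.experiments.index):
            raise ValueError("values and experiment metadata indexes differ")
        missing = {"gene_symbol", "assay"} - set(self.experiments.columns)
        if missing:
            raise ValueError(f"experiment metadata lacks columns {sorted(missing)}")
        bad = set(self.experiments["assay"]) - set(ASSAYS)
        if bad:
            raise ValueError(f"unknown assay labels: {sorted(bad)}")

    def experiment_ids(self, gene: str, assay_group: str = ALL_ASSAYS) -> list[str]:
        meta = self.experiments
        mask = meta["gene_symbol"] == gene
        if assay_group != ALL_ASSAYS:
            mask &= meta["assay"] == assay_group
        return list(meta.index[mask])

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "PerformanceMatrix":
        """Build from long-format rows: experiment_id, matrix_id, assay,
        gene_symbol, value."""
        values = df.pivot_table(index="experiment_id", columns="matrix_id",
                                values="value", aggfunc="first")
        meta = (df[["experiment_id", "gene_symbol", "assay"]]
                .drop_duplicates("experiment_id").set_index("experiment_id"))
        return cls(values.loc[meta.index], meta)

    def to_long(self) -> pd.DataFrame:
        long = (self.values.stack().rename("value").reset_index())
        long.columns = ["experiment_id", "matrix_id", "value"]
        return long.merge(self.experiments, left_on="experiment_id",
                          right_index=True)


@dataclass(frozen=True)
class QualityThresholds:
    """Strict lower bounds a gene's best raw performance must exceed to be
    reported: AUC for ChIP-seq/HT-SELEX, Pearson r for PBM."""

    auc_min: float = 0.75
    r_min: float = 0.35

    def threshold_for(self, assay: str) -> float:
        return self.r_min if assay == "pbm" else self.auc_min


@dataclass
class FamilyAnnotation:
    """Opaque family labels: matrix_id -> family and gene_symbol -> family."""

    matrix_family: Mapping[str, str]
    gene_family: Mapping[str, str]

    @classmethod
    def from_table(cls, df: pd.DataFrame,
                   family_col: str = "tfclass_family") -> "FamilyAnnotation":
        df = df.dropna(subset=[family_col])
        return cls(dict(zip(df["matrix_id"], df[family_col])),
                   dict(zip(df["gene_symbol"], df[family_col])))


def ranks_within_experiment(row: pd.Series) -> pd.Series:
    """Ranks of one experiment's row: rank 1 for the highest value, ties get
    the average of the spanned ranks, missing values get no rank."""
    present = row.dropna()
    if present.empty:
        raise ValueError("cannot rank an all-missing experiment row")
    ranks = stats.rankdata(-present.to_numpy())
    return pd.Series(ranks, index=present.index)


def aggregate_rank_score(matrix_id: str, gene: str, assay_group: str,
                         perf: PerformanceMatrix) -> float:
    """Geometric mean of the matrix's within-experiment ranks over the gene's
    experiments in the assay group (lower = better; minimum 1)."""
    exp_ids = perf.experiment_ids(gene, assay_group)
    ranks = []
    for eid in exp_ids:
        row = perf.values.loc[eid]
        if pd.isna(row.get(matrix_id, np.nan)):
            continue
        ranks.append(ranks_within_experiment(row)[matrix_id])
    if not ranks:
        raise ValueError(
            f"matrix {matrix_id} has no evaluated experiments for gene {gene} "
            f"in assay group {assay_group}")
    if len(ranks) == 1:
        return float(ranks[0])
    return float(stats.gmean(ranks))


def best_matrix_per_gene(gene: str, assay_group: str,
                         perf: PerformanceMatrix) -> str:
    """Matrix with the best (lowest) aggregate rank score for the gene; ties
    broken by higher mean raw performance, then lexicographic id."""
    exp_ids = perf.experiment_ids(gene, assay_group)
    if not exp_ids:
        raise ValueError(f"gene {gene} has no experiments in {assay_group}")
    sub = perf.values.loc[exp_ids]
    candidates = sub.columns[sub.notna().any(axis=0)]
    best: tuple[float, float, str] | None = None
    for mid in candidates:
        score = aggregate_rank_score(mid, gene, assay_group, perf)
        key = (score, -float(sub[mid].mean()), str(mid))
        if best is None or key < best:
            best = key
    assert best is not None
    return best[2]


def best_matrix_report(perf: PerformanceMatrix,
                       assay_groups: Sequence[str] = ASSAYS + (ALL_ASSAYS,)
                       ) -> pd.DataFrame:
    """One row per (gene, assay group): the best matrix, its aggregate rank
    score, and the gene's best raw value achieved by that matrix."""
    rows = []
    genes = sorted(set(perf.experiments["gene_symbol"]))
    for group in assay_groups:
        for gene in genes:
            exp_ids = perf.experiment_ids(gene, group)
            if not exp_ids:
                continue
            mid = best_matrix_per_gene(gene, group, perf)
            sub = perf.values.loc[exp_ids, mid]
            rows.append({
                "gene_symbol": gene,
                "assay_group": group,
                "matrix_id": mid,
                "aggregate_rank_score": aggregate_rank_score(mid, gene, group,
                                                             perf),
                "best_value": float(sub.max()),
            })
    return pd.DataFrame(rows)


def quality_filter(report: pd.DataFrame,
                   thresholds: QualityThresholds = QualityThresholds(),
                   perf: PerformanceMatrix | None = None) -> pd.DataFrame:
    """Keep report rows whose best raw value strictly exceeds the
    assay-appropriate threshold.  Rows for the pooled ``all`` group pass if
    the (gene, matrix) pair passes in at least one assay type ("or"
    semantics), which requires ``perf`` for the per-assay values."""
    keep = []
    for _, row in report.iterrows():
        group = row["assay_group"]
        if group != ALL_ASSAYS:
            keep.append(row["best_value"] > thresholds.threshold_for(group))
            continue
        if perf is None:
            raise ValueError("filtering the pooled group requires perf")
        passed = False
        for assay in ASSAYS:
            eids = [e for e in perf.experiment_ids(row["gene_symbol"], assay)]
            if not eids:
                continue
            vals = perf.values.loc[eids, row["matrix_id"]].dropna()
            if not vals.empty and vals.max() > thresholds.threshold_for(assay):
                passed = True
                break
        keep.append(passed)
    return report[np.array(keep, dtype=bool)].reset_index(drop=True)


def family_cross_table(perf: PerformanceMatrix, fam: FamilyAnnotation,
                       min_pwms: int = 2, min_datasets: int = 2,
                       assay_group: str = ALL_ASSAYS) -> pd.DataFrame:
    """Mean performance per (matrix family, experiment family) cell.

    Cell (F1, F2) averages all values of matrices annotated to family F1
    against experiments whose TF belongs to family F2; families contributing
    fewer than ``min_pwms`` matrices (rows) or ``min_datasets`` experiments
    (columns) are omitted."""
    long = perf.to_long()
    if assay_group != ALL_ASSAYS:
        long = long[long["assay"] == assay_group]
    long = long.assign(
        pwm_family=long["matrix_id"].map(fam.matrix_family),
        exp_family=long["gene_symbol"].map(fam.gene_family),
    ).dropna(subset=["pwm_family", "exp_family"])

    pwm_counts = (long[["matrix_id", "pwm_family"]].drop_duplicates()
                  .groupby("pwm_family").size())
    ds_counts = (long[["experiment_id", "exp_family"]].drop_duplicates()
                 .groupby("exp_family").size())
    keep_pwm = set(pwm_counts.index[pwm_counts >= min_pwms])
    keep_ds = set(ds_counts.index[ds_counts >= min_datasets])
    long = long[long["pwm_family"].isin(keep_pwm)
                & long["exp_family"].isin(keep_ds)]
    return long.pivot_table(index="pwm_family", columns="exp_family",
                            values="value", aggfunc="mean")


def nonredundant_library(perf: PerformanceMatrix,
                         thresholds: QualityThresholds | None = None,
                         assay_group: str = ALL_ASSAYS) -> set[str]:
    """Union over genes of the best matrix per gene (a matrix that is best
    for several genes appears once); optionally restricted to genes passing
    the quality filter."""
    report = best_matrix_report(perf, assay_groups=(assay_group,))
    if thresholds is not None:
        report = quality_filter(report, thresholds, perf=perf)
    return set(report["matrix_id"])
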