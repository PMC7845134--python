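"""Cohort signature scoring and gene–signature correlation.

A per-sample activity score for a gene set (e.g. the 57-gene YAP signature)
is computed with the single-sample GSEA (ssGSEA) running-sum statistic:
genes are ranked by expression, the weighted in-set empirical CDF (weights
= rank statistic^alpha) is compared against the uniform out-of-set ECDF,
and the score is the sum of their differences over all ranks. Genes below
the sample-wise low-expression cutoff (log2 TPM < -1) are removed before
ranking. Candidate target genes are then prioritized by their per-study
Pearson correlation with the signature score, with low-expression studies
labeled ``LowEx`` and excluded, and samples are classified high/low by a
median split (value >= median is high) for downstream survival fitting.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Config, adjust_pvalues

__all__ = [
    "read_geneset",
    "ssgsea_score",
    "ssgsea_scores",
    "correlate_with_signature",
    "median_split",
    "survival_table",
]


def read_geneset(path: str) -> tuple[str, list[str]]:
    """Read a one-gene-per-line set file; first line is the set name."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError("geneset file needs a name line and >= 1 gene")
    name, genes = lines[0], lines[1:]
    if len(set(genes)) != len(genes):
        raise ValueError("geneset contains duplicate gene ids")
    return name, genes


def ssgsea_score(
    expression: pd.Series,
    geneset: Iterable[str],
    alpha: float = 0.25,
    low_expr_cut: float | None = -1.0,
) -> float:
    """ssGSEA running-sum score of one sample.

    Genes with expression strictly below ``low_expr_cut`` are dropped
    sample-wise first. Remaining genes are ranked by expression descending
    (ties broken by gene id); with rank statistics N..1 the score is

        sum_i [ P_in(i) - P_out(i) ]

    where P_in is the cumulative |rank|^alpha weight over in-set genes and
    P_out the cumulative count over out-of-set genes. ``alpha = 0`` gives
    the unweighted Kolmogorov-Smirnov running sum. Returns NaN (with a
    warning) when no geneset gene survives the filter.
    """
    expr = expression.dropna()
    if low_expr_cut is not None:
        expr = expr[expr >= low_expr_cut]
    genes = set(geneset)
    if not genes:
        raise ValueError("geneset is empty")
    order = expr.to_frame("x")
    order["gene"] = order.index.astype(str)
    order = order.sort_values(["x", "gene"], ascending=[False, True], kind="stable")
    n = len(order)
    in_set = order["gene"].isin(genes).to_numpy()
    n_in = int(in_set.sum())
    if n_in == 0:
        warnings.warn("no geneset gene above the expression filter")
        return float("nan")
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets rank N
    w = np.where(in_set, np.abs(ranks) ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    if n == n_in:
        p_out = np.zeros(n)  # degenerate: every gene in-set
    else:
        p_out = np.cumsum(~in_set) / float(n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: pd.DataFrame,
    geneset: Iterable[str],
    alpha: float = 0.25,
    low_expr_cut: float | None = -1.0,
    normalize: bool = False,
) -> pd.Series:
    """Per-sample scores for a genes × samples table.

    ``normalize`` rescales by the score range across samples (the range
    normalization of the reference implementation); off by default since
    only the ordering and median split are consumed downstream.
    """
    scores = pd.Series({
        s: ssgsea_score(expr[s], geneset, alpha, low_expr_cut)
        for s in expr.columns
    }, name="ssgsea")
    if normalize:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return scores


def correlate_with_signature(
    cohort: pd.DataFrame,
    gene_id: str,
    scores: pd.Series,
    cfg: Config | None = None,
) -> pd.DataFrame:
    """Per-study Pearson correlation of one gene with the signature score.

    ``cohort`` rows are samples with a ``study`` column and gene expression
    columns (log2 TPM scale). Studies where the gene's mean expression is
    below ``low_expr_log2tpm`` are labeled ``LowEx`` and excluded from
    testing; a constant gene yields status ``ns``. P-values are adjusted
    across tested studies (BH or Bonferroni per config).
    """
    cfg = cfg or Config()
    if gene_id not in cohort.columns:
        raise ValueError(f"gene {gene_id!r} absent from cohort table")
    rows = []
    for study, sub in cohort.groupby("study"):
        x = sub[gene_id].to_numpy(dtype=float)
        y = scores.loc[sub.index].to_numpy(dtype=float)
        if len(sub) < 3:
            rows.append({"study": study, "r": np.nan, "p": np.nan, "status": "ns"})
            continue
        if x.mean() < cfg.low_expr_log2tpm:
            rows.append({"study": study, "r": np.nan, "p": np.nan, "status": "LowEx"})
            continue
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            warnings.warn(f"constant values in study {study}; correlation undefined")
            rows.append({"study": study, "r": np.nan, "p": np.nan, "status": "ns"})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"study": study, "r": float(r), "p": float(p), "status": "tested"})
    out = pd.DataFrame(rows).set_index("study")
    tested = out["status"] == "tested"
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = adjust_pvalues(
            out.loc[tested, "p"].to_numpy(), cfg.multiple_testing)
        out.loc[tested, "status"] = np.where(
            out.loc[tested, "p_adj"] < 0.05, "sig", "ns")
    return out


def median_split(values: pd.Series | Sequence[float]) -> pd.Series:
    """Label values ``high`` when >= the median, else ``low``."""
    s = pd.Series(values, dtype=float)
    med = s.median()
    return pd.Series(np.where(s >= med, "high", "low"), index=s.index, name="group")


def survival_table(
    cohort: pd.DataFrame,
    labels: pd.Series,
    time_col: str = "OS_time",
    event_col: str = "OS_event",
) -> pd.DataFrame:
    """Survival-ready export: sample, group, time, event (for external
    Kaplan-Meier / Cox fitting, which is out of scope here)."""
    out = cohort[[time_col, event_col]].copy()
    out["group"] = labels.loc[out.index]
    return out
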