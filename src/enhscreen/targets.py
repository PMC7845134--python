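"""Cis target-gene assignment for hit enhancers.

For every hit enhancer, expression of enhancer-knockout cells (two
independent sgRNA vectors per enhancer) relative to non-targeting controls
is searched for downregulated genes whose TSS lies within the cis window
(default up to 5 Mbp) of the enhancer's sgRNA cut sites. Candidates are
ranked by mean knockdown (both KO samples) and then by distance; TAD
co-membership is reported as supporting annotation.

Expression tables are genes × samples DataFrames (RPKM/TPM scale); gene
annotation is a DataFrame with ``gene_id, chrom, tss, start, end, strand``.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Config, GenomicInterval, quantile_normalize

__all__ = [
    "quantile_normalize_expression",
    "relative_expression",
    "assign_targets",
    "tad_comembership",
]


def quantile_normalize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Cross-sample quantile normalization of a genes × samples table."""
    return quantile_normalize(expr)


def relative_expression(
    norm: pd.DataFrame,
    control_sample_ids: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2 expression of each sample relative to the mean of the
    non-targeting control samples: log2((x + eps) / (ctrl_mean + eps))."""
    missing = [c for c in control_sample_ids if c not in norm.columns]
    if missing:
        raise ValueError(f"control samples absent from table: {missing}")
    ctrl_mean = norm[list(control_sample_ids)].mean(axis=1)
    return np.log2(norm.add(pseudocount).div(ctrl_mean + pseudocount, axis=0))


def assign_targets(
    region_id: str,
    cut_sites: Sequence[tuple[str, int]],
    rel_expr: pd.DataFrame,
    ko_samples: Sequence[str],
    genes: pd.DataFrame,
    cfg: Config | None = None,
    significant_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Candidate target genes of one enhancer region.

    A gene qualifies when its TSS lies within
    [target_window_min_bp, target_window_bp] of the nearest cut site
    (same chromosome) and its mean relative log2 expression across the
    region's two KO samples is <= -down_lfc_min. Candidates are ranked by
    mean log2FC ascending, then by distance. ``significant_genes``, when
    given (an external differential-expression call set), additionally
    restricts the candidates.
    """
    cfg = cfg or Config()
    if len(ko_samples) < 2:
        raise ValueError("two KO samples per region are required")
    rows = []
    for _, g in genes.iterrows():
        dists = [abs(int(g["tss"]) - pos)
                 for chrom, pos in cut_sites if chrom == g["chrom"]]
        if not dists:
            continue
        dist = min(dists)
        if not (cfg.target_window_min_bp <= dist <= cfg.target_window_bp):
            continue
        if g["gene_id"] not in rel_expr.index:
            continue
        if significant_genes is not None and g["gene_id"] not in set(significant_genes):
            continue
        mean_lfc = float(rel_expr.loc[g["gene_id"], list(ko_samples)].mean())
        if mean_lfc <= -cfg.down_lfc_min:
            rows.append({
                "region_id": region_id,
                "gene_id": g["gene_id"],
                "mean_log2fc": mean_lfc,
                "distance_bp": dist,
            })
    if not rows:
        warnings.warn(f"region {region_id}: no downregulated gene in window")
        return pd.DataFrame(
            columns=["region_id", "gene_id", "mean_log2fc", "distance_bp"])
    out = pd.DataFrame(rows).sort_values(
        ["mean_log2fc", "distance_bp", "gene_id"], kind="stable")
    out.index = np.arange(1, len(out) + 1)
    out.index.name = "rank"
    return out


def tad_comembership(
    region: GenomicInterval,
    gene_tss: tuple[str, int],
    tads: Sequence[GenomicInterval],
) -> bool:
    """True iff one TAD interval contains both the region anchor and the
    gene TSS (TADs consumed as plain intervals; no contact-matrix logic)."""
    chrom, pos = gene_tss
    for tad in tads:
        if tad.chrom != region.chrom or tad.chrom != chrom:
            continue
        region_in = tad.start <= region.start and region.end <= tad.end
        tss_in = tad.start <= pos < tad.end
        if region_in and tss_in:
            return True
    return False
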