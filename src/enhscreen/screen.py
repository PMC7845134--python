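"""Dual-cell-line CRISPR screen scoring.

Guide counts from the activated-YAP line and the control line are
normalized on the non-targeting guides (median-of-ratios size factors
computed on controls only), turned into per-guide T20-vs-T0 log2
fold-changes averaged over replicates, and summarized per enhancer region
as the mean LFC of the ``k`` most depleted guides (k = 2). A region is a
selective hit when it shows no depletion in the control line
(score_ctrl >= -ctrl_score_bound) and ranks among the ``top_k_hits`` most
negative selectivity values (score_yap - score_ctrl). Hits are finally
filtered on bidirectional eRNA activity.

Sample columns follow ``<cellline>_<rep>_<timepoint>`` with timepoints
``T0`` / ``T20``.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Config, GenomicInterval
from scipy.stats import gmean

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "parse_sample_name",
    "control_normalize",
    "guide_log2fc",
    "region_score",
    "select_hits",
    "apply_erna_filter",
]

_SAMPLE_RE = re.compile(r"^(?P<cell_line>.+)_(?P<replicate>[^_]+)_(?P<timepoint>T0|T20)$")


def parse_sample_name(name: str) -> dict:
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValueError(
            f"sample {name!r} does not follow <cellline>_<rep>_<timepoint>")
    return m.groupdict()


@dataclass
class CountMatrix:
    """Guides × samples count table with annotation parsed from column names."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("guide_ids must be unique")
        ann = self.annotations()
        pairs = ann.groupby(["cell_line", "replicate"])["timepoint"].apply(set)
        incomplete = pairs[pairs != {"T0", "T20"}]
        if len(incomplete):
            raise ValueError(
                f"samples missing a timepoint: {list(incomplete.index)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def annotations(self) -> pd.DataFrame:
        rows = {c: parse_sample_name(c) for c in self.counts.columns}
        return pd.DataFrame.from_dict(rows, orient="index")

    def replicates(self) -> list[str]:
        return sorted(self.annotations()["replicate"].unique())


def control_normalize(
    counts: CountMatrix | pd.DataFrame,
    control_ids: Sequence[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization anchored on control guides.

    The size factor of a sample is the median, over control guides with
    all-positive counts, of count / geometric-mean-across-samples(count),
    rescaled so the size factors have geometric mean 1 (which makes the
    normalization exactly idempotent); normalized counts are counts divided
    by the sample's size factor. This holds non-targeting guides drift-free
    by construction, so depletion is measured against the controls.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    ctrl = df.loc[df.index.intersection(control_ids)]
    ctrl = ctrl[(ctrl > 0).all(axis=1)]
    if ctrl.empty:
        raise ValueError("no control guide with all-positive counts")
    if len(ctrl) < 5:
        warnings.warn(f"only {len(ctrl)} admissible control guides")
    geo = gmean(ctrl.to_numpy(dtype=float), axis=1)
    ratios = ctrl.div(geo, axis=0)
    size_factors = ratios.median(axis=0)
    size_factors = size_factors / gmean(size_factors.to_numpy())
    return df.div(size_factors, axis=1), size_factors


def guide_log2fc(
    norm: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-guide log2((T20 + ps) / (T0 + ps)) per replicate plus the
    replicate average, per cell line.

    Returns a frame indexed by guide with columns
    ``lfc_<cellline>_<rep>`` and ``lfc_<cellline>_avg``.
    """
    ann = pd.DataFrame.from_dict(
        {c: parse_sample_name(c) for c in norm.columns}, orient="index")
    out = pd.DataFrame(index=norm.index)
    for cell_line, grp in ann.groupby("cell_line"):
        rep_cols = []
        for rep, sub in grp.groupby("replicate"):
            t0 = sub.index[sub["timepoint"] == "T0"][0]
            t20 = sub.index[sub["timepoint"] == "T20"][0]
            col = f"lfc_{cell_line}_{rep}"
            out[col] = np.log2(
                (norm[t20] + pseudocount) / (norm[t0] + pseudocount))
            rep_cols.append(col)
        out[f"lfc_{cell_line}_avg"] = out[rep_cols].mean(axis=1)
    return out


def region_score(
    guide_lfc: pd.DataFrame,
    guide_to_regions: Mapping[str, Sequence[str]],
    cell_line: str,
    k: int = 2,
    replicate_order: str = "average_first",
) -> pd.DataFrame:
    """Region depletion score: mean LFC of the ``k`` most depleted guides.

    ``average_first`` (default) averages each guide's LFC over replicates
    before picking the k most depleted guides per region; ``score_first``
    scores each replicate separately and averages the per-replicate region
    scores. Ties are broken by guide_id order. Regions with fewer than k
    guides use all of them.
    """
    if replicate_order not in ("average_first", "score_first"):
        raise ValueError(f"unknown replicate_order {replicate_order!r}")
    members: dict[str, list[str]] = {}
    for gid, regions in guide_to_regions.items():
        if gid not in guide_lfc.index:
            continue
        for rid in regions:
            members.setdefault(rid, []).append(gid)

    if replicate_order == "average_first":
        value_cols = [f"lfc_{cell_line}_avg"]
    else:
        value_cols = [c for c in guide_lfc.columns
                      if c.startswith(f"lfc_{cell_line}_") and not c.endswith("_avg")]
        if not value_cols:
            raise ValueError(f"no per-replicate columns for {cell_line!r}")

    rows = []
    for rid, gids in members.items():
        per_col = []
        for col in value_cols:
            vals = guide_lfc.loc[gids, col].sort_index()
            vals = vals.sort_values(kind="stable")  # stable: guide_id tie-break
            per_col.append(vals.iloc[:min(k, len(vals))].mean())
        rows.append({"region_id": rid, "score": float(np.mean(per_col)),
                     "n_guides": len(gids)})
    return (pd.DataFrame(rows, columns=["region_id", "score", "n_guides"])
            .set_index("region_id").sort_index())


def select_hits(
    scores_yap: pd.DataFrame,
    scores_ctrl: pd.DataFrame,
    cfg: Config | None = None,
    positive_control_regions: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank regions by selectivity and return the top hits.

    Eligible regions show no depletion in the control line
    (score_ctrl >= -ctrl_score_bound); they are ranked by selectivity
    (score_yap - score_ctrl) ascending, most selectively depleted first.
    Positive-control pseudo-regions are excluded from the hit list and
    returned separately. Ranking ties are broken by region_id.
    """
    cfg = cfg or Config()
    common = scores_yap.index.intersection(scores_ctrl.index)
    if not scores_yap.index.equals(scores_ctrl.index):
        missing = scores_yap.index.symmetric_difference(scores_ctrl.index)
        raise ValueError(f"score tables disagree on regions: {list(missing)[:5]}")
    table = pd.DataFrame({
        "score_yap": scores_yap.loc[common, "score"],
        "score_ctrl": scores_ctrl.loc[common, "score"],
        "n_guides": scores_yap.loc[common, "n_guides"],
    })
    table["selectivity"] = table["score_yap"] - table["score_ctrl"]
    table["passed_ctrl_bound"] = table["score_ctrl"] >= -cfg.ctrl_score_bound

    is_pos = table.index.isin(positive_control_regions)
    pos_table = table[is_pos].copy()
    eligible = table[~is_pos & table["passed_ctrl_bound"]]
    if eligible.empty:
        warnings.warn("no eligible region; empty hit list")
    hits = (eligible.assign(_rid=eligible.index.astype(str))
            .sort_values(["selectivity", "_rid"], kind="stable")
            .drop(columns="_rid")
            .head(cfg.top_k_hits).copy())
    hits["rank"] = np.arange(1, len(hits) + 1)
    return hits, pos_table


def apply_erna_filter(
    hits: pd.DataFrame,
    elements: pd.DataFrame,
    regions: Mapping[str, GenomicInterval],
) -> pd.DataFrame:
    """Keep hits whose region overlaps an eRNA-active bidirectional element.

    ``elements`` must carry ``erna_flag`` (see
    :func:`enhscreen.annotation.erna_differential`); hits with no
    overlapping flagged element are dropped and logged.
    """
    if "erna_flag" not in elements.columns:
        raise ValueError("elements lack the erna_flag column")
    active = elements[elements["erna_flag"]]
    keep = []
    for rid in hits.index:
        iv = regions.get(rid)
        if iv is None:
            logger.info("hit %s has no region interval; dropped", rid)
            keep.append(False)
            continue
        hit_any = bool(((active["chrom"] == iv.chrom)
                        & (active["anchor_start"] < iv.end)
                        & (iv.start < active["anchor_end"])).any())
        if not hit_any:
            logger.info("hit %s dropped by eRNA filter", rid)
        keep.append(hit_any)
    return hits[np.array(keep, dtype=bool)] if len(hits) else hits
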