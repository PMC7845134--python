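"""Proteome differential filtering, set overlap, and client intersection.

Differential tables come either as raw log2 LFQ abundances (3 replicates ×
2 conditions, missing values allowed) that are filtered for at least two
valid values per condition and tested with an empirical-Bayes moderated
t-statistic, or as precomputed ``log2fc / p_raw / p_adj`` columns consumed
unchanged (pass-through, used when working from published differential
tables). Significant sets use strict inequalities exactly as printed
(p < cut, |log2FC| > cut). Overlaps are tested with a one-sided Fisher
exact (hypergeometric upper tail). Translocon client candidates are the
four-way intersection of proteins upregulated under both overexpression
conditions and downregulated under both knockouts; the signal-peptide flag
is reported per candidate but never used as a filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import adjust_pvalues

__all__ = [
    "OverlapResult",
    "valid_value_filter",
    "differential_protein",
    "diff_records_from_table",
    "threshold_set",
    "overlap_test",
    "client_candidates",
    "preranked_metric",
]

_ABUND_RE = re.compile(r"^abundance_(?P<cond>.+)_(?P<rep>[^_]+)$")


def _condition_columns(table: pd.DataFrame) -> dict[str, list[str]]:
    conds: dict[str, list[str]] = {}
    for c in table.columns:
        m = _ABUND_RE.match(c)
        if m:
            conds.setdefault(m.group("cond"), []).append(c)
    if len(conds) != 2:
        raise ValueError(
            f"expected abundance columns for exactly 2 conditions, got {sorted(conds)}")
    return conds


def valid_value_filter(table: pd.DataFrame, min_valid: int = 2) -> pd.DataFrame:
    """Keep proteins with >= ``min_valid`` non-missing replicates in *both*
    conditions (the 2-of-3 valid-value rule)."""
    conds = _condition_columns(table)
    mask = pd.Series(True, index=table.index)
    for cols in conds.values():
        mask &= table[cols].notna().sum(axis=1) >= min_valid
    return table.loc[mask].copy()


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def differential_protein(
    table: pd.DataFrame,
    treatment: str,
    control: str,
) -> pd.DataFrame:
    """Moderated two-sample t per protein with empirical-Bayes shrinkage.

    The per-protein pooled variance ``s²`` (d residual df) is shrunk toward
    a prior ``s0²`` with ``d0`` prior df: posterior variance
    ``(d0·s0² + d·s²) / (d0 + d)``; the moderated t uses ``d0 + d`` df.
    ``d0`` and ``s0²`` are estimated by method-of-moments on log s² across
    proteins (matching the scaled-F model of sample variances). With a
    single protein no prior can be estimated and the statistic reduces to
    the ordinary two-sample t. P-values are BH-adjusted.
    """
    conds = _condition_columns(table)
    for cond in (treatment, control):
        if cond not in conds:
            raise ValueError(f"condition {cond!r} not in table")
    a = table[conds[treatment]].to_numpy(dtype=float)
    b = table[conds[control]].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    d = n1 + n2 - 2
    if np.any(d <= 0):
        raise ValueError("zero residual degrees of freedom; "
                         "apply valid_value_filter first")
    m1 = np.nanmean(a, axis=1)
    m2 = np.nanmean(b, axis=1)
    v1 = np.nanvar(a, axis=1, ddof=1)
    v2 = np.nanvar(b, axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    lfc = m1 - m2

    ok = s2 > 0
    if ok.sum() >= 2:
        e = (np.log(s2[ok]) - special.digamma(d[ok] / 2.0)
             + np.log(d[ok] / 2.0))
        evar = np.var(e, ddof=1) - np.mean(special.polygamma(1, d[ok] / 2.0))
        if evar > 0:
            d0 = 2.0 * _trigamma_inverse(evar)
            s0_sq = np.exp(np.mean(e) + special.digamma(d0 / 2.0)
                           - np.log(d0 / 2.0))
        else:
            d0, s0_sq = np.inf, float(np.exp(np.mean(e)))
    else:
        d0, s0_sq = 0.0, 0.0  # no shrinkage possible

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, 1e6)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = np.minimum(d0 + d, 1e6)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({
        "log2fc": lfc,
        "t": t,
        "p_raw": p,
        "p_adj": adjust_pvalues(p, "BH"),
        "df_prior": d0,
    }, index=table.index)


def diff_records_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Pass-through mode: consume precomputed differential columns unchanged."""
    required = {"log2fc", "p_raw"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"differential table lacks columns {sorted(missing)}")
    out = table[[c for c in ("log2fc", "p_raw", "p_adj") if c in table.columns]].copy()
    if "p_adj" not in out.columns:
        out["p_adj"] = adjust_pvalues(out["p_raw"].to_numpy(), "BH")
    return out


def threshold_set(
    records: pd.DataFrame,
    p_field: str = "adj",
    p_cut: float = 0.05,
    lfc_cut: float = 0.5,
    direction: str = "up",
) -> set:
    """Proteins passing strict significance cutoffs.

    ``p < p_cut`` and a strict, signed fold-change inequality:
    ``log2fc > lfc_cut`` for ``up``, ``log2fc < -lfc_cut`` for ``down``.
    Values exactly at a cutoff are excluded (the inequalities are strict,
    exactly as the printed rules state them).
    """
    col = {"raw": "p_raw", "adj": "p_adj"}.get(p_field)
    if col is None:
        raise ValueError("p_field must be 'raw' or 'adj'")
    p_ok = records[col] < p_cut
    if direction == "up":
        lfc_ok = records["log2fc"] > lfc_cut
    elif direction == "down":
        lfc_ok = records["log2fc"] < -lfc_cut
    else:
        raise ValueError("direction must be 'up' or 'down'")
    return set(records.index[p_ok & lfc_ok])


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    fisher_p: float

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap larger than the smaller set")
        if max(self.n_a, self.n_b) > self.n_universe:
            raise ValueError("set larger than universe")


def overlap_test(set_a: Iterable, set_b: Iterable, universe: Iterable) -> OverlapResult:
    """One-sided Fisher exact test of set overlap enrichment.

    p = hypergeometric upper tail P(X >= |A ∩ B|) drawing |B| items from a
    universe containing |A| marked items.
    """
    u = set(universe)
    a = set(set_a)
    b = set(set_b)
    if not (a <= u and b <= u):
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return OverlapResult(len(a), len(b), k, len(u), min(1.0, p))


def client_candidates(
    up_oe_1: pd.DataFrame,
    up_oe_2: pd.DataFrame,
    down_ko_1: pd.DataFrame,
    down_ko_2: pd.DataFrame,
    sp_flags: Mapping[str, bool] | None = None,
    p_cut: float = 0.05,
    lfc_cut: float = 0.7,
) -> pd.DataFrame:
    """Translocon client candidates: the four-way intersection of proteins
    upregulated (raw p < p_cut, log2FC > lfc_cut) in both overexpression
    tables and downregulated (raw p < p_cut, log2FC < -lfc_cut) in both
    knockout tables. The signal-peptide flag is annotated post hoc, never
    used to filter."""
    sets = [
        threshold_set(up_oe_1, "raw", p_cut, lfc_cut, "up"),
        threshold_set(up_oe_2, "raw", p_cut, lfc_cut, "up"),
        threshold_set(down_ko_1, "raw", p_cut, lfc_cut, "down"),
        threshold_set(down_ko_2, "raw", p_cut, lfc_cut, "down"),
    ]
    clients = sorted(set.intersection(*sets))
    sp = {} if sp_flags is None else sp_flags
    return pd.DataFrame({
        "protein_id": clients,
        "signal_peptide": [bool(sp.get(p, False)) for p in clients],
    }).set_index("protein_id")


def preranked_metric(records: pd.DataFrame) -> pd.Series:
    """Pre-ranked enrichment metric ``-log10(p_raw) * sign(log2fc)``,
    sorted descending with ties broken by protein id (RNK-compatible)."""
    with np.errstate(divide="ignore"):
        score = -np.log10(records["p_raw"].to_numpy())
    score = score * np.sign(records["log2fc"].to_numpy())
    out = pd.Series(score, index=records.index, name="score")
    return out.sort_index().sort_values(ascending=False, kind="stable")
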