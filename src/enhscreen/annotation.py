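"""Enhancer-element calling from bidirectional nascent transcription.

Candidate enhancers are called as pairs of opposite-strand transcription
units (TUs) whose start sites lie no more than ``max_pair_gap_bp`` apart —
bidirectional eRNA production being a hallmark of active regulatory
elements. TEAD4 motif occurrences are located inside candidate regions by
an exact IUPAC consensus scan, and differential eRNA output between a
high-activity and a low-activity condition flags transcriptionally active
elements.

TU tables are pandas DataFrames with columns ``chrom, start, end, strand``
plus one ``count_<sample>`` column per sample; normalization adds matching
``norm_<sample>`` columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, iupac_matches, quantile_normalize, reverse_complement

__all__ = [
    "MotifSite",
    "tss",
    "filter_and_normalize_tus",
    "call_bidirectional_elements",
    "scan_motifs",
    "erna_differential",
]


@dataclass(frozen=True)
class MotifSite:
    """An exact motif occurrence; ``matched_sequence`` is the motif-strand
    sequence (reverse-complemented genome slice for ``-`` sites)."""

    motif_id: str
    interval: GenomicInterval
    matched_sequence: str
    region_id: str | None = None


def _count_cols(tus: pd.DataFrame) -> list[str]:
    cols = [c for c in tus.columns if c.startswith("count_")]
    if not cols:
        raise ValueError("TU table has no count_<sample> columns")
    return cols


def tss(row) -> int:
    """Start-site coordinate of a TU: interval start for ``+`` TUs, interval
    end for ``-`` TUs (the biological 5' end)."""
    return int(row["start"]) if row["strand"] == "+" else int(row["end"])


def filter_and_normalize_tus(tus: pd.DataFrame, min_reads: int = 20) -> pd.DataFrame:
    """Drop TUs below ``min_reads`` in every sample, then quantile-normalize.

    Returns a copy with ``norm_<sample>`` columns added; after normalization
    all per-sample value distributions are identical.
    """
    cols = _count_cols(tus)
    if len(cols) < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    keep = (tus[cols] >= min_reads).any(axis=1)
    out = tus.loc[keep].copy()
    norm = quantile_normalize(out[cols])
    for c in cols:
        out["norm_" + c[len("count_"):]] = norm[c]
    return out


def call_bidirectional_elements(tus: pd.DataFrame, max_gap: int = 800) -> pd.DataFrame:
    """Pair opposite-strand TUs whose start sites are <= ``max_gap`` apart.

    Pairing is a matching (no TU reused), built greedily by ascending gap
    with deterministic tie-breaking (leftmost start site, then the ``+`` TU
    index). Returns one row per element with the anchor interval spanning
    both start sites and the source TU row labels.
    """
    bad = set(tus["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"TUs with invalid strand: {sorted(bad)}")
    tss_all = np.where(tus["strand"] == "+", tus["start"], tus["end"]).astype(int)
    tss_by_idx = pd.Series(tss_all, index=tus.index)
    plus = tus.index[tus["strand"] == "+"]
    minus = tus.index[tus["strand"] == "-"]
    candidates = []
    for chrom in sorted(set(tus["chrom"])):
        p_idx = plus[tus.loc[plus, "chrom"] == chrom]
        m_idx = minus[tus.loc[minus, "chrom"] == chrom]
        if not len(p_idx) or not len(m_idx):
            continue
        pt = tss_by_idx[p_idx].to_numpy()
        mt = tss_by_idx[m_idx].to_numpy()
        gaps = np.abs(pt[:, None] - mt[None, :])
        for i, j in zip(*np.nonzero(gaps <= max_gap)):
            candidates.append((int(gaps[i, j]), int(min(pt[i], mt[j])),
                               p_idx[i], m_idx[j]))
    candidates.sort(key=lambda t: (t[0], t[1], str(t[2]), str(t[3])))
    used: set = set()
    rows = []
    for gap, _, pi, mi in candidates:
        if pi in used or mi in used:
            continue
        used.update((pi, mi))
        t_plus, t_minus = tss(tus.loc[pi]), tss(tus.loc[mi])
        lo, hi = min(t_plus, t_minus), max(t_plus, t_minus)
        rows.append({
            "element_id": f"elem_{len(rows):04d}",
            "chrom": tus.loc[pi, "chrom"],
            "anchor_start": lo,
            "anchor_end": hi + 1,  # span both start sites, half-open
            "gap": gap,
            "plus_tu": pi,
            "minus_tu": mi,
        })
    return pd.DataFrame(
        rows, columns=["element_id", "chrom", "anchor_start", "anchor_end",
                       "gap", "plus_tu", "minus_tu"])


def scan_motifs(
    genome: Mapping[str, object],
    regions: Mapping[str, GenomicInterval] | Sequence[GenomicInterval],
    consensus: str = "GGAATG",
) -> list[MotifSite]:
    """All exact IUPAC matches of ``consensus`` on both strands inside regions.

    Coordinates are 0-based half-open on the top strand; sites are
    deduplicated per (chrom, position, strand) even when regions overlap.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    if not isinstance(regions, Mapping):
        regions = {f"region_{i:04d}": iv for i, iv in enumerate(regions)}
    m = len(consensus)
    rc = reverse_complement(consensus)
    seen: set[tuple[str, int, str]] = set()
    sites: list[MotifSite] = []
    for rid, iv in regions.items():
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"region {rid} extends beyond chromosome {iv.chrom}")
        seq = str(chrom_seq[iv.start:iv.end]).upper()
        for off in range(0, len(seq) - m + 1):
            window = seq[off:off + m]
            pos = iv.start + off
            for strand, pattern in (("+", consensus), ("-", rc)):
                if iupac_matches(pattern, window):
                    key = (iv.chrom, pos, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    matched = window if strand == "+" else reverse_complement(window)
                    sites.append(MotifSite(
                        motif_id=f"motif_{len(sites):05d}",
                        interval=GenomicInterval(iv.chrom, pos, pos + m, strand),
                        matched_sequence=matched,
                        region_id=rid,
                    ))
    return sites


def erna_differential(
    elements: pd.DataFrame,
    tus: pd.DataFrame,
    condition_samples: Mapping[str, str],
    high: str,
    low: str,
    min_log2fc: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-element eRNA levels per condition and an activity flag.

    The element level in a condition is the sum of the paired TUs'
    quantile-normalized expression; the flag marks elements with
    ``log2((high + eps) / (low + eps)) >= min_log2fc``.
    """
    for cond in (high, low):
        if cond not in condition_samples:
            raise ValueError(f"missing condition {cond!r}")
    out = elements.copy()
    for cond, sample in condition_samples.items():
        col = "norm_" + sample
        if col not in tus.columns:
            raise ValueError(f"TU table lacks normalized column {col!r}")
        out["level_" + cond] = [
            float(tus.loc[r["plus_tu"], col] + tus.loc[r["minus_tu"], col])
            for _, r in elements.iterrows()
        ]
    eps = pseudocount
    out["erna_log2fc"] = np.log2(
        (out["level_" + high] + eps) / (out["level_" + low] + eps))
    out["erna_flag"] = out["erna_log2fc"] >= min_log2fc
    return out
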