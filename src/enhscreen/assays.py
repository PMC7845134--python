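"""Small quantitative assay computations.

* Mutational load of a CRISPR-edited amplicon: per-position mutation counts
  and the fraction of reads carrying at least one mutation (mismatch,
  insertion or deletion) inside a window.
* ChIP-qPCR relative enrichment: percent-input by the delta-Ct method,
  normalized over a negative-control region.
* Competitive-proliferation readout: the odds of perturbed (non-GFP) cells
  against GFP-labeled competitors, relative to day 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import GenomicInterval

__all__ = [
    "AlignmentRecord",
    "read_sam",
    "read_alignment_tsv",
    "mutation_profile",
    "relative_enrichment",
    "competition_fitness",
]

_OPS = ("match", "mismatch", "insertion", "deletion")
_CIGAR_CODE = {7: "match", 8: "mismatch", 1: "insertion", 2: "deletion"}
_CIGAR_CHAR = {"=": "match", "X": "mismatch", "I": "insertion", "D": "deletion"}
_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read, reduced to reference start plus an operation list
    of (op, length) with op in {match, mismatch, insertion, deletion}."""

    read_id: str
    ref_start: int
    ops: tuple

    def __post_init__(self) -> None:
        if not self.ops:
            raise ValueError("alignment without operations")
        for op, length in self.ops:
            if op not in _OPS:
                raise ValueError(f"unsupported operation {op!r}")
            if length < 1:
                raise ValueError("operation lengths must be >= 1")

    def ref_span(self) -> tuple[int, int]:
        """Half-open reference interval covered by this read."""
        length = sum(l for op, l in self.ops if op != "insertion")
        return self.ref_start, self.ref_start + length


def parse_cigar(cigar: str) -> tuple:
    """Parse a CIGAR string restricted to =/X/I/D operations."""
    consumed = "".join(f"{l}{c}" for l, c in _CIGAR_RE.findall(cigar))
    if consumed != cigar or not cigar:
        raise ValueError(f"unsupported CIGAR {cigar!r} (only =, X, I, D)")
    return tuple((_CIGAR_CHAR[c], int(l)) for l, c in _CIGAR_RE.findall(cigar))


def read_sam(path: str) -> list[AlignmentRecord]:
    """Read alignments from a SAM file (=/X/I/D CIGARs required, as emitted
    by amplicon aligners run with extended CIGAR output)."""
    records = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            ops = []
            for code, length in aln.cigartuples:
                if code not in _CIGAR_CODE:
                    raise ValueError(
                        f"read {aln.query_name}: unsupported CIGAR op code {code}")
                ops.append((_CIGAR_CODE[code], length))
            records.append(AlignmentRecord(
                read_id=aln.query_name,
                ref_start=aln.reference_start,
                ops=tuple(ops),
            ))
    return records


def read_alignment_tsv(path: str) -> list[AlignmentRecord]:
    """Read the internal TSV format: read_id, ref_start (0-based), cigar."""
    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentRecord(str(r["read_id"]), int(r["ref_start"]),
                        parse_cigar(str(r["cigar"])))
        for _, r in df.iterrows()
    ]


def mutation_profile(
    alignments: Iterable[AlignmentRecord],
    window: GenomicInterval,
) -> tuple[pd.Series, float]:
    """Per-position mutation counts and the mutated-read fraction.

    A read is mutated iff at least one non-match operation overlaps the
    window. Mismatches and deletions occupy the reference positions they
    span; an insertion is assigned to the reference boundary position at
    which it occurs. The fraction divides by reads overlapping the window.
    """
    positions = np.arange(window.start, window.end)
    counts = pd.Series(0, index=positions, dtype=int)
    n_overlapping = 0
    n_mutated = 0
    for aln in alignments:
        span = aln.ref_span()
        if span[1] <= window.start or span[0] >= window.end:
            continue
        n_overlapping += 1
        hit_positions: set[int] = set()
        pos = aln.ref_start
        for op, length in aln.ops:
            if op == "match":
                pos += length
            elif op in ("mismatch", "deletion"):
                for p in range(pos, pos + length):
                    if window.start <= p < window.end:
                        hit_positions.add(p)
                pos += length
            else:  # insertion: boundary position, consumes no reference
                if window.start <= pos < window.end:
                    hit_positions.add(pos)
        if hit_positions:
            n_mutated += 1
            for p in hit_positions:
                counts.loc[p] += 1
    fraction = n_mutated / n_overlapping if n_overlapping else float("nan")
    return counts, fraction


def relative_enrichment(
    measurements: pd.DataFrame,
    nc_names: str | Sequence[str],
) -> pd.Series:
    """ChIP-qPCR relative binding per target.

    Percent-input per target is ``input_fraction * 2^(Ct_input - Ct_ip)``
    (perfect amplification efficiency assumed); relative binding divides by
    the percent-input of the negative-control region (mean over several NC
    regions when a list is given).
    """
    required = {"target", "Ct_ip", "Ct_input", "input_fraction"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    if (measurements[["Ct_ip", "Ct_input"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    df = measurements.set_index("target")
    pct = df["input_fraction"] * 2.0 ** (df["Ct_input"] - df["Ct_ip"])
    names = [nc_names] if isinstance(nc_names, str) else list(nc_names)
    missing = [n for n in names if n not in pct.index]
    if missing:
        raise ValueError(f"negative control(s) absent: {missing}")
    return (pct / pct.loc[names].mean()).rename("relative_binding")


def competition_fitness(series: pd.DataFrame) -> pd.Series:
    """Relative abundance of sgRNA-carrying (non-GFP) cells per timepoint.

    With g the GFP fraction, the readout is the non-GFP/GFP odds normalized
    to day 0: ``((1-g_t)/g_t) / ((1-g_0)/g_0)``. 1 is neutral; < 1 means
    depletion of the sgRNA-carrying population.
    """
    required = {"day", "gfp_fraction"}
    if not required <= set(series.columns):
        raise ValueError(f"series needs columns {sorted(required)}")
    g = series.set_index("day")["gfp_fraction"].astype(float).sort_index()
    if ((g <= 0) | (g >= 1)).any():
        raise ValueError("GFP fractions must lie strictly inside (0, 1)")
    odds = (1.0 - g) / g
    return (odds / odds.iloc[0]).rename("relative_abundance")
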