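"""Shared genomic and statistical primitives.

Coordinates are 0-based half-open throughout the package (BED-native).
External 1-based inclusive region strings such as ``chr19:41729486-41729491``
are converted at the boundary by :func:`parse_region_string` /
:func:`format_region_string`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenomicInterval",
    "Config",
    "DiffRecord",
    "parse_region_string",
    "format_region_string",
    "adjust_pvalues",
    "quantile_normalize",
    "reverse_complement",
    "iupac_matches",
]

# ---------------------------------------------------------------------------
# sequence alphabet helpers

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_matches(pattern: str, seq: str) -> bool:
    """Exact IUPAC consensus match of ``pattern`` against a concrete sequence.

    Ambiguity codes are expanded on the pattern side only; an ``N`` (or any
    non-ACGT character) in the *subject* sequence never matches, so masked
    genome stretches cannot produce spurious sites.
    """
    if len(pattern) != len(seq):
        return False
    for p, s in zip(pattern.upper(), seq.upper()):
        if s not in "ACGT" or s not in IUPAC_SETS.get(p, ""):
            return False
    return True


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def distance_to_point(self, pos: int) -> int:
        """Distance from a point coordinate to this interval (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0


_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_region_string(s: str) -> GenomicInterval:
    """Parse a 1-based inclusive ``chrom:start-end`` string.

    ``chr19:41729486-41729491`` denotes a 6-bp interval and becomes
    ``GenomicInterval('chr19', 41729485, 41729491)``.
    """
    m = _REGION_RE.match(s.strip())
    if m is None:
        raise ValueError(f"malformed region string: {s!r}")
    chrom, a, b = m.group(1), int(m.group(2)), int(m.group(3))
    if a < 1 or a > b:
        raise ValueError(f"invalid 1-based coordinates in {s!r}")
    return GenomicInterval(chrom, a - 1, b)


def format_region_string(iv: GenomicInterval) -> str:
    """Inverse of :func:`parse_region_string` (1-based inclusive output)."""
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"


@dataclass
class Config:
    """Every numeric rule threshold used across the pipeline.

    Defaults encode the published analysis rules: the 800-bp bidirectional
    pairing gap, the 3-bp Cas9 cut-distance rule around a TEAD4 motif, the
    top-2-most-depleted region score, the top-10 selective hit list, the
    1–5 Mbp cis target window, the proteomics significance cutoffs, and the
    cohort low-expression / ssGSEA settings.
    """

    max_pair_gap_bp: int = 800
    max_cut_distance_bp: int = 3
    pam: str = "NGG"
    protospacer_len: int = 20
    max_guides_per_motif: int = 2
    k_depleted: int = 2
    top_k_hits: int = 10
    erna_min_log2fc: float = 1.0
    ctrl_score_bound: float = 0.25
    target_window_bp: int = 5_000_000
    target_window_min_bp: int = 0
    down_lfc_min: float = 0.25
    lfc_pseudocount: float = 1.0
    prot_adjp_cut: float = 0.05
    prot_lfc_cut: float = 0.5
    client_rawp_cut: float = 0.05
    client_lfc_cut: float = 0.7
    low_expr_log2tpm: float = -1.0
    ssgsea_alpha: float = 0.25
    multiple_testing: str = "BH"
    replicate_order: str = "average_first"  # or "score_first"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_depleted < 1:
            raise ValueError("k_depleted must be >= 1")
        if len(self.pam) != 3:
            raise ValueError("PAM must be a 3-nt IUPAC string")
        if self.multiple_testing not in ("BH", "bonferroni"):
            raise ValueError("multiple_testing must be 'BH' or 'bonferroni'")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite")

    @classmethod
    def from_file(cls, path: str) -> "Config":
        """Load a config from a YAML key=value file mirroring field names."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class DiffRecord:
    """A feature-level differential result (shared by RNA and protein)."""

    feature_id: str
    log2fc: float
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        for name in ("p_raw", "p_adj"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")


# ---------------------------------------------------------------------------
# statistics


def adjust_pvalues(p: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment.

    ``BH`` is the Benjamini-Hochberg step-up FDR; ``bonferroni`` is
    ``min(1, m * p)``. Output order matches input order.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if arr.size == 0:
        return arr.copy()
    if np.any(np.isnan(arr)) or np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(arr, method=key)[1]


def quantile_normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Cross-sample quantile normalization of a features × samples table.

    Every column is mapped onto the common distribution of per-rank row
    means, so all column distributions are identical afterwards while the
    within-column ordering is preserved. Ties within a column receive the
    mean of the reference values they span (``rankdata`` average ranks).
    """
    if frame.shape[1] < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    values = frame.to_numpy(dtype=float)
    order = np.sort(values, axis=0)
    reference = order.mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    from scipy.stats import rankdata

    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        # interpolate the reference at fractional (tied) ranks
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)
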