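"""Motif-constrained CRISPR sgRNA design.

Guides are standard SpCas9 20-nt protospacers adjacent to an NGG PAM; the
blunt cut falls 3 bp 5' of the PAM. A guide is admissible for a motif when
that cut boundary lands inside the motif or within ``max_cut_distance_bp``
(default 3 bp, inclusive) of either edge — disrupting the motif rather than
merely its neighborhood. Candidates are ranked by cut-to-motif distance
(in-motif cuts first), then leftmost cut, then ``+`` before ``-``, and
truncated to ``max_guides_per_motif``.

The assembled library deduplicates guides shared between motifs and adds
non-targeting scramble controls (random 20-mers absent from the genome) and
positive controls targeting a designated transgene contig.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Config, GenomicInterval, iupac_matches, reverse_complement
from .annotation import MotifSite

__all__ = [
    "GuideRNA",
    "Library",
    "enumerate_pams",
    "cut_position",
    "guides_for_motif",
    "build_library",
]


@dataclass(frozen=True)
class GuideRNA:
    """One sgRNA vector.

    ``protospacer`` is stored in genome top-strand orientation (the spacer
    sequence delivered in the vector is its reverse complement for ``-``
    guides); ``pam`` is the guide-strand PAM and therefore matches the
    configured IUPAC PAM for targeting guides. ``cut_pos`` is the 0-based
    boundary coordinate of the blunt cut, 3 bp 5' of the PAM.
    """

    guide_id: str
    protospacer: str
    pam: str
    chrom: str | None
    strand: str
    protospacer_start: int
    cut_pos: int
    motif_ids: frozenset = frozenset()
    region_ids: tuple = ()
    guide_class: str = "targeting"

    @property
    def spacer_seq(self) -> str:
        """The spacer as synthesized (guide orientation)."""
        return (self.protospacer if self.strand == "+"
                else reverse_complement(self.protospacer))


@dataclass
class Library:
    """The assembled guide library with summary bookkeeping."""

    guides: list

    @property
    def targeting(self) -> list:
        return [g for g in self.guides if g.guide_class == "targeting"]

    def summary(self) -> dict:
        regions = set()
        motifs = set()
        for g in self.targeting:
            regions.update(g.region_ids)
            motifs.update(g.motif_ids)
        distinct = {(g.protospacer, g.pam) for g in self.guides}
        return {
            "regions_targeted": len(regions),
            "motifs_targeted": len(motifs),
            "distinct_guides": len(distinct),
            "n_nt_controls": sum(g.guide_class == "nt_control" for g in self.guides),
            "n_positive_controls": sum(
                g.guide_class == "positive_control" for g in self.guides),
        }

    def guide_to_regions(self) -> dict:
        """guide_id -> tuple of region ids (targeting and positive-control)."""
        return {g.guide_id: g.region_ids for g in self.guides if g.region_ids}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.guides:
            rows.append({
                "guide_id": g.guide_id,
                "protospacer": g.protospacer,
                "pam": g.pam,
                "chrom": g.chrom if g.chrom is not None else ".",
                "strand": g.strand,
                "protospacer_start": g.protospacer_start,
                "cut_pos": g.cut_pos,
                "region_id": ",".join(g.region_ids) if g.region_ids else ".",
                "motif_ids": ",".join(sorted(g.motif_ids)) if g.motif_ids else ".",
                "guide_class": g.guide_class,
            })
        return pd.DataFrame(rows)


def enumerate_pams(sequence: str, pam: str = "NGG") -> list[tuple[int, str]]:
    """All (top-strand start, strand) positions of PAM matches.

    A ``+`` hit means the top-strand 3-mer itself matches the PAM; a ``-``
    hit means its reverse complement does (i.e. the PAM reads on the bottom
    strand). ``N`` in the subject sequence never matches.
    """
    seq = sequence.upper()
    rc_pam = reverse_complement(pam)
    hits = []
    for p in range(len(seq) - len(pam) + 1):
        window = seq[p:p + len(pam)]
        if iupac_matches(pam, window):
            hits.append((p, "+"))
        if iupac_matches(rc_pam, window):
            hits.append((p, "-"))
    return hits


def cut_position(pam_start: int, strand: str, pam_len: int = 3) -> int:
    """Blunt-cut boundary coordinate for a PAM starting at ``pam_start``.

    ``+`` guides cut 3 bp upstream of the PAM start; ``-`` guides cut 3 bp
    downstream of the PAM end (mirror image on the bottom strand).
    """
    if strand == "+":
        return pam_start - 3
    if strand == "-":
        return pam_start + pam_len + 3
    raise ValueError(f"invalid strand {strand!r}")


def _cut_distance(cut: int, motif: GenomicInterval) -> int:
    """Distance from a cut boundary to the motif interval (0 when the cut
    lies between motif.start and motif.end inclusive)."""
    if cut < motif.start:
        return motif.start - cut
    if cut > motif.end:
        return cut - motif.end
    return 0


def guides_for_motif(
    genome: Mapping[str, object],
    motif: MotifSite,
    cfg: Config | None = None,
) -> list[GuideRNA]:
    """All admissible guides for one motif site, ranked and truncated.

    Admissible: the cut boundary lies within ``max_cut_distance_bp`` of the
    motif interval (inclusive both sides) and the full protospacer + PAM fit
    inside the chromosome. Returns at most ``max_guides_per_motif`` guides;
    an empty list (with a warning) when the motif sits too close to the
    contig edge or no PAM is in reach.
    """
    cfg = cfg or Config()
    iv = motif.interval
    chrom_seq = genome[iv.chrom]
    chrom_len = len(chrom_seq)
    ps_len = cfg.protospacer_len
    d = cfg.max_cut_distance_bp
    if iv.start < ps_len + d or iv.end + ps_len + d > chrom_len:
        warnings.warn(
            f"motif {motif.motif_id} too close to contig edge; no guides")
        return []
    # candidate PAM starts: + cuts at p-3 in [start-d, end+d]; - cuts at p+6
    ws = max(0, iv.start - d - 6)
    we = min(chrom_len, iv.end + d + 3 + 6)
    window = str(chrom_seq[ws:we]).upper()
    candidates = []
    for off, strand in enumerate_pams(window, cfg.pam):
        p = ws + off
        cut = cut_position(p, strand, len(cfg.pam))
        dist = _cut_distance(cut, iv)
        if dist > d:
            continue
        if strand == "+":
            ps_start, ps_end = p - ps_len, p
            pam_seq = str(chrom_seq[p:p + len(cfg.pam)]).upper()
        else:
            ps_start, ps_end = p + len(cfg.pam), p + len(cfg.pam) + ps_len
            pam_seq = reverse_complement(str(chrom_seq[p:p + len(cfg.pam)]).upper())
        if ps_start < 0 or ps_end > chrom_len:
            continue
        protospacer = str(chrom_seq[ps_start:ps_end]).upper()
        candidates.append((dist, cut, 0 if strand == "+" else 1, GuideRNA(
            guide_id=f"{motif.motif_id}:{strand}{cut}",
            protospacer=protospacer,
            pam=pam_seq,
            chrom=iv.chrom,
            strand=strand,
            protospacer_start=ps_start,
            cut_pos=cut,
            motif_ids=frozenset({motif.motif_id}),
            region_ids=(motif.region_id,) if motif.region_id else (),
        )))
    candidates.sort(key=lambda t: t[:3])
    return [g for *_, g in candidates[:cfg.max_guides_per_motif]]


def _genome_haystack(genome: Mapping[str, object]) -> str:
    parts = []
    for chrom in genome.keys():  # dict and pyfaidx.Fasta both expose keys()
        s = str(genome[chrom][:]) if not isinstance(genome[chrom], str) else genome[chrom]
        parts.append(s.upper())
    fwd = "#".join(parts)
    return fwd + "#" + reverse_complement(fwd)


def build_library(
    genome: Mapping[str, object],
    regions: Mapping[str, GenomicInterval],
    motifs: Sequence[MotifSite],
    n_nt_controls: int = 50,
    positive_targets: Sequence[str] = (),
    cfg: Config | None = None,
    rng: np.random.Generator | None = None,
    n_positive_per_target: int = 5,
) -> Library:
    """Assemble the full library: targeting guides (deduplicated by
    (protospacer, PAM) with merged motif ids), non-targeting scramble
    controls with no exact genomic match on either strand, and positive
    controls cutting along each designated transgene contig."""
    cfg = cfg or Config()
    rng = rng or np.random.default_rng(cfg.seed)
    by_key: dict[tuple[str, str], GuideRNA] = {}
    for motif in motifs:
        for g in guides_for_motif(genome, motif, cfg):
            key = (g.protospacer, g.pam)
            if key in by_key:
                prev = by_key[key]
                merged_regions = tuple(dict.fromkeys(prev.region_ids + g.region_ids))
                by_key[key] = GuideRNA(
                    guide_id=prev.guide_id,
                    protospacer=prev.protospacer, pam=prev.pam,
                    chrom=prev.chrom, strand=prev.strand,
                    protospacer_start=prev.protospacer_start,
                    cut_pos=prev.cut_pos,
                    motif_ids=prev.motif_ids | g.motif_ids,
                    region_ids=merged_regions,
                )
            else:
                by_key[key] = g
    guides = list(by_key.values())
    for i, g in enumerate(guides):
        object.__setattr__(g, "guide_id", f"sg{i:05d}")

    # positive controls: cut sites along each designated transgene contig
    for contig in positive_targets:
        seq = str(genome[contig][:]) if not isinstance(genome[contig], str) else genome[contig]
        chosen = 0
        for p, strand in enumerate_pams(seq, cfg.pam):
            if chosen >= n_positive_per_target:
                break
            cut = cut_position(p, strand, len(cfg.pam))
            if strand == "+":
                ps_start, ps_end = p - cfg.protospacer_len, p
                pam_seq = seq[p:p + len(cfg.pam)].upper()
            else:
                ps_start, ps_end = p + len(cfg.pam), p + len(cfg.pam) + cfg.protospacer_len
                pam_seq = reverse_complement(seq[p:p + len(cfg.pam)].upper())
            if ps_start < 0 or ps_end > len(seq):
                continue
            guides.append(GuideRNA(
                guide_id=f"pos_{contig}_{chosen:02d}",
                protospacer=seq[ps_start:ps_end].upper(),
                pam=pam_seq, chrom=contig, strand=strand,
                protospacer_start=ps_start, cut_pos=cut,
                region_ids=(f"posctrl_{contig}",),
                guide_class="positive_control",
            ))
            chosen += 1

    # non-targeting scramble controls: random 20-mers absent from the genome
    haystack = _genome_haystack(genome)
    bases = np.array(list("ACGT"))
    made = 0
    attempts = 0
    max_attempts = 100 * max(1, n_nt_controls)
    while made < n_nt_controls:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not generate the requested non-targeting controls")
        spacer = "".join(rng.choice(bases, size=cfg.protospacer_len))
        if spacer in haystack:
            continue
        guides.append(GuideRNA(
            guide_id=f"nt_{made:03d}",
            protospacer=spacer, pam="NNN", chrom=None, strand=".",
            protospacer_start=-1, cut_pos=-1,
            guide_class="nt_control",
        ))
        made += 1
    return Library(guides=guides)


def write_protospacer_fasta(library: Library, path: str) -> None:
    with open(path, "w") as fh:
        for g in library.guides:
            fh.write(f">{g.guide_id}\n{g.spacer_seq}\n")
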