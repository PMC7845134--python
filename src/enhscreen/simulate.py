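"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the design of a dual-cell-line enhancer CRISPR
screen: a small genome carrying motif-bearing enhancer regions (each with a
guaranteed PAM so the cut-distance rule can be satisfied, plus a fraction
of deliberately untargetable motifs), guide count matrices with depletion
planted only in the activated-YAP line, bidirectional TU pairs with
condition-specific eRNA output, cis knockdown of one target gene per
disrupted enhancer, proteomics tables with planted signal-peptide client
proteins, and a tumor cohort whose designated gene tracks a signature
score.

Every generator is a pure function of (config, seed): fixed seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import GenomicInterval
from .annotation import MotifSite

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Reference",
    "make_reference",
    "simulate_screen_counts",
    "simulate_groseq",
    "simulate_expression",
    "simulate_proteomics",
    "simulate_protein_abundances",
    "simulate_cohort",
    "write_reference",
]

MOTIF_CONSENSUS = "GGAATG"
TRANSGENE_CONTIG = "transgene_YAP5SA"


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic screen.

    The defaults mirror the screen design: three replicate lentiviral
    pools, negative-binomial guide counts with mean 500 and dispersion 0.1
    (variance = mu + phi*mu^2), a -1.5 log2 depletion planted only in the
    activated-YAP line for 10 of 200 enhancer regions, a 4-fold eRNA
    increase at true-hit enhancers, a 2-fold cis knockdown of the planted
    target gene, and 2 planted translocon clients among the simulated
    proteome.
    """

    n_chrom: int = 2
    chrom_len_bp: int = 2_000_000
    n_regions: int = 200
    region_len_bp: int = 200
    frac_true_hits: float = 0.05
    depletion_log2fc: float = -1.5
    nb_mean: float = 500.0
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    erna_log2fc_true: float = 2.0
    n_erna_inactive_hits: int = 0
    target_knockdown_log2fc: float = -1.0
    expr_noise_sd_log2: float = 0.15
    target_expr_log2_range: tuple = (5.0, 8.0)
    background_expr_log2_range: tuple = (0.0, 8.0)
    erna_noise_sd_log2: float = 0.3
    tu_baseline_log2_range: tuple = (4.5, 9.5)
    erna_baseline_log2_range: tuple = (5.0, 7.0)
    n_decoy_tus: int = 1500
    n_lowcount_tus: int = 20
    frac_untargetable_motifs: float = 0.1
    n_background_genes_per_region: int = 2
    n_nt_controls: int = 50
    n_proteins: int = 400
    n_clients: int = 2
    n_signature_genes: int = 57
    cohort_n_samples: int = 500
    cohort_coupling: float = 0.6
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.frac_true_hits < 1:
            raise ValueError("frac_true_hits must lie in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible generator per simulation stage."""
        return np.random.default_rng([self.seed, stream])

    @property
    def n_true_hits(self) -> int:
        return int(round(self.frac_true_hits * self.n_regions))


@dataclass
class GroundTruth:
    """Planted truth used by tests and the acceptance script."""

    true_hit_region_ids: set
    target_gene_by_region: dict
    erna_inactive_region_ids: set
    client_protein_ids: set
    signature_gene_ids: set

    def to_json(self, path: str) -> None:
        data = {
            "true_hit_region_ids": sorted(self.true_hit_region_ids),
            "target_gene_by_region": self.target_gene_by_region,
            "erna_inactive_region_ids": sorted(self.erna_inactive_region_ids),
            "client_protein_ids": sorted(self.client_protein_ids),
            "signature_gene_ids": sorted(self.signature_gene_ids),
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            set(d["true_hit_region_ids"]), d["target_gene_by_region"],
            set(d["erna_inactive_region_ids"]), set(d["client_protein_ids"]),
            set(d["signature_gene_ids"]))


@dataclass
class Reference:
    """Synthetic genome, enhancer regions, planted motif sites and genes."""

    genome: dict
    regions: dict
    planted_motifs: list
    genes: pd.DataFrame


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    codes = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return codes[rng.integers(0, len(codes), n)].tobytes().decode()


def make_reference(sim: SimulationConfig) -> tuple[Reference, GroundTruth]:
    """Build the genome, regions, motif sites, genes and planted truth.

    Every region carries one motif-consensus occurrence flanked so that an
    NGG PAM cuts inside the motif (targetable by construction); a fraction
    of regions carries a second motif embedded in a G/C-free context that
    admits no PAM within the cut-distance rule (untargetable by
    construction). Each region receives one designated target gene and
    background genes with TSSs inside the cis window.
    """
    rng = sim.rng(1)
    per_chrom = int(np.ceil(sim.n_regions / sim.n_chrom))
    spacing = sim.chrom_len_bp // (per_chrom + 1)
    if spacing < sim.region_len_bp + 3000:
        raise ValueError("infeasible packing: chromosomes too short for the "
                         "requested number of regions")
    genome: dict[str, str] = {}
    regions: dict[str, GenomicInterval] = {}
    motifs: list[MotifSite] = []
    gene_rows = []
    region_idx = 0
    m = len(MOTIF_CONSENSUS)
    for ci in range(sim.n_chrom):
        chrom = f"chr{ci + 1}"
        seq = list(_random_seq(rng, sim.chrom_len_bp))
        for k in range(per_chrom):
            if region_idx >= sim.n_regions:
                break
            rid = f"region_{region_idx:04d}"
            center = spacing * (k + 1)
            start = center - sim.region_len_bp // 2
            iv = GenomicInterval(chrom, start, start + sim.region_len_bp)
            regions[rid] = iv
            # targetable motif: consensus followed by a TGG PAM, so the
            # blunt cut (pam_start - 3) lands inside the motif
            mstart = center - m // 2
            island = MOTIF_CONSENSUS + "TGG"
            seq[mstart:mstart + len(island)] = island
            motifs.append(MotifSite(
                motif_id=f"pm_{region_idx:04d}",
                interval=GenomicInterval(chrom, mstart, mstart + m, "+"),
                matched_sequence=MOTIF_CONSENSUS,
                region_id=rid,
            ))
            if rng.random() < sim.frac_untargetable_motifs:
                # second motif in an A/T-only context: no NGG PAM can place
                # a cut within the allowed distance of the motif
                ustart = start + sim.region_len_bp - 40
                ctx = (_random_seq(rng, 13, "AT") + MOTIF_CONSENSUS
                       + _random_seq(rng, 13, "AT"))
                seq[ustart - 13:ustart - 13 + len(ctx)] = ctx
                motifs.append(MotifSite(
                    motif_id=f"um_{region_idx:04d}",
                    interval=GenomicInterval(chrom, ustart, ustart + m, "+"),
                    matched_sequence=MOTIF_CONSENSUS,
                    region_id=rid,
                ))
            # genes: one designated target plus background genes, all TSSs
            # within the cis window of the region
            tgt_off = int(rng.integers(10_000, 50_000)) * (1 if rng.random() < 0.5 else -1)
            tss = int(np.clip(center + tgt_off, 2000, sim.chrom_len_bp - 3000))
            gene_rows.append({
                "gene_id": f"g{region_idx:04d}_tgt", "chrom": chrom,
                "tss": tss, "start": tss, "end": tss + 2000, "strand": "+",
            })
            for b in range(sim.n_background_genes_per_region):
                off = int(rng.integers(5_000, 60_000)) * (1 if rng.random() < 0.5 else -1)
                btss = int(np.clip(center + off, 2000, sim.chrom_len_bp - 3000))
                gene_rows.append({
                    "gene_id": f"g{region_idx:04d}_bg{b}", "chrom": chrom,
                    "tss": btss, "start": btss, "end": btss + 2000, "strand": "+",
                })
            region_idx += 1
        genome[chrom] = "".join(seq)
    genome[TRANSGENE_CONTIG] = _random_seq(rng, 300)

    all_rids = sorted(regions)
    true_hits = set(rng.choice(all_rids, size=sim.n_true_hits, replace=False))
    n_inactive = min(sim.n_erna_inactive_hits, len(true_hits))
    inactive = set(rng.choice(sorted(true_hits), size=n_inactive, replace=False))
    truth = GroundTruth(
        true_hit_region_ids=true_hits,
        target_gene_by_region={
            rid: f"g{int(rid.split('_')[1]):04d}_tgt" for rid in all_rids},
        erna_inactive_region_ids=inactive,
        client_protein_ids={f"prot_{i:04d}" for i in range(sim.n_clients)},
        signature_gene_ids={f"SIG{i:03d}" for i in range(sim.n_signature_genes)},
    )
    genes = pd.DataFrame(gene_rows)
    return Reference(genome=genome, regions=regions, planted_motifs=motifs,
                     genes=genes), truth


def simulate_screen_counts(
    library,
    truth: GroundTruth,
    sim: SimulationConfig,
) -> dict:
    """Guide count matrices for the activated-YAP and control lines.

    Counts follow a gamma-Poisson hierarchy: each (guide, replicate, cell
    line) draws a latent pool abundance a ~ Gamma(1/phi, mu*phi) — the
    representation of that guide in that lentiviral pool — and T0 ~
    Poisson(a), T20 ~ Poisson(a * 2^lfc). Marginally T0 is exactly
    NB(mu, phi) with variance mu + phi*mu^2, and T20 counts are scaled by
    2^lfc in expectation. Depletion (lfc = depletion_log2fc) applies to
    guides of true-hit regions and, for positive-control guides, in the
    activated-YAP line only; non-targeting controls are drift-free.
    """
    classes = {g.guide_class for g in library.guides}
    if "nt_control" not in classes:
        raise ValueError("library lacks non-targeting control guides")
    if "positive_control" not in classes:
        raise ValueError("library lacks positive control guides")
    rng = sim.rng(2)
    phi = sim.nb_dispersion
    mu = sim.nb_mean
    guide_ids = [g.guide_id for g in library.guides]
    depleted = np.array([
        (g.guide_class == "positive_control")
        or (g.guide_class == "targeting"
            and bool(set(g.region_ids) & truth.true_hit_region_ids))
        for g in library.guides
    ])
    out = {}
    for cell_line in ("yap", "ctrl"):
        lfc = np.where(depleted & (cell_line == "yap"), sim.depletion_log2fc, 0.0)
        cols = {}
        for rep in range(1, sim.n_replicates + 1):
            a = rng.gamma(shape=1.0 / phi, scale=mu * phi, size=len(guide_ids))
            cols[f"{cell_line}_r{rep}_T0"] = rng.poisson(a)
            cols[f"{cell_line}_r{rep}_T20"] = rng.poisson(a * 2.0 ** lfc)
        out[cell_line] = pd.DataFrame(cols, index=pd.Index(guide_ids, name="guide_id"))
    return out


def simulate_groseq(
    regions: Mapping[str, GenomicInterval],
    truth: GroundTruth,
    sim: SimulationConfig,
) -> pd.DataFrame:
    """Nascent-transcription TU table for a high- and a low-activity line.

    Each region emits one divergent TU pair whose start sites are at most
    800 bp apart; true-hit regions (unless planted eRNA-inactive) produce
    2^erna_log2fc_true more signal in the high-activity condition.
    Background TU expression is log-uniform over a broad dynamic range so
    the planted signal occupies a realistic sliver of the distribution.
    Unpaired decoy TUs (no opposite-strand partner within the gap rule) and
    low-count TUs (below the read filter) are planted deliberately.
    """
    rng = sim.rng(3)
    rows = []

    def baseline(log2_range) -> float:
        return float(2.0 ** rng.uniform(*log2_range))

    centers: dict[str, list[int]] = {}
    for rid in sorted(regions):
        iv = regions[rid]
        center = (iv.start + iv.end) // 2
        centers.setdefault(iv.chrom, []).append(center)
        gap = int(rng.integers(100, 801))
        tss_minus = center - (gap - gap // 2)
        tss_plus = tss_minus + gap
        active = (rid in truth.true_hit_region_ids
                  and rid not in truth.erna_inactive_region_ids)
        ratio = 2.0 ** sim.erna_log2fc_true if active else 1.0
        for strand, start, end in (
            ("+", tss_plus, tss_plus + 1000),
            ("-", tss_minus - 1000, tss_minus),
        ):
            # eRNAs sit in the lower part of the TU expression range
            base = baseline(sim.erna_baseline_log2_range)
            low = base * 2.0 ** rng.normal(0.0, sim.erna_noise_sd_log2)
            high = base * ratio * 2.0 ** rng.normal(0.0, sim.erna_noise_sd_log2)
            rows.append({"chrom": iv.chrom, "start": start, "end": end,
                         "strand": strand, "region_id": rid,
                         "count_high": int(round(high)),
                         "count_low": int(round(low))})
    # decoys: isolated single TUs between regions, one strand per chromosome
    # and >= 2.5 kb from region centers, so none acquires a partner
    slots: list[tuple[str, int]] = []
    for chrom in sorted(centers):
        bounds = [0] + sorted(centers[chrom]) + [max(centers[chrom]) + 50_000]
        for a, b in zip(bounds[:-1], bounds[1:]):
            slots.extend((chrom, p) for p in range(a + 2500, b - 2500, 1000))
    n_wanted = sim.n_decoy_tus + sim.n_lowcount_tus
    if len(slots) < n_wanted:
        raise ValueError("infeasible decoy packing: too few inter-region slots")
    chrom_order = sorted(centers)
    for i, (chrom, pos) in enumerate(slots[:n_wanted]):
        strand = "+" if chrom_order.index(chrom) % 2 == 0 else "-"
        lowcount = i >= sim.n_decoy_tus
        level = 5.0 if lowcount else baseline(sim.tu_baseline_log2_range)
        rows.append({
            "chrom": chrom, "start": pos, "end": pos + 800, "strand": strand,
            "region_id": ".",
            "count_high": int(round(level * 2.0 ** rng.normal(0, 0.2))),
            "count_low": int(round(level * 2.0 ** rng.normal(0, 0.2))),
        })
    return pd.DataFrame(rows)


def simulate_expression(
    regions: Mapping[str, GenomicInterval],
    truth: GroundTruth,
    sim: SimulationConfig,
    genes: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Expression table (RPKM-like) for enhancer-KO and control samples.

    Two KO samples per true-hit region plus two non-targeting controls.
    The planted target gene of each true-hit region is scaled by
    2^target_knockdown_log2fc in both of that region's KO samples; every
    other value is log-normal noise around a per-gene baseline. Returns the
    table and the map region -> its two KO sample names.
    """
    rng = sim.rng(4)
    gene_ids = list(genes["gene_id"])
    # designated targets are decently expressed; the background spans down
    # to near-silent genes, as in a real transcriptome, so a knockdown of a
    # target is not clamped by the rank floor of quantile normalization
    is_target = np.array([g.endswith("_tgt") for g in gene_ids])
    baseline = np.where(
        is_target,
        2.0 ** rng.uniform(*sim.target_expr_log2_range, size=len(gene_ids)),
        2.0 ** rng.uniform(*sim.background_expr_log2_range, size=len(gene_ids)))
    hit_rids = sorted(truth.true_hit_region_ids)
    ko_samples = {rid: [f"{rid}_KO1", f"{rid}_KO2"] for rid in hit_rids}
    samples = [s for rid in hit_rids for s in ko_samples[rid]] + ["NT1", "NT2"]
    data = {}
    for s in samples:
        noise = 2.0 ** rng.normal(0.0, sim.expr_noise_sd_log2, size=len(gene_ids))
        vals = baseline * noise
        data[s] = vals
    expr = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    kd = 2.0 ** sim.target_knockdown_log2fc
    for rid in hit_rids:
        tgt = truth.target_gene_by_region[rid]
        for s in ko_samples[rid]:
            expr.loc[tgt, s] *= kd
    return expr, ko_samples


def simulate_proteomics(
    truth: GroundTruth,
    sim: SimulationConfig,
    p_cut: float = 0.05,
    lfc_cut: float = 0.7,
) -> tuple[dict, pd.Series]:
    """Four differential protein tables plus signal-peptide flags.

    Planted clients pass all four client criteria (up in both
    overexpression tables, down in both knockout tables, raw p below cut,
    |log2FC| above cut); every non-client is guaranteed to violate at least
    one criterion. Clients always carry a signal peptide.
    """
    from .core import adjust_pvalues

    rng = sim.rng(5)
    proteins = [f"prot_{i:04d}" for i in range(sim.n_proteins)]
    clients = truth.client_protein_ids
    tables: dict[str, pd.DataFrame] = {}
    specs = [("yap_oe", +1), ("tram2_oe", +1), ("ko1", -1), ("ko2", -1)]
    raw = {}
    for name, sign in specs:
        lfc = rng.normal(0.0, 0.4, size=len(proteins))
        p = rng.uniform(0.0, 1.0, size=len(proteins))
        for i, pid in enumerate(proteins):
            if pid in clients:
                lfc[i] = sign * (lfc_cut + 0.3 + abs(rng.normal(0.0, 0.3)))
                p[i] = rng.uniform(0.0005, 0.6 * p_cut)
        raw[name] = (lfc, p)
    # enforce that non-clients violate at least one of the four criteria
    for i, pid in enumerate(proteins):
        if pid in clients:
            continue
        passes = all(
            raw[name][1][i] < p_cut and sign * raw[name][0][i] > lfc_cut
            for name, sign in specs)
        if passes:
            raw[specs[0][0]][1][i] = 0.6
    for name, _ in specs:
        lfc, p = raw[name]
        tables[name] = pd.DataFrame({
            "log2fc": lfc, "p_raw": p, "p_adj": adjust_pvalues(p, "BH"),
        }, index=pd.Index(proteins, name="protein_id"))
    sp = pd.Series(rng.random(len(proteins)) < 0.3,
                   index=proteins, name="signal_peptide")
    sp.loc[sorted(clients)] = True
    return tables, sp


def simulate_protein_abundances(
    n_proteins: int = 200,
    n_changed: int = 20,
    effect_log2: float = 1.0,
    n_replicates: int = 3,
    missing_rate: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, set]:
    """Raw log2 LFQ abundance table (2 conditions × replicates) with a
    known changed subset and missing-at-random values; for exercising the
    valid-value filter and the moderated t."""
    rng = np.random.default_rng(seed)
    proteins = [f"prot_{i:04d}" for i in range(n_proteins)]
    base = rng.uniform(20, 30, size=n_proteins)
    sd = rng.uniform(0.1, 0.5, size=n_proteins)
    changed = set(proteins[:n_changed])
    cols = {}
    for cond, shift in (("trt", effect_log2), ("ctl", 0.0)):
        for rep in range(1, n_replicates + 1):
            vals = base + rng.normal(0.0, sd)
            if shift:
                vals = vals + np.where(
                    [p in changed for p in proteins], shift, 0.0)
            mask = rng.random(n_proteins) < missing_rate
            cols[f"abundance_{cond}_r{rep}"] = np.where(mask, np.nan, vals)
    return pd.DataFrame(cols, index=pd.Index(proteins, name="protein_id")), changed


def simulate_cohort(
    truth: GroundTruth,
    sim: SimulationConfig,
    gene_id: str = "GENE_TARGET",
    n_background_genes: int = 100,
) -> pd.DataFrame:
    """Cohort expression (log2 TPM) + survival, with a designated gene
    whose expression correlates with the signature score.

    Signature genes load on a latent activity; the designated gene is
    constructed to have Pearson r ~ cohort_coupling with the realized
    ssGSEA score. Survival times decrease monotonically in the score
    (exponential hazard link). One additional small study expresses the
    designated gene below the low-expression cutoff (LowEx case).
    """
    from .cohort import ssgsea_scores

    rng = sim.rng(6)
    n = sim.cohort_n_samples
    sig_genes = sorted(truth.signature_gene_ids)
    samples = [f"S{i:04d}" for i in range(n)]
    latent = rng.normal(0.0, 1.0, size=n)
    data = {}
    for g in sig_genes:
        load = rng.uniform(0.5, 1.0)
        data[g] = 3.0 + load * latent + rng.normal(0.0, 0.6, size=n)
    for i in range(n_background_genes):
        data[f"BG{i:03d}"] = 3.0 + rng.normal(0.0, 1.0, size=n)
    expr = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))
    scores = ssgsea_scores(expr.T, sig_genes)
    z = (scores - scores.mean()) / scores.std(ddof=0)
    r = sim.cohort_coupling
    noise = rng.normal(0.0, 1.0, size=n)
    expr[gene_id] = 3.0 + r * z.to_numpy() + np.sqrt(max(0.0, 1 - r * r)) * noise

    studies = np.array(["STUDY_%s" % "ABCD"[i % 4] for i in range(n)])
    hazard = 0.02 * np.exp(0.8 * z.to_numpy())
    time = rng.exponential(1.0 / hazard)
    censor = 80.0
    event = (time <= censor).astype(int)
    time = np.minimum(time, censor)

    cohort = pd.concat([
        pd.DataFrame({"study": studies, "OS_time": time, "OS_event": event},
                     index=expr.index),
        expr,
    ], axis=1)

    # extra LowEx study: designated gene below the expression cutoff
    n_low = 40
    low = pd.DataFrame(
        {g: 3.0 + rng.normal(0.0, 1.0, size=n_low) for g in expr.columns},
        index=pd.Index([f"L{i:04d}" for i in range(n_low)], name="sample_id"))
    low[gene_id] = -2.0 + 0.3 * rng.normal(0.0, 1.0, size=n_low)
    low.insert(0, "OS_event", rng.integers(0, 2, size=n_low))
    low.insert(0, "OS_time", rng.uniform(1, censor, size=n_low))
    low.insert(0, "study", "STUDY_LOW")
    return pd.concat([cohort, low], axis=0)


# ---------------------------------------------------------------------------
# plain-text exports


def write_fasta(genome: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            seq = genome[chrom] if isinstance(genome[chrom], str) else str(genome[chrom][:])
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed6(intervals: Mapping[str, GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(intervals):
            iv = intervals[name]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_reference(ref: Reference, truth: GroundTruth, outdir: str) -> None:
    """Write genome FASTA, region/motif BED6, gene TSV and truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ref.genome, out / "genome.fa")
    write_bed6(ref.regions, out / "regions.bed")
    write_bed6({m.motif_id: m.interval for m in ref.planted_motifs},
               out / "motifs.bed")
    ref.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
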