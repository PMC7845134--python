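"""End-to-end orchestration of the enhancer-screen inference chain on
synthetic data: reference construction, motif scanning, library design,
screen simulation and scoring, eRNA filtering, cis target assignment,
proteomic client intersection, and cohort signature scoring."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import Config
from .annotation import (call_bidirectional_elements, erna_differential,
                         filter_and_normalize_tus, scan_motifs)
from .guides import Library, build_library
from .screen import (CountMatrix, apply_erna_filter, control_normalize,
                     guide_log2fc, region_score, select_hits)
from .targets import (assign_targets, quantile_normalize_expression,
                      relative_expression)
from .proteomics import client_candidates
from .cohort import correlate_with_signature, median_split, ssgsea_scores
from .simulate import (MOTIF_CONSENSUS, TRANSGENE_CONTIG, GroundTruth,
                       Reference, SimulationConfig, make_reference,
                       simulate_cohort, simulate_expression, simulate_groseq,
                       simulate_proteomics, simulate_screen_counts)

__all__ = ["PipelineResult", "run_screen_stage", "run_pipeline"]


@dataclass
class PipelineResult:
    sim: SimulationConfig
    cfg: Config
    reference: Reference
    truth: GroundTruth
    library: Library
    guide_lfc: pd.DataFrame
    scores: dict
    hits: pd.DataFrame
    positive_controls: pd.DataFrame
    elements: pd.DataFrame
    filtered_hits: pd.DataFrame
    target_calls: dict
    clients: pd.DataFrame
    cohort_correlation: pd.DataFrame

    @property
    def recovered_hits(self) -> set:
        return set(self.hits.index) & self.truth.true_hit_region_ids

    @property
    def rank1_target_regions(self) -> set:
        """Hit regions whose planted target gene is the top-ranked call."""
        out = set()
        for rid, calls in self.target_calls.items():
            if len(calls) and calls.iloc[0]["gene_id"] == \
                    self.truth.target_gene_by_region.get(rid):
                out.add(rid)
        return out


def run_screen_stage(
    reference: Reference,
    truth: GroundTruth,
    sim: SimulationConfig,
    cfg: Config,
):
    """Design the library, simulate counts, and score both cell lines."""
    motifs = scan_motifs(reference.genome, reference.regions, MOTIF_CONSENSUS)
    library = build_library(
        reference.genome, reference.regions, motifs,
        n_nt_controls=sim.n_nt_controls,
        positive_targets=[TRANSGENE_CONTIG],
        cfg=cfg, rng=sim.rng(7))
    counts = simulate_screen_counts(library, truth, sim)
    combined = pd.concat([counts["yap"], counts["ctrl"]], axis=1)
    matrix = CountMatrix(combined)
    nt_ids = [g.guide_id for g in library.guides if g.guide_class == "nt_control"]
    norm, _ = control_normalize(matrix, nt_ids)
    lfc = guide_log2fc(norm, cfg.lfc_pseudocount)
    g2r = library.guide_to_regions()
    scores = {
        line: region_score(lfc, g2r, line, cfg.k_depleted, cfg.replicate_order)
        for line in ("yap", "ctrl")
    }
    hits, pos = select_hits(scores["yap"], scores["ctrl"], cfg,
                            positive_control_regions=[f"posctrl_{TRANSGENE_CONTIG}"])
    return library, lfc, scores, hits, pos


def run_pipeline(sim: SimulationConfig | None = None,
                 cfg: Config | None = None) -> PipelineResult:
    """Run every stage on synthetic data with planted ground truth."""
    sim = sim or SimulationConfig()
    cfg = cfg or Config()
    reference, truth = make_reference(sim)
    library, lfc, scores, hits, pos = run_screen_stage(reference, truth, sim, cfg)

    # eRNA activity filter
    tus = simulate_groseq(reference.regions, truth, sim)
    ntus = filter_and_normalize_tus(tus)
    elements = call_bidirectional_elements(ntus, cfg.max_pair_gap_bp)
    elements = erna_differential(
        elements, ntus, {"high": "high", "low": "low"}, "high", "low",
        cfg.erna_min_log2fc, cfg.lfc_pseudocount)
    filtered_hits = apply_erna_filter(hits, elements, reference.regions)

    # cis target assignment for hit regions with KO expression data
    expr, ko_samples = simulate_expression(
        reference.regions, truth, sim, reference.genes)
    norm_expr = quantile_normalize_expression(expr)
    rel = relative_expression(norm_expr, ["NT1", "NT2"], cfg.lfc_pseudocount)
    guide_cuts: dict[str, list[tuple[str, int]]] = {}
    for g in library.targeting:
        for rid in g.region_ids:
            guide_cuts.setdefault(rid, []).append((g.chrom, g.cut_pos))
    target_calls = {}
    for rid in hits.index:
        if rid not in ko_samples:
            continue
        target_calls[rid] = assign_targets(
            rid, guide_cuts.get(rid, []), rel, ko_samples[rid],
            reference.genes, cfg)

    # proteomic client intersection
    tables, sp = simulate_proteomics(
        truth, sim, cfg.client_rawp_cut, cfg.client_lfc_cut)
    clients = client_candidates(
        tables["tram2_oe"], tables["yap_oe"], tables["ko1"], tables["ko2"],
        sp, cfg.client_rawp_cut, cfg.client_lfc_cut)

    # cohort signature correlation
    cohort = simulate_cohort(truth, sim)
    gene_cols = [c for c in cohort.columns
                 if c not in ("study", "OS_time", "OS_event")]
    sig_scores = ssgsea_scores(
        cohort[gene_cols].T, sorted(truth.signature_gene_ids),
        cfg.ssgsea_alpha, cfg.low_expr_log2tpm)
    correlation = correlate_with_signature(cohort, "GENE_TARGET", sig_scores, cfg)

    return PipelineResult(
        sim=sim, cfg=cfg, reference=reference, truth=truth, library=library,
        guide_lfc=lfc, scores=scores, hits=hits, positive_controls=pos,
        elements=elements, filtered_hits=filtered_hits,
        target_calls=target_calls, clients=clients,
        cohort_correlation=correlation)
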