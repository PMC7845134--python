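# Methods

This note records the models, rules, and design choices behind the
package, in the spirit of a methods supplement: what is computed, under
which assumptions, which knobs matter, and what the synthetic data do and
do not establish.

## The inference chain

The pipeline treats an enhancer CRISPR screen as a chain of small,
well-defined decision rules rather than one monolithic model:

1. **Enhancer calling.** Bidirectional transcription marks active
   regulatory elements. TUs with < 20 reads in every sample are dropped;
   remaining counts are quantile-normalized so all samples share one
   distribution. Opposite-strand TUs whose start sites (interval start for
   `+` TUs, interval end for `-` TUs) lie ≤ 800 bp apart are paired
   greedily by ascending gap, ties broken by leftmost start site then TU
   identity, and each TU joins at most one element. The 800-bp bound is
   inclusive.
2. **eRNA activity.** An element's level per condition is the sum of its
   two TUs' normalized expression; it is called active when
   log2((high + ε)/(low + ε)) ≥ 1 with ε = 1. This is a fold-change rule,
   not a significance test — no replicate structure is assumed for the
   nascent-RNA data — and the threshold is a config knob
   (`erna_min_log2fc`).
3. **Guide design.** Guides follow SpCas9 geometry: 20-nt protospacer,
   NGG PAM, blunt cut 3 bp 5′ of the PAM (between protospacer positions
   17 and 18). The admissibility rule is interval-based: the cut boundary
   must lie in [motif.start − 3, motif.end + 3], inclusive on both sides
   ("within the motif or up to 3 bp from its edges"). Among admissible
   candidates, cuts inside the motif are preferred over near-motif cuts,
   then leftmost cut, then `+` strand before `-`; at most 2 guides per
   motif are kept. Non-targeting controls are random 20-mers verified to
   have no exact match in the (synthetic) genome on either strand; on a
   real genome one would additionally want an off-target score, which is
   deliberately out of scope.
4. **Screen scoring.** Size factors are the median, over non-targeting
   guides with all-positive counts, of count / geometric-mean-across-
   samples, rescaled to geometric mean 1. The rescaling makes the
   normalization exactly idempotent and leaves relative factors unchanged;
   anchoring on the controls encodes the design assumption that scramble
   guides are fitness-neutral. Guide LFC is log2((T20 + 1)/(T0 + 1)) per
   replicate, averaged over replicates; the region score is the mean of
   the k = 2 most depleted guides (all guides when a region has fewer
   than k; ties broken by guide id). Averaging over replicates before
   taking the k most depleted is the default; the alternative order
   (per-replicate region scores, then average) is exposed as
   `replicate_order="score_first"`.
5. **Hit selection.** Selectivity = score_YAP − score_ctrl. Regions
   depleted in the control line (score_ctrl < −0.25) are ineligible — the
   screen looks for enhancers whose loss matters only under activated
   YAP. Eligible regions are ranked by selectivity ascending and the top
   10 kept; positive-control pseudo-regions are excluded from the list
   and reported separately. The 0.25 eligibility bound is a design knob
   (`ctrl_score_bound`): no published formula exists for "selective
   depletion only in" one line, so the rule is made explicit and tunable.
6. **Target assignment.** Candidates need a TSS within
   [`target_window_min_bp`, `target_window_bp`] (defaults 0 and 5 Mbp) of
   the nearest guide cut site and a mean relative log2 expression ≤ −0.25
   across the region's two KO samples, ranked by knockdown then distance.
   The published "within 1–5 Mbp" phrase is ambiguous between an annulus
   and an upper bound; both readings are supported by the two window
   knobs, with the upper-bound reading as default since published
   candidate targets include genes much closer than 1 Mbp. Downregulation
   here is an effect-size floor on quantile-normalized relative levels;
   an external differential-expression call set can be supplied to
   restrict candidates to formally significant genes.
7. **Proteomics.** When raw LFQ abundances are given, proteins need ≥ 2
   valid values in each condition; the test is a moderated two-sample t
   with empirical-Bayes variance shrinkage: posterior variance
   (d₀s₀² + d·s²)/(d₀ + d) with the prior (d₀, s₀²) estimated by matching
   the moments of log s² across proteins (scaled-F model; the trigamma
   equation is inverted by Newton iteration). With a single protein no
   prior exists and the statistic reduces to the ordinary t. A
   pass-through mode consumes published log2FC/p columns unchanged, so
   count reproduction from published tables never depends on re-fitting.
   Threshold sets use strict inequalities exactly as printed. The Fisher
   universe is the set of proteins present (post filter) in both compared
   tables, and the test is one-sided for enrichment. Client candidates
   are the four-way intersection (up in both overexpressions, down in
   both knockouts, raw p < 0.05, |log2FC| > 0.7); the signal-peptide flag
   is annotated but never filters, mirroring the post-hoc check in the
   original analysis.
8. **Cohort scoring.** ssGSEA per sample: genes below log2 TPM = −1 are
   dropped sample-wise; remaining genes are ranked by expression
   descending (ties by gene id); with rank statistics N..1 the score is
   Σᵢ (P_in(i) − P_out(i)), P_in the cumulative |rank|^α weight over
   in-set genes (α = 0.25, the reference implementation's default) and
   P_out the cumulative out-of-set count. The score is left un-normalized
   by default because only its ordering and median split are consumed;
   range normalization across samples is available as an option. Per
   study, Pearson r of a gene against the score is computed unless the
   study's mean expression of the gene is below −1 (`LowEx`); p-values
   are adjusted across studies by BH (default) or Bonferroni — both are
   offered because the source analyses used each in different places.
   Median split labels value ≥ median as high. Survival fitting itself
   (Cox, Kaplan-Meier) is routine and left to dedicated packages; a
   survival-ready table is exported.

## The synthetic-data generator

The generator emulates the screen's design: two cell lines × three
replicate lentiviral pools × two timepoints; 200 enhancer regions on two
2-Mb chromosomes, each carrying a planted motif with a PAM placed so the
cut lands inside the motif (plus, in ~10% of regions, a second motif in a
G/C-free context that admits no PAM within the cut rule — untargetable by
construction); 10 planted true hits with −1.5 log2 depletion in the
activated-YAP line only; divergent TU pairs per region with a 4-fold eRNA
elevation at true hits; one designated target gene per region knocked down
2-fold in that region's KO samples; 400 simulated proteins with 2 planted
signal-peptide clients; a 500-sample cohort whose designated gene tracks
the signature score with Pearson r ≈ 0.6.

Counts follow a gamma-Poisson hierarchy: each (guide, replicate, line)
draws a latent pool abundance a ~ Gamma(1/φ, μφ) — the representation of
that guide in that lentiviral pool — and T0 ~ Poisson(a),
T20 ~ Poisson(a·2^LFC). Marginally T0 is exactly NB(μ, φ) with variance
μ + φμ² (μ = 500, φ = 0.1), and T20 is scaled by 2^LFC in expectation.
Sharing the latent abundance between the two timepoints of one replicate
is the point of sequencing T0 at all: pool representation varies guide to
guide and carries through the experiment, so the ratio T20/T0 cancels it.
An independent-draws model would instead charge the full overdispersion
(LFC sd ≈ 0.38 at these parameters) to every ratio, which corresponds to
an assay where the T0 measurement provides no pairing information — not
how pooled screens behave.

Several background distributions are chosen for realism because rank-based
normalization makes them load-bearing:

- TU expression spans a broad log-uniform range (2^4.5–2^9.5) over ~1900
  TUs. With a small, homogeneous TU set, the planted 4-fold elevation of
  20 TUs dominates the distribution tail and quantile normalization
  compresses exactly the signal being measured; a realistically broad and
  large background (real nascent-RNA TU catalogs run to tens of
  thousands) keeps the planted signal a sliver of the distribution.
  eRNA baselines sit in the lower part of that range (2^5–2^7), as eRNAs
  do relative to mRNA-scale TUs.
- Expression-table target genes are decently expressed (2^5–2^8) over a
  background that reaches near-silent genes (2^0–2^8). A knockdown of a
  gene already at the distribution floor is invisible after quantile
  normalization (the rank floor clamps it back); published enhancer
  targets are well-expressed genes.
- Per-sample expression noise is 0.15 log2 — the replicate-level
  variability of deep mRNA-seq for expressed genes. The synthetic gene
  density inside the 5-Mb window is ~15× the human genome's, so the
  rank-1 test faces many more competitors than a real locus; realistic
  per-gene noise keeps the comparison meaningful rather than
  noise-dominated.

Every generator is a pure function of (config, seed); fixed seeds give
byte-identical files. Decoy TUs (isolated, one strand per chromosome,
≥ 2.5 kb from region centers) and low-count TUs exercise the pairing and
read filters; proteomics non-clients are explicitly checked to violate at
least one client criterion.

What passing tests on these data show: the decision rules are implemented
exactly (boundaries, tie-breaks, strict inequalities), the scoring chain
recovers planted signal at realistic noise levels, and the null
calibration is honest (no planted depletion → chance-level recovery).
What they do not show: robustness to alignment artifacts, copy-number
confounding, guide-efficiency variation, off-target effects, batch
structure in proteomics, or tumor-cohort confounders — none of which are
modeled.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere internally; 1-based
  inclusive region strings and SAM positions are converted at the
  boundary.
- Pseudocounts (ε = 1) guard every log ratio; no infinities arise from
  zero counts.
- Quantile normalization maps tied values to the mean of the reference
  values their ranks span (average ranks, linear interpolation).
- Greedy pairing, guide ranking, hit ranking, target ranking, ssGSEA
  ranking and the pre-ranked metric all carry explicit deterministic
  tie-breaks (documented per function), so outputs are reproducible
  across platforms.
- Degenerate cases warn and return empty/NaN rather than raise where the
  scientific meaning is "nothing found": a motif too close to the contig
  edge, a region with no downregulated gene in the window, an empty
  eligible-region set, a gene set with no expressed member. Structural
  errors (malformed samples, missing conditions, out-of-range p-values)
  raise.
- The moderated-t prior falls back to no shrinkage (d₀ = 0) when fewer
  than two informative variances exist, and to complete shrinkage
  (d₀ = ∞, capped at 10⁶ df) when the observed spread of log s² is below
  its sampling floor.

## Problem sizes

Default analyses run on desk-scale instances: 200 regions / ~450 guides /
12 samples for the screen, ~1900 TUs for enhancer calling, 600 genes × 22
samples for expression, 400 proteins, 540 cohort samples × 158 genes. The
full pipeline completes in a few seconds; the 50-replicate null
calibration in under half a minute.

## Known limitations

- The TEAD4 motif model is an exact IUPAC consensus (`GGAATG`); a PWM
  with a score cutoff can be substituted where a trained model is
  available. The original motif model was not published.
- MAGeCK is represented only by its control-guide normalization plus LFC;
  the RRA ranking test is not part of the published hit rule (top-2
  depleted average) and is not implemented.
- Off-target search and guide-efficiency scoring are out of scope; the
  NT-control admissibility check (no exact 20-mer match) is adequate only
  for small synthetic genomes.
- Reproducing the published Fisher p-values exactly requires the
  published supplementary tables and their universe convention; the
  universe behind the printed values is not stated in the source, so this
  package defines it explicitly (proteins present in both tables).
- Whether amplicon mutation frequencies count reads or alleles is not
  specified in the source; reads are counted.
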