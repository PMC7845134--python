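"""Bidirectional element calling, motif scanning, eRNA differential."""

import numpy as np
import pandas as pd
import pytest

from enhscreen.annotation import (call_bidirectional_elements,
                                  erna_differential,
                                  filter_and_normalize_tus, scan_motifs, tss)
from enhscreen.core import GenomicInterval, reverse_complement
from enhscreen.simulate import SimulationConfig, make_reference, simulate_groseq


def _tu_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "count_s1", "count_s2"])


class TestFilterNormalize:
    def test_min_reads_filter(self):
        tus = _tu_frame([
            ("chr1", 0, 100, "+", 5, 10),      # below 20 everywhere: dropped
            ("chr1", 200, 300, "+", 5, 25),    # 25 in one sample: kept
            ("chr1", 400, 500, "-", 100, 50),
        ])
        out = filter_and_normalize_tus(tus, min_reads=20)
        assert list(out["start"]) == [200, 400]

    def test_identical_columns_preserved(self):
        tus = _tu_frame([("chr1", 0, 100, "+", 30, 30),
                         ("chr1", 200, 300, "-", 60, 60)])
        out = filter_and_normalize_tus(tus)
        np.testing.assert_allclose(out["norm_s1"], [30, 60])
        np.testing.assert_allclose(out["norm_s2"], [30, 60])

    def test_single_sample_rejected(self):
        tus = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                            "strand": ["+"], "count_only": [30]})
        with pytest.raises(ValueError):
            filter_and_normalize_tus(tus)


def _greedy_oracle(tus, max_gap):
    """Independent greedy matcher: repeatedly take the globally smallest
    admissible gap among unused TUs (same tie-breaks)."""
    avail = set(tus.index)
    pairs = []
    while True:
        best = None
        for pi in sorted(avail, key=str):
            if tus.loc[pi, "strand"] != "+":
                continue
            for mi in sorted(avail, key=str):
                if tus.loc[mi, "strand"] != "-":
                    continue
                if tus.loc[pi, "chrom"] != tus.loc[mi, "chrom"]:
                    continue
                gap = abs(tss(tus.loc[pi]) - tss(tus.loc[mi]))
                if gap > max_gap:
                    continue
                key = (gap, min(tss(tus.loc[pi]), tss(tus.loc[mi])),
                       str(pi), str(mi))
                if best is None or key < best[0]:
                    best = (key, pi, mi)
        if best is None:
            return pairs
        _, pi, mi = best
        avail -= {pi, mi}
        pairs.append((pi, mi))


class TestBidirectionalPairing:
    def test_gap_800_paired_801_not(self):
        # TSS+ at 1000 (start), TSS- at 1800 (end of the minus TU)
        paired = _tu_frame([("chr1", 1000, 2000, "+", 30, 30),
                            ("chr1", 800, 1800, "-", 30, 30)])
        assert len(call_bidirectional_elements(paired, 800)) == 1
        beyond = _tu_frame([("chr1", 1000, 2000, "+", 30, 30),
                            ("chr1", 801, 1801, "-", 30, 30)])  # gap 801
        assert len(call_bidirectional_elements(beyond, 800)) == 0

    def test_matching_is_injective_and_opposite_strand(self, rng):
        tus = _tu_frame([
            ("chr1", int(p), int(p) + 500, "+" if rng.random() < 0.5 else "-",
             30, 30)
            for p in rng.integers(0, 5000, size=12)
        ])
        el = call_bidirectional_elements(tus, 800)
        used = list(el["plus_tu"]) + list(el["minus_tu"])
        assert len(used) == len(set(used))
        for _, r in el.iterrows():
            assert tus.loc[r["plus_tu"], "strand"] == "+"
            assert tus.loc[r["minus_tu"], "strand"] == "-"
            assert r["gap"] <= 800

    def test_matches_independent_greedy_oracle(self, rng):
        for _ in range(10):
            tus = _tu_frame([
                ("chr1", int(p), int(p) + 300,
                 "+" if rng.random() < 0.5 else "-", 30, 30)
                for p in rng.integers(0, 4000, size=10)
            ])
            got = call_bidirectional_elements(tus, 800)
            expected = _greedy_oracle(tus, 800)
            assert list(zip(got["plus_tu"], got["minus_tu"])) == expected

    def test_shift_invariance(self):
        tus = _tu_frame([("chr1", 1000, 2000, "+", 30, 30),
                         ("chr1", 700, 1700, "-", 30, 30),
                         ("chr1", 4000, 5000, "+", 30, 30)])
        base = call_bidirectional_elements(tus, 800)
        shifted = tus.copy()
        shifted[["start", "end"]] += 12345
        out = call_bidirectional_elements(shifted, 800)
        assert list(out["anchor_start"]) == [a + 12345
                                             for a in base["anchor_start"]]
        assert list(out["plus_tu"]) == list(base["plus_tu"])

    def test_invalid_strand_rejected(self):
        tus = _tu_frame([("chr1", 0, 10, ".", 30, 30)])
        with pytest.raises(ValueError):
            call_bidirectional_elements(tus)


def _naive_motif_scan(seq, consensus):
    """Sliding-window oracle on both strands (exact ACGT consensus)."""
    hits = set()
    rc = reverse_complement(consensus)
    for i in range(len(seq) - len(consensus) + 1):
        w = seq[i:i + len(consensus)]
        if w == consensus:
            hits.add((i, "+"))
        if w == rc:
            hits.add((i, "-"))
    return hits


class TestScanMotifs:
    def test_forward_site(self):
        genome = {"chr1": "TTGGAATGTT"}
        sites = scan_motifs(genome, [GenomicInterval("chr1", 0, 10)], "GGAATG")
        assert len(sites) == 1
        s = sites[0]
        assert (s.interval.start, s.interval.end, s.interval.strand) == (2, 8, "+")
        assert s.matched_sequence == "GGAATG"

    def test_reverse_site(self):
        genome = {"chr1": "AACATTCCAA"}
        sites = scan_motifs(genome, [GenomicInterval("chr1", 0, 10)], "GGAATG")
        assert len(sites) == 1
        assert sites[0].interval.strand == "-"
        assert sites[0].matched_sequence == "GGAATG"

    def test_matches_naive_scan(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        # plant a few sites so the test is not vacuous
        seq = seq[:100] + "GGAATG" + seq[106:500] + "CATTCC" + seq[506:]
        genome = {"chr1": seq}
        sites = scan_motifs(genome, [GenomicInterval("chr1", 0, len(seq))],
                            "GGAATG")
        got = {(s.interval.start, s.interval.strand) for s in sites}
        assert got == _naive_motif_scan(seq, "GGAATG")
        assert len(got) >= 2

    def test_strand_duality(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        n = len(seq)
        fwd = scan_motifs({"c": seq}, [GenomicInterval("c", 0, n)], "GGAATG")
        rev = scan_motifs({"c": reverse_complement(seq)},
                          [GenomicInterval("c", 0, n)], "GGAATG")
        mirrored = {(n - s.interval.end, {"+": "-", "-": "+"}[s.interval.strand])
                    for s in rev}
        assert {(s.interval.start, s.interval.strand) for s in fwd} == mirrored

    def test_region_beyond_chromosome_raises(self):
        with pytest.raises(ValueError):
            scan_motifs({"chr1": "ACGT"}, [GenomicInterval("chr1", 0, 10)],
                        "GG")

    def test_n_in_genome_never_matches(self):
        sites = scan_motifs({"chr1": "TTGGAATNTT"},
                            [GenomicInterval("chr1", 0, 10)], "GGAATG")
        assert sites == []


class TestErnaDifferential:
    def _elements(self, levels):
        tus = _tu_frame([("chr1", 1000, 2000, "+", 30, 30),
                         ("chr1", 700, 1700, "-", 30, 30)])
        tus["norm_s1"], tus["norm_s2"] = levels
        el = call_bidirectional_elements(tus, 800)
        return erna_differential(el, tus, {"high": "s1", "low": "s2"},
                                 "high", "low", min_log2fc=1.0)

    def test_equal_levels_not_flagged(self):
        el = self._elements(([4.0, 4.0], [4.0, 4.0]))
        assert el["erna_log2fc"].iloc[0] == pytest.approx(0.0)
        assert not el["erna_flag"].iloc[0]

    def test_pseudocount_arithmetic(self):
        # element levels high = 31, low = 7 -> log2(32/8) = 2
        el = self._elements(([16.0, 15.0], [3.0, 4.0]))
        assert el["erna_log2fc"].iloc[0] == pytest.approx(2.0)
        assert bool(el["erna_flag"].iloc[0])

    def test_missing_condition_raises(self):
        with pytest.raises(ValueError):
            tus = _tu_frame([("chr1", 1000, 2000, "+", 30, 30),
                             ("chr1", 700, 1700, "-", 30, 30)])
            tus["norm_s1"] = 1.0
            el = call_bidirectional_elements(tus, 800)
            erna_differential(el, tus, {"high": "s1"}, "high", "low")

    def test_true_elements_flagged_in_simulation(self):
        """Planted 4-fold elements pass the log2FC >= 1 filter in >= 95%
        of cases (Monte-Carlo across seeds under the synthetic model)."""
        flagged = total = 0
        for seed in (11, 12, 13):
            sim = SimulationConfig(seed=seed, n_regions=100,
                                   frac_true_hits=0.3)
            ref, truth = make_reference(sim)
            tus = simulate_groseq(ref.regions, truth, sim)
            ntus = filter_and_normalize_tus(tus)
            el = call_bidirectional_elements(ntus)
            el = erna_differential(el, ntus, {"high": "high", "low": "low"},
                                   "high", "low")
            rid = pd.Series(
                [ntus.loc[r["plus_tu"], "region_id"] for _, r in el.iterrows()],
                index=el.index)
            truly_active = rid.isin(truth.true_hit_region_ids)
            flagged += int(el.loc[truly_active, "erna_flag"].sum())
            total += int(truly_active.sum())
        assert total >= 80
        assert flagged / total >= 0.95
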