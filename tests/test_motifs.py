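"""PWM construction, scanning, regions, enrichment, TSS clustering,
motif→TSS linking."""

import math

import numpy as np
import pytest

from dsrna.motifs import (
    FivePrimeEnd,
    GeneModel,
    MSE_CONSENSUS,
    URS1_CONSENSUS,
    call_tss_clusters,
    consensus_to_pwm,
    extract_downstream_regions,
    extract_upstream_regions,
    link_motifs_to_tss,
    motif_enrichment,
    reverse_complement,
    scan_pwm,
    MotifHit,
    Region,
    TssCluster,
)


class TestConsensusToPwm:
    def test_single_base_column(self):
        pwm = consensus_to_pwm("A", eps=0.01)
        np.testing.assert_allclose(pwm.probs[:, 0], [0.97, 0.01, 0.01, 0.01])

    def test_n_is_uniform(self):
        pwm = consensus_to_pwm("N", eps=0.01)
        np.testing.assert_allclose(pwm.probs[:, 0], 0.25)

    def test_two_fold_degenerate_column(self):
        pwm = consensus_to_pwm("R", eps=0.01)
        np.testing.assert_allclose(pwm.probs[:, 0], [0.49, 0.01, 0.49, 0.01])

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            consensus_to_pwm("AXC")

    def test_columns_sum_to_one(self):
        for cons in (URS1_CONSENSUS, MSE_CONSENSUS, "NRYSWKMBDHV"):
            pwm = consensus_to_pwm(cons)
            np.testing.assert_allclose(pwm.probs.sum(axis=0), 1.0, atol=1e-9)


def brute_force_scan(seq, pwm):
    """Per-window log-odds sums by plain loops (uniform background)."""
    W = pwm.width
    scores = []
    for i in range(len(seq) - W + 1):
        s = 0.0
        for j, ch in enumerate(seq[i : i + W]):
            if ch == "N":
                continue  # neutral under uniform background
            s += math.log2(pwm.probs["ACGT".index(ch), j] / 0.25)
        scores.append(s)
    return scores


class TestScanPwm:
    def test_consensus_scores_fraction_one(self):
        pwm = consensus_to_pwm(URS1_CONSENSUS)
        hits = scan_pwm(URS1_CONSENSUS, pwm, min_score_fraction=0.999)
        assert len(hits) >= 1
        assert hits[0].start == 0 and hits[0].score_fraction == pytest.approx(1.0)

    def test_planted_consensus_recovered_in_random_background(self, rng):
        background = "".join(rng.choice(list("ACGT"), 500))
        seq = background[:200] + URS1_CONSENSUS + background[200:]
        pwm = consensus_to_pwm(URS1_CONSENSUS)
        hits = scan_pwm(seq, pwm, min_score_fraction=0.95, strands="both")
        assert [(h.start, h.strand) for h in hits] == [(200, "+")]

    def test_matches_brute_force_on_long_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), 2000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        pwm = consensus_to_pwm(MSE_CONSENSUS)
        oracle = brute_force_scan(seq, pwm)
        hits = scan_pwm(seq, pwm, min_score_fraction=-np.inf, strands="+")
        assert len(hits) == len(oracle)
        got = {h.start: h.score for h in hits}
        for i, s in enumerate(oracle):
            assert got[i] == pytest.approx(s, abs=1e-9)

    def test_strand_symmetry(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        pwm = consensus_to_pwm(MSE_CONSENSUS)
        fw = scan_pwm(seq, pwm, 0.8, strands="both")
        rc = scan_pwm(reverse_complement(seq), pwm, 0.8, strands="both")
        L, W = len(seq), pwm.width
        mirrored = sorted(
            (L - h.end, "+" if h.strand == "-" else "-", round(h.score, 9))
            for h in rc
        )
        assert mirrored == sorted((h.start, h.strand, round(h.score, 9)) for h in fw)

    def test_short_sequence_gives_empty(self):
        assert scan_pwm("ACG", consensus_to_pwm(URS1_CONSENSUS), 0.5) == []


class TestRegions:
    GENOME = {"chrI": "".join(
        np.random.default_rng(1).choice(list("ACGT"), 7000)
    )}

    def test_plus_gene_downstream_window(self):
        g = GeneModel("g", "chrI", 4000, 5000, "+")
        r = extract_downstream_regions([g], self.GENOME, 1000)["g"]
        assert (r.start, r.end) == (5000, 6000)
        assert r.seq == self.GENOME["chrI"][5000:6000]
        assert not r.truncated

    def test_minus_gene_downstream_is_reverse_complemented(self):
        g = GeneModel("g", "chrI", 5000, 6000, "-")
        r = extract_downstream_regions([g], self.GENOME, 1000)["g"]
        assert (r.start, r.end) == (4000, 5000)
        assert r.seq == reverse_complement(self.GENOME["chrI"][4000:5000])

    def test_upstream_regions_mirror_downstream(self):
        plus = GeneModel("p", "chrI", 4000, 5000, "+")
        minus = GeneModel("m", "chrI", 4000, 5000, "-")
        up = extract_upstream_regions([plus, minus], self.GENOME, 1000)
        assert (up["p"].start, up["p"].end) == (3000, 4000)
        assert (up["m"].start, up["m"].end) == (5000, 6000)

    def test_chromosome_edge_truncates_with_flag(self):
        g = GeneModel("g", "chrI", 6000, 6700, "+")
        r = extract_downstream_regions([g], self.GENOME, 1000)["g"]
        assert r.truncated and len(r.seq) == 300

    def test_hit_coordinates_round_trip(self):
        """Region-local hits map to genomic coordinates whose genomic
        slice re-extracts to the scanned subsequence."""
        pwm = consensus_to_pwm(URS1_CONSENSUS)
        for strand in "+-":
            g = GeneModel("g", "chrI", 3000, 4000, strand)
            region = extract_downstream_regions([g], self.GENOME, 1000)["g"]
            hits = scan_pwm(region.seq, pwm, min_score_fraction=-np.inf, strands="both")
            for hit in hits[:50]:
                gh = region.hit_to_genomic(hit)
                local = region.seq[hit.start : hit.end]
                genomic = self.GENOME["chrI"][gh.start : gh.end]
                # the motif-oriented sequence must be identical either way
                motif_local = local if hit.strand == "+" else reverse_complement(local)
                motif_genomic = genomic if gh.strand == "+" else reverse_complement(genomic)
                assert motif_local == motif_genomic


def hypergeom_tail_oracle(k, M, K, N):
    """P(X >= k) for X ~ Hypergeom(M, K, N), by exact rational enumeration."""
    total = 0
    for x in range(k, min(K, N) + 1):
        total += math.comb(K, x) * math.comb(M - K, N - x)
    return total / math.comb(M, N)


class TestEnrichment:
    @staticmethod
    def _regions(flags):
        # positive regions contain the URS1 consensus; negatives are A-runs
        out = []
        for i, pos in enumerate(flags):
            seq = ("AT" * 30 + URS1_CONSENSUS + "TA" * 30) if pos else "AT" * 40
            out.append(Region(f"r{i}", "chrI", 0, len(seq), "+", seq))
        return out

    def test_matches_exhaustive_enumeration(self):
        fg = self._regions([True] * 8 + [False] * 2)
        bg = self._regions([True] * 10 + [False] * 90)
        pwm = consensus_to_pwm(URS1_CONSENSUS)
        res = motif_enrichment(fg, bg, pwm, 0.95)
        assert (res.fg_positive, res.bg_positive) == (8, 10)
        oracle = hypergeom_tail_oracle(8, 110, 18, 10)
        assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_equal_rates_give_unit_odds(self):
        fg = self._regions([True, False])
        bg = self._regions([True, False] * 5)
        res = motif_enrichment(fg, bg, consensus_to_pwm(URS1_CONSENSUS), 0.95)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_extreme_table_haldane_and_closed_form(self):
        fg = self._regions([True] * 3)
        bg = self._regions([False] * 7)
        res = motif_enrichment(fg, bg, consensus_to_pwm(URS1_CONSENSUS), 0.95)
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1
        # all successes drawn into the foreground: p = 1 / C(10, 3)
        assert res.p_value == pytest.approx(1 / math.comb(10, 3), rel=1e-9)

    def test_published_style_urn_case(self):
        # urn with 10 successes / 90 failures, draw 10, P(X >= 4)
        from scipy.stats import hypergeom

        oracle = hypergeom_tail_oracle(4, 100, 10, 10)
        assert hypergeom.sf(3, 100, 10, 10) == pytest.approx(oracle, rel=1e-12)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            motif_enrichment([], self._regions([True]), consensus_to_pwm("ACGT"), 0.9)


class TestTssClusters:
    def test_single_pile_is_one_cluster(self):
        ends = [FivePrimeEnd("c", 100, "+", 5)]
        (c,) = call_tss_clusters(ends, min_count=3, merge_window=10)
        assert (c.position, c.read_count) == (100, 5)

    def test_nearby_positions_merge_with_modal_representative(self):
        ends = [FivePrimeEnd("c", 100, "+", 3), FivePrimeEnd("c", 104, "+", 2)]
        (c,) = call_tss_clusters(ends, min_count=3, merge_window=10)
        assert (c.position, c.read_count) == (100, 5)

    def test_distant_positions_stay_separate(self):
        ends = [FivePrimeEnd("c", 100, "+", 3), FivePrimeEnd("c", 200, "+", 3)]
        clusters = call_tss_clusters(ends, min_count=3, merge_window=10)
        assert [c.position for c in clusters] == [100, 200]

    def test_minus_strand_tie_breaks_downstream(self):
        ends = [FivePrimeEnd("c", 100, "-", 2), FivePrimeEnd("c", 105, "-", 2)]
        (c,) = call_tss_clusters(ends, min_count=3, merge_window=10)
        assert c.position == 105  # 5'-most in the - transcription direction

    def test_low_count_clusters_dropped(self):
        ends = [FivePrimeEnd("c", 100, "+", 2)]
        assert call_tss_clusters(ends, min_count=3, merge_window=10) == []


class TestLinking:
    def test_plus_gene_offset_convention(self):
        gene = GeneModel("g", "chrI", 4000, 5000, "+")
        hit = MotifHit("chrI", 5100, 5110, "-", 10.0, 1.0, "MSE")
        tss = TssCluster("chrI", 5050, "-", 20, 5048, 5052)
        rep = link_motifs_to_tss([gene], {"g": [hit]}, [tss], 100)
        assert len(rep.links) == 1 and rep.links[0].offset == 50

    def test_too_far_not_linked(self):
        gene = GeneModel("g", "chrI", 4000, 5000, "+")
        hit = MotifHit("chrI", 5100, 5110, "-", 10.0, 1.0, "MSE")
        tss = TssCluster("chrI", 4950, "-", 20, 4948, 4952)
        rep = link_motifs_to_tss([gene], {"g": [hit]}, [tss], 100)
        assert rep.links == [] and rep.n_linked_genes == 0

    def test_same_strand_tss_never_links(self):
        gene = GeneModel("g", "chrI", 4000, 5000, "+")
        hit = MotifHit("chrI", 5100, 5110, "-", 10.0, 1.0, "MSE")
        tss = TssCluster("chrI", 5050, "+", 20, 5048, 5052)
        rep = link_motifs_to_tss([gene], {"g": [hit]}, [tss], 100)
        assert rep.links == []

    def test_minus_gene_offset_convention(self):
        gene = GeneModel("g", "chrI", 4000, 5000, "-")
        hit = MotifHit("chrI", 3500, 3510, "+", 10.0, 1.0, "MSE")
        tss = TssCluster("chrI", 3559, "+", 20, 3557, 3561)
        rep = link_motifs_to_tss([gene], {"g": [hit]}, [tss], 100)
        assert len(rep.links) == 1 and rep.links[0].offset == 50
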