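"""Generator contracts: forced values, moments, truth completeness,
determinism."""

import numpy as np
import pytest

from dsrna import dataio
from dsrna.motifs import consensus_to_pwm, scan_pwm
from dsrna.synthetic import (
    SimulationConfig,
    _nb_draw,
    simulate_motif_tss_loci,
    simulate_pulse_tracks,
    simulate_reactivity_series,
    simulate_stranded_counts,
    write_locus_files,
)


class TestConfigValidation:
    def test_intermolecular_without_suppression_rejected(self):
        with pytest.raises(ValueError, match="suppression_fraction"):
            SimulationConfig(fraction_dsrna_targets=0.1, suppression_fraction=0.0)

    def test_induced_level_below_background_rejected(self):
        with pytest.raises(ValueError, match="induced_ratio_level"):
            SimulationConfig(induced_ratio_level=0.1, antisense_background=0.15)

    def test_region_too_short_for_motif_plus_offset_rejected(self):
        with pytest.raises(ValueError, match="region_length"):
            SimulationConfig(region_length=100, tss_offset_max=100)


class TestReactivitySeries:
    def test_zero_noise_stable_class_is_constant_across_stages(self):
        cfg = SimulationConfig(
            n_transcripts=3, transcript_length=40, noise_sd=0.0, missing_rate=0.0,
            fraction_dsrna_targets=0.0, fraction_intramolecular=0.0, seed=1,
        )
        profiles, _ = simulate_reactivity_series(cfg)
        ref = profiles[("tx0000", "V")].reactivity
        for s in cfg.stages:
            np.testing.assert_array_equal(profiles[("tx0000", s)].reactivity, ref)

    def test_intermolecular_suppression_is_exact(self):
        cfg = SimulationConfig(
            n_transcripts=2, transcript_length=40, noise_sd=0.0, missing_rate=0.0,
            fraction_dsrna_targets=1.0, fraction_intramolecular=0.0,
            suppression_fraction=0.6, suppression_window=("T1", "T4"), seed=1,
        )
        profiles, _ = simulate_reactivity_series(cfg)
        v = profiles[("tx0000", "V")].reactivity
        t4 = profiles[("tx0000", "T4")].reactivity
        np.testing.assert_allclose(t4, 0.4 * v, rtol=0, atol=1e-15)

    def test_intramolecular_shift_is_balanced(self):
        cfg = SimulationConfig(
            n_transcripts=3, transcript_length=60, noise_sd=0.0, missing_rate=0.0,
            fraction_dsrna_targets=0.0, fraction_intramolecular=1.0, seed=5,
        )
        profiles, _ = simulate_reactivity_series(cfg)
        for i in range(3):
            tid = f"tx{i:04d}"
            delta = (
                profiles[(tid, "V")].reactivity - profiles[(tid, "T2")].reactivity
            )
            assert np.median(delta) == pytest.approx(0.0, abs=1e-15)
            assert np.abs(delta).max() > 0  # but positions did move

    def test_ac_restricted_baseline_median_is_exact(self):
        cfg = SimulationConfig(
            n_transcripts=4, transcript_length=100, noise_sd=0.0,
            missing_rate=0.0, seed=3, baseline_median=0.5,
        )
        profiles, _ = simulate_reactivity_series(cfg)
        p = profiles[("tx0001", "V")]
        ac = np.isin(p.base, ("A", "C"))
        assert np.median(p.reactivity[ac]) == pytest.approx(0.5, abs=1e-12)

    def test_truth_has_exact_quota_and_one_row_per_transcript(self):
        cfg = SimulationConfig(
            n_transcripts=50, transcript_length=30,
            fraction_dsrna_targets=0.08, fraction_intramolecular=0.10, seed=8,
        )
        _, truth = simulate_reactivity_series(cfg)
        assert len(truth) == 50 and truth.transcript_id.is_unique
        counts = truth.remodeling_class.value_counts()
        assert counts["intermolecular"] == 4 and counts["intramolecular"] == 5


class TestStrandedCounts:
    def test_background_only_ratio_is_flat(self):
        cfg = SimulationConfig(
            n_genes=30, fraction_nat_genes=0.0, fraction_early_antisense=0.0,
            pulse_genes_fraction=0.0, dispersion=0.0, mean_depth=200000,
            depth_log_sd=0.0, seed=2,
        )
        counts, _ = simulate_stranded_counts(cfg)
        ratio = counts.antisense / (counts.sense + counts.antisense)
        np.testing.assert_allclose(ratio, 0.15, atol=0.01)

    def test_activation_switches_ratio_level(self):
        cfg = SimulationConfig(
            n_genes=10, fraction_nat_genes=1.0, fraction_early_antisense=0.0,
            pulse_genes_fraction=0.0, dispersion=0.0, mean_depth=200000,
            depth_log_sd=0.0, induced_ratio_level=0.5,
            activation_interval_mass={("P", "T0"): 1.0}, seed=2,
        )
        counts, truth = simulate_stranded_counts(cfg)
        assert (truth.interval == "P->T0").all()
        ratio = counts.antisense / (counts.sense + counts.antisense)
        iV, iP, iT0 = (cfg.stages.rank(s) for s in ("V", "P", "T0"))
        np.testing.assert_allclose(ratio[:, [iV, iP]], 0.15, atol=0.01)
        np.testing.assert_allclose(ratio[:, iT0:], 0.5, atol=0.01)

    def test_nb_draw_moments(self, rng):
        mu, disp, n = 40.0, 0.3, 10000
        draws = _nb_draw(rng, np.full(n, mu), disp)
        var = mu + disp * mu * mu
        se_mean = np.sqrt(var / n)
        # SE of the sample variance via the fourth-moment normal approx
        se_var = np.sqrt(2.0 / (n - 1)) * var * 2  # generous bound
        assert abs(draws.mean() - mu) < 3 * se_mean
        assert abs(draws.var(ddof=1) - var) < 3 * se_var

    def test_strand_split_preserves_total_and_quota(self):
        cfg = SimulationConfig(n_genes=40, seed=6)
        counts, truth = simulate_stranded_counts(cfg)
        assert len(truth) == 40 and truth.gene_id.is_unique
        assert truth.nat_active.sum() == round(0.30 * 40)
        assert truth.pulsed.sum() == round(0.10 * 40)
        assert (truth.pulsed <= truth.nat_active).all()


class TestPulseTracks:
    def test_quota_and_peak_inside_window(self):
        cfg = SimulationConfig(n_pulse_tracks=40, seed=4)
        tracks, ids, truth = simulate_pulse_tracks(cfg)
        assert tracks.shape == (40, 9)
        assert truth.pulsed.sum() == 12  # 30% quota
        assert set(truth.loc[truth.pulsed, "peak_stage"]) <= {"P", "T0", "T1"}


class TestMotifTssLoci:
    def test_noise_free_geometry(self):
        cfg = SimulationConfig(
            n_loci=6, tss_jitter_sd=0.0, artifact_end_fraction=0.0,
            fraction_active_loci=1.0, fraction_convergent=0.0, seed=7,
        )
        sim = simulate_motif_tss_loci(cfg)
        truth = sim.truth.set_index("gene_id")
        positions = {}
        for e in sim.ends:
            positions.setdefault((e.position, e.strand), 0)
            positions[(e.position, e.strand)] += e.count
        for gid, row in truth.iterrows():
            # every read 5' end sits exactly on the true TSS
            assert (row.tss_pos, row.tss_strand) in positions
            assert positions[(row.tss_pos, row.tss_strand)] == cfg.reads_per_tss
            # TSS is downstream of the motif in the antisense direction
            if row.strand == "+":
                assert row.tss_strand == "-"
                assert 0 <= row.motif_start - row.tss_pos <= 100
            else:
                assert row.tss_strand == "+"
                assert 0 <= row.tss_pos - row.motif_end + 1 <= 100
            assert row.offset <= 100

    def test_planted_motifs_are_the_only_max_score_matches(self):
        cfg = SimulationConfig(n_loci=8, fraction_active_loci=1.0, seed=9)
        sim = simulate_motif_tss_loci(cfg)
        genome = sim.genome["chrI"]
        truth = sim.truth.set_index("gene_id")
        for name, consensus in (("URS1", "TCGGCGGCTA"), ("MSE", "GNCRCAAAW")):
            pwm = consensus_to_pwm(consensus)
            hits = scan_pwm(genome, pwm, min_score_fraction=1.0 - 1e-9,
                            strands="both", chrom="chrI")
            found = {(h.start, h.end) for h in hits}
            planted = {
                (int(r.motif_start), int(r.motif_end))
                for _, r in truth[truth.motif_id == name].iterrows()
            }
            assert planted <= found
            # scrubbing leaves no background match of either motif class
            extras = found - planted - {
                (int(r.urs1_up_start), int(r.urs1_up_end))
                for _, r in truth[truth.convergent].iterrows()
            }
            assert extras == set()

    def test_truth_covers_every_locus_once(self):
        cfg = SimulationConfig(n_loci=12, seed=3)
        sim = simulate_motif_tss_loci(cfg)
        assert len(sim.truth) == 12 and sim.truth.gene_id.is_unique
        assert len(sim.genes) == 12


def test_emitted_files_are_deterministic(tmp_path):
    cfg = SimulationConfig(n_transcripts=5, transcript_length=30,
                           n_genes=10, n_loci=5, seed=42)
    for d in ("a", "b"):
        out = tmp_path / d
        profiles, rtruth = simulate_reactivity_series(cfg)
        dataio.write_reactivity_table(profiles, out.mkdir() or out / "r.tsv")
        counts, _ = simulate_stranded_counts(cfg)
        dataio.write_stranded_counts(counts, out / "c.tsv")
        write_locus_files(simulate_motif_tss_loci(cfg), out)
    for name in ("r.tsv", "c.tsv", "genome.fasta", "genes.bed",
                 "five_prime_ends.bed", "locus_truth.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
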