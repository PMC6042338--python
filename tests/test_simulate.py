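"""Synthetic-data generator: determinism, planted truth, emitted formats."""

import numpy as np
import pytest

from pausefold import mfe_fold
from pausefold.fold import fold_windows
from pausefold.params import revcomp
from pausefold.pause_sites import coverage_histogram, fit_powerlaw_null
from pausefold.simulate import (SimulationConfig, make_genome, read_manifest,
                                simulate, write_manifest)


class TestMakeGenome:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=5, chrom_length=50_000, n_genes=4)
        g1, _ = make_genome(cfg)
        g2, _ = make_genome(cfg)
        assert g1 == g2

    def test_gc_content_matches_target(self):
        cfg = SimulationConfig(seed=5, chrom_length=200_000, n_genes=4,
                               background_gc=0.5)
        genome, _ = make_genome(cfg)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        se = np.sqrt(0.25 / len(seq))
        assert abs(gc - 0.5) <= 3 * se

    def test_gaps_contain_only_n(self):
        cfg = SimulationConfig(seed=5, chrom_length=100_000, n_genes=2,
                               n_gaps=2, gap_length=1000)
        genome, gaps = make_genome(cfg)
        for s, e in gaps["chr1"]:
            assert set(genome["chr1"][s:e]) == {"N"}


class TestSimulatedTruth:
    def test_state_fractions_exact_by_construction(self, sim_small):
        cfg = sim_small.config
        states = sim_small.manifest["state"]
        assert (states == "PAU").sum() == round(len(states) * cfg.paused_fraction)
        assert (states == "NP2").sum() == round(len(states) * cfg.no_polii_fraction)

    def test_manifest_round_trips(self, sim_small, tmp_path):
        p = tmp_path / "manifest.tsv"
        write_manifest(sim_small.manifest, p)
        back = read_manifest(p)
        assert back.shape == sim_small.manifest.shape
        assert (back["state"] == sim_small.manifest["state"]).all()
        assert (back["pause_pos"] == sim_small.manifest["pause_pos"]).all()

    def test_planted_hairpin_far_below_background(self, sim_small):
        """The MFE of each planted element must undercut the 1st percentile
        of background 30-nt windows."""
        genome = sim_small.genome
        rng = np.random.default_rng(0)
        bg = []
        for _ in range(300):
            s = int(rng.integers(0, len(genome["chr1"]) - 30))
            seq = genome["chr1"][s:s + 30]
            if "N" not in seq:
                bg.append(mfe_fold(seq).delta_g)
        background_p1 = np.percentile(bg, 1)
        pau = sim_small.manifest[sim_small.manifest["state"] == "PAU"]
        for row in pau.itertuples():
            region = genome[row.chrom][int(row.hairpin_start):
                                       int(row.hairpin_end)]
            if row.strand == "-":
                region = revcomp(region)
            assert mfe_fold(region).delta_g < background_p1

    def test_minus_strand_hairpin_reverse_complemented(self, sim_small):
        """The non-template-strand element of a minus-strand gene reads as a
        foldable hairpin only after reverse-complementing the reference."""
        pau = sim_small.manifest.query("state == 'PAU' and strand == '-'")
        assert len(pau) > 0
        row = pau.iloc[0]
        ref = sim_small.genome[row.chrom][int(row.hairpin_start):
                                          int(row.hairpin_end)]
        assert mfe_fold(revcomp(ref)).delta_g < -5

    def test_npa_promoters_lack_planted_structure(self, sim_small):
        """Non-paused promoters carry no planted element: their best TSS
        window energy stays in the background range."""
        genome = sim_small.genome
        npa = sim_small.manifest.query("state == 'NPA'").head(3)
        pau = sim_small.manifest.query("state == 'PAU'").head(3)

        def best_dg(row):
            lo = min(row.tss, row.pause_pos if row.pause_pos >= 0 else row.tss)
            sign = 1 if row.strand == "+" else -1
            s, e = sorted((row.tss - sign * 60, row.tss + sign * 120))
            return np.nanmin(fold_windows(genome[row.chrom][s:e]))

        worst_pau = max(best_dg(r) for r in pau.itertuples())
        best_npa = min(best_dg(r) for r in npa.itertuples())
        assert worst_pau < best_npa

    def test_mnet_argmax_is_planted_pause(self, sim_small):
        pau = sim_small.manifest.query("state == 'PAU'")
        for row in pau.itertuples():
            arr = sim_small.mnet.array(row.chrom, row.strand)
            lo, hi = sorted((row.tss, int(row.pause_pos)))
            window = arr[lo - 50:hi + 51]
            assert (lo - 50) + int(np.argmax(window)) == row.pause_pos

    def test_traveling_ratio_separates_planted_states(self, sim_small):
        from pausefold import traveling_ratio
        states = sim_small.manifest.set_index("gene_id")["state"]
        for g in sim_small.genes:
            st = states[g.gene_id]
            if st == "NP2":
                continue
            rec = traveling_ratio(g, sim_small.chip)
            if st == "PAU":
                assert rec.tr > 2
            else:
                assert rec.tr <= 2

    def test_noise_histogram_recovers_generating_exponent(self):
        """Pooled mNET noise away from genes refits the generating power law
        within a loose tolerance (finite-sample log-log fit)."""
        data = simulate(SimulationConfig(seed=3, n_genes=10,
                                         chrom_length=400_000))
        occupied = np.zeros(400_000, bool)
        for g in data.genes:
            occupied[max(g.tx_start - 3000, 0):g.tx_end + 3000] = True
        vals = []
        for strand in "+-":
            arr = data.mnet.array("chr1", strand)
            vals.append(arr[~occupied])
        vals = np.concatenate(vals)
        null = fit_powerlaw_null(coverage_histogram(vals[vals > 0]))
        assert null.b == pytest.approx(data.config.noise_b, abs=0.4)

    def test_emitted_files_parse(self, sim_small, tmp_path):
        from pausefold.coverage import read_bed, read_bedgraph, read_narrowpeak
        from pausefold.genome import read_fasta, read_genes_bed
        sim_small.write_all(tmp_path)
        genome = read_fasta(tmp_path / "genome.fa")
        assert genome.keys() == sim_small.genome.keys()
        assert genome["chr1"] == sim_small.genome["chr1"]
        genes = read_genes_bed(tmp_path / "genes.bed")
        assert len(genes) == len(sim_small.genes)
        chip = read_narrowpeak(tmp_path / "chip_peaks.narrowPeak")
        assert len(chip) == len(sim_small.chip_peaks)
        gro = read_bed(tmp_path / "gro_peaks.bed")
        assert len(gro) == len(sim_small.gro_peaks)
        sizes = sim_small.chrom_sizes
        mnet = read_bedgraph(tmp_path / "mnet_plus.bedgraph", sizes,
                             tmp_path / "mnet_minus.bedgraph")
        assert np.allclose(mnet.array("chr1", "+"),
                           sim_small.mnet.array("chr1", "+"))
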