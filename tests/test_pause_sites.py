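"""Pause-site calling: overlap filter, power-law null, FDR, ranking, spikes."""

import numpy as np
import pandas as pd
import pytest

from pausefold import (CoverageTrack, GeneModel, classify_genic,
                       fit_powerlaw_null, mnet_fdr_filter, overlap_filter,
                       rank_loci, strongest_spike)
from pausefold.pause_sites import coverage_histogram

A_TRUE, B_TRUE = 0.965, 2.443


def peaks(rows, cols=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=list(cols))


class TestOverlapFilter:
    CHIP = peaks([("chr1", 1000, 2000)])

    def test_majority_overlap_retained(self):
        gro = peaks([("chr1", 1949, 2049)])  # 51 of 100 nt inside
        assert len(overlap_filter(gro, self.CHIP)) == 1

    def test_exactly_half_dropped(self):
        gro = peaks([("chr1", 1950, 2050)])  # exactly 50 nt
        assert len(overlap_filter(gro, self.CHIP)) == 0

    def test_no_chip_peaks_empty(self):
        gro = peaks([("chr1", 1000, 1100)])
        assert len(overlap_filter(gro, peaks([]))) == 0

    def test_single_best_peak_decides(self):
        # two chip peaks each covering 30 nt of a 100-nt GRO peak: no
        # single peak exceeds half, so the candidate is dropped
        chip = peaks([("chr1", 1000, 1030), ("chr1", 1070, 1100)])
        gro = peaks([("chr1", 1000, 1100)])
        assert len(overlap_filter(gro, chip)) == 0


class TestPowerLawFit:
    def test_exact_recovery_from_tabulated_density(self):
        """Fitting the tabulated noise density a*x^-b over coverage 3..100
        returns the generating parameters to better than 4 decimals."""
        freq = np.zeros(101)
        x = np.arange(3, 101)
        freq[x] = A_TRUE * x ** (-B_TRUE)
        null = fit_powerlaw_null(freq)
        assert null.a == pytest.approx(A_TRUE, abs=1e-10)
        assert null.b == pytest.approx(B_TRUE, abs=1e-10)

    def test_flat_frequencies_give_zero_exponent(self):
        freq = np.zeros(101)
        freq[3:101] = 7.0
        null = fit_powerlaw_null(freq)
        assert null.b == pytest.approx(0.0, abs=1e-12)

    def test_large_sample_within_three_standard_errors(self, rng):
        x = np.arange(3, 101)
        pmf = x ** (-B_TRUE)
        pmf /= pmf.sum()
        draws = rng.choice(x, p=pmf, size=1_000_000)
        null = fit_powerlaw_null(coverage_histogram(draws), normalize=True)
        assert abs(null.b - B_TRUE) <= 3 * null.b_err + 0.02

    def test_degenerate_histogram_rejected(self):
        freq = np.zeros(101)
        freq[5] = 100
        with pytest.raises(ValueError):
            fit_powerlaw_null(freq)

    def test_survival_is_monotone_and_bounded(self):
        null = fit_powerlaw_null(
            np.concatenate(([0, 0, 0], A_TRUE * np.arange(3, 101.) ** -B_TRUE)))
        ps = [null.survival(c) for c in range(0, 200, 5)]
        assert ps[0] == 1.0
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[-1] > 0

    def test_tail_sum_vs_integral_agree_roughly(self):
        null = fit_powerlaw_null(
            np.concatenate(([0, 0, 0], A_TRUE * np.arange(3, 101.) ** -B_TRUE)))
        for c in (10, 50, 120):
            assert null.survival(c) == pytest.approx(
                null.survival(c, method="integral"), rel=0.5)


class TestFdrFilter:
    def _null(self):
        freq = np.zeros(101)
        x = np.arange(3, 101)
        freq[x] = A_TRUE * x ** (-B_TRUE)
        return fit_powerlaw_null(freq)

    def test_extreme_signal_retained_among_null(self, rng):
        x = np.arange(3, 101)
        pmf = x ** -B_TRUE
        pmf /= pmf.sum()
        cov = list(rng.choice(x, p=pmf, size=100)) + [5000]
        loci = pd.DataFrame({"chrom": "chr1", "start": range(101),
                             "end": range(1, 102), "mnet_cov": cov})
        kept = mnet_fdr_filter(loci, self._null())
        assert 5000 in kept["mnet_cov"].values

    def test_zero_coverage_never_retained(self):
        loci = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [1],
                             "mnet_cov": [0]})
        assert len(mnet_fdr_filter(loci, self._null())) == 0

    def test_null_draws_retained_at_most_at_fdr_level(self, rng):
        """Pure-null loci pass the 5% BH filter at no more than the nominal
        rate plus binomial error, across seeds."""
        null = self._null()
        x = np.arange(3, 101)
        pmf = x ** -B_TRUE
        pmf /= pmf.sum()
        n = 2000
        rates = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            cov = r.choice(x, p=pmf, size=n)
            loci = pd.DataFrame({"chrom": "chr1", "start": range(n),
                                 "end": range(1, n + 1), "mnet_cov": cov})
            rates.append(len(mnet_fdr_filter(loci, null)) / n)
        se = np.sqrt(0.05 * 0.95 / (n * len(rates)))
        assert np.mean(rates) <= 0.05 + 3 * se


class TestRankLoci:
    def _loci(self, n):
        return pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(n) * 1000,
                             "end": np.arange(n) * 1000 + 100})

    def test_consistent_ranks_preserved(self):
        loci = self._loci(3)
        signals = {a: np.array([30.0, 20.0, 10.0])
                   for a in ("chip", "gro", "net", "mnet")}
        out = rank_loci(loci, signals)
        assert list(out["sum_rank"]) == [4.0, 8.0, 12.0]
        assert list(out["final_rank"]) == [1, 2, 3]
        assert list(out["start"]) == [0, 1000, 2000]

    def test_monotone_transform_invariance(self, rng):
        loci = self._loci(20)
        signals = {a: rng.uniform(1, 100, 20)
                   for a in ("chip", "gro", "net", "mnet")}
        base = rank_loci(loci, signals)
        warped = dict(signals)
        warped["gro"] = np.log1p(signals["gro"]) ** 3
        again = rank_loci(loci, warped)
        assert list(base["start"]) == list(again["start"])

    def test_all_ties_use_average_ranks_and_positional_break(self):
        loci = self._loci(4)
        signals = {a: np.full(4, 5.0) for a in ("chip", "gro", "net", "mnet")}
        out = rank_loci(loci, signals)
        assert (out["chip_rank"] == 2.5).all()
        assert list(out["start"]) == [0, 1000, 2000, 3000]
        assert sorted(out["final_rank"]) == [1, 2, 3, 4]

    def test_missing_track_rejected(self):
        with pytest.raises(ValueError):
            rank_loci(self._loci(3), {"chip": np.ones(3)})


class TestStrongestSpike:
    def _track(self, positions, heights, strand="+"):
        t = CoverageTrack({"chr1": 1000}, stranded=True)
        for p, h in zip(positions, heights):
            t.array("chr1", strand)[p] = h
        return t

    def test_single_position(self):
        t = self._track([500], [9])
        spike, second, dist = strongest_spike("chr1", 400, 600, "+", t)
        assert spike == 500 and second is None and dist is None

    def test_tie_goes_five_prime(self):
        t = self._track([450, 470], [7, 7])
        spike, second, _ = strongest_spike("chr1", 400, 600, "+", t)
        assert spike == 450 and second == 470
        t2 = self._track([450, 470], [7, 7], "-")
        spike, second, _ = strongest_spike("chr1", 400, 600, "-", t2)
        assert spike == 470 and second == 450

    def test_second_spike_distance(self):
        t = self._track([500, 520], [9, 4])
        spike, second, dist = strongest_spike("chr1", 400, 600, "+", t)
        assert (spike, second, dist) == (500, 520, 20)

    def test_all_zero_flagged(self):
        t = CoverageTrack({"chr1": 1000}, stranded=True)
        assert strongest_spike("chr1", 0, 100, "+", t) == (None, None, None)


class TestClassifyGenic:
    GENES = [GeneModel("g", "chr1", "+", 10_000, 14_000)]

    def test_locus_inside_gene(self):
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [10_050],
                             "end": [10_150], "spike_pos": [10_100]})
        out = classify_genic(loci, self.GENES)
        assert out["genic_class"].iloc[0] == "intragenic"
        assert out["dist_tss"].iloc[0] == 100

    def test_minus_strand_signed_distance(self):
        genes = [GeneModel("g", "chr1", "-", 10_000, 14_000)]  # TSS 13_999
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [13_850],
                             "end": [13_950], "spike_pos": [13_899]})
        out = classify_genic(loci, genes)
        assert out["genic_class"].iloc[0] == "intragenic"
        assert out["dist_tss"].iloc[0] == 100  # downstream in transcription

    def test_empty_chromosome_intergenic(self):
        loci = pd.DataFrame({"chrom": ["chr9"], "start": [100],
                             "end": [200], "spike_pos": [150]})
        out = classify_genic(loci, self.GENES)
        assert out["genic_class"].iloc[0] == "intergenic"
        assert np.isinf(out["dist_tss"].iloc[0])
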