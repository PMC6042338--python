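"""Folding engine: energy model, dynamic program, oracle agreement, G4s."""

import numpy as np
import pytest

from pausefold import (FoldParams, enumerate_structures_oracle, g4_scan,
                       mfe_fold, score_structure)
from pausefold.fold import fold_windows
from pausefold.params import get_model

from conftest import random_dna


class TestMfeFold:
    def test_unfoldable_sequence_is_unpaired_at_zero(self):
        res = mfe_fold("A" * 30)
        assert res.delta_g == 0.0
        assert res.structure == "." * 30
        assert res.seq_length == 30

    def test_simple_hairpin_matches_hand_summed_energy(self):
        """GCGCTTTTGCGC folds into a 4-bp stem with a TTTT loop: three G/C
        stack terms plus the hairpin-loop(4) penalty, summed by hand from
        the same parameter table."""
        res = mfe_fold("GCGCTTTTGCGC")
        m = get_model(FoldParams())
        hand = (m.stack_energy("G", "C") + m.stack_energy("C", "G")
                + m.stack_energy("G", "C") + m.hairpin_energy(4)) / 100
        assert res.delta_g == pytest.approx(hand)
        assert res.structure == "((((....))))"

    def test_matches_enumeration_on_random_sequences(self, rng):
        for _ in range(120):
            seq = random_dna(rng, int(rng.integers(5, 15)))
            dp = mfe_fold(seq).delta_g
            oracle = min(e for _, e in enumerate_structures_oracle(seq))
            assert dp == oracle, seq

    def test_structure_rescoring_is_self_consistent(self, rng):
        """The traceback structure re-scores to exactly the reported MFE,
        including longer sequences with interior loops and bulges."""
        for n in (20, 35, 60):
            for _ in range(10):
                seq = random_dna(rng, n)
                res = mfe_fold(seq)
                if "(" not in res.structure:
                    continue
                assert score_structure(seq, res.pairs()) == res.delta_g

    def test_structure_pairs_are_watson_crick(self, rng):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for _ in range(20):
            seq = random_dna(rng, 40)
            res = mfe_fold(seq)
            for i, j in res.pairs():
                assert seq[j] == comp[seq[i]]
                assert j - i - 1 >= 3

    def test_deterministic(self):
        seq = "GGCGCATTTTGCGCCATATGCATGCGGCCG"
        assert mfe_fold(seq) == mfe_fold(seq)

    @pytest.mark.parametrize("stem", ["GCGC", "GCGCAT", "GGCGCA"])
    def test_stem_extension_never_raises_energy(self, stem):
        """Adding one closing complementary pair to a hairpin stem adds one
        (negative) stack term, so the MFE cannot increase."""
        from pausefold.params import revcomp
        inner = stem + "TTTT" + revcomp(stem)
        prev = mfe_fold(inner).delta_g
        for outer in "GACT":
            ext = outer + inner + revcomp(outer)
            assert mfe_fold(ext).delta_g <= prev

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mfe_fold("")
        with pytest.raises(ValueError):
            mfe_fold("ACGTN")
        with pytest.raises(ValueError):
            FoldParams(temperature=150)
        with pytest.raises(ValueError):
            FoldParams(min_hairpin_loop=2)

    def test_temperature_and_salt_change_stability(self):
        seq = "GCGCGCTTTTGCGCGC"
        cold = mfe_fold(seq, FoldParams(temperature=20)).delta_g
        hot = mfe_fold(seq, FoldParams(temperature=80)).delta_g
        assert cold < hot
        high_salt = mfe_fold(seq, FoldParams(monovalent_salt=1.0)).delta_g
        low_salt = mfe_fold(seq, FoldParams(monovalent_salt=0.01)).delta_g
        assert high_salt < low_salt


class TestOracle:
    def test_unpairable_sequence_has_single_empty_structure(self):
        assert enumerate_structures_oracle("AAAA") == [("....", 0.0)]

    def test_minimum_hairpin_loop_excludes_short_loops(self):
        # GCGC could pair G1:C4 but the loop would be < 3 nt
        assert enumerate_structures_oracle("GCGC") == [("....", 0.0)]

    def test_lonely_pairs_are_excluded_by_default(self):
        # GAAAAC admits only the single pair G1:C6, which has no stacking
        # neighbor and is therefore excluded as a lonely pair
        assert enumerate_structures_oracle("GAAAAC") == [("......", 0.0)]
        lonely = enumerate_structures_oracle(
            "GAAAAC", FoldParams(allow_lonely_pairs=True))
        assert "(....)" in [s for s, _ in lonely]
        dp = mfe_fold("GAAAAC", FoldParams(allow_lonely_pairs=True)).delta_g
        assert dp == min(0.0, min(e for _, e in lonely))

    def test_length_guard(self):
        with pytest.raises(ValueError):
            enumerate_structures_oracle("A" * 19)


class TestG4:
    def test_canonical_motif_found_once_spanning_string(self):
        s = "GGGTTAGGGTTAGGGTTAGGG"
        motifs = g4_scan(s)
        assert len(motifs) == 1
        assert (motifs[0].start, motifs[0].end) == (0, len(s))
        assert motifs[0].n_tracts == 4
        assert motifs[0].bonus_energy < 0

    def test_no_motif_in_at_sequence(self):
        assert g4_scan("ATATATATATAT") == []

    def test_allowing_g4_never_raises_mfe(self, rng):
        core = "GGGTTAGGGTTAGGGTTAGGG"
        for _ in range(10):
            seq = random_dna(rng, 10) + core + random_dna(rng, 10)
            off = mfe_fold(seq, FoldParams(allow_g4=False)).delta_g
            on = mfe_fold(seq, FoldParams(allow_g4=True)).delta_g
            assert on <= off

    def test_g4_structure_marks_tracts(self):
        s = "GGGTTAGGGTTAGGGTTAGGG" + "A" * 8
        res = mfe_fold(s, FoldParams(allow_g4=True))
        assert res.structure[:3] == "+++"
        assert len(res.structure) == len(s)


class TestFoldWindows:
    def test_sliding_scan_equals_per_window_folds(self, rng):
        seq = random_dna(rng, 90)
        scan = fold_windows(seq, window=30, step=1)
        direct = [mfe_fold(seq[i:i + 30]).delta_g for i in range(61)]
        assert np.allclose(scan, direct)

    def test_n_windows_are_missing(self):
        seq = "GCGCTTTTGCGC" + "N" * 5 + "GCGCTTTTGCGC" + "A" * 30
        scan = fold_windows(seq, window=12, step=1)
        assert np.isnan(scan[1])
        assert scan[0] == mfe_fold(seq[:12]).delta_g

    def test_reverse_complement_symmetry(self, rng):
        """The nearest-neighbor table is reverse-complement symmetric, so
        the profile of the reverse-complemented sequence is the original
        profile with the window order reversed."""
        from pausefold.params import revcomp
        seq = random_dna(rng, 70)
        fwd = fold_windows(seq, window=30, step=1)
        rev = fold_windows(revcomp(seq), window=30, step=1)
        assert np.allclose(fwd, rev[::-1])
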