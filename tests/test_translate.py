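import numpy as np
import pytest
from scipy import stats

import superdna as sd
from superdna.translate import (
    CODONS_OF_AA,
    SegmentTargets,
    ewma_predictor,
    segment_target_mse,
)


def seq(s: str) -> sd.SymbolicSequence:
    return sd.SymbolicSequence.from_string(s)


class TestTranslation:
    @pytest.mark.parametrize(
        "dna,protein",
        [("ATGAAA", "MK"), ("ATGTAA", "M*"), ("ATGAAAG", "MK")],  # partial codon dropped
    )
    def test_standard_code(self, dna, protein):
        assert sd.translate_seq(seq(dna)).residues == protein

    def test_frames(self):
        assert sd.translate_seq(seq("CATGAAA"), frame=1).residues == "MK"

    def test_code_degeneracy(self):
        # 61 sense codons onto 20 residues, 3 stops
        n_sense = sum(len(v) for aa, v in CODONS_OF_AA.items() if aa != "*")
        assert n_sense == 61
        assert len(CODONS_OF_AA) - 1 == 20
        assert len(CODONS_OF_AA["*"]) == 3


class TestRandomReverseTranslation:
    def test_single_codon_residue(self):
        assert str(sd.reverse_translate_random(sd.ProteinSequence("M"), 0)) == "ATG"

    def test_round_trip_identity(self, rng):
        protein = sd.ProteinSequence("MKLVWREQSTPACDFGHIyn".upper())
        for s in range(5):
            dna = sd.reverse_translate_random(protein, s)
            assert sd.translate_seq(dna).residues == protein.residues

    def test_uniform_codon_choice(self):
        """Leucine's 6 codons are drawn uniformly over seeds."""
        protein = sd.ProteinSequence("L" * 10_000)
        dna = sd.reverse_translate_random(protein, 123)
        obs = {}
        s = str(dna)
        for i in range(0, len(s), 3):
            obs[s[i : i + 3]] = obs.get(s[i : i + 3], 0) + 1
        assert set(obs) == set(CODONS_OF_AA["L"])
        res = stats.chisquare(list(obs.values()))
        assert res.pvalue > 0.01

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            sd.ProteinSequence("MKX1")


class TestBackAndForth:
    def test_degrades_architecture_preserves_protein(self, small_genome):
        cfg, genome = small_genome
        recon, report = sd.back_and_forth_test(genome, seed=9)
        assert (
            sd.translate_seq(recon).residues == sd.translate_seq(genome).residues
        )
        assert report["reconstructed"]["sigma_n"] < report["original"]["sigma_n"]
        assert (
            report["reconstructed"]["hurst_large_scale"]
            < report["original"]["hurst_large_scale"]
        )

    def test_shuffled_genome_loses_less_sigma(self, small_genome):
        """A shuffled genome has no correlations to destroy, so the
        back-and-forth test changes sigma_n much less."""
        cfg, genome = small_genome
        _, rep_lrc = sd.back_and_forth_test(genome, seed=10)
        _, rep_shuf = sd.back_and_forth_test(sd.shuffle(genome, 11), seed=10)
        drop_lrc = rep_lrc["original"]["sigma_n"] - rep_lrc["reconstructed"]["sigma_n"]
        drop_shuf = (
            rep_shuf["original"]["sigma_n"] - rep_shuf["reconstructed"]["sigma_n"]
        )
        assert drop_lrc > 5 * abs(drop_shuf)


class TestTargetPrediction:
    def test_constant_history_fixed_point(self):
        profile = sd.segment_counts(seq("GA" * 600))  # xi_S = 0.5 everywhere
        targets = sd.predict_segment_targets(profile, 4)
        np.testing.assert_allclose(targets.xi_s, 0.5)

    def test_zero_future_segments(self):
        profile = sd.segment_counts(seq("GA" * 600))
        assert len(sd.predict_segment_targets(profile, 0)) == 0

    def test_prediction_stays_in_range(self, small_genome):
        cfg, genome = small_genome
        profile = sd.segment_counts(genome)
        targets = sd.predict_segment_targets(profile, 50)
        for arr in (targets.xi_s, targets.a_of_w, targets.g_of_s):
            assert np.all((arr >= 0) & (arr <= 1))

    def test_ewma_tracks_recent_segments(self):
        pred = ewma_predictor(half_life=5)
        history = np.concatenate([np.full(50, 0.3), np.full(20, 0.7)])
        # 20 recent segments = 4 half-lives: weight 1 - 2^-4 on the recent level
        assert pred(history) == pytest.approx(0.3 + 0.4 * (1 - 2**-4), abs=0.01)
        with pytest.raises(ValueError):
            pred(np.array([]))


class TestGuidedReverseTranslation:
    def make_targets(self, n, xi=0.5):
        return SegmentTargets(
            np.full(n, xi), np.full(n, 0.5), np.full(n, 0.5)
        )

    def test_round_trip_identity(self):
        protein = sd.ProteinSequence("MKLVWREQSTPACDFGHIYN" * 10)
        targets = self.make_targets(4)
        dna = sd.reverse_translate_guided(protein, targets, seed=1)
        assert sd.translate_seq(dna).residues == protein.residues

    def test_extreme_target_prefers_strong_codons(self):
        # proline: CCx; with xi_S target 1.0 the wobble base must be strong
        targets = SegmentTargets(np.ones(1), np.full(1, 0.5), np.full(1, 0.5))
        dna = str(sd.reverse_translate_guided(sd.ProteinSequence("PPPP"), targets, 0))
        wobble = dna[2::3]
        assert set(wobble) <= {"C", "G"}

    def test_insufficient_targets_rejected(self):
        with pytest.raises(ValueError, match="targets cover"):
            sd.reverse_translate_guided(
                sd.ProteinSequence("M" * 200), self.make_targets(1), 0
            )

    def test_guided_beats_random(self, small_genome):
        """Guided codon choice tracks segment targets far better than
        uniform random reverse translation (averaged over seeds)."""
        cfg, genome = small_genome
        profile = sd.segment_counts(genome)
        protein = sd.translate_seq(
            sd.SymbolicSequence(genome.codes[:9000], genome.alphabet)
        )
        targets = sd.predict_segment_targets(profile, 60)
        mse_g, mse_r = [], []
        for s in range(20):
            g = sd.reverse_translate_guided(protein, targets, s)
            r = sd.reverse_translate_random(protein, s)
            mse_g.append(segment_target_mse(g, targets))
            mse_r.append(segment_target_mse(r, targets))
        assert np.mean(mse_g) < np.mean(mse_r)

    def test_uninformative_targets_match_random_gc(self, small_genome):
        cfg, genome = small_genome
        protein = sd.translate_seq(
            sd.SymbolicSequence(genome.codes[:30_000], genome.alphabet)
        )
        n_seg = -(-3 * len(protein) // 150)
        targets = self.make_targets(n_seg, xi=0.5)
        guided = sd.reverse_translate_guided(protein, targets, 3)
        random_ = sd.reverse_translate_random(protein, 3)
        assert abs(guided.gc_content() - random_.gc_content()) < 0.02
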