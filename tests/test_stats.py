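import math

import numpy as np
import pytest

from seqk.kmers import (
    NucleotideSequence,
    UNIFORM_BACKGROUND,
    center_counts,
    count_kmers,
    fit_background,
)
from seqk.stats import (
    IncompatibleVectorsError,
    StatisticKind,
    UndefinedDissimilarityError,
    d2_raw,
    d2s_stat,
    d2star_stat,
    dissim,
    dissim_from_sequences,
    freq_distances,
    pairwise_matrix,
)

from _oracles import (
    naive_d2s,
    naive_d2star,
    naive_dissim_d2,
    naive_dissim_d2s,
    naive_dissim_d2star,
)
from conftest import random_residues, random_sequence


def counts(residues, k):
    return count_kmers(NucleotideSequence("s", residues), k)


def centered(residues, k, bg_mode="empirical"):
    seq = NucleotideSequence("s", residues)
    bg = UNIFORM_BACKGROUND if bg_mode == "uniform" else fit_background(seq)
    return center_counts(count_kmers(seq, k), bg)


class TestRawD2:
    @pytest.mark.parametrize(
        "x, y, expected",
        [("ACGT", "ACGT", 4), ("AAAA", "CCCC", 0), ("AACC", "AAGG", 4)],
    )
    def test_inner_product_examples(self, x, y, expected):
        assert d2_raw(counts(x, 1), counts(y, 1)) == expected

    def test_k_mismatch_rejected(self):
        with pytest.raises(IncompatibleVectorsError):
            d2_raw(counts("ACGT", 1), counts("ACGT", 2))


class TestCenteredStatistics:
    def test_d2s_homopolymer_pair_uniform(self):
        # X̄ = Ȳ = (3,−1,−1,−1): 9/√18 + 3/√2 = 3√2
        xc = centered("AAAA", 1, "uniform")
        assert d2s_stat(xc, xc) == pytest.approx(3 * math.sqrt(2))

    def test_d2s_all_zero_centered(self):
        xc = centered("ACGT", 1)
        assert d2s_stat(xc, xc) == 0.0

    def test_d2s_self_statistic_identity(self, rng):
        # D2S(x, x) = Σ_w |X̄_w| / √2
        for _ in range(10):
            xc = centered(random_residues(rng, int(rng.integers(10, 60))), 2)
            expected = np.abs(xc.values).sum() / math.sqrt(2)
            assert d2s_stat(xc, xc) == pytest.approx(expected)

    def test_d2star_homopolymer_pair_uniform(self):
        # denominator per word = √(4·¼·4·¼) = 1, so D2* = 9+1+1+1
        xc = centered("AAAA", 1, "uniform")
        assert d2star_stat(xc, xc) == pytest.approx(12.0)

    def test_d2star_zero_probability_words_skipped(self):
        # p_C = p_G = p_T = 0 under the all-A background
        xc = centered("AAAA", 1)
        assert np.isfinite(d2star_stat(xc, xc))
        assert d2star_stat(xc, xc) == 0.0  # X̄_A = 0 too

    def test_agrees_with_naive_loop_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 4))
            x = random_residues(rng, int(rng.integers(k + 3, 50)))
            y = random_residues(rng, int(rng.integers(k + 3, 50)))
            xc, yc = centered(x, k), centered(y, k)
            assert d2s_stat(xc, yc) == pytest.approx(naive_d2s(x, y, k), abs=1e-9)
            assert d2star_stat(xc, yc) == pytest.approx(
                naive_d2star(x, y, k), abs=1e-9
            )

    def test_exchange_symmetry(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 4))
            xc = centered(random_residues(rng, 40), k)
            yc = centered(random_residues(rng, 30), k)
            assert d2s_stat(xc, yc) == pytest.approx(d2s_stat(yc, xc))
            assert d2star_stat(xc, yc) == pytest.approx(d2star_stat(yc, xc))


class TestFrequencyDistances:
    def test_identical_sequences(self):
        assert freq_distances(counts("ACGT", 2), counts("ACGT", 2)) == (0, 0, 0)

    def test_disjoint_homopolymers(self):
        eu, ma, ch = freq_distances(counts("AAAA", 1), counts("CCCC", 1))
        assert (eu, ma, ch) == (pytest.approx(math.sqrt(2)), 2.0, 1.0)

    def test_norm_ordering(self, rng):
        for _ in range(30):
            k = int(rng.integers(1, 4))
            x = counts(random_residues(rng, 30), k)
            y = counts(random_residues(rng, 50), k)
            eu, ma, ch = freq_distances(x, y)
            assert ch <= eu + 1e-12 <= ma + 1e-12


class TestDissimilarities:
    def test_self_dissimilarity_is_zero(self, rng):
        x = random_residues(rng, 50)
        assert dissim(counts(x, 2), counts(x, 2), StatisticKind.D2) == pytest.approx(0)
        xc = centered(x, 2)
        assert dissim(xc, xc, StatisticKind.D2S) == pytest.approx(0)
        assert dissim(xc, xc, StatisticKind.D2STAR) == pytest.approx(0)

    def test_orthogonal_counts_give_half(self):
        assert dissim(counts("AAAA", 1), counts("CCCC", 1), StatisticKind.D2) == 0.5

    def test_cosine_example(self):
        # cos = 4/(√8·√8) = ½ so d2 = ¼
        assert dissim(
            counts("AACC", 1), counts("AAGG", 1), StatisticKind.D2
        ) == pytest.approx(0.25)

    def test_agrees_with_naive_oracles(self, rng):
        # k >= 2: at k=1 empirical centering is identically zero and the
        # centered dissimilarities are undefined by construction
        for _ in range(100):
            k = int(rng.integers(2, 4))
            x = random_residues(rng, int(rng.integers(k + 5, 60)))
            y = random_residues(rng, int(rng.integers(k + 5, 60)))
            assert dissim(counts(x, k), counts(y, k), StatisticKind.D2) == pytest.approx(
                naive_dissim_d2(x, y, k), abs=1e-9
            )
            xc, yc = centered(x, k), centered(y, k)
            assert dissim(xc, yc, StatisticKind.D2S) == pytest.approx(
                naive_dissim_d2s(x, y, k), abs=1e-9
            )
            assert dissim(xc, yc, StatisticKind.D2STAR) == pytest.approx(
                naive_dissim_d2star(x, y, k), abs=1e-9
            )

    def test_bounds(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 4))
            x = random_residues(rng, 40)
            y = random_residues(rng, 40)
            assert 0 <= dissim(counts(x, k), counts(y, k), StatisticKind.D2) <= 0.5
            xc, yc = centered(x, k), centered(y, k)
            for kind in (StatisticKind.D2S, StatisticKind.D2STAR):
                assert -1e-12 <= dissim(xc, yc, kind) <= 1 + 1e-12

    def test_zero_norm_vector_rejected(self):
        x = counts("NN", 1)  # no countable windows
        with pytest.raises(UndefinedDissimilarityError):
            dissim(x, counts("ACGT", 1), StatisticKind.D2)

    def test_long_iid_sequences_have_similar_composition(self):
        rng = np.random.default_rng(7)
        x = random_sequence(rng, 10000, "x")
        y = random_sequence(rng, 10000, "y")
        d = dissim_from_sequences(x, y, k=4, kind=StatisticKind.D2)
        assert d < 0.05


class TestPairwiseMatrix:
    def test_single_sequence(self, rng):
        m = pairwise_matrix([random_sequence(rng, 30)], k=2)
        assert m.values.shape == (1, 1) and m.values[0, 0] == 0.0

    def test_matches_per_pair_calls(self, rng):
        seqs = [random_sequence(rng, 40, f"s{i}") for i in range(3)]
        for kind in StatisticKind:
            m = pairwise_matrix(seqs, k=2, kind=kind)
            for i in range(3):
                for j in range(3):
                    expected = dissim_from_sequences(seqs[i], seqs[j], 2, kind)
                    assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_zero_diagonal(self, rng):
        seqs = [random_sequence(rng, 60, f"s{i}") for i in range(5)]
        m = pairwise_matrix(seqs, k=3, kind=StatisticKind.D2S)
        assert np.allclose(m.values, m.values.T, atol=1e-9)
        assert np.allclose(np.diag(m.values), 0.0, atol=1e-9)

    def test_duplicated_record_has_zero_offdiagonal(self, rng):
        s = random_sequence(rng, 50, "dup")
        m = pairwise_matrix([s, NucleotideSequence("dup2", s.residues)], k=2)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_short_sequence_reported_by_id(self, rng):
        seqs = [random_sequence(rng, 40, "ok"), NucleotideSequence("tiny", "AC")]
        with pytest.raises(Exception, match="tiny"):
            pairwise_matrix(seqs, k=4)
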