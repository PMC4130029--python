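"""k-mer counting, frequencies, similarity F, and conservation counting.

Sparse counting and the similarity score are cross-checked against the
brute-force dense-vector oracles in oracles.py.
"""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmersim import (
    conserved_window_count,
    count_kmers,
    get_alphabet,
    kmer_frequencies,
    shared_kmer_count,
    similarity,
)

from oracles import dense_counts, dense_similarity

SEV10 = get_alphabet("se-v10")
IDENT = get_alphabet("identity-protein")
DNA = get_alphabet("identity-dna")

dna_seq = st.text(alphabet="ACGT", min_size=3, max_size=50)
protein_seq = st.text(alphabet=sorted(IDENT.residues), min_size=3, max_size=50)


class TestCountKmers:
    def test_worked_dna_example(self, dna):
        table = count_kmers("ATATAC", 3, dna)
        assert table.counts == {"ATA": 2, "TAT": 1, "TAC": 1}
        assert table.effective_windows == 4
        assert table.raw_length == 6
        assert table.skipped_windows == 0

    def test_single_window(self, dna):
        assert count_kmers("AAA", 3, dna).counts == {"AAA": 1}

    def test_sequence_shorter_than_k_is_empty(self, dna):
        table = count_kmers("AT", 3, dna)
        assert table.counts == {}
        assert table.effective_windows == 0

    def test_counts_are_in_representative_space(self, sev10):
        # SAT -> AAA under SE-V(10)
        assert count_kmers("SAT", 3, sev10).counts == {"AAA": 1}

    def test_windows_with_unknown_symbols_are_skipped(self, dna):
        table = count_kmers("ATNAT", 2, dna)
        assert table.counts == {"AT": 2}
        assert table.skipped_windows == 2
        assert table.effective_windows == 2

    def test_nonpositive_k_rejected(self, dna):
        with pytest.raises(ValueError):
            count_kmers("ATAT", 0, dna)

    @settings(derandomize=True, max_examples=150)
    @given(seq=dna_seq, k=st.integers(1, 4))
    def test_window_conservation_invariant(self, seq, k):
        """Sum of counts equals the number of valid windows, which for a
        clean sequence is length - k + 1."""
        table = count_kmers(seq, k, DNA)
        assert sum(table.counts.values()) == table.effective_windows
        assert table.effective_windows == max(0, len(seq) - k + 1)
        assert table.skipped_windows == 0

    @settings(derandomize=True, max_examples=100)
    @given(seq=protein_seq, k=st.integers(1, 3))
    def test_sparse_matches_dense_oracle(self, seq, k):
        sparse = count_kmers(seq, k, SEV10).counts
        dense = dense_counts(seq, k, SEV10)
        for tup, n in dense.items():
            assert sparse.get(tup, 0) == n
        assert set(sparse) <= set(dense)


class TestFrequencies:
    def test_worked_dna_example(self, dna):
        freqs = kmer_frequencies(count_kmers("ATATAC", 3, dna)).frequencies
        assert freqs == {"ATA": 0.5, "TAT": 0.25, "TAC": 0.25}

    def test_single_window_frequency_is_one(self, dna):
        assert kmer_frequencies(count_kmers("ACG", 3, dna)).frequency("ACG") == 1.0

    def test_empty_table_is_an_error(self, dna):
        with pytest.raises(ValueError):
            kmer_frequencies(count_kmers("A", 3, dna))

    @settings(derandomize=True, max_examples=100)
    @given(seq=dna_seq, k=st.integers(1, 3))
    def test_frequencies_sum_to_one(self, seq, k):
        table = count_kmers(seq, k, DNA)
        total = sum(kmer_frequencies(table).frequencies.values())
        assert math.isclose(total, 1.0, abs_tol=1e-12)


class TestSimilarity:
    def test_self_similarity_is_one(self, protein):
        assert similarity("ACDEFGHIKLM", "ACDEFGHIKLM", 3, protein) == 1.0

    def test_disjoint_kmer_sets_give_zero(self, dna):
        assert similarity("ATATAC", "GGGGGG", 3, dna) == 0.0

    def test_kinase_pair_matches_dense_oracle_value(self, kinase_fragments, sev10, protein):
        """Frozen oracle values for the first two aligned kinase fragments:
        15 shared 3-mer occurrences out of 21 windows under SE-V(10),
        14/21 under the plain amino-acid alphabet."""
        s1, s2 = kinase_fragments[:2]
        assert similarity(s1, s2, 3, sev10) == pytest.approx(15 / 21, abs=1e-12)
        assert similarity(s1, s2, 3, protein) == pytest.approx(14 / 21, abs=1e-12)

    def test_short_sequence_yields_zero_with_warning(self, dna, caplog):
        with caplog.at_level("WARNING", logger="kmersim"):
            assert similarity("AT", "ATATAC", 3, dna) == 0.0
        assert "shorter than k" in caplog.text

    def test_empty_sequence_is_an_error(self, dna):
        with pytest.raises(ValueError):
            similarity("", "ATAT", 2, dna)

    def test_mismatched_k_tables_rejected(self, dna):
        with pytest.raises(ValueError):
            shared_kmer_count(count_kmers("ATAT", 2, dna), count_kmers("ATAT", 3, dna))

    @settings(derandomize=True, max_examples=150)
    @given(x=dna_seq, y=dna_seq, k=st.integers(1, 4))
    def test_symmetric_and_bounded(self, x, y, k):
        f_xy = similarity(x, y, k, DNA)
        assert f_xy == similarity(y, x, k, DNA)
        assert 0.0 <= f_xy <= 1.0

    @settings(derandomize=True, max_examples=75)
    @given(x=protein_seq, y=protein_seq, k=st.integers(1, 3))
    def test_matches_dense_oracle(self, x, y, k):
        assert similarity(x, y, k, SEV10) == pytest.approx(
            dense_similarity(x, y, k, SEV10), abs=1e-12
        )

    def test_compressed_alphabet_never_lowers_similarity(self):
        """Merging residues into classes can only merge count bins, and
        sum-of-mins over merged bins dominates the unmerged sum; related
        pairs therefore score at least as high under any reduced alphabet."""
        rng = random.Random(17)
        residues = sorted(IDENT.residues)
        compressed = [get_alphabet(n) for n in
                      ("se-v10", "dayhoff6", "murphy10", "se-b14")]
        for _ in range(200):
            base = "".join(rng.choice(residues) for _ in range(60))
            mutated = "".join(
                rng.choice(residues) if rng.random() < 0.15 else ch for ch in base
            )
            f_ident = similarity(base, mutated, 3, IDENT)
            for alpha in compressed:
                assert similarity(base, mutated, 3, alpha) >= f_ident


class TestConservedWindows:
    def test_kinase_conservation_under_both_alphabets(self, kinase_fragments, protein, sev10):
        """Compressing the alphabet raises conservation: 12 -> 19 conserved
        columns, 4 -> 10 conserved 3-mers, 3 -> 8 conserved 4-mers."""
        for k, alpha, expected in [
            (1, protein, 12), (1, sev10, 19),
            (3, protein, 4), (3, sev10, 10),
            (4, protein, 3), (4, sev10, 8),
        ]:
            assert conserved_window_count(kinase_fragments, k, alpha) == expected

    def test_identical_sequences_have_all_windows_conserved(self, protein):
        seqs = ["ACDEFGHIKL"] * 3
        for k in (1, 3, 7, 10):
            assert conserved_window_count(seqs, k, protein) == 10 - k + 1

    def test_unequal_lengths_rejected(self, protein):
        with pytest.raises(ValueError, match="equal length"):
            conserved_window_count(["ACD", "ACDE"], 1, protein)

    def test_fewer_than_two_sequences_rejected(self, protein):
        with pytest.raises(ValueError):
            conserved_window_count(["ACD"], 1, protein)

    def test_unknown_symbol_column_is_never_conserved(self, protein):
        assert conserved_window_count(["AXC", "AXC"], 1, protein) == 2
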