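"""Count k-mers in a short DNA sequence and score a pair of sequences.

The similarity F(X, Y) is the number of k-mer occurrences the two
sequences share, divided by the window count of the shorter one — a
number in [0, 1] that needs no alignment.
"""

from kmersim import count_kmers, get_alphabet, kmer_frequencies, similarity

dna = get_alphabet("identity-dna")

table = count_kmers("ATATAC", 3, dna)
print("3-mer counts of ATATAC:", table.counts)
print("windows scanned:", table.effective_windows)
print("frequencies:", kmer_frequencies(table).frequencies)
# ATA occurs twice in the 4 windows of this length-6 sequence, so its
# frequency is 0.5; the frequencies always sum to 1.

x, y = "ATATACGGAT", "ATATACGGTT"
print(f"F({x}, {y}) at k=3:", round(similarity(x, y, 3, dna), 6))
# 6 of the 8 windows of the shorter sequence are shared: F = 0.75.
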