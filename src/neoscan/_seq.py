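"""Small shared sequence helpers (DNA alphabet, strand arithmetic)."""

from __future__ import annotations

from Bio.Seq import Seq

DNA = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase)."""
    return str(Seq(seq).reverse_complement())


def complement(base: str) -> str:
    """Watson-Crick complement of a single base."""
    return COMPLEMENT[base.upper()]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def count_overlapping(haystack: str, needle: str) -> int:
    """Occurrences of needle in haystack, overlaps allowed."""
    if not needle:
        return 0
    n, i = 0, haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n
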