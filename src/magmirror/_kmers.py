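"""Canonical k-mer primitives shared across the package.

All sketching and containment machinery works on *canonical* k-mers: the
lexicographic minimum of a k-mer and its reverse complement, so that the
same molecule sequenced on either strand yields the same k-mer set.
Windows containing any non-ACGT character (N, ambiguity codes) are skipped.
"""

from __future__ import annotations

from typing import Iterable

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_BASE2BITS = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per-base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Set of canonical k-mers of ``seq``; non-ACGT windows are skipped."""
    seq = seq.upper()
    out: set[str] = set()
    n = len(seq)
    if n < k:
        return out
    # Track the rightmost invalid character to skip windows cheaply.
    last_bad = -1
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            last_bad = i
        if i >= k - 1 and last_bad <= i - k:
            kmer = seq[i - k + 1 : i + 1]
            rc = revcomp(kmer)
            out.add(kmer if kmer <= rc else rc)
    return out


def genome_kmers(sequences: Iterable[str], k: int) -> set[str]:
    """Union of canonical k-mer sets over multiple sequences."""
    out: set[str] = set()
    for s in sequences:
        out |= canonical_kmers(s, k)
    return out


def splitmix64(x: int) -> int:
    """Deterministic 64-bit finalizer (SplitMix64); stable across runs."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def encode_kmer(kmer: str) -> int:
    """2-bit encode an ACGT k-mer (k <= 31) into an integer."""
    v = 0
    for ch in kmer:
        v = (v << 2) | _BASE2BITS[ch]
    return v


def hash_kmer(kmer: str, seed: int = 0) -> int:
    """Seeded, run-stable 64-bit hash of a canonical k-mer."""
    return splitmix64(encode_kmer(kmer) ^ (seed & 0xFFFFFFFFFFFFFFFF))
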