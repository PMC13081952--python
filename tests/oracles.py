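"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's interval arithmetic: everything is
computed with per-base boolean arrays or exhaustive enumeration, so that
agreement with the fast path is meaningful.
"""

from __future__ import annotations

import numpy as np

from magmirror.groundtruth import ContigGenomeMap
from magmirror.refdb import GenomeRecord


def per_base_tp(genome: GenomeRecord, bin_contigs: set[str], cmap: ContigGenomeMap) -> int:
    """TP basepairs via boolean coverage arrays over every genome sequence."""
    masks = {sid: np.zeros(len(s), dtype=bool) for sid, s in genome.sequences}
    for cid in bin_contigs:
        for h in cmap.hits_of(cid):
            if h.genome_id == genome.genome_id:
                masks[h.genome_seq_id][h.g_start : h.g_end] = True
    return int(sum(m.sum() for m in masks.values()))


def per_base_fp(genome: GenomeRecord, bin_contigs: set[str], cmap: ContigGenomeMap) -> int:
    """FP basepairs via boolean arrays over each contig's positions."""
    fp = 0
    for cid in bin_contigs:
        mask = np.zeros(cmap.contig_lengths[cid], dtype=bool)
        for h in cmap.hits_of(cid):
            if h.genome_id == genome.genome_id:
                mask[h.c_start : h.c_end] = True
        fp += int((~mask).sum())
    return fp


def per_base_assembled(genome: GenomeRecord, cmap: ContigGenomeMap) -> int:
    """Assembled portion of the genome: bases covered by ANY qualifying contig."""
    return per_base_tp(genome, set(cmap.hits.keys()), cmap)


def brute_force_n50(lengths: list[int]) -> int:
    """N50 by exhaustively scanning prefix sums of descending lengths."""
    total = sum(lengths)
    ordered = sorted(lengths, reverse=True)
    acc = 0
    for length in ordered:
        acc += length
        if acc * 2 >= total:
            return length
    raise ValueError("empty")


def exhaustive_tetra_freqs(seq: str) -> dict[str, float]:
    """Canonical 4-mer frequencies by direct window enumeration."""
    comp = str.maketrans("ACGT", "TGCA")
    counts: dict[str, float] = {}
    n = 0
    for i in range(len(seq) - 3):
        w = seq[i : i + 4]
        if any(c not in "ACGT" for c in w):
            continue
        rc = w.translate(comp)[::-1]
        counts[min(w, rc)] = counts.get(min(w, rc), 0) + 1
        n += 1
    return {k: v / n for k, v in counts.items()}
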