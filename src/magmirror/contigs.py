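"""Contig-level binning-bias analysis.

Quantifies how contig properties relate to binning success: the cosine
distance between a contig's tetranucleotide composition and its genome's,
the Euclidean distance between a contig's cross-sample coverage vector and
the mean vector of its genome's contigs, a base-pair-level percentile
discretization of those distances, and recall curves per percentile and
per contig group (all / prophage / shared).
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cosine as _cosine

from ._kmers import revcomp
from .groundtruth import ContigGenomeMap

# 136 canonical tetranucleotides: each 4-mer pooled with its reverse
# complement; 16 are their own reverse complement.
CANONICAL_TETRAMERS: list[str] = sorted(
    {
        min(kmer, revcomp(kmer))
        for kmer in ("".join(t) for t in itertools.product("ACGT", repeat=4))
    }
)
_TETRA_INDEX = {t: i for i, t in enumerate(CANONICAL_TETRAMERS)}


def tetranucleotide_composition(sequence: str) -> np.ndarray:
    """Normalized canonical 4-mer frequency vector (length 136).

    Windows containing non-ACGT characters are skipped; frequencies sum
    to one over valid windows."""
    seq = sequence.upper()
    counts = np.zeros(len(CANONICAL_TETRAMERS))
    for i in range(len(seq) - 3):
        w = seq[i : i + 4]
        idx = _TETRA_INDEX.get(min(w, revcomp(w)))
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence has no valid 4-mer window")
    return counts / total


def composition_distance(contig_vec: np.ndarray, genome_vec: np.ndarray) -> float:
    """Cosine distance 1 - u.v/(|u||v|), in [0, 2]."""
    u = np.asarray(contig_vec, dtype=float)
    v = np.asarray(genome_vec, dtype=float)
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(_cosine(u, v))


def coverage_distance(contig_cov: np.ndarray, genome_mean_cov: np.ndarray) -> float:
    """Euclidean distance between a contig's cross-sample coverage vector
    and its genome's mean contig coverage vector."""
    u = np.asarray(contig_cov, dtype=float)
    v = np.asarray(genome_mean_cov, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"coverage vector length mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


ITEM_COLUMNS = ["sample_id", "contig_id", "genome_id", "length", "distance"]


def percentile_discretize(items: pd.DataFrame) -> pd.DataFrame:
    """Assign each (contig, genome) item to a base-pair percentile 0-99.

    Items (pooled across samples) are ordered by ascending distance (ties
    broken by sample_id, contig_id, genome_id). With s_c the cumulative
    length of strictly preceding items, l_c the item's length, and
    ``bases`` = total length / 100, the item gets the percentile p with
    p*bases < s_c + l_c/2 <= (p+1)*bases. Exact integer arithmetic; every
    item gets exactly one percentile.
    """
    missing = [c for c in ITEM_COLUMNS if c not in items.columns]
    if missing:
        raise ValueError(f"items table missing columns: {missing}")
    if items.empty:
        raise ValueError("cannot discretize an empty item set")
    ordered = items.sort_values(
        ["distance", "sample_id", "contig_id", "genome_id"], kind="mergesort"
    ).reset_index(drop=True)
    lengths = ordered["length"].to_numpy(dtype=np.int64)
    total = int(lengths.sum())
    s = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    # midpoint inequality with bases = total/100, scaled to integers:
    # p * 2*total < 200*s_c + 100*l_c <= (p+1) * 2*total
    m2 = 200 * s + 100 * lengths
    denom = 2 * total
    p = (m2 + denom - 1) // denom - 1
    ordered["percentile"] = np.clip(p, 0, 99).astype(int)
    return ordered


def correctly_binned(
    contig_id: str,
    genome_id: str,
    sample_id: str,
    membership: Mapping[str, str],
    representative_map: Mapping[tuple[str, str], str | None],
) -> bool:
    """A contig-genome item is correctly binned iff the contig sits in the
    genome's representative bin for that sample; unbinned contigs count as
    incorrect."""
    rep = representative_map.get((genome_id, sample_id))
    if rep is None:
        return False
    return membership.get(contig_id) == rep


def percentile_recall(
    assignments: pd.DataFrame,
    membership_by_sample: Mapping[str, Mapping[str, str]],
    representative_map: Mapping[tuple[str, str], str | None],
) -> pd.DataFrame:
    """Per-percentile base-pair recall.

    ``assignments`` is the output of :func:`percentile_discretize`;
    ``membership_by_sample`` maps sample_id -> contig -> bin. Returns a
    table (percentile, tp_bp, fn_bp, recall)."""
    tab = assignments.copy()
    tab["correct"] = [
        correctly_binned(
            r.contig_id, r.genome_id, r.sample_id,
            membership_by_sample.get(r.sample_id, {}), representative_map,
        )
        for r in tab.itertuples(index=False)
    ]
    rows = []
    for p, grp in tab.groupby("percentile", sort=True):
        tp = int(grp.loc[grp.correct, "length"].sum())
        fn = int(grp.loc[~grp.correct, "length"].sum())
        rows.append((int(p), tp, fn, tp / (tp + fn) if tp + fn else float("nan")))
    return pd.DataFrame(rows, columns=["percentile", "tp_bp", "fn_bp", "recall"])


def classify_prophage(
    contig_hits: Iterable[tuple[str, int, int]],
    provirus_intervals: Mapping[str, list[tuple[int, int]]],
    min_coverage: float = 0.25,
) -> bool:
    """Prophage contig classification.

    True iff, for some mapped genome, the contig's genome interval is
    entirely inside a provirus, contains an entire provirus, or covers at
    least 25% of a provirus (all intervals 0-based half-open on genome
    coordinates)."""
    for genome_id, c_lo, c_hi in contig_hits:
        for p_lo, p_hi in provirus_intervals.get(genome_id, []):
            if p_lo <= c_lo and c_hi <= p_hi:
                return True
            if c_lo <= p_lo and p_hi <= c_hi:
                return True
            overlap = min(c_hi, p_hi) - max(c_lo, p_lo)
            if overlap > 0 and p_hi > p_lo and overlap / (p_hi - p_lo) >= min_coverage:
                return True
    return False


def classify_shared(
    contig_id: str,
    cmap: ContigGenomeMap,
    recoverable_genomes: set[str],
) -> bool:
    """Shared contig: qualifying hits to two or more recoverable genomes."""
    hit = {g for g in cmap.genomes_of(contig_id) if g in recoverable_genomes}
    return len(hit) >= 2


def group_recall(
    features: pd.DataFrame,
    genome_id: str,
    sample_id: str,
    group: str = "all",
) -> float | None:
    """Base-pair recall over a genome's mapped contigs in a group.

    ``features`` needs columns genome_id, sample_id, length, correct, and
    boolean group columns is_prophage / is_shared. ``group`` is one of
    "all", "prophage", "shared". None when the group is empty for the
    genome."""
    sel = (features.genome_id == genome_id) & (features.sample_id == sample_id)
    if group == "prophage":
        sel &= features.is_prophage
    elif group == "shared":
        sel &= features.is_shared
    elif group != "all":
        raise ValueError(f"unknown contig group {group!r}")
    sub = features.loc[sel]
    total = int(sub["length"].sum())
    if total == 0:
        return None
    return int(sub.loc[sub.correct, "length"].sum()) / total


def coverage_from_provenance(
    provenance: pd.DataFrame,
    contig_truth: pd.DataFrame,
    read_length: int,
    sample_id: str,
) -> pd.DataFrame:
    """Truth-derived mean depth per contig for one sample.

    Counts simulated fragments whose start falls within each contig's
    source interval on its genome and converts to mean depth
    (pairs * 2 * read_length / contig length). ``contig_truth`` needs
    columns contig_id, genome_id, seq_id, start, end. Exact at fragment
    resolution; an external depth table can be used instead via
    :func:`read_depth_table`.
    """
    rows = []
    for r in contig_truth.itertuples(index=False):
        sel = provenance[
            (provenance.genome_id == r.genome_id)
            & (provenance.seq_id == r.seq_id)
            & (provenance.start >= r.start)
            & (provenance.start < r.end)
        ]
        length = r.end - r.start
        depth = len(sel) * 2 * read_length / length if length else 0.0
        rows.append((r.contig_id, sample_id, depth))
    return pd.DataFrame(rows, columns=["contig_id", "sample_id", "mean_depth"])


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """External depth-table adapter (contig_id, sample_id, mean_depth)."""
    tab = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "sample_id": str})
    for col in ("contig_id", "sample_id", "mean_depth"):
        if col not in tab.columns:
            raise ValueError(f"depth table missing column {col!r}")
    return tab


def read_provirus_table(
    path: str | Path,
    seqid_to_genome: Mapping[str, str] | None = None,
    min_score: float = 0.9,
) -> dict[str, list[tuple[int, int]]]:
    """Provirus annotation adapter (geNomad-style dialect).

    Expects columns seq_name, start, end (1-based inclusive), virus_score;
    keeps high-confidence rows (virus score >= 0.9) and returns 0-based
    half-open intervals keyed by genome id."""
    tab = pd.read_csv(path, sep="\t", dtype={"seq_name": str})
    for col in ("seq_name", "start", "end", "virus_score"):
        if col not in tab.columns:
            raise ValueError(f"provirus table missing column {col!r}")
    out: dict[str, list[tuple[int, int]]] = {}
    for r in tab.itertuples(index=False):
        if float(r.virus_score) < min_score:
            continue
        gid = seqid_to_genome[r.seq_name] if seqid_to_genome else r.seq_name
        lo, hi = int(r.start), int(r.end)
        if hi < lo:
            lo, hi = hi, lo
        out.setdefault(gid, []).append((lo - 1, hi))
    return out
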