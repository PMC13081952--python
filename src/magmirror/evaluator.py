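"""Base-pair-resolution evaluation of binning results against ground truth.

For every ground-truth genome in a sample, true positives are the genome
basepairs covered by qualifying alignments of the contigs in a bin; the
bin with the highest recall is the genome's representative bin (a bin may
represent several genomes). False positives are the representative bin's
contig basepairs that do not map to the genome. Recall, precision and
F-score follow from TP/FN/FP. Interval unions make split and repeat hits
count each genome basepair once.

Downstream filters implemented here: the recoverable-genome filter
(recall >= 0.7 and precision >= 0.9 under at least one pipeline), the
expected-coverage filter (>= 2.5x), MIMAG-style quality classes from
completeness/contamination estimates, and removal of bins flagged as
contaminated by a chimerism screen (GUNC-style pass/fail reports).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .groundtruth import ContigGenomeMap
from .mirror import MirrorSpecification
from .readsim import DEFAULT_READ_LENGTH, expected_coverage
from .refdb import GenomeRecord, ReferenceDB

RECALL_GATE = 0.7
PRECISION_GATE = 0.9
COVERAGE_GATE = 2.5


def union_size(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length covered by a set of half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_start: int | None = None
    cur_end = 0
    for s, e in ivs:
        if s >= e:
            continue
        if cur_start is None or s > cur_end:
            if cur_start is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_start is not None:
        total += cur_end - cur_start
    return total


def _genome_intervals(
    genome_id: str, contigs: Iterable[str], cmap: ContigGenomeMap
) -> dict[str, list[tuple[int, int]]]:
    """Genome-side intervals (per genome sequence) of qualifying hits from
    the given contigs to the genome."""
    per_seq: dict[str, list[tuple[int, int]]] = {}
    for cid in contigs:
        for h in cmap.hits_of(cid):
            if h.genome_id == genome_id:
                per_seq.setdefault(h.genome_seq_id, []).append((h.g_start, h.g_end))
    return per_seq


def genome_bin_recall(
    genome: GenomeRecord, bin_contigs: set[str], cmap: ContigGenomeMap
) -> tuple[int, int]:
    """(tp_bp, fn_bp): genome basepairs covered / not covered by the bin's
    qualifying contigs. Overlapping hits count each basepair once."""
    per_seq = _genome_intervals(genome.genome_id, bin_contigs, cmap)
    tp = sum(union_size(ivs) for ivs in per_seq.values())
    return tp, genome.total_length - tp


def select_representative(
    genome: GenomeRecord,
    bins: Mapping[str, set[str]],
    cmap: ContigGenomeMap,
) -> tuple[str | None, int, int]:
    """Representative bin = argmax recall; ties to the lexicographically
    smallest bin_id. With no bins at all returns (None, 0, genome length)."""
    best: tuple[str, int] | None = None
    for bin_id in sorted(bins):
        tp, _ = genome_bin_recall(genome, bins[bin_id], cmap)
        if best is None or tp > best[1]:
            best = (bin_id, tp)
    if best is None:
        return None, 0, genome.total_length
    return best[0], best[1], genome.total_length - best[1]


def genome_precision(
    genome: GenomeRecord,
    representative_contigs: set[str],
    cmap: ContigGenomeMap,
    tp: int,
) -> tuple[int, float, float]:
    """(fp_bp, precision, fscore) for the representative bin.

    FP counts, per contig in the bin, the contig bases not covered by any
    qualifying contig-side interval to this genome — so a partially
    mapping contig contributes only its unmapped bases. precision is 0 by
    convention when tp = fp = 0."""
    fp = 0
    for cid in representative_contigs:
        covered = union_size(
            (h.c_start, h.c_end)
            for h in cmap.hits_of(cid)
            if h.genome_id == genome.genome_id
        )
        fp += cmap.contig_lengths[cid] - covered
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / genome.total_length
    fscore = (
        2 * recall * precision / (recall + precision) if (recall + precision) > 0 else 0.0
    )
    return fp, precision, fscore


@dataclass(frozen=True)
class GenomeEval:
    genome_id: str
    sample_id: str
    pipeline: str
    representative_bin_id: str | None
    tp_bp: int
    fn_bp: int
    fp_bp: int
    recall: float
    precision: float
    fscore: float


def evaluate_bins(
    genomes: Iterable[GenomeRecord],
    bins: Mapping[str, set[str]],
    cmap: ContigGenomeMap,
    sample_id: str = "sample",
    pipeline: str = "pipeline",
) -> list[GenomeEval]:
    """Per-genome evaluation of one binning result."""
    out: list[GenomeEval] = []
    for genome in genomes:
        rep, tp, fn = select_representative(genome, bins, cmap)
        if rep is None:
            fp, precision, fscore = 0, 0.0, 0.0
        else:
            fp, precision, fscore = genome_precision(genome, bins[rep], cmap, tp)
        out.append(
            GenomeEval(
                genome_id=genome.genome_id,
                sample_id=sample_id,
                pipeline=pipeline,
                representative_bin_id=rep,
                tp_bp=tp,
                fn_bp=fn,
                fp_bp=fp,
                recall=tp / genome.total_length,
                precision=precision,
                fscore=fscore,
            )
        )
    return out


def evals_to_frame(evals: Iterable[GenomeEval]) -> pd.DataFrame:
    """Tidy per-genome table (one row per genome x sample x pipeline) —
    the export handed to external mixed-model statistics."""
    return pd.DataFrame([e.__dict__ for e in evals])


def recoverable_set(
    evals: Iterable[GenomeEval],
    recall_gate: float = RECALL_GATE,
    precision_gate: float = PRECISION_GATE,
) -> set[tuple[str, str]]:
    """(genome, sample) pairs recovered at recall >= 0.7 AND precision
    >= 0.9 by at least one pipeline (both thresholds inclusive, and both
    required of the same pipeline)."""
    out: set[tuple[str, str]] = set()
    for e in evals:
        if e.recall >= recall_gate and e.precision >= precision_gate:
            out.add((e.genome_id, e.sample_id))
    return out


def coverage_filter(
    spec: MirrorSpecification,
    db: ReferenceDB,
    threshold: float = COVERAGE_GATE,
    read_length: int = DEFAULT_READ_LENGTH,
    pairs: bool = True,
) -> set[str]:
    """Genomes whose expected fold-coverage under the specification is at
    least ``threshold`` (default 2.5x)."""
    return {
        e.genome_id
        for e in spec.entries
        if expected_coverage(spec, db, e.genome_id, read_length, pairs) >= threshold
    }


def classify_mimag(completeness: float, contamination: float) -> str:
    """MIMAG-style quality class from completeness/contamination estimates.

    HQ: completeness > 90 and contamination < 5; MQ: completeness >= 50 and
    contamination < 10; LQ: contamination < 10; else UNCLASSIFIED.
    Contamination estimates may exceed 100%.
    """
    if not (0.0 <= completeness <= 100.0):
        raise ValueError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0:
        raise ValueError(f"negative contamination {contamination}")
    if completeness > 90 and contamination < 5:
        return "HQ"
    if completeness >= 50 and contamination < 10:
        return "MQ"
    if contamination < 10:
        return "LQ"
    return "UNCLASSIFIED"


def read_checkm2_report(path: str | Path) -> pd.DataFrame:
    """CheckM2-dialect quality report (columns Name, Completeness,
    Contamination), with a MIMAG class added per row."""
    tab = pd.read_csv(path, sep="\t", dtype={"Name": str})
    for col in ("Name", "Completeness", "Contamination"):
        if col not in tab.columns:
            raise ValueError(f"quality report missing column {col!r}")
    tab = tab.rename(
        columns={
            "Name": "bin_id",
            "Completeness": "checkm2_completeness",
            "Contamination": "checkm2_contamination",
        }
    )
    tab["mimag_class"] = [
        classify_mimag(c, x)
        for c, x in zip(tab.checkm2_completeness, tab.checkm2_contamination)
    ]
    return tab


def read_gunc_report(path: str | Path) -> dict[str, bool]:
    """GUNC-dialect report: mapping bin_id -> pass flag (column
    'pass.GUNC', values True/False)."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if "genome" not in tab.columns or "pass.GUNC" not in tab.columns:
        raise ValueError("GUNC report requires columns 'genome' and 'pass.GUNC'")
    return {
        g: str(p).strip().lower() in ("true", "1", "pass")
        for g, p in zip(tab["genome"], tab["pass.GUNC"])
    }


@dataclass(frozen=True)
class GuncFilterSummary:
    removed_fraction: float
    removed_mean_recall: float | None
    removed_mean_one_minus_precision: float | None


def apply_gunc_filter(
    evals: list[GenomeEval],
    gunc_pass: Mapping[str, bool],
    missing: str = "error",
) -> tuple[list[GenomeEval], GuncFilterSummary]:
    """Drop evaluation rows whose representative bin fails the chimerism
    screen. ``missing`` controls bins absent from the report:
    "error" (default) or "pass"."""
    kept: list[GenomeEval] = []
    removed: list[GenomeEval] = []
    for e in evals:
        if e.representative_bin_id is None:
            kept.append(e)
            continue
        if e.representative_bin_id not in gunc_pass:
            if missing == "pass":
                kept.append(e)
                continue
            raise KeyError(
                f"bin {e.representative_bin_id!r} missing from GUNC report"
            )
        (kept if gunc_pass[e.representative_bin_id] else removed).append(e)
    n = len(kept) + len(removed)
    summary = GuncFilterSummary(
        removed_fraction=len(removed) / n if n else 0.0,
        removed_mean_recall=(
            sum(e.recall for e in removed) / len(removed) if removed else None
        ),
        removed_mean_one_minus_precision=(
            sum(1 - e.precision for e in removed) / len(removed) if removed else None
        ),
    )
    return kept, summary


def assembly_recall(
    genome: GenomeRecord,
    bins: Mapping[str, set[str]],
    cmap: ContigGenomeMap,
) -> float | None:
    """Recall against the assembled portion of the genome only: the
    denominator is the union of genome intervals over ALL qualifying
    contigs in the assembly. None when nothing of the genome assembled."""
    per_seq = _genome_intervals(genome.genome_id, cmap.hits.keys(), cmap)
    assembled = sum(union_size(ivs) for ivs in per_seq.values())
    if assembled == 0:
        return None
    _, tp, _ = select_representative(genome, bins, cmap)
    return tp / assembled


def read_bin_table(
    path: str | Path, sample_prefix_delim: str | None = None
) -> dict[str, str]:
    """Bin membership TSV (contig_id, bin_id) -> mapping. A contig may be
    assigned to at most one bin. ``sample_prefix_delim`` strips a leading
    sample prefix from contig names (binner-dependent naming in
    multi-sample modes)."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("contig_id", "bin_id"):
        if col not in tab.columns:
            raise ValueError(f"bin table missing column {col!r}")
    out: dict[str, str] = {}
    for cid, bid in zip(tab.contig_id, tab.bin_id):
        if sample_prefix_delim is not None and sample_prefix_delim in cid:
            cid = cid.split(sample_prefix_delim, 1)[1]
        if cid in out and out[cid] != bid:
            raise ValueError(f"contig {cid!r} assigned to more than one bin")
        out[cid] = bid
    return out


def bins_from_membership(membership: Mapping[str, str]) -> dict[str, set[str]]:
    """Invert contig->bin membership into bin -> contig set."""
    bins: dict[str, set[str]] = {}
    for cid, bid in membership.items():
        bins.setdefault(bid, set()).add(cid)
    return bins
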