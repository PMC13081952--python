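"""Contig -> ground-truth-genome mapping from filtered tabular alignments.

Assemblies are aligned against the genomes of a sample's mirror
specification (externally with blastn, or with the built-in exact-match
aligner for fixtures). Alignments qualify as ground truth when percent
identity is >= 99% and the alignment length is between 99% and 101% of the
contig length; qualifying hits are stored at interval resolution on both
the genome and the contig side.

Coordinates are 0-based half-open internally; the 1-based inclusive BLAST
convention (with possibly reversed subject coordinates on the minus
strand) is converted at the parser boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from ._kmers import revcomp
from .refdb import GenomeRecord

IDENTITY_GATE = 99.0
LENGTH_GATE = (0.99, 1.01)


@dataclass(frozen=True)
class AlignmentRecord:
    contig_id: str
    genome_seq_id: str
    genome_id: str
    percent_identity: float
    alignment_length: int
    contig_start: int  # 0-based half-open
    contig_end: int
    genome_start: int  # 0-based half-open, orientation-normalized
    genome_end: int


class Hit(NamedTuple):
    genome_id: str
    genome_seq_id: str
    g_start: int
    g_end: int
    c_start: int
    c_end: int


@dataclass
class ContigGenomeMap:
    """Qualifying alignments per contig, at interval resolution."""

    contig_lengths: dict[str, int]
    hits: dict[str, list[Hit]] = field(default_factory=dict)

    def hits_of(self, contig_id: str) -> list[Hit]:
        return self.hits.get(contig_id, [])

    def genomes_of(self, contig_id: str) -> set[str]:
        return {h.genome_id for h in self.hits_of(contig_id)}

    def contigs_mapping_to(self, genome_id: str) -> set[str]:
        return {
            cid for cid, hs in self.hits.items() if any(h.genome_id == genome_id for h in hs)
        }


def parse_blast_tabular(
    path: str | Path,
    contig_lengths: Mapping[str, int],
    seqid_to_genome: Mapping[str, str],
) -> list[AlignmentRecord]:
    """Parse 12-column tabular alignments (blastn -outfmt 6).

    Subject coordinates are normalized to start < end; the subject sequence
    id is resolved to a genome id via ``seqid_to_genome``.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            qid, sid = fields[0], fields[1]
            if qid not in contig_lengths:
                raise ValueError(f"line {lineno}: unknown query contig id {qid!r}")
            if sid not in seqid_to_genome:
                raise ValueError(f"line {lineno}: unknown subject sequence id {sid!r}")
            pident = float(fields[2])
            alen = int(fields[3])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            if qend < qstart:
                raise ValueError(
                    f"line {lineno}: qend < qstart (queries are plus-strand)"
                )
            g_lo, g_hi = (sstart, send) if sstart <= send else (send, sstart)
            records.append(
                AlignmentRecord(
                    contig_id=qid,
                    genome_seq_id=sid,
                    genome_id=seqid_to_genome[sid],
                    percent_identity=pident,
                    alignment_length=alen,
                    contig_start=qstart - 1,
                    contig_end=qend,
                    genome_start=g_lo - 1,
                    genome_end=g_hi,
                )
            )
    return records


def filter_qualifying(
    records: Iterable[AlignmentRecord],
    contig_lengths: Mapping[str, int],
    identity_gate: float = IDENTITY_GATE,
    length_gate: tuple[float, float] = LENGTH_GATE,
) -> ContigGenomeMap:
    """Keep alignments with identity >= 99% and length within 99-101% of
    the contig length. All qualifying hits are retained (a contig may map
    to several genomes, and repeatedly to one genome)."""
    cmap = ContigGenomeMap(contig_lengths=dict(contig_lengths))
    lo, hi = length_gate
    for rec in records:
        if rec.contig_id not in contig_lengths:
            raise KeyError(f"contig {rec.contig_id!r} missing from contig_lengths")
        lc = contig_lengths[rec.contig_id]
        if rec.percent_identity < identity_gate:
            continue
        if not (lo * lc <= rec.alignment_length <= hi * lc):
            continue
        cmap.hits.setdefault(rec.contig_id, []).append(
            Hit(
                genome_id=rec.genome_id,
                genome_seq_id=rec.genome_seq_id,
                g_start=rec.genome_start,
                g_end=rec.genome_end,
                c_start=rec.contig_start,
                c_end=rec.contig_end,
            )
        )
    return cmap


def oracle_align(
    contigs: Mapping[str, str],
    genomes: Iterable[GenomeRecord],
) -> list[AlignmentRecord]:
    """Exact-match aligner for fixtures: one full-length 100%-identity
    record per (contig, genome sequence, occurrence), on either strand.
    Contigs with no occurrence produce no records."""
    records: list[AlignmentRecord] = []
    for rec in genomes:
        for seq_id, seq in rec.sequences:
            for cid in sorted(contigs):
                cseq = contigs[cid].upper()
                seen: set[int] = set()
                for probe in (cseq, revcomp(cseq)):
                    pos = seq.find(probe)
                    while pos != -1:
                        if pos not in seen:  # palindromic contigs match both strands
                            seen.add(pos)
                            records.append(
                                AlignmentRecord(
                                    contig_id=cid,
                                    genome_seq_id=seq_id,
                                    genome_id=rec.genome_id,
                                    percent_identity=100.0,
                                    alignment_length=len(cseq),
                                    contig_start=0,
                                    contig_end=len(cseq),
                                    genome_start=pos,
                                    genome_end=pos + len(cseq),
                                )
                            )
                        pos = seq.find(probe, pos + 1)
    return records


CMAP_COLUMNS = [
    "contig_id", "contig_length", "genome_id", "genome_seq_id",
    "g_start", "g_end", "c_start", "c_end",
]


def write_contig_genome_map(cmap: ContigGenomeMap, path: str | Path) -> None:
    rows = []
    for cid in sorted(cmap.hits):
        for h in cmap.hits[cid]:
            rows.append(
                (cid, cmap.contig_lengths[cid], h.genome_id, h.genome_seq_id,
                 h.g_start, h.g_end, h.c_start, h.c_end)
            )
    pd.DataFrame(rows, columns=CMAP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_contig_genome_map(
    path: str | Path, contig_lengths: Mapping[str, int] | None = None
) -> ContigGenomeMap:
    tab = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "genome_id": str,
                                             "genome_seq_id": str})
    lengths = dict(contig_lengths) if contig_lengths else {}
    cmap = ContigGenomeMap(contig_lengths=lengths)
    for r in tab.itertuples(index=False):
        lengths.setdefault(r.contig_id, int(r.contig_length))
        cmap.hits.setdefault(r.contig_id, []).append(
            Hit(r.genome_id, r.genome_seq_id, int(r.g_start), int(r.g_end),
                int(r.c_start), int(r.c_end))
        )
    return cmap
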