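"""Profiler-report parsing plus a desk-scale built-in profiler.

Parses the tabular dialects emitted by Sylph-style k-mer profilers:
the *profile* table (species-level relative abundances) and the *query*
table (per-genome coverage-adjusted ANI with a confidence interval and an
effective k-mer coverage token). Column names drift between profiler
versions, so they are pinned in a single overridable dialect descriptor.

The built-in profiler is a k-mer containment stand-in so that the whole
mirror-construction pipeline is testable without any external tool; it is
not a replica of any specific profiler's statistical model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from ._kmers import canonical_kmers, genome_kmers
from .refdb import ReferenceDB, containment_ani

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SylphDialect:
    """Column names of the profiler's tabular outputs (version-dependent)."""

    genome_column: str = "Genome_file"
    profile_abundance_column: str = "Taxonomic_abundance"
    query_ani_column: str = "Adjusted_ANI"
    query_eff_lambda_column: str = "Eff_lambda"
    query_ci_column: str = "ANI_5-95_percentile"  # "lo-hi" string
    abundance_is_percent: bool = True


DEFAULT_DIALECT = SylphDialect()


@dataclass(frozen=True)
class SpeciesProfileRow:
    species_representative_id: str
    relative_abundance: float  # fraction in [0, 1]


@dataclass(frozen=True)
class GenomeQueryRow:
    genome_id: str
    adjusted_ani: float  # percent; NaN when the profiler left it blank
    ani_ci_lower: float
    eff_lambda_token: str  # "LOW", "HIGH", or a numeric coverage token


def _require_columns(tab: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in tab.columns]
    if missing:
        raise ValueError(f"{what} missing required columns: {missing}")


def parse_profile_table(
    path: str | Path,
    name_mapping: Mapping[str, str] | None = None,
    dialect: SylphDialect = DEFAULT_DIALECT,
) -> list[SpeciesProfileRow]:
    """Parse a profile table into species abundance rows.

    ``name_mapping`` maps the profiler's genome-name column onto species
    representative ids (identity when omitted). Zero-abundance rows are
    dropped; percent-dialect abundances are converted to fractions.
    """
    tab = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(
        tab, [dialect.genome_column, dialect.profile_abundance_column], "profile table"
    )
    names = tab[dialect.genome_column].tolist()
    abundances = tab[dialect.profile_abundance_column].tolist()
    rows: list[SpeciesProfileRow] = []
    for i, (name, raw) in enumerate(zip(names, abundances), start=2):
        try:
            ab = float(raw)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric abundance {raw!r} at line {i} of {path}"
            ) from None
        if dialect.abundance_is_percent:
            ab /= 100.0
        if ab == 0.0:
            continue
        sid = name_mapping[name] if name_mapping is not None else name
        rows.append(SpeciesProfileRow(species_representative_id=sid, relative_abundance=ab))
    total = sum(r.relative_abundance for r in rows)
    if total > 1.0 + 1e-6:
        raise ValueError(f"profile abundances sum to {total} > 1")
    return rows


def parse_query_table(
    path: str | Path,
    dialect: SylphDialect = DEFAULT_DIALECT,
) -> list[GenomeQueryRow]:
    """Parse a query table into per-genome ANI rows (keyed by genome_id)."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(
        tab,
        [
            dialect.genome_column,
            dialect.query_ani_column,
            dialect.query_eff_lambda_column,
            dialect.query_ci_column,
        ],
        "query table",
    )
    rows: list[GenomeQueryRow] = []
    seen: set[str] = set()
    it = zip(
        tab[dialect.genome_column].tolist(),
        tab[dialect.query_ani_column].tolist(),
        tab[dialect.query_eff_lambda_column].tolist(),
        tab[dialect.query_ci_column].tolist(),
    )
    for i, (gid, raw_ani, token, raw_ci) in enumerate(it, start=2):
        if gid in seen:
            raise ValueError(f"duplicate genome_id {gid!r} at line {i} of {path}")
        seen.add(gid)
        try:
            ani = float(raw_ani)
        except (TypeError, ValueError):
            ani = math.nan  # blank / non-numeric ANI tolerated (e.g. LOW coverage)
        try:
            ci_lower = float(str(raw_ci).split("-")[0])
        except (TypeError, ValueError, IndexError):
            raise ValueError(
                f"unparseable ANI confidence interval {raw_ci!r} at line {i} of {path}"
            ) from None
        rows.append(
            GenomeQueryRow(
                genome_id=gid, adjusted_ani=ani, ani_ci_lower=ci_lower,
                eff_lambda_token=str(token),
            )
        )
    return rows


def write_profile_table(
    rows: list[SpeciesProfileRow],
    path: str | Path,
    dialect: SylphDialect = DEFAULT_DIALECT,
) -> None:
    scale = 100.0 if dialect.abundance_is_percent else 1.0
    pd.DataFrame(
        {
            dialect.genome_column: [r.species_representative_id for r in rows],
            dialect.profile_abundance_column: [r.relative_abundance * scale for r in rows],
        }
    ).to_csv(path, sep="\t", index=False)


def write_query_table(
    rows: list[GenomeQueryRow],
    path: str | Path,
    dialect: SylphDialect = DEFAULT_DIALECT,
) -> None:
    pd.DataFrame(
        {
            dialect.genome_column: [r.genome_id for r in rows],
            dialect.query_ani_column: [
                "" if math.isnan(r.adjusted_ani) else repr(r.adjusted_ani)
                for r in rows
            ],
            dialect.query_eff_lambda_column: [r.eff_lambda_token for r in rows],
            dialect.query_ci_column: [
                f"{r.ani_ci_lower!r}-{max(r.ani_ci_lower, r.adjusted_ani)!r}"
                if not math.isnan(r.adjusted_ani)
                else f"{r.ani_ci_lower!r}-{r.ani_ci_lower!r}"
                for r in rows
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def _read_fastq_seqs(paths: list[str | Path]) -> list[str]:
    seqs: list[str] = []
    for p in paths:
        for rec in SeqIO.parse(str(p), "fastq"):
            seqs.append(str(rec.seq).upper())
    return seqs


@dataclass
class BuiltinProfileResult:
    profile: list[SpeciesProfileRow]
    query: list[GenomeQueryRow]
    warnings: list[str] = field(default_factory=list)


def builtin_profile(
    sample_reads: list[str | Path],
    db: ReferenceDB,
    k: int = 21,
    read_floor: int = 50,
    read_length: int | None = None,
) -> BuiltinProfileResult:
    """Desk-scale profiler stand-in based on canonical k-mer containment.

    Species abundances: each read is assigned to the species representative
    with the highest k-mer containment (ties to the lexicographically
    smaller species id); abundance = assigned-read fraction, renormalized.

    Per-genome query rows: adjusted ANI from the containment of the
    genome's k-mers in the pooled read k-mer set via the closed-form
    containment→ANI map; the CI lower bound uses a normal approximation on
    the containment. The effective-coverage token is "LOW" when fewer than
    ``read_floor`` reads match the genome, "HIGH" at >= 10x the floor, and
    the numeric coverage estimate in between.
    """
    reads = _read_fastq_seqs(list(sample_reads))
    if not reads or not db.genomes:
        raise ValueError("builtin_profile requires non-empty reads and database")
    if read_length is None:
        read_length = max(len(r) for r in reads)

    rep_by_species = db.representatives  # species_cluster_id -> genome_id
    rep_sets = {
        sid: genome_kmers(db.record(gid).seq_strings(), k)
        for sid, gid in sorted(rep_by_species.items())
    }
    read_sets = [canonical_kmers(r, k) for r in reads]

    counts: dict[str, int] = {sid: 0 for sid in rep_sets}
    for rs in read_sets:
        if not rs:
            continue
        best_sid, best_c = None, 0.0
        for sid in sorted(rep_sets):
            c = len(rs & rep_sets[sid]) / len(rs)
            if c > best_c:
                best_sid, best_c = sid, c
        if best_sid is not None:
            counts[best_sid] += 1

    warnings: list[str] = []
    assigned = sum(counts.values())
    profile: list[SpeciesProfileRow] = []
    if assigned == 0:
        warnings.append("no read matched any species representative")
        logger.warning(warnings[-1])
    else:
        for sid in sorted(counts):
            if counts[sid] > 0:
                profile.append(
                    SpeciesProfileRow(
                        species_representative_id=rep_by_species[sid],
                        relative_abundance=counts[sid] / assigned,
                    )
                )

    pooled: set[str] = set()
    for rs in read_sets:
        pooled |= rs

    query: list[GenomeQueryRow] = []
    for gid in sorted(db.genomes):
        rec = db.record(gid)
        gset = genome_kmers(rec.seq_strings(), k)
        if not gset:
            continue
        inter = len(gset & pooled)
        if inter == 0:
            continue
        c = inter / len(gset)
        ani = containment_ani(c, k)
        c_lo = max(0.0, c - 1.96 * math.sqrt(c * (1.0 - c) / len(gset)))
        ci_lower = containment_ani(c_lo, k)
        matched_reads = sum(
            1 for rs in read_sets if rs and len(rs & gset) / len(rs) >= 0.5
        )
        if matched_reads < read_floor:
            token = "LOW"
        elif matched_reads >= 10 * read_floor:
            token = "HIGH"
        else:
            token = f"{matched_reads * read_length / rec.total_length:.3f}"
        query.append(
            GenomeQueryRow(
                genome_id=gid, adjusted_ani=ani, ani_ci_lower=ci_lower,
                eff_lambda_token=token,
            )
        )
    return BuiltinProfileResult(profile=profile, query=query, warnings=warnings)
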