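"""Mirror specification: ground-truth genome set and abundances for a sample.

Given a sample's species-level profile and per-genome query results, this
module decides which reference genomes "mirror" the sample's strain
content, and at what abundance, producing the ground-truth manifest that
read simulation and evaluation consume.

Strain evidence gate: a genome is a potential strain of its species if its
effective k-mer coverage token is not "LOW", its coverage-adjusted ANI is
>= 99.8%, and — unless coverage is "HIGH" — the lower bound of the ANI
confidence interval is >= 99.5%. Candidates are grouped by strain cluster,
at most three clusters are kept (chosen at random when more qualify), one
genome per cluster is selected (isolates first, then N50, then ANI), and
the species abundance is split across the selected strains with
logNormal(mu=1, sigma=2) weights normalized to sum to one. A species with
non-zero abundance but no passing candidate falls back to a single genome
(isolates first, then adjusted ANI, then N50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .profiling import GenomeQueryRow, SpeciesProfileRow
from .refdb import ReferenceDB

ANI_GATE = 99.8
CI_GATE = 99.5
MAX_STRAIN_CLUSTERS = 3
LOGNORMAL_MU = 1.0
LOGNORMAL_SIGMA = 2.0


@dataclass(frozen=True)
class StrainCandidate:
    genome_id: str
    strain_cluster_id: str
    adjusted_ani: float
    ani_ci_lower: float
    eff_lambda_token: str
    is_isolate: bool
    n50: int


@dataclass(frozen=True)
class MirrorEntry:
    genome_id: str
    relative_abundance: float
    source: str  # "strain_evidence" | "species_fallback"


@dataclass
class MirrorSpecification:
    """Ground truth of one simulated sample."""

    sample_id: str
    entries: list[MirrorEntry]
    num_reads: int
    seed: int

    def __post_init__(self) -> None:
        gids = [e.genome_id for e in self.entries]
        if len(gids) != len(set(gids)):
            raise ValueError("specification entries must have unique genome_ids")
        if self.entries:
            total = sum(e.relative_abundance for e in self.entries)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"entry abundances sum to {total}, expected 1")

    def abundance_of(self, genome_id: str) -> float:
        for e in self.entries:
            if e.genome_id == genome_id:
                return e.relative_abundance
        raise KeyError(genome_id)


def passes_gate(row: GenomeQueryRow) -> bool:
    """Three-condition strain-evidence gate (all thresholds inclusive)."""
    if row.eff_lambda_token == "LOW":
        return False
    if math.isnan(row.adjusted_ani) or row.adjusted_ani < ANI_GATE:
        return False
    if row.eff_lambda_token == "HIGH":
        return True
    return row.ani_ci_lower >= CI_GATE


def select_strain_candidates(
    query_rows: list[GenomeQueryRow],
    db: ReferenceDB,
    species_cluster_id: str,
) -> list[StrainCandidate]:
    """Gate the species' query rows into potential strain genomes."""
    members = set(db.species_members(species_cluster_id))
    out: list[StrainCandidate] = []
    for row in query_rows:
        if row.genome_id not in members or not passes_gate(row):
            continue
        rec = db.record(row.genome_id)
        if rec.strain_cluster_id is None:
            raise ValueError(
                f"genome {rec.genome_id!r} has no strain cluster; run cluster_strains first"
            )
        out.append(
            StrainCandidate(
                genome_id=rec.genome_id,
                strain_cluster_id=rec.strain_cluster_id,
                adjusted_ani=row.adjusted_ani,
                ani_ci_lower=row.ani_ci_lower,
                eff_lambda_token=row.eff_lambda_token,
                is_isolate=rec.is_isolate,
                n50=rec.n50,
            )
        )
    return out


def pick_strain_representative(candidates: list[StrainCandidate]) -> str:
    """Pick one genome within a strain cluster: isolates over MAGs, then
    higher N50, then higher ANI, then lexicographic genome_id."""
    if not candidates:
        raise ValueError("cannot pick a representative from an empty candidate list")
    best = sorted(
        candidates,
        key=lambda c: (not c.is_isolate, -c.n50, -c.adjusted_ani, c.genome_id),
    )[0]
    return best.genome_id


def cap_strain_clusters(
    clusters: list[str], rng: np.random.Generator, max_clusters: int = MAX_STRAIN_CLUSTERS
) -> list[str]:
    """Keep at most ``max_clusters`` strain clusters, sampling uniformly
    without replacement when more qualify (input order preserved)."""
    if len(clusters) <= max_clusters:
        return list(clusters)
    chosen = rng.choice(len(clusters), size=max_clusters, replace=False)
    keep = set(int(i) for i in chosen)
    return [c for i, c in enumerate(clusters) if i in keep]


def assign_strain_abundances(
    species_abundance: float, n_strains: int, rng: np.random.Generator
) -> list[float]:
    """Split a species abundance across strains with logNormal(mu=1, sigma=2)
    weights (exp of a Normal on the log scale), normalized to sum to one."""
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if n_strains == 1:
        return [species_abundance]
    draws = np.exp(rng.normal(loc=LOGNORMAL_MU, scale=LOGNORMAL_SIGMA, size=n_strains))
    return [float(x) for x in species_abundance * draws / draws.sum()]


def fallback_species_representative(
    query_rows: list[GenomeQueryRow],
    db: ReferenceDB,
    species_cluster_id: str,
) -> str:
    """Single-genome fallback for a species with no passing strain evidence:
    isolates first, then adjusted ANI, then N50, then genome_id. Genomes
    absent from the query table rank below every profiled ANI."""
    members = db.species_members(species_cluster_id)
    if not members:
        raise ValueError(f"species cluster {species_cluster_id!r} is empty")
    ani = {r.genome_id: r.adjusted_ani for r in query_rows}

    def key(gid: str):
        rec = db.record(gid)
        a = ani.get(gid, -math.inf)
        if math.isnan(a):
            a = -math.inf
        return (not rec.is_isolate, -a, -rec.n50, gid)

    return sorted(members, key=key)[0]


def build_specification(
    profile: list[SpeciesProfileRow],
    query: list[GenomeQueryRow],
    db: ReferenceDB,
    num_reads: int,
    seed: int,
    sample_id: str = "sample",
) -> MirrorSpecification:
    """Assemble the mirror specification for one sample.

    Deterministic given (profile, query, db, seed): a single RNG seeded
    from ``seed`` drives both the random cluster cap and the logNormal
    abundance split, and species are processed in profile order.
    """
    rng = np.random.default_rng(seed)
    by_genome = {r.genome_id: r for r in query}
    entries: list[MirrorEntry] = []
    for prow in profile:
        rep = prow.species_representative_id
        try:
            sid = db.species_of_representative(rep)
        except KeyError:
            raise ValueError(f"profiled species representative {rep!r} absent from database")
        member_rows = [by_genome[g] for g in db.species_members(sid) if g in by_genome]
        candidates = select_strain_candidates(member_rows, db, sid)
        if candidates:
            groups: dict[str, list[StrainCandidate]] = {}
            for c in candidates:
                groups.setdefault(c.strain_cluster_id, []).append(c)
            cluster_ids = sorted(groups)
            kept = cap_strain_clusters(cluster_ids, rng)
            chosen = [pick_strain_representative(groups[cid]) for cid in kept]
            abundances = assign_strain_abundances(prow.relative_abundance, len(chosen), rng)
            for gid, ab in zip(chosen, abundances):
                entries.append(MirrorEntry(gid, ab, "strain_evidence"))
        else:
            gid = fallback_species_representative(member_rows, db, sid)
            entries.append(MirrorEntry(gid, prow.relative_abundance, "species_fallback"))

    total = sum(e.relative_abundance for e in entries)
    if total <= 0:
        raise ValueError("specification has zero total abundance")
    entries = [
        MirrorEntry(e.genome_id, e.relative_abundance / total, e.source) for e in entries
    ]
    return MirrorSpecification(
        sample_id=sample_id, entries=entries, num_reads=num_reads, seed=seed
    )


SPEC_COLUMNS = ["sample_id", "genome_id", "relative_abundance", "source", "seed", "num_reads"]


def write_specification(spec: MirrorSpecification, path: str | Path) -> None:
    """Write the ground-truth manifest TSV consumed by read simulation and
    evaluation. Abundances use repr so the file round-trips exactly."""
    pd.DataFrame(
        {
            "sample_id": [spec.sample_id] * len(spec.entries),
            "genome_id": [e.genome_id for e in spec.entries],
            "relative_abundance": [repr(e.relative_abundance) for e in spec.entries],
            "source": [e.source for e in spec.entries],
            "seed": [spec.seed] * len(spec.entries),
            "num_reads": [spec.num_reads] * len(spec.entries),
        }
    ).to_csv(path, sep="\t", index=False)


def read_specification(path: str | Path) -> MirrorSpecification:
    tab = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "genome_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in SPEC_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"specification file missing columns: {missing}")
    if tab.empty:
        raise ValueError("specification file has no entries")
    entries = [
        MirrorEntry(r.genome_id, float(r.relative_abundance), r.source)
        for r in tab.itertuples(index=False)
    ]
    return MirrorSpecification(
        sample_id=str(tab.sample_id.iloc[0]),
        entries=entries,
        num_reads=int(tab.num_reads.iloc[0]),
        seed=int(tab.seed.iloc[0]),
    )
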