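"""Two-level (species / strain) reference genome database.

The simulator draws genomes from a collection of isolate genomes and MAGs
clustered hierarchically: species clusters at the conventional 95% ANI
boundary (supplied with the input metadata) and strain clusters at 98% ANI
(assigned here, either from an externally computed pairwise-ANI table such
as dRep output, or with the built-in containment-based ANI estimator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._kmers import genome_kmers

STRAIN_ANI_CUTOFF = 98.0

METADATA_COLUMNS = [
    "genome_id",
    "fasta_path",
    "is_isolate",
    "species_cluster_id",
    "is_species_representative",
]


def compute_n50(lengths: list[int]) -> int:
    """N50: with lengths sorted descending, the length at which the
    cumulative sum first reaches half the total."""
    if not lengths:
        raise ValueError("cannot compute N50 of an empty genome")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")


@dataclass
class GenomeRecord:
    """One reference genome: ordered sequences plus cluster memberships."""

    genome_id: str
    sequences: list[tuple[str, str]]  # (seq_id, uppercase DNA)
    is_isolate: bool
    species_cluster_id: str
    is_species_representative: bool = False
    strain_cluster_id: str | None = None  # assigned by cluster_strains
    fasta_path: str | None = None
    total_length: int = field(init=False)
    n50: int = field(init=False)

    def __post_init__(self) -> None:
        lengths = [len(s) for _, s in self.sequences]
        if any(l == 0 for l in lengths):
            raise ValueError(f"genome {self.genome_id!r} has an empty sequence")
        self.total_length = sum(lengths)
        self.n50 = compute_n50(lengths)

    def seq_strings(self) -> list[str]:
        return [s for _, s in self.sequences]


@dataclass
class SpeciesCluster:
    cluster_id: str
    members: list[str]
    representative: str


@dataclass
class ReferenceDB:
    """Genome collection with nested species / strain cluster structure."""

    genomes: dict[str, GenomeRecord]
    species_clusters: dict[str, SpeciesCluster]
    strain_clusters: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cl in self.species_clusters.values():
            if cl.representative not in cl.members:
                raise ValueError(
                    f"species cluster {cl.cluster_id!r}: representative "
                    f"{cl.representative!r} is not a member"
                )

    def record(self, genome_id: str) -> GenomeRecord:
        return self.genomes[genome_id]

    def species_members(self, species_cluster_id: str) -> list[str]:
        return self.species_clusters[species_cluster_id].members

    def representative_of(self, species_cluster_id: str) -> str:
        return self.species_clusters[species_cluster_id].representative

    def species_of_representative(self, genome_id: str) -> str:
        """Species cluster whose representative is ``genome_id``."""
        for cl in self.species_clusters.values():
            if cl.representative == genome_id:
                return cl.cluster_id
        raise KeyError(f"no species cluster has representative {genome_id!r}")

    @property
    def representatives(self) -> dict[str, str]:
        """Mapping species_cluster_id -> representative genome_id."""
        return {c.cluster_id: c.representative for c in self.species_clusters.values()}


def load_genome_collection(genome_dir: str | Path, metadata_table: str | Path) -> ReferenceDB:
    """Load a preclustered genome collection from FASTA files plus a
    metadata TSV (columns: genome_id, fasta_path, is_isolate,
    species_cluster_id, is_species_representative).

    FASTA paths are resolved relative to ``genome_dir``. Strain clusters are
    left unassigned; call :func:`cluster_strains` afterwards.
    """
    genome_dir = Path(genome_dir)
    meta = pd.read_csv(metadata_table, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")

    genomes: dict[str, GenomeRecord] = {}
    for row in meta.itertuples(index=False):
        gid = row.genome_id
        fasta = genome_dir / row.fasta_path
        if not fasta.exists():
            raise FileNotFoundError(f"FASTA for genome {gid!r} not found: {fasta}")
        sequences = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta), "fasta")
        ]
        if not sequences:
            raise ValueError(f"FASTA for genome {gid!r} contains no sequences")
        genomes[gid] = GenomeRecord(
            genome_id=gid,
            sequences=sequences,
            is_isolate=bool(int(row.is_isolate)),
            species_cluster_id=row.species_cluster_id,
            is_species_representative=bool(int(row.is_species_representative)),
            fasta_path=str(fasta),
        )

    species_clusters: dict[str, SpeciesCluster] = {}
    for sid, grp in meta.groupby("species_cluster_id", sort=True):
        reps = [r.genome_id for r in grp.itertuples() if int(r.is_species_representative)]
        if len(reps) != 1:
            raise ValueError(
                f"species cluster {sid!r} must have exactly one representative, "
                f"found {len(reps)}"
            )
        species_clusters[sid] = SpeciesCluster(
            cluster_id=sid, members=list(grp.genome_id), representative=reps[0]
        )
    return ReferenceDB(genomes=genomes, species_clusters=species_clusters)


def containment_ani(c: float, k: int) -> float:
    """Closed-form ANI (percent) from k-mer containment ``c``.

    ANI = 100 * (1 + ln(2c/(1+c)) / k), clamped to [0, 100]; c = 0 maps to 0.
    """
    if c <= 0.0:
        return 0.0
    ani = 100.0 * (1.0 + math.log(2.0 * c / (1.0 + c)) / k)
    return min(100.0, max(0.0, ani))


def estimate_ani(a: GenomeRecord, b: GenomeRecord, k: int = 21) -> float:
    """Symmetric containment-based ANI estimate between two genomes.

    Containment c = |K_a ∩ K_b| / min(|K_a|, |K_b|) over canonical k-mer
    sets. A desk-scale stand-in for alignment-based ANI; an externally
    computed pairwise-ANI table can be supplied to :func:`cluster_strains`
    instead.
    """
    ka = genome_kmers(a.seq_strings(), k)
    kb = genome_kmers(b.seq_strings(), k)
    if not ka or not kb:
        raise ValueError(
            f"genome {a.genome_id if not ka else b.genome_id!r} has no "
            f"sequence of length >= k={k}"
        )
    c = len(ka & kb) / min(len(ka), len(kb))
    return containment_ani(c, k)


def _load_ani_table(path: str | Path, known_ids: set[str]) -> dict[tuple[str, str], float]:
    tab = pd.read_csv(path, sep="\t", dtype={"genome_a": str, "genome_b": str})
    for col in ("genome_a", "genome_b", "ani_percent"):
        if col not in tab.columns:
            raise ValueError(f"ANI table missing column {col!r}")
    lut: dict[tuple[str, str], float] = {}
    for row in tab.itertuples(index=False):
        for gid in (row.genome_a, row.genome_b):
            if gid not in known_ids:
                raise ValueError(f"ANI table references unknown genome_id {gid!r}")
        ani = float(row.ani_percent)
        lut[(row.genome_a, row.genome_b)] = ani
        lut[(row.genome_b, row.genome_a)] = ani
    return lut


def cluster_strains(
    db: ReferenceDB,
    ani_table: str | Path | None = None,
    cutoff: float = STRAIN_ANI_CUTOFF,
    k: int = 21,
) -> ReferenceDB:
    """Assign strain clusters (98% ANI) nested within each species cluster.

    Greedy seed-based agglomeration: within each species cluster, genomes
    are visited in order of descending total length (ties by genome_id);
    each genome joins the first existing strain cluster whose *seed* genome
    has ANI >= cutoff with it, else seeds a new cluster. Deterministic.
    Mutates ``db`` in place and returns it.
    """
    lut = _load_ani_table(ani_table, set(db.genomes)) if ani_table is not None else None

    def pair_ani(x: GenomeRecord, y: GenomeRecord) -> float:
        if lut is not None:
            return lut.get((x.genome_id, y.genome_id), 0.0)
        return estimate_ani(x, y, k=k)

    db.strain_clusters = {}
    for sid in sorted(db.species_clusters):
        members = db.species_members(sid)
        ordered = sorted(
            (db.record(g) for g in members),
            key=lambda r: (-r.total_length, r.genome_id),
        )
        seeds: list[GenomeRecord] = []
        assignment: dict[str, int] = {}
        for rec in ordered:
            joined = False
            for i, seed in enumerate(seeds):
                if pair_ani(seed, rec) >= cutoff:
                    assignment[rec.genome_id] = i
                    joined = True
                    break
            if not joined:
                assignment[rec.genome_id] = len(seeds)
                seeds.append(rec)
        for gid, idx in assignment.items():
            scid = f"{sid}.{idx}"
            db.record(gid).strain_cluster_id = scid
            db.strain_clusters.setdefault(scid, []).append(gid)
    return db
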