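"""Synthetic genome collections with planted structure.

Generates everything the rest of the package consumes, entirely from a
seed: species/strain-structured genome collections at a controlled
substitution rate, verbatim shared segments between genomes, prophage-like
insertions with shifted GC composition, fragmented "assemblies" with
controlled coverage loss, oracle and deliberately corrupted bin tables,
and quality-control report tables in the CheckM2/GUNC dialects. Every
planted feature is recorded in truth tables, so tests can assert exact
base-pair accounting.

What this emulates: the structures the contig-bias analysis studies
(strains near the 98% ANI boundary, contigs shared across genomes,
prophage regions compositionally distinct from their host). What it does
not: realistic error models, chimeric assembler artifacts, or real phage
biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluator import GenomeEval
from .refdb import GenomeRecord, ReferenceDB, SpeciesCluster

BASES = np.array(list("ACGT"))
PROPHAGE_GC_SHIFT = 0.15  # GC fraction increase of prophage segments


@dataclass
class FixtureSpec:
    """Plan for one synthetic genome collection."""

    seed: int = 0
    n_species: int = 3
    strains_per_species: list[int] = field(default_factory=lambda: [2, 2, 1])
    genome_length: int = 40_000
    strain_substitution_rate: float = 0.01
    gc_content: float = 0.5
    # (donor_genome_id, recipient_genome_id, length)
    shared_segment_plan: list[tuple[str, str, int]] = field(default_factory=list)
    # (genome_id, length, position)
    prophage_plan: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.strains_per_species) != self.n_species:
            raise ValueError("strains_per_species must have n_species entries")
        if not (0.0 <= self.strain_substitution_rate <= 1.0):
            raise ValueError("substitution rate must be in [0, 1]")
        for _, length, pos in self.prophage_plan:
            if pos < 0 or pos > self.genome_length:
                raise ValueError("prophage position outside genome bounds")
        for _, _, length in self.shared_segment_plan:
            if length > self.genome_length:
                raise ValueError("shared segment longer than genome")


def genome_id_for(species_index: int, strain_index: int) -> str:
    return f"sp{species_index}_st{strain_index}"


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _mutate_seq(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alts = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alts[int(rng.integers(0, 3))]
    return "".join(arr)


@dataclass
class CollectionTruth:
    # genome_id -> list of 0-based half-open prophage intervals
    prophages: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    # (donor, recipient, donor_start, recipient_start, length)
    shared_segments: list[tuple[str, str, int, int, int]] = field(default_factory=list)


def generate_collection(fspec: FixtureSpec) -> tuple[ReferenceDB, CollectionTruth]:
    """Build a seeded reference collection with planted structure.

    Per species, strain 0 is the ancestor (flagged isolate and species
    representative); further strains substitute bases at the configured
    rate. Shared segments are then copied verbatim donor -> recipient
    (replacing recipient bases, so genome lengths are preserved), and
    prophage segments with +15% GC are inserted at their planned
    positions. Strain clusters are left unassigned.
    """
    rng = np.random.default_rng(fspec.seed)
    seqs: dict[str, str] = {}
    meta: list[tuple[str, str, bool, bool]] = []  # gid, species, isolate, rep
    for si in range(fspec.n_species):
        ancestor = _random_dna(fspec.genome_length, fspec.gc_content, rng)
        for sj in range(fspec.strains_per_species[si]):
            gid = genome_id_for(si, sj)
            seqs[gid] = (
                ancestor if sj == 0
                else _mutate_seq(ancestor, fspec.strain_substitution_rate, rng)
            )
            meta.append((gid, f"sp{si}", sj == 0, sj == 0))

    truth = CollectionTruth()
    for donor, recipient, length in fspec.shared_segment_plan:
        dseq, rseq = seqs[donor], seqs[recipient]
        d_start = int(rng.integers(0, len(dseq) - length + 1))
        r_start = int(rng.integers(0, len(rseq) - length + 1))
        segment = dseq[d_start : d_start + length]
        seqs[recipient] = rseq[:r_start] + segment + rseq[r_start + length :]
        truth.shared_segments.append((donor, recipient, d_start, r_start, length))

    occupied: dict[str, list[tuple[int, int]]] = {}
    for gid, length, pos in fspec.prophage_plan:
        for lo, hi in occupied.get(gid, []):
            if pos < hi and pos + length > lo:
                raise ValueError(f"overlapping prophage insertions planned for {gid!r}")
        gc = min(1.0, fspec.gc_content + PROPHAGE_GC_SHIFT)
        segment = _random_dna(length, gc, rng)
        seqs[gid] = seqs[gid][:pos] + segment + seqs[gid][pos:]
        truth.prophages.setdefault(gid, []).append((pos, pos + length))
        occupied.setdefault(gid, []).append((pos, pos + length))

    genomes = {
        gid: GenomeRecord(
            genome_id=gid,
            sequences=[(f"{gid}_seq0", seqs[gid])],
            is_isolate=isolate,
            species_cluster_id=species,
            is_species_representative=rep,
        )
        for gid, species, isolate, rep in meta
    }
    clusters: dict[str, SpeciesCluster] = {}
    for gid, species, _, rep in meta:
        cl = clusters.setdefault(
            species, SpeciesCluster(cluster_id=species, members=[], representative="")
        )
        cl.members.append(gid)
        if rep:
            cl.representative = gid
    return ReferenceDB(genomes=genomes, species_clusters=clusters), truth


def write_collection(db: ReferenceDB, out_dir: str | Path) -> Path:
    """Materialize a collection as FASTA files plus the metadata TSV read
    by load_genome_collection. Returns the metadata path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for gid in sorted(db.genomes):
        rec = db.record(gid)
        fasta = out_dir / f"{gid}.fasta"
        with open(fasta, "w") as fh:
            for sid, s in rec.sequences:
                fh.write(f">{sid}\n{s}\n")
        rows.append(
            (gid, fasta.name, int(rec.is_isolate), rec.species_cluster_id,
             int(rec.is_species_representative))
        )
    meta_path = out_dir / "metadata.tsv"
    pd.DataFrame(
        rows,
        columns=["genome_id", "fasta_path", "is_isolate", "species_cluster_id",
                 "is_species_representative"],
    ).to_csv(meta_path, sep="\t", index=False)
    return meta_path


TRUTH_MAP_COLUMNS = ["contig_id", "genome_id", "seq_id", "start", "end"]


def fragment_assembly(
    db: ReferenceDB,
    mean_len: int = 2000,
    loss_fraction: float = 0.0,
    seed: int = 0,
    min_len: int = 500,
    genome_ids: list[str] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Cut genomes into contigs at seeded breakpoints, withholding a
    seeded subset covering about ``loss_fraction`` of each genome's bases.

    Contig lengths are roughly geometric around ``mean_len`` (floored at
    ``min_len``); contigs are exact substrings of their source genome.
    Returns (contig sequences, truth map with source intervals).
    """
    if not 0.0 <= loss_fraction < 1.0:
        raise ValueError("loss_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    rows = []
    for gid in sorted(genome_ids if genome_ids is not None else db.genomes):
        rec = db.record(gid)
        seq_lookup = dict(rec.sequences)
        pieces: list[tuple[str, int, int]] = []  # seq_id, start, end
        for sid, s in rec.sequences:
            pos = 0
            while pos < len(s):
                length = max(min_len, int(rng.geometric(1.0 / mean_len)))
                end = min(len(s), pos + length)
                if len(s) - end < min_len:  # absorb short tails
                    end = len(s)
                pieces.append((sid, pos, end))
                pos = end
        drop: set[int] = set()
        if loss_fraction > 0:
            target = loss_fraction * rec.total_length
            order = rng.permutation(len(pieces))
            dropped = 0
            for idx in order:
                if dropped >= target:
                    break
                sid, lo, hi = pieces[idx]
                drop.add(int(idx))
                dropped += hi - lo
        for i, (sid, lo, hi) in enumerate(pieces):
            if i in drop:
                continue
            cid = f"{gid}_c{i}"
            contigs[cid] = seq_lookup[sid][lo:hi]
            rows.append((cid, gid, sid, lo, hi))
    return contigs, pd.DataFrame(rows, columns=TRUTH_MAP_COLUMNS)


def write_contigs_fasta(contigs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(contigs):
            fh.write(f">{cid}\n{contigs[cid]}\n")


def make_bins(
    truth_map: pd.DataFrame,
    mode: str = "oracle",
    swap_fraction: float = 0.0,
    drop_fraction: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Contig -> bin membership derived from the truth map.

    "oracle" bins each contig with its source genome. "corrupted"
    additionally reassigns a seeded subset of contigs (about
    ``swap_fraction`` of bases) to a random other bin and unbins about
    ``drop_fraction`` of bases."""
    membership = {r.contig_id: f"bin_{r.genome_id}" for r in truth_map.itertuples()}
    if mode == "oracle":
        return membership
    if mode != "corrupted":
        raise ValueError(f"unknown bin mode {mode!r}")
    if not (0 <= swap_fraction <= 1 and 0 <= drop_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lengths = {r.contig_id: r.end - r.start for r in truth_map.itertuples()}
    total = sum(lengths.values())
    bin_ids = sorted(set(membership.values()))
    order = [truth_map.contig_id.iloc[int(i)] for i in rng.permutation(len(truth_map))]
    swapped = dropped = 0
    for cid in order:
        if swapped < swap_fraction * total:
            others = [b for b in bin_ids if b != membership[cid]]
            if others:
                membership[cid] = others[int(rng.integers(0, len(others)))]
                swapped += lengths[cid]
        elif dropped < drop_fraction * total:
            del membership[cid]
            dropped += lengths[cid]
    return membership


def make_quality_tables(
    evals: list[GenomeEval],
    out_dir: str | Path,
    noise_sd: float = 0.0,
    completeness_bias: float = 0.0,
    contamination_bias: float = 0.0,
    gunc_contamination_threshold: float = 10.0,
    gunc_flip_rate: float = 0.0,
    seed: int = 0,
) -> tuple[Path, Path]:
    """Emit CheckM2-dialect and GUNC-dialect report TSVs from evaluations.

    Completeness = 100*recall + bias + noise (clamped to [0, 100]);
    contamination = 100*(1-precision) + bias + noise (clamped >= 0);
    gunc_pass = (true contamination percent < threshold), flipped at a
    seeded error rate. One row per distinct representative bin."""
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seen: dict[str, GenomeEval] = {}
    for e in evals:
        if e.representative_bin_id is not None:
            seen.setdefault(e.representative_bin_id, e)
    checkm_rows, gunc_rows = [], []
    for bin_id in sorted(seen):
        e = seen[bin_id]
        comp = 100.0 * e.recall + completeness_bias + (
            rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
        )
        cont = 100.0 * (1.0 - e.precision) + contamination_bias + (
            rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
        )
        comp = min(100.0, max(0.0, comp))
        cont = max(0.0, cont)
        checkm_rows.append((bin_id, comp, cont))
        passed = (100.0 * (1.0 - e.precision)) < gunc_contamination_threshold
        if gunc_flip_rate > 0 and rng.random() < gunc_flip_rate:
            passed = not passed
        gunc_rows.append((bin_id, passed))
    checkm_path = out_dir / "checkm2_report.tsv"
    gunc_path = out_dir / "gunc_report.tsv"
    pd.DataFrame(checkm_rows, columns=["Name", "Completeness", "Contamination"]).to_csv(
        checkm_path, sep="\t", index=False
    )
    pd.DataFrame(gunc_rows, columns=["genome", "pass.GUNC"]).to_csv(
        gunc_path, sep="\t", index=False
    )
    return checkm_path, gunc_path
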