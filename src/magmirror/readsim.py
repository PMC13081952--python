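"""Paired-end read simulation from a mirror specification.

Two paths are provided. The built-in sampler generates error-controlled
paired reads with a full provenance table (read -> genome, sequence,
fragment start, strand), suitable for desk-scale pipelines where exact
ground truth is required. For full-scale work the module instead emits the
exact InSilicoSeq command line together with its draft/abundance input
files, leaving execution to the user.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._kmers import revcomp
from .mirror import MirrorSpecification
from .refdb import ReferenceDB

DEFAULT_READ_LENGTH = 126
PHRED_CHAR = "?"  # constant Phred 30


@dataclass
class SimulatedReadSet:
    fastq_r1: Path
    fastq_r2: Path
    provenance: pd.DataFrame  # read_id, genome_id, seq_id, start, strand
    realized_counts: dict[str, int]  # genome_id -> read-pair count


def sequence_weights(
    spec: MirrorSpecification, db: ReferenceDB, length_reweight: bool = False
) -> dict[str, float]:
    """Per-genome read-sampling weights.

    By default specification abundances are used directly as sequence
    abundances (pass-through). With ``length_reweight`` they are treated as
    taxonomic abundances and converted: w_g ∝ abundance_g * length_g.
    """
    w = {}
    for e in spec.entries:
        rec = db.record(e.genome_id)
        w[e.genome_id] = (
            e.relative_abundance * rec.total_length if length_reweight
            else e.relative_abundance
        )
    total = sum(w.values())
    if total <= 0:
        raise ValueError("abundance weights sum to zero")
    return {g: v / total for g, v in w.items()}


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    n = len(read)
    hits = np.flatnonzero(rng.random(n) < rate)
    if hits.size == 0:
        return read
    chars = list(read)
    for i in hits:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[int(rng.integers(0, len(alts)))]
    return "".join(chars)


def simulate_reads(
    spec: MirrorSpecification,
    db: ReferenceDB,
    out_dir: str | Path,
    read_length: int = DEFAULT_READ_LENGTH,
    insert_mean: int = 300,
    insert_sd: int = 25,
    error_rate: float = 0.0,
    seed: int = 0,
    length_reweight: bool = False,
    num_pairs: int | None = None,
) -> SimulatedReadSet:
    """Sample paired-end reads according to the specification abundances.

    Read-pair counts per genome are multinomial over the abundance weights;
    fragments start uniformly on a length-weighted random sequence of the
    genome, on a random strand; mate 2 is the reverse complement of the
    fragment end. Substitution errors are i.i.d. at ``error_rate``; base
    qualities are constant Phred 30. ``spec.num_reads`` is interpreted as
    total read *pairs* by default; pass ``num_pairs`` to override.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    total_pairs = spec.num_reads if num_pairs is None else num_pairs
    if total_pairs <= 0:
        raise ValueError("number of read pairs must be positive")

    weights = sequence_weights(spec, db, length_reweight=length_reweight)
    genome_ids = sorted(weights)
    insert_floor = 2 * read_length
    for gid in genome_ids:
        rec = db.record(gid)
        if max(len(s) for s in rec.seq_strings()) < insert_floor:
            raise ValueError(
                f"genome {gid!r} has no sequence long enough for the insert "
                f"size ({insert_floor} bp)"
            )

    counts = rng.multinomial(total_pairs, [weights[g] for g in genome_ids])
    realized = {g: int(c) for g, c in zip(genome_ids, counts)}

    r1_path = out_dir / f"{spec.sample_id}_R1.fastq"
    r2_path = out_dir / f"{spec.sample_id}_R2.fastq"
    qual = PHRED_CHAR * read_length
    prov_rows: list[tuple[str, str, str, int, str]] = []
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        pair_idx = 0
        for gid in genome_ids:
            n = realized[gid]
            if n == 0:
                continue
            rec = db.record(gid)
            seqs = [(sid, s) for sid, s in rec.sequences if len(s) >= insert_floor]
            lens = np.array([len(s) for _, s in seqs], dtype=float)
            seq_choice = rng.choice(len(seqs), size=n, p=lens / lens.sum())
            inserts = np.clip(
                np.rint(rng.normal(insert_mean, insert_sd, size=n)).astype(int),
                insert_floor,
                None,
            )
            strands = rng.random(n) < 0.5
            u = rng.random(n)
            for j in range(n):
                sid, s = seqs[int(seq_choice[j])]
                ins = min(int(inserts[j]), len(s))
                start = int(u[j] * (len(s) - ins + 1))
                frag = s[start : start + ins]
                strand = "-" if strands[j] else "+"
                if strand == "-":
                    frag = revcomp(frag)
                m1 = _mutate(frag[:read_length], error_rate, rng)
                m2 = _mutate(revcomp(frag[-read_length:]), error_rate, rng)
                rid = f"{spec.sample_id}_p{pair_idx}"
                f1.write(f"@{rid}/1\n{m1}\n+\n{qual}\n")
                f2.write(f"@{rid}/2\n{m2}\n+\n{qual}\n")
                prov_rows.append((rid, gid, sid, start, strand))
                pair_idx += 1

    provenance = pd.DataFrame(
        prov_rows, columns=["read_id", "genome_id", "seq_id", "start", "strand"]
    )
    return SimulatedReadSet(
        fastq_r1=r1_path, fastq_r2=r2_path, provenance=provenance,
        realized_counts=realized,
    )


def write_provenance(readset: SimulatedReadSet, path: str | Path) -> None:
    readset.provenance.to_csv(path, sep="\t", index=False)


def emit_insilicoseq_command(
    spec: MirrorSpecification,
    db: ReferenceDB,
    output_prefix: str | Path,
    length_reweight: bool = False,
) -> str:
    """Write the draft/abundance inputs and return the external-simulator
    command line (InSilicoSeq dialect, HiSeq error model).

    The draft list holds one genome FASTA path per specification entry
    (genomes without a source FASTA are materialized next to the prefix);
    the abundance file holds the sequence abundance of each genome.
    """
    prefix = Path(output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    weights = sequence_weights(spec, db, length_reweight=length_reweight)

    draft_path = prefix.parent / f"{prefix.name}_draft_list.txt"
    abundance_path = prefix.parent / f"{prefix.name}_abundance_list.txt"
    fasta_dir = prefix.parent / f"{prefix.name}_genomes"

    draft_lines = []
    for e in spec.entries:
        rec = db.record(e.genome_id)
        if rec.fasta_path is not None:
            draft_lines.append(str(rec.fasta_path))
        else:
            fasta_dir.mkdir(parents=True, exist_ok=True)
            fp = fasta_dir / f"{e.genome_id}.fasta"
            with open(fp, "w") as fh:
                for sid, s in rec.sequences:
                    fh.write(f">{sid}\n{s}\n")
            draft_lines.append(str(fp))
    draft_path.write_text("\n".join(draft_lines) + "\n")
    abundance_path.write_text(
        "".join(f"{e.genome_id}\t{repr(weights[e.genome_id])}\n" for e in spec.entries)
    )

    cmd = (
        f"iss generate --draft {shlex.quote(str(draft_path))} "
        f"--abundance_file {shlex.quote(str(abundance_path))} "
        f"--n_reads {spec.num_reads} --model HiSeq "
        f"--output {shlex.quote(str(prefix))} --seed {spec.seed}"
    )
    return cmd


def expected_coverage(
    spec: MirrorSpecification,
    db: ReferenceDB,
    genome_id: str,
    read_length: int = DEFAULT_READ_LENGTH,
    pairs: bool = True,
) -> float:
    """Expected fold-coverage of a genome under the specification:
    abundance * num_reads * read_length * (2 if paired) / genome length."""
    rec = db.record(genome_id)
    if rec.total_length == 0:
        raise ValueError(f"genome {genome_id!r} has zero length")
    ab = spec.abundance_of(genome_id)
    return ab * spec.num_reads * read_length * (2 if pairs else 1) / rec.total_length
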