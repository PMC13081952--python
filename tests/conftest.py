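from __future__ import annotations

import numpy as np
import pytest

from magmirror.fixtures import FixtureSpec, fragment_assembly, generate_collection
from magmirror.groundtruth import filter_qualifying, oracle_align
from magmirror.refdb import GenomeRecord, cluster_strains


def make_record(
    genome_id: str,
    length: int = 1000,
    seed: int = 0,
    is_isolate: bool = False,
    species: str = "spX",
    n_seqs: int = 1,
    representative: bool = False,
) -> GenomeRecord:
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    per = length // n_seqs
    seqs = [
        (f"{genome_id}_s{i}", "".join(bases[rng.integers(0, 4, per)]))
        for i in range(n_seqs)
    ]
    return GenomeRecord(
        genome_id=genome_id,
        sequences=seqs,
        is_isolate=is_isolate,
        species_cluster_id=species,
        is_species_representative=representative,
    )


@pytest.fixture(scope="session")
def small_collection():
    """3 species (2+2+1 strains), clustered, with a fragmented assembly
    and its qualifying contig->genome map."""
    fspec = FixtureSpec(
        seed=42, n_species=3, strains_per_species=[2, 2, 1], genome_length=25_000,
        strain_substitution_rate=0.01,
    )
    db, truth = generate_collection(fspec)
    cluster_strains(db)
    contigs, truth_map = fragment_assembly(db, mean_len=2000, seed=42)
    lengths = {cid: len(s) for cid, s in contigs.items()}
    cmap = filter_qualifying(oracle_align(contigs, list(db.genomes.values())), lengths)
    return {
        "db": db,
        "truth": truth,
        "contigs": contigs,
        "truth_map": truth_map,
        "cmap": cmap,
    }
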