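"""Score binning results at base-pair resolution against ground truth.

Fragments a genome collection into an 'assembly', maps contigs back with
the exact aligner, then compares a perfect (oracle) binning with a
deliberately corrupted one. Recall = recovered fraction of each genome;
precision = fraction of the representative bin that truly belongs to it.
"""

from magmirror import evaluate_bins, evals_to_frame, recoverable_set
from magmirror.evaluator import bins_from_membership
from magmirror.fixtures import FixtureSpec, fragment_assembly, generate_collection, make_bins
from magmirror.groundtruth import filter_qualifying, oracle_align

db, _ = generate_collection(
    FixtureSpec(seed=3, n_species=3, strains_per_species=[1, 1, 1],
                genome_length=25_000)
)
contigs, truth_map = fragment_assembly(db, mean_len=2000, seed=3)
lengths = {c: len(s) for c, s in contigs.items()}
cmap = filter_qualifying(oracle_align(contigs, list(db.genomes.values())), lengths)
genomes = list(db.genomes.values())

for label, kwargs in [("oracle", {}),
                      ("corrupted", dict(mode="corrupted", swap_fraction=0.15,
                                         drop_fraction=0.10, seed=3))]:
    bins = bins_from_membership(make_bins(truth_map, **kwargs))
    evals = evaluate_bins(genomes, bins, cmap, sample_id="s0", pipeline=label)
    print(f"\n{label} binning:")
    print(evals_to_frame(evals)[
        ["genome_id", "representative_bin_id", "tp_bp", "fn_bp", "fp_bp",
         "recall", "precision", "fscore"]
    ].round(3).to_string(index=False))
    rec = recoverable_set(evals)
    print(f"recoverable (recall>=0.7 & precision>=0.9): {sorted(g for g, _ in rec)}")

print("\nThe oracle pipeline scores 1.0 everywhere; swapping 15% and dropping")
print("10% of contig bases shows up directly in the TP/FP base-pair accounting.")
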