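import numpy as np
import pandas as pd
import pytest

from magmirror.contigs import composition_distance, tetranucleotide_composition
from magmirror.evaluator import (
    GenomeEval,
    bins_from_membership,
    classify_mimag,
    evaluate_bins,
    read_checkm2_report,
    read_gunc_report,
)
from magmirror.fixtures import (
    FixtureSpec,
    fragment_assembly,
    generate_collection,
    make_bins,
    make_quality_tables,
)
from magmirror.groundtruth import filter_qualifying, oracle_align
from magmirror.refdb import estimate_ani


class TestGenerateCollection:
    @pytest.mark.parametrize("seed", range(5))
    def test_ani_separates_within_and_between_species(self, seed):
        db, _ = generate_collection(
            FixtureSpec(seed=seed, n_species=2, strains_per_species=[2, 2],
                        genome_length=15_000, strain_substitution_rate=0.01)
        )
        within = estimate_ani(db.record("sp0_st0"), db.record("sp0_st1"))
        between = estimate_ani(db.record("sp0_st0"), db.record("sp1_st0"))
        assert within >= 98.0
        assert between <= 85.0

    def test_planted_shared_segment_found_in_both_genomes(self):
        fspec = FixtureSpec(
            seed=2, n_species=2, strains_per_species=[1, 1], genome_length=20_000,
            shared_segment_plan=[("sp0_st0", "sp1_st0", 5000)],
        )
        db, truth = generate_collection(fspec)
        (donor, recipient, d_start, r_start, length) = truth.shared_segments[0]
        segment = db.record(donor).sequences[0][1][d_start : d_start + length]
        recs = oracle_align({"shared": segment}, list(db.genomes.values()))
        assert {r.genome_id for r in recs} == {donor, recipient}

    def test_prophage_intervals_recorded_exactly(self):
        fspec = FixtureSpec(
            seed=3, n_species=1, strains_per_species=[1], genome_length=20_000,
            prophage_plan=[("sp0_st0", 3000, 5000)],
        )
        db, truth = generate_collection(fspec)
        assert truth.prophages == {"sp0_st0": [(5000, 8000)]}
        assert db.record("sp0_st0").total_length == 23_000

    def test_prophage_composition_is_distinct(self):
        fspec = FixtureSpec(
            seed=4, n_species=1, strains_per_species=[1], genome_length=30_000,
            prophage_plan=[("sp0_st0", 5000, 10_000)],
        )
        db, truth = generate_collection(fspec)
        seq = db.record("sp0_st0").sequences[0][1]
        (lo, hi) = truth.prophages["sp0_st0"][0]
        host = tetranucleotide_composition(seq[:lo])
        phage = tetranucleotide_composition(seq[lo:hi])
        host2 = tetranucleotide_composition(seq[hi:])
        assert composition_distance(phage, host) > 3 * composition_distance(host2, host)

    def test_overlapping_prophage_plan_rejected(self):
        fspec = FixtureSpec(
            seed=5, n_species=1, strains_per_species=[1], genome_length=20_000,
            prophage_plan=[("sp0_st0", 3000, 5000), ("sp0_st0", 1000, 6000)],
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_collection(fspec)

    def test_seed_determinism(self):
        fspec = FixtureSpec(seed=6, n_species=2, strains_per_species=[2, 1],
                            genome_length=5000)
        a, _ = generate_collection(fspec)
        b, _ = generate_collection(fspec)
        assert all(
            a.record(g).sequences == b.record(g).sequences for g in a.genomes
        )


class TestFragmentAssembly:
    def test_zero_loss_tiles_each_genome_exactly(self):
        db, _ = generate_collection(
            FixtureSpec(seed=7, n_species=1, strains_per_species=[2],
                        genome_length=30_000)
        )
        contigs, truth_map = fragment_assembly(db, mean_len=2000, seed=1)
        for gid, grp in truth_map.groupby("genome_id"):
            ivs = sorted((r.start, r.end) for r in grp.itertuples())
            assert ivs[0][0] == 0
            assert ivs[-1][1] == db.record(gid).total_length
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                assert b == c  # contiguous, no gaps or overlaps

    def test_contigs_are_exact_substrings(self):
        db, _ = generate_collection(
            FixtureSpec(seed=8, n_species=1, strains_per_species=[1],
                        genome_length=20_000)
        )
        contigs, truth_map = fragment_assembly(db, mean_len=1500, seed=2)
        seq = db.record("sp0_st0").sequences[0][1]
        for r in truth_map.itertuples():
            assert contigs[r.contig_id] == seq[r.start : r.end]

    def test_loss_fraction_accounting(self):
        db, _ = generate_collection(
            FixtureSpec(seed=9, n_species=1, strains_per_species=[1],
                        genome_length=50_000)
        )
        contigs, truth_map = fragment_assembly(db, mean_len=2000, loss_fraction=0.3,
                                               seed=3)
        retained = sum(len(s) for s in contigs.values())
        max_len = max(r.end - r.start for r in truth_map.itertuples())
        assert 0.7 * 50_000 - max_len <= retained <= 0.7 * 50_000

    def test_seed_determinism(self):
        db, _ = generate_collection(
            FixtureSpec(seed=10, n_species=1, strains_per_species=[1],
                        genome_length=10_000)
        )
        a = fragment_assembly(db, seed=4)
        b = fragment_assembly(db, seed=4)
        assert a[0] == b[0]
        assert a[1].equals(b[1])


class TestMakeBins:
    def _pipeline(self, seed=11, loss=0.0):
        db, _ = generate_collection(
            FixtureSpec(seed=seed, n_species=2, strains_per_species=[1, 1],
                        genome_length=20_000)
        )
        contigs, truth_map = fragment_assembly(db, mean_len=2000, loss_fraction=loss,
                                               seed=seed)
        lengths = {c: len(s) for c, s in contigs.items()}
        cmap = filter_qualifying(oracle_align(contigs, list(db.genomes.values())),
                                 lengths)
        return db, contigs, truth_map, cmap

    def test_oracle_bins_give_perfect_scores_at_zero_loss(self):
        db, _, truth_map, cmap = self._pipeline()
        bins = bins_from_membership(make_bins(truth_map))
        for e in evaluate_bins(list(db.genomes.values()), bins, cmap):
            assert e.recall == e.precision == e.fscore == 1.0

    def test_dropping_contigs_reduces_tp_by_exactly_their_span(self):
        db, _, truth_map, cmap = self._pipeline(seed=12)
        membership = make_bins(truth_map)
        g0 = truth_map[truth_map.genome_id == "sp0_st0"]
        victims = g0.head(3)
        dropped_bp = int((victims.end - victims.start).sum())
        for cid in victims.contig_id:
            del membership[cid]
        bins = bins_from_membership(membership)
        e = [x for x in evaluate_bins(list(db.genomes.values()), bins, cmap)
             if x.genome_id == "sp0_st0"][0]
        assert e.tp_bp == db.record("sp0_st0").total_length - dropped_bp

    def test_injected_foreign_contig_sets_fp_exactly(self):
        db, contigs, truth_map, cmap = self._pipeline(seed=13)
        membership = make_bins(truth_map)
        foreign = truth_map[truth_map.genome_id == "sp1_st0"].iloc[0]
        membership[foreign.contig_id] = "bin_sp0_st0"
        bins = bins_from_membership(membership)
        e = [x for x in evaluate_bins(list(db.genomes.values()), bins, cmap)
             if x.genome_id == "sp0_st0"][0]
        assert e.fp_bp == foreign.end - foreign.start

    def test_corrupted_mode_is_deterministic(self):
        _, _, truth_map, _ = self._pipeline(seed=14)
        a = make_bins(truth_map, mode="corrupted", swap_fraction=0.2,
                      drop_fraction=0.1, seed=5)
        b = make_bins(truth_map, mode="corrupted", swap_fraction=0.2,
                      drop_fraction=0.1, seed=5)
        assert a == b


class TestMakeQualityTables:
    def _evals(self, n=4):
        rng = np.random.default_rng(0)
        return [
            GenomeEval(f"g{i}", "s", "p", f"b{i}", 0, 0, 0,
                       float(rng.uniform(0.2, 1.0)), float(rng.uniform(0.5, 1.0)), 0.0)
            for i in range(n)
        ]

    def test_zero_noise_matches_true_classification(self, tmp_path):
        evals = self._evals()
        cpath, gpath = make_quality_tables(evals, tmp_path)
        tab = read_checkm2_report(cpath)
        by_bin = {e.representative_bin_id: e for e in evals}
        for r in tab.itertuples(index=False):
            e = by_bin[r.bin_id]
            assert r.mimag_class == classify_mimag(
                100 * e.recall, 100 * (1 - e.precision)
            )

    def test_positive_bias_shifts_mean_completeness(self, tmp_path):
        rng = np.random.default_rng(1)
        evals = [
            GenomeEval(f"g{i}", "s", "p", f"b{i}", 0, 0, 0,
                       float(rng.uniform(0.3, 0.8)), 1.0, 0.0)
            for i in range(1000)
        ]
        cpath, _ = make_quality_tables(evals, tmp_path, noise_sd=1.0,
                                       completeness_bias=10.0, seed=2)
        tab = read_checkm2_report(cpath)
        recall = {e.representative_bin_id: e.recall for e in evals}
        diffs = [r.checkm2_completeness - 100 * recall[r.bin_id]
                 for r in tab.itertuples(index=False)]
        assert abs(np.mean(diffs) - 10.0) < 0.5

    def test_gunc_dialect_round_trips(self, tmp_path):
        evals = self._evals()
        _, gpath = make_quality_tables(evals, tmp_path,
                                       gunc_contamination_threshold=20.0)
        flags = read_gunc_report(gpath)
        for e in evals:
            assert flags[e.representative_bin_id] == (100 * (1 - e.precision) < 20.0)
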