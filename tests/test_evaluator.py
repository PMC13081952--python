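import numpy as np
import pandas as pd
import pytest

from conftest import make_record
from oracles import per_base_assembled, per_base_fp, per_base_tp

from magmirror.evaluator import (
    GenomeEval,
    apply_gunc_filter,
    assembly_recall,
    bins_from_membership,
    classify_mimag,
    coverage_filter,
    evaluate_bins,
    genome_bin_recall,
    genome_precision,
    read_bin_table,
    read_checkm2_report,
    read_gunc_report,
    recoverable_set,
    select_representative,
    union_size,
)
from magmirror.fixtures import make_bins
from magmirror.groundtruth import ContigGenomeMap, Hit
from magmirror.mirror import MirrorEntry, MirrorSpecification
from magmirror.refdb import GenomeRecord, ReferenceDB, SpeciesCluster


def hit(gid, g0, g1, c0=None, c1=None, seq=None):
    return Hit(gid, seq or f"{gid}_s0", g0, g1, c0 if c0 is not None else 0,
               c1 if c1 is not None else g1 - g0)


def genome(gid="gA", length=10_000):
    return GenomeRecord(gid, [(f"{gid}_s0", "A" * length)], True, "sp")


class TestGenomeBinRecall:
    def test_overlapping_intervals_union_once(self):
        g = genome()
        cmap = ContigGenomeMap(
            contig_lengths={"c1": 4000, "c2": 5000},
            hits={"c1": [hit("gA", 0, 4000)], "c2": [hit("gA", 3000, 8000)]},
        )
        tp, fn = genome_bin_recall(g, {"c1", "c2"}, cmap)
        assert (tp, fn) == (8000, 2000)

    def test_empty_bin(self):
        g = genome()
        cmap = ContigGenomeMap(contig_lengths={})
        assert genome_bin_recall(g, set(), cmap) == (0, 10_000)

    def test_identical_intervals_counted_once(self):
        g = genome()
        cmap = ContigGenomeMap(
            contig_lengths={"c1": 1000, "c2": 1000},
            hits={"c1": [hit("gA", 0, 1000)], "c2": [hit("gA", 0, 1000)]},
        )
        assert genome_bin_recall(g, {"c1", "c2"}, cmap)[0] == 1000

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        g = genome(length=int(rng.integers(5000, 50_000)))
        contigs = {}
        hits = {}
        for i in range(int(rng.integers(1, 30))):
            lo = int(rng.integers(0, g.total_length - 100))
            hi = int(rng.integers(lo + 1, min(g.total_length, lo + 5000)))
            cid = f"c{i}"
            contigs[cid] = hi - lo
            hits[cid] = [hit("gA", lo, hi)]
        cmap = ContigGenomeMap(contig_lengths=contigs, hits=hits)
        bin_contigs = set(contigs)
        tp, fn = genome_bin_recall(g, bin_contigs, cmap)
        assert tp == per_base_tp(g, bin_contigs, cmap)
        assert tp + fn == g.total_length


class TestSelectRepresentative:
    def _cmap(self):
        return ContigGenomeMap(
            contig_lengths={"c1": 4000, "c2": 9000, "c3": 5000},
            hits={
                "c1": [hit("gA", 0, 4000)],
                "c2": [hit("gA", 0, 9000)],
                "c3": [hit("gA", 0, 5000)],
            },
        )

    def test_highest_recall_wins(self):
        rep, tp, fn = select_representative(
            genome(), {"b1": {"c1"}, "b2": {"c2"}}, self._cmap()
        )
        assert (rep, tp) == ("b2", 9000)

    def test_ties_break_to_smallest_bin_id(self):
        rep, _, _ = select_representative(
            genome(), {"b2": {"c3"}, "b1": {"c3"}}, self._cmap()
        )
        assert rep == "b1"

    def test_no_bins_returns_none(self):
        rep, tp, fn = select_representative(genome(), {}, self._cmap())
        assert (rep, tp, fn) == (None, 0, 10_000)

    def test_same_bin_can_represent_two_genomes(self):
        gA, gB = genome("gA", 5000), genome("gB", 5000)
        cmap = ContigGenomeMap(
            contig_lengths={"c1": 5000},
            hits={"c1": [hit("gA", 0, 5000), hit("gB", 0, 5000)]},
        )
        bins = {"b1": {"c1"}}
        assert select_representative(gA, bins, cmap)[0] == "b1"
        assert select_representative(gB, bins, cmap)[0] == "b1"


class TestGenomePrecision:
    def test_foreign_contig_counts_fully_as_fp(self):
        g = genome()
        cmap = ContigGenomeMap(
            contig_lengths={"c1": 5000, "foreign": 1000},
            hits={"c1": [hit("gA", 0, 5000)]},  # foreign has no hits to gA
        )
        fp, precision, fscore = genome_precision(g, {"c1", "foreign"}, cmap, tp=5000)
        assert fp == 1000
        assert precision == pytest.approx(5000 / 6000)

    def test_fully_mapping_bin_has_precision_one(self):
        g = genome(length=5000)
        cmap = ContigGenomeMap(
            contig_lengths={"c1": 5000}, hits={"c1": [hit("gA", 0, 5000)]}
        )
        fp, precision, _ = genome_precision(g, {"c1"}, cmap, tp=5000)
        assert (fp, precision) == (0, 1.0)

    def test_fscore_is_harmonic_mean(self):
        g = genome()
        # tp 8000 of 10000 -> recall .8; choose fp to make precision .8
        cmap = ContigGenomeMap(
            contig_lengths={"c1": 8000, "x": 2000},
            hits={"c1": [hit("gA", 0, 8000)]},
        )
        _, precision, fscore = genome_precision(g, {"c1", "x"}, cmap, tp=8000)
        assert precision == pytest.approx(0.8)
        assert fscore == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = genome(length=20_000)
        contigs, hits = {}, {}
        for i in range(10):
            lc = int(rng.integers(200, 3000))
            cid = f"c{i}"
            contigs[cid] = lc
            if rng.random() < 0.7:
                lo = int(rng.integers(0, g.total_length - lc))
                c0 = int(rng.integers(0, lc // 2))
                c1 = int(rng.integers(c0 + 1, lc + 1))
                hits[cid] = [hit("gA", lo, lo + (c1 - c0), c0, c1)]
        cmap = ContigGenomeMap(contig_lengths=contigs, hits=hits)
        bin_contigs = set(contigs)
        tp, _ = genome_bin_recall(g, bin_contigs, cmap)
        fp, _, _ = genome_precision(g, bin_contigs, cmap, tp)
        assert fp == per_base_fp(g, bin_contigs, cmap)


class TestRecoverableSet:
    def e(self, gid, sample, pipeline, recall, precision):
        return GenomeEval(gid, sample, pipeline, "b", 0, 0, 0, recall, precision, 0.0)

    def test_single_passing_pipeline_suffices(self):
        evals = [self.e("g", "s", "p1", 0.71, 0.91), self.e("g", "s", "p2", 0.1, 0.1)]
        assert recoverable_set(evals) == {("g", "s")}

    def test_conjunction_required_within_one_pipeline(self):
        evals = [self.e("g", "s", "p1", 0.9, 0.89), self.e("g", "s", "p2", 0.69, 0.99)]
        assert recoverable_set(evals) == set()

    def test_thresholds_inclusive(self):
        assert recoverable_set([self.e("g", "s", "p", 0.7, 0.9)]) == {("g", "s")}
        assert recoverable_set([self.e("g", "s", "p", 0.6999, 0.9)]) == set()


class TestCoverageFilter:
    def _setup(self, abundance):
        g = GenomeRecord("g", [("s0", "A" * 400_000)], True, "sp", True)
        other = GenomeRecord("o", [("s0", "C" * 400_000)], True, "sp2", True)
        db = ReferenceDB(
            genomes={"g": g, "o": other},
            species_clusters={"sp": SpeciesCluster("sp", ["g"], "g"),
                              "sp2": SpeciesCluster("sp2", ["o"], "o")},
        )
        spec = MirrorSpecification(
            "s",
            [MirrorEntry("g", abundance, "species_fallback"),
             MirrorEntry("o", 1 - abundance, "species_fallback")],
            num_reads=10_000, seed=0,
        )
        return spec, db

    def test_boundary_inclusive(self):
        spec, db = self._setup(0.5)  # exactly 2.5x at read length 100
        assert "g" in coverage_filter(spec, db, read_length=100)

    def test_just_below_dropped(self):
        spec, db = self._setup(0.498)
        assert "g" not in coverage_filter(spec, db, read_length=100)

    def test_zero_threshold_keeps_all(self):
        spec, db = self._setup(0.1)
        assert coverage_filter(spec, db, threshold=0.0) == {"g", "o"}


class TestClassifyMimag:
    @pytest.mark.parametrize(
        "completeness,contamination,expected",
        [
            (95, 3, "HQ"),
            (95, 8, "MQ"),  # contamination too high for HQ
            (90, 4, "MQ"),  # completeness must exceed 90 for HQ
            (50, 9.9, "MQ"),
            (49.9, 9.9, "LQ"),
            (40, 12, "UNCLASSIFIED"),
            (95, 150, "UNCLASSIFIED"),  # estimates can exceed 100%
        ],
    )
    def test_classes(self, completeness, contamination, expected):
        assert classify_mimag(completeness, contamination) == expected

    def test_out_of_range_completeness_rejected(self):
        with pytest.raises(ValueError):
            classify_mimag(101, 0)


class TestGuncFilter:
    def _evals(self):
        return [
            GenomeEval("g1", "s", "p", "b1", 0, 0, 0, 0.9, 0.95, 0.92),
            GenomeEval("g2", "s", "p", "b2", 0, 0, 0, 0.8, 0.85, 0.82),
            GenomeEval("g3", "s", "p", "b3", 0, 0, 0, 0.4, 0.99, 0.57),
            GenomeEval("g4", "s", "p", "b4", 0, 0, 0, 0.6, 0.70, 0.65),
        ]

    def test_all_pass_is_identity(self):
        evals = self._evals()
        kept, summary = apply_gunc_filter(evals, {f"b{i}": True for i in range(1, 5)})
        assert kept == evals
        assert summary.removed_fraction == 0.0

    def test_half_fail_removes_half_with_hand_computed_means(self):
        kept, summary = apply_gunc_filter(
            self._evals(), {"b1": True, "b2": False, "b3": True, "b4": False}
        )
        assert [e.genome_id for e in kept] == ["g1", "g3"]
        assert summary.removed_fraction == 0.5
        assert summary.removed_mean_recall == pytest.approx((0.8 + 0.6) / 2)
        assert summary.removed_mean_one_minus_precision == pytest.approx(
            (0.15 + 0.30) / 2
        )

    def test_missing_bin_is_error_by_default_but_can_pass(self):
        with pytest.raises(KeyError):
            apply_gunc_filter(self._evals(), {"b1": True})
        kept, _ = apply_gunc_filter(self._evals(), {"b1": True}, missing="pass")
        assert len(kept) == 4


class TestAssemblyRecall:
    def test_half_assembled_genome_fully_binned(self):
        g = genome()
        cmap = ContigGenomeMap(
            contig_lengths={"c1": 5000}, hits={"c1": [hit("gA", 0, 5000)]}
        )
        bins = {"b1": {"c1"}}
        assert assembly_recall(g, bins, cmap) == 1.0
        _, tp, _ = select_representative(g, bins, cmap)
        assert tp / g.total_length == 0.5

    def test_nothing_assembled_is_missing(self):
        g = genome()
        cmap = ContigGenomeMap(contig_lengths={})
        assert assembly_recall(g, {}, cmap) is None

    def test_fully_assembled_equals_plain_recall(self, small_collection):
        db, cmap = small_collection["db"], small_collection["cmap"]
        bins = bins_from_membership(make_bins(small_collection["truth_map"]))
        for gid in db.genomes:
            g = db.record(gid)
            ar = assembly_recall(g, bins, cmap)
            _, tp, _ = select_representative(g, bins, cmap)
            assert per_base_assembled(g, cmap) == g.total_length
            assert ar == pytest.approx(tp / g.total_length)


class TestAdapters:
    def test_bin_table_round_trip_and_prefix_strip(self, tmp_path):
        path = tmp_path / "bins.tsv"
        pd.DataFrame(
            [("s1|c1", "b1"), ("s1|c2", "b2")], columns=["contig_id", "bin_id"]
        ).to_csv(path, sep="\t", index=False)
        assert read_bin_table(path, sample_prefix_delim="|") == {"c1": "b1", "c2": "b2"}

    def test_contig_in_two_bins_rejected(self, tmp_path):
        path = tmp_path / "bins.tsv"
        pd.DataFrame(
            [("c1", "b1"), ("c1", "b2")], columns=["contig_id", "bin_id"]
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError):
            read_bin_table(path)

    def test_checkm2_and_gunc_dialects(self, tmp_path):
        cpath = tmp_path / "checkm2.tsv"
        pd.DataFrame(
            [("b1", 95.0, 2.0), ("b2", 55.0, 8.0)],
            columns=["Name", "Completeness", "Contamination"],
        ).to_csv(cpath, sep="\t", index=False)
        tab = read_checkm2_report(cpath)
        assert list(tab.mimag_class) == ["HQ", "MQ"]
        gpath = tmp_path / "gunc.tsv"
        pd.DataFrame(
            [("b1", True), ("b2", False)], columns=["genome", "pass.GUNC"]
        ).to_csv(gpath, sep="\t", index=False)
        assert read_gunc_report(gpath) == {"b1": True, "b2": False}


class TestUnionSize:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_boolean_array(self, seed):
        rng = np.random.default_rng(seed)
        ivs = []
        mask = np.zeros(10_000, dtype=bool)
        for _ in range(20):
            lo = int(rng.integers(0, 9000))
            hi = int(rng.integers(lo, min(10_000, lo + 2000)))
            ivs.append((lo, hi))
            mask[lo:hi] = True
        assert union_size(ivs) == int(mask.sum())
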