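"""Gene mapping and burden feature construction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cnvclassify import CnvRecord, GeneModel, GeneSetCollection, Subject
from cnvclassify.features import (
    SetSizeFilter,
    build_features,
    define_subsets,
    filter_sets,
    map_cnv_to_genes,
    randomize_features,
)


def gene(gid, chrom, start, end, exons=None):
    return GeneModel(gid, chrom, ((start, end),), tuple(exons) if exons else None)


class TestMapCnvToGenes:
    def test_transcript_overlap_maps_and_chrom_mismatch_does_not(self):
        genes = [gene("A", "chr1", 150, 300), gene("B", "chr2", 100, 200)]
        recs = [CnvRecord("S", "chr1", 100, 200, "loss")]
        assert map_cnv_to_genes(recs, genes) == [frozenset({"A"})]

    def test_exonic_mode_requires_exon_data(self):
        genes = [gene("A", "chr1", 0, 1000)]
        with pytest.raises(ValueError, match="exon"):
            map_cnv_to_genes([CnvRecord("S", "chr1", 0, 500, "loss")], genes, mode="exonic")

    def test_exonic_mode_is_stricter(self):
        g = gene("A", "chr1", 0, 10_000, exons=[(0, 100), (9_000, 10_000)])
        cnv_intronic = CnvRecord("S", "chr1", 500, 8_000, "loss")
        assert map_cnv_to_genes([cnv_intronic], [g], mode="transcript") == [frozenset({"A"})]
        assert map_cnv_to_genes([cnv_intronic], [g], mode="exonic") == [frozenset()]

    @pytest.mark.parametrize("mode", ["transcript", "exonic"])
    def test_matches_brute_force_interval_scan(self, mode):
        rng = np.random.default_rng(2)
        genes = []
        for i in range(50):
            s = int(rng.integers(0, 2_000_000))
            e = s + int(rng.integers(1_000, 100_000))
            mid = (s + e) // 2
            genes.append(gene(f"G{i}", f"chr{1 + i % 3}", s, e, exons=[(s, mid), (mid + 10, e)]))
        recs = [
            CnvRecord(
                "S",
                f"chr{1 + int(rng.integers(0, 3))}",
                int(start := rng.integers(0, 2_000_000)),
                int(start) + int(rng.integers(30_000, 500_000)),
                "loss",
            )
            for _ in range(30)
        ]
        got = map_cnv_to_genes(recs, genes, mode=mode)
        for rec, mapped in zip(recs, got):
            expected = set()
            for g in genes:
                if g.chrom != rec.chrom:
                    continue
                ivs = g.transcript_intervals if mode == "transcript" else g.exon_intervals
                if any(s < rec.end and e > rec.start for s, e in ivs):
                    expected.add(g.gene_id)
            assert mapped == expected


def tiny_collection(sets, universe):
    return GeneSetCollection(
        sets={k: ("", frozenset(v)) for k, v in sets.items()}, universe=frozenset(universe)
    )


class TestBuildFeatures:
    def setup_method(self):
        self.universe = [f"G{i}" for i in range(6)]
        self.genes = [gene(g, "chr1", i * 1000, i * 1000 + 500) for i, g in enumerate(self.universe)]

    def _run(self, subjects, recs, sets, scope="all"):
        gm = map_cnv_to_genes(recs, self.genes)
        return build_features(subjects, recs, gm, tiny_collection(sets, self.universe), scope=scope)

    def test_counts_distinct_genes_not_events(self):
        subj = [Subject("S", "case")]
        recs = [
            CnvRecord("S", "chr1", 0, 100, "loss"),  # hits G0
            CnvRecord("S", "chr1", 200, 400, "loss"),  # hits G0 again
            CnvRecord("S", "chr1", 1000, 1100, "loss"),  # hits G1
        ]
        m = self._run(subj, recs, {"S1": {"G0", "G2"}})
        assert m.values_df.loc["S", "S1_loss"] == 1  # distinct genes, not events
        assert m.values_df.loc["S", "total_count"] == 2

    def test_set_intersection_counts_only_members(self):
        subj = [Subject("S", "case")]
        recs = [CnvRecord("S", "chr1", 0, 1400, "loss")]  # hits G0, G1
        m = self._run(subj, recs, {"S1": {"G1", "G3"}})
        assert m.values_df.loc["S", "S1_loss"] == 1

    def test_zero_burden_subjects_dropped_but_reported(self):
        subj = [Subject("A", "case"), Subject("B", "control")]
        recs = [CnvRecord("A", "chr1", 0, 100, "loss")]
        m = self._run(subj, recs, {"S1": {"G0"}})
        assert m.subjects == ["A"] and m.dropped_subjects == ["B"]

    def test_loss_only_scope_has_no_gain_columns(self):
        subj = [Subject("A", "case")]
        recs = [
            CnvRecord("A", "chr1", 0, 100, "loss"),
            CnvRecord("A", "chr1", 1000, 1100, "gain"),
        ]
        m = self._run(subj, recs, {"S1": {"G0", "G1"}}, scope="loss_only")
        assert all(not c.endswith("_gain") for c in m.feature_names)
        # total restricted to losses: the gain-hit gene G1 is not counted
        assert m.values_df.loc["A", "total_count"] == 1

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        subjects = [Subject(f"S{i}", "case" if i % 2 else "control") for i in range(5)]
        recs = []
        for s in subjects:
            for _ in range(rng.integers(1, 4)):
                start = int(rng.integers(0, 5)) * 1000
                recs.append(
                    CnvRecord(
                        s.subject_id,
                        "chr1",
                        start,
                        start + int(rng.integers(100, 2500)),
                        "loss" if rng.random() < 0.5 else "gain",
                    )
                )
        sets = {
            "A": {"G0", "G1", "G2"},
            "B": {"G2", "G3"},
            "C": {"G0", "G5"},
        }
        gm = map_cnv_to_genes(recs, self.genes)
        m = self._run(subjects, recs, sets)
        for s in subjects:
            hit = {"loss": set(), "gain": set()}
            for rec, genes_hit in zip(recs, gm):
                if rec.subject_id == s.subject_id:
                    hit[rec.dosage] |= genes_hit
            if not (hit["loss"] | hit["gain"]):
                assert s.subject_id in m.dropped_subjects
                continue
            for name, members in sets.items():
                assert m.values_df.loc[s.subject_id, f"{name}_loss"] == len(hit["loss"] & members)
                assert m.values_df.loc[s.subject_id, f"{name}_gain"] == len(hit["gain"] & members)
            assert m.values_df.loc[s.subject_id, "total_count"] == len(hit["loss"] | hit["gain"])

    def test_partition_conservation_on_singleton_sets(self):
        # singleton sets covering the universe: loss counts sum to the
        # subject's distinct lost-gene count
        subj = [Subject("S", "case")]
        recs = [
            CnvRecord("S", "chr1", 0, 1400, "loss"),
            CnvRecord("S", "chr1", 3000, 3100, "loss"),
        ]
        singletons = {g: {g} for g in self.universe}
        m = self._run(subj, recs, singletons, scope="loss_only")
        loss_cols = [c for c in m.feature_names if c.endswith("_loss")]
        assert m.values_df.loc["S", loss_cols].sum() == m.values_df.loc["S", "total_count"]


class TestFilterSets:
    def test_bounds_are_inclusive(self):
        sizes = {f"s{n}": {f"g{i}" for i in range(n)} for n in (99, 100, 3000, 3001)}
        coll = tiny_collection(sizes, {f"g{i}" for i in range(3001)})
        kept = filter_sets(coll, SetSizeFilter(100, 3000))
        assert set(kept) == {"s100", "s3000"}

    def test_min_only_bound(self):
        sizes = {f"s{n}": {f"g{i}" for i in range(n)} for n in (49, 50)}
        coll = tiny_collection(sizes, {f"g{i}" for i in range(50)})
        assert set(filter_sets(coll, SetSizeFilter(min_size=50))) == {"s50"}

    def test_empty_result_warns(self):
        coll = tiny_collection({"s2": {"a", "b"}}, {"a", "b"})
        with pytest.warns(UserWarning):
            out = filter_sets(coll, SetSizeFilter(min_size=10))
        assert len(out) == 0


class TestRandomizeFeatures:
    def test_identity_permutation_is_noop(self):
        coll = tiny_collection({"A": {"g1", "g2"}}, {"g1", "g2", "g3"})
        out = randomize_features(coll, permutation={g: g for g in coll.universe})
        assert out.members("A") == coll.members("A")

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_cardinalities_preserved(self, seed):
        coll = tiny_collection(
            {"A": {"g1", "g2"}, "B": {"g3", "g4", "g5"}}, {f"g{i}" for i in range(1, 9)}
        )
        out = randomize_features(coll, seed=seed)
        assert out.sizes() == coll.sizes()

    def test_expected_count_over_all_permutations(self):
        # universe of 6, set of size 2, subject hitting 3 genes: the mean
        # randomized count over all 720 permutations is 2 * 3/6 = 1.0
        universe = [f"g{i}" for i in range(6)]
        coll = tiny_collection({"A": {"g0", "g1"}}, universe)
        hit = {"g0", "g2", "g4"}
        counts = []
        for perm in itertools.permutations(universe):
            mapping = dict(zip(universe, perm))
            out = randomize_features(coll, permutation=mapping)
            counts.append(len(out.members("A") & hit))
        assert np.mean(counts) == pytest.approx(1.0)


class TestDefineSubsets:
    def test_flags_from_single_records(self):
        genes = [gene("A", "chr1", 0, 1000)]
        subjects = [Subject("L", "case"), Subject("N", "case"), Subject("C", "control")]
        recs = [
            CnvRecord("L", "chr1", 0, 500, "loss"),
            CnvRecord("N", "chr2", 0, 500, "loss"),  # non-genic: chr2 has no gene
        ]
        gm = map_cnv_to_genes(recs, genes)
        flags = define_subsets(subjects, recs, gm)
        assert flags.loc["L", "any_genic"] and flags.loc["L", "loss_carrier"]
        assert not flags.loc["L", ["gain_carrier", "de_novo_carrier", "pathogenic_carrier"]].any()
        assert not flags.loc["N"].any()  # non-genic CNV sets no flags
        assert not flags.loc["C"].any()

    def test_flag_counts_match_brute_force(self, signal_cohort):
        gm = map_cnv_to_genes(signal_cohort.records, signal_cohort.gene_models)
        flags = define_subsets(signal_cohort.subjects, signal_cohort.records, gm)
        expected = {f: set() for f in flags.columns}
        for rec, genes_hit in zip(signal_cohort.records, gm):
            if not genes_hit:
                continue
            expected["any_genic"].add(rec.subject_id)
            expected["loss_carrier" if rec.dosage == "loss" else "gain_carrier"].add(rec.subject_id)
            if rec.inheritance == "de_novo":
                expected["de_novo_carrier"].add(rec.subject_id)
            if rec.clinical_class == "pathogenic":
                expected["pathogenic_carrier"].add(rec.subject_id)
        for col in flags.columns:
            assert set(flags.index[flags[col]]) == expected[col]


def test_union_bound_invariant(signal_cohort, signal_artifacts):
    # for every set: S_loss + S_gain >= distinct genes of S hit by CNVs of
    # either dosage (a gene hit by both a loss and a gain counts once on
    # the right, twice on the left)
    gene_map, matrix, _ = signal_artifacts
    df = matrix.values_df
    hit_union = {sid: set() for sid in df.index}
    for rec, genes_hit in zip(signal_cohort.records, gene_map):
        if rec.subject_id in hit_union:
            hit_union[rec.subject_id] |= genes_hit
    set_ids = sorted({c[:-5] for c in df.columns if c.endswith("_loss")})
    for sid in set_ids:
        members = signal_cohort.gene_sets.members(sid)
        union_count = df.index.map(lambda s: len(hit_union[s] & members))
        assert (df[f"{sid}_loss"] + df[f"{sid}_gain"] >= union_count).all()
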