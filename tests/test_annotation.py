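"""Functional consensus, annotation loading/propagation, resampling null,
and the per-term frequency/trend table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shortloops import (
    AnnotationMap,
    classify_term_trend,
    consensus_distribution,
    functional_consensus,
    resampling_null,
    term_frequency_table,
)
from shortloops.annotation import GOGraph, load_annotations
from shortloops.network import InteractionNetwork
from shortloops.synth import (
    SynthConfig,
    module_term,
    plant_clique,
    synthetic_annotations,
    write_annotations_gaf,
    write_annotations_tsv,
)

from .conftest import er_net


class TestFunctionalConsensus:
    def test_identical_sets_full_consensus(self):
        ann = AnnotationMap({p: {"A", "B"} for p in "xyz"})
        assert functional_consensus(("x", "y", "z"), ann) == 100.0

    def test_one_common_of_four(self):
        ann = AnnotationMap(
            {"x": {"A", "B"}, "y": {"A", "C"}, "z": {"A", "D"}}
        )
        assert functional_consensus(("x", "y", "z"), ann) == 25.0

    def test_disjoint_sets_zero(self):
        ann = AnnotationMap({"x": {"A"}, "y": {"B"}, "z": {"C"}})
        assert functional_consensus(("x", "y", "z"), ann) == 0.0

    def test_unannotated_member_raises_keyerror(self):
        ann = AnnotationMap({"x": {"A"}, "y": {"A"}})
        with pytest.raises(KeyError):
            functional_consensus(("x", "y", "ghost"), ann)

    @given(perm=st.permutations(["x", "y", "z"]))
    @settings(max_examples=6, derandomize=True)
    def test_member_permutation_invariance(self, perm):
        ann = AnnotationMap(
            {"x": {"A", "B"}, "y": {"A", "C"}, "z": {"B", "C"}}
        )
        assert functional_consensus(tuple(perm), ann) == functional_consensus(
            ("x", "y", "z"), ann
        )

    def test_shared_term_never_decreases_consensus(self):
        base = {"x": {"A", "B"}, "y": {"A", "C"}, "z": {"A"}}
        before = functional_consensus(("x", "y", "z"), AnnotationMap(base))
        shared = {p: ts | {"S"} for p, ts in base.items()}
        after = functional_consensus(("x", "y", "z"), AnnotationMap(shared))
        assert after >= before

    def test_private_term_never_increases_consensus(self):
        base = {"x": {"A", "B"}, "y": {"A", "B"}, "z": {"A", "B"}}
        before = functional_consensus(("x", "y", "z"), AnnotationMap(base))
        private = dict(base)
        private["x"] = base["x"] | {"P"}
        after = functional_consensus(("x", "y", "z"), AnnotationMap(private))
        assert after <= before


class TestLoading:
    def test_tsv_propagation_to_ancestors(self, tmp_path, mini_ontology):
        t_leaf = module_term(0, 0)  # depth 3
        ann_path = tmp_path / "a.tsv"
        ann_path.write_text(f"p1\t{t_leaf}\n")
        ann, go = load_annotations(ann_path, mini_ontology)
        assert t_leaf in ann["p1"]
        assert len(ann["p1"]) == 3  # leaf + depth-2 + depth-1 parents
        assert go.roots[0] not in ann["p1"]

    def test_propagation_off(self, tmp_path, mini_ontology):
        t_leaf = module_term(0, 0)
        ann_path = tmp_path / "a.tsv"
        ann_path.write_text(f"p1\t{t_leaf}\n")
        ann, _ = load_annotations(ann_path, mini_ontology, propagate=False)
        assert ann["p1"] == {t_leaf}

    def test_gaf_not_qualifier_dropped(self, tmp_path, mini_ontology):
        t = module_term(0, 0)
        row = lambda p, qual: "\t".join(
            ["SYN", p, p, qual, t, "ref", "IEA", "", "P", "", "",
             "protein", "taxon:0", "20150223", "SYN", "", ""]
        )
        gaf = tmp_path / "a.gaf"
        gaf.write_text(
            "!gaf-version: 2.2\n"
            + row("p1", "involved_in") + "\n"
            + row("p2", "NOT|involved_in") + "\n"
        )
        ann, _ = load_annotations(gaf, mini_ontology)
        assert "p1" in ann and "p2" not in ann

    def test_gaf_aspect_filter(self, tmp_path, mini_ontology):
        t = module_term(0, 0)
        def row(p, aspect):
            return "\t".join(
                ["SYN", p, p, "involved_in", t, "ref", "IEA", "", aspect,
                 "", "", "protein", "taxon:0", "20150223", "SYN", "", ""]
            )
        gaf = tmp_path / "a.gaf"
        gaf.write_text("!gaf-version: 2.2\n" + row("p1", "P") + "\n" + row("p2", "F") + "\n")
        ann, _ = load_annotations(gaf, mini_ontology)
        assert "p1" in ann and "p2" not in ann

    def test_unknown_term_kept_as_leaf_with_warning(self, tmp_path, mini_ontology):
        ann_path = tmp_path / "a.tsv"
        ann_path.write_text("p1\tGO:1234567\n")
        with pytest.warns(UserWarning, match="absent from the ontology"):
            ann, _ = load_annotations(ann_path, mini_ontology)
        assert ann["p1"] == {"GO:1234567"}

    def test_zero_annotated_proteins_rejected(self, tmp_path, mini_ontology):
        root = "GO:9000000"
        ann_path = tmp_path / "a.tsv"
        ann_path.write_text(f"p1\t{root}\n")  # root-only: stripped
        with pytest.raises(ValueError, match="zero annotated"):
            load_annotations(ann_path, mini_ontology)

    def test_gaf_and_tsv_agree(self, tmp_path, mini_ontology):
        net = er_net(20, 0.2, seed=2)
        nodes = sorted(net.nodes)
        ann = synthetic_annotations(
            net, [nodes[:6], nodes[6:12]],
            SynthConfig(
                coherence=1.0, background_rate=0.2, background_terms=5, seed=4
            ),
        )
        gaf, tsv = tmp_path / "a.gaf", tmp_path / "a.tsv"
        write_annotations_gaf(ann, gaf)
        write_annotations_tsv(ann, tsv)
        from_gaf, _ = load_annotations(gaf, mini_ontology)
        from_tsv, _ = load_annotations(tsv, mini_ontology)
        assert dict(from_gaf) == dict(from_tsv)


class TestGOGraph:
    def test_depths_and_children(self, mini_ontology):
        go = GOGraph.from_obo(mini_ontology)
        assert go.roots == ["GO:9000000"]
        assert go.depth["GO:9000000"] == 0
        assert go.depth[module_term(0, 0)] == 3
        assert go.n_children("GO:9000000") == 3
        assert go.ancestors(module_term(0, 0)) >= {"GO:9000000"}

    def test_acyclic_depths_defined_everywhere(self, mini_ontology):
        go = GOGraph.from_obo(mini_ontology)
        assert set(go.depth) == set(go.parents)


class TestConsensusDistribution:
    def test_all_full_consensus_top_bin(self):
        ann = AnnotationMap({p: {"A"} for p in "abcd"})
        loops = {3: [("a", "b", "c"), ("b", "c", "d")]}
        res = consensus_distribution(loops, ann)
        assert res.histogram[3] == [0.0, 0.0, 0.0, 1.0]

    def test_two_loops_opposite_bins(self):
        ann = AnnotationMap(
            {
                # loop 1: consensus 1/10 = 10%
                "a": {"A", "B", "C", "D"},
                "b": {"A", "E", "F", "G"},
                "c": {"A", "H", "I", "J"},
                # loop 2: consensus 4/5 = 80%
                "x": {"A", "B", "C", "D"},
                "y": {"A", "B", "C", "D"},
                "z": {"A", "B", "C", "D", "E"},
            }
        )
        res = consensus_distribution(
            {3: [("a", "b", "c"), ("x", "y", "z")]}, ann
        )
        assert res.histogram[3] == [0.5, 0.0, 0.0, 0.5]

    def test_unannotated_loops_counted_separately(self):
        ann = AnnotationMap({p: {"A"} for p in "abc"})
        res = consensus_distribution(
            {3: [("a", "b", "c"), ("a", "b", "q")]}, ann
        )
        assert res.excluded[3] == 1
        assert sum(res.histogram[3]) == pytest.approx(1.0, abs=1e-12)

    def test_mass_conservation(self):
        net = er_net(25, 0.3, seed=6)
        nodes = sorted(net.nodes)
        ann = synthetic_annotations(
            net, [nodes[:12]],
            SynthConfig(coherence=0.7, background_rate=0.3, seed=1),
        )
        from shortloops import enumerate_loops

        loops = {L: enumerate_loops(net, L) for L in (3, 4)}
        res = consensus_distribution(loops, ann)
        for L, hist in res.histogram.items():
            if res.values[L]:
                assert sum(hist) == pytest.approx(1.0, abs=1e-12)

    def test_no_scorable_loops_rejected(self):
        ann = AnnotationMap({"a": {"A"}})
        with pytest.raises(ValueError, match="scorable"):
            consensus_distribution({3: [("x", "y", "z")]}, ann)


class TestResamplingNull:
    def test_degenerate_identical_annotation(self, triangle):
        ann = AnnotationMap({p: {"A", "B"} for p in triangle.nodes})
        res = resampling_null(triangle, ann, 3, n_samples=500, seed=0)
        assert np.all(res.null == 100.0)
        assert res.p_value == 1.0

    def test_seed_determinism(self):
        net = er_net(20, 0.25, seed=3)
        ann = AnnotationMap(
            {p: {f"T{hash(p) % 5}", "C"} for p in net.nodes}
        )
        a = resampling_null(net, ann, 3, n_samples=300, seed=9)
        b = resampling_null(net, ann, 3, n_samples=300, seed=9)
        assert np.array_equal(a.null, b.null)
        assert a.p_value == b.p_value

    def test_p_value_in_unit_interval(self):
        net = er_net(20, 0.25, seed=3)
        ann = AnnotationMap(
            {p: {f"T{hash(p) % 7}"} for p in net.nodes}
        )
        res = resampling_null(net, ann, 3, n_samples=200, seed=2)
        assert 0 < res.p_value <= 1

    def test_small_sample_warns(self, triangle):
        ann = AnnotationMap({p: {"A"} for p in triangle.nodes})
        with pytest.warns(UserWarning, match="n_samples"):
            resampling_null(triangle, ann, 3, n_samples=50, seed=0)

    def test_planted_module_signal_detected(self):
        """Loops inside a coherent planted clique beat the resampling null."""
        net = er_net(60, 0.05, seed=8)
        nodes = sorted(net.nodes)
        clique_nodes = nodes[:8]
        net = plant_clique(net, 8, nodes=clique_nodes)
        cfg = SynthConfig(
            coherence=1.0, background_rate=0.05, terms_per_module=5, seed=3
        )
        ann = synthetic_annotations(net, [clique_nodes], cfg)
        # give non-module proteins some scattered annotation
        extra = {
            p: ann[p] if p in ann else {f"T{i % 11}", f"T{(i * 3) % 11}"}
            for i, p in enumerate(nodes)
        }
        ann = AnnotationMap(extra)
        res = resampling_null(net, ann, 3, n_samples=2000, seed=5)
        assert res.p_value < 0.05
        assert res.observed_mean > float(np.mean(res.null))


class TestTermTrends:
    @pytest.mark.parametrize(
        "net_freq,loops,expected",
        [
            (5, (12, 9, 7), "1"),
            (20, (10, 8, 5), "3"),  # monotone decreasing, all below network
            (20, (10, 12, 5), "2"),  # below network but not monotone
        ],
    )
    def test_worked_examples(self, net_freq, loops, expected):
        assert classify_term_trend(net_freq, loops) == expected

    def test_removed_complex_relabels(self):
        assert classify_term_trend(5, (12, 9, 7), True) == "4"
        assert classify_term_trend(20, (10, 8, 5), True) == "5"
        assert classify_term_trend(20, (10, 12, 5), True) == "5"

    def test_mixed_pattern_unclassified(self):
        assert classify_term_trend(10, (5, 15, 8)) == "unclassified"


class TestTermFrequencyTable:
    @pytest.fixture
    def clique_fixture(self, mini_ontology):
        net = er_net(40, 0.08, seed=12)
        nodes = sorted(net.nodes)
        clique_nodes = nodes[:6]
        net = plant_clique(net, 6, nodes=clique_nodes)
        cfg = SynthConfig(
            coherence=1.0, background_rate=0.4, terms_per_module=4,
            background_terms=5, seed=7,
        )
        ann = synthetic_annotations(net, [clique_nodes], cfg)
        go = GOGraph.from_obo(mini_ontology)
        return net, ann, go

    def test_clique_confined_term_enriched_in_loops(self, clique_fixture):
        from shortloops import enumerate_loops

        net, ann, go = clique_fixture
        loops = {L: enumerate_loops(net, L) for L in (3, 4, 5)}
        table = term_frequency_table(net, loops, ann, go)
        t = module_term(0, 0)
        row = table.loc[t]
        assert row["freq_loop3"] > row["freq_network"]

    def test_general_terms_excluded(self, clique_fixture):
        from shortloops import enumerate_loops

        net, ann, go = clique_fixture
        loops = {L: enumerate_loops(net, L) for L in (3, 4)}
        table = term_frequency_table(net, loops, ann, go)
        for term in table.index:
            d = go.depth.get(term)
            assert d is None or d >= 2
            if d == 2:
                assert go.n_children(term) <= 4

    def test_absent_term_zero_loop_frequency(self, clique_fixture):
        from shortloops import enumerate_loops

        net, ann, go = clique_fixture
        loops = {3: enumerate_loops(net, 3)}
        table = term_frequency_table(net, loops, ann, go)
        # background terms at rate .4 are rarely in any consensus set but
        # always carried by some protein
        zeros = table[table["freq_loop3"] == 0.0]
        assert (zeros["freq_network"] > 0).all()

    def test_frequencies_bounded(self, clique_fixture):
        from shortloops import enumerate_loops

        net, ann, go = clique_fixture
        loops = {L: enumerate_loops(net, L) for L in (3, 4)}
        table = term_frequency_table(net, loops, ann, go)
        for col in ("freq_network", "freq_loop3", "freq_loop4"):
            assert ((table[col] >= 0) & (table[col] <= 100)).all()
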