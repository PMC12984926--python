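import igraph
import pytest

from phoscoreg import (
    AnnotationEdge,
    CoRegulationCall,
    ExpressionLabel,
    SiteKey,
    ValidationError,
    build_network,
    export_network,
    hypergeometric_ora,
    overlay_annotations,
)
from phoscoreg.annotate import (
    edge_tsv_frame,
    read_annotation_tsv,
    read_edge_tsv,
    read_gmt,
    read_label_tsv,
)
from phoscoreg.coregulation import PairStateCounts

from exact_oracles import hypergeom_upper_tail_exact

ANCHOR = SiteKey("PKN1", "S", 916)


def call(partner, direction="positive", passes=True, p=0.001, d=10, c=0):
    pair = PairStateCounts(
        anchor=ANCHOR, partner=partner, uu=d // 2, dd=d - d // 2,
        ud=c // 2, du=c - c // 2, a=50, b=20,
        supporting_pmids_pos=frozenset({"p1", "p2", "p3"}),
        supporting_conditions_pos=frozenset(f"c{i}" for i in range(d)),
    )
    return CoRegulationCall(pair=pair, fet_p=p, direction=direction, passes_filters=passes)


class TestOverlay:
    def test_binary_interactor_edge_tags_the_call(self):
        calls = [call(SiteKey("PDPK1", "S", 241))]
        edges = [AnnotationEdge("PDPK1", "PKN1", "binary_interactor", "curated-db")]
        out = overlay_annotations(calls, edges)
        assert out[0].annotations == {"binary_interactor"}

    def test_empty_edge_table_leaves_calls_unchanged(self):
        calls = [call(SiteKey("PDPK1", "S", 241))]
        assert overlay_annotations(calls, []) == calls

    def test_multiple_edge_types_all_attach(self):
        calls = [call(SiteKey("PDPK1", "S", 241))]
        edges = [
            AnnotationEdge("PDPK1", "PKN1", "binary_interactor", "db1"),
            AnnotationEdge("PKN1", "PDPK1", "kinase_of", "db2"),
            AnnotationEdge("MAPT", "PKN1", "substrate_of", "db3"),  # different partner
        ]
        out = overlay_annotations(calls, edges)
        assert out[0].annotations == {"binary_interactor", "kinase_of"}

    def test_never_drops_calls(self):
        calls = [call(SiteKey(f"P{i}", "S", i + 1), passes=False) for i in range(5)]
        assert len(overlay_annotations(calls, [])) == 5

    def test_edge_type_vocabulary_enforced(self):
        with pytest.raises(ValidationError):
            AnnotationEdge("A", "B", "likes", "db")


class TestHypergeometricOra:
    def test_zero_overlap_gives_p_one(self):
        res = hypergeometric_ora({"A"}, {"set1": {"B", "C"}}, {"A", "B", "C", "D"})
        assert res[0].p == 1.0

    def test_forced_overlap_gives_p_one(self):
        universe = {"A", "B", "C"}
        res = hypergeometric_ora(universe, {"all": set(universe)}, universe)
        assert res[0].p == pytest.approx(1.0)

    def test_worked_example_against_mass_summation(self):
        universe = {f"G{i}" for i in range(20)}
        gene_set = {f"G{i}" for i in range(5)}
        query = {"G0", "G1", "G2", "G10", "G11"}  # overlap 3
        res = hypergeometric_ora(query, {"s": gene_set}, universe)
        expected = float(hypergeom_upper_tail_exact(3, 20, 5, 5))
        assert res[0].p == pytest.approx(expected, abs=1e-12)
        assert (res[0].overlap, res[0].set_size, res[0].query_size) == (3, 5, 5)

    def test_agrees_with_exact_tail_over_a_grid(self):
        for N in (10, 57, 200):
            universe = {f"G{i}" for i in range(N)}
            for K in (1, N // 3, N // 2):
                gene_set = {f"G{i}" for i in range(K)}
                for n in (1, N // 4, N // 2):
                    query = {f"G{i}" for i in range(N - n, N)}
                    k = len(gene_set & query)
                    res = hypergeometric_ora(query, {"s": gene_set}, universe)
                    assert res[0].p == pytest.approx(
                        float(hypergeom_upper_tail_exact(k, N, K, n)), abs=1e-12
                    )

    def test_empty_universe_and_stray_query_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            hypergeometric_ora(set(), {}, set())
        with pytest.raises(ValidationError, match="outside"):
            hypergeometric_ora({"X"}, {}, {"A"})


class TestNetwork:
    def three_calls(self):
        return [
            call(SiteKey("PDPK1", "S", 241)),
            call(SiteKey("IRS2", "S", 306)),
            call(SiteKey("HSPB1", "S", 78), direction="negative"),
        ]

    def test_nodes_and_signed_edges(self):
        g = build_network(self.three_calls())
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 3
        kinds = sorted(d["interaction"] for _, _, d in g.edges(data=True))
        assert kinds == ["neg_coreg", "pos_coreg", "pos_coreg"]

    def test_expression_label_and_activity_flag(self):
        labels = [
            ExpressionLabel("PDPK1", "up", "HCC",
                            frozenset({SiteKey("PDPK1", "S", 241)}))
        ]
        g = build_network(self.three_calls(), labels=labels)
        node = g.nodes["PDPK1:S241"]
        assert node["expression"] == "up"
        assert node["activity_associated"] is True
        assert g.nodes["IRS2:S306"]["expression"] == ""

    def test_no_passing_calls_keeps_anchor_only(self):
        calls = [call(SiteKey("PDPK1", "S", 241), passes=False)]
        g = build_network(calls)
        assert list(g.nodes) == ["PKN1:S916"]

    def test_annotation_edges_join_network_proteins(self):
        edges = [
            AnnotationEdge("PDPK1", "PKN1", "binary_interactor", "db"),
            AnnotationEdge("ZZZ", "PKN1", "kinase_of", "db"),  # not in network
        ]
        g = build_network(self.three_calls(), edges=edges)
        assert g.number_of_edges() == 4
        assert ("PDPK1:S241", "PKN1:S916", "binary_interactor") in g.edges(keys=True)

    def test_node_count_is_anchor_plus_distinct_partners(self):
        calls = self.three_calls() + [call(SiteKey("PDPK1", "S", 241))]  # duplicate partner
        g = build_network(calls)
        assert g.number_of_nodes() == 1 + 3


class TestExports:
    def test_sif_has_one_line_per_edge(self, tmp_path):
        g = build_network(TestNetwork().three_calls())
        path = tmp_path / "net.sif"
        export_network(g, "SIF", path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        assert all(len(line.split("\t")) == 3 for line in lines)

    def test_edge_tsv_round_trip_is_byte_identical(self, tmp_path):
        g = build_network(
            TestNetwork().three_calls(),
            edges=[AnnotationEdge("PDPK1", "PKN1", "binary_interactor", "db")],
            labels=[ExpressionLabel("IRS2", "up", "HCC")],
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_network(g, "edge_TSV", p1)
        export_network(read_edge_tsv(p1), "edge_TSV", p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_graphml_parses_in_independent_reader(self, tmp_path):
        g = build_network(TestNetwork().three_calls())
        path = tmp_path / "net.graphml"
        export_network(g, "GraphML", path)
        parsed = igraph.Graph.Read_GraphML(str(path))
        assert parsed.vcount() == g.number_of_nodes()
        assert parsed.ecount() == g.number_of_edges()

    def test_unknown_format_rejected(self, tmp_path):
        g = build_network(TestNetwork().three_calls())
        with pytest.raises(ValueError, match="unknown export format"):
            export_network(g, "DOT", tmp_path / "x")


class TestTableReaders:
    def test_annotation_tsv(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text(
            "source\ttarget\tedge_type\tevidence\tsite\n"
            "PDPK1\tPKN1\tbinary_interactor\tdb1\t\n"
            "PKN1\tABI2\tsubstrate_of\tdb2\tS242\n"
        )
        edges = read_annotation_tsv(path)
        assert edges[0].site_specific is None
        assert edges[1].site_specific == SiteKey("ABI2", "S", 242)

    def test_label_tsv_with_activity_sites(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text(
            "protein\tdirection\tcontext\tactivity_sites\n"
            "CEP55\tup\tHCC\tS425;S428\nHSPB1\tdown\tHCC\t\n"
        )
        labels = read_label_tsv(path)
        assert labels[0].activity_associated_sites == {
            SiteKey("CEP55", "S", 425), SiteKey("CEP55", "S", 428)
        }
        assert labels[1].activity_associated_sites == frozenset()

    def test_gmt_reader(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text(
            "insulin_signaling\tdesc\tPDPK1\tIRS2\tPRKAA1\n"
            "cytoskeleton\tdesc\tMARCKS\tMAPT\n"
        )
        sets = read_gmt(path)
        assert sets["insulin_signaling"] == {"PDPK1", "IRS2", "PRKAA1"}
        assert len(sets) == 2
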