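import json

import networkx as nx
import pytest

from hoipy.courses import CourseGraph, build_course_graph
from hoipy.model import EntityKind, Term, normalize_curie
from hoipy.viz import (
    DEFAULT_PALETTE,
    edge_style_for,
    load_palette,
    node_table,
    parse_cx,
    style_for,
    to_cx,
    to_graphml,
    to_sif,
)

CHRONIC = "HOIP:0060195"
SENOLYTICS = "HOIP:0060418"


@pytest.fixture(scope="module")
def chronic_graph(graph):
    return build_course_graph(graph, CHRONIC)


@pytest.fixture(scope="module")
def senolytics_graph(graph):
    return build_course_graph(graph, SENOLYTICS, include_isa=True)


class TestNodeStyles:
    def test_human_molecule_is_red_square(self, doc):
        style = style_for(doc.term("PR:P20700"))
        assert style.shape == "square"
        assert style.color == DEFAULT_PALETTE["material_entity_human"]

    def test_non_human_molecule_is_orange_square(self, doc):
        style = style_for(doc.term("CHEBI:6801"))
        assert style.shape == "square"
        assert style.color == DEFAULT_PALETTE["material_entity"]

    def test_negation_marked_process_is_grey(self, doc):
        style = style_for(doc.term("HOIP:9900032"))
        assert style.color == DEFAULT_PALETTE["negated"]
        assert style.shape == "circle"

    def test_plain_process_is_circle(self):
        assert style_for(Term("X:1", entity_kind=EntityKind.PROCESS)).shape \
            == "circle"

    def test_unknown_kind_gets_default_style(self):
        style = style_for(Term("X:1", entity_kind=EntityKind.OTHER))
        assert style.color == DEFAULT_PALETTE["default"]

    def test_is_a_edges_are_dotted_without_arrow(self):
        assert edge_style_for("is_a").line == "dotted"
        assert not edge_style_for("is_a").arrow
        assert edge_style_for("has_result").line == "solid"
        assert edge_style_for("has_result").arrow


class TestSif:
    def test_line_count_equals_edge_count(self, chronic_graph):
        lines = to_sif(chronic_graph).strip().splitlines()
        assert len(lines) == len(chronic_graph.edges)

    def test_contains_printed_ccf_to_cgas_edge(self, chronic_graph):
        assert "HOIP:0060190\thas_result\tHOIP:0060172" in to_sif(chronic_graph)

    def test_single_edge_graph(self):
        cg = CourseGraph(course_id=None,
                         nodes={(normalize_curie("X:1"), EntityKind.PROCESS, "direct"),
                                (normalize_curie("X:2"), EntityKind.PROCESS, "direct")},
                         edges={(normalize_curie("X:1"), "has_result",
                                 normalize_curie("X:2"), "asserted")})
        assert to_sif(cg) == "X:1\thas_result\tX:2\n"


class TestGraphml:
    def test_parses_and_counts_agree(self, chronic_graph, doc):
        text = to_graphml(chronic_graph, doc)
        g = nx.parse_graphml(text)
        assert g.number_of_nodes() == len(chronic_graph.nodes)
        assert g.number_of_edges() == len(chronic_graph.edges)

    def test_senolytics_export_has_grey_node_and_dotted_isa(self, senolytics_graph, doc):
        text = to_graphml(senolytics_graph, doc)
        assert DEFAULT_PALETTE["negated"] in text
        assert "dotted" in text and "is_a" in text


class TestCx:
    def test_round_trips_losslessly(self, chronic_graph, doc):
        back = parse_cx(to_cx(chronic_graph, doc))
        assert len(back["nodes"]) == len(chronic_graph.nodes)
        represented = {n["represents"] for n in back["nodes"].values()}
        assert represented == {str(n[0]) for n in chronic_graph.nodes}
        id_of = {n["represents"]: i for i, n in back["nodes"].items()}
        edges = {(id_of[str(s)], rel, id_of[str(t)])
                 for (s, rel, t, _st) in chronic_graph.edges}
        assert set(back["edges"].values()) == edges

    def test_empty_graph_is_valid_cx(self):
        text = to_cx(CourseGraph(course_id=None), None)
        data = json.loads(text)
        back = parse_cx(text)
        assert back["nodes"] == {} and back["edges"] == {}
        assert any("status" in frag for frag in data)

    def test_node_attributes_carry_definition_and_links(self, chronic_graph, doc):
        back = parse_cx(to_cx(chronic_graph, doc))
        by_represents = {back["nodes"][i]["represents"]: back["nodeAttributes"][i]
                         for i in back["nodes"]}
        attrs = by_represents["HOIP:0060102"]
        assert attrs["uri"].endswith("/HOIP0060102")
        assert "definition" in attrs and "pubmed" in attrs

    def test_grey_and_dotted_styles_present(self, senolytics_graph, doc):
        back = parse_cx(to_cx(senolytics_graph, doc))
        colors = {a.get("color") for a in back["nodeAttributes"].values()}
        lines = {a.get("line") for a in back["edgeAttributes"].values()}
        assert DEFAULT_PALETTE["negated"] in colors
        assert "dotted" in lines


class TestNodeTable:
    def test_row_count_and_bioportal_uri(self, chronic_graph, doc):
        rows = node_table(chronic_graph, doc).strip().splitlines()
        assert len(rows) - 1 == len(chronic_graph.nodes)
        sasp = [r for r in rows if r.startswith("HOIP:0060102\t")]
        assert sasp and sasp[0].split("\t")[5].endswith("/HOIP0060102")

    def test_empty_graph_gives_header_only(self, doc):
        rows = node_table(CourseGraph(course_id=None), doc).strip().splitlines()
        assert rows == ["id\tlabel\tentity_kind\tdefinition\txrefs\turi\tpubmed"]


def test_exports_are_deterministic(chronic_graph, doc):
    assert to_sif(chronic_graph) == to_sif(chronic_graph)
    assert to_graphml(chronic_graph, doc) == to_graphml(chronic_graph, doc)
    assert to_cx(chronic_graph, doc) == to_cx(chronic_graph, doc)


def test_exports_agree_on_counts(chronic_graph, doc):
    sif_lines = to_sif(chronic_graph).strip().splitlines()
    g = nx.parse_graphml(to_graphml(chronic_graph, doc))
    back = parse_cx(to_cx(chronic_graph, doc))
    assert len(sif_lines) == g.number_of_edges() == len(back["edges"])
    assert g.number_of_nodes() == len(back["nodes"])


def test_palette_overrides_from_yaml(tmp_path, doc):
    cfg = tmp_path / "palette.yaml"
    cfg.write_text("negated: '#123456'\n")
    palette = load_palette(cfg)
    assert style_for(doc.term("HOIP:9900032"), palette).color == "#123456"
    assert palette["disease"] == DEFAULT_PALETTE["disease"]
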