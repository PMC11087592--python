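"""Exporters for course graphs: SIF, GraphML and CX (NDEx exchange JSON).

Styling follows the course-network drawing conventions: processes are
circles and material entities squares; molecules are orange, red when the
molecule is human; roles light green, phenotypes green, symptoms blue,
diseases red; negation-marked "no X" processes are grey.  Subsumption
(``is_a``) edges are dotted and arrowless, causal and part-whole edges solid
with arrows.  Exact colors are a configurable palette (YAML/JSON) since only
the color names are conventional.

All exports are deterministic byte-for-byte for a given graph and palette.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import yaml

from .courses import CourseGraph
from .model import (
    Curie,
    EntityKind,
    IS_A,
    OntologyDocument,
    Term,
    bioportal_uri,
)

__all__ = [
    "NodeStyle",
    "EdgeStyle",
    "DEFAULT_PALETTE",
    "load_palette",
    "style_for",
    "edge_style_for",
    "to_sif",
    "to_graphml",
    "to_cx",
    "parse_cx",
    "node_table",
]


@dataclass(frozen=True)
class NodeStyle:
    shape: str  # circle | square
    color: str
    border: str = "#333333"


@dataclass(frozen=True)
class EdgeStyle:
    line: str  # solid | dotted
    arrow: bool


DEFAULT_PALETTE = {
    "process": "#FFFFFF",
    "course": "#D3D3D3",
    "material_entity": "#FFA500",
    "material_entity_human": "#FF0000",
    "role": "#90EE90",
    "phenotype": "#008000",
    "symptom": "#0000FF",
    "disease": "#FF0000",
    "anatomical_entity": "#F5DEB3",
    "negated": "#808080",
    "default": "#FFFFFF",
}


def load_palette(path) -> dict:
    """Merge a YAML/JSON palette file over the default palette."""
    with open(path, "r", encoding="utf-8") as fh:
        overrides = yaml.safe_load(fh) or {}
    palette = dict(DEFAULT_PALETTE)
    palette.update(overrides)
    return palette


def style_for(term: Term, palette: Optional[dict] = None) -> NodeStyle:
    """Node style from entity kind, taxon flag and negation marker."""
    pal = palette or DEFAULT_PALETTE
    shape = "square" if term.entity_kind is EntityKind.MATERIAL_ENTITY else "circle"
    if term.negated:
        color = pal["negated"]
    elif term.entity_kind is EntityKind.MATERIAL_ENTITY and term.is_human:
        color = pal["material_entity_human"]
    else:
        color = pal.get(term.entity_kind.value, pal["default"])
    return NodeStyle(shape=shape, color=color)


def edge_style_for(relation: str) -> EdgeStyle:
    if relation == IS_A:
        return EdgeStyle(line="dotted", arrow=False)
    return EdgeStyle(line="solid", arrow=True)


def _styles(graph: CourseGraph, doc: OntologyDocument, palette) -> dict:
    styles = {}
    for (cid, kind, _origin) in graph.nodes:
        term = doc.terms.get(cid) or Term(cid, entity_kind=kind)
        styles[cid] = style_for(term, palette)
    return styles


def _pubmed_link(term: Term) -> str:
    for x in term.xrefs:
        if x.startswith("PMID:"):
            return f"https://pubmed.ncbi.nlm.nih.gov/{x.split(':', 1)[1]}/"
    return ""


# --------------------------------------------------------------------------
# SIF
# --------------------------------------------------------------------------


def to_sif(graph: CourseGraph) -> str:
    """One line per edge: ``source<TAB>relation<TAB>target``."""
    lines = [f"{s}\t{rel}\t{t}" for (s, rel, t, _status) in graph.sorted_edges()]
    return "\n".join(lines) + ("\n" if lines else "")


# --------------------------------------------------------------------------
# GraphML
# --------------------------------------------------------------------------


def to_graphml(graph: CourseGraph, doc: OntologyDocument,
               palette: Optional[dict] = None) -> str:
    styles = _styles(graph, doc, palette)
    g = nx.MultiDiGraph()
    for (cid, kind, origin) in sorted(graph.nodes, key=lambda n: str(n[0])):
        term = doc.terms.get(cid) or Term(cid, entity_kind=kind)
        st = styles[cid]
        g.add_node(str(cid), label=term.label, entity_kind=kind.value,
                   origin=origin, shape=st.shape, color=st.color,
                   border=st.border, definition=term.definition,
                   uri=bioportal_uri(cid), pubmed=_pubmed_link(term))
    for (s, rel, t, status) in graph.sorted_edges():
        es = edge_style_for(rel)
        g.add_edge(str(s), str(t), relation=rel, status=status,
                   line=es.line, arrow=es.arrow)
    return "\n".join(nx.generate_graphml(g)) + "\n"


# --------------------------------------------------------------------------
# CX (NDEx exchange)
# --------------------------------------------------------------------------


def to_cx(graph: CourseGraph, doc: OntologyDocument,
          palette: Optional[dict] = None) -> str:
    """CX JSON with nodes, edges, nodeAttributes and edgeAttributes aspects."""
    styles = _styles(graph, doc, palette)
    node_list = sorted(graph.nodes, key=lambda n: str(n[0]))
    node_id = {n[0]: i for i, n in enumerate(node_list)}
    edge_list = graph.sorted_edges()

    nodes_aspect = []
    node_attrs = []
    for (cid, kind, origin) in node_list:
        term = doc.terms.get(cid) or Term(cid, entity_kind=kind)
        i = node_id[cid]
        nodes_aspect.append({"@id": i, "n": term.label or str(cid),
                             "r": str(cid)})
        st = styles[cid]
        for name, value in (
            ("entity_kind", kind.value),
            ("origin", origin),
            ("shape", st.shape),
            ("color", st.color),
            ("definition", term.definition),
            ("uri", bioportal_uri(cid)),
            ("pubmed", _pubmed_link(term)),
        ):
            node_attrs.append({"po": i, "n": name, "v": value})

    edges_aspect = []
    edge_attrs = []
    base = len(node_list)
    for j, (s, rel, t, status) in enumerate(edge_list):
        eid = base + j
        edges_aspect.append({"@id": eid, "s": node_id[s], "t": node_id[t],
                             "i": rel})
        es = edge_style_for(rel)
        for name, value in (("status", status), ("line", es.line),
                            ("arrow", es.arrow)):
            edge_attrs.append({"po": eid, "n": name, "v": value})

    meta = [
        {"name": "nodes", "elementCount": len(nodes_aspect), "idCounter": base,
         "version": "1.0"},
        {"name": "edges", "elementCount": len(edges_aspect),
         "idCounter": base + len(edges_aspect), "version": "1.0"},
        {"name": "nodeAttributes", "elementCount": len(node_attrs),
         "version": "1.0"},
        {"name": "edgeAttributes", "elementCount": len(edge_attrs),
         "version": "1.0"},
    ]
    document = [
        {"numberVerification": [{"longNumber": 281474976710655}]},
        {"metaData": meta},
        {"nodes": nodes_aspect},
        {"edges": edges_aspect},
        {"nodeAttributes": node_attrs},
        {"edgeAttributes": edge_attrs},
        {"status": [{"error": "", "success": True}]},
    ]
    return json.dumps(document, indent=1)


def parse_cx(text: str) -> dict:
    """Re-import a CX document (lossless for nodes/edges/attributes)."""
    aspects = {}
    for fragment in json.loads(text):
        for name, data in fragment.items():
            aspects.setdefault(name, []).extend(data)
    nodes = {n["@id"]: {"name": n.get("n"), "represents": n.get("r")}
             for n in aspects.get("nodes", [])}
    edges = {e["@id"]: (e["s"], e["i"], e["t"]) for e in aspects.get("edges", [])}
    node_attrs = {}
    for a in aspects.get("nodeAttributes", []):
        node_attrs.setdefault(a["po"], {})[a["n"]] = a["v"]
    edge_attrs = {}
    for a in aspects.get("edgeAttributes", []):
        edge_attrs.setdefault(a["po"], {})[a["n"]] = a["v"]
    return {"nodes": nodes, "edges": edges, "nodeAttributes": node_attrs,
            "edgeAttributes": edge_attrs}


# --------------------------------------------------------------------------
# Node table
# --------------------------------------------------------------------------


def node_table(graph: CourseGraph, doc: OntologyDocument) -> str:
    """Per-node TSV: id, label, kind, definition, xrefs, URI, PubMed link."""
    header = "id\tlabel\tentity_kind\tdefinition\txrefs\turi\tpubmed"
    rows = [header]
    for (cid, kind, _origin) in sorted(graph.nodes, key=lambda n: str(n[0])):
        term = doc.terms.get(cid) or Term(cid, entity_kind=kind)
        definition = term.definition.replace("\t", " ").replace("\n", " ")
        rows.append("\t".join([
            str(cid), term.label, kind.value, definition,
            "|".join(term.xrefs), bioportal_uri(cid), _pubmed_link(term),
        ]))
    return "\n".join(rows) + "\n"
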