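"""Read and write documents from/to OWL serializations (RDF/XML, Turtle).

Only the constructs the course model uses are mapped: named-class
subsumptions, subclass-of-restriction axioms with ``owl:someValuesFrom``
over a *named* filler, object-property declarations with
``owl:TransitiveProperty`` / ``owl:inverseOf`` / ``owl:propertyChainAxiom``,
and the annotation properties that feed term fields (label, definition,
description, database cross-references).  Everything else encountered under
``rdfs:subClassOf`` is skipped and reported, with deterministic source
locations so reports are reproducible.

The annotation IRIs are configurable (:class:`AnnotationConfig`) with
defaults matching common OBO practice.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.collection import Collection
from rdflib.namespace import DCTERMS, OWL, RDF, RDFS

from .errors import CurieParseError, OwlReadError, OwlWriteError
from .model import (
    Axiom,
    AxiomKind,
    Curie,
    EntityKind,
    OntologyDocument,
    RelationType,
    Term,
    bioportal_uri,
    normalize_curie,
)

__all__ = ["ParseReport", "AnnotationConfig", "read_ontology", "write_ontology"]

REL = Namespace("http://purl.obolibrary.org/obo/hoip#")
OBOINOWL = Namespace("http://www.geneontology.org/formats/oboInOwl#")
IAO_DEFINITION = URIRef("http://purl.obolibrary.org/obo/IAO_0000115")
ONTOLOGY_IRI = URIRef("http://purl.obolibrary.org/obo/hoip/fragment.owl")

_FORMATS = {"turtle": "turtle", "rdfxml": "xml"}
_META_PREFIX = "metadata_"


@dataclass
class ParseReport:
    """What the reader accepted, skipped, and could not resolve."""

    accepted_axioms: int = 0
    skipped_constructs: list = field(default_factory=list)  # (description, location)
    dangling_refs: list = field(default_factory=list)

    @property
    def constructs_encountered(self) -> int:
        return self.accepted_axioms + len(self.skipped_constructs)

    def as_dict(self) -> dict:
        return {
            "accepted_axioms": self.accepted_axioms,
            "skipped_constructs": [list(s) for s in self.skipped_constructs],
            "dangling_refs": [str(c) for c in self.dangling_refs],
        }


@dataclass(frozen=True)
class AnnotationConfig:
    label: URIRef = RDFS.label
    definition: URIRef = IAO_DEFINITION
    description: URIRef = DCTERMS.description
    xref: URIRef = OBOINOWL.hasDbXref


def _rdflib_format(fmt: str) -> str:
    try:
        return _FORMATS[fmt]
    except KeyError:
        raise OwlWriteError(
            f"unknown serialization {fmt!r}; expected one of {sorted(_FORMATS)}"
        ) from None


def _class_iri(curie: Curie) -> URIRef:
    return URIRef(bioportal_uri(curie))


def _relation_iri(name: str) -> URIRef:
    return REL[name]


def _relation_name(iri: URIRef) -> str:
    s = str(iri)
    if "#" in s:
        return s.rsplit("#", 1)[1]
    return s.rstrip("/").rsplit("/", 1)[-1]


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------


def write_ontology(doc: OntologyDocument, format: str = "turtle") -> str:
    """Serialize a document; ``read_ontology`` reproduces it (order-insensitive)."""
    fmt = _rdflib_format(format)
    g = Graph()
    g.bind("owl", OWL)
    g.bind("hoiprel", REL)
    g.bind("oboInOwl", OBOINOWL)
    g.bind("dcterms", DCTERMS)
    ann = AnnotationConfig()

    g.add((ONTOLOGY_IRI, RDF.type, OWL.Ontology))
    for key in sorted(doc.metadata):
        g.add((ONTOLOGY_IRI, REL[_META_PREFIX + key], Literal(doc.metadata[key])))

    for name in sorted(doc.relations):
        rel = doc.relations[name]
        iri = _relation_iri(name)
        g.add((iri, RDF.type, OWL.ObjectProperty))
        if rel.label:
            g.add((iri, ann.label, Literal(rel.label)))
        if rel.transitive:
            g.add((iri, RDF.type, OWL.TransitiveProperty))
        if rel.inverse_of:
            g.add((iri, OWL.inverseOf, _relation_iri(rel.inverse_of)))
        if rel.chain:
            node = BNode(f"chain_{name}")
            Collection(g, node, [_relation_iri(r) for r in rel.chain])
            g.add((iri, OWL.propertyChainAxiom, node))
        if rel.domain_kind is not None:
            g.add((iri, REL.domain_kind, Literal(rel.domain_kind.value)))
        if rel.range_kind is not None:
            g.add((iri, REL.range_kind, Literal(rel.range_kind.value)))

    for cid in sorted(doc.terms, key=str):
        term = doc.terms[cid]
        iri = _class_iri(cid)
        g.add((iri, RDF.type, OWL.Class))
        if term.label:
            g.add((iri, ann.label, Literal(term.label)))
        g.add((iri, REL.entity_kind, Literal(term.entity_kind.value)))
        if term.definition:
            g.add((iri, ann.definition, Literal(term.definition)))
        if term.description:
            g.add((iri, ann.description, Literal(term.description)))
        for xref in term.xrefs:
            g.add((iri, ann.xref, Literal(xref)))
        if term.stage is not None:
            g.add((iri, REL.stage, Literal(term.stage)))
        if term.negated:
            g.add((iri, REL.negated, Literal(True)))
        if term.taxon is not None:
            g.add((iri, REL.in_taxon, Literal(term.taxon)))

    for i, ax in enumerate(sorted(
            doc.axioms,
            key=lambda a: (str(a.subject), a.kind.value, a.relation or "",
                           str(a.object)))):
        if ax.kind is AxiomKind.SUBCLASS_OF:
            g.add((_class_iri(ax.subject), RDFS.subClassOf, _class_iri(ax.object)))
        elif ax.kind is AxiomKind.EXISTENTIAL:
            restriction = BNode(f"restr{i:05d}")
            g.add((restriction, RDF.type, OWL.Restriction))
            g.add((restriction, OWL.onProperty, _relation_iri(ax.relation)))
            g.add((restriction, OWL.someValuesFrom, _class_iri(ax.object)))
            g.add((_class_iri(ax.subject), RDFS.subClassOf, restriction))
        else:  # pragma: no cover - enum is closed
            raise OwlWriteError(f"unsupported axiom kind {ax.kind!r}")
    if fmt == "xml":
        return _serialize_rdfxml(g)
    return g.serialize(format=fmt)


_NSMAP = (
    ("rdf", str(RDF)),
    ("rdfs", str(RDFS)),
    ("owl", str(OWL)),
    ("hoiprel", str(REL)),
    ("oboInOwl", str(OBOINOWL)),
    ("dcterms", str(DCTERMS)),
    ("obo", "http://purl.obolibrary.org/obo/"),
)


def _qname(uri: URIRef) -> str:
    s = str(uri)
    for prefix, ns in _NSMAP:
        if s.startswith(ns):
            local = s[len(ns):]
            if local and not local[0].isdigit() and "/" not in local \
                    and "#" not in local:
                return f"{prefix}:{local}"
    raise OwlWriteError(f"no namespace prefix for predicate {uri}")


def _serialize_rdfxml(g: Graph) -> str:
    """Deterministic RDF/XML: subjects, predicates and objects in sorted order.

    rdflib's own RDF/XML serializer emits subjects in hash order, which is
    not stable across processes; exports here must be byte-for-byte
    reproducible.  Property chains are emitted as ``rdf:parseType="Collection"``.
    """
    from xml.sax.saxutils import escape, quoteattr

    list_nodes = set(g.subjects(RDF.first, None))
    subjects = sorted(
        {s for s in g.subjects() if s not in list_nodes},
        key=lambda s: (isinstance(s, BNode), str(s)))

    out = ['<?xml version="1.0" encoding="utf-8"?>']
    attrs = " ".join(f'xmlns:{p}="{ns}"' for p, ns in _NSMAP)
    out.append(f"<rdf:RDF {attrs}>")
    for s in subjects:
        ref = (f"rdf:nodeID={quoteattr(str(s))}" if isinstance(s, BNode)
               else f"rdf:about={quoteattr(str(s))}")
        out.append(f"  <rdf:Description {ref}>")
        pairs = sorted(g.predicate_objects(s), key=lambda po: (_qname(po[0]),
                                                               str(po[1])))
        for p, o in pairs:
            q = _qname(p)
            if isinstance(o, BNode) and o in list_nodes:
                out.append(f'    <{q} rdf:parseType="Collection">')
                for item in Collection(g, o):
                    out.append(
                        f"      <rdf:Description rdf:about={quoteattr(str(item))}/>")
                out.append(f"    </{q}>")
            elif isinstance(o, BNode):
                out.append(f"    <{q} rdf:nodeID={quoteattr(str(o))}/>")
            elif isinstance(o, URIRef):
                out.append(f"    <{q} rdf:resource={quoteattr(str(o))}/>")
            else:
                dt = (f" rdf:datatype={quoteattr(str(o.datatype))}"
                      if o.datatype else "")
                out.append(f"    <{q}{dt}>{escape(str(o))}</{q}>")
        out.append("  </rdf:Description>")
    out.append("</rdf:RDF>")
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------


def _load_graph(source, fmt: str) -> Graph:
    g = Graph()
    try:
        if hasattr(source, "read"):
            g.parse(source, format=fmt)
        elif isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
            g.parse(str(source), format=fmt)
        else:
            g.parse(data=source, format=fmt)
    except Exception as exc:
        raise OwlReadError(f"cannot parse {fmt} input: {exc}") from exc
    return g


def read_ontology(source, format: str = "turtle",
                  annotations: Optional[AnnotationConfig] = None
                  ) -> Tuple[OntologyDocument, ParseReport]:
    """Parse a serialization into a document plus a parse report.

    ``source`` may be a path, an open stream, or a string of RDF text.
    Identifiers that appear in axioms without a class declaration are listed
    in ``report.dangling_refs`` (they are not fabricated as terms).
    """
    fmt = _rdflib_format(format)
    ann = annotations or AnnotationConfig()
    g = _load_graph(source, fmt)
    doc = OntologyDocument()
    report = ParseReport()

    for s, p, o in g.triples((ONTOLOGY_IRI, None, None)):
        pred = str(p)
        if pred.startswith(str(REL[_META_PREFIX])):
            doc.metadata[pred[len(str(REL[_META_PREFIX])):]] = str(o)

    # Object properties.
    for iri in sorted(set(g.subjects(RDF.type, OWL.ObjectProperty)), key=str):
        name = _relation_name(iri)
        transitive = (iri, RDF.type, OWL.TransitiveProperty) in g
        inverse = g.value(iri, OWL.inverseOf)
        chain_head = g.value(iri, OWL.propertyChainAxiom)
        chain = None
        if chain_head is not None:
            chain = tuple(_relation_name(m)
                          for m in Collection(g, chain_head))
        label = g.value(iri, ann.label)
        domain_kind = g.value(iri, REL.domain_kind)
        range_kind = g.value(iri, REL.range_kind)
        doc.add_relation(RelationType(
            id=name,
            label=str(label) if label is not None else "",
            transitive=transitive,
            inverse_of=_relation_name(inverse) if inverse is not None else None,
            chain=chain,
            domain_kind=EntityKind(str(domain_kind)) if domain_kind else None,
            range_kind=EntityKind(str(range_kind)) if range_kind else None,
        ))
    # Mirror inverse declarations stated only on one side.
    for name in sorted(doc.relations):
        rel = doc.relations[name]
        if rel.inverse_of and rel.inverse_of in doc.relations:
            partner = doc.relations[rel.inverse_of]
            if partner.inverse_of is None:
                from dataclasses import replace

                doc.relations[rel.inverse_of] = replace(partner, inverse_of=name)

    # Classes.
    for iri in sorted(set(g.subjects(RDF.type, OWL.Class)), key=str):
        if isinstance(iri, BNode):
            continue
        try:
            cid = normalize_curie(str(iri))
        except CurieParseError:
            report.skipped_constructs.append(
                ("class with unrecognized IRI", str(iri)))
            continue
        kind = g.value(iri, REL.entity_kind)
        label = g.value(iri, ann.label)
        definition = g.value(iri, ann.definition)
        description = g.value(iri, ann.description)
        stage = g.value(iri, REL.stage)
        negated = g.value(iri, REL.negated)
        taxon = g.value(iri, REL.in_taxon)
        xrefs = tuple(sorted(str(x) for x in g.objects(iri, ann.xref)))
        doc.add_term(Term(
            id=cid,
            label=str(label) if label is not None else "",
            entity_kind=EntityKind(str(kind)) if kind is not None else EntityKind.OTHER,
            definition=str(definition) if definition is not None else "",
            description=str(description) if description is not None else "",
            xrefs=xrefs,
            stage=str(stage) if stage is not None else None,
            negated=bool(negated is not None and str(negated).lower() == "true"),
            taxon=str(taxon) if taxon is not None else None,
        ))

    # Subclass constructs (named subsumption or someValuesFrom restriction).
    seen_axioms = set()
    subclass_triples = sorted(g.triples((None, RDFS.subClassOf, None)),
                              key=lambda t: (str(t[0]), str(t[2])))
    for n, (s, _p, o) in enumerate(subclass_triples):
        location = f"subClassOf[{n}]"
        if isinstance(s, BNode):
            report.skipped_constructs.append(
                ("subclass axiom with anonymous subject", location))
            continue
        try:
            subject = normalize_curie(str(s))
        except CurieParseError:
            report.skipped_constructs.append(
                (f"unrecognized subject IRI {s}", location))
            continue
        if isinstance(o, URIRef):
            try:
                obj = normalize_curie(str(o))
            except CurieParseError:
                report.skipped_constructs.append(
                    (f"unrecognized superclass IRI {o}", location))
                continue
            ax = Axiom(subject, AxiomKind.SUBCLASS_OF, obj)
        else:  # blank node: expect a someValuesFrom restriction
            if (o, RDF.type, OWL.Restriction) not in g:
                report.skipped_constructs.append(
                    ("anonymous superclass that is not a restriction", location))
                continue
            prop = g.value(o, OWL.onProperty)
            filler = g.value(o, OWL.someValuesFrom)
            if prop is None or filler is None:
                report.skipped_constructs.append(
                    ("restriction without onProperty/someValuesFrom", location))
                continue
            if not isinstance(filler, URIRef):
                report.skipped_constructs.append(
                    ("restriction with anonymous filler", location))
                continue
            try:
                obj = normalize_curie(str(filler))
            except CurieParseError:
                report.skipped_constructs.append(
                    (f"unrecognized filler IRI {filler}", location))
                continue
            ax = Axiom(subject, AxiomKind.EXISTENTIAL, obj,
                       relation=_relation_name(prop))
        if ax not in seen_axioms:
            seen_axioms.add(ax)
            doc.add_axiom(ax)
        report.accepted_axioms += 1

    report.dangling_refs = doc.dangling_references()
    return doc, report
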