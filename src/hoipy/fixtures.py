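"""Synthetic ontologies: the curated cellular-senescence fixture and random
documents with independently computed closures.

``build_senescence_fixture`` encodes the published cellular-senescence
course network: the course taxonomy (embryonic, adult, acute, chronic,
chronic-with-type-2-diabetes, senolytics) with its verbatim textual
definitions, the p21 activation chains of the adult (ATM → p53 →
regulation of gene expression by p53 → p21) and embryonic (TGF-beta → SMAD
→ regulation by SMAD → p21) courses, DDR signaling with its ATR/ATM
sub-processes, SASP secretion with its outputs/role/location, the type-2
diabetes chain ending in insulin resistance, the LMNB1 → cGAS-STING chain,
cross-course CXCL8/IL-8 edges into two COVID-19 courses, the senolytics
negation chain, and the four homeostasis-imbalance stage tags per course.

Identifiers that the published record does not print (stage-model processes,
regulation nodes, negation nodes, COVID course ids, IL-8 course variants,
the SASP-factor role and the senescent-cell location) are minted in the
reserved ``HOIP:99xxxxx`` block; they are synthetic, fixture-local ids.
Where the record prints two different ids for the same label (IL-6
signaling, p53 signaling, the 8-digit embryonic course spelling) both are
kept as distinct terms cross-linked with ``equivalent:`` xrefs.

``random_ontology`` generates random course-free class hierarchies with
causal DAGs (occasionally cyclic), part-whole nesting and chain-triggering
motifs; its ground-truth closure is computed constructively with graph
reachability (a third code path, independent of both reasoner
implementations).
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass

import networkx as nx

from .errors import ParameterError
from .imbalance import Stage
from .model import (
    Curie,
    EntityKind,
    HAS_PART,
    HAS_RESULT,
    HAS_OUTPUT,
    HAS_ROLE,
    MANIFESTS_SYMPTOM,
    OCCURS_IN,
    REALIZES_DISEASE,
    OntologyDocument,
    RelationType,
    Term,
    canonical_relation_registry,
    existential,
    normalize_curie,
    subclass_of,
)

__all__ = ["FixtureSpec", "build_senescence_fixture", "random_ontology"]

K = EntityKind

_COURSE_DEFINITIONS = {
    "HOIP:0060024": "A course constituting multiple processes that lead to "
                    "cellular senescence.",
    "HOIP:0060267": "A cellular senescence course that occurs during "
                    "embryogenesis.",
    "HOIP:0060315": "A cellular senescence course in adults.",
    "HOIP:0060196": "An adult cellular senescence course that can cause "
                    "transient cellular senescence.",
    "HOIP:0060195": "An adult cellular senescence course that can result in a "
                    "sustained cellular senescence process, which may lead to "
                    "the senescence-associated secretory phenotype (SASP), and "
                    "chronic inflammation due to senescent cell accumulation.",
}

# (id, label, kind, stage, negated, taxon, xrefs)
_TERMS = [
    # Courses.
    ("HOIP:0060024", "cellular senescence course", K.COURSE, None, False, None, ()),
    ("HOIP:0060267", "embryonic cellular senescence course", K.COURSE, None,
     False, None, ("equivalent:HOIP:00600267",)),
    ("HOIP:00600267", "embryonic cellular senescence course", K.COURSE, None,
     False, None, ("equivalent:HOIP:0060267",)),
    ("HOIP:0060315", "adult cellular senescence course", K.COURSE, None, False, None, ()),
    ("HOIP:0060196", "acute cellular senescence course", K.COURSE, None, False, None, ()),
    ("HOIP:0060195", "chronic cellular senescence course", K.COURSE, None, False, None, ()),
    ("HOIP:0060423", "chronic cellular senescence course associated with type 2 "
     "diabetes mellitus", K.COURSE, None, False, None, ()),
    ("HOIP:0060418", "senolytics course", K.COURSE, None, False, None, ()),
    ("HOIP:9900001", "COVID-19 associated with ARDS course", K.COURSE, None, False, None, ()),
    ("HOIP:9900002", "severe COVID-19 course", K.COURSE, None, False, None, ()),
    # Root course member.
    ("HOIP:0060129", "cellular senescence", K.PROCESS, None, False, None, ()),
    # Adult p21 chain and DDR.
    ("HOIP:0060110", "ATM signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:0060055", "p53 signaling", K.PROCESS, None, False, None,
     ("equivalent:HOIP:0060321",)),
    ("HOIP:9900011", "regulation of gene expression by p53", K.PROCESS, None, False, None, ()),
    ("HOIP:0060325", "p21 signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:0060337", "DDR signaling", K.PROCESS, Stage.STRESS_RESPONSE.value, False, None, ()),
    ("HOIP:0060140", "ATR signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:0060144", "CHK1 signaling [adult cellular senescence]", K.PROCESS,
     None, False, None, ("PMID:33328614",)),
    # Embryonic course.
    ("HOIP:0060269", "TGF beta signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:0060290", "SMAD signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:9900012", "regulation of gene expression by SMAD", K.PROCESS, None, False, None, ()),
    ("HOIP:9900060", "increasing demand for embryonic pattern specification",
     K.PROCESS, Stage.STRESS_DEMAND.value, False, None, ()),
    ("HOIP:9900061", "developmental stress response", K.PROCESS,
     Stage.STRESS_RESPONSE.value, False, None, ()),
    ("HOIP:9900062", "homeostatic imbalance (embryonic)", K.PROCESS,
     Stage.IMBALANCE.value, False, None, ()),
    ("HOIP:9900063", "cellular senescence (transient) [embryonic]", K.PROCESS,
     Stage.OUTCOME.value, False, None, ()),
    ("HOIP:9900064", "tissue remodelling", K.PROCESS, None, False, None, ()),
    ("HOIP:9900065", "embryonic pattern specification", K.PROCESS, None, False, None, ()),
    # Acute course.
    ("HOIP:9900070", "increasing demand for the oncogenic stress response",
     K.PROCESS, Stage.STRESS_DEMAND.value, False, None, ()),
    ("HOIP:9900071", "PTEN loss", K.PROCESS, None, False, None, ()),
    ("HOIP:9900072", "oncogenic stress response", K.PROCESS,
     Stage.STRESS_RESPONSE.value, False, None, ()),
    ("HOIP:9900073", "homeostatic imbalance (acute)", K.PROCESS,
     Stage.IMBALANCE.value, False, None, ()),
    ("HOIP:9900074", "cellular senescence (transient)", K.PROCESS,
     Stage.OUTCOME.value, False, None, ()),
    ("HOIP:9900075", "negative regulation of tumour proliferation", K.PROCESS,
     None, False, None, ()),
    # Chronic course.
    ("HOIP:9900080", "increasing demand for the cellular stress response",
     K.PROCESS, Stage.STRESS_DEMAND.value, False, None, ()),
    ("HOIP:9900082", "homeostatic imbalance (chronic)", K.PROCESS,
     Stage.IMBALANCE.value, False, None, ()),
    ("HOIP:0060240", "cellular senescence (sustained)", K.PROCESS,
     Stage.OUTCOME.value, False, None, ()),
    ("HOIP:0060308", "accumulation of senescent cells (sustained)", K.PROCESS,
     None, False, None, ()),
    ("HOIP:0060113", "chronic inflammation", K.PROCESS, None, False, None, ()),
    ("HOIP:0060102", "SASP secretion", K.PROCESS, None, False, None, ()),
    ("HOIP:0060112", "fibrosis", K.PROCESS, None, False, None, ()),
    ("HOIP:0060182", "negative regulation of tissue regeneration", K.PROCESS,
     None, False, None, ()),
    ("HOIP:0060639", "IL-6 signaling [chronic cellular senescence]", K.PROCESS,
     None, False, None, ("equivalent:HOIP:0004327",)),
    ("HOIP:0004327", "IL-6 signaling", K.PROCESS, None, False, None,
     ("equivalent:HOIP:0060639",)),
    ("HOIP:0060640", "CXCL8/IL-8 signaling [chronic cellular senescence]",
     K.PROCESS, None, False, None, ()),
    ("HOIP:0041903", "CXCL8 (IL-8) signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:9900030", "NFKB signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:0060431", "telomere shortening", K.PROCESS, None, False, None, ()),
    ("HOIP:0060294", "p16 signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:0060321", "p53 signaling [chronic cellular senescence]", K.PROCESS,
     None, False, None, ("equivalent:HOIP:0060055",)),
    ("HOIP:0060162", "senescence-associated heterochromatin focus formation",
     K.PROCESS, None, False, None, ()),
    ("HOIP:0060132", "LMNB1 degradation in lysosome", K.PROCESS, None, False, None, ()),
    ("HOIP:0060190", "release of cytosolic chromatin fragments", K.PROCESS,
     None, False, None, ()),
    ("HOIP:0060172", "cGAS signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:0060179", "STING signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:0060183", "IRF activation", K.PROCESS, None, False, None, ()),
    # Type 2 diabetes course.
    ("HOIP:0060453", "type B pancreatic cell exhaustion/hypofunction",
     K.PROCESS, None, False, None, ()),
    ("HOIP:0060455", "positive regulation of SASP secretion", K.PROCESS, None, False, None, ()),
    ("HOIP:0060432", "SASP secretion [chronic cellular senescence associated "
     "with type 2 diabetes mellitus]", K.PROCESS, None, False, None, ()),
    ("HOIP:0060427", "insulin resistance", K.PROCESS, None, False, None, ()),
    ("HOIP:0060504", "FOXO signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:0060512", "TLR4 signaling", K.PROCESS, None, False, None, ()),
    ("HOIP:0060496", "increasing urine production", K.PROCESS, None, False, None, ()),
    # Senolytics course.
    ("HOIP:0060417", "negative regulation of NFKB signaling", K.PROCESS,
     None, False, None, ()),
    ("HOIP:9900031", "no NFKB signaling", K.PROCESS, None, True, None, ()),
    ("HOIP:9900032", "no SASP secretion", K.PROCESS, None, True, None, ()),
    # COVID-19 courses.
    ("HOIP:9900041", "CXCL8 signaling [COVID-19 associated with ARDS]",
     K.PROCESS, None, False, None, ()),
    ("HOIP:9900042", "CXCL8 signaling [severe COVID-19]", K.PROCESS, None, False, None, ()),
    ("HOIP:9900043", "neutrophil extracellular trap formation/NETosis",
     K.PROCESS, None, False, None, ()),
    ("HOIP:0041811", "thrombus formation in the lung (very high)", K.PROCESS,
     None, False, None, ()),
    ("HOIP:0039281", "microvascular dysfunction", K.PROCESS, None, False, None, ()),
    # Generalizing superclasses.
    ("GO:0006954", "inflammatory response", K.PROCESS, None, False, None, ()),
    ("GO:0045087", "innate immune response", K.PROCESS, None, False, None, ()),
    # Molecules, role, location, symptom, disease.
    ("PR:P05231", "interleukin-6 (human)", K.MATERIAL_ENTITY, None, False,
     "NCBITaxon:9606", ()),
    ("PR:P10145", "interleukin-8 (human)", K.MATERIAL_ENTITY, None, False,
     "NCBITaxon:9606", ()),
    ("PR:P20700", "lamin B1 (human)", K.MATERIAL_ENTITY, None, False,
     "NCBITaxon:9606", ()),
    ("CHEBI:6801", "metformin", K.MATERIAL_ENTITY, None, False, None, ()),
    ("HOIP:9900021", "SASP factor", K.ROLE, None, False, None, ()),
    ("HOIP:9900022", "senescent cell", K.ANATOMICAL_ENTITY, None, False, None, ()),
    ("SYMP:0000565", "polyuria", K.SYMPTOM, None, False, None, ()),
    ("DOID:9352", "type 2 diabetes mellitus", K.DISEASE, None, False, None, ()),
]

_SUBCLASSES = [
    # Course taxonomy.
    ("HOIP:0060267", "HOIP:0060024"),
    ("HOIP:00600267", "HOIP:0060024"),
    ("HOIP:0060315", "HOIP:0060024"),
    ("HOIP:0060196", "HOIP:0060315"),
    ("HOIP:0060195", "HOIP:0060315"),
    ("HOIP:0060423", "HOIP:0060195"),
    ("HOIP:0060418", "HOIP:0060195"),
    # Process specialization / generalization.
    ("HOIP:0060240", "HOIP:0060129"),
    ("HOIP:0060417", "HOIP:9900030"),
    ("HOIP:0060640", "HOIP:0041903"),
    ("HOIP:9900041", "HOIP:0041903"),
    ("HOIP:9900042", "HOIP:0041903"),
    ("HOIP:0060639", "HOIP:0004327"),
    ("HOIP:0060113", "GO:0006954"),
    ("HOIP:0060172", "GO:0045087"),
    ("HOIP:0060179", "GO:0045087"),
    ("HOIP:9900043", "GO:0045087"),
]

_COURSE_PARTS = {
    "HOIP:0060024": ["HOIP:0060129"],
    "HOIP:0060315": ["HOIP:0060110", "HOIP:0060055", "HOIP:9900011",
                     "HOIP:0060325", "HOIP:0060337", "HOIP:0060140",
                     "HOIP:0060144"],
    "HOIP:0060267": ["HOIP:0060269", "HOIP:0060290", "HOIP:9900012",
                     "HOIP:0060325", "HOIP:9900060", "HOIP:9900061",
                     "HOIP:9900062", "HOIP:9900063", "HOIP:9900064",
                     "HOIP:9900065"],
    "HOIP:0060196": ["HOIP:9900070", "HOIP:9900072", "HOIP:9900073",
                     "HOIP:9900074", "HOIP:9900075"],
    "HOIP:0060195": ["HOIP:0060431", "HOIP:0060294", "HOIP:0060321",
                     "HOIP:0060162", "HOIP:0060240", "HOIP:0060308",
                     "HOIP:0060113", "HOIP:0060102", "HOIP:9900030",
                     "HOIP:0060640", "HOIP:0060639", "HOIP:0060132",
                     "HOIP:0060190", "HOIP:0060172", "HOIP:0060179",
                     "HOIP:0060183", "HOIP:9900080", "HOIP:9900082"],
    "HOIP:0060423": ["HOIP:0060431", "HOIP:0060453", "HOIP:0060455",
                     "HOIP:0060432", "HOIP:0060427", "HOIP:0060504",
                     "HOIP:0060512", "HOIP:0060496"],
    "HOIP:0060418": ["HOIP:0060417", "HOIP:9900031", "HOIP:9900032"],
    "HOIP:9900001": ["HOIP:9900041", "HOIP:9900043", "HOIP:0041811"],
    "HOIP:9900002": ["HOIP:9900042", "HOIP:0039281"],
}

_PROCESS_PARTS = [
    ("HOIP:0060337", "HOIP:0060140"),
    ("HOIP:0060337", "HOIP:0060110"),
    ("HOIP:9900070", "HOIP:9900071"),
    ("HOIP:0060102", "HOIP:0060639"),
    ("HOIP:0060102", "HOIP:0060640"),
]

_CAUSAL_EDGES = [
    # Adult p21 chain.
    ("HOIP:0060110", "HOIP:0060055"),
    ("HOIP:0060055", "HOIP:9900011"),
    ("HOIP:9900011", "HOIP:0060325"),
    ("HOIP:0060140", "HOIP:0060055"),
    ("HOIP:0060144", "HOIP:0060055"),
    # Embryonic p21 chain and stage model.
    ("HOIP:0060269", "HOIP:0060290"),
    ("HOIP:0060290", "HOIP:9900012"),
    ("HOIP:9900012", "HOIP:0060325"),
    ("HOIP:9900060", "HOIP:9900061"),
    ("HOIP:9900061", "HOIP:9900062"),
    ("HOIP:9900062", "HOIP:9900063"),
    ("HOIP:9900063", "HOIP:9900064"),
    ("HOIP:9900064", "HOIP:9900065"),
    # Acute stage model.
    ("HOIP:9900070", "HOIP:9900072"),
    ("HOIP:9900072", "HOIP:9900073"),
    ("HOIP:9900073", "HOIP:9900074"),
    ("HOIP:9900074", "HOIP:9900075"),
    # Chronic stage model and SASP consequences.
    ("HOIP:9900080", "HOIP:0060337"),
    ("HOIP:0060337", "HOIP:9900082"),
    ("HOIP:9900082", "HOIP:0060240"),
    ("HOIP:0060240", "HOIP:0060308"),
    ("HOIP:0060308", "HOIP:0060102"),
    ("HOIP:0060102", "HOIP:0060113"),
    ("HOIP:0060102", "HOIP:0060112"),
    ("HOIP:0060102", "HOIP:0060182"),
    ("HOIP:0060639", "HOIP:0060113"),
    ("HOIP:0060640", "HOIP:0060113"),
    # LMNB1 / cGAS-STING innate-immunity chain.
    ("HOIP:0060132", "HOIP:0060190"),
    ("HOIP:0060190", "HOIP:0060172"),
    ("HOIP:0060172", "HOIP:0060179"),
    ("HOIP:0060179", "HOIP:0060183"),
    ("HOIP:0060179", "HOIP:9900030"),
    ("HOIP:9900030", "HOIP:0060640"),
    # Type 2 diabetes chain.
    ("HOIP:0060431", "HOIP:0060453"),
    ("HOIP:0060453", "HOIP:0060455"),
    ("HOIP:0060455", "HOIP:0060432"),
    ("HOIP:0060432", "HOIP:0060427"),
    ("HOIP:0060504", "HOIP:0060427"),
    ("HOIP:0060512", "HOIP:0060427"),
    ("HOIP:0060427", "HOIP:0060496"),
    # Senolytics negation chain.
    ("HOIP:0060417", "HOIP:9900031"),
    ("HOIP:9900031", "HOIP:9900032"),
    # COVID-19 chains.
    ("HOIP:9900041", "HOIP:9900043"),
    ("HOIP:9900043", "HOIP:0041811"),
    ("HOIP:9900042", "HOIP:0039281"),
]

_ATTACHMENTS = [
    ("HOIP:0060102", HAS_OUTPUT, "PR:P05231"),
    ("HOIP:0060102", HAS_OUTPUT, "PR:P10145"),
    ("HOIP:0060102", HAS_ROLE, "HOIP:9900021"),
    ("HOIP:0060102", OCCURS_IN, "HOIP:9900022"),
    ("HOIP:0060132", "has_participant", "PR:P20700"),
    ("HOIP:0060417", "has_participant", "CHEBI:6801"),
    ("HOIP:0060496", MANIFESTS_SYMPTOM, "SYMP:0000565"),
    ("HOIP:0060427", REALIZES_DISEASE, "DOID:9352"),
]


def build_senescence_fixture() -> OntologyDocument:
    """The curated cellular-senescence course ontology (pure, deterministic)."""
    doc = OntologyDocument(metadata={
        "version": "1.0",
        "source": "curated cellular-senescence course network",
    })
    for rel in canonical_relation_registry().values():
        doc.add_relation(rel)
    doc.add_relation(RelationType("has_participant", "has participant"))

    for cid, label, kind, stage, negated, taxon, xrefs in _TERMS:
        doc.add_term(Term(
            id=normalize_curie(cid), label=label, entity_kind=kind,
            definition=_COURSE_DEFINITIONS.get(cid, ""), xrefs=xrefs,
            stage=stage, negated=negated, taxon=taxon,
        ))

    for sub, sup in _SUBCLASSES:
        doc.add_axiom(subclass_of(sub, sup, provenance="fixture"))
    for course, parts in _COURSE_PARTS.items():
        for part in parts:
            doc.add_axiom(existential(course, HAS_PART, part, provenance="fixture"))
    for whole, part in _PROCESS_PARTS:
        doc.add_axiom(existential(whole, HAS_PART, part, provenance="fixture"))
    for src, dst in _CAUSAL_EDGES:
        doc.add_axiom(existential(src, HAS_RESULT, dst, provenance="fixture"))
    for subj, rel, obj in _ATTACHMENTS:
        doc.add_axiom(existential(subj, rel, obj, provenance="fixture"))
    return doc


# --------------------------------------------------------------------------
# Random ontologies with constructive ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the random-ontology generator.

    Densities default to the sparsity typical of curated process ontologies:
    short causal chains, shallow specialization, occasional part-whole
    nesting.
    """

    n_classes: int = 30
    max_out_degree: int = 2
    chain_density: float = 0.2
    specialization_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes <= 0 or self.max_out_degree <= 0:
            raise ParameterError("n_classes and max_out_degree must be positive")
        for name in ("chain_density", "specialization_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")


def random_ontology(spec: FixtureSpec):
    """A random document plus its constructively computed closure.

    Same seed, same output.  The ground-truth closure is derived from the
    generated structure with plain graph reachability and shares no code with
    either reasoner implementation.
    """
    rng = random.Random(spec.seed)
    doc = OntologyDocument(metadata={"version": "random",
                                     "source": f"seed={spec.seed}"})
    for rel in canonical_relation_registry().values():
        doc.add_relation(rel)

    ids = [Curie("HOIP", f"88{i:05d}") for i in range(spec.n_classes)]
    for i, cid in enumerate(ids):
        doc.add_term(Term(cid, label=f"random process {i}",
                          entity_kind=EntityKind.PROCESS))

    axioms = set()

    def put(ax):
        if ax not in axioms:
            axioms.add(ax)
            doc.add_axiom(ax)

    # Specialization forest.
    for i in range(1, spec.n_classes):
        if rng.random() < spec.specialization_rate:
            parent = rng.randrange(i)
            put(subclass_of(ids[i], ids[parent], provenance="fixture"))

    # Causal DAG (topological by index).
    for i in range(spec.n_classes - 1):
        for _ in range(rng.randint(0, spec.max_out_degree)):
            j = rng.randrange(i + 1, spec.n_classes)
            put(existential(ids[i], HAS_RESULT, ids[j], provenance="fixture"))

    # Occasional feedback edge (biological cycles are permitted).
    if spec.n_classes >= 3 and rng.random() < 0.3:
        j = rng.randrange(1, spec.n_classes)
        i = rng.randrange(j)
        put(existential(ids[j], HAS_RESULT, ids[i], provenance="fixture"))

    # Part-whole nesting aimed at chain-triggering motifs.
    causal_sources = sorted({a.subject for a in doc.existential_axioms()
                             if a.relation == HAS_RESULT}, key=str)
    for i in range(spec.n_classes):
        if causal_sources and rng.random() < spec.chain_density:
            target = rng.choice(causal_sources)
            if target != ids[i]:
                put(existential(ids[i], HAS_PART, target, provenance="fixture"))

    # A few output attachments to exercise unpaired relations.
    for i in range(spec.n_classes):
        if rng.random() < 0.1:
            j = rng.randrange(spec.n_classes)
            if j != i:
                put(existential(ids[i], HAS_OUTPUT, ids[j], provenance="fixture"))

    return doc, _constructive_closure(doc)


def _reachable_pairs(nodes, edges) -> frozenset:
    """(u, v) with a path of >= 1 edge from u to v (self-loops via cycles)."""
    adj = defaultdict(set)
    for (a, b) in edges:
        adj[a].add(b)
    pairs = set()
    for start in nodes:
        stack = list(adj[start])
        seen = set()
        while stack:
            nxt = stack.pop()
            if nxt in seen:
                continue
            seen.add(nxt)
            pairs.add((start, nxt))
            stack.extend(adj[nxt])
    return frozenset(pairs)


def _constructive_closure(doc: OntologyDocument) -> frozenset:
    """Ground-truth closure from graph reachability (independent code path).

    For a relation with a declared inverse, the completion rules let an edge
    endpoint move to any class connected to it in the (undirected)
    specialization hierarchy; for an unpaired relation the subject may only
    specialize and the object only generalize.  Transitive relations then
    close under composition, and property chains join their two components.
    """
    rels = doc.effective_relations()
    classes = sorted(set(doc.terms) | doc.referenced_curies(), key=str)

    sub_edges = [(a.subject, a.object) for a in doc.subclass_axioms()
                 if a.subject != a.object]
    hierarchy = nx.DiGraph()
    hierarchy.add_nodes_from(classes)
    hierarchy.add_edges_from(sub_edges)
    ancestors = {c: {c} | nx.descendants(hierarchy, c) for c in classes}
    descendants = {c: {c} | nx.ancestors(hierarchy, c) for c in classes}
    undirected = hierarchy.to_undirected()
    component = {}
    for comp in nx.connected_components(undirected):
        frozen = frozenset(comp)
        for c in comp:
            component[c] = frozen

    asserted = defaultdict(set)
    for ax in doc.existential_axioms():
        asserted[ax.relation].add((ax.subject, ax.object))

    entailed = {}
    done = set()
    plain = [n for n in sorted(rels) if rels[n].chain is None]
    for name in plain:
        if name in done:
            continue
        rel = rels[name]
        inv = rel.inverse_of
        if inv is not None and inv in rels:
            merged = set(asserted[name]) | {(o, s) for (s, o) in asserted[inv]}
            base = {(x, y)
                    for (a, b) in merged
                    for x in component.get(a, {a})
                    for y in component.get(b, {b})}
            if rel.transitive:
                base = set(_reachable_pairs(classes, base))
            entailed[name] = base
            entailed[inv] = {(y, x) for (x, y) in base}
            done.update((name, inv))
        else:
            base = {(x, y)
                    for (a, b) in asserted[name]
                    for x in descendants.get(a, {a})
                    for y in ancestors.get(b, {b})}
            if rel.transitive:
                base = set(_reachable_pairs(classes, base))
            entailed[name] = base
            done.add(name)

    for name in sorted(rels):
        rel = rels[name]
        if rel.chain is None:
            continue
        first, second = rel.chain
        by_mid = defaultdict(set)
        for (x, y) in entailed.get(first, ()):
            by_mid[y].add(x)
        composed = {(x, z)
                    for (m, z) in entailed.get(second, ())
                    for x in by_mid.get(m, ())}
        direct = {(x, y)
                  for (a, b) in asserted[name]
                  for x in descendants.get(a, {a})
                  for y in ancestors.get(b, {b})}
        entailed[name] = composed | direct

    closure = set()
    for name, pairs in entailed.items():
        closure.update((s, name, o) for (s, o) in pairs)
    return frozenset(closure)
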