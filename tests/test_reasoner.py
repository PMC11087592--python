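import pytest

from hoipy.errors import ChainConfigError, GuardLimitError, UnknownTermError
from hoipy.fixtures import FixtureSpec, random_ontology
from hoipy.model import (
    EntityKind,
    HAS_PART_RESULT,
    HAS_RESULT,
    HAS_CAUSE,
    OntologyDocument,
    RelationType,
    Term,
    existential,
    normalize_curie,
    subclass_of,
)
from hoipy.reasoner import brute_force_closure, entails, materialize

H = normalize_curie


def _chain_doc(n, relation=HAS_RESULT):
    """A pure causal path P:0 -> P:1 -> ... -> P:n (n edges)."""
    d = OntologyDocument()
    for i in range(n + 1):
        d.add_term(Term(f"P:{i}", entity_kind=EntityKind.PROCESS))
    for i in range(n):
        d.add_axiom(existential(f"P:{i}", relation, f"P:{i+1}"))
    return d


def test_empty_document_has_no_edges():
    g = materialize(OntologyDocument())
    assert not g.edges and not g.subsumptions
    assert brute_force_closure(OntologyDocument()) == frozenset()


def test_single_transitive_edge_without_inverse_is_closed():
    d = OntologyDocument()
    d.add_term(Term("P:0"))
    d.add_term(Term("P:1"))
    d.add_relation(RelationType("leads_to", transitive=True))
    d.add_axiom(existential("P:0", "leads_to", "P:1"))
    assert brute_force_closure(d) == {(H("P:0"), "leads_to", H("P:1"))}
    assert materialize(d).triples() == {(H("P:0"), "leads_to", H("P:1"))}


def test_transitive_path_closure_has_closed_form_count():
    """A causal path of length n entails exactly n(n+1)/2 causal edges."""
    for n in (1, 4, 10):
        g = materialize(_chain_doc(n))
        result_edges = [k for k in g.edges if k[1] == HAS_RESULT]
        assert len(result_edges) == n * (n + 1) // 2
        # Inverse coherence: every causal edge has its mirrored inverse.
        for (s, _r, o) in result_edges:
            assert g.has_edge(o, HAS_CAUSE, s)


def test_indirect_causes_entailed_along_p21_chain(graph):
    # ATM -> p53 -> regulation by p53 -> p21, transitively closed.
    assert entails(graph, "HOIP:0060110", HAS_RESULT, "HOIP:0060325")
    res = entails(graph, "HOIP:0060110", HAS_RESULT, "HOIP:0060055")
    assert res.holds and res.derivation and "asserted" in res.derivation[0]


def test_property_chain_connects_whole_to_part_results(graph):
    # DDR has_part {ATR, ATM}; ATM reaches p21; chain gives has_part_result.
    assert entails(graph, "HOIP:0060337", HAS_PART_RESULT, "HOIP:0060325")
    assert entails(graph, "HOIP:0060140", HAS_RESULT, "HOIP:0060325")
    assert entails(graph, "HOIP:0060110", HAS_RESULT, "HOIP:0060325")


def test_chain_requires_declared_relations():
    d = OntologyDocument()
    d.add_term(Term("P:0"))
    d.add_relation(RelationType("combo", chain=("ghost", "has_result")))
    with pytest.raises(ChainConfigError):
        materialize(d, registry=d.relations)


def test_no_self_causation_on_acyclic_fixture():
    g = materialize(_chain_doc(4))
    assert not entails(g, "P:0", HAS_RESULT, "P:0")


def test_cycle_terminates_and_entails_every_ordered_pair():
    d = OntologyDocument()
    for x in "ABC":
        d.add_term(Term(f"P:{x}", entity_kind=EntityKind.PROCESS))
    for a, b in (("A", "B"), ("B", "C"), ("C", "A")):
        d.add_axiom(existential(f"P:{a}", HAS_RESULT, f"P:{b}"))
    g = materialize(d)
    for a in "ABC":
        for b in "ABC":
            assert entails(g, f"P:{a}", HAS_RESULT, f"P:{b}")


def test_entails_rejects_unknown_identifier(graph):
    with pytest.raises(UnknownTermError):
        entails(graph, "HOIP:1234567", HAS_RESULT, "HOIP:0060325")


def test_every_inferred_edge_has_a_derivation(graph):
    for edge in graph.edges.values():
        assert edge.derivation
        if edge.status == "asserted":
            assert len(edge.derivation) == 1


def test_materialization_is_idempotent(doc, graph):
    # Asserting the (non-self-causal) closure back adds nothing new.
    enriched = doc.copy()
    have = {a.triple for a in doc.existential_axioms()}
    for (s, r, o) in sorted(graph.triples(), key=lambda t: (str(t[0]), t[1], str(t[2]))):
        if (s, r, o) not in have and not (r in (HAS_RESULT, HAS_CAUSE) and s == o):
            enriched.add_axiom(existential(s, r, o, provenance="fixture"))
    assert materialize(enriched).triples() == graph.triples()


def test_monotonicity_adding_axioms_never_retracts():
    base_doc, _ = random_ontology(FixtureSpec(n_classes=12, seed=5))
    base = materialize(base_doc).triples()
    grown = base_doc.copy()
    grown.add_axiom(subclass_of("HOIP:8800011", "HOIP:8800000",
                                provenance="fixture"))
    grown.add_axiom(existential("HOIP:8800000", HAS_RESULT, "HOIP:8800011",
                                provenance="fixture"))
    assert materialize(grown).triples() >= base


def test_materializer_agrees_with_brute_force_on_random_documents():
    for seed in range(25):
        docr, truth = random_ontology(FixtureSpec(n_classes=5 + seed, seed=seed))
        mat = materialize(docr).triples()
        assert mat == brute_force_closure(docr) == truth, f"seed={seed}"


def test_inverse_coherence_on_curated_closure(graph):
    causal = [(s, o) for (s, r, o) in graph.edges if r == HAS_RESULT]
    for s, o in causal:
        assert graph.has_edge(o, HAS_CAUSE, s)
    reverse = [(s, o) for (s, r, o) in graph.edges if r == HAS_CAUSE]
    for s, o in reverse:
        assert graph.has_edge(o, HAS_RESULT, s)


def test_brute_force_guard_refuses_large_documents():
    d = OntologyDocument()
    for i in range(201):
        d.add_term(Term(f"P:{i}"))
    with pytest.raises(GuardLimitError):
        brute_force_closure(d)


def test_triple_table_export(graph):
    tsv = graph.to_tsv()
    lines = tsv.strip().splitlines()
    assert lines[0] == "subject\trelation\tobject\tstatus"
    assert len(lines) - 1 == len(graph.edges)
    assert "HOIP:0060110\thas_result\tHOIP:0060055\tasserted" in lines
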