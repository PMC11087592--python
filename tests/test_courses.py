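import networkx as nx
import pytest

from hoipy.courses import (
    build_course_graph,
    causal_paths,
    causes_of,
    common_generalized_processes,
    course_members,
    cross_course_results,
    generalized_causal_network,
    member_ids,
    results_of,
    specialization_pairs,
)
from hoipy.errors import EntityKindError, MappingError, ScopeError
from hoipy.fixtures import FixtureSpec, random_ontology
from hoipy.model import (
    EntityKind,
    HAS_PART,
    HAS_RESULT,
    OntologyDocument,
    Term,
    existential,
    normalize_curie,
    subclass_of,
)
from hoipy.reasoner import materialize

H = normalize_curie

CHRONIC = "HOIP:0060195"
ADULT = "HOIP:0060315"
EMBRYONIC = "HOIP:0060267"
T2DM = "HOIP:0060423"


def _ids(members):
    return {str(m.process) for m in members}


class TestCourseMembers:
    def test_chronic_course_inherits_specializes_and_adds(self, graph):
        members = {str(m.process): m for m in course_members(graph, CHRONIC)}
        # Printed membership: telomere shortening, p16, p53, SAHF formation.
        for pid in ("HOIP:0060431", "HOIP:0060294", "HOIP:0060321",
                    "HOIP:0060162"):
            assert pid in members
        # Sustained senescence replaces the inherited general process.
        assert members["HOIP:0060240"].origin == "specialized"
        assert str(members["HOIP:0060240"].specializes) == "HOIP:0060129"
        assert "HOIP:0060129" not in members
        # Added processes.
        assert members["HOIP:0060308"].origin == "direct"
        assert members["HOIP:0060113"].origin == "direct"
        # Inherited from the adult course.
        assert members["HOIP:0060337"].origin == "inherited"

    def test_specialization_pairs_require_materialized_subsumption(self, graph):
        pairs = specialization_pairs(graph, CHRONIC)
        assert any(str(p.general) == "HOIP:0060129"
                   and str(p.specialized) == "HOIP:0060240" for p in pairs)
        for p in pairs:
            assert (p.specialized, p.general) in graph.subsumptions

    def test_course_without_parts_or_supercourse_is_empty(self):
        d = OntologyDocument()
        d.add_term(Term("X:1", entity_kind=EntityKind.COURSE))
        assert course_members(materialize(d), "X:1") == []

    def test_non_course_identifier_is_rejected(self, graph):
        with pytest.raises(EntityKindError):
            course_members(graph, "HOIP:0060102")

    def test_inheritance_monotonicity(self, graph):
        sup = member_ids(graph, ADULT)
        sub = member_ids(graph, CHRONIC)
        for m in sup:
            specialized = {a for (a, b) in graph.subsumptions if b == m}
            assert m in sub or (specialized & sub)


class TestCausalQueries:
    def test_insulin_resistance_causes_in_diabetes_course(self, graph):
        found = {str(c) for c in causes_of(graph, "HOIP:0060427", T2DM)}
        assert found == {"HOIP:0060431", "HOIP:0060453", "HOIP:0060455",
                         "HOIP:0060432", "HOIP:0060504", "HOIP:0060512"}

    def test_course_scoping_is_sound(self, graph):
        scope = member_ids(graph, T2DM)
        assert set(causes_of(graph, "HOIP:0060427", T2DM)) <= scope

    def test_scope_error_when_process_outside_course(self, graph):
        with pytest.raises(ScopeError):
            causes_of(graph, "HOIP:0060269", T2DM)  # TGF-beta is embryonic

    def test_source_node_has_no_causes(self, graph):
        assert causes_of(graph, "HOIP:9900060") == []

    def test_sink_node_has_no_results(self, graph):
        assert results_of(graph, "HOIP:0060496") == []

    def test_sasp_secretion_downstream_results(self, graph):
        found = {str(c) for c in results_of(graph, "HOIP:0060102")}
        assert {"HOIP:0060113", "HOIP:0060112", "HOIP:0060182"} <= found

    def test_causes_results_duality_on_random_documents(self):
        for seed in (3, 11, 27):
            d, _ = random_ontology(FixtureSpec(n_classes=15, seed=seed))
            g = materialize(d)
            for x in d.terms:
                for y in results_of(g, x):
                    assert x in set(causes_of(g, y))
                for y in causes_of(g, x):
                    assert x in set(results_of(g, y))


class TestCausalPaths:
    def test_printed_diabetes_chain_is_returned(self, graph):
        paths = causal_paths(graph, "HOIP:0060431", "HOIP:0060427", 6)
        expected = [H(c) for c in ("HOIP:0060431", "HOIP:0060453",
                                   "HOIP:0060455", "HOIP:0060432",
                                   "HOIP:0060427")]
        assert expected in paths

    def test_trivial_self_path(self, graph):
        assert causal_paths(graph, "HOIP:0060102", "HOIP:0060102", 3) == \
            [[H("HOIP:0060102")]]

    def test_paths_use_asserted_edges_and_are_entailed(self, graph, doc):
        asserted = {(a.subject, a.object) for a in doc.existential_axioms()
                    if a.relation == HAS_RESULT}
        for path in causal_paths(graph, "HOIP:9900080", "HOIP:0060113", 8):
            for a, b in zip(path, path[1:]):
                assert (a, b) in asserted
                assert graph.has_edge(a, HAS_RESULT, b)

    def test_path_count_matches_dfs_enumeration(self):
        d, _ = random_ontology(FixtureSpec(n_classes=12, max_out_degree=3,
                                           seed=9))
        g = materialize(d)
        edges = {(a.subject, a.object) for a in d.existential_axioms()
                 if a.relation == HAS_RESULT}
        adj = {}
        for (a, b) in edges:
            adj.setdefault(a, set()).add(b)

        def dfs(node, dst, used, depth):
            if node == dst:
                return 1
            if depth == 0:
                return 0
            return sum(dfs(n, dst, used | {n}, depth - 1)
                       for n in adj.get(node, ()) if n not in used)

        nodes = sorted(d.terms, key=str)
        for src in nodes[:4]:
            for dst in nodes[-4:]:
                if src == dst:
                    continue
                found = causal_paths(g, src, dst, 5)
                assert len(found) == dfs(src, dst, {src}, 5)


class TestCrossCourse:
    def test_il8_results_reported_per_course(self, graph):
        out = {str(k): {str(x) for x in v}
               for k, v in cross_course_results(graph, "HOIP:0041903").items()}
        assert "HOIP:0060113" in out[CHRONIC]
        assert "HOIP:0041811" in out["HOIP:9900001"]
        assert "HOIP:0039281" in out["HOIP:9900002"]

    def test_process_absent_from_all_courses_gives_empty_map(self, graph):
        assert cross_course_results(graph, "HOIP:0060112") == {}

    def test_per_course_results_equal_membership_filtered_results(self, graph):
        out = cross_course_results(graph, "HOIP:0041903")
        variants = {H("HOIP:0041903")} | graph.subclasses(H("HOIP:0041903"))
        for course, hits in out.items():
            scope = member_ids(graph, course)
            expected = set()
            for v in variants & scope:
                expected |= {o for o in graph.objects(v, HAS_RESULT) if o != v}
            expected &= scope
            expected -= variants
            assert set(hits) == expected


class TestGeneralization:
    def test_shared_innate_immunity_superclasses_across_courses(self, graph):
        triples = common_generalized_processes(graph, CHRONIC, "HOIP:9900001")
        as_str = {(str(a), str(b), str(c)) for a, b, c in triples}
        assert ("GO:0045087", "HOIP:0060172", "HOIP:9900043") in as_str
        assert ("HOIP:0041903", "HOIP:0060640", "HOIP:9900041") in as_str

    def test_disjoint_hierarchies_share_nothing(self):
        d = OntologyDocument()
        for cid in ("X:1", "X:2"):
            d.add_term(Term(cid, entity_kind=EntityKind.COURSE))
        for pid in ("X:3", "X:4"):
            d.add_term(Term(pid, entity_kind=EntityKind.PROCESS))
        d.add_axiom(existential("X:1", HAS_PART, "X:3"))
        d.add_axiom(existential("X:2", HAS_PART, "X:4"))
        g = materialize(d)
        assert common_generalized_processes(g, "X:1", "X:2") == []

    def test_matches_all_pairs_ancestor_intersection(self, graph):
        # Independent re-computation with explicit ancestor sets.
        a_members = member_ids(graph, CHRONIC)
        b_members = member_ids(graph, "HOIP:9900001")
        expected = set()
        for a in a_members:
            for b in b_members:
                anc_a = {a} | {sup for (sub, sup) in graph.subsumptions
                               if sub == a}
                anc_b = {b} | {sup for (sub, sup) in graph.subsumptions
                               if sub == b}
                common = anc_a & anc_b
                if not common:
                    continue
                minimal = [c for c in common
                           if not any(d != c and (d, c) in graph.subsumptions
                                      for d in common)]
                expected.add((sorted(minimal, key=str)[0], a, b))
        assert set(common_generalized_processes(graph, CHRONIC,
                                                "HOIP:9900001")) == expected

    def test_generalized_network_contains_il8_netosis_thrombus_path(self, graph):
        level = {"HOIP:0060640": "HOIP:0041903", "HOIP:9900041": "HOIP:0041903"}
        cg = generalized_causal_network(graph, [CHRONIC, "HOIP:9900001"], level)
        edges = {(str(s), str(t)) for (s, _r, t, _st) in cg.edges}
        assert ("HOIP:0041903", "HOIP:9900043") in edges
        assert ("HOIP:9900043", "HOIP:0041811") in edges

    def test_identity_abstraction_reproduces_course_edges(self, graph):
        cg = generalized_causal_network(graph, [EMBRYONIC], {})
        scope = member_ids(graph, EMBRYONIC)
        expected = {(m1, m2) for m1 in scope
                    for m2 in graph.objects(m1, HAS_RESULT) & scope if m1 != m2}
        assert {(s, t) for (s, _r, t, _st) in cg.edges} == expected

    def test_abstraction_target_must_be_ancestor(self, graph):
        with pytest.raises(MappingError):
            generalized_causal_network(
                graph, [CHRONIC], {"HOIP:0060640": "HOIP:0060113"})


def test_course_graph_edges_connect_course_nodes(graph):
    cg = build_course_graph(graph, CHRONIC)
    node_ids = {n[0] for n in cg.nodes}
    for (s, _rel, t, _status) in cg.edges:
        assert s in node_ids and t in node_ids
    assert (H("HOIP:0060190"), HAS_RESULT, H("HOIP:0060172"), "asserted") \
        in cg.edges
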