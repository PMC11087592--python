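"""Course membership, inheritance/specialization, and causal queries.

A *course* is a process sequence: the totality of processes through which a
phenomenon (here, cellular senescence) is realized.  Courses list their
member processes with ``has_part`` and form a subclass hierarchy; a
sub-course inherits the members of its super-courses, may *specialize* an
inherited member (assert a part that is a subclass of it, which then replaces
the general process) or *add* new members.

Causal queries (``causes_of`` / ``results_of``) run on the materialized
closure of the whole document and are then filtered to the members of the
requested course; crossing course boundaries is explicit via
``cross_course_results``.  Path enumeration uses asserted causal edges only —
on the closure every reachable pair would be one transitive edge.
All outputs are deterministically ordered (lexicographic by identifier).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .errors import EntityKindError, MappingError, ScopeError, UnknownTermError
from .model import (
    AxiomKind,
    Curie,
    EntityKind,
    HAS_PART,
    HAS_RESULT,
    IS_A,
    MANIFESTS_SYMPTOM,
    OCCURS_IN,
    REALIZES_DISEASE,
    HAS_OUTPUT,
    HAS_ROLE,
    normalize_curie,
)
from .reasoner import ASSERTED, InferredGraph

__all__ = [
    "Member",
    "CourseGraph",
    "SpecializationPair",
    "course_members",
    "causes_of",
    "results_of",
    "causal_paths",
    "cross_course_results",
    "common_generalized_processes",
    "generalized_causal_network",
    "build_course_graph",
]

DIRECT = "direct"
INHERITED = "inherited"
SPECIALIZED = "specialized"

#: Relations that attach non-process entities (molecules, roles, locations,
#: symptoms, diseases) to a process; included in exported course graphs.
ATTACHMENT_RELATIONS = (
    HAS_OUTPUT, HAS_ROLE, OCCURS_IN, MANIFESTS_SYMPTOM, REALIZES_DISEASE,
    "has_participant",
)


@dataclass(frozen=True)
class Member:
    process: Curie
    origin: str  # direct | inherited | specialized
    specializes: Optional[Curie] = None


@dataclass(frozen=True)
class SpecializationPair:
    general: Curie
    specialized: Curie
    course: Curie


@dataclass
class CourseGraph:
    """A per-course causal network of typed nodes and typed edges."""

    course_id: Optional[Curie]
    nodes: set = field(default_factory=set)   # (Curie, EntityKind, origin)
    edges: set = field(default_factory=set)   # (src, relation, dst, status)
    stage_tags: dict = field(default_factory=dict)

    def node_ids(self) -> list:
        return sorted({n[0] for n in self.nodes}, key=str)

    def sorted_edges(self) -> list:
        return sorted(self.edges, key=lambda e: (str(e[0]), e[1], str(e[2])))


# --------------------------------------------------------------------------
# Membership
# --------------------------------------------------------------------------


def _require_course(graph: InferredGraph, course: Curie) -> None:
    doc = graph.source_doc
    term = doc.terms.get(course)
    if term is None:
        raise UnknownTermError(str(course))
    if term.entity_kind is not EntityKind.COURSE:
        raise EntityKindError(f"{course} is {term.entity_kind.value}, not a course")


def _direct_parts(graph: InferredGraph, course: Curie) -> list:
    doc = graph.source_doc
    parts = {ax.object for ax in doc.existential_axioms()
             if ax.relation == HAS_PART and ax.subject == course}
    return sorted(parts, key=str)


def _is_strict_sub(graph: InferredGraph, sub: Curie, sup: Curie) -> bool:
    return (sub, sup) in graph.subsumptions


def course_members(graph: InferredGraph, course) -> list:
    """Members of a course with their origin.

    Direct ``has_part`` fillers, plus parts inherited from every
    super-course; an inherited part is replaced when the course (or a closer
    sub-course) asserts a part that is a strict subclass of it, recorded with
    origin ``specialized``.
    """
    course = normalize_curie(course)
    _require_course(graph, course)
    doc = graph.source_doc

    supercourses = sorted(
        (c for c in graph.superclasses(course)
         if c in doc.terms and doc.terms[c].entity_kind is EntityKind.COURSE),
        key=str)
    inherited = set()
    for sup in supercourses:
        inherited.update(_direct_parts(graph, sup))
    # Specialization between inherited levels: keep the most specific.
    for p in sorted(inherited, key=str):
        for q in sorted(inherited, key=str):
            if p != q and _is_strict_sub(graph, p, q):
                inherited.discard(q)

    members: dict = {}
    for p in sorted(inherited, key=str):
        members[p] = Member(p, INHERITED)
    for p in _direct_parts(graph, course):
        replaced = None
        for q in sorted(inherited, key=str):
            if q != p and _is_strict_sub(graph, p, q):
                replaced = q
                break
        if replaced is not None:
            members.pop(replaced, None)
            members[p] = Member(p, SPECIALIZED, specializes=replaced)
        else:
            members[p] = Member(p, DIRECT)
    return [members[k] for k in sorted(members, key=str)]


def member_ids(graph: InferredGraph, course) -> set:
    return {m.process for m in course_members(graph, course)}


def specialization_pairs(graph: InferredGraph, course) -> list:
    course = normalize_curie(course)
    return sorted(
        (SpecializationPair(m.specializes, m.process, course)
         for m in course_members(graph, course) if m.specializes is not None),
        key=lambda p: (str(p.general), str(p.specialized)))


# --------------------------------------------------------------------------
# Causal queries
# --------------------------------------------------------------------------


def _scope(graph: InferredGraph, process: Curie, course) -> Optional[set]:
    if course is None:
        return None
    scope = member_ids(graph, normalize_curie(course))
    if process not in scope:
        raise ScopeError(f"{process} is not a member of course {course}")
    return scope


def causes_of(graph: InferredGraph, process, course=None) -> list:
    """All processes entailed causally upstream of ``process`` (transitive).

    With ``course`` given the result is restricted to that course's members;
    ``process`` itself must then be a member.
    """
    process = normalize_curie(process)
    if graph.source_doc is not None and process not in graph.source_doc.terms:
        raise UnknownTermError(str(process))
    scope = _scope(graph, process, course)
    found = {s for s in graph.subjects(HAS_RESULT, process) if s != process}
    if scope is not None:
        found &= scope
    return sorted(found, key=str)


def results_of(graph: InferredGraph, process, course=None) -> list:
    """Mirror of :func:`causes_of` downstream (via the has_cause inverse)."""
    process = normalize_curie(process)
    if graph.source_doc is not None and process not in graph.source_doc.terms:
        raise UnknownTermError(str(process))
    scope = _scope(graph, process, course)
    found = {o for o in graph.objects(process, HAS_RESULT) if o != process}
    if scope is not None:
        found &= scope
    return sorted(found, key=str)


def _asserted_causal_digraph(graph: InferredGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    doc = graph.source_doc
    for ax in doc.existential_axioms():
        if ax.relation == HAS_RESULT:
            g.add_edge(ax.subject, ax.object)
    return g


def causal_paths(graph: InferredGraph, src, dst, max_len: int) -> list:
    """All simple paths over *asserted* causal edges, up to ``max_len`` edges."""
    src = normalize_curie(src)
    dst = normalize_curie(dst)
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    doc = graph.source_doc
    for c in (src, dst):
        if c not in doc.terms:
            raise UnknownTermError(str(c))
    if src == dst:
        return [[src]]
    g = _asserted_causal_digraph(graph)
    if src not in g or dst not in g:
        return []
    paths = [list(p) for p in nx.all_simple_paths(g, src, dst, cutoff=max_len)]
    return sorted(paths, key=lambda p: [str(c) for c in p])


def _all_courses(graph: InferredGraph) -> list:
    doc = graph.source_doc
    return sorted((t.id for t in doc.terms.values()
                   if t.entity_kind is EntityKind.COURSE), key=str)


def cross_course_results(graph: InferredGraph, process_class) -> dict:
    """Entailed downstream results of a process class, per course.

    For every course the class — or any course-specific subclass of it —
    belongs to, report the entailed results restricted to that course's
    members.  Courses with no results are omitted.
    """
    process_class = normalize_curie(process_class)
    if process_class not in graph.source_doc.terms:
        raise UnknownTermError(str(process_class))
    variants = {process_class} | graph.subclasses(process_class)
    out = {}
    for course in _all_courses(graph):
        scope = member_ids(graph, course)
        hits = set()
        for v in sorted(variants & scope, key=str):
            hits.update(o for o in graph.objects(v, HAS_RESULT) if o != v)
        hits &= scope
        hits -= variants
        if hits:
            out[course] = sorted(hits, key=str)
    return out


def common_generalized_processes(graph: InferredGraph, course_a, course_b,
                                 exclude=()) -> list:
    """Pairs of members from two courses sharing a generalizing superclass.

    Returns triples ``(superclass, member_a, member_b)`` where the
    superclass is the least common subsumer (ties broken by identifier
    order).  ``exclude`` removes trivial roots from consideration.
    """
    course_a = normalize_curie(course_a)
    course_b = normalize_curie(course_b)
    excluded = {normalize_curie(c) for c in exclude}
    members_a = member_ids(graph, course_a)
    members_b = member_ids(graph, course_b)

    def anc_or_self(c):
        return ({c} | graph.superclasses(c)) - excluded

    triples = set()
    for a in sorted(members_a, key=str):
        for b in sorted(members_b, key=str):
            common = anc_or_self(a) & anc_or_self(b)
            if not common:
                continue
            minimal = [c for c in common
                       if not any(d != c and (d, c) in graph.subsumptions
                                  for d in common)]
            lcs = sorted(minimal, key=str)[0]
            triples.add((lcs, a, b))
    return sorted(triples, key=lambda t: (str(t[0]), str(t[1]), str(t[2])))


def generalized_causal_network(graph: InferredGraph, courses: Iterable,
                               level: dict) -> CourseGraph:
    """Quotient causal network over an abstraction map.

    ``level`` maps member processes to a chosen superclass (identity for
    unmapped members); nodes are the abstraction targets and an edge is
    present iff some pair of mapped members carries an entailed causal edge
    within any listed course.
    """
    doc = graph.source_doc
    level = {normalize_curie(k): normalize_curie(v) for k, v in level.items()}
    for member, target in sorted(level.items(), key=lambda kv: str(kv[0])):
        if target != member and (member, target) not in graph.subsumptions:
            raise MappingError(
                f"abstraction target {target} is not an ancestor of {member}")

    out = CourseGraph(course_id=None)
    for course in sorted((normalize_curie(c) for c in courses), key=str):
        scope = member_ids(graph, course)
        mapped = {m: level.get(m, m) for m in scope}
        for m, t in sorted(mapped.items(), key=lambda kv: str(kv[0])):
            kind = doc.terms[t].entity_kind if t in doc.terms else EntityKind.OTHER
            out.nodes.add((t, kind, DIRECT))
        for m1 in sorted(scope, key=str):
            for m2 in sorted(graph.objects(m1, HAS_RESULT) & scope, key=str):
                t1, t2 = mapped[m1], mapped[m2]
                if t1 == t2:
                    continue
                status = (ASSERTED if graph.edges[(m1, HAS_RESULT, m2)].status
                          == ASSERTED else "inferred")
                out.edges.add((t1, HAS_RESULT, t2, status))
    return out


# --------------------------------------------------------------------------
# Export-ready course graphs
# --------------------------------------------------------------------------


def build_course_graph(graph: InferredGraph, course, include_attachments: bool = True,
                       include_isa: bool = False) -> CourseGraph:
    """Assemble the asserted network of one course for export.

    Nodes are the course members plus (optionally) attached molecules, roles,
    locations, symptoms and diseases; edges are the asserted causal and
    part-whole edges among members plus the attachment edges.  With
    ``include_isa`` the general class of every specialized member is included
    and linked by a dotted ``is_a`` edge, mirroring how inherited processes
    are drawn across super- and sub-courses.
    """
    course = normalize_curie(course)
    doc = graph.source_doc
    members = course_members(graph, course)
    ids = {m.process for m in members}

    cg = CourseGraph(course_id=course)
    for m in members:
        term = doc.terms.get(m.process)
        kind = term.entity_kind if term else EntityKind.OTHER
        cg.nodes.add((m.process, kind, m.origin))
        if term is not None and term.stage is not None:
            cg.stage_tags[m.process] = term.stage

    for ax in doc.existential_axioms():
        if ax.subject not in ids:
            continue
        if ax.relation in (HAS_RESULT, HAS_PART) and ax.object in ids:
            cg.edges.add((ax.subject, ax.relation, ax.object, ASSERTED))
        elif include_attachments and ax.relation in ATTACHMENT_RELATIONS:
            term = doc.terms.get(ax.object)
            kind = term.entity_kind if term else EntityKind.OTHER
            cg.nodes.add((ax.object, kind, DIRECT))
            cg.edges.add((ax.subject, ax.relation, ax.object, ASSERTED))

    if include_isa:
        for m in members:
            if m.specializes is not None:
                term = doc.terms.get(m.specializes)
                kind = term.entity_kind if term else EntityKind.OTHER
                cg.nodes.add((m.specializes, kind, INHERITED))
                cg.edges.add((m.process, IS_A, m.specializes, ASSERTED))
        node_ids = {n[0] for n in cg.nodes}
        for (a, b) in sorted(graph.subsumptions, key=lambda p: (str(p[0]), str(p[1]))):
            if a in node_ids and b in node_ids:
                cg.edges.add((a, IS_A, b, ASSERTED))
    return cg
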