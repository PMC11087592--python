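"""Materialization of entailed edges under the fragment's rule calculus.

The calculus closes the asserted edge set under six completion rules:

* R1 — subsumption transitivity: ``A ⊑ B, B ⊑ C ⇒ A ⊑ C``;
* R2 — restriction inheritance: ``A ⊑ B, B -R-> C ⇒ A -R-> C``;
* R3 — filler generalization: ``A -R-> B, B ⊑ C ⇒ A -R-> C``;
* R4 — transitive relations: ``A -R-> B, B -R-> C ⇒ A -R-> C``;
* R5 — property chains ``S = R1 ∘ R2``: ``A -R1-> B, B -R2-> C ⇒ A -S-> C``;
* R6 — inverse completion: ``A -R-> B ⇒ B -R⁻-> A``.

No rule derives new subsumptions, so the class hierarchy is closed once
(R1) and the edge rules run to a least fixpoint by semi-naive evaluation:
only newly derived edges re-fire rules, in deterministic (insertion) order,
so derivation traces are reproducible.  Termination is guaranteed because
the class and relation sets are finite and rules only add edges.

Note that for inverse-paired relations the combination of R2/R3/R6 lets an
edge migrate to sub- *and* super-classes of either endpoint; see the methods
note for why this edge-inheritance semantics is used.

``brute_force_closure`` is an independent, naive re-implementation used as
a testing oracle; it shares no code with ``materialize``.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ChainConfigError, GuardLimitError, UnknownTermError
from .model import (
    Axiom,
    AxiomKind,
    Curie,
    OntologyDocument,
    RelationType,
)

__all__ = [
    "InferredEdge",
    "InferredGraph",
    "EntailmentResult",
    "materialize",
    "brute_force_closure",
    "entails",
]

ASSERTED = "asserted"
INFERRED = "inferred"


@dataclass(frozen=True)
class InferredEdge:
    subject: Curie
    relation: str
    object: Curie
    status: str
    derivation: tuple

    @property
    def key(self) -> tuple:
        return (self.subject, self.relation, self.object)


@dataclass
class InferredGraph:
    """The materialized closure of one document."""

    edges: dict = field(default_factory=dict)  # (s, rel, o) -> InferredEdge
    subsumptions: frozenset = frozenset()      # strict (sub, super) pairs
    source_doc: Optional[OntologyDocument] = None
    _out: dict = field(default_factory=dict, repr=False)   # rel -> s -> set(o)
    _in: dict = field(default_factory=dict, repr=False)    # rel -> o -> set(s)

    def has_edge(self, subject, relation: str, obj) -> bool:
        return (subject, relation, obj) in self.edges

    def objects(self, subject, relation: str) -> set:
        return set(self._out.get(relation, {}).get(subject, ()))

    def subjects(self, relation: str, obj) -> set:
        return set(self._in.get(relation, {}).get(obj, ()))

    def superclasses(self, c) -> set:
        return {b for (a, b) in self.subsumptions if a == c}

    def subclasses(self, c) -> set:
        return {a for (a, b) in self.subsumptions if b == c}

    def triples(self) -> set:
        return set(self.edges)

    def to_tsv(self) -> str:
        """Triple table: subject, relation, object, status."""
        lines = ["subject\trelation\tobject\tstatus"]
        for key in sorted(self.edges, key=lambda k: (str(k[0]), k[1], str(k[2]))):
            e = self.edges[key]
            lines.append(f"{e.subject}\t{e.relation}\t{e.object}\t{e.status}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class EntailmentResult:
    holds: bool
    derivation: Optional[tuple] = None

    def __bool__(self) -> bool:
        return self.holds


# --------------------------------------------------------------------------
# Materialization (semi-naive)
# --------------------------------------------------------------------------


def _subsumption_closure(doc: OntologyDocument) -> frozenset:
    """Strict transitive closure of asserted named subsumptions (R1)."""
    direct = defaultdict(set)
    for ax in doc.subclass_axioms():
        if ax.subject != ax.object:
            direct[ax.subject].add(ax.object)
    pairs = set()
    for start in sorted(direct, key=str):
        stack = sorted(direct[start], key=str)
        seen = set()
        while stack:
            nxt = stack.pop()
            if nxt in seen:
                continue
            seen.add(nxt)
            if nxt != start:
                pairs.add((start, nxt))
            stack.extend(sorted(direct.get(nxt, ()), key=str))
    return frozenset(pairs)


def _check_chains(rels: dict) -> None:
    for name, rel in rels.items():
        if rel.chain is not None:
            for link in rel.chain:
                if link not in rels:
                    raise ChainConfigError(
                        f"chain of {name!r} references undeclared relation {link!r}")


def materialize(doc: OntologyDocument, registry: Optional[dict] = None) -> InferredGraph:
    """Compute the least fixpoint of the completion rules for ``doc``."""
    rels = dict(registry) if registry is not None else doc.effective_relations()
    _check_chains(rels)

    subs = _subsumption_closure(doc)
    supers_of = defaultdict(list)
    subs_of = defaultdict(list)
    for a, b in sorted(subs, key=lambda p: (str(p[0]), str(p[1]))):
        supers_of[a].append(b)
        subs_of[b].append(a)

    # chain triggers: relation R -> [(chain_name, position)]
    chain_first = defaultdict(list)
    chain_second = defaultdict(list)
    for name, rel in sorted(rels.items()):
        if rel.chain is not None:
            chain_first[rel.chain[0]].append(name)
            chain_second[rel.chain[1]].append(name)

    graph = InferredGraph(subsumptions=subs, source_doc=doc)
    out = graph._out
    inc = graph._in
    queue: deque = deque()

    def add(s, r, o, status, derivation) -> None:
        key = (s, r, o)
        if key in graph.edges:
            return
        edge = InferredEdge(s, r, o, status, tuple(derivation))
        graph.edges[key] = edge
        out.setdefault(r, {}).setdefault(s, set()).add(o)
        inc.setdefault(r, {}).setdefault(o, set()).add(s)
        queue.append(edge)

    for ax in sorted(doc.existential_axioms(),
                     key=lambda a: (str(a.subject), a.relation, str(a.object))):
        add(ax.subject, ax.relation, ax.object, ASSERTED,
            (f"asserted: {ax.subject} {ax.relation} {ax.object}",))

    def fmt(s, r, o) -> str:
        return f"{s} {r} {o}"

    while queue:
        e = queue.popleft()
        s, r, o = e.subject, e.relation, e.object
        rel = rels.get(r)
        # R2: push the edge down to subclasses of the subject.
        for sub in subs_of.get(s, ()):
            add(sub, r, o, INFERRED, (f"R2: {sub} ⊑ {s}", fmt(s, r, o)))
        # R3: generalize the filler to superclasses of the object.
        for sup in supers_of.get(o, ()):
            add(s, r, sup, INFERRED, (fmt(s, r, o), f"R3: {o} ⊑ {sup}"))
        # R4: compose along a transitive relation.
        if rel is not None and rel.transitive:
            for o2 in sorted(out.get(r, {}).get(o, ()), key=str):
                add(s, r, o2, INFERRED, ("R4", fmt(s, r, o), fmt(o, r, o2)))
            for s0 in sorted(inc.get(r, {}).get(s, ()), key=str):
                add(s0, r, o, INFERRED, ("R4", fmt(s0, r, s), fmt(s, r, o)))
        # R5: property chains.
        for chain_name in chain_first.get(r, ()):
            second = rels[chain_name].chain[1]
            for o2 in sorted(out.get(second, {}).get(o, ()), key=str):
                add(s, chain_name, o2, INFERRED,
                    ("R5", fmt(s, r, o), fmt(o, second, o2)))
        for chain_name in chain_second.get(r, ()):
            first = rels[chain_name].chain[0]
            for s0 in sorted(inc.get(first, {}).get(s, ()), key=str):
                add(s0, chain_name, o, INFERRED,
                    ("R5", fmt(s0, first, s), fmt(s, r, o)))
        # R6: inverse completion.
        if rel is not None and rel.inverse_of is not None:
            add(o, rel.inverse_of, s, INFERRED, ("R6", fmt(s, r, o)))
    return graph


def entails(graph: InferredGraph, subject, relation: str, obj) -> EntailmentResult:
    """Is the edge (or a generalization already in the closure) entailed?

    The materialized closure contains every subsumption-entailed
    generalization, so this is a membership check that returns the recorded
    derivation trace.
    """
    from .model import normalize_curie

    s = normalize_curie(subject)
    o = normalize_curie(obj)
    doc = graph.source_doc
    if doc is not None:
        for c in (s, o):
            if c not in doc.terms and c not in doc.referenced_curies():
                raise UnknownTermError(str(c))
    edge = graph.edges.get((s, relation, o))
    if edge is None:
        return EntailmentResult(False, None)
    return EntailmentResult(True, edge.derivation)


# --------------------------------------------------------------------------
# Brute-force oracle (independent code path)
# --------------------------------------------------------------------------


def brute_force_closure(doc: OntologyDocument, registry: Optional[dict] = None,
                        max_classes: int = 200) -> frozenset:
    """Naive fixpoint: re-apply every rule to everything until no change.

    Intended as a small-document testing oracle; refuses documents with more
    than ``max_classes`` classes.  Returns the set of entailed
    ``(subject, relation, object)`` triples (asserted edges included).
    """
    classes = set(doc.terms) | doc.referenced_curies()
    if len(classes) > max_classes:
        raise GuardLimitError(
            f"brute-force oracle limited to {max_classes} classes, "
            f"got {len(classes)}")
    rels = dict(registry) if registry is not None else doc.effective_relations()
    _check_chains(rels)

    subs = {(a.subject, a.object) for a in doc.subclass_axioms()
            if a.subject != a.object}
    edges = {(a.subject, a.relation, a.object) for a in doc.existential_axioms()}

    changed = True
    while changed:
        changed = False
        # R1 on subsumptions.
        new_subs = set()
        for (a, b) in subs:
            for (c, d) in subs:
                if b == c and a != d:
                    new_subs.add((a, d))
        if not new_subs <= subs:
            subs |= new_subs
            changed = True

        new_edges = set()
        sub_down = defaultdict(set)   # class -> its subclasses
        sup_up = defaultdict(set)     # class -> its superclasses
        for (a, b) in subs:
            sub_down[b].add(a)
            sup_up[a].add(b)
        by_rel = defaultdict(set)
        for (s, r, o) in edges:
            by_rel[r].add((s, o))
        for (s, r, o) in edges:
            for a in sub_down.get(s, ()):        # R2
                new_edges.add((a, r, o))
            for b in sup_up.get(o, ()):          # R3
                new_edges.add((s, r, b))
            rel = rels.get(r)
            if rel is not None:
                if rel.transitive:               # R4
                    for (s2, o2) in by_rel[r]:
                        if s2 == o:
                            new_edges.add((s, r, o2))
                if rel.inverse_of is not None:   # R6
                    new_edges.add((o, rel.inverse_of, s))
        for name, rel in rels.items():           # R5
            if rel.chain is not None:
                r1, r2 = rel.chain
                for (s, o) in by_rel[r1]:
                    for (s2, o2) in by_rel[r2]:
                        if s2 == o:
                            new_edges.add((s, name, o2))
        if not new_edges <= edges:
            edges |= new_edges
            changed = True
    return frozenset(edges)
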