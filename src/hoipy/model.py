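"""Typed in-memory model of a homeostasis-imbalance process ontology fragment.

The fragment is deliberately small: named classes (terms), object properties
with a few logical characteristics (transitivity, inverses, a two-step
property chain), and two axiom shapes — named-class subsumption and
existential restrictions over named fillers.  An existential axiom
``X ⊑ ∃R.Y`` is read as a directed, typed edge ``X -R-> Y`` between classes;
all reasoning in this package happens at the class level (no individuals).

Entity kinds (process, course, molecule, role, ...) are stored explicitly on
each term rather than derived from upper-ontology ancestry, because the
upper layers of the source ontologies are out of scope here.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from .errors import AxiomError, CurieParseError

__all__ = [
    "Curie",
    "EntityKind",
    "Term",
    "RelationType",
    "AxiomKind",
    "Axiom",
    "OntologyDocument",
    "ValidationReport",
    "Violation",
    "normalize_curie",
    "canonical_relation_registry",
    "validate_document",
    "bioportal_uri",
    "HAS_PART",
    "PART_OF",
    "HAS_RESULT",
    "HAS_CAUSE",
    "HAS_PART_RESULT",
    "HAS_OUTPUT",
    "HAS_ROLE",
    "OCCURS_IN",
    "MANIFESTS_SYMPTOM",
    "REALIZES_DISEASE",
    "IS_A",
]


# --------------------------------------------------------------------------
# Compact identifiers
# --------------------------------------------------------------------------

_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)[:_]([A-Za-z0-9][A-Za-z0-9.-]*)$")
_TAIL_UNDERSCORE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*?)_([A-Za-z0-9][A-Za-z0-9.-]*)$")
_TAIL_FUSED_RE = re.compile(r"^([A-Za-z]+)([0-9]+)$")


@dataclass(frozen=True, order=True)
class Curie:
    """A compact identifier ``PREFIX:LOCALID`` (e.g. ``HOIP:0060102``)."""

    prefix: str
    local_id: str

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    def __repr__(self) -> str:
        return f"Curie({str(self)!r})"

    @classmethod
    def parse(cls, raw: "str | Curie") -> "Curie":
        return normalize_curie(raw)


def normalize_curie(raw: "str | Curie") -> Curie:
    """Normalize an identifier to colon form.

    Accepts ``PREFIX:LOCAL``, ``PREFIX_LOCAL``, OBO-style IRIs ending in
    ``PREFIX_LOCAL``, and BioPortal-style IRIs ending in ``PREFIXLOCAL``
    (e.g. ``http://purl.bioontology.org/ontology/HOIP/HOIP0060144``).
    Idempotent on its own output.
    """
    if isinstance(raw, Curie):
        return raw
    if not isinstance(raw, str):
        raise CurieParseError(f"not an identifier: {raw!r}")
    s = raw.strip()
    if not s:
        raise CurieParseError("empty identifier")
    if s.startswith(("http://", "https://")):
        if "#" in s:
            tail = s.rsplit("#", 1)[1]
        else:
            tail = s.rstrip("/").rsplit("/", 1)[-1]
        m = _TAIL_UNDERSCORE_RE.match(tail)
        if m:
            return Curie(m.group(1), m.group(2))
        m = _TAIL_FUSED_RE.match(tail)
        if m:
            return Curie(m.group(1), m.group(2))
        raise CurieParseError(f"cannot extract an identifier from IRI {raw!r}")
    m = _CURIE_RE.match(s)
    if m:
        return Curie(m.group(1), m.group(2))
    raise CurieParseError(f"malformed identifier {raw!r}")


def bioportal_uri(curie: "Curie | str") -> str:
    """External URI for a term: BioPortal pattern for HOIP ids, OBO PURL otherwise."""
    c = normalize_curie(curie)
    if c.prefix == "HOIP":
        return f"http://purl.bioontology.org/ontology/HOIP/HOIP{c.local_id}"
    return f"http://purl.obolibrary.org/obo/{c.prefix}_{c.local_id}"


# --------------------------------------------------------------------------
# Terms and relations
# --------------------------------------------------------------------------


class EntityKind(str, enum.Enum):
    COURSE = "course"
    PROCESS = "process"
    MATERIAL_ENTITY = "material_entity"
    ROLE = "role"
    DISEASE = "disease"
    SYMPTOM = "symptom"
    PHENOTYPE = "phenotype"
    ANATOMICAL_ENTITY = "anatomical_entity"
    OTHER = "other"


@dataclass
class Term:
    """One ontology class.

    ``stage`` carries the optional homeostasis-imbalance stage annotation
    (see :mod:`hoipy.imbalance`), ``negated`` marks "no X" processes (which
    are ordinary process terms, not logical complements), and ``taxon`` holds
    an optional taxon restriction such as ``NCBITaxon:9606`` for human
    molecules.
    """

    id: Curie
    label: str = ""
    entity_kind: EntityKind = EntityKind.OTHER
    definition: str = ""
    description: str = ""
    xrefs: tuple = ()
    stage: Optional[str] = None
    negated: bool = False
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        self.id = normalize_curie(self.id)
        self.entity_kind = EntityKind(self.entity_kind)
        self.xrefs = tuple(sorted(self.xrefs))

    @property
    def is_human(self) -> bool:
        return self.taxon is not None and self.taxon.endswith("9606")


@dataclass(frozen=True)
class RelationType:
    """A named object property with its logical characteristics."""

    id: str
    label: str = ""
    transitive: bool = False
    inverse_of: Optional[str] = None
    chain: Optional[tuple] = None
    domain_kind: Optional[EntityKind] = None
    range_kind: Optional[EntityKind] = None

    def __post_init__(self) -> None:
        if self.chain is not None:
            object.__setattr__(self, "chain", tuple(self.chain))
            if len(self.chain) != 2:
                raise AxiomError(
                    f"relation {self.id!r}: a property chain must have exactly "
                    f"two elements, got {self.chain!r}"
                )


# Canonical relation names used throughout the package.
HAS_PART = "has_part"
PART_OF = "part_of"
HAS_RESULT = "has_result"
HAS_CAUSE = "has_cause"
HAS_PART_RESULT = "has_part_result"
HAS_OUTPUT = "has_output"
HAS_ROLE = "has_role"
OCCURS_IN = "occurs_in"
MANIFESTS_SYMPTOM = "manifests_symptom"
REALIZES_DISEASE = "realizes_disease"
#: Pseudo-relation used only in exports to draw subsumption (dotted) edges.
IS_A = "is_a"

_CAUSAL_RELATIONS = frozenset({HAS_RESULT, HAS_CAUSE})


def canonical_relation_registry(has_part_transitive: bool = False) -> dict:
    """The fixed registry of relations the course model is built from.

    ``has_result``/``has_cause`` are transitive inverses (the causal
    relation), ``has_part``/``part_of`` are inverses (non-transitive by
    default; flip with ``has_part_transitive``), and ``has_part_result`` is
    defined by the property chain ``has_part ∘ has_result`` so that a whole
    process is linked to the downstream results of its sub-processes.
    """
    rels = [
        RelationType(HAS_PART, "has part", transitive=has_part_transitive,
                     inverse_of=PART_OF),
        RelationType(PART_OF, "part of", transitive=has_part_transitive,
                     inverse_of=HAS_PART),
        RelationType(HAS_RESULT, "has result", transitive=True,
                     inverse_of=HAS_CAUSE),
        RelationType(HAS_CAUSE, "has cause", transitive=True,
                     inverse_of=HAS_RESULT),
        RelationType(HAS_PART_RESULT, "has part result",
                     chain=(HAS_PART, HAS_RESULT)),
        RelationType(HAS_OUTPUT, "has output"),
        RelationType(HAS_ROLE, "has role", range_kind=EntityKind.ROLE),
        RelationType(OCCURS_IN, "occurs in"),
        RelationType(MANIFESTS_SYMPTOM, "manifests symptom",
                     range_kind=EntityKind.SYMPTOM),
        RelationType(REALIZES_DISEASE, "realizes disease",
                     domain_kind=EntityKind.PROCESS,
                     range_kind=EntityKind.DISEASE),
    ]
    return {r.id: r for r in rels}


# --------------------------------------------------------------------------
# Axioms and documents
# --------------------------------------------------------------------------


class AxiomKind(str, enum.Enum):
    SUBCLASS_OF = "subclass_of"
    EXISTENTIAL = "existential"


@dataclass(frozen=True)
class Axiom:
    """A subclass axiom: named subsumption or ``subject ⊑ ∃relation.object``.

    ``provenance`` is bookkeeping only and does not take part in equality.
    """

    subject: Curie
    kind: AxiomKind
    object: Curie
    relation: Optional[str] = None
    provenance: str = field(default="asserted", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject", normalize_curie(self.subject))
        object.__setattr__(self, "object", normalize_curie(self.object))
        object.__setattr__(self, "kind", AxiomKind(self.kind))
        if self.kind is AxiomKind.SUBCLASS_OF and self.relation is not None:
            raise AxiomError("subclass_of axioms carry no relation")
        if self.kind is AxiomKind.EXISTENTIAL and not self.relation:
            raise AxiomError("existential axioms require a relation")
        if (
            self.kind is AxiomKind.EXISTENTIAL
            and self.relation in _CAUSAL_RELATIONS
            and self.subject == self.object
        ):
            raise AxiomError(f"asserted self-cause on {self.subject}")

    @property
    def triple(self) -> tuple:
        return (self.subject, self.relation, self.object)


def subclass_of(subject, obj, provenance: str = "asserted") -> Axiom:
    return Axiom(normalize_curie(subject), AxiomKind.SUBCLASS_OF,
                 normalize_curie(obj), provenance=provenance)


def existential(subject, relation: str, obj, provenance: str = "asserted") -> Axiom:
    return Axiom(normalize_curie(subject), AxiomKind.EXISTENTIAL,
                 normalize_curie(obj), relation=relation, provenance=provenance)


@dataclass
class OntologyDocument:
    """Terms, relations and axioms of one ontology fragment."""

    terms: dict = field(default_factory=dict)
    relations: dict = field(default_factory=dict)
    axioms: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    def add_term(self, term: Term) -> Term:
        if term.id in self.terms:
            raise AxiomError(f"duplicate term id {term.id}")
        self.terms[term.id] = term
        return term

    def add_relation(self, relation: RelationType) -> RelationType:
        self.relations[relation.id] = relation
        return relation

    def add_axiom(self, axiom: Axiom) -> Axiom:
        self.axioms.append(axiom)
        return axiom

    # -- access -----------------------------------------------------------

    def term(self, curie) -> Term:
        from .errors import UnknownTermError

        c = normalize_curie(curie)
        try:
            return self.terms[c]
        except KeyError:
            raise UnknownTermError(str(c)) from None

    def subclass_axioms(self) -> Iterator[Axiom]:
        return (a for a in self.axioms if a.kind is AxiomKind.SUBCLASS_OF)

    def existential_axioms(self) -> Iterator[Axiom]:
        return (a for a in self.axioms if a.kind is AxiomKind.EXISTENTIAL)

    def referenced_curies(self) -> set:
        out = set()
        for a in self.axioms:
            out.add(a.subject)
            out.add(a.object)
        return out

    def dangling_references(self) -> list:
        return sorted((c for c in self.referenced_curies() if c not in self.terms),
                      key=str)

    def effective_relations(self) -> dict:
        """Canonical registry overlaid with document-local declarations."""
        rels = canonical_relation_registry()
        rels.update(self.relations)
        return rels

    def copy(self) -> "OntologyDocument":
        return OntologyDocument(
            terms={k: replace(v) for k, v in self.terms.items()},
            relations=dict(self.relations),
            axioms=list(self.axioms),
            metadata=dict(self.metadata),
        )


def documents_equal(a: OntologyDocument, b: OntologyDocument) -> bool:
    """Order-insensitive equality on (terms, relations, axioms)."""
    return (
        a.terms == b.terms
        and a.relations == b.relations
        and set(a.axioms) == set(b.axioms)
    )


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    kind: str
    message: str


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def of_kind(self, kind: str) -> list:
        return [v for v in self.violations if v.kind == kind]

    def as_dict(self) -> dict:
        return {
            "ok": self.ok,
            "violations": [{"kind": v.kind, "message": v.message}
                           for v in self.violations],
        }


def validate_document(doc: OntologyDocument, registry: Optional[dict] = None) -> ValidationReport:
    """Check domain/range constraints, relation declarations and references.

    Violations are data, not exceptions: external ontologies referenced by a
    fragment will usually not be fully present, so dangling identifiers are
    reported rather than treated as fatal.
    """
    rels = dict(registry) if registry is not None else canonical_relation_registry()
    rels.update(doc.relations)
    report = ValidationReport()

    for name, rel in sorted(rels.items()):
        if rel.inverse_of is not None:
            partner = rels.get(rel.inverse_of)
            if partner is None or partner.inverse_of != name:
                report.violations.append(Violation(
                    "inverse_asymmetry",
                    f"relation {name!r} declares inverse {rel.inverse_of!r} "
                    f"without a mirrored declaration"))
        if rel.chain is not None:
            for link in rel.chain:
                if link not in rels:
                    report.violations.append(Violation(
                        "unknown_relation",
                        f"chain of {name!r} references undeclared relation {link!r}"))

    for c in doc.dangling_references():
        report.violations.append(Violation(
            "dangling", f"axiom references {c} which has no term"))

    for ax in doc.existential_axioms():
        rel = rels.get(ax.relation)
        if rel is None:
            report.violations.append(Violation(
                "unknown_relation",
                f"axiom {ax.subject} -{ax.relation}-> {ax.object} uses an "
                f"undeclared relation"))
            continue
        subj = doc.terms.get(ax.subject)
        obj = doc.terms.get(ax.object)
        if rel.domain_kind is not None and subj is not None \
                and subj.entity_kind is not rel.domain_kind:
            report.violations.append(Violation(
                "domain",
                f"{ax.subject} ({subj.entity_kind.value}) violates domain "
                f"{rel.domain_kind.value} of {ax.relation!r}"))
        if rel.range_kind is not None and obj is not None \
                and obj.entity_kind is not rel.range_kind:
            report.violations.append(Violation(
                "range",
                f"{ax.object} ({obj.entity_kind.value}) violates range "
                f"{rel.range_kind.value} of {ax.relation!r}"))
    return report
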