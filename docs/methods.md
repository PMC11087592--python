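# Methods

## The ontology fragment

`hoipy` models a deliberately small OWL-DL fragment: named classes with
entity kinds stored explicitly per term (course, process, material entity,
role, disease, symptom, phenotype, anatomical entity), object properties
with transitivity, inverses and one two-element property chain, and two
axiom shapes — named subsumption and existential restrictions over named
fillers. Universal restrictions, intersections, complement classes,
individuals and annotation-property reasoning are out of scope; annotation
data (labels, definitions, cross-references, stage tags) ride along but do
not affect inference. "No X" processes (e.g. *no SASP secretion*) are
ordinary process terms carrying a boolean negation marker, not logical
complements: the fragment cannot express complement classes, and the
negation marker is only interpreted by validation-free styling rules.

All reasoning is at the class level. An existential axiom `X ⊑ ∃has_result.Y`
is treated as a directed causal edge between the classes `X` and `Y`; every
query the package answers is a class-level subsumption-style question.

## Rule calculus and its semantics

`materialize` closes the asserted edges under:

* **R1** subsumption transitivity (`A ⊑ B, B ⊑ C ⇒ A ⊑ C`);
* **R2** restriction inheritance (`A ⊑ B, B -R-> C ⇒ A -R-> C`);
* **R3** filler generalization (`A -R-> B, B ⊑ C ⇒ A -R-> C`);
* **R4** transitive composition;
* **R5** property chains (`S = R1 ∘ R2`);
* **R6** inverse completion (`A -R-> B ⇒ B -R⁻-> A`).

No rule creates subsumptions, so the hierarchy is closed once and the edge
rules run to a least fixpoint by semi-naive evaluation (only new edges
re-fire rules) in a deterministic order; derivation traces record the first
proof found and are reproducible. Termination follows from finiteness: rules
only add edges over fixed class/relation sets. Cycles are permitted —
biological feedback is real — and a cyclic causal loop closes to all ordered
pairs on the cycle, including self-loops in the closure (asserted
self-causes remain forbidden).

One consequence of taking R2, R3 and R6 together deserves emphasis: for an
inverse-paired relation, an edge endpoint can migrate both down (R2 on the
edge) *and* up the hierarchy (R6 to the inverse edge, R3 on its filler, R6
back). Iterating the two moves lets an endpoint reach any class connected to
it in the undirected specialization hierarchy. This is more permissive than
strict OWL existential semantics (where `B' ⊑ B` does not entail
`A ⊑ ∃R.B'`), and it is the package's chosen semantics: the calculus is a
graph-completion view of class-level edges in which causal knowledge
recorded on any variant of a process is shared across its specialization
family, and the inverse-coherence guarantee (`A has_result B` iff
`B has_cause A`) is non-negotiable. Queries stay meaningful because they are
filtered by course membership. Three independent implementations — the
semi-naive engine, a naive brute-force fixpoint, and the generator's
constructive closure built from graph reachability (undirected hierarchy
components for paired relations, descendant×ancestor closure for unpaired
ones, reachability for transitive ones, a join for the chain) — are required
by the test suite to agree exactly.

`has_part` is not transitive by default (only the causal pair is); the
registry constructor takes a flag to flip this.

## Course membership and queries

A course's members are its direct `has_part` fillers plus the parts of all
super-courses. Specialization detection: an asserted part of a sub-course
*replaces* an inherited part exactly when the materialized subsumptions say
it is a strict subclass of it; otherwise it is an added part. The same rule
resolves specialization between inherited levels.

Causal queries compute on the whole closure and then filter to course
members; crossing courses is explicit (`cross_course_results`, which also
follows course-specific subclasses of the queried process class). Path
enumeration uses asserted causal edges only — on the closure every reachable
pair is one transitive edge, so paths would be meaningless there — and a
path query from a node to itself returns the single zero-length path by
convention. All outputs are ordered lexicographically by normalized
identifier.

`common_generalized_processes` returns least common subsumers per member
pair (ties broken by identifier order); callers may pass identifiers to
exclude as trivial roots. `generalized_causal_network` builds the quotient
graph of an abstraction map after checking every target is an ancestor of
its member.

## The four-stage pattern

Stage tags (stress demand, stress response, imbalance, outcome) are
curator-supplied annotations on terms — the unified model is a
representation pattern, not a classifier — with a label-based heuristic
pre-tagger offered as a starting point and always overridable. The pattern
check requires a witness quadruple whose consecutive pairs are causally
*entailed*, not directly asserted, matching the coarse-grained arrows of the
stage model. No numeric "degree of imbalance" is attempted; quantifying
imbalance is an open problem the representation deliberately leaves to
curation.

## I/O and exports

OWL reading/writing goes through rdflib, restricted to the fragment:
restriction fillers must be named classes, anything else under
`rdfs:subClassOf` is skipped and reported with deterministic locations, and
identifiers referenced without a declaration are reported as dangling rather
than fabricated. Annotation IRIs default to OBO practice (`rdfs:label`,
IAO definition, `dcterms:description`, `oboInOwl:hasDbXref`) and are
configurable. Stage tags, negation markers and taxon restrictions round-trip
as annotation triples. RDF/XML output is produced by a small sorted-order
emitter because rdflib's RDF/XML serializer orders subjects by hash, which
is not stable across processes; parsing (both formats) and Turtle output use
rdflib directly. All writers are byte-deterministic for a given document.

Exports: SIF (edge list), GraphML (via networkx, with node/edge style
attributes) and CX (NDEx exchange JSON with nodes, edges, nodeAttributes,
edgeAttributes aspects; layout aspects are omitted — layout is a viewer
concern). Styling conventions: processes circles, material entities squares;
molecules orange, red when taxon-flagged human; roles light green,
phenotypes green, symptoms blue, diseases red; negation-marked processes
grey; subsumption (`is_a`) edges dotted and arrowless. Exact hex values are
a palette (YAML/JSON) because only the color names are conventional.

## The curated fixture and the generator

The curated document encodes the published course network: the course
taxonomy with its verbatim textual definitions, the adult and embryonic p21
chains, DDR with ATR/ATM parts (exercising the property chain), SASP
secretion with outputs/role/location, the type-2-diabetes chain, the LMNB1 →
cGAS-STING chain, CXCL8/IL-8 variants crossing into two COVID-19 courses,
the senolytics negation chain with metformin attached via a document-level
`has_participant` relation, and stage tags for the embryonic, acute and
chronic courses. Identifiers the published record does not print are minted
in a reserved `HOIP:99xxxxx` block and are synthetic, fixture-local ids;
where the record prints two ids for one label both are kept as distinct
terms cross-linked with `equivalent:` xrefs, since which spelling is
canonical is not stated. Edges described only in prose are encoded as single
asserted causal edges, keeping slash-labels as one term.

The random generator emulates curated-ontology sparsity: a specialization
forest (rate 0.3), a causal DAG with out-degree ≤ 2 per class and an
occasional feedback edge, part-whole links biased toward chain-triggering
motifs (density 0.2), and a few output attachments to exercise unpaired
relations. It does **not** emulate real-data features such as multi-parent
hierarchies, annotation noise, imported foreign terms or inter-ontology
cross-products, so passing property tests demonstrates correctness of the
calculus and I/O on in-fragment structure, not robustness to arbitrary
third-party OWL. Ground truth is computed constructively during generation
and the same seed always reproduces the same document.

## Problem sizes and numerical choices

The curated ontology has 80 terms and 132 axioms; its closure (≈2,000
edges) materializes in well under a second. Oracle comparisons use 100
random ontologies of 5–50 classes (exact set equality, a few seconds in
total); round-trip checks use the curated document plus 20 random documents
per serialization. There are no tolerances anywhere — every comparison in
the package and its tests is exact set or string equality. Ordering
ambiguities (derivations, witnesses, least common subsumers) are always
resolved lexicographically by normalized identifier.

## Known limitations

* The calculus is not an OWL-DL reasoner: no consistency checking, no
  unsatisfiability (the fragment cannot express contradiction), and the
  edge-inheritance semantics described above is deliberately broader than
  existential-restriction entailment.
* Course membership relies on explicit `has_part` axioms; processes
  attached only by causal edges are not members.
* Stage tagging is manual; the heuristic pre-tagger is lexical and will
  mis-tag labels that mention stress incidentally.
* Edges are qualitative; no causal strength, probability or imbalance
  magnitude is represented.
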