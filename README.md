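# hoipy

Cellular senescence — the stable proliferative arrest a cell enters under
stress — links molecular signaling to tissue damage and age-related disease,
but the knowledge describing it is scattered across textbooks, reviews and a
dozen biomedical ontologies. `hoipy` is a toolkit for working with
*homeostasis-imbalance process ontologies*: knowledge bases that organize
such mechanisms as **courses** (process sequences such as the embryonic,
acute and chronic cellular-senescence courses) whose member processes are
connected by a transitive causal relation. It is aimed at knowledge
engineers and aging researchers who want to query, check and visualize these
causal networks without running a full OWL reasoner or a SPARQL endpoint.

## The model

An ontology fragment is a set of classes (processes, courses, molecules,
roles, diseases, symptoms, ...) with two axiom shapes: named subsumption
`X ⊑ Y` and existential restrictions `X ⊑ ∃R.Y`, read as typed edges
`X -R-> Y`. The relation registry is fixed:

* `has_part` / `part_of` — inverses; courses list member processes with
  `has_part`, and processes may nest sub-processes;
* `has_result` / `has_cause` — transitive inverses; the causal relation
  between processes;
* `has_part_result` — defined by the property chain
  `has_part ∘ has_result ⊑ has_part_result`, linking a whole process to the
  downstream results of its parts;
* `has_output`, `has_role`, `occurs_in`, `manifests_symptom` (range:
  symptom) and `realizes_disease` (domain: process, range: disease).

`materialize` computes the least fixpoint of six completion rules
(subsumption transitivity; inheritance of edges by subclasses;
generalization of fillers to superclasses; transitive composition; property
chains; inverse completion), tagging every edge `asserted` or `inferred`
with a derivation trace. Course-level queries (`course_members`,
`causes_of`, `results_of`, `causal_paths`, `cross_course_results`,
`generalized_causal_network`) run on the closure and respect course
membership, including inheritance and specialization of member processes
along the course hierarchy. Each course can additionally be checked against
the four-stage homeostasis-imbalance pattern — (1) stress demand,
(2) stress response, (3) imbalance, (4) outcome — and exported as SIF,
GraphML or CX with the standard styling conventions (processes as circles,
material entities as squares, human molecules red, negation-marked "no X"
processes grey, subsumption edges dotted).

The `fixtures` module ships a curated cellular-senescence course ontology
(seven senescence courses plus two COVID-19 courses, the p21 activation
chains, the DDR/ATR/ATM part-whole motif, the SASP secretion description,
the type-2-diabetes chain ending in insulin resistance, the LMNB1 →
cGAS-STING chain and a senolytics negation chain), and a seeded random
generator whose ground-truth closure is computed constructively —
independently of both reasoner implementations — for property testing.

## Worked example

```python
from hoipy import (build_senescence_fixture, materialize, causes_of,
                   causal_paths, check_course_pattern)

doc = build_senescence_fixture()
graph = materialize(doc)

# What can cause insulin resistance within the diabetes-associated course?
print([str(c) for c in causes_of(graph, "HOIP:0060427", "HOIP:0060423")])
# ['HOIP:0060431', 'HOIP:0060432', 'HOIP:0060453',
#  'HOIP:0060455', 'HOIP:0060504', 'HOIP:0060512']

# One supporting path: telomere shortening -> beta-cell exhaustion ->
# positive regulation of SASP secretion -> SASP secretion -> insulin resistance
print(causal_paths(graph, "HOIP:0060431", "HOIP:0060427", 6)[0])
# [Curie('HOIP:0060431'), Curie('HOIP:0060453'), Curie('HOIP:0060455'),
#  Curie('HOIP:0060432'), Curie('HOIP:0060427')]

# The chronic course realizes all four homeostasis-imbalance stages.
print(check_course_pattern(graph, "HOIP:0060195").to_json())
# {"course": "HOIP:0060195",
#  "stages_present": ["imbalance", "outcome", "stress_demand", "stress_response"],
#  "ordered_witness": ["HOIP:9900080", "HOIP:0060337",
#                      "HOIP:9900082", "HOIP:0060240"],
#  "missing": []}
```

The six identifiers returned by `causes_of` are the transitive upstream
processes of insulin resistance (`HOIP:0060427`) that belong to the
chronic-senescence-with-type-2-diabetes course: telomere shortening, the
beta-cell exhaustion/SASP chain, FOXO signaling and TLR4 signaling. The
witness path of the pattern check names one tagged process per stage whose
consecutive pairs are causally entailed.

The same operations are available from the shell:

```bash
hoipy gen-fixture -o senescence.ttl
hoipy causes senescence.ttl --process HOIP:0060427 --course HOIP:0060423
hoipy export-viz senescence.ttl --course HOIP:0060418 --viz-format cx --include-isa
```

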