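"""The four-stage homeostasis-imbalance pattern.

A course is described by four stages: (1) stress, i.e. a rising functional
demand; (2) the stress response, the functioning process acting to maintain
homeostasis; (3) the imbalance between the two; and (4) the outcome (here,
cellular senescence and its sequelae).  Stages are curator-supplied
annotations on process terms — the pattern is a representation convention,
not a classifier — although a label-based heuristic pre-tagger is provided
as a starting point.

``check_course_pattern`` reports which stages a course covers and, when
possible, a witness path: one process per stage whose consecutive pairs are
causally entailed (entailment, not direct edges, matching the coarse arrows
of the stage diagram).
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import dataclass, field
from typing import Optional

from .errors import StageConflictError
from .model import Curie, EntityKind, HAS_RESULT, OntologyDocument, normalize_curie
from .reasoner import InferredGraph, entails

__all__ = ["Stage", "PatternReport", "assign_stage", "check_course_pattern",
           "suggest_stages"]


class Stage(str, enum.Enum):
    STRESS_DEMAND = "stress_demand"
    STRESS_RESPONSE = "stress_response"
    IMBALANCE = "imbalance"
    OUTCOME = "outcome"


_ORDER = (Stage.STRESS_DEMAND, Stage.STRESS_RESPONSE, Stage.IMBALANCE,
          Stage.OUTCOME)


@dataclass
class PatternReport:
    course: Curie
    stages_present: set
    ordered_witness: Optional[list]
    missing: set

    def as_dict(self) -> dict:
        return {
            "course": str(self.course),
            "stages_present": sorted(s.value for s in self.stages_present),
            "ordered_witness": ([str(c) for c in self.ordered_witness]
                                if self.ordered_witness else None),
            "missing": sorted(s.value for s in self.missing),
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)


def assign_stage(doc: OntologyDocument, process, stage: Stage,
                 force: bool = False) -> OntologyDocument:
    """Tag a process with a stage annotation (idempotent; conflicts need force)."""
    stage = Stage(stage)
    term = doc.term(process)
    if term.stage is not None and term.stage != stage.value and not force:
        raise StageConflictError(
            f"{term.id} already tagged {term.stage!r}; pass force=True to retag")
    term.stage = stage.value
    return doc


def check_course_pattern(graph: InferredGraph, course) -> PatternReport:
    """Which of the four stages does a course cover, and in causal order?

    The witness is the lexicographically first quadruple
    (demand, response, imbalance, outcome) of tagged members whose
    consecutive pairs are causally entailed.
    """
    from .courses import course_members

    course = normalize_curie(course)
    doc = graph.source_doc
    by_stage = {s: [] for s in _ORDER}
    for m in course_members(graph, course):
        term = doc.terms.get(m.process)
        if term is not None and term.stage is not None:
            by_stage[Stage(term.stage)].append(m.process)
    for s in _ORDER:
        by_stage[s].sort(key=str)

    present = {s for s in _ORDER if by_stage[s]}
    missing = set(_ORDER) - present

    witness = None
    if not missing:
        for combo in itertools.product(*(by_stage[s] for s in _ORDER)):
            if len(set(combo)) < 4:
                continue
            if all(entails(graph, a, HAS_RESULT, b)
                   for a, b in zip(combo, combo[1:])):
                witness = list(combo)
                break
    return PatternReport(course, present, witness, missing)


_DEMAND_HINTS = ("demand", "stress")
_RESPONSE_HINTS = ("stress response", "response")


def suggest_stages(doc: OntologyDocument) -> dict:
    """Label-based heuristic pre-tagging; always overridable by curation."""
    suggestions = {}
    for term in sorted(doc.terms.values(), key=lambda t: str(t.id)):
        if term.entity_kind is not EntityKind.PROCESS or term.stage is not None:
            continue
        label = term.label.lower()
        if any(h in label for h in _RESPONSE_HINTS) and "demand" not in label:
            suggestions[term.id] = Stage.STRESS_RESPONSE
        elif any(h in label for h in _DEMAND_HINTS):
            suggestions[term.id] = Stage.STRESS_DEMAND
        elif "imbalance" in label:
            suggestions[term.id] = Stage.IMBALANCE
    return suggestions
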