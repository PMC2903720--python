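"""Context weights and per-ontology score aggregation.

Every annotation gets an integer weight from its provenance context:
preferred-name match 10, synonym match 8, mapping expansion 7, and is_a
ancestor at level n ``floor(1 + 10 * exp(-0.2 * n))`` (9 at n=1, 7 at n=2,
4 at n=5, 3 at n=8, decaying to 1 for n > 12). An ontology's score is the
sum of its annotations' weights; the normalized score divides by the
ontology's concept count, favouring small specialized ontologies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

from .expansion import ANCESTOR, MAPPED, ExpandedAnnotation
from .matcher import DIRECT_PREFERRED, DIRECT_SYNONYM, DirectAnnotation, Span
from .store import ConceptRef, OntorecoError, Repository

Annotation = Union[DirectAnnotation, ExpandedAnnotation]


@dataclass(frozen=True)
class WeightTable:
    """Per-context annotation weights; defaults are the standard scheme above."""

    direct_preferred: float = 10.0
    direct_synonym: float = 8.0
    mapped: float = 7.0
    ancestor_a: float = 1.0
    ancestor_b: float = 10.0
    ancestor_k: float = 0.2

    def __post_init__(self) -> None:
        if min(self.direct_preferred, self.direct_synonym, self.mapped) <= 0:
            raise OntorecoError("context weights must be positive")


DEFAULT_WEIGHTS = WeightTable()


def annotation_weight(context: str, ancestor_level: int | None = None,
                      table: WeightTable = DEFAULT_WEIGHTS) -> float:
    """Weight of one annotation given its provenance context.

    Ancestor weights use the exponential decay a + b*e^(-k*n) truncated to
    an integer (floor), giving 9, 7, 4, 3 at levels 1, 2, 5, 8 and 1 beyond
    level 12 under the default parameters.
    """
    if context == DIRECT_PREFERRED:
        return table.direct_preferred
    if context == DIRECT_SYNONYM:
        return table.direct_synonym
    if context == MAPPED:
        return table.mapped
    if context == ANCESTOR:
        if ancestor_level is None or ancestor_level < 1:
            raise OntorecoError("ancestor context requires ancestor_level >= 1")
        return float(math.floor(
            table.ancestor_a + table.ancestor_b * math.exp(-table.ancestor_k * ancestor_level)
        ))
    raise OntorecoError(f"unknown annotation context {context!r}")


def weigh(annotations: Sequence[Annotation],
          table: WeightTable = DEFAULT_WEIGHTS) -> list[tuple[Annotation, float]]:
    """Attach a weight to every annotation."""
    out: list[tuple[Annotation, float]] = []
    for ann in annotations:
        level = getattr(ann, "ancestor_level", None)
        out.append((ann, annotation_weight(ann.context, level, table)))
    return out


def dedupe(weighted: Sequence[tuple[Annotation, float]]) -> list[tuple[Annotation, float]]:
    """Keep the single highest-weight annotation per (concept, span).

    Prevents one textual mention from crediting an ontology twice, e.g. when
    a mapping lands on a concept that was already matched directly.
    """
    best: dict[tuple[ConceptRef, tuple[int, int]], tuple[Annotation, float]] = {}
    for ann, weight in weighted:
        key = (ann.concept_ref, (ann.span.start, ann.span.end))
        if key not in best or weight > best[key][1]:
            best[key] = (ann, weight)
    return list(best.values())


@dataclass
class OntologyScore:
    """Aggregate for one ontology: raw score, size-normalized score, count."""

    ontology_id: str
    score: float
    normalized_score: float
    annotation_count: int
    weights: list[float] = field(default_factory=list)


def aggregate(weighted: Sequence[tuple[Annotation, float]],
              repo: Repository) -> list[OntologyScore]:
    """Sum weights per ontology; ontologies with zero annotations are omitted.

    normalized_score = score / ontology concept count, exactly.
    """
    totals: dict[str, list[float]] = {}
    for ann, weight in weighted:
        ontology_id = ann.concept_ref[0]
        if ontology_id not in repo.ontologies:
            raise OntorecoError(f"annotation references unknown ontology {ontology_id!r}")
        totals.setdefault(ontology_id, []).append(weight)
    scores = []
    for ontology_id in sorted(totals):
        weights = totals[ontology_id]
        score = sum(weights)
        size = repo.ontologies[ontology_id].size()
        scores.append(
            OntologyScore(
                ontology_id=ontology_id,
                score=score,
                normalized_score=score / size,
                annotation_count=len(weights),
                weights=sorted(weights, reverse=True),
            )
        )
    return scores
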