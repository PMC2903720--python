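"""Semantic expansion of direct annotations.

Two independent passes over the direct annotations: cross-ontology mapping
expansion (the CR+M method) and optional is_a ancestor expansion. Both
conserve the seed's text span; mapping expansion is single-hop (mappings of
mapped concepts are not chased, and mapped concepts do not re-seed ancestor
expansion).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .matcher import DirectAnnotation, Span
from .store import ConceptRef, Repository

MAPPED = "mapped"
ANCESTOR = "ancestor"


@dataclass(frozen=True)
class ExpandedAnnotation:
    """An annotation derived from a direct one via a mapping or is_a ancestry."""

    concept_ref: ConceptRef
    span: Span
    context: str  # MAPPED | ANCESTOR
    seed: DirectAnnotation
    ancestor_level: int | None = None  # minimal is_a distance, ANCESTOR only

    def __post_init__(self) -> None:
        if self.context == ANCESTOR and (self.ancestor_level is None or self.ancestor_level < 1):
            raise ValueError("ancestor expansion requires ancestor_level >= 1")
        if self.context == MAPPED and self.concept_ref[0] == self.seed.concept_ref[0]:
            raise ValueError("mapping expansion must cross ontologies")


def expand_mappings(direct: list[DirectAnnotation], repo: Repository) -> list[ExpandedAnnotation]:
    """One expanded annotation per (direct annotation, outgoing mapping).

    Single hop: only mappings whose source is the directly annotated concept
    are followed. The seed's span is inherited unchanged. Duplicate
    (concept, span) pairs across the combined direct+expanded set are
    resolved later, at scoring time, by keeping the highest-weight one.
    """
    expanded: list[ExpandedAnnotation] = []
    for ann in direct:
        for target in repo.mapping_index.get(ann.concept_ref, ()):
            expanded.append(
                ExpandedAnnotation(concept_ref=target, span=ann.span,
                                   context=MAPPED, seed=ann)
            )
    return expanded


def expand_isa(direct: list[DirectAnnotation], repo: Repository,
               max_level: int | None = None) -> list[ExpandedAnnotation]:
    """Ancestor expansion along the is_a hierarchy, off by default in ranking.

    For each direct annotation, every distinct ancestor within ``max_level``
    edges (``None`` = unlimited) yields one expansion whose level is the
    shortest-path edge count. Each (ancestor, span) pair is emitted once,
    at its minimal level over all seeds sharing that span.
    """
    graphs: dict[str, nx.DiGraph] = {}
    best: dict[tuple[ConceptRef, Span], ExpandedAnnotation] = {}
    for ann in direct:
        ontology_id, local_id = ann.concept_ref
        ontology = repo.ontologies.get(ontology_id)
        if ontology is None or local_id not in ontology.concepts:
            continue
        graph = graphs.setdefault(ontology_id, ontology.isa_graph())
        levels = nx.single_source_shortest_path_length(graph, local_id, cutoff=max_level)
        for ancestor, level in levels.items():
            if level < 1:
                continue
            key = ((ontology_id, ancestor), ann.span)
            current = best.get(key)
            if current is None or level < (current.ancestor_level or 0):
                best[key] = ExpandedAnnotation(
                    concept_ref=(ontology_id, ancestor), span=ann.span,
                    context=ANCESTOR, seed=ann, ancestor_level=level,
                )
    return sorted(
        best.values(),
        key=lambda e: (e.span.start, e.span.end, e.concept_ref, e.ancestor_level),
    )
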