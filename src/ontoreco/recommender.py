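"""End-to-end ontology recommendation and ranking rendering.

The pipeline: compile the term dictionary from the (optionally group-filtered)
repository, recognize concepts in the input, expand via mappings when the
CR+M method is selected, weigh each annotation by context, deduplicate
(concept, span) pairs keeping the highest weight, aggregate per ontology and
rank by the selected output value (raw score for corpus coverage, size-
normalized score to surface small specialized ontologies).

Two input scenarios: ``corpus`` treats the input as free text; ``keyword``
treats each non-empty line as an independent phrase (no span crosses a line)
and defaults to longest-only matching.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Any

from .expansion import expand_mappings
from .matcher import DirectAnnotation, MatchConfig, Span, compile_dictionary, recognize
from .scoring import (
    DEFAULT_WEIGHTS,
    Annotation,
    OntologyScore,
    WeightTable,
    aggregate,
    dedupe,
    weigh,
)
from .store import ConfigError, OntorecoError, Repository

logger = logging.getLogger("ontoreco")

CR = "CR"
CR_M = "CR+M"

JSON_SCHEMA = "ontoreco.ranking/1"


@dataclass
class RunConfig:
    """Everything that parameterizes one recommendation run."""

    method: str = CR  # CR | CR+M
    scenario: str = "corpus"  # corpus | keyword
    output_value: str = "score"  # score | normalized
    repository_filter: set[str] = field(default_factory=set)
    match: MatchConfig = field(default_factory=MatchConfig)
    weights: WeightTable = DEFAULT_WEIGHTS
    top_k: int = 15

    def __post_init__(self) -> None:
        if self.method not in (CR, CR_M):
            raise ConfigError(f"unknown method {self.method!r}; expected CR or CR+M")
        if self.scenario not in ("corpus", "keyword"):
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.output_value not in ("score", "normalized"):
            raise ConfigError(f"unknown output value {self.output_value!r}")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")

    def resolved_match(self) -> MatchConfig:
        """Apply the scenario default for longest_only when unset."""
        if self.match.longest_only is None:
            return replace(self.match, longest_only=self.scenario == "keyword")
        return self.match

    def digest(self) -> dict[str, Any]:
        match = self.resolved_match()
        return {
            "method": self.method,
            "scenario": self.scenario,
            "output_value": self.output_value,
            "repository_filter": sorted(self.repository_filter),
            "longest_only": match.longest_only,
            "min_term_size": match.min_term_size,
            "use_default_stopwords": match.use_default_stopwords,
            "top_k": self.top_k,
        }

    @classmethod
    def from_params(cls, params: dict[str, Any]) -> "RunConfig":
        """Build a RunConfig from flat service-style parameter names.

        Recognized keys: longestOnly, withDefaultStopWords, minTermSize,
        activateMapping, scenario, outputValue, topK, repositoryFilter, and
        weight overrides under ``weights`` (preferred, synonym, mapped,
        ancestor_a, ancestor_b, ancestor_k).
        """
        known = {"longestOnly", "withDefaultStopWords", "minTermSize", "activateMapping",
                 "scenario", "outputValue", "topK", "repositoryFilter", "weights"}
        unknown = set(params) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        weights = DEFAULT_WEIGHTS
        if "weights" in params:
            overrides = params["weights"]
            weights = WeightTable(
                direct_preferred=overrides.get("preferred", DEFAULT_WEIGHTS.direct_preferred),
                direct_synonym=overrides.get("synonym", DEFAULT_WEIGHTS.direct_synonym),
                mapped=overrides.get("mapped", DEFAULT_WEIGHTS.mapped),
                ancestor_a=overrides.get("ancestor_a", DEFAULT_WEIGHTS.ancestor_a),
                ancestor_b=overrides.get("ancestor_b", DEFAULT_WEIGHTS.ancestor_b),
                ancestor_k=overrides.get("ancestor_k", DEFAULT_WEIGHTS.ancestor_k),
            )
        return cls(
            method=CR_M if params.get("activateMapping", False) else CR,
            scenario=params.get("scenario", "corpus"),
            output_value=params.get("outputValue", "score"),
            repository_filter=set(params.get("repositoryFilter", ())),
            match=MatchConfig(
                longest_only=params.get("longestOnly"),
                min_term_size=int(params.get("minTermSize", 3)),
                use_default_stopwords=bool(params.get("withDefaultStopWords", True)),
            ),
            weights=weights,
            top_k=int(params.get("topK", 15)),
        )


@dataclass(frozen=True)
class RankingEntry:
    ontology_id: str
    display_name: str
    score: float
    normalized_score: float
    rank: int
    annotation_count: int


@dataclass
class Ranking:
    """Ordered per-ontology results plus an echo of the run configuration."""

    entries: list[RankingEntry]
    output_value: str
    config_echo: dict[str, Any] = field(default_factory=dict)

    def top(self, k: int) -> "Ranking":
        return Ranking(self.entries[:k], self.output_value, self.config_echo)


def _rank(scores: list[OntologyScore], repo: Repository, output_value: str) -> list[RankingEntry]:
    """Sort descending by the selected value, ties ascending by ontology id;
    tied values share the smaller rank (competition ranking 1-2-2-4)."""
    key = (lambda s: s.normalized_score) if output_value == "normalized" else (lambda s: s.score)
    ordered = sorted(scores, key=lambda s: (-key(s), s.ontology_id))
    entries: list[RankingEntry] = []
    for position, score in enumerate(ordered, start=1):
        if entries and key(score) == key(ordered[position - 2]):
            rank = entries[-1].rank
        else:
            rank = position
        entries.append(
            RankingEntry(
                ontology_id=score.ontology_id,
                display_name=repo.ontologies[score.ontology_id].display_name,
                score=score.score,
                normalized_score=score.normalized_score,
                rank=rank,
                annotation_count=score.annotation_count,
            )
        )
    return entries


def annotate(input_text: str, repo: Repository, config: RunConfig) -> list[Annotation]:
    """Run recognition (and mapping expansion for CR+M) without aggregating.

    Keyword scenario: recognition runs per line; spans are shifted back into
    the coordinates of the full input so that occurrences on different lines
    stay distinct.
    """
    match = config.resolved_match()
    dictionary = compile_dictionary(repo, match)
    if config.scenario == "keyword":
        direct: list[DirectAnnotation] = []
        offset = 0
        for line in input_text.split("\n"):
            if line.strip():
                for ann in recognize(line, dictionary, match):
                    span = Span(ann.span.start + offset, ann.span.end + offset, ann.span.surface)
                    direct.append(DirectAnnotation(ann.concept_ref, span, ann.context))
            offset += len(line) + 1
    else:
        direct = recognize(input_text, dictionary, match)
    annotations: list[Annotation] = list(direct)
    if config.method == CR_M:
        annotations.extend(expand_mappings(direct, repo))
    return annotations


def recommend(input_text: str, repo: Repository, config: RunConfig | None = None) -> Ranking:
    """Score and rank every ontology of the repository against the input."""
    config = config or RunConfig()
    if not input_text.strip():
        raise OntorecoError("input text is empty")
    if not repo.ontologies:
        raise OntorecoError("repository is empty")
    scoped = repo.filtered(config.repository_filter)
    annotations = annotate(input_text, scoped, config)
    if not annotations:
        logger.warning("no annotations found; returning an empty ranking")
        return Ranking([], config.output_value, config.digest())
    weighted = dedupe(weigh(annotations, config.weights))
    scores = aggregate(weighted, scoped)
    entries = _rank(scores, scoped, config.output_value)[: config.top_k]
    return Ranking(entries, config.output_value, config.digest())


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render(ranking: Ranking, format: str = "text") -> str:
    """Render a ranking as ``text``, ``xml``, ``json`` or ``cloud``.

    The tag cloud maps the selected output value linearly onto integer font
    weights 1..10 (min..max of the ranking; a single value maps to 10).
    """
    if format == "text":
        return _render_text(ranking)
    if format == "xml":
        return _render_xml(ranking)
    if format == "json":
        return _render_json(ranking)
    if format == "cloud":
        return _render_cloud(ranking)
    raise OntorecoError(f"unknown output format {format!r}")


def _render_text(ranking: Ranking) -> str:
    header = f"{'rank':>4}  {'ontology':<24} {'score':>10} {'normalized':>12} {'annotations':>12}"
    lines = [header, "-" * len(header)]
    for e in ranking.entries:
        lines.append(
            f"{e.rank:>4}  {e.ontology_id:<24} {e.score:>10g} "
            f"{e.normalized_score:>12.4f} {e.annotation_count:>12}"
        )
    return "\n".join(lines) + "\n"


def _render_xml(ranking: Ranking) -> str:
    root = ET.Element("recommendation", attrib={"outputValue": ranking.output_value})
    for e in ranking.entries:
        node = ET.SubElement(root, "ontology",
                             attrib={"id": e.ontology_id, "name": e.display_name})
        ET.SubElement(node, "score").text = f"{e.score:g}"
        ET.SubElement(node, "normalizedScore").text = f"{e.normalized_score:.4f}"
        ET.SubElement(node, "rank").text = str(e.rank)
        ET.SubElement(node, "annotations").text = str(e.annotation_count)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def _render_json(ranking: Ranking) -> str:
    payload = {
        "schema": JSON_SCHEMA,
        "output_value": ranking.output_value,
        "config": ranking.config_echo,
        "entries": [
            {
                "ontology_id": e.ontology_id,
                "display_name": e.display_name,
                "score": e.score,
                "normalized_score": e.normalized_score,
                "rank": e.rank,
                "annotation_count": e.annotation_count,
            }
            for e in ranking.entries
        ],
    }
    return json.dumps(payload, sort_keys=True, indent=2) + "\n"


def ranking_from_json(text: str) -> Ranking:
    """Inverse of ``render(..., "json")``."""
    payload = json.loads(text)
    if payload.get("schema") != JSON_SCHEMA:
        raise OntorecoError(f"unsupported ranking schema {payload.get('schema')!r}")
    entries = [RankingEntry(**e) for e in payload["entries"]]
    return Ranking(entries, payload["output_value"], payload.get("config", {}))


def _render_cloud(ranking: Ranking) -> str:
    if not ranking.entries:
        return ""
    select = (lambda e: e.normalized_score) if ranking.output_value == "normalized" \
        else (lambda e: e.score)
    values = [select(e) for e in ranking.entries]
    lo, hi = min(values), max(values)
    lines = []
    for e in ranking.entries:
        if hi == lo:
            weight = 10
        else:
            weight = 1 + round(9 * (select(e) - lo) / (hi - lo))
        lines.append(f"{e.display_name}\t{weight}")
    return "\n".join(lines) + "\n"
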