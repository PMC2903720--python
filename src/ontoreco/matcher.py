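"""Dictionary compilation and syntactic concept recognition.

The matcher compiles a flat term dictionary from every concept preferred
name and synonym in a repository, then scans input text for token-aligned
occurrences. Matching is case-insensitive, collapses whitespace and applies
a naive English plural fold (a trailing ``s`` on the final token is stripped
only when the unstripped phrase has no dictionary hit). ``longest_only``
suppresses any annotation whose span is a strict sub-interval of another
annotation's span, regardless of which ontology produced either one.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

from .store import ConceptRef, OntorecoError, Repository

logger = logging.getLogger("ontoreco")

DIRECT_PREFERRED = "direct_preferred"
DIRECT_SYNONYM = "direct_synonym"

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


def default_stopwords() -> frozenset[str]:
    """The built-in English stopword list (one word per line resource file)."""
    text = resources.files("ontoreco.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w.strip().casefold() for w in text.splitlines() if w.strip())


@dataclass
class MatchConfig:
    """Concept-recognition parameters.

    ``longest_only=None`` means "decide from the scenario" (keyword runs
    default to True, corpus runs to False); the resolved value is what
    :func:`recognize` consumes.
    """

    longest_only: bool | None = None
    min_term_size: int = 3
    use_default_stopwords: bool = True
    stopwords: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_term_size < 1:
            raise OntorecoError("min_term_size must be >= 1")

    def effective_stopwords(self) -> frozenset[str]:
        words = frozenset(w.casefold() for w in self.stopwords)
        if self.use_default_stopwords:
            words = words | default_stopwords()
        return words


class DictionaryEntry(NamedTuple):
    normalized_term: str
    concept_ref: ConceptRef
    term_kind: str  # "preferred" | "synonym"


class Span(NamedTuple):
    """Character span, 0-based half-open; ``surface`` is the exact slice."""

    start: int
    end: int
    surface: str


@dataclass(frozen=True)
class DirectAnnotation:
    """A dictionary term recognized in text, tied to one concept."""

    concept_ref: ConceptRef
    span: Span
    context: str  # DIRECT_PREFERRED | DIRECT_SYNONYM


def normalize_term(term: str) -> str:
    """Case-fold and reduce to word tokens joined by single spaces.

    The same normalization is applied to dictionary terms and to candidate
    text phrases, so punctuation and whitespace differences never block a
    match ("Breast-Cancer" matches the entry for "breast cancer").
    """
    return " ".join(_TOKEN_RE.findall(term.casefold()))


def compile_dictionary(repo: Repository, config: MatchConfig | None = None) -> set[DictionaryEntry]:
    """One entry per preferred name and synonym of every concept.

    Terms shorter than ``min_term_size`` characters after normalization, or
    equal to a stopword, are excluded (counts are logged).
    """
    config = config or MatchConfig()
    stopwords = config.effective_stopwords()
    entries: set[DictionaryEntry] = set()
    too_short = 0
    stopped = 0
    for ontology in repo.ontologies.values():
        for concept in ontology.concepts.values():
            for term, kind in concept.terms():
                normalized = normalize_term(term)
                if len(normalized) < config.min_term_size:
                    too_short += 1
                    continue
                if normalized in stopwords:
                    stopped += 1
                    continue
                entries.add(DictionaryEntry(normalized, concept.ref, kind))
    if too_short or stopped:
        logger.info(
            "dictionary: excluded %d term(s) below min_term_size=%d and %d stopword term(s)",
            too_short, config.min_term_size, stopped,
        )
    return entries


def _depluralize(token: str) -> str | None:
    """Naive English plural fold: strip one trailing 's' (not 'ss')."""
    if len(token) > 2 and token.endswith("s") and not token.endswith("ss"):
        return token[:-1]
    return None


def _candidate_keys(tokens: Sequence[str]) -> list[str]:
    """Lookup keys for a token window: exact, then final-token-depluralized."""
    keys = [" ".join(tokens)]
    folded = _depluralize(tokens[-1])
    if folded is not None:
        keys.append(" ".join([*tokens[:-1], folded]))
    return keys


def recognize(text: str, dictionary: Iterable[DictionaryEntry],
              config: MatchConfig | None = None) -> list[DirectAnnotation]:
    """Produce one direct annotation per dictionary entry matching the text.

    Matches must align with token boundaries on both ends (no mid-word hits).
    Every occurrence of a term is annotated independently. The plural fold is
    applied only when the literal phrase has no dictionary hit. Single-token
    phrases that are stopwords never match. With ``longest_only`` resolved to
    True, annotations strictly contained in a longer span are suppressed.

    Output is sorted by (start, end, ontology_id, local_id, context).
    """
    config = config or MatchConfig()
    if not text.strip():
        raise OntorecoError("input text is empty")
    index: dict[str, list[DictionaryEntry]] = {}
    max_tokens = 1
    for entry in dictionary:
        index.setdefault(entry.normalized_term, []).append(entry)
        max_tokens = max(max_tokens, entry.normalized_term.count(" ") + 1)
    stopwords = config.effective_stopwords()

    tokens = list(_TOKEN_RE.finditer(text))
    norm = [t.group().casefold() for t in tokens]
    annotations: list[DirectAnnotation] = []
    for i in range(len(tokens)):
        for j in range(i, min(i + max_tokens, len(tokens))):
            window = norm[i:j + 1]
            if j == i and window[0] in stopwords:
                continue
            matched: list[DictionaryEntry] = []
            for key in _candidate_keys(window):
                matched = index.get(key, [])
                if matched:
                    break
            if not matched:
                continue
            start, end = tokens[i].start(), tokens[j].end()
            span = Span(start, end, text[start:end])
            for entry in matched:
                context = DIRECT_PREFERRED if entry.term_kind == "preferred" else DIRECT_SYNONYM
                annotations.append(DirectAnnotation(entry.concept_ref, span, context))

    if config.longest_only:
        annotations = suppress_subsumed(annotations)
    annotations.sort(key=lambda a: (a.span.start, a.span.end,
                                    a.concept_ref[0], a.concept_ref[1], a.context))
    return annotations


def suppress_subsumed(annotations: list[DirectAnnotation]) -> list[DirectAnnotation]:
    """Drop annotations whose span is a strict sub-interval of another's.

    Equal spans survive (containment is strict), as do overlapping but
    non-nested spans. Idempotent; never increases the annotation count.
    """
    spans = {(a.span.start, a.span.end) for a in annotations}

    def subsumed(span: Span) -> bool:
        return any(
            s <= span.start and span.end <= e and (s, e) != (span.start, span.end)
            for s, e in spans
        )

    return [a for a in annotations if not subsumed(a.span)]
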