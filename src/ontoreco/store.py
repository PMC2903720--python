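"""Ontology repository: concepts, is_a hierarchy, and cross-ontology mappings.

Ontologies are supplied as flat OBO files restricted to the tags that matter
for lexical annotation (``[Term]`` stanzas with ``id``, ``name``, ``synonym``,
``is_a``, ``is_obsolete``); everything else an OBO file may contain is ignored.
Cross-ontology point-to-point mappings come from a 4-column TSV. The
:class:`Repository` bundles a set of ontologies with a forward mapping index
and is the single input object of the recommendation pipeline.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import yaml

logger = logging.getLogger("ontoreco")

GROUP_TAGS = ("umls", "bioportal", "other")

#: (ontology_id, local_id) pair addressing one concept in a repository.
ConceptRef = tuple[str, str]


class OntorecoError(Exception):
    """Base class for all errors raised by this package."""


class OboParseError(OntorecoError):
    """Malformed OBO input; carries the 1-based line number of the offence."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class ValidationError(OntorecoError):
    """An ontology or repository violates a structural invariant."""


class ConfigError(OntorecoError):
    """Invalid run configuration or manifest."""


@dataclass
class Concept:
    """A node in one ontology: local id, preferred name, and synonyms.

    The preferred name and each synonym are independent dictionary terms;
    synonyms that duplicate the preferred name (case-insensitively) are
    dropped at load time.
    """

    ontology_id: str
    local_id: str
    preferred_name: str
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.preferred_name = self.preferred_name.strip()
        if not self.preferred_name:
            raise ValidationError(
                f"concept {self.ontology_id}/{self.local_id} has an empty preferred name"
            )
        pref_cf = self.preferred_name.casefold()
        seen: set[str] = set()
        deduped: list[str] = []
        for syn in self.synonyms:
            syn = syn.strip()
            cf = syn.casefold()
            if not syn or cf == pref_cf or cf in seen:
                continue
            seen.add(cf)
            deduped.append(syn)
        self.synonyms = deduped

    @property
    def ref(self) -> ConceptRef:
        return (self.ontology_id, self.local_id)

    def terms(self) -> Iterator[tuple[str, str]]:
        """Yield (term, kind) pairs, kind in {"preferred", "synonym"}."""
        yield self.preferred_name, "preferred"
        for syn in self.synonyms:
            yield syn, "synonym"


@dataclass
class Ontology:
    """An identified set of concepts plus its is_a hierarchy.

    ``size`` (the concept count) is the denominator of the normalized score,
    so it is the number of *concepts*, not of lexical terms.
    """

    ontology_id: str
    display_name: str
    concepts: dict[str, Concept] = field(default_factory=dict)
    isa_edges: set[tuple[str, str]] = field(default_factory=set)  # (child, parent)
    group_tag: str = "other"

    def __post_init__(self) -> None:
        if self.group_tag not in GROUP_TAGS:
            raise ValidationError(
                f"unknown group_tag {self.group_tag!r}; expected one of {GROUP_TAGS}"
            )

    def add_concept(self, concept: Concept) -> None:
        if concept.local_id in self.concepts:
            raise ValidationError(
                f"duplicate concept id {concept.local_id!r} in ontology {self.ontology_id}"
            )
        self.concepts[concept.local_id] = concept

    def size(self) -> int:
        return len(self.concepts)

    def validate(self) -> None:
        """Check edge endpoints and acyclicity; raise ValidationError on failure."""
        if not self.concepts:
            raise ValidationError(f"ontology {self.ontology_id} has no concepts")
        for child, parent in self.isa_edges:
            if child not in self.concepts or parent not in self.concepts:
                raise ValidationError(
                    f"is_a edge {child}->{parent} in {self.ontology_id} "
                    "references an unknown concept"
                )
        graph = self.isa_graph()
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            return
        raise ValidationError(
            f"is_a cycle in ontology {self.ontology_id}: "
            + " -> ".join(str(edge[0]) for edge in cycle)
        )

    def isa_graph(self) -> nx.DiGraph:
        """Directed child->parent graph over local ids (all concepts as nodes)."""
        graph = nx.DiGraph()
        graph.add_nodes_from(self.concepts)
        graph.add_edges_from(self.isa_edges)
        return graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return (
            self.ontology_id == other.ontology_id
            and self.isa_edges == other.isa_edges
            and {k: (c.preferred_name, tuple(sorted(c.synonyms))) for k, c in self.concepts.items()}
            == {k: (c.preferred_name, tuple(sorted(c.synonyms))) for k, c in other.concepts.items()}
        )


@dataclass(frozen=True)
class Mapping:
    """A directed point-to-point link between concepts of two ontologies."""

    source: ConceptRef
    target: ConceptRef

    def __post_init__(self) -> None:
        if self.source[0] == self.target[0]:
            raise ValidationError(
                f"mapping {self.source} -> {self.target} stays within one ontology"
            )


@dataclass
class Repository:
    """Ontologies plus mappings, with a forward index for expansion lookups."""

    ontologies: dict[str, Ontology] = field(default_factory=dict)
    mappings: list[Mapping] = field(default_factory=list)
    mapping_index: dict[ConceptRef, list[ConceptRef]] = field(default_factory=dict)

    def add_ontology(self, ontology: Ontology) -> None:
        if ontology.ontology_id in self.ontologies:
            raise ValidationError(f"duplicate ontology id {ontology.ontology_id!r}")
        ontology.validate()
        self.ontologies[ontology.ontology_id] = ontology

    def resolve(self, ref: ConceptRef) -> Concept | None:
        ont = self.ontologies.get(ref[0])
        if ont is None:
            return None
        return ont.concepts.get(ref[1])

    def rebuild_mapping_index(self) -> None:
        index: dict[ConceptRef, list[ConceptRef]] = {}
        for m in self.mappings:
            index.setdefault(m.source, []).append(m.target)
        self.mapping_index = index

    def validate(self) -> None:
        for ont in self.ontologies.values():
            ont.validate()
        for m in self.mappings:
            if self.resolve(m.source) is None or self.resolve(m.target) is None:
                raise ValidationError(f"mapping {m.source} -> {m.target} does not resolve")
        rebuilt: dict[ConceptRef, list[ConceptRef]] = {}
        for m in self.mappings:
            rebuilt.setdefault(m.source, []).append(m.target)
        if rebuilt != self.mapping_index:
            raise ValidationError("mapping_index is out of sync with mappings")

    def filtered(self, group_tags: set[str] | None) -> "Repository":
        """Sub-repository restricted to ontologies whose group_tag is selected.

        Mappings are kept only when both endpoints remain loaded. ``None`` or
        an empty set selects everything.
        """
        if not group_tags:
            return self
        sub = Repository()
        for ont in self.ontologies.values():
            if ont.group_tag in group_tags:
                sub.ontologies[ont.ontology_id] = ont
        sub.mappings = [
            m
            for m in self.mappings
            if m.source[0] in sub.ontologies and m.target[0] in sub.ontologies
        ]
        sub.rebuild_mapping_index()
        return sub


# ---------------------------------------------------------------------------
# OBO-subset I/O
# ---------------------------------------------------------------------------

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def _unescape(value: str) -> str:
    return re.sub(r"\\(.)", r"\1", value)


def load_obo(path: str | Path, ontology_id: str, group_tag: str = "other",
             display_name: str | None = None) -> Ontology:
    """Load one ontology from an OBO 1.2 flat file (lexical subset).

    Recognized tags inside ``[Term]`` stanzas: ``id``, ``name``, ``synonym``
    (scope qualifiers such as EXACT/BROAD are discarded, the quoted text is
    kept), ``is_a`` and ``is_obsolete``. Obsolete terms are dropped together
    with their edges. Any other tag or stanza type is ignored.

    Raises :class:`OboParseError` with a line number on malformed input,
    duplicate term ids, or (via validation) is_a cycles.
    """
    path = Path(path)
    ontology = Ontology(
        ontology_id=ontology_id,
        display_name=display_name or ontology_id,
        group_tag=group_tag,
    )
    raw_edges: list[tuple[str, str, int]] = []  # (child, parent, line)
    obsolete: set[str] = set()

    stanza_type: str | None = None
    term: dict | None = None
    term_line = 0

    def flush() -> None:
        nonlocal term
        if term is None:
            return
        if "id" not in term:
            raise OboParseError("[Term] stanza lacks an id", term_line)
        if "name" not in term:
            raise OboParseError(f"[Term] {term['id']} lacks a name", term_line)
        for parent, lineno in term.get("edges", []):
            raw_edges.append((term["id"], parent, lineno))
        if term.get("obsolete"):
            obsolete.add(term["id"])
        else:
            try:
                ontology.add_concept(
                    Concept(
                        ontology_id=ontology_id,
                        local_id=term["id"],
                        preferred_name=term["name"],
                        synonyms=term.get("synonyms", []),
                    )
                )
            except ValidationError as exc:
                raise OboParseError(str(exc), term_line) from exc
        term = None

    with path.open("r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("!")[0].rstrip() if not raw.lstrip().startswith("!") else ""
            line = line.strip()
            if not line:
                continue
            if line.startswith("["):
                flush()
                stanza_type = line
                if line == "[Term]":
                    term = {}
                    term_line = lineno
                continue
            if stanza_type != "[Term]" or term is None:
                continue  # header line or non-Term stanza
            if ":" not in line:
                raise OboParseError(f"malformed tag line {line!r}", lineno)
            tag, _, value = line.partition(":")
            tag = tag.strip()
            value = value.strip()
            if tag == "id":
                term["id"] = value
            elif tag == "name":
                if not value:
                    raise OboParseError("empty name", lineno)
                term["name"] = value
            elif tag == "synonym":
                match = _SYNONYM_RE.match(value)
                if not match:
                    raise OboParseError(f"malformed synonym line {value!r}", lineno)
                term.setdefault("synonyms", []).append(_unescape(match.group("text")))
            elif tag == "is_a":
                parent = value.split()[0] if value else ""
                if not parent:
                    raise OboParseError("empty is_a target", lineno)
                # defer resolution: the parent may be defined later in the file
                term.setdefault("edges", []).append((parent, lineno))
            elif tag == "is_obsolete":
                term["obsolete"] = value.lower() == "true"
        flush()

    for child, parent, lineno in raw_edges:
        if child in obsolete or parent in obsolete:
            continue
        if child not in ontology.concepts or parent not in ontology.concepts:
            raise OboParseError(
                f"is_a edge {child} -> {parent} references an unknown term", lineno
            )
        ontology.isa_edges.add((child, parent))

    ontology.validate()
    logger.info(
        "loaded ontology %s: %d concepts, %d is_a edges (%d obsolete dropped)",
        ontology_id, ontology.size(), len(ontology.isa_edges), len(obsolete),
    )
    return ontology


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Write an ontology back to the OBO subset read by :func:`load_obo`."""
    path = Path(path)
    lines = ["format-version: 1.2", f"ontology: {ontology.ontology_id.lower()}", ""]
    parents: dict[str, list[str]] = {}
    for child, parent in sorted(ontology.isa_edges):
        parents.setdefault(child, []).append(parent)
    for local_id in sorted(ontology.concepts):
        concept = ontology.concepts[local_id]
        lines.append("[Term]")
        lines.append(f"id: {local_id}")
        lines.append(f"name: {concept.preferred_name}")
        for syn in concept.synonyms:
            escaped = syn.replace("\\", "\\\\").replace('"', '\\"')
            lines.append(f'synonym: "{escaped}" EXACT []')
        for parent in parents.get(local_id, []):
            lines.append(f"is_a: {parent}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Mappings TSV
# ---------------------------------------------------------------------------

def load_mappings(path: str | Path, repo: Repository) -> Repository:
    """Append mappings from a 4-column TSV and rebuild the forward index.

    Columns: source_ontology, source_id, target_ontology, target_id. Lines
    starting with ``#`` are comments. Rows whose endpoints do not resolve to
    loaded concepts are skipped with a logged warning; a wrong column count
    is an error.
    """
    path = Path(path)
    skipped = 0
    with path.open("r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise OntorecoError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
                )
            source = (fields[0].strip(), fields[1].strip())
            target = (fields[2].strip(), fields[3].strip())
            if repo.resolve(source) is None or repo.resolve(target) is None:
                skipped += 1
                logger.warning(
                    "%s:%d: mapping %s/%s -> %s/%s has an unresolvable endpoint; skipped",
                    path, lineno, *source, *target,
                )
                continue
            repo.mappings.append(Mapping(source=source, target=target))
    repo.rebuild_mapping_index()
    repo.skipped_mappings = skipped  # type: ignore[attr-defined]
    return repo


def ontology_size(ontology: Ontology) -> int:
    """Concept count — the denominator of the normalized score."""
    return ontology.size()


# ---------------------------------------------------------------------------
# Repository manifest
# ---------------------------------------------------------------------------

def load_repository(manifest_path: str | Path) -> Repository:
    """Load a full repository from a YAML manifest.

    Schema::

        ontologies:
          - path: nci.obo            # relative to the manifest
            ontology_id: NCI
            display_name: NCI Thesaurus
            group_tag: umls          # umls | bioportal | other
        mappings: mappings.tsv       # optional

    """
    manifest_path = Path(manifest_path)
    try:
        manifest = yaml.safe_load(manifest_path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid manifest {manifest_path}: {exc}") from exc
    if not isinstance(manifest, dict) or "ontologies" not in manifest:
        raise ConfigError(f"manifest {manifest_path} lacks an 'ontologies' list")
    base = manifest_path.parent
    repo = Repository()
    for entry in manifest["ontologies"]:
        try:
            obo_path = base / entry["path"]
            ontology_id = entry["ontology_id"]
        except (TypeError, KeyError) as exc:
            raise ConfigError(f"manifest entry {entry!r} lacks path/ontology_id") from exc
        repo.add_ontology(
            load_obo(
                obo_path,
                ontology_id=ontology_id,
                group_tag=entry.get("group_tag", "other"),
                display_name=entry.get("display_name"),
            )
        )
    if manifest.get("mappings"):
        load_mappings(base / manifest["mappings"], repo)
    else:
        repo.rebuild_mapping_index()
    return repo


def build_repository(ontologies: Iterable[Ontology],
                     mappings: Iterable[Mapping] = ()) -> Repository:
    """Assemble and validate a repository from in-memory objects."""
    repo = Repository()
    for ont in ontologies:
        repo.add_ontology(ont)
    for m in mappings:
        if repo.resolve(m.source) is None or repo.resolve(m.target) is None:
            raise ValidationError(f"mapping {m.source} -> {m.target} does not resolve")
        repo.mappings.append(m)
    repo.rebuild_mapping_index()
    return repo
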