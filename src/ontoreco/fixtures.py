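"""Pinned worked-example repository and synthetic repository/corpus generators.

The worked example is a three-ontology miniature (NCI Thesaurus, FMA, Human
Disease) with two cross-ontology mappings, built so that annotating the
melanoma sentence reproduces a known set of six direct and two mapped
annotations exactly. Two concepts deliberately carry preferred names that do
not occur in the sentence ("Eye structure" in NCI, "Epidermal melanocyte" in
FMA): those concepts must be credited only through mappings for the expected
per-ontology totals (NCI 35, FMA 25, Human Disease 10) to emerge.

The synthetic generators produce seeded random repositories (with a coarse
small/medium/large size mix and designated hub ontologies that attract
mappings) and corpora of sampled ontology terms interleaved with noise
tokens drawn from a disjoint character alphabet, so noise can never hit the
dictionary by accident.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import yaml

from .store import (
    Concept,
    Mapping,
    Ontology,
    OntorecoError,
    Repository,
    build_repository,
    write_obo,
)

#: Sentence driving the worked example.
WORKED_EXAMPLE_SENTENCE = (
    "Melanoma is a malignant tumor of melanocytes which are found "
    "predominantly in skin but also in the bowel and the eye."
)


def worked_example_repository() -> Repository:
    """The pinned three-ontology repository behind the worked example.

    NCI (4 concepts), FMA (3 concepts), Human Disease/40465 (1 concept);
    mappings NCI/C0025201 -> FMA/C0025201 and FMA/C0015392 -> NCI/C0015392.
    """
    nci = Ontology("NCI", "NCI Thesaurus", group_tag="umls")
    nci.add_concept(Concept("NCI", "C0025201", "Melanocyte"))
    nci.add_concept(Concept("NCI", "C0025202", "Melanoma"))
    nci.add_concept(Concept("NCI", "C0027651", "Neoplasm", synonyms=["tumor"]))
    # reached only via the FMA mapping: its name must not occur in the sentence
    nci.add_concept(Concept("NCI", "C0015392", "Eye structure"))

    fma = Ontology("FMA", "Foundational Model of Anatomy", group_tag="umls")
    fma.add_concept(Concept("FMA", "C0015392", "Eye"))
    fma.add_concept(Concept("FMA", "C0021853", "Intestine", synonyms=["bowel"]))
    # reached only via the NCI mapping: must not match "melanocytes" directly
    fma.add_concept(Concept("FMA", "C0025201", "Epidermal melanocyte"))

    doid = Ontology("40465", "Human Disease", group_tag="bioportal")
    doid.add_concept(Concept("40465", "DOID:1909", "Melanoma"))

    return build_repository(
        [nci, fma, doid],
        [
            Mapping(("NCI", "C0025201"), ("FMA", "C0025201")),
            Mapping(("FMA", "C0015392"), ("NCI", "C0015392")),
        ],
    )


def write_worked_example(out_dir: str | Path) -> Path:
    """Materialize the worked example as OBO files + mappings TSV + manifest.

    Returns the manifest path, loadable with :func:`ontoreco.store.load_repository`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    repo = worked_example_repository()
    manifest: dict = {"ontologies": [], "mappings": "mappings.tsv"}
    for ontology_id, ontology in repo.ontologies.items():
        filename = f"{ontology_id.lower()}.obo"
        write_obo(ontology, out_dir / filename)
        manifest["ontologies"].append(
            {
                "path": filename,
                "ontology_id": ontology_id,
                "display_name": ontology.display_name,
                "group_tag": ontology.group_tag,
            }
        )
    rows = [
        "# source_ontology\tsource_id\ttarget_ontology\ttarget_id",
        *(f"{m.source[0]}\t{m.source[1]}\t{m.target[0]}\t{m.target[1]}" for m in repo.mappings),
    ]
    (out_dir / "mappings.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False), encoding="utf-8")
    return manifest_path


# ---------------------------------------------------------------------------
# Synthetic repositories
# ---------------------------------------------------------------------------

#: Term vocabulary uses the first half of the alphabet, noise the second,
#: so generated noise tokens can never collide with dictionary terms.
_VOCAB_ALPHABET = "abcdefghijklm"
_NOISE_ALPHABET = "nopqrstuvwxyz"

#: Size-class mix mirroring the production repository's coarse shape
#: (about half the ontologies are small, a sixth are large), with concept
#: counts scaled down to keep simulated repositories fast to annotate.
SIZE_CLASSES = (
    ("small", 0.47, (5, 20)),
    ("medium", 0.36, (20, 80)),
    ("large", 0.17, (80, 200)),
)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic repository; the seed pins everything."""

    n_ontologies: int = 5
    size_distribution: tuple = SIZE_CLASSES
    mapping_density: float = 0.05
    hub_fraction: float = 0.2
    vocabulary_size: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mapping_density <= 1:
            raise OntorecoError("mapping_density must be in [0, 1]")
        if self.n_ontologies < 1:
            raise OntorecoError("n_ontologies must be >= 1")


def _make_vocabulary(rng: random.Random, size: int) -> list[str]:
    words: set[str] = set()
    while len(words) < size:
        words.add("".join(rng.choices(_VOCAB_ALPHABET, k=rng.randint(4, 9))))
    return sorted(words)


def generate_repository(spec: FixtureSpec) -> Repository:
    """Seeded random repository with hub ontologies of elevated mapping in-degree.

    Every concept receives a unique preferred name from the vocabulary (so
    distinct ontologies never collide on preferred names) and 0-2 synonyms
    drawn from a shared synonym pool (collisions allowed, as in real
    terminologies). is_a parents are sampled among earlier concepts, which
    makes the hierarchy acyclic by construction. Mappings are sampled per
    (source concept, target ontology) at ``mapping_density``, with hub
    ontologies three times as likely to be a target.
    """
    rng = random.Random(spec.seed)
    class_names = [c[0] for c in spec.size_distribution]
    class_weights = [c[1] for c in spec.size_distribution]
    class_ranges = {c[0]: c[2] for c in spec.size_distribution}

    sizes = []
    for _ in range(spec.n_ontologies):
        cls = rng.choices(class_names, weights=class_weights)[0]
        lo, hi = class_ranges[cls]
        sizes.append(rng.randint(lo, hi))
    total = sum(sizes)
    if spec.vocabulary_size < total:
        raise OntorecoError(
            f"vocabulary of {spec.vocabulary_size} words cannot name {total} concepts"
        )
    vocabulary = _make_vocabulary(rng, spec.vocabulary_size)
    rng.shuffle(vocabulary)
    names = iter(vocabulary)
    synonym_pool = _make_vocabulary(rng, max(64, total // 2))

    ontologies: list[Ontology] = []
    for index, size in enumerate(sizes):
        ontology_id = f"ONT{index:03d}"
        ontology = Ontology(ontology_id, f"Synthetic ontology {index}", group_tag="other")
        local_ids = []
        for c in range(size):
            local_id = f"{ontology_id}:{c:05d}"
            n_syn = rng.choices([0, 1, 2], weights=[0.5, 0.3, 0.2])[0]
            synonyms = rng.sample(synonym_pool, n_syn)
            ontology.add_concept(Concept(ontology_id, local_id, next(names), synonyms))
            if local_ids and rng.random() < 0.8:
                ontology.isa_edges.add((local_id, rng.choice(local_ids)))
            local_ids.append(local_id)
        ontologies.append(ontology)

    n_hubs = max(1, round(spec.hub_fraction * spec.n_ontologies)) if spec.n_ontologies > 1 else 0
    hubs = {o.ontology_id for o in ontologies[:n_hubs]}
    mappings: list[Mapping] = []
    for source_ont in ontologies:
        for target_ont in ontologies:
            if source_ont.ontology_id == target_ont.ontology_id:
                continue
            density = spec.mapping_density * (3.0 if target_ont.ontology_id in hubs else 1.0)
            density = min(density, 1.0)
            target_ids = sorted(target_ont.concepts)
            for local_id in sorted(source_ont.concepts):
                if rng.random() < density:
                    mappings.append(
                        Mapping(
                            (source_ont.ontology_id, local_id),
                            (target_ont.ontology_id, rng.choice(target_ids)),
                        )
                    )
    return build_repository(ontologies, mappings)


def generate_corpus(repo: Repository, source_ontology: str, n_terms: int,
                    noise_fraction: float, seed: int) -> str:
    """Seeded corpus of terms sampled from one ontology, plus dictionary-proof noise.

    ``n_terms`` phrases are sampled (with replacement) from the source
    ontology's preferred names and synonyms; noise tokens are added so they
    make up about ``noise_fraction`` of all phrases. Phrases are joined with
    ". " so no accidental multi-word match can straddle two phrases.
    """
    if not 0 <= noise_fraction < 1:
        raise OntorecoError("noise_fraction must be in [0, 1)")
    ontology = repo.ontologies.get(source_ontology)
    if ontology is None:
        raise OntorecoError(f"unknown source ontology {source_ontology!r}")
    terms = [term for concept in ontology.concepts.values() for term, _ in concept.terms()]
    if not terms:
        raise OntorecoError(f"ontology {source_ontology} has no terms")
    rng = random.Random(seed)
    phrases = [rng.choice(sorted(terms)) for _ in range(n_terms)]
    n_noise = int(round(n_terms * noise_fraction / (1.0 - noise_fraction)))
    for _ in range(n_noise):
        phrases.append("".join(rng.choices(_NOISE_ALPHABET, k=rng.randint(4, 9))))
    rng.shuffle(phrases)
    return ". ".join(phrases) + "."
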