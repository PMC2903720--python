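import pytest

from ontoreco import (
    Concept,
    Mapping,
    Ontology,
    Repository,
    build_repository,
    worked_example_repository,
)


@pytest.fixture(scope="session")
def worked_repo() -> Repository:
    return worked_example_repository()


@pytest.fixture()
def treatment_repo() -> Repository:
    """Toy MeSH/SNOMED-CT pair: 'treatment' exists only in MSH, mapped across."""
    msh = Ontology("MSH", "MeSH", group_tag="umls")
    msh.add_concept(Concept("MSH", "C0087111", "treatment"))
    snomed = Ontology("SNOMEDCT", "SNOMED-CT", group_tag="umls")
    snomed.add_concept(Concept("SNOMEDCT", "C0087111", "therapeutic procedure"))
    return build_repository(
        [msh, snomed],
        [Mapping(("MSH", "C0087111"), ("SNOMEDCT", "C0087111"))],
    )


def make_ontology(ontology_id: str, names: dict[str, str | tuple[str, list[str]]],
                  edges: set[tuple[str, str]] = frozenset(), group_tag: str = "other") -> Ontology:
    """Terse ontology builder: names maps local_id -> name or (name, synonyms)."""
    ont = Ontology(ontology_id, ontology_id, group_tag=group_tag)
    for local_id, spec in names.items():
        if isinstance(spec, tuple):
            name, synonyms = spec
        else:
            name, synonyms = spec, []
        ont.add_concept(Concept(ontology_id, local_id, name, list(synonyms)))
    ont.isa_edges = set(edges)
    ont.validate()
    return ont
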