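# ontoreco

Which ontology should you use to annotate your data? Researchers tagging
biomedical datasets — microarray metadata, clinical guideline text, keyword
lists describing a new domain — face hundreds of candidate ontologies and
terminologies, and picking the right one by hand is slow and error-prone.
`ontoreco` is an ontology *recommender*: given a repository of ontologies and
a piece of text (or a keyword list), it ranks the ontologies by how well
their concepts cover the input.

## How it works

1. **Concept recognition (CR).** A dictionary is compiled from every concept
   preferred name and synonym in the repository. The input text is scanned
   for token-aligned, case-insensitive occurrences of dictionary terms (with
   a naive plural fold, so "melanocytes" hits *Melanocyte*). Each hit is a
   *direct annotation*. An optional longest-only mode suppresses any
   annotation whose span is strictly contained in a longer match — if
   "breast cancer" matches as a whole, the partial hits "breast" and
   "cancer" are blocked, in every ontology.
2. **Mapping expansion (CR+M).** Cross-ontology point-to-point mappings
   (e.g. UMLS CUI-based links) propagate each direct annotation one hop to
   the mapped concept, crediting *reference* ontologies that are frequent
   mapping targets even when the literal term is absent from them.
3. **Scoring.** Each annotation is weighted by its provenance context:

   | context                    | weight              |
   |----------------------------|---------------------|
   | preferred-name match       | 10                  |
   | synonym match              | 8                   |
   | mapping expansion          | 7                   |
   | is_a ancestor at level *n* | ⌊1 + 10·e^(−0.2·n)⌋ |

   An ontology's **score** is the sum of its annotations' weights; its
   **normalized score** divides by the ontology's concept count, surfacing
   small, specialized ontologies. Duplicate (concept, span) pairs keep only
   the highest-weight annotation, so one textual mention never credits an
   ontology twice. (is_a ancestor expansion is implemented but not used for
   ranking: it would systematically favor ontologies with deep multiple
   inheritance.)
4. **Ranking.** Ontologies are sorted descending by the selected output
   value, ties share the smaller rank, and results render as a text table,
   XML, JSON, or tag-cloud font weights.

Ontologies are supplied as flat OBO files (the lexical subset: `id`, `name`,
`synonym`, `is_a`, `is_obsolete`), mappings as a 4-column TSV, and the
repository as a small YAML manifest.

## Worked example

The built-in fixture is a three-ontology miniature (NCI Thesaurus, FMA,
Human Disease) with two cross-ontology mappings:

```python
import ontoreco as o

repo = o.worked_example_repository()
config = o.RunConfig(method=o.CR_M, scenario="corpus", output_value="score")
ranking = o.recommend(o.WORKED_EXAMPLE_SENTENCE, repo, config)
print(o.render(ranking, "text"))
```

prints

```
rank  ontology                      score   normalized  annotations
-------------------------------------------------------------------
   1  NCI                              35       8.7500            4
   2  FMA                              25       8.3333            3
   3  40465                            10      10.0000            1
```

The sentence ("Melanoma is a malignant tumor of melanocytes which are found
predominantly in skin but also in the bowel and the eye.") yields six direct
annotations — *Melanoma* (10) and *Melanocyte* (10) and the synonym *tumor*
→ *Neoplasm* (8) in NCI, *Eye* (10) and the synonym *bowel* → *Intestine*
(8) in FMA, *Melanoma* (10) in Human Disease — plus two mapping expansions
of weight 7 (NCI *Melanocyte* → FMA, FMA *Eye* → NCI). Summing per ontology
gives 35 / 25 / 10; the normalized column divides by the ontology sizes
(4 / 3 / 1 concepts).

The same run from the shell:

```sh
ontoreco fixtures --out fixture/
ontoreco recommend --repo fixture/manifest.yaml --input text.txt \
    --scenario corpus --method crm --value score --format text
```

Synthetic repositories and corpora for experiments come from
`ontoreco simulate --seed N --out DIR` or, in Python,
`generate_repository(FixtureSpec(...))` / `generate_corpus(...)`.

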