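# Methods

## Model

`ontoreco` treats ontology recommendation as an annotation-scoring problem.
A repository `R` is a set of ontologies (each a set of concepts with
preferred names, synonyms, and an acyclic is_a hierarchy) plus a list of
directed cross-ontology point-to-point mappings. For an input text `T`, the
pipeline produces a multiset of annotations `A(T, R)` and scores ontology
`o` as

    score(o) = Σ { w(a) : a ∈ A(T, R), a's concept ∈ o }
    normalized_score(o) = score(o) / |concepts(o)|

where `w(a)` depends only on how `a` was obtained: 10 for a preferred-name
match, 8 for a synonym match, 7 for a single-hop mapping expansion, and
`⌊1 + 10·e^(−0.2·n)⌋` for an is_a ancestor at minimal edge distance `n`.
Raw score answers "which ontology covers my data best" (coverage; under
CR+M, additionally connectivity, since mapping targets accumulate weight-7
credit); normalized score answers "which small ontology is specialized for
my data" (it is essentially term-overlap fraction for keyword inputs).

### Assumptions

- Concept recognition is purely lexical. No disambiguation, stemming beyond
  a plural fold, or semantic similarity is attempted; a string that matches
  is an annotation, whatever its sense in context.
- Cross-ontology identity is expressed *only* by explicit mapping rows.
  There is no implicit unification of concepts sharing a CUI-like local id;
  two rows are needed for a symmetric link.
- Mapping expansion is single-hop and does not re-seed further expansion;
  chaining would double-count hub ontologies.
- is_a ancestor expansion is implemented (`expand_isa`) but deliberately not
  wired into `recommend`: ranking with it rewards ontologies for deep
  multiple inheritance rather than for covering the input.

## Matching rules

Terms and candidate phrases share one normalization: case-fold, extract
`\w+` tokens, join with single spaces. Consequences: matching ignores
punctuation and whitespace differences ("Breast-Cancer" hits the entry for
"breast cancer"), and matches must align with token boundaries on both ends
("eye" never fires inside "dyeing"). The plural fold strips one trailing
"s" (not "ss") from the final token, and only when the literal phrase has
no dictionary hit, so "measles" is never folded away from its own entry.

Filtering: terms shorter than `min_term_size` (default 3 characters) are
excluded from the dictionary; terms equal to a stopword are excluded, and a
stopword token in the text never matches as a single-token phrase (stopwords
do not block multi-word phrases they are part of). The default list is a
fixed ~60-word English function-word list shipped as a package resource; the
original service documents that a default stopword list exists but not its
content, so the list here is version-controlled and overridable in
`MatchConfig`.

`longest_only` suppression removes annotations whose span is a *strict*
sub-interval of another annotation's span, across all ontologies. Equal
spans and overlapping-but-not-nested spans all survive; the operation is
idempotent. Keyword runs default to `longest_only=true`, corpus runs to
`false` (both overridable) — keyword lists are clean term inventories where
partial matches are noise, while corpora benefit from counting every
mention.

Spans are 0-based half-open character offsets internally; the recognizer is
checked against a brute-force oracle (every dictionary term tried at every
token position) on randomized inputs.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_term_size` | 3 chars | shortest dictionary term admitted |
| `use_default_stopwords` | true | apply the shipped stopword list |
| `longest_only` | by scenario | suppress strictly contained spans |
| `method` | CR | CR (recognition only) or CR+M (adds mapping expansion) |
| `output_value` | score | `score` or `normalized` |
| `top_k` | 15 | entries reported per ranking |
| weights | 10 / 8 / 7, a=1 b=10 k=0.2 | context weights; all overridable |

The flat service-style configuration keys (`longestOnly`,
`withDefaultStopWords`, `minTermSize`, `activateMapping`) are accepted by
`RunConfig.from_params` and the CLI `--config` file.

## Numerical choices

- **Ancestor weight rounding.** The decay `1 + 10·e^(−0.2n)` is floored to
  an integer per annotation (9 at n=1, 7 at n=2, 4 at n=5, 3 at n=8, 1 for
  n>12). Floor is the convention consistent with all of those per-level
  example values; conventional rounding would give 8 at n=2. Flooring happens
  per annotation, before summation.
- **Deduplication.** Identical (concept, span) pairs keep only the
  highest-weight annotation, so a mapping landing on a directly matched
  concept, or a synonym that equals a preferred name, cannot double-credit
  an ontology for one mention. Multi-path ancestors take the minimal level
  (the most favorable weight) — deterministic and monotone.
- **Ranking ties.** Entries sort descending by the selected value with ties
  broken ascending by ontology id; tied values share the smaller rank
  (competition ranking).
- **Determinism.** Scores are exact sums of small integers in doubles;
  JSON output is key-sorted and byte-stable, keeping full float precision so
  the JSON render round-trips exactly. Text and XML renders show the
  normalized score to 4 decimals. The tag cloud maps the selected value
  linearly onto integer font weights 1–10 (all-equal collapses to 10).
- **Degenerate inputs.** Empty input text is an error; an input with zero
  annotations is not — it yields an empty ranking with a logged warning, and
  every renderer accepts an empty ranking.

## Synthetic data

`generate_repository(FixtureSpec)` emulates the coarse shape of a large
ontology repository: a small/medium/large size mix of 47% / 36% / 17%
(concept counts 5–20 / 20–80 / 80–200 — scaled-down size classes chosen to
keep simulated repositories cheap to annotate while preserving the skew),
0–2 synonyms per concept from a shared pool, is_a parents sampled among
earlier concepts (acyclic by construction), and designated hub ontologies
whose probability of being a mapping target is tripled, reproducing the
hub-and-spoke character of real mapping networks. Preferred names are
unique repository-wide; synonym collisions across ontologies are allowed,
as in real terminologies.

`generate_corpus` samples `n_terms` phrases from one source ontology and
interleaves noise tokens drawn from a disjoint character alphabet
(vocabulary uses a–m, noise n–z), so noise can never accidentally hit the
dictionary; phrases are joined with ". " so no match straddles two phrases.
Everything is pinned by the seed.

What the generators do **not** emulate: real term-length and morphology
distributions, ambiguous/polysemous terms, semantic coherence between a
concept and its synonyms, realistic mapping topology beyond hub in-degree,
and production-scale dictionaries (millions of terms). Passing the
planted-ontology recovery test therefore shows the pipeline's machinery is
sound — coverage signal propagates from matched terms to rankings — not
that rankings on real biomedical corpora reach any particular quality.

## Worked-example fixture

The pinned three-ontology repository is the minimal one reproducing a known
annotation set for the melanoma sentence: NCI (4 concepts), FMA (3),
Human Disease (1), with mappings NCI/C0025201→FMA/C0025201 and
FMA/C0015392→NCI/C0015392. Two concepts are reachable *only* through
mappings, so their preferred names are deliberately chosen not to occur in
the sentence: NCI/C0015392 is named "Eye structure" and FMA/C0025201
"Epidermal melanocyte". Had they carried the bare names "Eye" and
"Melanocyte", they would match directly at weight 10 and the per-ontology
totals would exceed the expected 35 / 25 / 10. The fixture also contains no
"skin" concept: the sentence's "skin" must produce no annotation.

## Design choices

- Duplicate ontologies (the same terminology loaded under two ids) are not
  merged; each scores independently. A group tag (`umls` / `bioportal` /
  `other`) per ontology supports repository-level filtering instead of
  semantic-type switches.
- One mapping row is one directed link; bidirectionality is two rows.
- The OBO reader supports exactly the lexical subset the pipeline consumes
  (`id`, `name`, `synonym`, `is_a`, `is_obsolete`); other tags are ignored,
  obsolete terms dropped, cycles and duplicate ids rejected at load with
  line numbers. A writer provides the inverse for round-trip fixtures.

## Known limitations

- Lexical matching only: "cold" the disease and "cold" the sensation are
  indistinguishable.
- The plural fold is naive English; no other inflection, and no
  multilingual support.
- Mapping quality is taken at face value; a wrong mapping row credits the
  wrong ontology.
- Scores grow with input length, so raw scores are comparable only within
  one run, never across inputs.
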