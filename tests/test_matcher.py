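"""Concept recognition: dictionary compilation, matching, span suppression."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontoreco import (
    DIRECT_PREFERRED,
    DIRECT_SYNONYM,
    Concept,
    DictionaryEntry,
    DirectAnnotation,
    MatchConfig,
    Ontology,
    OntorecoError,
    Span,
    build_repository,
    compile_dictionary,
    default_stopwords,
    normalize_term,
    recognize,
    suppress_subsumed,
)


def dictionary(*terms: str) -> set[DictionaryEntry]:
    """Toy dictionary: every term is a preferred name of its own concept."""
    return {
        DictionaryEntry(normalize_term(t), ("ONT", f"C{i}"), "preferred")
        for i, t in enumerate(terms)
    }


def spans(annotations) -> set[tuple[int, int]]:
    return {(a.span.start, a.span.end) for a in annotations}


class TestCompileDictionary:
    def make_repo(self, *concepts):
        ont = Ontology("ONT", "ONT")
        for c in concepts:
            ont.add_concept(c)
        return build_repository([ont])

    def test_preferred_only(self):
        repo = self.make_repo(Concept("ONT", "1", "Melanoma"))
        entries = compile_dictionary(repo)
        assert entries == {DictionaryEntry("melanoma", ("ONT", "1"), "preferred")}

    def test_synonym_gets_its_own_entry(self):
        repo = self.make_repo(Concept("ONT", "1", "Neoplasm", ["tumor"]))
        entries = compile_dictionary(repo)
        assert {e.normalized_term for e in entries} == {"neoplasm", "tumor"}
        kinds = {e.normalized_term: e.term_kind for e in entries}
        assert kinds == {"neoplasm": "preferred", "tumor": "synonym"}

    def test_short_terms_excluded(self):
        repo = self.make_repo(Concept("ONT", "1", "Eo", ["eosinophil"]))
        entries = compile_dictionary(repo, MatchConfig(min_term_size=3))
        assert {e.normalized_term for e in entries} == {"eosinophil"}

    def test_stopword_terms_excluded(self):
        repo = self.make_repo(Concept("ONT", "1", "The", ["melanoma"]))
        entries = compile_dictionary(repo)
        assert {e.normalized_term for e in entries} == {"melanoma"}

    def test_terms_normalized(self):
        repo = self.make_repo(Concept("ONT", "1", "  Breast   Cancer "))
        entries = compile_dictionary(repo)
        assert {e.normalized_term for e in entries} == {"breast cancer"}


class TestRecognize:
    def test_breast_cancer_all_matches(self):
        d = dictionary("breast", "cancer", "breast cancer")
        anns = recognize("breast cancer", d, MatchConfig(longest_only=False))
        assert spans(anns) == {(0, 6), (7, 13), (0, 13)}

    def test_breast_cancer_longest_only(self):
        d = dictionary("breast", "cancer", "breast cancer")
        anns = recognize("breast cancer", d, MatchConfig(longest_only=True))
        assert spans(anns) == {(0, 13)}
        assert {a.span.surface for a in anns} == {"breast cancer"}

    def test_plural_folding(self):
        anns = recognize("the melanocytes divide", dictionary("melanocyte"))
        assert len(anns) == 1
        assert anns[0].span.surface == "melanocytes"

    def test_plural_fold_skipped_when_literal_matches(self):
        """'measles' must match the entry 'measles', not a folded 'measle'."""
        anns = recognize("measles outbreak", dictionary("measles", "measle"))
        assert len(anns) == 1
        assert anns[0].concept_ref == ("ONT", "C0")

    def test_no_mid_word_matches(self):
        assert recognize("dyeing wool", dictionary("eye")) == []

    def test_every_occurrence_annotated(self):
        anns = recognize("tumor and tumor", dictionary("tumor"))
        assert spans(anns) == {(0, 5), (10, 15)}

    def test_same_term_in_two_ontologies_yields_two_annotations(self):
        d = {
            DictionaryEntry("melanoma", ("A", "1"), "preferred"),
            DictionaryEntry("melanoma", ("B", "1"), "synonym"),
        }
        anns = recognize("melanoma", d)
        assert {(a.concept_ref, a.context) for a in anns} == {
            (("A", "1"), DIRECT_PREFERRED),
            (("B", "1"), DIRECT_SYNONYM),
        }

    def test_punctuation_does_not_block_phrase(self):
        anns = recognize("breast-cancer trial", dictionary("breast cancer"))
        assert len(anns) == 1 and anns[0].span.surface == "breast-cancer"

    def test_stopword_token_never_matches_alone(self):
        d = {DictionaryEntry("the", ("ONT", "C0"), "preferred")}
        assert recognize("the end", d) == []

    def test_empty_text_is_error(self):
        with pytest.raises(OntorecoError, match="empty"):
            recognize("   ", dictionary("x"))

    def test_output_sorted(self):
        d = dictionary("bowel", "eye", "bowel and eye")
        anns = recognize("bowel and eye", d, MatchConfig(longest_only=False))
        keys = [(a.span.start, a.span.end, *a.concept_ref) for a in anns]
        assert keys == sorted(keys)


class TestSuppressSubsumed:
    def ann(self, start, end, ont="ONT", cid="C"):
        return DirectAnnotation((ont, cid), Span(start, end, "x" * (end - start)),
                                DIRECT_PREFERRED)

    def test_contained_spans_removed(self):
        anns = [self.ann(0, 6), self.ann(7, 13), self.ann(0, 13)]
        assert spans(suppress_subsumed(anns)) == {(0, 13)}

    def test_disjoint_spans_survive(self):
        anns = [self.ann(0, 6), self.ann(8, 14)]
        assert suppress_subsumed(anns) == anns

    def test_equal_spans_from_two_ontologies_both_survive(self):
        anns = [self.ann(0, 6, "A"), self.ann(0, 6, "B")]
        assert suppress_subsumed(anns) == anns

    def test_overlapping_non_nested_both_survive(self):
        anns = [self.ann(0, 8), self.ann(4, 12)]
        assert suppress_subsumed(anns) == anns

    def test_idempotent_and_never_grows(self):
        anns = [self.ann(0, 6), self.ann(1, 5), self.ann(2, 4), self.ann(9, 12)]
        once = suppress_subsumed(anns)
        assert len(once) <= len(anns)
        assert suppress_subsumed(once) == once


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

WORDS = st.text(alphabet="abcd", min_size=3, max_size=5)
TERMS = st.lists(
    st.lists(WORDS, min_size=1, max_size=2).map(" ".join),
    min_size=1, max_size=12, unique=True,
)
TEXTS = st.lists(WORDS, min_size=1, max_size=15).map(" ".join)


def brute_force_recognize(text: str, dictionary, config: MatchConfig):
    """Independent oracle: try every dictionary term over every token window."""
    terms = {}
    for entry in dictionary:
        terms.setdefault(entry.normalized_term, []).append(entry)
    stop = config.effective_stopwords()
    tokens = list(re.finditer(r"\w+", text))
    found = []
    for i in range(len(tokens)):
        for j in range(i, len(tokens)):
            words = [t.group().casefold() for t in tokens[i:j + 1]]
            if i == j and words[0] in stop:
                continue
            phrase = " ".join(words)
            folded = None
            last = words[-1]
            if len(last) > 2 and last.endswith("s") and not last.endswith("ss"):
                folded = " ".join(words[:-1] + [last[:-1]])
            hit = phrase if phrase in terms else (folded if folded in terms else None)
            if hit is None:
                continue
            span = Span(tokens[i].start(), tokens[j].end(),
                        text[tokens[i].start():tokens[j].end()])
            for entry in terms[hit]:
                context = DIRECT_PREFERRED if entry.term_kind == "preferred" \
                    else DIRECT_SYNONYM
                found.append(DirectAnnotation(entry.concept_ref, span, context))
    if config.longest_only:
        found = suppress_subsumed(found)
    return sorted(found, key=lambda a: (a.span.start, a.span.end,
                                        a.concept_ref[0], a.concept_ref[1], a.context))


@settings(max_examples=150, derandomize=True, deadline=None)
@given(terms=TERMS, text=TEXTS, longest=st.booleans())
def test_recognize_matches_brute_force_oracle(terms, text, longest):
    d = dictionary(*terms)
    config = MatchConfig(longest_only=longest)
    assert recognize(text, d, config) == brute_force_recognize(text, d, config)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(terms=TERMS, text=TEXTS)
def test_longest_only_output_is_subset(terms, text):
    d = dictionary(*terms)
    full = recognize(text, d, MatchConfig(longest_only=False))
    longest = recognize(text, d, MatchConfig(longest_only=True))
    assert set(longest) <= set(full)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(terms=TERMS, text=TEXTS)
def test_matching_is_case_insensitive(terms, text):
    d = dictionary(*terms)
    lower = recognize(text, d)
    upper = recognize(text.upper(), d)
    assert [(a.span.start, a.span.end, a.concept_ref) for a in lower] == \
        [(a.span.start, a.span.end, a.concept_ref) for a in upper]


@settings(max_examples=60, derandomize=True, deadline=None)
@given(terms=TERMS, text=TEXTS)
def test_spans_slice_back_to_surface(terms, text):
    for ann in recognize(text, dictionary(*terms)):
        assert text[ann.span.start:ann.span.end] == ann.span.surface


def test_default_stopwords_cover_function_words():
    stop = default_stopwords()
    assert {"the", "of", "and", "in", "is", "a"} <= stop
    assert len(stop) >= 40
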