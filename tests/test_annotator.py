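"""NER matching, sentence splitting, and conflict resolution."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litprior.annotator import (
    Annotation,
    annotate,
    conflict_stats,
    resolve_conflicts,
    split_sentences,
)
from litprior.lexicon import TYPE_PRECEDENCE

from conftest import make_lexicon


class TestSplitSentences:
    def test_two_sentences(self):
        assert len(split_sentences("A b. C d.")) == 2

    def test_no_terminator_single_span(self):
        text = "no terminator here"
        assert split_sentences(text) == [(0, len(text))]

    def test_initialism_kept_intact(self):
        text = "E. coli causes X. Y follows."
        spans = split_sentences(text)
        assert len(spans) == 2
        assert text[spans[0][0] : spans[0][1]] == "E. coli causes X."

    def test_abbreviation_not_split(self):
        text = "Compared vs. Controls it rose. More text."
        spans = split_sentences(text)
        assert text[spans[0][0] : spans[0][1]] == "Compared vs. Controls it rose."

    @pytest.mark.parametrize(
        "text",
        ["", "   ", "One. Two! Three? Four", "Single sentence only", "Lower. case next."],
    )
    def test_spans_partition_non_whitespace(self, text):
        spans = split_sentences(text)
        covered = set()
        for s, e in spans:
            assert not text[s].isspace() and not text[e - 1].isspace()
            assert not (covered & set(range(s, e)))
            covered |= set(range(s, e))
        non_ws = {i for i, c in enumerate(text) if not c.isspace()}
        assert covered >= non_ws  # every non-whitespace char in exactly one span


class TestAnnotate:
    def test_single_phenotype_match(self, phenotype_lexicon):
        text = "patient had seizure"
        anns = annotate(text, [phenotype_lexicon])
        assert len(anns) == 1
        a = anns[0]
        assert (a.start, a.end) == (12, 19)
        assert a.matched_text == text[a.start : a.end] == "seizure"
        assert a.entity_id == "HP:0001250"

    def test_ambiguous_term_annotated_once_per_type(self, phenotype_lexicon, gene_lexicon):
        # "Warts" names both a gene and a phenotype: both types report it
        anns = annotate("warts on hand", [phenotype_lexicon, gene_lexicon])
        assert {(a.entity_type, a.entity_id) for a in anns} == {
            ("phenotype", "HP:0200043"),
            ("gene", "HGNC:6514"),
        }
        assert len({(a.start, a.end) for a in anns}) == 1

    def test_no_plural_inflection(self, phenotype_lexicon):
        assert annotate("recurrent seizures", [phenotype_lexicon]) == []

    def test_case_insensitive_long_terms(self, phenotype_lexicon):
        assert len(annotate("SEIZURE noted", [phenotype_lexicon])) == 1

    def test_short_gene_terms_require_exact_case(self, gene_lexicon):
        assert annotate("wts overexpression", [gene_lexicon]) == []
        anns = annotate("WTS overexpression", [gene_lexicon])
        assert [a.entity_id for a in anns] == ["HGNC:6514"]

    def test_leftmost_longest_per_type(self, phenotype_lexicon):
        lex = make_lexicon(
            "phenotype", {"HP:1": ["cleft palate"], "HP:2": ["submucosal cleft palate"]}
        )
        anns = annotate("a submucosal cleft palate was seen", [lex])
        assert [a.entity_id for a in anns] == ["HP:2"]

    def test_within_type_shared_term_yields_k_annotations(self, gene_lexicon):
        anns = annotate("cox2 levels", [gene_lexicon])
        assert [a.entity_id for a in anns] == ["HGNC:7421", "HGNC:9605"]

    def test_stoplisted_terms_never_matched(self):
        lex = make_lexicon("gene", {"HGNC:1": ["notch1"]}, stoplist={"notch1"})
        assert annotate("notch1 pathway", [lex]) == []

    def test_deterministic(self, phenotype_lexicon, gene_lexicon, disease_lexicon):
        text = "Warts and seizure in Rett syndrome with submucosal cleft palate"
        lexes = [phenotype_lexicon, gene_lexicon, disease_lexicon]
        assert annotate(text, lexes) == annotate(text, lexes)

    def test_matched_text_rematches_term_set(self, phenotype_lexicon, disease_lexicon):
        from litprior.lexicon import normalize_term

        text = "Submucosal  cleft palate and SEIZURE."
        for a in annotate(text, [phenotype_lexicon, disease_lexicon]):
            lex = phenotype_lexicon if a.entity_type == "phenotype" else disease_lexicon
            norms = {normalize_term(t) for t in lex.entries[a.entity_id].terms}
            assert normalize_term(a.matched_text) in norms

    def test_empty_text(self, phenotype_lexicon):
        assert annotate("", [phenotype_lexicon]) == []


def ann(start, end, etype, eid="X:1"):
    return Annotation("d1", start, end, etype, eid, "x" * (end - start))


class TestResolveConflicts:
    def test_phenotype_wins_over_disease(self):
        out = resolve_conflicts([ann(10, 25, "disease"), ann(10, 25, "phenotype")])
        assert [a.entity_type for a in out] == ["phenotype"]

    def test_disease_wins_over_gene(self):
        out = resolve_conflicts([ann(3, 9, "gene"), ann(0, 9, "disease")])
        assert [a.entity_type for a in out] == ["disease"]

    def test_same_type_longest_span_wins(self):
        out = resolve_conflicts([ann(0, 7, "phenotype", "HP:1"), ann(0, 15, "phenotype", "HP:2")])
        assert [(a.start, a.end, a.entity_id) for a in out] == [(0, 15, "HP:2")]

    def test_same_span_same_type_ambiguity_retained(self):
        out = resolve_conflicts([ann(0, 4, "gene", "HGNC:1"), ann(0, 4, "gene", "HGNC:2")])
        assert [a.entity_id for a in out] == ["HGNC:1", "HGNC:2"]

    def test_non_overlapping_all_kept(self):
        anns = [ann(0, 4, "gene"), ann(5, 9, "disease"), ann(10, 14, "phenotype")]
        assert len(resolve_conflicts(anns)) == 3

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 30),
                st.integers(1, 8),
                st.sampled_from(["phenotype", "disease", "gene"]),
                st.sampled_from(["A:1", "A:2", "B:1"]),
            ),
            max_size=12,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_no_lower_precedence_survivor_overlaps_higher(self, raw):
        anns = [ann(s, s + ln, t, e) for s, ln, t, e in raw]
        out = resolve_conflicts(anns)
        for a, b in itertools.combinations(out, 2):
            if a.entity_type != b.entity_type:
                assert not a.overlaps(b)
        # highest-precedence annotations always survive within-type rules:
        # every input overlapped by a surviving higher-precedence span is out
        out_set = set(out)
        for a in anns:
            for b in out_set:
                if TYPE_PRECEDENCE[b.entity_type] < TYPE_PRECEDENCE[a.entity_type]:
                    if a.overlaps(b):
                        assert a not in out_set


class TestConflictStats:
    def test_single_phenotype_disease_resolution(self):
        before = [ann(0, 5, "phenotype"), ann(0, 5, "disease")]
        after = resolve_conflicts(before)
        stats = conflict_stats(before, after)
        assert stats[("disease", "phenotype")] == 1
        assert stats[("gene", "phenotype")] == 0
        assert stats[("disease", "gene")] == 0

    def test_no_overlaps_all_zero(self):
        before = [ann(0, 5, "phenotype"), ann(6, 9, "disease")]
        stats = conflict_stats(before, resolve_conflicts(before))
        assert all(v == 0 for v in stats.values())

    def test_matches_bruteforce_on_mixed_set(self):
        before = [
            ann(0, 5, "phenotype", "HP:1"),
            ann(2, 8, "disease", "OR:1"),
            ann(6, 12, "gene", "HG:1"),
            ann(20, 25, "disease", "OR:2"),
            ann(23, 30, "gene", "HG:2"),
            ann(40, 44, "phenotype", "HP:2"),
        ]
        after = resolve_conflicts(before)
        stats = conflict_stats(before, after)
        # brute-force oracle over all pairs
        expected = {("disease", "phenotype"): 0, ("gene", "phenotype"): 0, ("disease", "gene"): 0}
        after_set = set(after)
        for a, b in itertools.combinations(before, 2):
            if a.entity_type != b.entity_type and a.overlaps(b):
                hi, lo = sorted((a, b), key=lambda x: TYPE_PRECEDENCE[x.entity_type])
                if hi in after_set and lo not in after_set:
                    expected[tuple(sorted((a.entity_type, b.entity_type)))] += 1
        assert stats == expected
        assert stats[("disease", "phenotype")] == 1  # HP:1 vs OR:1
        assert stats[("disease", "gene")] >= 1  # OR:2 vs HG:2
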