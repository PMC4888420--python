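"""Workflow engine: proposals, decisions, coverage and the re-use mechanism."""

import pytest

from odmannotate import (AnnotationSignature, ConceptCode, DecisionRecord,
                         TermIndex, UnknownTargetError,
                         annotate_corpus_reuse_first, apply_decisions,
                         build_index, coverage, decisions_from_tsv,
                         decisions_to_tsv, lookup_exact, make_synonym_corpus,
                         propose_all, set_annotation)
from conftest import small_model


class TestCoverage:
    def test_none_annotated(self):
        assert coverage(small_model("M", ("a", "b"), (None, None))) == 0.0

    def test_all_annotated(self):
        assert coverage(small_model("M", ("a",), ("C0005890",))) == 1.0

    def test_one_of_four(self):
        model = small_model("M", ("a", "b", "c", "d"),
                            ("C0005890", None, None, None))
        assert coverage(model) == 0.25

    def test_empty_target_set_defined_as_one(self):
        model = small_model("M")
        model.items.clear()
        model.groups[0].item_refs.clear()
        assert coverage(model) == 1.0


class TestProposeAll:
    def test_fully_annotated_model_gets_empty_map(self, table1_corpus,
                                                  table1_index, toy_vocab):
        assert propose_all(table1_corpus[0], table1_index, toy_vocab) == {}

    def test_one_list_per_unannotated_item(self, table1_index, toy_vocab):
        model = small_model("M", ("a", "b", "c"), (None, None, None))
        assert set(propose_all(model, table1_index, toy_vocab)) == \
            {"IT.1", "IT.2", "IT.3"}

    def test_indexed_name_proposes_repository_first(self, toy_vocab):
        index = build_index([small_model("M1", ("Height",), ("C0005890",))])
        model = small_model("M2", ("Height",), (None,))
        (sl,) = propose_all(model, index, toy_vocab).values()
        top = sl.suggestions[0]
        assert top.origin == "repository"
        assert top.signature.canonical == "C0005890"


class TestApplyDecisions:
    def test_bookkeeping_of_one_reuse(self, toy_vocab):
        index = build_index([small_model("M1", ("Height",), ("C0005890",))])
        model = small_model("M2", ("Height", "Weight"), (None, None))
        decisions = [DecisionRecord("IT.1", "reuse", (ConceptCode("C0005890"),))]
        model, index, report = apply_decisions(model, decisions, index, toy_vocab)
        assert report.counts["reuse"] == 1
        assert report.coverage_after - report.coverage_before == pytest.approx(0.5)
        (entry,) = lookup_exact(index, "Height")
        assert entry.count == 2
        assert report.warnings == []

    def test_idempotent_on_second_application(self, toy_vocab):
        index = TermIndex()
        model = small_model("M1", ("Height",), (None,))
        decisions = [DecisionRecord("IT.1", "vocabulary", (ConceptCode("C0005890"),))]
        model, index, _ = apply_decisions(model, decisions, index, toy_vocab)
        snapshot = {k: e.count for k, e in index.entries.items()}
        model, index, report2 = apply_decisions(model, decisions, index, toy_vocab)
        assert {k: e.count for k, e in index.entries.items()} == snapshot
        assert report2.coverage_before == report2.coverage_after == 1.0

    def test_cross_model_reuse_increments_lookup_counts(self, toy_vocab):
        first = small_model("M1", ("Date of Birth",), ("C0421451",))
        index = build_index([first])
        second = small_model("M2", ("Date of Birth",), (None,))
        decisions = [DecisionRecord("IT.1", "reuse", (ConceptCode("C0421451"),))]
        second, index, _ = apply_decisions(second, decisions, index, toy_vocab)
        (entry,) = lookup_exact(index, "Date of Birth")
        assert entry.count == 2 and entry.signature.canonical == "C0421451"

    def test_skip_leaves_target_unannotated_and_listed(self, toy_vocab):
        model = small_model("M1", ("Door-to-balloon time",), (None,))
        model, _, report = apply_decisions(
            model, [DecisionRecord("IT.1", "skip")], TermIndex(), toy_vocab)
        assert model.items[0].annotation is None
        assert report.skipped == ["IT.1"]
        assert report.counts["skip"] == 1

    def test_unknown_target_is_fatal(self, toy_vocab):
        with pytest.raises(UnknownTargetError, match="IT.9"):
            apply_decisions(small_model("M1"),
                            [DecisionRecord("IT.9", "skip")],
                            TermIndex(), toy_vocab)

    def test_reuse_of_unindexed_signature_warns_but_applies(self, toy_vocab):
        model = small_model("M1", ("Height",), (None,))
        decisions = [DecisionRecord("IT.1", "reuse", (ConceptCode("C0489786"),))]
        model, _, report = apply_decisions(model, decisions, TermIndex(), toy_vocab)
        assert model.items[0].annotation.canonical == "C0489786"
        assert len(report.warnings) == 1

    def test_coverage_never_decreases(self, toy_vocab):
        model = small_model("M1", ("a", "b"), ("C0005890", None))
        for decisions in ([], [DecisionRecord("IT.2", "skip")],
                          [DecisionRecord("IT.2", "vocabulary",
                                          (ConceptCode("C0005910"),))]):
            before = coverage(model)
            model, _, report = apply_decisions(model, decisions, TermIndex(),
                                               toy_vocab)
            assert report.coverage_after >= before

    def test_incremental_index_equals_rebuild(self, toy_vocab):
        corpus, vocab, _ = make_synonym_corpus(3, 6, 2, seed=11)
        annotated, index, _ = annotate_corpus_reuse_first(corpus, vocab)
        assert index.entries == build_index(annotated).entries

    def test_action_counts_sum_to_decisions_applied(self, toy_vocab):
        model = small_model("M1", ("a", "b", "c"), (None, None, None))
        decisions = [
            DecisionRecord("IT.1", "vocabulary", (ConceptCode("C0005890"),)),
            DecisionRecord("IT.2", "postcoordinate",
                           (ConceptCode("C0011008"), ConceptCode("C0027361"))),
            DecisionRecord("IT.3", "skip"),
        ]
        _, _, report = apply_decisions(model, decisions, TermIndex(), toy_vocab)
        assert sum(report.counts.values()) == 3
        assert model.items[1].annotation.canonical == "C0011008+C0027361"


class TestDecisionsTsv:
    def test_round_trip(self):
        decisions = [
            DecisionRecord("IT.1", "reuse", (ConceptCode("C0005890"),), "ok"),
            DecisionRecord("CL.BP:LA", "postcoordinate",
                           (ConceptCode("C0005615"), ConceptCode("C0011008"))),
            DecisionRecord("IT.3", "skip"),
        ]
        assert decisions_from_tsv(decisions_to_tsv(decisions)) == decisions

    def test_non_skip_requires_codes(self):
        with pytest.raises(ValueError):
            DecisionRecord("IT.1", "reuse")


class TestReuseConvergence:
    def test_synonym_clusters_converge_to_single_signatures(self):
        from odmannotate import group_elements, label_map_from_truth

        corpus, vocab, truth = make_synonym_corpus(4, 8, 3, seed=5)
        annotated, _index, _ = annotate_corpus_reuse_first(corpus, vocab)
        rows = group_elements(annotated, label_map_from_truth(truth))
        assert all(r.variant_count == 1 for r in rows)
        assert all(r.total_occurrences == 8 for r in rows)
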