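"""Group resolution: transitive closure, keep-record cascade, conservation."""

import pytest

from citedupe.blocking import CandidatePair
from citedupe.classify import PairDecision, Verdict
from citedupe.io_formats import CitationSet
from citedupe.resolve import (
    DedupConfig,
    DuplicateGroup,
    LabelMode,
    RemovalReason,
    apply_manual,
    build_groups,
    dedupe,
    select_keeps,
)
from citedupe.synthetic import PerturbationConfig, default_corpus, generate

from conftest import make_citation


def _auto(a, b):
    return PairDecision(
        pair=CandidatePair(id_a=min(a, b), id_b=max(a, b), rounds=frozenset({1})),
        verdict=Verdict.AUTO_DUPLICATE,
        rule_name="auto",
    )


def _manual(a, b):
    return PairDecision(
        pair=CandidatePair(id_a=min(a, b), id_b=max(a, b), rounds=frozenset({1})),
        verdict=Verdict.MANUAL_REVIEW,
        rule_name="manual",
    )


class TestBuildGroups:
    def test_chain_resolves_transitively(self):
        groups = build_groups([_auto("A", "B"), _auto("B", "C"), _auto("C", "D")])
        assert [g.member_ids for g in groups] == [frozenset("ABCD")]

    def test_no_auto_pairs_no_groups(self):
        assert build_groups([_manual("A", "B")]) == []

    def test_disjoint_pairs_make_disjoint_groups(self):
        groups = build_groups([_auto("A", "B"), _auto("C", "D")])
        assert {g.member_ids for g in groups} == {frozenset("AB"), frozenset("CD")}


class TestSelectKeeps:
    def _set(self, *citations):
        return CitationSet(list(citations))

    def test_abstract_preferred(self):
        cs = self._set(
            make_citation("A", abstract="has one"),
            make_citation("B", abstract=""),
        )
        (g,) = select_keeps([DuplicateGroup(frozenset("AB"))], cs)
        assert g.keep_id == "A"
        assert g.removal_reason == {"B": RemovalReason.NO_ABSTRACT}

    def test_newest_year_preferred_when_both_have_abstracts(self):
        cs = self._set(
            make_citation("A", year="2020"),
            make_citation("B", year="2021"),
        )
        (g,) = select_keeps([DuplicateGroup(frozenset("AB"))], cs)
        assert g.keep_id == "B"
        assert g.removal_reason == {"A": RemovalReason.OLDER_VERSION}

    def test_second_listed_removed_on_full_tie(self):
        cs = self._set(make_citation("A"), make_citation("B"))
        (g,) = select_keeps([DuplicateGroup(frozenset("AB"))], cs)
        assert g.keep_id == "A"
        assert g.removal_reason == {"B": RemovalReason.SECOND_LISTED}

    def test_keep_label_outranks_abstract(self):
        cs = self._set(
            make_citation("A", abstract="text", label=""),
            make_citation("B", abstract="", label="OLD_SEARCH"),
        )
        (g,) = select_keeps(
            [DuplicateGroup(frozenset("AB"))], cs,
            label_mode=LabelMode.KEEP, label="OLD_SEARCH",
        )
        assert g.keep_id == "B"
        assert g.removal_reason == {"A": RemovalReason.LABEL_PREFERENCE}

    def test_drop_label_prefers_removing_labelled_member(self):
        cs = self._set(
            make_citation("A", label="HUMAN_REMOVED"),
            make_citation("B", label=""),
        )
        (g,) = select_keeps(
            [DuplicateGroup(frozenset("AB"))], cs,
            label_mode=LabelMode.DROP, label="HUMAN_REMOVED",
        )
        assert g.keep_id == "B"
        assert g.removal_reason == {"A": RemovalReason.LABEL_PREFERENCE}

    def test_exactly_one_keep_in_larger_group(self):
        cs = self._set(
            make_citation("A", abstract=""),
            make_citation("B", abstract=""),
            make_citation("C", abstract="only one with text"),
        )
        (g,) = select_keeps([DuplicateGroup(frozenset("ABC"))], cs)
        assert g.keep_id == "C"
        assert set(g.removal_reason) == {"A", "B"}

    def test_unknown_member_rejected(self):
        cs = self._set(make_citation("A"), make_citation("B"))
        with pytest.raises(ValueError, match="Z"):
            select_keeps([DuplicateGroup(frozenset(("A", "Z")))], cs)

    def test_groups_need_two_members(self):
        with pytest.raises(ValueError):
            DuplicateGroup(frozenset("A"))


class TestDedupe:
    def test_no_candidates_keeps_everything(self):
        cs = CitationSet([
            make_citation("A"),
            make_citation(
                "B",
                title="Entirely unrelated title words",
                author="Zed, Z.",
                year="1991",
                journal="Annals of Metabolism",
                doi="10.5/zzz",
                pages="900-911",
                volume="77",
                issue="9",
                isbn_issn="9999-0000",
                abstract="nothing shared here",
            ),
        ])
        res = dedupe(cs)
        assert res.kept.ids == cs.ids
        assert len(res.removed) == 0
        assert res.groups == []

    def test_conservation_and_single_keep_per_group(self):
        corpus = default_corpus(2)
        res = dedupe(corpus.citations)
        assert len(res.kept) + len(res.removed) == len(corpus.citations)
        removed_ids = set(res.removed.ids)
        for g in res.groups:
            assert g.keep_id in g.member_ids
            assert (g.member_ids - {g.keep_id}) <= removed_ids
        # groups pairwise disjoint
        seen = set()
        for g in res.groups:
            assert not (g.member_ids & seen)
            seen |= g.member_ids

    def test_idempotence(self):
        corpus = generate(150, 0.4, perturb=PerturbationConfig(seed=6))
        once = dedupe(corpus.citations)
        twice = dedupe(once.kept)
        assert len(twice.removed) == 0
        assert twice.kept.ids == once.kept.ids

    def test_golden_counts_on_seeded_corpus(self):
        """Frozen from a verified run (all 47 injected copies removed)."""
        corpus = generate(100, 0.4, perturb=PerturbationConfig(seed=11))
        res = dedupe(corpus.citations)
        assert (len(res.kept), len(res.removed), len(res.groups)) == (100, 47, 40)
        assert corpus.n_removable == 47

    def test_label_preference_changes_keeps_not_groups(self):
        corpus = default_corpus(4)
        plain = dedupe(corpus.citations)
        labelled = dedupe(
            corpus.citations,
            DedupConfig(label_mode=LabelMode.KEEP, label="EMBASE"),
        )
        assert [g.member_ids for g in plain.groups] == [
            g.member_ids for g in labelled.groups
        ]
        assert len(plain.removed) == len(labelled.removed)

    def test_empty_input_fails(self):
        from citedupe.io_formats import EmptyInputError

        with pytest.raises(EmptyInputError):
            dedupe(CitationSet())

    def test_deterministic_under_fixed_seed(self):
        corpus_a = default_corpus(9)
        corpus_b = default_corpus(9)
        ra, rb = dedupe(corpus_a.citations), dedupe(corpus_b.citations)
        assert ra.kept.ids == rb.kept.ids
        assert ra.removed.ids == rb.removed.ids
        assert [g.keep_id for g in ra.groups] == [g.keep_id for g in rb.groups]


class TestApplyManual:
    def _result_with_manual_pair(self):
        # identical DOIs, dissimilar titles: flagged for review, not auto
        cs = CitationSet([
            make_citation("A", doi="10.1/shared", title="First conference abstract",
                          author="Smith, J.", pages="1-2", volume="1", issue="1"),
            make_citation("B", doi="10.1/shared",
                          title="Totally different second piece",
                          author="Zhang, Q.", journal="Annals of Metabolism",
                          year="2019", pages="77-80", volume="6", issue="2",
                          isbn_issn="5555-7777",
                          abstract="Unrelated abstract text entirely"),
        ])
        return cs, dedupe(cs)

    def test_manual_pair_surfaced_not_removed(self):
        cs, res = self._result_with_manual_pair()
        assert len(res.removed) == 0
        assert [(s.pair.id_a, s.pair.id_b) for s in res.manual_pairs] == [("A", "B")]

    def test_keep_choice_moves_loser_to_removed(self):
        cs, res = self._result_with_manual_pair()
        updated = apply_manual(res, {("A", "B"): "A"})
        assert updated.kept.ids == ["A"]
        assert updated.removed.ids == ["B"]
        assert len(updated.kept) + len(updated.removed) == len(cs)
        assert updated.manual_pairs == []

    def test_not_duplicate_leaves_result_unchanged(self):
        _, res = self._result_with_manual_pair()
        updated = apply_manual(res, {("A", "B"): "not duplicate"})
        assert updated.kept.ids == res.kept.ids
        assert len(updated.removed) == 0

    def test_empty_choices_is_identity(self):
        _, res = self._result_with_manual_pair()
        updated = apply_manual(res, {})
        assert updated.kept.ids == res.kept.ids
        assert updated.manual_pairs == res.manual_pairs

    def test_choice_on_non_manual_pair_rejected(self):
        _, res = self._result_with_manual_pair()
        with pytest.raises(ValueError, match="non-manual"):
            apply_manual(res, {("A", "X"): "A"})
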