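"""Match filters: verdict assignment, rule config, and monotonicity."""

from collections import Counter
from dataclasses import replace

import pytest

from citedupe.blocking import CandidatePair, candidate_pairs
from citedupe.classify import (
    Condition,
    MatchRule,
    Verdict,
    classify_all,
    classify_pair,
    default_ruleset,
    load_ruleset,
)
from citedupe.normalize import MATCH_FIELDS, normalize_set
from citedupe.similarity import PairScore, score_pair
from citedupe.synthetic import PerturbationConfig, generate


def _score(sim, missing=(), year_a=2020, year_b=2020):
    return PairScore(
        pair=CandidatePair(id_a="a", id_b="b", rounds=frozenset({1})),
        sim=sim,
        missing=frozenset(missing),
        year_a=year_a,
        year_b=year_b,
    )


def _perfect():
    return _score({f: 1.0 for f in MATCH_FIELDS})


class TestDefaultRuleset:
    def test_auto_rules_precede_manual_rules(self):
        rules = default_ruleset()
        autos = [r.priority for r in rules if r.verdict is Verdict.AUTO_DUPLICATE]
        manuals = [r.priority for r in rules if r.verdict is Verdict.MANUAL_REVIEW]
        assert autos and manuals
        assert max(autos) < min(manuals)

    def test_manual_rule_for_matching_doi_alone(self):
        assert any(
            r.verdict is Verdict.MANUAL_REVIEW
            and any(c.field == "doi" and c.op == "eq" and c.value == 1.0
                    for c in r.conditions)
            for r in default_ruleset()
        )

    def test_manual_rules_for_similar_title_dissimilar_author_or_journal(self):
        manuals = [r for r in default_ruleset() if r.verdict is Verdict.MANUAL_REVIEW]
        fields_with_lt = {
            c.field for r in manuals for c in r.conditions if c.op == "lt"
        }
        assert {"author", "journal"} <= fields_with_lt

    def test_every_auto_rule_requires_two_independent_fields(self):
        for r in default_ruleset():
            if r.verdict is Verdict.AUTO_DUPLICATE:
                assert len({c.field for c in r.conditions}) >= 2, r.name


class TestClassifyPair:
    def test_perfect_match_is_auto(self):
        d = classify_pair(_perfect(), default_ruleset())
        assert d.verdict is Verdict.AUTO_DUPLICATE

    def test_matching_doi_with_dissimilar_title_goes_to_manual(self):
        s = _score({"doi": 1.0, "title": 0.60, "journal": 0.40, "author": 0.5})
        d = classify_pair(s, default_ruleset())
        assert d.verdict is Verdict.MANUAL_REVIEW
        assert d.rule_name == "manual_doi_only"

    def test_no_signal_is_non_duplicate(self):
        s = _score({f: 0.45 for f in MATCH_FIELDS})
        d = classify_pair(s, default_ruleset())
        assert d.verdict is Verdict.NON_DUPLICATE
        assert d.rule_name == "none"

    def test_threshold_predicate_on_missing_field_is_false(self):
        # identical title+author but the year is missing on one side:
        # the year_within condition cannot hold, and without abstract/doi/pages
        # corroboration nothing may auto-fire
        s = _score(
            {"title": 1.0, "author": 1.0},
            missing=set(MATCH_FIELDS) - {"title", "author"},
            year_a=None,
            year_b=None,
        )
        d = classify_pair(s, default_ruleset())
        assert d.verdict is not Verdict.AUTO_DUPLICATE

    def test_year_within_one_tolerates_epub_print_drift(self):
        s = _score({"title": 1.0, "author": 1.0, "year": 0.9}, year_a=2020, year_b=2021)
        assert classify_pair(s, default_ruleset()).verdict is Verdict.AUTO_DUPLICATE
        far = _score({"title": 1.0, "author": 1.0, "year": 0.9}, year_a=2018, year_b=2021)
        assert classify_pair(far, default_ruleset()).verdict is not Verdict.AUTO_DUPLICATE

    def test_empty_ruleset_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(_perfect(), [])


class TestRulesetConfig:
    def test_unknown_field_fails_at_load_time(self, tmp_path):
        p = tmp_path / "rules.yaml"
        p.write_text(
            "- name: bad\n  verdict: AUTO_DUPLICATE\n  priority: 1\n"
            "  conditions:\n  - {field: subtitle, op: ge, value: 0.9}\n"
        )
        with pytest.raises(ValueError, match="subtitle"):
            load_ruleset(p)

    def test_yaml_round_trip_equals_defaults(self, tmp_path):
        import yaml

        rules = default_ruleset()
        payload = [
            {
                "name": r.name,
                "verdict": r.verdict.value,
                "priority": r.priority,
                "conditions": [
                    {"field": c.field, "op": c.op, "value": c.value}
                    for c in r.conditions
                ],
            }
            for r in rules
        ]
        p = tmp_path / "rules.yaml"
        p.write_text(yaml.safe_dump(payload))
        assert load_ruleset(p) == rules

    def test_condition_validation(self):
        with pytest.raises(ValueError, match="op"):
            Condition(field="title", op="gt", value=0.5)
        with pytest.raises(ValueError, match="0,1"):
            Condition(field="title", op="ge", value=1.5)
        with pytest.raises(ValueError, match="year"):
            Condition(field="title", op="year_within", value=1)


class TestClassifyAll:
    def test_empty_input(self):
        assert classify_all([]) == []

    def test_single_perfect_pair(self):
        out = classify_all([_perfect()])
        assert [d.verdict for d in out] == [Verdict.AUTO_DUPLICATE]

    def test_decisions_partition_the_pairs(self):
        corpus = generate(80, 0.5, perturb=PerturbationConfig(seed=3))
        norm = normalize_set(corpus.citations)
        by_id = {n.record_id: n for n in norm}
        pairs = candidate_pairs(norm)
        scores = [score_pair(by_id[p.id_a], by_id[p.id_b], p) for p in pairs]
        decisions = classify_all(scores)
        assert len(decisions) == len(pairs)
        assert {(d.pair.id_a, d.pair.id_b) for d in decisions} == {
            (p.id_a, p.id_b) for p in pairs
        }

    def test_golden_verdict_counts_on_seeded_corpus(self):
        """Frozen from a verified run: 147-record corpus, 55 candidate pairs,
        all classified automatic (the perturbations leave titles exactly
        matching after normalization, so the title+author+year filter fires)."""
        corpus = generate(100, 0.4, perturb=PerturbationConfig(seed=11))
        norm = normalize_set(corpus.citations)
        by_id = {n.record_id: n for n in norm}
        pairs = candidate_pairs(norm)
        scores = [score_pair(by_id[p.id_a], by_id[p.id_b], p) for p in pairs]
        counts = Counter(d.verdict.value for d in classify_all(scores))
        assert len(corpus.citations) == 147
        assert len(pairs) == 55
        assert counts == {"AUTO_DUPLICATE": 55}


class TestMonotonicity:
    def test_raising_auto_thresholds_never_increases_auto_count(self):
        corpus = generate(120, 0.5, perturb=PerturbationConfig(seed=21))
        norm = normalize_set(corpus.citations)
        by_id = {n.record_id: n for n in norm}
        pairs = candidate_pairs(norm)
        scores = [score_pair(by_id[p.id_a], by_id[p.id_b], p) for p in pairs]

        def auto_count(rules):
            return sum(
                1 for d in classify_all(scores, rules)
                if d.verdict is Verdict.AUTO_DUPLICATE
            )

        base_rules = default_ruleset()
        base = auto_count(base_rules)
        for bump in (0.01, 0.03, 0.05):
            raised = [
                replace(
                    r,
                    conditions=tuple(
                        replace(c, value=min(1.0, c.value + bump))
                        if c.op == "ge"
                        else c
                        for c in r.conditions
                    ),
                )
                if r.verdict is Verdict.AUTO_DUPLICATE
                else r
                for r in base_rules
            ]
            assert auto_count(raised) <= base
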