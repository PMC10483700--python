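"""Match filters: deciding what a scored candidate pair is.

Most blocked pairs are not duplicates; deterministic rules over the
per-field similarities sort them into three bins:

* ``AUTO_DUPLICATE`` — confidently the same publication; resolved without
  human input. Every stock AUTO rule demands agreement on at least two
  independent fields, which is what keeps the false-positive rate near zero.
* ``MANUAL_REVIEW`` — just short of the automatic filters (e.g. matching
  DOIs, or a near-identical title with an unexpectedly dissimilar author or
  journal — the classic shared-DOI conference-abstract trap); kept for a
  human to adjudicate.
* ``NON_DUPLICATE`` — no rule fired.

Rules are evaluated in priority order (AUTO before MANUAL); the first rule
whose conditions all hold wins. A threshold predicate that references a
field missing in either record is false — rules meant to tolerate missing
abstracts simply must not mention the abstract. The whole ruleset is plain
data and can be replaced from a YAML file.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import yaml

from .normalize import MATCH_FIELDS
from .similarity import PairScore

logger = logging.getLogger(__name__)


class Verdict(str, Enum):
    AUTO_DUPLICATE = "AUTO_DUPLICATE"
    MANUAL_REVIEW = "MANUAL_REVIEW"
    NON_DUPLICATE = "NON_DUPLICATE"


_OPS = ("ge", "lt", "eq", "present", "year_within")


@dataclass(frozen=True)
class Condition:
    """One predicate over a PairScore: field {>=, <, ==} threshold,
    field present, or |year_a - year_b| <= k."""

    field: str
    op: str
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown condition op {self.op!r}; expected one of {_OPS}")
        if self.field != "year" and self.op == "year_within":
            raise ValueError("year_within applies to the year field only")
        if self.field not in MATCH_FIELDS:
            raise ValueError(f"condition references unknown field {self.field!r}")
        if self.op in ("ge", "lt", "eq") and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"threshold {self.value} outside [0,1]")

    def holds(self, score: PairScore) -> bool:
        if self.op == "present":
            return self.field in score.sim
        if self.op == "year_within":
            if score.year_a is None or score.year_b is None:
                return False
            return abs(score.year_a - score.year_b) <= self.value
        sim = score.sim.get(self.field)
        if sim is None:  # missing field: threshold predicates are false
            return False
        if self.op == "ge":
            return sim >= self.value
        if self.op == "lt":
            return sim < self.value
        return sim == self.value  # eq


@dataclass(frozen=True)
class MatchRule:
    name: str
    verdict: Verdict
    priority: int
    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError(f"rule {self.name!r} has no conditions")
        if self.verdict is Verdict.NON_DUPLICATE:
            raise ValueError("rules decide AUTO_DUPLICATE or MANUAL_REVIEW only")

    def matches(self, score: PairScore) -> bool:
        return all(c.holds(score) for c in self.conditions)


@dataclass(frozen=True)
class PairDecision:
    pair: object  # CandidatePair
    verdict: Verdict
    rule_name: str = "none"


def default_ruleset() -> list[MatchRule]:
    """The stock match filters.

    AUTO rules (priority 1-5) demand corroboration on at least two
    independent fields plus, where years exist, an at-most-one-year gap
    (absorbing e-publication vs print-year drift). MANUAL rules (6-8) catch
    the near-misses worth human eyes.
    """

    def c(field: str, op: str, value: float = 0.0) -> Condition:
        return Condition(field=field, op=op, value=value)

    return [
        MatchRule("auto_title_author_year", Verdict.AUTO_DUPLICATE, 1, (
            c("title", "ge", 0.95), c("author", "ge", 0.80), c("year", "year_within", 1),
        )),
        MatchRule("auto_title_abstract_year", Verdict.AUTO_DUPLICATE, 2, (
            c("title", "ge", 0.90), c("abstract", "ge", 0.90), c("year", "year_within", 1),
        )),
        MatchRule("auto_doi_title", Verdict.AUTO_DUPLICATE, 3, (
            c("doi", "eq", 1.0), c("title", "ge", 0.90),
        )),
        MatchRule("auto_title_pages", Verdict.AUTO_DUPLICATE, 4, (
            c("title", "ge", 0.98), c("pages", "eq", 1.0),
        )),
        MatchRule("auto_title_volume", Verdict.AUTO_DUPLICATE, 5, (
            c("title", "ge", 0.98), c("volume", "eq", 1.0),
        )),
        MatchRule("manual_doi_only", Verdict.MANUAL_REVIEW, 6, (
            c("doi", "eq", 1.0),
        )),
        MatchRule("manual_title_low_author", Verdict.MANUAL_REVIEW, 7, (
            c("title", "ge", 0.90), c("author", "lt", 0.80),
        )),
        MatchRule("manual_title_low_journal", Verdict.MANUAL_REVIEW, 8, (
            c("title", "ge", 0.85), c("journal", "lt", 0.60),
        )),
    ]


def load_ruleset(path) -> list[MatchRule]:
    """Load match rules from YAML/JSON-style config.

    Schema: a list of {name, verdict, priority, conditions:
    [{field, op: ge|lt|eq|present|year_within, value}]}. Validation errors
    (unknown fields, bad ops, out-of-range thresholds) are raised at load
    time, never per-pair.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list) or not data:
        raise ValueError(f"ruleset {path} must be a non-empty list of rules")
    rules = []
    for i, entry in enumerate(data):
        try:
            conditions = tuple(
                Condition(
                    field=cond["field"],
                    op=cond["op"],
                    value=float(cond.get("value", 0.0)),
                )
                for cond in entry["conditions"]
            )
            rules.append(
                MatchRule(
                    name=str(entry["name"]),
                    verdict=Verdict(entry["verdict"]),
                    priority=int(entry["priority"]),
                    conditions=conditions,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"invalid rule at index {i} in {path}: {exc}") from exc
    return sorted(rules, key=lambda r: r.priority)


def classify_pair(score: PairScore, rules: Sequence[MatchRule]) -> PairDecision:
    """First matching rule by priority decides; no rule -> NON_DUPLICATE."""
    if not rules:
        raise ValueError("classify_pair requires a non-empty ruleset")
    for rule in sorted(rules, key=lambda r: r.priority):
        if rule.matches(score):
            return PairDecision(pair=score.pair, verdict=rule.verdict, rule_name=rule.name)
    return PairDecision(pair=score.pair, verdict=Verdict.NON_DUPLICATE)


def classify_all(
    scores: Iterable[PairScore], rules: Sequence[MatchRule] | None = None
) -> list[PairDecision]:
    if rules is None:
        rules = default_ruleset()
    ordered = sorted(rules, key=lambda r: r.priority)
    decisions = [classify_pair(s, ordered) for s in scores]
    counts = Counter(d.verdict.value for d in decisions)
    logger.info("classified %d pairs: %s", len(decisions), dict(counts))
    return decisions
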