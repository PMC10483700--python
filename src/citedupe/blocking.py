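"""Candidate-pair generation by exact-match blocking.

All-pairs comparison of an aggregated search is quadratic and infeasible at
review scale, so comparison is restricted to pairs that agree *exactly* (on
the normalized view) on at least one blocking key. Fifteen conjunctive keys are applied
in four rounds; a pair surfaced by any round is a candidate, and the union is
independent of round order. The rounds exist as provenance/staging structure
only — historically they bound peak memory on very large datasets.

A key containing a missing field never matches: agreement on absent data is
vacuous, and letting every no-DOI record pair with every other would be
catastrophic for specificity.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import yaml

from .normalize import MATCH_FIELDS, NormalizedCitation


@dataclass(frozen=True)
class BlockingRule:
    """One conjunctive key: the named fields must be non-missing and equal."""

    round: int
    required_fields: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required_fields:
            raise ValueError("blocking rule needs at least one field")
        unknown = self.required_fields - set(MATCH_FIELDS)
        if unknown:
            raise ValueError(f"blocking rule references unknown fields: {sorted(unknown)}")

    def key(self, c: NormalizedCitation) -> tuple[str, ...] | None:
        """The record's key tuple under this rule, or None if any field is missing."""
        vals = []
        for f in sorted(self.required_fields):
            if c.is_missing(f):
                return None
            vals.append(c.get(f))
        return tuple(vals)


@dataclass(frozen=True)
class CandidatePair:
    """An unordered candidate pair; ``id_a < id_b`` canonically."""

    id_a: str
    id_b: str
    rounds: frozenset[int]

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError("CandidatePair requires id_a < id_b")


_DEFAULT_ROUNDS: Sequence[tuple[int, Sequence[Sequence[str]]]] = (
    (1, (("title", "pages"), ("title", "author"), ("title", "abstract"), ("doi",))),
    (2, (("author", "year", "pages"), ("journal", "volume", "pages"),
         ("isbn_issn", "volume", "pages"), ("title", "isbn_issn"))),
    (3, (("year", "pages", "volume"), ("year", "issue", "volume"),
         ("year", "pages", "issue"))),
    (4, (("author", "year"), ("title", "year"), ("title", "volume"),
         ("title", "journal"))),
)


def default_rules() -> list[BlockingRule]:
    """The 15 stock blocking keys, grouped in 4 rounds.

    Round 1: (title, pages) | (title, author) | (title, abstract) | doi
    Round 2: (author, year, pages) | (journal, volume, pages)
             | (isbn, volume, pages) | (title, isbn)
    Round 3: (year, pages, volume) | (year, issue, volume) | (year, pages, issue)
    Round 4: (author, year) | (title, year) | (title, volume) | (title, journal)
    """
    return [
        BlockingRule(round=r, required_fields=frozenset(fields))
        for r, keys in _DEFAULT_ROUNDS
        for fields in keys
    ]


def load_rules(path) -> list[BlockingRule]:
    """Load blocking rules from YAML: ``{round: [[field, ...], ...], ...}``."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping) or not data:
        raise ValueError(f"blocking config {path} must map round -> list of field lists")
    rules = []
    for rnd, keys in data.items():
        for fields in keys:
            rules.append(BlockingRule(round=int(rnd), required_fields=frozenset(fields)))
    return rules


def blocked_index(
    citations: Sequence[NormalizedCitation], rule: BlockingRule
) -> dict[tuple[str, ...], list[str]]:
    """Group record ids by their (fully non-missing) key tuple under one rule."""
    index: dict[tuple[str, ...], list[str]] = defaultdict(list)
    for c in citations:
        key = rule.key(c)
        if key is not None:
            index[key].append(c.record_id)
    return {k: v for k, v in index.items()}


def candidate_pairs(
    citations: Sequence[NormalizedCitation],
    rules: Iterable[BlockingRule] | None = None,
) -> list[CandidatePair]:
    """Enumerate all pairs surfaced by any rule, with round provenance.

    Output is sorted canonically and independent of input order; duplicate
    record ids in the input are a validation failure.
    """
    ids = [c.record_id for c in citations]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate record_ids in candidate_pairs input")
    if rules is None:
        rules = default_rules()
    found: dict[tuple[str, str], set[int]] = defaultdict(set)
    for rule in rules:
        for _, members in blocked_index(citations, rule).items():
            if len(members) < 2:
                continue
            for a, b in combinations(sorted(members), 2):
                found[(a, b)].add(rule.round)
    return [
        CandidatePair(id_a=a, id_b=b, rounds=frozenset(rounds))
        for (a, b), rounds in sorted(found.items())
    ]
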