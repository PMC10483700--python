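"""Duplicate-group resolution and the end-to-end deduplication pipeline.

Automatic duplicate pairs are merged into groups by connected components
(transitive closure), so a chain A=B, B=C, C=D forms one group of four even
when A and D never surfaced as a pair. Within each group exactly one record
is kept, chosen by an ordered preference cascade:

0. user label preference, when configured (keep- or drop-side);
1. records with an abstract outrank records without one;
2. the most recent year outranks older versions (e-pub vs print drift);
3. the earliest-listed record wins — i.e. the second listed is removed.

Pairs classified for manual review never join groups; they ride along in the
result so a human can adjudicate them afterwards via :func:`apply_manual`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .blocking import BlockingRule, CandidatePair, candidate_pairs, default_rules
from .classify import MatchRule, PairDecision, Verdict, classify_all, default_ruleset
from .io_formats import Citation, CitationSet, EmptyInputError
from .normalize import normalize_set
from .similarity import PairScore, score_pair


class RemovalReason(str, Enum):
    NO_ABSTRACT = "NO_ABSTRACT"
    OLDER_VERSION = "OLDER_VERSION"
    SECOND_LISTED = "SECOND_LISTED"
    LABEL_PREFERENCE = "LABEL_PREFERENCE"


class LabelMode(str, Enum):
    NONE = "none"
    KEEP = "keep"   # labelled members outrank others
    DROP = "drop"   # labelled members are preferentially removed


@dataclass
class DuplicateGroup:
    """A resolved set of mutually-duplicate records with one keeper."""

    member_ids: frozenset[str]
    keep_id: str | None = None
    removal_reason: dict[str, RemovalReason] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a duplicate group needs at least 2 members")
        if self.keep_id is not None and self.keep_id not in self.member_ids:
            raise ValueError("keep_id must be a group member")


@dataclass
class DedupConfig:
    blocking_rules: Sequence[BlockingRule] | None = None
    match_rules: Sequence[MatchRule] | None = None
    label_mode: LabelMode = LabelMode.NONE
    label: str = ""


@dataclass
class DedupResult:
    kept: CitationSet
    removed: CitationSet
    groups: list[DuplicateGroup]
    manual_pairs: list[PairScore]

    def __post_init__(self) -> None:
        removed_ids = {c.record_id for c in self.removed}
        expected = set()
        for g in self.groups:
            expected |= g.member_ids - {g.keep_id}
        if removed_ids != expected:
            raise ValueError("removed set does not equal union of non-keep group members")


def build_groups(decisions: Iterable[PairDecision]) -> list[DuplicateGroup]:
    """Connected components over AUTO_DUPLICATE pairs (keeps unassigned)."""
    g = nx.Graph()
    for d in decisions:
        if d.verdict is Verdict.AUTO_DUPLICATE:
            g.add_edge(d.pair.id_a, d.pair.id_b)
    return [
        DuplicateGroup(member_ids=frozenset(comp))
        for comp in sorted(nx.connected_components(g), key=min)
    ]


def _keep_sort_key(
    c: Citation,
    position: int,
    label_mode: LabelMode,
    label: str,
):
    """Smaller sorts first = preferred keep. Cascade: label, abstract,
    newest year, input position."""
    if label_mode is LabelMode.KEEP:
        label_rank = 0 if c.label == label else 1
    elif label_mode is LabelMode.DROP:
        label_rank = 1 if c.label == label else 0
    else:
        label_rank = 0
    has_abstract = 0 if c.abstract.strip() else 1
    try:
        year = int(c.year)
    except ValueError:
        year = -1  # missing/corrupt year loses the recency comparison
    return (label_rank, has_abstract, -year, position)


def select_keeps(
    groups: Iterable[DuplicateGroup],
    cs: CitationSet,
    label_mode: LabelMode = LabelMode.NONE,
    label: str = "",
) -> list[DuplicateGroup]:
    """Assign one keeper per group by the preference cascade and record, for
    every removed member, the first cascade criterion on which it lost."""
    position = {rid: i for i, rid in enumerate(cs.ids)}
    out: list[DuplicateGroup] = []
    for g in groups:
        unknown = sorted(g.member_ids - position.keys())
        if unknown:
            raise ValueError(f"group members not in citation set: {unknown}")
        members = sorted(g.member_ids, key=lambda r: position[r])
        keyed = {
            rid: _keep_sort_key(cs[rid], position[rid], label_mode, label)
            for rid in members
        }
        keep = min(members, key=keyed.__getitem__)
        reasons: dict[str, RemovalReason] = {}
        kk = keyed[keep]
        for rid in members:
            if rid == keep:
                continue
            rk = keyed[rid]
            if rk[0] != kk[0]:
                reasons[rid] = RemovalReason.LABEL_PREFERENCE
            elif rk[1] != kk[1]:
                reasons[rid] = RemovalReason.NO_ABSTRACT
            elif rk[2] != kk[2]:
                reasons[rid] = RemovalReason.OLDER_VERSION
            else:
                reasons[rid] = RemovalReason.SECOND_LISTED
        out.append(DuplicateGroup(member_ids=g.member_ids, keep_id=keep,
                                  removal_reason=reasons))
    return out


def _split(cs: CitationSet, groups: Sequence[DuplicateGroup]) -> tuple[CitationSet, CitationSet]:
    drop: set[str] = set()
    for g in groups:
        drop |= g.member_ids - {g.keep_id}
    kept = [c for c in cs if c.record_id not in drop]
    removed = [c for c in cs if c.record_id in drop]
    return (CitationSet(kept, cs.provenance), CitationSet(removed, cs.provenance))


def dedupe(cs: CitationSet, config: DedupConfig | None = None) -> DedupResult:
    """Run the full pipeline: normalize, block, score, classify, resolve.

    Deterministic given the config and input order. Raises EmptyInputError
    on an empty citation set.
    """
    if config is None:
        config = DedupConfig()
    if len(cs) == 0:
        raise EmptyInputError("cannot deduplicate an empty citation set")
    normalized = normalize_set(cs)
    by_id = {n.record_id: n for n in normalized}
    pairs = candidate_pairs(
        normalized, config.blocking_rules if config.blocking_rules is not None else default_rules()
    )
    scores = [score_pair(by_id[p.id_a], by_id[p.id_b], p) for p in pairs]
    rules = config.match_rules if config.match_rules is not None else default_ruleset()
    decisions = classify_all(scores, rules)
    groups = build_groups(decisions)
    groups = select_keeps(groups, cs, config.label_mode, config.label)
    kept, removed = _split(cs, groups)
    manual = {
        (d.pair.id_a, d.pair.id_b)
        for d in decisions
        if d.verdict is Verdict.MANUAL_REVIEW
    }
    manual_scores = [s for s in scores if (s.pair.id_a, s.pair.id_b) in manual]
    return DedupResult(kept=kept, removed=removed, groups=groups,
                       manual_pairs=manual_scores)


def apply_manual(
    result: DedupResult,
    choices: Mapping[tuple[str, str], str],
    original: CitationSet | None = None,
) -> DedupResult:
    """Fold human review decisions into a result.

    ``choices`` maps a manual pair ``(id_a, id_b)`` to the record_id to keep,
    or to the string ``"not duplicate"`` to leave both. Choices referencing a
    pair that was not flagged for manual review are a validation failure.
    """
    manual_keys = {(s.pair.id_a, s.pair.id_b): s for s in result.manual_pairs}
    to_remove: set[str] = set()
    extra_groups: list[DuplicateGroup] = []
    for key, choice in choices.items():
        key = tuple(sorted(key))  # type: ignore[assignment]
        if key not in manual_keys:
            raise ValueError(f"choice references a non-manual pair: {key}")
        if choice == "not duplicate":
            continue
        if choice not in key:
            raise ValueError(f"keep id {choice!r} is not a member of pair {key}")
        loser = key[0] if choice == key[1] else key[1]
        to_remove.add(loser)
        extra_groups.append(
            DuplicateGroup(
                member_ids=frozenset(key),
                keep_id=choice,
                removal_reason={loser: RemovalReason.SECOND_LISTED},
            )
        )
    kept = [c for c in result.kept if c.record_id not in to_remove]
    moved = [c for c in result.kept if c.record_id in to_remove]
    remaining_manual = [
        s for s in result.manual_pairs
        if tuple(sorted((s.pair.id_a, s.pair.id_b))) not in
        {tuple(sorted(k)) for k in choices}
    ]
    return DedupResult(
        kept=CitationSet(kept, result.kept.provenance),
        removed=CitationSet(result.removed.citations + moved, result.removed.provenance),
        groups=result.groups + extra_groups,
        manual_pairs=remaining_manual,
    )
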