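"""Jaro and Jaro-Winkler string similarity, and per-field pair scoring.

The Jaro similarity of two strings counts characters that match within a
sliding window of half the longer string's length (minus one), penalised by
transpositions among the matched characters:

    jaro = (m/|s1| + m/|s2| + (m - t)/m) / 3

with ``m`` matches and ``t`` transpositions (half the number of matched
positions whose characters disagree); 0 when nothing matches. The Winkler
variant boosts pairs sharing a prefix:

    jw = jaro + ell * p * (1 - jaro)

where ``ell`` is the common-prefix length capped at ``max_prefix`` (default
4) and ``p`` the prefix scale (default 0.1, the record-linkage literature's
standard choice; no long-string boost variant is applied).

Scoring a candidate pair applies Jaro-Winkler field-wise over the ten
compared fields on the normalized view. A field empty in either record is
reported as *missing*, not scored 0: a missing abstract is no evidence of
difference, and the match filters decide explicitly how to treat absence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .blocking import CandidatePair
from .normalize import MATCH_FIELDS, NormalizedCitation

DEFAULT_PREFIX_SCALE = 0.1
DEFAULT_MAX_PREFIX = 4


def jaro(s1: str, s2: str) -> float:
    """Jaro similarity in [0, 1]; symmetric; 1.0 iff equal and non-empty.

    Raises ValueError when both strings are empty — that case must be routed
    through missing-field handling by the caller.
    """
    if not s1 and not s2:
        raise ValueError("jaro undefined for two empty strings")
    if not s1 or not s2:
        return 0.0
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    window = max(len1, len2) // 2 - 1
    if window < 0:
        window = 0
    matched2 = [False] * len2
    m1: list[str] = []
    m2_idx: list[int] = []
    for i, ch in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not matched2[j] and s2[j] == ch:
                matched2[j] = True
                m1.append(ch)
                m2_idx.append(j)
                break
    m = len(m1)
    if m == 0:
        return 0.0
    m2 = [s2[j] for j in sorted(m2_idx)]
    half_transposed = sum(a != b for a, b in zip(m1, m2))
    t = half_transposed / 2.0
    return (m / len1 + m / len2 + (m - t) / m) / 3.0


def jaro_winkler(
    s1: str,
    s2: str,
    prefix_scale: float = DEFAULT_PREFIX_SCALE,
    max_prefix: int = DEFAULT_MAX_PREFIX,
) -> float:
    """Jaro-Winkler similarity; reduces to :func:`jaro` when prefix_scale=0."""
    if not 0.0 <= prefix_scale <= 0.25:
        raise ValueError("prefix_scale must lie in [0, 0.25]")
    j = jaro(s1, s2)
    ell = 0
    for a, b in zip(s1, s2):
        if a != b or ell >= max_prefix:
            break
        ell += 1
    return j + ell * prefix_scale * (1.0 - j)


@dataclass(frozen=True)
class PairScore:
    """Per-field similarities for one candidate pair.

    ``sim`` maps each compared field to a value in [0, 1]; fields empty in
    either record appear in ``missing`` instead. ``year_a``/``year_b`` carry
    the numeric years (when valid) for the classifier's ±k-year predicate.
    """

    pair: CandidatePair
    sim: Mapping[str, float]
    missing: frozenset[str]
    year_a: int | None = None
    year_b: int | None = None

    def __post_init__(self) -> None:
        bad = {f: v for f, v in self.sim.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"similarities outside [0,1]: {bad}")
        overlap = set(self.sim) & self.missing
        if overlap:
            raise ValueError(f"fields both scored and missing: {sorted(overlap)}")


def score_pair(
    a: NormalizedCitation,
    b: NormalizedCitation,
    pair: CandidatePair | None = None,
    prefix_scale: float = DEFAULT_PREFIX_SCALE,
    max_prefix: int = DEFAULT_MAX_PREFIX,
) -> PairScore:
    """Score one candidate pair field-wise with Jaro-Winkler."""
    if pair is None:
        lo, hi = sorted((a.record_id, b.record_id))
        pair = CandidatePair(id_a=lo, id_b=hi, rounds=frozenset())
    sim: dict[str, float] = {}
    missing: set[str] = set()
    for f in MATCH_FIELDS:
        va, vb = a.get(f), b.get(f)
        if a.is_missing(f) or b.is_missing(f) or not va or not vb:
            missing.add(f)
        else:
            sim[f] = jaro_winkler(va, vb, prefix_scale, max_prefix)
    return PairScore(
        pair=pair,
        sim=sim,
        missing=frozenset(missing),
        year_a=int(a.year) if a.year else None,
        year_b=int(b.year) if b.year else None,
    )
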