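"""Independent reference implementations used only as test oracles.

These deliberately re-derive results from first principles (direct formula
transcription, brute-force enumeration) and share no code with the package.
"""

from __future__ import annotations

from itertools import combinations


def ref_jaro(s1: str, s2: str) -> float:
    """Direct transcription of the Jaro formula.

    Matches are characters equal within a window of floor(max(|s1|,|s2|)/2)-1,
    each character usable once; t is half the count of matched positions whose
    characters disagree; sim = (m/|s1| + m/|s2| + (m-t)/m) / 3, 0 if m = 0.
    """
    if not s1 or not s2:
        return 0.0
    w = max(len(s1), len(s2)) // 2 - 1
    used = set()
    pairs = []  # (index in s1, index in s2)
    for i in range(len(s1)):
        for j in range(len(s2)):
            if j in used:
                continue
            if s2[j] == s1[i] and abs(i - j) <= max(w, 0):
                used.add(j)
                pairs.append((i, j))
                break
    m = len(pairs)
    if m == 0:
        return 0.0
    seq1 = [s1[i] for i, _ in pairs]                      # s1 order
    seq2 = [s2[j] for _, j in sorted(pairs, key=lambda p: p[1])]  # s2 order
    t = sum(1 for a, b in zip(seq1, seq2) if a != b) / 2
    return (m / len(s1) + m / len(s2) + (m - t) / m) / 3


def ref_jaro_winkler(s1: str, s2: str, p: float = 0.1, max_l: int = 4) -> float:
    j = ref_jaro(s1, s2)
    ell = 0
    while ell < min(len(s1), len(s2), max_l) and s1[ell] == s2[ell]:
        ell += 1
    return j + ell * p * (1 - j)


def brute_force_pairs(normalized, rules):
    """All-pairs evaluation of the blocking rules: the O(n^2) definition."""
    found = {}
    for a, b in combinations(normalized, 2):
        rounds = set()
        for rule in rules:
            ok = True
            for f in rule.required_fields:
                if a.is_missing(f) or b.is_missing(f) or a.get(f) != b.get(f):
                    ok = False
                    break
            if ok:
                rounds.add(rule.round)
        if rounds:
            key = tuple(sorted((a.record_id, b.record_id)))
            found[key] = frozenset(rounds)
    return found
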