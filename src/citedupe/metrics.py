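"""Confusion-matrix evaluation of a deduplication run against gold labels.

Gold labels assign each record either to a gold duplicate group or mark it
unique. Per-record adjudication credits any single kept member of a gold
group as its legitimate keep (the gold standard defines groups, not which
member must survive):

* removed & gold-removable           -> TP
* kept & (gold-unique or the group's credited keep) -> TN
* kept but gold-removable            -> FN
* removed but gold-unique, or a group whose every member was removed
  (one member should have survived)  -> FP

From the counts: precision TP/(TP+FP), sensitivity TP/(TP+FN), specificity
TN/(TN+FP), F1 the harmonic mean of precision and sensitivity. Standard
errors use the binomial form sqrt(p(1-p)/n) by default, with n = TP+FN for
sensitivity and FP+TN for specificity; ``se_mode="literal"`` gives the plain
p(1-p)/n variant for comparison. Undefined metrics (zero denominator) are
reported as None, never 0.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .resolve import DedupResult

#: Gold label value marking a record with no duplicates.
UNIQUE = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp, tn=self.tn + other.tn,
            fn=self.fn + other.fn, fp=self.fp + other.fp,
        )


@dataclass(frozen=True)
class MetricSet:
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    se_sensitivity: float | None
    se_specificity: float | None


def read_gold(path: str | Path) -> dict[str, str | None]:
    """Read gold labels from CSV {record_id, gold_duplicate_id}; an empty
    gold_duplicate_id marks a unique record."""
    gold: dict[str, str | None] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            gid = (row.get("gold_duplicate_id") or "").strip()
            gold[row["record_id"].strip()] = gid or UNIQUE
    return gold


def confusion(result: DedupResult, gold: Mapping[str, str | None]) -> ConfusionCounts:
    """Adjudicate every record in the result against the gold labels."""
    kept_ids = [c.record_id for c in result.kept]
    removed_ids = [c.record_id for c in result.removed]
    all_ids = kept_ids + removed_ids
    missing = sorted(set(all_ids) - set(gold))
    if missing:
        raise ValueError(f"records absent from gold labels: {missing}")

    # per gold group: which members survived?
    kept_by_group: dict[str, list[str]] = {}
    for rid in kept_ids:
        gid = gold[rid]
        if gid is not UNIQUE:
            kept_by_group.setdefault(gid, []).append(rid)

    tp = tn = fn = fp = 0
    credited: dict[str, str] = {}  # gold group -> the one kept member credited as keep
    for gid, members in kept_by_group.items():
        credited[gid] = members[0]
    for rid in kept_ids:
        gid = gold[rid]
        if gid is UNIQUE or credited.get(gid) == rid:
            tn += 1
        else:
            fn += 1  # extra survivor of a gold group: a missed duplicate
    seen_groups_removed: set[str] = set()
    for rid in removed_ids:
        gid = gold[rid]
        if gid is UNIQUE:
            fp += 1
        elif gid in credited or gid in seen_groups_removed:
            tp += 1
        else:
            # whole gold group removed: the first removal wrongly took the
            # record that should have survived
            seen_groups_removed.add(gid)
            fp += 1
    counts = ConfusionCounts(tp=tp, tn=tn, fn=fn, fp=fp)
    assert counts.total == len(all_ids)
    return counts


def compute_metrics(c: ConfusionCounts, se_mode: str = "sqrt") -> MetricSet:
    """Precision, sensitivity, specificity, F1 and SEs from raw counts."""
    if se_mode not in ("sqrt", "literal"):
        raise ValueError("se_mode must be 'sqrt' or 'literal'")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    precision = ratio(c.tp, c.tp + c.fp)
    sensitivity = ratio(c.tp, c.tp + c.fn)
    specificity = ratio(c.tn, c.tn + c.fp)
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)

    def se(p: float | None, n: int) -> float | None:
        if p is None or n == 0:
            return None
        v = p * (1 - p) / n
        return math.sqrt(v) if se_mode == "sqrt" else v

    return MetricSet(
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        se_sensitivity=se(sensitivity, c.tp + c.fn),
        se_specificity=se(specificity, c.fp + c.tn),
    )


def pool_counts(tables: Iterable[ConfusionCounts]) -> ConfusionCounts:
    """Element-wise sum of confusion tables (for pooled overall metrics)."""
    tables = list(tables)
    if not tables:
        raise ValueError("pool_counts requires at least one table")
    out = tables[0]
    for t in tables[1:]:
        out = out + t
    return out


def write_report(
    rows: Mapping[str, tuple[ConfusionCounts, MetricSet]], path: str | Path
) -> Path:
    """Emit an evaluation report CSV with one row per labelled run."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "tp", "tn", "fn", "fp",
                    "sensitivity", "se_sensitivity",
                    "specificity", "se_specificity", "precision", "f1"])
        for name, (c, m) in rows.items():
            fmt = lambda v: "" if v is None else f"{v:.3f}"
            w.writerow([name, c.tp, c.tn, c.fn, c.fp,
                        fmt(m.sensitivity), fmt(m.se_sensitivity),
                        fmt(m.specificity), fmt(m.se_specificity),
                        fmt(m.precision), fmt(m.f1)])
    return path
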