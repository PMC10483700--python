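# citedupe

Automated deduplication of aggregated systematic-search citation sets.

Systematic reviewers search several bibliographic databases and merge the
exports; the same publication then appears repeatedly, re-indexed with each
database's formatting quirks. Screening duplicates wastes reviewer time and
risks double-counting studies in meta-analysis — while *over*-eager
deduplication silently discards evidence. `citedupe` removes duplicate
citations automatically, with a bias toward never removing a record it is
not sure about: borderline pairs are set aside for human review instead of
being deleted.

## Method

The pipeline is deterministic record linkage:

1. **normalize** — upper-case, strip punctuation, canonicalise DOI prefixes,
   mark missing fields, rename anonymous authors `UNKNOWN`;
2. **block** — candidate pairs must agree 100% on at least one of 15 key
   combinations in 4 rounds (e.g. title+author, author+year, DOI alone);
   missing fields never match;
3. **score** — Jaro–Winkler similarity (prefix scale 0.1, cap 4) per field
   across title, author, year, journal, ISBN/ISSN, abstract, DOI, issue,
   pages, volume;
4. **classify** — priority-ordered match filters declare each pair
   AUTO_DUPLICATE, MANUAL_REVIEW (e.g. matching DOIs with dissimilar
   titles), or NON_DUPLICATE; every auto rule needs agreement on ≥ 2
   independent fields;
5. **resolve** — auto pairs merge into duplicate groups by connected
   components; one record per group is kept (label preference → has
   abstract → newest year → first listed);
6. **evaluate** — against gold labels: sensitivity TP/(TP+FN), specificity
   TN/(TN+FP), precision TP/(TP+FP), F1, with binomial standard errors
   `sqrt(p(1−p)/n)`.

A synthetic-corpus generator with ground-truth duplicate structure
(`citedupe.synthetic`) emulates multi-database overlap — DOI prefix
dialects, missing abstracts, page-range truncation, e-pub/print year drift,
author-format changes — so the whole pipeline is testable offline. See
`docs/methods.md` for the full model, parameter defaults and limitations.

## Worked example

Library use:

```python
import citedupe as cd

corpus = cd.default_corpus(7)            # ~1,000-record synthetic search
result = cd.dedupe(corpus.citations)
m = cd.compute_metrics(cd.confusion(result, corpus.gold))
print(f"{len(corpus.citations)} records -> kept {len(result.kept)}, "
      f"removed {len(result.removed)} in {len(result.groups)} groups")
print(f"sensitivity={m.sensitivity:.3f} specificity={m.specificity:.3f}")
```

prints

```
1026 records -> kept 660, removed 366 in 264 groups
sensitivity=1.000 specificity=1.000
```

i.e. all 366 injected duplicate copies were removed (none of the 660 unique
publications was touched), grouped into 264 duplicate sets of 2–4 records.

The same workflow from the shell:

```sh
$ citedupe simulate --n-unique 500 --dup-rate 0.4 --seed 42 --out corpus
wrote 789 records to corpus/corpus.csv (gold labels: corpus/corpus.gold.csv)

$ citedupe dedupe --input corpus/corpus.csv --out dedup
789 records in -> 500 kept, 289 removed in 200 duplicate groups; 0 pairs for manual review

$ citedupe evaluate --kept dedup/kept.csv --removed dedup/removed.csv \
      --gold corpus/corpus.gold.csv
tp=289 tn=500 fn=0 fp=0 sensitivity=1.000 specificity=1.000 precision=1.000 f1=1.000
```

`citedupe dedupe` accepts RIS, EndNote XML, BibTeX and CSV inputs
(repeatable `--input`), and writes `kept.ris`/`kept.csv`, `removed.csv`
(with duplicate ids and removal reasons), `manual.csv` (side-by-side review
sheet with all similarities), `flagged.csv` (every record with a shared
duplicate id per group) and an auditable `summary.json` with the effective
rules. Manual decisions are applied with
`citedupe review --result-dir dedup --choices choices.csv`. Match filters
and blocking keys can be replaced with `--ruleset`/`--blocking` YAML files.

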