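# Methods

## The problem

A systematic review's search is run against several bibliographic databases
(PubMed, EMBASE, Web of Science, Scopus, ...), and the same publication is
typically retrieved by more than one of them — overlap between major
biomedical databases can reach three quarters of a search result. The
aggregated export therefore contains *duplicate citations*: distinct records
describing one publication, differing only in formatting quirks of each
database (case and punctuation, DOI prefix style, missing abstracts,
truncated page ranges, e-publication vs print year, author-name formatting).
Removing them by hand is slow at the 10,000–80,000-record scale of
preclinical reviews; failing to remove them biases screening and
meta-analysis, while removing a *non*-duplicate (a false positive) silently
discards evidence. `citedupe` automates this with a deterministic
record-linkage pipeline tuned for very high specificity.

Two records of the *same* publication are duplicates; the same study
published in two journals, or a conference abstract / preprint / article
trio, are not, and the pipeline does not attempt to merge those.

## Pipeline

1. **Normalization** (`citedupe.normalize`). All comparisons run on a
   cleaned view of the 11 text fields: upper-cased, punctuation removed,
   whitespace collapsed. Hyphens and apostrophes are deleted outright
   (merging `re-view`/`review` and `cat's`/`cats`) while every other
   punctuation character becomes a space (preserving token boundaries in
   titles). Missing or anonymous authors (`Anonymous`, `Anon`, `et al`,
   `No author`, empty) become `UNKNOWN`. DOIs are canonicalised by stripping
   resolver prefixes (`https://doi.org/`, `dx.doi.org`, `doi:`); the dots
   and slashes inside a DOI are structural and kept, its hyphens are not.
   Years must be 4 digits or they count as missing. Normalization is total,
   deterministic and idempotent; raw records are never mutated.

2. **Blocking** (`citedupe.blocking`). All-pairs comparison is quadratic, so
   candidate pairs are generated by 15 exact-match keys in 4 rounds:

   | Round | Keys (all fields must match 100%, none missing) |
   |---|---|
   | 1 | title+pages, title+author, title+abstract, doi |
   | 2 | author+year+pages, journal+volume+pages, isbn+volume+pages, title+isbn |
   | 3 | year+pages+volume, year+issue+volume, year+pages+issue |
   | 4 | author+year, title+year, title+volume, title+journal |

   A pair surfaced by any round is a candidate; the union is independent of
   round order (rounds are retained as provenance — historically they
   bounded peak memory on large datasets). A key touching a missing field
   never matches: agreement on absent data is vacuous, and letting all
   no-DOI records pair with each other would destroy specificity. The
   indexed implementation is property-tested equal to the brute-force
   all-pairs definition.

3. **Similarity** (`citedupe.similarity`). Each candidate pair is scored
   field-wise with Jaro-Winkler similarity over the ten compared fields
   (title, author, year, journal, isbn/issn, abstract, doi, issue, pages,
   volume). Jaro: `(m/|s1| + m/|s2| + (m−t)/m)/3` with matches `m` counted
   within a window of `⌊max(|s1|,|s2|)/2⌋−1` and transpositions `t`;
   Winkler boost `j + ℓ·p·(1−j)` with prefix length `ℓ ≤ 4` and scale
   `p = 0.1` — the record-linkage literature's standard parameters; no
   long-string boost variant. A field empty in either record is reported
   *missing*, never scored 0: a missing abstract is not evidence of
   difference.

4. **Classification** (`citedupe.classify`). Deterministic match filters
   over the similarity vector assign each pair one of three verdicts. The
   shipped defaults (fully replaceable from YAML) are, in priority order:

   * AUTO_DUPLICATE: title ≥ 0.95 ∧ author ≥ 0.80 ∧ year within ±1;
     title ≥ 0.90 ∧ abstract ≥ 0.90 ∧ year within ±1;
     doi = 1.0 ∧ title ≥ 0.90; title ≥ 0.98 ∧ pages = 1.0;
     title ≥ 0.98 ∧ volume = 1.0.
   * MANUAL_REVIEW: doi = 1.0 alone (publishers reuse one DOI across
     conference-abstract collections, the classic false-positive trap);
     title ≥ 0.90 ∧ author < 0.80; title ≥ 0.85 ∧ journal < 0.60.
   * Otherwise NON_DUPLICATE.

   Every automatic rule demands agreement on at least two independent
   fields; the ±1-year window absorbs e-publication vs print-year drift.
   A threshold predicate on a missing field is false — rules meant to
   tolerate missing abstracts must simply not reference the abstract.
   The numeric thresholds are this package's own calibration, validated
   against the synthetic corpora below; they are the tunables a user should
   reach for first, which is why the whole ruleset is external data rather
   than code.

5. **Resolution** (`citedupe.resolve`). Automatic pairs are merged into
   duplicate groups by connected components, so a chain A=B, B=C, C=D forms
   one group of four even though A and D never co-occurred in a pair (the
   pairwise alternative can strand extra records on non-transitive chains;
   the transitive semantics is adopted here deliberately). One record per
   group is kept, by an ordered cascade: user label preference when
   configured (keep-side or drop-side); then records with abstracts; then
   the most recent year ("most up-to-date version", with year the only date
   the data model carries); finally the earliest-listed record — i.e. the
   second listed is removed. The label option changes only *which* record
   survives, never how many. Manual-review pairs ride along unresolved
   until a human decides (`apply_manual`, or `citedupe review`).

6. **Evaluation** (`citedupe.metrics`). Against gold labels
   (record → gold group or unique), records are adjudicated per-record:
   removed duplicates are TP, surviving uniques TN, missed duplicates FN,
   removed uniques FP; any single kept member of a gold group is credited
   as its legitimate keep, and if a whole gold group is removed, exactly
   one of those removals is an FP. Metrics: precision TP/(TP+FP),
   sensitivity TP/(TP+FN), specificity TN/(TN+FP), F1 the harmonic mean of
   precision and sensitivity. Standard errors default to the binomial
   `sqrt(p(1−p)/n)` with `n = TP+FN` (sensitivity) or `FP+TN`
   (specificity); a `literal` mode computing `p(1−p)/n` without the square
   root exists because that variant also circulates in print, but only the
   sqrt form is consistent with published benchmark tables. Undefined
   metrics (zero denominators) are reported as `None`, never 0.

## Synthetic corpora

The generator (`citedupe.synthetic`) emulates multi-database overlap with
known ground truth, so every stage is testable without external data. Base
records get plausible random fields (titles of 6–14 words over a fixed
vocabulary, 1–8 surname-initial authors, journals from a fixed list with
stable ISSNs, years 1990–2024, DOIs `10.<4 digits>/<8 alnum>`) — enough
entropy that unrelated records essentially never collide on a blocking key,
which the oracle-equivalence tests exercise. A configured fraction of
publications receives 2–4 record instances; each extra copy is
independently perturbed:

| knob | default | emulates |
|---|---|---|
| p_missing_abstract | 0.3 | databases that index no abstract |
| p_missing_doi | 0.2 | sparse DOI coverage |
| p_missing_pages | 0.1 | missing pagination |
| p_year_drift | 0.1 | e-pub vs print year, ±1 |
| p_page_truncate | 0.2 | `1234-1239` → `1234-9` |
| p_case_punct | 0.3 | case/punctuation dialects |
| p_author_format | 0.3 | `Smith, J. M.` vs `Smith JM` |
| doi_dialects | 4 prefixes | resolver-prefix styles |

The stock study corpus (`default_corpus(seed)`) is 660 unique publications
at duplication rate 0.4 with copy counts ~ {2: 0.7, 3: 0.2, 4: 0.1} —
about 1,030 records, a desk-scale stand-in for real search exports chosen
to keep the full test suite fast. Copies carry a different database label
than their original (label models provenance and is not a compared field).

**What the generator does not model** — and hence what passing tests do not
establish about real data: title typos and re-translations, conference
abstract/preprint near-duplicates, shared DOIs across distinct works,
records corrupted beyond field-level noise, and real-world field
distributions. On the synthetic conditions the default filters sit well
inside the ≥ 0.95 sensitivity / ≥ 0.99 specificity envelope asserted by the
acceptance tests; real exports are harder, and the envelope should be read
as a regression property of the pipeline, not a performance claim about any
particular dataset.

## Numerical and design notes

* Jaro-Winkler is implemented here (with the standard greedy left-to-right
  match assignment) and verified to 1e-12 against an independent direct
  transcription of the formulas on random pairs, plus hand-computed values.
* Ties everywhere are broken deterministically: rules by priority (list
  order, first match wins), keeps by input position, groups sorted by their
  smallest member id. Identical input + config ⇒ byte-identical outputs.
* `jaro("", "")` is undefined by construction and raises; field scoring
  routes empty values through missing-field handling instead.
* Blocking on `author` treats the `UNKNOWN` placeholder as a value, so two
  anonymous-author records *can* block on author+year; the match filters
  still require title or abstract corroboration before auto-removal.
* Encoding: UTF-8 (BOM tolerated) with a logged Latin-1 fallback. Multiple
  authors are joined into one `"; "`-separated string — the method compares
  author strings, not author lists.
* Degenerate inputs: empty citation sets are an explicit error (never a
  silent empty result); records with no recognised fields are retained with
  empty fields; groups of fewer than two members are rejected.

## Known limitations

* No Unicode case-folding beyond upper-casing (diacritics are preserved;
  `Müller` ≠ `Mueller`).
* "Most up-to-date version" is operationalised as the larger numeric year;
  exports rarely carry reliable separate e-pub dates.
* The manual-review workflow is CSV-based; there is no interactive UI.
* Thresholds were chosen for high specificity on biomedical exports;
  corpora with systematically sparse metadata (no DOIs, no pages) will
  lean on the title+author and title+year keys and may need a custom
  ruleset.
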