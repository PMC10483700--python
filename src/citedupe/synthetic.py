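"""Synthetic multi-database search corpora with ground-truth duplicates.

Aggregated systematic searches contain the same publication indexed by
several databases, each with its own formatting quirks. The generator
emulates exactly that: it creates unique base records with plausible random
bibliographic fields, then gives a configurable fraction of them duplicate
copies, each copy independently perturbed with the field-level variants seen
across real exports — case/punctuation noise, DOI prefix dialects, missing
abstracts/DOIs/pages, page-range truncation ("1234-1239" -> "1234-9"),
e-pub-vs-print year drift of one year, and author formatting differences
("Smith, J. M." vs "Smith JM").

Every record carries a gold label (its duplicate group, or unique), so each
pipeline stage can be evaluated without any external data. Generation is
fully deterministic under a seed. What the generator does *not* model:
conference abstracts/preprints as near-duplicates of journal articles,
title typos, or translated titles — see the package docs for what that
implies about test coverage.
"""

from __future__ import annotations

import csv
import random
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

from .io_formats import CITATION_FIELDS, Citation, CitationSet, write_citations

_WORDS = (
    "effects treatment model rats mice outcomes chronic acute neural cardiac "
    "hepatic renal cortical spinal evaluation randomised controlled analysis "
    "systematic disease injury ischemia stroke diabetes depression memory "
    "inflammation oxidative stress receptor inhibition expression protein "
    "gene pathway signalling dose response behaviour cognitive motor deficit "
    "recovery function plasticity lesion infarct volume apoptosis microglia "
    "astrocyte neuron synaptic hippocampal prefrontal therapy drug novel "
    "candidate agonist antagonist blockade administration intervention sham "
    "placebo longitudinal cohort assessment imaging biomarker serum plasma "
    "tissue vascular perfusion hypoxia reperfusion preconditioning remote "
    "mitochondrial metabolic glucose insulin lipid profile weight survival"
).split()

_SURNAMES = (
    "Smith Jones Brown Wilson Taylor Davies Evans Thomas Johnson Roberts "
    "Walker Wright Robinson Thompson White Hughes Edwards Green Hall Wood "
    "Harris Lewis Martin Jackson Clarke Patel Khan Singh Chen Wang Li Zhang "
    "Liu Yang Kim Park Sato Tanaka Suzuki Garcia Martinez Lopez Gonzalez "
    "Hernandez Muller Schmidt Fischer Weber Meyer Wagner Becker Hoffmann "
    "Rossi Ferrari Ricci Moreau Bernard Dubois Petrov Ivanov Novak Kowalski "
    "Nielsen Hansen Larsen Andersson Johansson Karlsson Virtanen Korhonen "
    "Silva Santos Oliveira Pereira Costa Almeida OBrien Murphy Kelly Ryan"
).split()

_JOURNALS = tuple(
    f"Journal of {a} {b}"
    for a, b in zip(
        "Experimental Clinical Preclinical Translational Molecular Cellular "
        "Comparative Integrative Systems Quantitative".split(),
        "Neuroscience Cardiology Pharmacology Physiology Medicine Pathology "
        "Biology Psychiatry Toxicology Endocrinology".split(),
    )
) + tuple(
    f"Annals of {x}" for x in
    "Neurology Metabolism Inflammation Oncology Hepatology".split()
) + tuple(
    f"{x} Research" for x in
    "Brain Stroke Diabetes Behavioural Cardiovascular".split()
)

_DATABASES = ("PUBMED", "EMBASE", "WOS", "SCOPUS")

DOI_DIALECTS = ("", "doi:", "https://doi.org/", "http://dx.doi.org/")


@dataclass(frozen=True)
class PerturbationConfig:
    """Per-copy perturbation probabilities mirroring real export variation."""

    p_missing_abstract: float = 0.3
    p_missing_doi: float = 0.2
    p_missing_pages: float = 0.1
    p_year_drift: float = 0.1
    p_page_truncate: float = 0.2
    p_case_punct: float = 0.3
    p_author_format: float = 0.3
    doi_dialects: tuple[str, ...] = DOI_DIALECTS
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            k: v for k, v in self.__dict__.items()
            if k.startswith("p_")
        }
        bad = {k: v for k, v in probs.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"probabilities outside [0,1]: {bad}")


NO_PERTURBATION = PerturbationConfig(
    p_missing_abstract=0.0, p_missing_doi=0.0, p_missing_pages=0.0,
    p_year_drift=0.0, p_page_truncate=0.0, p_case_punct=0.0,
    p_author_format=0.0, doi_dialects=("",),
)

#: Default copy-count distribution: most duplicated records occur twice.
DEFAULT_COPIES = {2: 0.7, 3: 0.2, 4: 0.1}


@dataclass
class SyntheticCorpus:
    citations: CitationSet
    gold: dict[str, str | None]  # record_id -> gold group id, None = unique
    n_unique: int
    config: PerturbationConfig = field(default_factory=PerturbationConfig)

    @property
    def n_removable(self) -> int:
        """Number of records a perfect deduplicator removes."""
        from collections import Counter

        sizes = Counter(g for g in self.gold.values() if g is not None)
        return sum(k - 1 for k in sizes.values())


def _issn_for(journal: str, rng_seed: int = 17) -> str:
    h = 0
    for ch in journal:
        h = (h * 31 + ord(ch)) % 10**8
    s = f"{h:08d}"
    return f"{s[:4]}-{s[4:]}"


def _make_base(rng: random.Random, index: int) -> Citation:
    n_title = rng.randint(6, 14)
    title = " ".join(rng.choice(_WORDS) for _ in range(n_title)).capitalize()
    n_auth = rng.randint(1, 8)
    authors = []
    for _ in range(n_auth):
        surname = rng.choice(_SURNAMES)
        initials = ". ".join(rng.choice(string.ascii_uppercase)
                             for _ in range(rng.randint(1, 2))) + "."
        authors.append(f"{surname}, {initials}")
    journal = rng.choice(_JOURNALS)
    year = rng.randint(1990, 2024)
    start = rng.randint(1, 2999)
    pages = f"{start}-{start + rng.randint(1, 15)}"
    abstract = " ".join(rng.choice(_WORDS) for _ in range(rng.randint(30, 60)))
    abstract = abstract.capitalize() + "."
    doi = f"10.{rng.randint(1000, 9999)}/" + "".join(
        rng.choice(string.ascii_lowercase + string.digits) for _ in range(8)
    )
    return Citation(
        record_id=f"base-{index}",
        author="; ".join(authors),
        year=str(year),
        title=title,
        journal=journal,
        abstract=abstract,
        doi=doi,
        isbn_issn=_issn_for(journal),
        pages=pages,
        volume=str(rng.randint(1, 200)),
        issue=str(rng.randint(1, 12)),
        label=rng.choice(_DATABASES),
        source_format="CSV",
    )


def _reformat_author(author: str) -> str:
    """'Smith, J. M.; Jones, A.' -> 'Smith JM; Jones A'."""
    parts = []
    for tok in author.split(";"):
        tok = tok.strip()
        if "," in tok:
            surname, _, initials = tok.partition(",")
            initials = initials.replace(".", "").replace(" ", "")
            parts.append(f"{surname.strip()} {initials}".strip())
        else:
            parts.append(tok)
    return "; ".join(parts)


def _case_punct_noise(rng: random.Random, text: str) -> str:
    mode = rng.randrange(3)
    if mode == 0:
        text = text.upper()
    elif mode == 1:
        text = text.lower()
    else:
        text = text.title()
    if rng.random() < 0.5:
        text = text.rstrip(".")
    else:
        text = text.rstrip(".") + "."
    return text


def _truncate_pages(pages: str) -> str:
    """'1234-1239' -> '1234-9' (drop the end page's shared prefix)."""
    start, sep, end = pages.partition("-")
    if not sep or len(end) != len(start):
        return pages
    i = 0
    while i < len(start) and start[i] == end[i]:
        i += 1
    return f"{start}-{end[i:]}" if i and i < len(end) else pages


def _perturb(rng: random.Random, base: Citation, copy_id: str,
             cfg: PerturbationConfig) -> Citation:
    c = replace(base, record_id=copy_id,
                label=rng.choice([d for d in _DATABASES if d != base.label]))
    if rng.random() < cfg.p_missing_abstract:
        c = replace(c, abstract="")
    if rng.random() < cfg.p_missing_doi:
        c = replace(c, doi="")
    elif cfg.doi_dialects and c.doi:
        c = replace(c, doi=rng.choice(list(cfg.doi_dialects)) + c.doi)
    if rng.random() < cfg.p_missing_pages:
        c = replace(c, pages="")
    elif rng.random() < cfg.p_page_truncate:
        c = replace(c, pages=_truncate_pages(c.pages))
    if rng.random() < cfg.p_year_drift and c.year:
        c = replace(c, year=str(int(c.year) + rng.choice((-1, 1))))
    if rng.random() < cfg.p_case_punct:
        c = replace(c, title=_case_punct_noise(rng, c.title))
        if c.abstract:
            c = replace(c, abstract=_case_punct_noise(rng, c.abstract))
    if rng.random() < cfg.p_author_format:
        c = replace(c, author=_reformat_author(c.author))
    return c


def generate(
    n_unique: int,
    duplication_rate: float,
    copies_distribution: Mapping[int, float] | None = None,
    perturb: PerturbationConfig | None = None,
) -> SyntheticCorpus:
    """Generate a corpus of ``n_unique`` publications, a ``duplication_rate``
    fraction of which are indexed more than once.

    ``copies_distribution`` gives the probability of a duplicated
    publication having 2, 3 or 4 record instances in total. Output order is
    shuffled deterministically by the perturbation seed.
    """
    if n_unique < 1:
        raise ValueError("n_unique must be >= 1")
    if not 0.0 <= duplication_rate <= 1.0:
        raise ValueError("duplication_rate must lie in [0,1]")
    if perturb is None:
        perturb = PerturbationConfig()
    dist = dict(copies_distribution or DEFAULT_COPIES)
    if abs(sum(dist.values()) - 1.0) > 1e-9 or not set(dist) <= {2, 3, 4}:
        raise ValueError("copies_distribution must be a probability map over {2,3,4}")
    rng = random.Random(perturb.seed)
    counts, weights = zip(*sorted(dist.items()))
    # exactly round(rate * n) publications are duplicated
    n_dup = round(duplication_rate * n_unique)
    dup_indices = set(rng.sample(range(1, n_unique + 1), n_dup))

    records: list[Citation] = []
    gold: dict[str, str | None] = {}
    for i in range(1, n_unique + 1):
        base = _make_base(rng, i)
        n_copies = rng.choices(counts, weights)[0] if i in dup_indices else 1
        group_id = f"G{i:05d}" if n_copies > 1 else None
        members = [replace(base, record_id=f"R{i:05d}a")]
        for k in range(2, n_copies + 1):
            suffix = string.ascii_lowercase[k - 1]
            members.append(_perturb(rng, base, f"R{i:05d}{suffix}", perturb))
        for m in members:
            gold[m.record_id] = group_id
        records.extend(members)
    rng.shuffle(records)
    return SyntheticCorpus(
        citations=CitationSet(records, provenance=["synthetic"]),
        gold=gold,
        n_unique=n_unique,
        config=perturb,
    )


def default_corpus(seed: int) -> SyntheticCorpus:
    """The stock desk-scale study corpus: 660 unique publications at a 0.4
    duplication rate (~1,030 records in total) with default perturbations."""
    return generate(
        n_unique=660,
        duplication_rate=0.4,
        copies_distribution=DEFAULT_COPIES,
        perturb=PerturbationConfig(seed=seed),
    )


def corpus_profile(corpus: SyntheticCorpus) -> dict:
    """Summarise a corpus: size, duplicate fraction, per-field missingness."""
    cs = corpus.citations
    n = len(cs)
    dup_records = sum(1 for g in corpus.gold.values() if g is not None)
    missing = {
        f: sum(1 for c in cs if not getattr(c, f).strip()) / n if n else 0.0
        for f in CITATION_FIELDS
    }
    return {
        "n_records": n,
        "n_unique_publications": corpus.n_unique,
        "n_duplicate_records": dup_records,
        "n_removable": corpus.n_removable,
        # fraction of records a perfect deduplicator removes
        "duplicate_fraction": corpus.n_removable / n if n else 0.0,
        "missingness": missing,
    }


def export_corpus(corpus: SyntheticCorpus, outdir: str | Path, stem: str = "corpus",
                  format: str = "CSV") -> tuple[Path, Path]:
    """Write the corpus (RIS or CSV) plus its gold-label CSV; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "ris" if format.upper() == "RIS" else "csv"
    data_path = write_citations(corpus.citations, outdir / f"{stem}.{ext}", format)
    gold_path = outdir / f"{stem}.gold.csv"
    with gold_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "gold_duplicate_id"])
        for c in corpus.citations:
            w.writerow([c.record_id, corpus.gold[c.record_id] or ""])
    return data_path, gold_path
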