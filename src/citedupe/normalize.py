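"""Cleaning and harmonisation of citation fields.

The matching stages never look at raw field values: they operate on a
normalized view in which case, punctuation and whitespace differences between
database exports have been erased. The steps are

* upper-case everything;
* drop hyphens and apostrophes outright (merging hyphenation variants such
  as "re-view" / "review" without splitting the token), replace every other
  punctuation character with a space, then collapse whitespace runs;
* rename missing or anonymous authors to ``UNKNOWN``;
* canonicalise DOIs by stripping resolver prefixes (``https://doi.org/``,
  ``dx.doi.org``, ``doi:``) while keeping the structural ``.`` and ``/`` of
  the DOI itself;
* treat a year as present only if it is a 4-digit number.

Normalization is total, deterministic and idempotent, and never mutates the
raw :class:`~citedupe.io_formats.Citation`.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import CITATION_FIELDS, Citation, CitationSet

#: Fields compared by the similarity stage (label is preference-only metadata).
MATCH_FIELDS = (
    "title",
    "author",
    "year",
    "journal",
    "isbn_issn",
    "abstract",
    "doi",
    "issue",
    "pages",
    "volume",
)

_ASCII_PUNCT = set("!\"#$%&'()*+,-./:;<=>?@[\\]^_`{|}~")
_JOIN_PUNCT = {"-", "'", "‐", "‑", "‒", "–", "—",
               "‘", "’"}

# "[Anonymous]" etc. reduce to these under clean_text before the check
_ANONYMOUS_AUTHORS = {"", "ANONYMOUS", "ANON", "NO AUTHOR", "ET AL"}

_DOI_PREFIX_RE = re.compile(
    r"^\s*(?:(?:https?://)?(?:dx\.)?doi\.org/|doi:\s*|doi\s+)",
    re.IGNORECASE,
)

_YEAR_RE = re.compile(r"^\d{4}$")


def _is_punct(ch: str) -> bool:
    return ch in _ASCII_PUNCT or unicodedata.category(ch).startswith("P")


def clean_text(value: str) -> str:
    """Generic text pipeline: upper-case, strip punctuation, collapse spaces."""
    out: list[str] = []
    for ch in value:
        if ch in _JOIN_PUNCT:
            continue
        if _is_punct(ch):
            out.append(" ")
        else:
            out.append(ch)
    return " ".join("".join(out).upper().split())


def clean_doi(value: str) -> str:
    """Canonical DOI: resolver prefix stripped, upper-cased, hyphens and
    apostrophes removed; '.' and '/' are structural in a DOI and kept."""
    value = _DOI_PREFIX_RE.sub("", value.strip())
    out = [ch for ch in value if ch not in _JOIN_PUNCT]
    return " ".join("".join(out).upper().split())


def clean_author(value: str) -> str:
    cleaned = clean_text(value)
    return "UNKNOWN" if cleaned in _ANONYMOUS_AUTHORS else cleaned


def clean_year(value: str) -> str:
    cleaned = clean_text(value)
    return cleaned if _YEAR_RE.match(cleaned) else ""


@dataclass(frozen=True)
class NormalizedCitation:
    """The cleaned view of a citation used by blocking and similarity."""

    record_id: str
    author: str = "UNKNOWN"
    year: str = ""
    title: str = ""
    journal: str = ""
    abstract: str = ""
    doi: str = ""
    isbn_issn: str = ""
    pages: str = ""
    volume: str = ""
    issue: str = ""
    label: str = ""
    missing_fields: frozenset[str] = field(default_factory=frozenset)

    def get(self, name: str) -> str:
        return getattr(self, name)

    def is_missing(self, name: str) -> bool:
        return name in self.missing_fields


_FIELD_CLEANERS = {
    "author": clean_author,
    "doi": clean_doi,
    "year": clean_year,
}


def normalize_citation(c: Citation) -> NormalizedCitation:
    """Produce the normalized view of one citation.

    ``missing_fields`` lists every field empty after cleaning; author is never
    listed because missing/anonymous authors become ``UNKNOWN``.
    """
    values: dict[str, str] = {}
    for name in CITATION_FIELDS:
        cleaner = _FIELD_CLEANERS.get(name, clean_text)
        values[name] = cleaner(getattr(c, name))
    missing = frozenset(n for n, v in values.items() if not v and n != "author")
    return NormalizedCitation(record_id=c.record_id, missing_fields=missing, **values)


def normalize_set(cs: CitationSet | Iterable[Citation]) -> list[NormalizedCitation]:
    """Element-wise :func:`normalize_citation`, order preserved."""
    return [normalize_citation(c) for c in cs]
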