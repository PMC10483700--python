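"""Reading and writing citation sets in bibliographic interchange formats.

Supported formats: RIS (tag-based), EndNote XML, BibTeX, and a fixed-header
CSV. Records are parsed into :class:`Citation` objects whose raw field values
are preserved verbatim; cleaning happens later in :mod:`citedupe.normalize`
as a non-destructive view.

Every record receives a stable ``record_id``. When the file itself carries an
identifier (RIS ``ID``, EndNote ``rec-number``, BibTeX citation key, CSV
``record_id`` column) that value is used; otherwise ids are assigned as
``<source-stem>-<ordinal>`` so that multi-file aggregations stay unique.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

#: Field names carried by every Citation besides record_id / source_format.
CITATION_FIELDS = (
    "author",
    "year",
    "title",
    "journal",
    "abstract",
    "doi",
    "isbn_issn",
    "pages",
    "volume",
    "issue",
    "label",
)

CSV_HEADER = ("record_id",) + CITATION_FIELDS

FORMATS = ("RIS", "ENDNOTE_XML", "BIBTEX", "CSV")

_EXTENSION_FORMATS = {
    ".ris": "RIS",
    ".txt": "RIS",
    ".xml": "ENDNOTE_XML",
    ".bib": "BIBTEX",
    ".bibtex": "BIBTEX",
    ".csv": "CSV",
}


class CitationError(Exception):
    """Base class for citation I/O failures."""


class EmptyInputError(CitationError):
    """A file parsed successfully but yielded zero records."""


class FormatDetectionError(CitationError):
    """AUTO format detection could not settle on a single candidate."""


@dataclass(frozen=True)
class Citation:
    """One bibliographic record as read from an export file.

    All text fields are free text and may be empty; they are never cleaned
    here. ``isbn_issn`` carries either an ISBN or an ISSN — exports mix the
    two in one slot. ``label`` is a user tag such as a search-batch name.
    """

    record_id: str
    author: str = ""
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
    source_format: str = "CSV"

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")


@dataclass
class CitationSet:
    """An ordered collection of citations with source provenance.

    Input order is significant downstream: the keep-record cascade breaks
    ties by position ("the second listed citation is removed").
    """

    citations: list[Citation] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.record_id for c in self.citations]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValueError(f"duplicate record_ids in CitationSet: {dupes}")

    def __len__(self) -> int:
        return len(self.citations)

    def __iter__(self) -> Iterator[Citation]:
        return iter(self.citations)

    def __getitem__(self, record_id: str) -> Citation:
        for c in self.citations:
            if c.record_id == record_id:
                return c
        raise KeyError(record_id)

    @property
    def ids(self) -> list[str]:
        return [c.record_id for c in self.citations]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_text(path: Path) -> str:
    raw = path.read_bytes()
    try:
        return raw.decode("utf-8-sig")
    except UnicodeDecodeError:
        logger.warning("%s is not UTF-8; falling back to Latin-1", path)
        return raw.decode("latin-1")


def detect_format(path: Path, text: str | None = None) -> str:
    """Detect a file's format from its extension, then a first-bytes sniff."""
    ext = path.suffix.lower()
    if ext in _EXTENSION_FORMATS and ext != ".txt":
        return _EXTENSION_FORMATS[ext]
    if text is None:
        text = _read_text(path)
    head = text.lstrip()[:2000]
    candidates = []
    if head.startswith("<"):
        candidates.append("ENDNOTE_XML")
    if re.search(r"^TY  - ", head, flags=re.M):
        candidates.append("RIS")
    if re.search(r"^@\w+\s*\{", head, flags=re.M):
        candidates.append("BIBTEX")
    first_line = head.splitlines()[0] if head else ""
    if "record_id" in first_line and "," in first_line:
        candidates.append("CSV")
    if len(candidates) == 1:
        return candidates[0]
    if not candidates:
        raise FormatDetectionError(f"cannot detect format of {path}")
    raise FormatDetectionError(
        f"ambiguous format for {path}: candidates {candidates}"
    )


def read_citations(path: str | Path, format: str = "AUTO") -> CitationSet:
    """Read one export file into a :class:`CitationSet`.

    Parameters
    ----------
    path:
        File to read.
    format:
        One of ``RIS``, ``ENDNOTE_XML``, ``BIBTEX``, ``CSV`` or ``AUTO``
        (extension first, then content sniff).

    Raises
    ------
    EmptyInputError
        If the file parses but contains zero records.
    """
    path = Path(path)
    if not path.exists():
        raise CitationError(f"cannot read {path}: no such file")
    text = _read_text(path)
    fmt = detect_format(path, text) if format == "AUTO" else format.upper()
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    reader = {
        "RIS": _parse_ris,
        "ENDNOTE_XML": _parse_endnote_xml,
        "BIBTEX": _parse_bibtex,
        "CSV": _parse_csv,
    }[fmt]
    records = list(reader(text, path.stem))
    if not records:
        raise EmptyInputError(f"no citation records parsed from {path} ({fmt})")
    return CitationSet(citations=records, provenance=[str(path)])


def read_many(paths: Sequence[str | Path], format: str = "AUTO") -> CitationSet:
    """Aggregate several files; ids stay unique because they are namespaced
    by source stem (files sharing a stem get a numeric suffix)."""
    all_citations: list[Citation] = []
    provenance: list[str] = []
    seen_stems: dict[str, int] = {}
    for p in paths:
        cs = read_citations(p, format=format)
        stem = Path(p).stem
        n = seen_stems.get(stem, 0)
        seen_stems[stem] = n + 1
        if n:  # same stem appeared before: qualify ids
            cs = CitationSet(
                [replace(c, record_id=f"{c.record_id}.{n}") for c in cs],
                cs.provenance,
            )
        all_citations.extend(cs.citations)
        provenance.extend(cs.provenance)
    return CitationSet(all_citations, provenance)


# -- RIS --------------------------------------------------------------------

_RIS_TAG_RE = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")

# tag -> Citation field; AU/SP/EP handled specially
_RIS_FIELD_TAGS = {
    "PY": "year",
    "Y1": "year",
    "TI": "title",
    "T1": "title",
    "JO": "journal",
    "JF": "journal",
    "T2": "journal",
    "AB": "abstract",
    "N2": "abstract",
    "DO": "doi",
    "SN": "isbn_issn",
    "VL": "volume",
    "IS": "issue",
    "LB": "label",
}


def _parse_ris(text: str, stem: str) -> Iterator[Citation]:
    current: dict[str, str] = {}
    authors: list[str] = []
    sp = ep = ""
    rec_id = ""
    last_tag = ""
    ordinal = 0
    in_record = False

    def finish() -> Citation | None:
        nonlocal ordinal
        if not in_record:
            return None
        ordinal += 1
        pages = current.get("pages", "")
        if not pages:
            if sp and ep:
                pages = f"{sp}-{ep}"
            elif sp:
                pages = sp
        rid = rec_id or f"{stem}-{ordinal}"
        year = current.get("year", "")
        m = re.match(r"(\d{4})", year)
        if m:
            year = m.group(1)
        return Citation(
            record_id=rid,
            author="; ".join(authors),
            year=year,
            title=current.get("title", ""),
            journal=current.get("journal", ""),
            abstract=current.get("abstract", ""),
            doi=current.get("doi", ""),
            isbn_issn=current.get("isbn_issn", ""),
            pages=pages,
            volume=current.get("volume", ""),
            issue=current.get("issue", ""),
            label=current.get("label", ""),
            source_format="RIS",
        )

    for line in text.splitlines():
        m = _RIS_TAG_RE.match(line)
        if m:
            tag, value = m.group(1), m.group(2).strip()
            last_tag = tag
            if tag == "TY":
                in_record = True
                continue
            if tag == "ER":
                rec = finish()
                if rec is not None:
                    yield rec
                current, authors, sp, ep, rec_id = {}, [], "", "", ""
                in_record = False
                continue
            if not in_record:
                continue
            if tag in ("AU", "A1", "A2"):
                if value:
                    authors.append(value)
            elif tag == "SP":
                # accept both "SP 123 / EP 130" and "SP 123-130"
                if "-" in value and not ep:
                    sp, _, ep = value.partition("-")
                    sp, ep = sp.strip(), ep.strip()
                else:
                    sp = value
            elif tag == "EP":
                ep = value
            elif tag == "ID":
                rec_id = value
            elif tag in _RIS_FIELD_TAGS:
                fld = _RIS_FIELD_TAGS[tag]
                if fld not in current or not current[fld]:
                    current[fld] = value
        elif in_record and line.strip():
            # continuation line: rejoin with newline so round trips preserve it
            fld = _RIS_FIELD_TAGS.get(last_tag)
            if fld and current.get(fld) is not None:
                current[fld] = current.get(fld, "") + "\n" + line.strip()
    rec = finish()
    if rec is not None:
        yield rec


def _ris_lines(c: Citation) -> Iterator[str]:
    yield "TY  - JOUR"
    yield f"ID  - {c.record_id}"
    for a in (p.strip() for p in c.author.split(";")):
        if a:
            yield f"AU  - {a}"
    if c.year:
        yield f"PY  - {c.year}"
    for tag, value in (
        ("TI", c.title),
        ("JO", c.journal),
        ("AB", c.abstract),
        ("DO", c.doi),
        ("SN", c.isbn_issn),
        ("VL", c.volume),
        ("IS", c.issue),
        ("LB", c.label),
    ):
        if value:
            first, *rest = value.split("\n")
            yield f"{tag}  - {first}"
            for cont in rest:  # continuation lines per RIS convention
                yield f"      {cont}"
    if c.pages:
        m = re.fullmatch(r"\s*(\S+?)\s*-\s*(\S+)\s*", c.pages)
        if m:
            yield f"SP  - {m.group(1)}"
            yield f"EP  - {m.group(2)}"
        else:
            yield f"SP  - {c.pages}"
    yield "ER  - "


# -- EndNote XML ------------------------------------------------------------


def _xml_text(node: etree._Element | None) -> str:
    """Text of a leaf element, unwrapping <style> runs; inner newlines are
    field content and survive round trips."""
    if node is None:
        return ""
    return "".join(node.itertext()).strip()


def _parse_endnote_xml(text: str, stem: str) -> Iterator[Citation]:
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise CitationError(f"malformed EndNote XML: {exc}") from exc
    for ordinal, rec in enumerate(root.iter("record"), start=1):
        try:
            authors = [
                _xml_text(a) for a in rec.findall(".//contributors/authors/author")
            ]
            pages = _xml_text(rec.find(".//pages"))
            pages = pages.replace("--", "-")
            rid = _xml_text(rec.find("rec-number")) or f"{stem}-{ordinal}"
            yield Citation(
                record_id=rid,
                author="; ".join(a for a in authors if a),
                year=_xml_text(rec.find(".//dates/year")),
                title=_xml_text(rec.find(".//titles/title")),
                journal=_xml_text(rec.find(".//titles/secondary-title"))
                or _xml_text(rec.find(".//periodical/full-title")),
                abstract=_xml_text(rec.find(".//abstract")),
                doi=_xml_text(rec.find(".//electronic-resource-num")),
                isbn_issn=_xml_text(rec.find(".//isbn")),
                pages=pages,
                volume=_xml_text(rec.find(".//volume")),
                issue=_xml_text(rec.find(".//number")),
                label=_xml_text(rec.find(".//label")),
                source_format="ENDNOTE_XML",
            )
        except ValueError as exc:  # pragma: no cover - defensive
            logger.warning("skipping malformed record %d in %s: %s", ordinal, stem, exc)


def _endnote_element(c: Citation) -> etree._Element:
    rec = etree.Element("record")
    etree.SubElement(rec, "rec-number").text = c.record_id
    contributors = etree.SubElement(rec, "contributors")
    authors = etree.SubElement(contributors, "authors")
    for a in (p.strip() for p in c.author.split(";")):
        if a:
            etree.SubElement(authors, "author").text = a
    titles = etree.SubElement(rec, "titles")
    etree.SubElement(titles, "title").text = c.title
    etree.SubElement(titles, "secondary-title").text = c.journal
    dates = etree.SubElement(rec, "dates")
    etree.SubElement(dates, "year").text = c.year
    for tag, value in (
        ("abstract", c.abstract),
        ("electronic-resource-num", c.doi),
        ("isbn", c.isbn_issn),
        ("pages", c.pages),
        ("volume", c.volume),
        ("number", c.issue),
        ("label", c.label),
    ):
        etree.SubElement(rec, tag).text = value
    return rec


# -- BibTeX -----------------------------------------------------------------

_BIB_ENTRY_RE = re.compile(r"@(\w+)\s*\{\s*([^,\s]*)\s*,", re.S)


def _bib_fields(body: str) -> dict[str, str]:
    """Parse ``field = {value}`` / ``field = "value"`` pairs from an entry body."""
    fields: dict[str, str] = {}
    i = 0
    n = len(body)
    while i < n:
        m = re.compile(r"\s*(\w+)\s*=\s*").match(body, i)
        if not m:
            break
        name = m.group(1).lower()
        i = m.end()
        if i >= n:
            break
        if body[i] == "{":
            depth, j = 0, i
            while j < n:
                if body[j] == "{":
                    depth += 1
                elif body[j] == "}":
                    depth -= 1
                    if depth == 0:
                        break
                j += 1
            value = body[i + 1 : j]
            i = j + 1
        elif body[i] == '"':
            j = body.find('"', i + 1)
            j = n if j < 0 else j
            value = body[i + 1 : j]
            i = j + 1
        else:
            m2 = re.compile(r"[^,]*").match(body, i)
            value = m2.group(0)
            i = m2.end()
        fields[name] = " ".join(value.split())
        comma = body.find(",", i)
        if comma < 0:
            break
        i = comma + 1
    return fields


def _parse_bibtex(text: str, stem: str) -> Iterator[Citation]:
    ordinal = 0
    for m in _BIB_ENTRY_RE.finditer(text):
        if m.group(1).lower() in ("comment", "preamble", "string"):
            continue
        ordinal += 1
        # entry body runs to the brace balancing the one opened after @type
        start = m.end()
        depth, j = 1, start
        while j < len(text) and depth:
            if text[j] == "{":
                depth += 1
            elif text[j] == "}":
                depth -= 1
            j += 1
        fields = _bib_fields(text[start : j - 1])
        author = "; ".join(
            a.strip() for a in re.split(r"\s+and\s+", fields.get("author", "")) if a.strip()
        )
        yield Citation(
            record_id=m.group(2) or f"{stem}-{ordinal}",
            author=author,
            year=fields.get("year", ""),
            title=fields.get("title", ""),
            journal=fields.get("journal", fields.get("booktitle", "")),
            abstract=fields.get("abstract", ""),
            doi=fields.get("doi", ""),
            isbn_issn=fields.get("isbn", fields.get("issn", "")),
            pages=fields.get("pages", "").replace("--", "-"),
            volume=fields.get("volume", ""),
            issue=fields.get("number", ""),
            label=fields.get("label", ""),
            source_format="BIBTEX",
        )


# -- CSV --------------------------------------------------------------------


def _parse_csv(text: str, stem: str) -> Iterator[Citation]:
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        return
    known = set(CSV_HEADER)
    header = [h.strip().lower() for h in reader.fieldnames]
    if not known & set(header):
        raise CitationError(
            f"CSV header {reader.fieldnames} has none of the expected columns {sorted(known)}"
        )
    for ordinal, row in enumerate(reader, start=1):
        row = {(k or "").strip().lower(): (v or "") for k, v in row.items()}
        yield Citation(
            record_id=row.get("record_id", "") or f"{stem}-{ordinal}",
            source_format="CSV",
            **{f: row.get(f, "").strip() for f in CITATION_FIELDS},
        )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_citations(cs: CitationSet, path: str | Path, format: str = "CSV") -> Path:
    """Write a citation set; ``read(write(s))`` reproduces all non-empty field
    values and the record order for every supported format."""
    path = Path(path)
    fmt = format.upper()
    if fmt == "RIS":
        body = "\n".join(line for c in cs for line in list(_ris_lines(c)) + [""])
        path.write_text(body, encoding="utf-8")
    elif fmt == "CSV":
        with path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(CSV_HEADER)
            for c in cs:
                w.writerow([c.record_id] + [getattr(c, f) for f in CITATION_FIELDS])
    elif fmt == "ENDNOTE_XML":
        root = etree.Element("xml")
        records = etree.SubElement(root, "records")
        for c in cs:
            records.append(_endnote_element(c))
        path.write_bytes(etree.tostring(root, pretty_print=True, encoding="utf-8"))
    else:
        raise ValueError(f"unsupported output format {format!r}")
    return path


def write_flagged(
    cs: CitationSet,
    groups: Iterable,
    path: str | Path,
) -> Path:
    """Write all original citations to CSV with a ``duplicate_id`` column.

    Members of the same duplicate group share one duplicate_id; every
    singleton receives its own. ``groups`` may be DuplicateGroup objects or
    plain collections of record ids.
    """
    path = Path(path)
    ids = set(cs.ids)
    assignment: dict[str, str] = {}
    counter = 0
    for g in groups:
        members = sorted(getattr(g, "member_ids", g))
        unknown = [m for m in members if m not in ids]
        if unknown:
            raise ValueError(f"duplicate group references unknown record_ids: {unknown}")
        counter += 1
        gid = f"DUP-{counter:05d}"
        for m in members:
            assignment[m] = gid
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(("duplicate_id",) + CSV_HEADER)
        for c in cs:
            if c.record_id in assignment:
                gid = assignment[c.record_id]
            else:
                counter += 1
                gid = f"DUP-{counter:05d}"
            w.writerow([gid, c.record_id] + [getattr(c, f) for f in CITATION_FIELDS])
    return path
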