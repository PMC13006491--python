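"""Read, validate, filter, and persist regulatory document corpora.

Documents travel as line-delimited JSON records (one document per line),
which streams comfortably at the 1e5--1e6 document scale regulatory
collections reach. Filtering produces a staged "funnel" accounting of how
many documents per source agency survive each criterion, in the shape
regulatory-intelligence reports conventionally print it.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

AGENCIES = ("FDA", "EMA", "WHO", "OTHER")

#: Stage labels in the fixed order filters are applied.
STAGE_INITIAL = "Initial collection"
STAGE_LANGUAGE = "Language filter"
STAGE_TIME_CONTENT = "Time & Content filter"


class CorpusError(Exception):
    """Raised for fatal corpus-level problems (unreadable file, duplicate ids)."""


@dataclass(frozen=True)
class Document:
    """One regulatory publication with metadata and plain-text content.

    ``text`` may be empty only when ``unextractable`` is set (e.g. a scanned
    PDF whose text could not be recovered); such documents are carried through
    the pipeline but embed to a flagged zero vector.
    """

    doc_id: str
    agency: str
    url: str = ""
    title: str = ""
    publication_date: _dt.date | None = None
    language: str | None = None
    category: str = ""
    text: str = ""
    unextractable: bool = False

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if self.agency not in AGENCIES:
            raise ValueError(f"unknown agency {self.agency!r}; expected one of {AGENCIES}")
        if not self.text and not self.unextractable:
            raise ValueError(f"document {self.doc_id!r} has empty text but is not flagged unextractable")

    def to_record(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "agency": self.agency,
            "url": self.url,
            "title": self.title,
            "publication_date": self.publication_date.isoformat() if self.publication_date else None,
            "language": self.language,
            "category": self.category,
            "text": self.text,
            "unextractable": self.unextractable,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Document":
        date = rec.get("publication_date")
        return cls(
            doc_id=rec["doc_id"],
            agency=rec["agency"],
            url=rec.get("url", ""),
            title=rec.get("title", ""),
            publication_date=_dt.date.fromisoformat(date) if date else None,
            language=rec.get("language"),
            category=rec.get("category", ""),
            text=rec.get("text", ""),
            unextractable=bool(rec.get("unextractable", False)),
        )


@dataclass
class Corpus:
    """An ordered, id-unique collection of documents."""

    documents: list[Document]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for d in self.documents:
            if d.doc_id in seen:
                raise CorpusError(f"duplicate doc_id {d.doc_id!r} in corpus")
            seen.add(d.doc_id)
        self._index = {d.doc_id: d for d in self.documents}

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._index

    def get(self, doc_id: str) -> Document:
        return self._index[doc_id]

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]


@dataclass(frozen=True)
class FilterConfig:
    """Funnel filter criteria: publication window, language, category.

    Defaults mirror a 2019-01-01 .. 2025-07-31 English-language window.
    Unknown dates are kept by default because source timestamps can reflect
    technical rather than content updates and are therefore unreliable as an
    exclusion criterion; unknown languages are dropped by default.
    """

    date_min: _dt.date = _dt.date(2019, 1, 1)
    date_max: _dt.date = _dt.date(2025, 7, 31)
    allowed_languages: frozenset[str] = frozenset({"en"})
    excluded_categories: frozenset[str] = frozenset()
    keep_unknown_date: bool = True
    keep_unknown_language: bool = False

    def __post_init__(self) -> None:
        if self.date_min > self.date_max:
            raise ValueError("date_min must be <= date_max")
        object.__setattr__(self, "allowed_languages", frozenset(self.allowed_languages))
        object.__setattr__(self, "excluded_categories", frozenset(self.excluded_categories))

    def passes_language(self, doc: Document) -> bool:
        if doc.language is None:
            return self.keep_unknown_language
        return doc.language in self.allowed_languages

    def passes_time(self, doc: Document) -> bool:
        if doc.publication_date is None:
            return self.keep_unknown_date
        return self.date_min <= doc.publication_date <= self.date_max

    def passes_category(self, doc: Document) -> bool:
        return doc.category not in self.excluded_categories


@dataclass(frozen=True)
class FunnelRow:
    agency: str
    stage_label: str
    count: int
    percent_of_initial: float


@dataclass
class FunnelReport:
    """Per-agency staged document counts, percentages relative to each
    agency's initial collection (rounded to one decimal), plus grand totals.

    ``exclusions`` attributes every filtered-out document to exactly one
    exclusion reason (the first failing criterion in stage order).
    """

    rows: list[FunnelRow] = field(default_factory=list)
    exclusions: dict[str, str] = field(default_factory=dict)

    def agency_rows(self, agency: str) -> list[FunnelRow]:
        return [r for r in self.rows if r.agency == agency]

    def validate(self) -> None:
        by_agency: dict[str, list[FunnelRow]] = {}
        for r in self.rows:
            by_agency.setdefault(r.agency, []).append(r)
        for agency, rows in by_agency.items():
            counts = [r.count for r in rows]
            if any(b > a for a, b in zip(counts, counts[1:])):
                raise ValueError(f"funnel counts for {agency} increase across stages")


def _pct(count: int, initial: int) -> float:
    return round(100.0 * count / initial, 1) if initial else 0.0


def load_corpus(path: str | Path, provenance: str | None = None) -> Corpus:
    """Load a JSONL corpus.

    Malformed lines are collected (with their line numbers) onto the returned
    corpus as ``corpus.load_errors`` and reported as a warning; they never
    abort the load. A duplicate ``doc_id`` violates a corpus invariant and is
    fatal, naming the offending id.
    """
    path = Path(path)
    try:
        raw = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise CorpusError(f"cannot read corpus file {path}: {exc}") from exc

    docs: list[Document] = []
    errors: list[tuple[int, str]] = []
    for lineno, line in enumerate(raw.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            docs.append(Document.from_record(json.loads(line)))
        except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
            errors.append((lineno, str(exc)))
    if errors:
        warnings.warn(f"{len(errors)} malformed record(s) in {path}; first at line {errors[0][0]}")
    corpus = Corpus(docs, provenance=provenance or str(path))
    corpus.load_errors = errors  # type: ignore[attr-defined]
    return corpus


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps(doc.to_record(), ensure_ascii=False) + "\n")


def apply_filters(corpus: Corpus, cfg: FilterConfig) -> tuple[Corpus, FunnelReport]:
    """Apply the funnel filters in fixed order: language, then time+category.

    Returns the surviving corpus and a :class:`FunnelReport` with per-agency
    counts at each stage. Each excluded document is attributed to exactly one
    reason: ``language``, ``time`` or ``category`` (first failure in stage
    order; within the combined stage, time is checked before category).
    """
    agencies = [a for a in AGENCIES if any(d.agency == a for d in corpus)]
    initial = {a: sum(1 for d in corpus if d.agency == a) for a in agencies}

    exclusions: dict[str, str] = {}
    after_lang: list[Document] = []
    for doc in corpus:
        if cfg.passes_language(doc):
            after_lang.append(doc)
        else:
            exclusions[doc.doc_id] = "language"
    survivors: list[Document] = []
    for doc in after_lang:
        if not cfg.passes_time(doc):
            exclusions[doc.doc_id] = "time"
        elif not cfg.passes_category(doc):
            exclusions[doc.doc_id] = "category"
        else:
            survivors.append(doc)

    lang_counts = {a: sum(1 for d in after_lang if d.agency == a) for a in agencies}
    final_counts = {a: sum(1 for d in survivors if d.agency == a) for a in agencies}

    rows: list[FunnelRow] = []
    for a in agencies:
        n0 = initial[a]
        rows.append(FunnelRow(a, STAGE_INITIAL, n0, _pct(n0, n0)))
        rows.append(FunnelRow(a, STAGE_LANGUAGE, lang_counts[a], _pct(lang_counts[a], n0)))
        rows.append(FunnelRow(a, STAGE_TIME_CONTENT, final_counts[a], _pct(final_counts[a], n0)))
    total0 = len(corpus)
    rows.append(FunnelRow("Total", STAGE_INITIAL, total0, _pct(total0, total0)))
    rows.append(FunnelRow("Total", "All filters", len(survivors), _pct(len(survivors), total0)))

    report = FunnelReport(rows=rows, exclusions=exclusions)
    report.validate()
    return Corpus(survivors, provenance=corpus.provenance + " [filtered]"), report


def write_funnel_report(report: FunnelReport, path: str | Path) -> None:
    """Write the funnel as a tab-delimited table: Agency | Filter Stage | Count | %."""
    path = Path(path)
    lines = ["Agency\tFilter Stage\tCount\t%"]
    for r in report.rows:
        lines.append(f"{r.agency}\t{r.stage_label}\t{r.count}\t{r.percent_of_initial:.1f}")
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise CorpusError(f"cannot write funnel report to {path}: {exc}") from exc


def read_funnel_report(path: str | Path) -> FunnelReport:
    rows = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        agency, stage, count, pct = line.split("\t")
        rows.append(FunnelRow(agency, stage, int(count), float(pct)))
    return FunnelReport(rows=rows)
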