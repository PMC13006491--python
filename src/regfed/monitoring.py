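"""Incremental monitoring: snapshot diffing, batch classification, and a
persistent append-only ledger.

A monitoring cycle consumes a local *sitemap snapshot* — any (url,
last-modified timestamp[, content digest]) listing, whether exported from a
real agency sitemap or generated as a fixture — diffs it against the
previous snapshot to find new/updated/removed URLs, scores and classifies
the corresponding document batch with a fixed pipeline, and appends the
outcome to a ledger. Classifying a corpus in batches yields exactly the
labels of a single pass, because scoring is per-document and the pipeline
components are fixed.

State persists as a JSON index plus a JSONL ledger, written with an atomic
replace so a failed update never corrupts the previous state.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .corpus_io import Corpus
from .ensemble_classifier import ThresholdConfig, classify_corpus
from .scoring_engine import EmbeddingBackend, KeywordTaxonomy, ReferenceSet, score_corpus


@dataclass(frozen=True)
class SnapshotEntry:
    url: str
    last_modified: str  # ISO timestamp
    digest: str | None = None


@dataclass
class SitemapSnapshot:
    source: str
    taken_at: str
    entries: dict[str, SnapshotEntry] = field(default_factory=dict)

    @classmethod
    def from_entries(cls, source: str, taken_at: str,
                     entries: Sequence[SnapshotEntry]) -> "SitemapSnapshot":
        index: dict[str, SnapshotEntry] = {}
        for e in entries:
            if e.url in index:
                raise ValueError(f"duplicate url in snapshot: {e.url}")
            index[e.url] = e
        return cls(source, taken_at, index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source": self.source,
            "taken_at": self.taken_at,
            "entries": [[e.url, e.last_modified, e.digest] for e in self.entries.values()],
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SitemapSnapshot":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls.from_entries(payload["source"], payload["taken_at"],
                                [SnapshotEntry(u, m, d) for u, m, d in payload["entries"]])


@dataclass(frozen=True)
class SnapshotDiff:
    new_urls: frozenset[str]
    updated_urls: frozenset[str]
    removed_urls: frozenset[str]


def diff_snapshots(old: SitemapSnapshot, new: SitemapSnapshot) -> SnapshotDiff:
    """New = in ``new`` only; updated = in both with changed timestamp or
    digest; removed = in ``old`` only. The three sets are disjoint."""
    if old.source != new.source:
        raise ValueError(f"cannot diff snapshots from different sources: "
                         f"{old.source!r} vs {new.source!r}")
    old_urls, new_urls = set(old.entries), set(new.entries)
    added = new_urls - old_urls
    removed = old_urls - new_urls
    updated = {
        u for u in old_urls & new_urls
        if old.entries[u].last_modified != new.entries[u].last_modified
        or old.entries[u].digest != new.entries[u].digest
    }
    return SnapshotDiff(frozenset(added), frozenset(updated), frozenset(removed))


# ---------------------------------------------------------------------------
# Pipeline + state
# ---------------------------------------------------------------------------

@dataclass
class ClassificationPipeline:
    """The fixed components a monitoring cycle scores and classifies with."""

    refs: ReferenceSet
    taxonomy: KeywordTaxonomy
    backend: EmbeddingBackend
    config: ThresholdConfig

    def validate(self) -> None:
        for name, comp in (("refs", self.refs), ("taxonomy", self.taxonomy),
                           ("backend", self.backend), ("config", self.config)):
            if comp is None:
                raise ValueError(f"pipeline component {name!r} missing")

    def score_and_classify(self, corpus: Corpus) -> tuple[pd.DataFrame, pd.Series]:
        scores = score_corpus(corpus, self.refs, self.taxonomy, self.backend)
        return scores, classify_corpus(scores, self.config).labels


@dataclass(frozen=True)
class BatchReport:
    batch_date: str
    n_new: int
    n_positive: int
    positive_rate: float  # NaN (undefined) for an empty batch


@dataclass
class MonitorState:
    """Known-document index, append-only classification ledger, batch history."""

    known: dict[str, dict] = field(default_factory=dict)  # doc_id -> {url, digest, last_scored}
    ledger: list[dict] = field(default_factory=list)
    batches: list[BatchReport] = field(default_factory=list)

    def labels(self) -> pd.Series:
        """Current label per document: the latest ledger entry wins."""
        latest: dict[str, bool] = {}
        for entry in self.ledger:
            latest[entry["doc_id"]] = bool(entry["label"])
        return pd.Series(latest, dtype=bool)

    # -- persistence -------------------------------------------------------
    def save(self, state_dir: str | Path) -> None:
        state_dir = Path(state_dir)
        state_dir.mkdir(parents=True, exist_ok=True)
        _atomic_write(state_dir / "state.json", json.dumps({
            "known": self.known,
            "batches": [b.__dict__ for b in self.batches],
        }))
        _atomic_write(state_dir / "ledger.jsonl",
                      "".join(json.dumps(e) + "\n" for e in self.ledger))

    @classmethod
    def load(cls, state_dir: str | Path) -> "MonitorState":
        state_dir = Path(state_dir)
        if not (state_dir / "state.json").exists():
            return cls()
        payload = json.loads((state_dir / "state.json").read_text(encoding="utf-8"))
        ledger = [json.loads(line) for line in
                  (state_dir / "ledger.jsonl").read_text(encoding="utf-8").splitlines()
                  if line.strip()]
        return cls(known=payload["known"],
                   ledger=ledger,
                   batches=[BatchReport(**b) for b in payload["batches"]])


def _atomic_write(path: Path, content: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(content, encoding="utf-8")
    os.replace(tmp, path)


def incremental_update(state: MonitorState, batch: Corpus,
                       pipeline: ClassificationPipeline,
                       batch_date: str = "",
                       updated_ids: frozenset[str] = frozenset()) -> tuple[MonitorState, BatchReport]:
    """Score and classify one batch, returning a new state plus its report.

    Only documents not yet in the ledger — or re-presented via
    ``updated_ids`` — are scored; re-applying the same batch is a ledger
    no-op. The pipeline is validated before any mutation and the input state
    is never modified (atomicity: on failure the caller's state is intact).
    Updated documents are re-scored and may change label; the old entry stays
    in the ledger with its timestamp.
    """
    pipeline.validate()
    new_state = copy.deepcopy(state)

    to_process = [d for d in batch if d.doc_id not in state.known or d.doc_id in updated_ids]
    n_new = len(to_process)
    if n_new == 0:
        report = BatchReport(batch_date, 0, 0, float("nan"))
        new_state.batches.append(report)
        return new_state, report

    sub = Corpus(to_process, provenance=f"batch {batch_date}")
    _, labels = pipeline.score_and_classify(sub)
    n_positive = int(labels.sum())
    for doc in to_process:
        new_state.known[doc.doc_id] = {"url": doc.url, "digest": None,
                                       "last_scored": batch_date}
        new_state.ledger.append({"doc_id": doc.doc_id, "label": bool(labels[doc.doc_id]),
                                 "batch_date": batch_date,
                                 "updated": doc.doc_id in updated_ids})
    report = BatchReport(batch_date, n_new, n_positive, n_positive / n_new)
    new_state.batches.append(report)
    return new_state, report
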