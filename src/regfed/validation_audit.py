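"""Decision-boundary ensemble validation and cross-agency bias auditing.

Boundary analysis restricts evaluation to documents whose scores fall inside
a window around a decision threshold — the region where classification
uncertainty is highest and where an OR-ensemble's complementary clauses
should show their value. Two window widths are used: a *narrow* absolute
window (±0.01) and a *wide* window of ±0.5 population standard deviations
of that score's corpus distribution.

The bias audit compares positive classification rates across source
agencies; systematic gaps point at a reference set (or taxonomy) that
under-represents one agency's terminology. ``diversify_references`` enlarges
the reference set with new exemplars and hands back a rescoring hook so
dependent score tables can be recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Corpus, Document
from .ensemble_classifier import ThresholdConfig, classify_corpus
from .optimization_evaluation import TestSet
from .scoring_engine import EmbeddingBackend, KeywordTaxonomy, ReferenceSet

NARROW_HALF_WIDTH = 0.01
WIDE_SIGMA_FACTOR = 0.5


@dataclass(frozen=True)
class BoundaryRegion:
    score_name: str
    center: float
    mode: str  # "narrow" | "wide"
    half_width: float

    def __post_init__(self) -> None:
        if self.mode not in ("narrow", "wide"):
            raise ValueError(f"unknown boundary mode {self.mode!r}")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


def make_region(score_table: pd.DataFrame, score_name: str, center: float,
                mode: str) -> BoundaryRegion:
    """Narrow regions use an absolute ±0.01 window; wide regions ±0.5σ of the
    full corpus distribution of that score."""
    if mode == "narrow":
        hw = NARROW_HALF_WIDTH
    else:
        sigma = float(score_table[score_name].to_numpy(dtype=float).std(ddof=0))
        if sigma == 0:
            raise ValueError(f"zero variance for {score_name!r}; wide region undefined")
        hw = WIDE_SIGMA_FACTOR * sigma
    return BoundaryRegion(score_name, center, mode, hw)


def boundary_members(score_table: pd.DataFrame, region: BoundaryRegion) -> set[str]:
    """Ids of documents with |score - center| <= half_width (inclusive).

    Membership carries an ulp-scale tolerance (1e-12) so that decimal window
    edges behave inclusively despite binary-float representation (a score of
    0.32 lies inside the 0.33 +- 0.01 window).
    """
    s = score_table[region.score_name]
    mask = (s - region.center).abs() <= region.half_width + 1e-12
    return set(score_table.index[mask])


@dataclass
class BoundaryReport:
    region: BoundaryRegion
    n_docs: int
    method_recall: dict[str, float]       # NaN when no test docs in region
    ensemble_recall: float
    method_positive_rate: dict[str, float]
    ensemble_positive_rate: float
    recall_delta_pp: dict[str, float]     # (ensemble - method) * 100
    positive_rate_delta_pp: dict[str, float]
    recall_undefined: bool = False


def _region_rates(labels: pd.Series, member_ids: list[str],
                  rel_in_region: list[str]) -> tuple[float, float]:
    pos_rate = float(labels.loc[member_ids].sum()) / len(member_ids) if member_ids else float("nan")
    if rel_in_region:
        recall = float(labels.loc[rel_in_region].sum()) / len(rel_in_region)
    else:
        recall = float("nan")
    return recall, pos_rate


def boundary_analysis(score_table: pd.DataFrame, test_set: TestSet,
                      ensemble_cfg: ThresholdConfig,
                      per_method_cfgs: Mapping[str, ThresholdConfig] | None = None,
                      modes: Sequence[str] = ("narrow", "wide")) -> list[BoundaryReport]:
    """For each ensemble clause threshold and each window width, compare each
    constituent method's recall/positive-rate inside the region against the
    full ensemble's, reporting deltas in percentage points.

    Recall uses only test-labeled region members (flagged undefined when the
    region holds none); positive rate uses all region members. By
    OR-dominance the ensemble recall delta is never negative.
    """
    if per_method_cfgs is None:
        per_method_cfgs = {name: ThresholdConfig(((name, thr),), label=name)
                           for name, thr in ensemble_cfg.clauses}
    ens_labels = classify_corpus(score_table, ensemble_cfg).labels
    method_labels = {m: classify_corpus(score_table, cfg).labels
                     for m, cfg in per_method_cfgs.items()}

    reports: list[BoundaryReport] = []
    for name, thr in ensemble_cfg.clauses:
        for mode in modes:
            region = make_region(score_table, name, thr, mode)
            members = sorted(boundary_members(score_table, region))
            rel_in_region = sorted(set(members) & test_set.relevant_ids)
            if not rel_in_region:
                warnings.warn(f"no test-labeled documents in {mode} region of {name!r}; "
                              "recall undefined")
            ens_recall, ens_pr = _region_rates(ens_labels, members, rel_in_region)
            m_recall, m_pr, d_rec, d_pr = {}, {}, {}, {}
            for m, labels in method_labels.items():
                r, p = _region_rates(labels, members, rel_in_region)
                m_recall[m], m_pr[m] = r, p
                d_rec[m] = (ens_recall - r) * 100.0
                d_pr[m] = (ens_pr - p) * 100.0
            reports.append(BoundaryReport(
                region=region, n_docs=len(members),
                method_recall=m_recall, ensemble_recall=ens_recall,
                method_positive_rate=m_pr, ensemble_positive_rate=ens_pr,
                recall_delta_pp=d_rec, positive_rate_delta_pp=d_pr,
                recall_undefined=not rel_in_region,
            ))
    return reports


# ---------------------------------------------------------------------------
# Cross-agency bias audit
# ---------------------------------------------------------------------------

@dataclass
class BiasReport:
    """Per-agency positive rates with the maximum pairwise gap and rate
    ratios. ``max_abs_gap`` is NaN (flagged) when fewer than two agencies
    have documents."""

    rates: dict[str, float]
    counts: dict[str, tuple[int, int]]  # agency -> (n_positive, n_docs)
    max_abs_gap: float
    rate_ratios: dict[tuple[str, str], float]
    gap_undefined: bool = False


def per_agency_positive_rates(labels: pd.Series, corpus: Corpus) -> BiasReport:
    """Positive classification rate per source agency.

    Agencies with zero documents are omitted with a warning; pairwise ratios
    are NaN when the denominator agency's rate is zero.
    """
    by_agency: dict[str, list[str]] = {}
    for doc in corpus:
        by_agency.setdefault(doc.agency, []).append(doc.doc_id)
    missing = [d for ids in by_agency.values() for d in ids if d not in labels.index]
    if missing:
        raise KeyError(f"{len(missing)} corpus doc(s) missing from labels")

    rates, counts = {}, {}
    for agency, ids in sorted(by_agency.items()):
        if not ids:
            warnings.warn(f"agency {agency} has no documents; omitted")
            continue
        n_pos = int(labels.loc[ids].sum())
        rates[agency] = n_pos / len(ids)
        counts[agency] = (n_pos, len(ids))

    ratios: dict[tuple[str, str], float] = {}
    gaps = []
    for a, b in combinations(sorted(rates), 2):
        gaps.append(abs(rates[a] - rates[b]))
        ratios[(a, b)] = rates[a] / rates[b] if rates[b] > 0 else float("nan")
    if len(rates) < 2:
        warnings.warn("fewer than two agencies; pairwise gap undefined")
        return BiasReport(rates, counts, float("nan"), ratios, gap_undefined=True)
    return BiasReport(rates, counts, max(gaps), ratios)


def diversify_references(refs: ReferenceSet, new_refs: Sequence[Document],
                         taxonomy: KeywordTaxonomy, backend: EmbeddingBackend,
                         rescore: Callable[[ReferenceSet], None] | None = None,
                         version: str | None = None) -> ReferenceSet:
    """Enlarge a reference set with new exemplar documents.

    New references must be id-disjoint from the existing ones (duplicate id
    is fatal). The returned set records the provenance of the additions in
    its version label; if a ``rescore`` hook is given it is invoked with the
    enlarged set so dependent score tables are recomputed immediately.
    """
    existing = {d.doc_id for d in refs.real_refs}
    dupes = [d.doc_id for d in new_refs if d.doc_id in existing]
    if dupes:
        raise ValueError(f"duplicate reference id(s): {dupes}")
    enlarged = ReferenceSet.build(
        list(refs.real_refs) + list(new_refs), taxonomy, backend,
        version=version or f"{refs.version}+{len(new_refs)}refs",
    )
    if rescore is not None:
        rescore(enlarged)
    return enlarged
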