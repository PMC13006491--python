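"""OR-ensemble threshold classification over named score components.

A document is labeled AI-relevant when *any* clause of a threshold
configuration is met (score >= threshold, inclusive — thresholds are
compared with exact floating-point >= so classification is bit-for-bit
reproducible per backend). The OR combination means the ensemble's positive
set is exactly the union of the per-clause positive sets, so ensemble recall
can never fall below any constituent clause's recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring_engine import SCORE_COLUMNS, ScoreVector

#: Score components a threshold clause may reference.
CLASSIFIER_SCORES = ("avg_ref_score", "max_ref_score", "ideal_score",
                     "ai_keyword_combined_score")


@dataclass(frozen=True)
class ThresholdConfig:
    """A non-empty set of (score_name, threshold) clauses combined by OR."""

    clauses: tuple[tuple[str, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("ThresholdConfig needs at least one clause")
        names = [n for n, _ in self.clauses]
        if len(set(names)) != len(names):
            raise ValueError("duplicate score_name in clauses")
        for name, thr in self.clauses:
            if name not in CLASSIFIER_SCORES:
                raise ValueError(f"unknown score component {name!r}")
            if not np.isfinite(thr):
                raise ValueError(f"non-finite threshold for {name!r}")
        if not self.label:
            object.__setattr__(self, "label", " OR ".join(f"{n}>={t:g}" for n, t in self.clauses))

    @property
    def score_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.clauses)

    def canonical(self) -> tuple[tuple[str, float], ...]:
        return tuple(sorted(self.clauses))


@dataclass(frozen=True)
class ConfigTemplate:
    """A clause set with thresholds left unbound, to be filled by the optimizer."""

    score_names: tuple[str, ...]
    label: str = ""

    def bind(self, thresholds: Sequence[float]) -> ThresholdConfig:
        if len(thresholds) != len(self.score_names):
            raise ValueError("threshold count must match clause count")
        return ThresholdConfig(tuple(zip(self.score_names, (float(t) for t in thresholds))),
                               label=self.label)


#: The default optimal configuration found for this class of corpus in
#: production use: keyword-combined OR average-reference similarity.
DEFAULT_CONFIG = ThresholdConfig(
    (("ai_keyword_combined_score", 0.33), ("avg_ref_score", 0.49)),
    label="keyword OR avg-reference",
)


@dataclass
class ClassificationResult:
    labels: pd.Series  # bool, indexed by doc_id
    positive_rate: float
    config: ThresholdConfig
    clause_counts: dict[str, int] = field(default_factory=dict)
    undefined_rate: bool = False

    @property
    def positive_ids(self) -> set[str]:
        return set(self.labels.index[self.labels])


def classify(scores: ScoreVector | Mapping[str, float], cfg: ThresholdConfig) -> bool:
    """True iff any clause is met (inclusive >=)."""
    if isinstance(scores, ScoreVector):
        scores = scores.as_dict()
    missing = [name for name, _ in cfg.clauses if name not in scores]
    if missing:
        raise KeyError(f"score component(s) {missing} missing from score vector")
    return any(scores[name] >= thr for name, thr in cfg.clauses)


def classify_corpus(score_table: pd.DataFrame, cfg: ThresholdConfig) -> ClassificationResult:
    """Label every document in the score table.

    ``clause_counts`` reports, per clause, how many positives that clause
    alone would have caught. An empty table yields positive_rate 0 flagged
    undefined.
    """
    n = len(score_table)
    if n == 0:
        empty = pd.Series(dtype=bool, index=pd.Index([], name="doc_id"))
        return ClassificationResult(empty, 0.0, cfg, {name: 0 for name, _ in cfg.clauses},
                                    undefined_rate=True)
    mask = np.zeros(n, dtype=bool)
    counts: dict[str, int] = {}
    for name, thr in cfg.clauses:
        if name not in score_table.columns:
            raise KeyError(f"score component {name!r} missing from score table")
        clause_mask = score_table[name].to_numpy() >= thr
        counts[name] = int(clause_mask.sum())
        mask |= clause_mask
    labels = pd.Series(mask, index=score_table.index)
    return ClassificationResult(labels, float(mask.sum()) / n, cfg, counts)


def enumerate_configurations(
    available: Sequence[str] = CLASSIFIER_SCORES,
) -> list[ConfigTemplate]:
    """The default family of scoring configurations: every single-score
    clause, plus every OR-pair of the keyword score with a similarity score.

    For the default four components this yields seven templates — four
    singles (average reference, maximum reference, ideal, keyword) and three
    pairs (keyword OR avg, keyword OR max, keyword OR ideal).
    """
    singles = [ConfigTemplate((name,), label=name) for name in available]
    kw = "ai_keyword_combined_score"
    pairs = []
    if kw in available:
        for other in available:
            if other != kw:
                pairs.append(ConfigTemplate((kw, other), label=f"{kw} OR {other}"))
    else:  # fall back to all pairs when the keyword score is not offered
        pairs = [ConfigTemplate(pair, label=" OR ".join(pair))
                 for pair in combinations(available, 2)]
    return singles + pairs
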