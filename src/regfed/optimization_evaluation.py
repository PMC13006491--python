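"""Classifier evaluation, recall-constrained threshold grid search, and
score-distribution diagnostics.

Evaluation uses three rates tailored to rare-event triage where only
positives of the test set are labeled:

* **Test Recall** — fraction of the labeled relevant test set captured.
* **High Priority Recall** — recall restricted to the high-confidence subset.
* **Positive Rate** — fraction of the whole corpus labeled positive, a
  direct proxy for the downstream manual review burden.

The optimizer enumerates threshold grids for each candidate clause template,
keeps every configuration whose Test Recall meets a floor (default 70%), and
ranks the feasible set by ascending Positive Rate; ties break by higher High
Priority Recall, then higher Test Recall, then fewer clauses, then a
canonical ordering of the clause tuples so output never depends on grid
enumeration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble_classifier import ConfigTemplate, ThresholdConfig, classify_corpus


@dataclass(frozen=True)
class TestSet:
    """Labeled AI-relevant document ids with a high-confidence subset."""

    relevant_ids: frozenset[str]
    high_confidence_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "relevant_ids", frozenset(self.relevant_ids))
        object.__setattr__(self, "high_confidence_ids", frozenset(self.high_confidence_ids))
        if not self.high_confidence_ids <= self.relevant_ids:
            raise ValueError("high_confidence_ids must be a subset of relevant_ids")
        if not self.relevant_ids:
            raise ValueError("test set must contain at least one relevant id")


@dataclass(frozen=True)
class EvaluationReport:
    config: ThresholdConfig
    test_recall: float
    high_priority_recall: float
    positive_rate: float


@dataclass(frozen=True)
class GridSpec:
    """Per-score threshold grids plus the recall floor.

    ``grids`` maps score_name -> (min, max, step); default grids span [0, 1]
    in steps of 0.01 for every score a template references.
    """

    grids: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    min_test_recall: float = 0.70
    default_grid: tuple[float, float, float] = (0.0, 1.0, 0.01)

    def thresholds(self, score_name: str) -> np.ndarray:
        lo, hi, step = self.grids.get(score_name, self.default_grid)
        if step <= 0:
            raise ValueError(f"grid step for {score_name!r} must be positive")
        n = int(round((hi - lo) / step))
        grid = lo + step * np.arange(n + 1)
        if grid.size == 0:
            raise ValueError(f"empty threshold grid for {score_name!r}")
        return grid


def _check_coverage(labels: pd.Series, test_set: TestSet) -> None:
    missing = test_set.relevant_ids - set(labels.index)
    if missing:
        raise KeyError(f"{len(missing)} test id(s) missing from labels, e.g. {sorted(missing)[:3]}")


def test_recall(labels: pd.Series, test_set: TestSet) -> float:
    """Fraction of the relevant test ids labeled positive."""
    _check_coverage(labels, test_set)
    rel = list(test_set.relevant_ids)
    return float(labels.loc[rel].sum()) / len(rel)


def high_priority_recall(labels: pd.Series, test_set: TestSet) -> float:
    """Recall restricted to the high-confidence subset."""
    if not test_set.high_confidence_ids:
        raise ValueError("high-confidence subset is empty")
    _check_coverage(labels, test_set)
    hi = list(test_set.high_confidence_ids)
    return float(labels.loc[hi].sum()) / len(hi)


def evaluate(score_table: pd.DataFrame, cfg: ThresholdConfig, test_set: TestSet) -> EvaluationReport:
    res = classify_corpus(score_table, cfg)
    return EvaluationReport(
        config=cfg,
        test_recall=test_recall(res.labels, test_set),
        high_priority_recall=high_priority_recall(res.labels, test_set),
        positive_rate=res.positive_rate,
    )


def _rank_key(r: EvaluationReport):
    return (
        r.positive_rate,
        -r.high_priority_recall,
        -r.test_recall,
        len(r.config.clauses),
        r.config.canonical(),
    )


def grid_search(score_table: pd.DataFrame, test_set: TestSet,
                templates: Sequence[ConfigTemplate], grid: GridSpec) -> list[EvaluationReport]:
    """Evaluate every template at every grid point; return the feasible
    frontier (Test Recall >= ``grid.min_test_recall``) ranked by ascending
    Positive Rate with deterministic tie-breaking.

    An infeasible constraint returns an empty ranking with a warning rather
    than raising: an empty frontier is a legitimate finding.

    The inner loop over the final clause's grid is vectorized; recall and
    positive-rate counts come from boolean index arithmetic, so a full
    2-clause 101x101 grid over a 1e5-document table evaluates in seconds.
    """
    n_docs = len(score_table)
    if n_docs == 0:
        raise ValueError("score table is empty")
    for doc_id in test_set.relevant_ids:
        if doc_id not in score_table.index:
            raise KeyError(f"test id {doc_id!r} missing from score table")

    idx = {d: i for i, d in enumerate(score_table.index)}
    rel_idx = np.fromiter((idx[d] for d in sorted(test_set.relevant_ids)), dtype=int)
    hi_idx = np.fromiter((idx[d] for d in sorted(test_set.high_confidence_ids)), dtype=int) \
        if test_set.high_confidence_ids else np.array([], dtype=int)
    if hi_idx.size == 0:
        raise ValueError("high-confidence subset is empty")

    reports: list[EvaluationReport] = []
    for tmpl in templates:
        arrays = []
        grids = []
        for name in tmpl.score_names:
            if name not in score_table.columns:
                raise KeyError(f"score component {name!r} missing from score table")
            arrays.append(score_table[name].to_numpy())
            grids.append(grid.thresholds(name))
        last_arr, last_grid = arrays[-1], grids[-1]
        # docs x thresholds mask for the vectorized final clause
        last_mask = last_arr[:, None] >= last_grid[None, :]
        outer_grids = grids[:-1]
        for combo in product(*(range(g.size) for g in outer_grids)):
            base = np.zeros(n_docs, dtype=bool)
            for arr, g, j in zip(arrays[:-1], outer_grids, combo):
                base |= arr >= g[j]
            pos = base[:, None] | last_mask
            n_pos = pos.sum(axis=0)
            rel_caught = pos[rel_idx].sum(axis=0)
            hi_caught = pos[hi_idx].sum(axis=0)
            tr = rel_caught / rel_idx.size
            feasible = np.nonzero(tr >= grid.min_test_recall)[0]
            for j in feasible:
                thresholds = [grids[k][combo[k]] for k in range(len(combo))] + [last_grid[j]]
                reports.append(EvaluationReport(
                    config=tmpl.bind(thresholds),
                    test_recall=float(tr[j]),
                    high_priority_recall=float(hi_caught[j]) / hi_idx.size,
                    positive_rate=float(n_pos[j]) / n_docs,
                ))
    if not reports:
        warnings.warn("no configuration meets the Test Recall constraint; empty ranking")
    return sorted(reports, key=_rank_key)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def error_correlation(per_method_labels: Mapping[str, pd.Series], test_set: TestSet,
                      mode: str = "errors",
                      score_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pairwise correlation of per-method behaviour on the test set.

    ``mode='errors'`` (default) correlates binary miss indicators over the
    relevant test ids (every test document is a known positive, so an error
    is a miss); for binary vectors Pearson correlation is the phi
    coefficient. ``mode='scores'`` correlates the raw score columns named by
    the method keys instead (requires ``score_table``). A zero-variance
    vector makes its pairs undefined: those entries are NaN and flagged with
    a warning.
    """
    methods = list(per_method_labels)
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    rel = sorted(test_set.relevant_ids)
    if mode == "errors":
        vectors = []
        for m in methods:
            labels = per_method_labels[m]
            _check_coverage(labels, test_set)
            vectors.append((~labels.loc[rel].astype(bool)).to_numpy(dtype=float))
    elif mode == "scores":
        if score_table is None:
            raise ValueError("mode='scores' requires score_table")
        vectors = [score_table.loc[rel, m].to_numpy(dtype=float) for m in methods]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    X = np.vstack(vectors)
    stds = X.std(axis=1)
    out = np.eye(len(methods))
    degenerate = [m for m, s in zip(methods, stds) if s == 0]
    if degenerate:
        warnings.warn(f"zero-variance vector(s) for {degenerate}; correlations undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                if stds[i] == 0 or stds[j] == 0:
                    out[i, j] = out[j, i] = np.nan
                else:
                    out[i, j] = out[j, i] = float(np.corrcoef(X[i], X[j])[0, 1])
    return pd.DataFrame(out, index=methods, columns=methods)


@dataclass(frozen=True)
class ScoreDistributionSummary:
    """Where a threshold sits relative to the corpus score distribution."""

    score_name: str
    mean: float
    std: float  # population standard deviation
    threshold: float
    z_position: float  # (threshold - mean) / std; NaN when undefined
    undefined: bool = False


def sigma_position(score_table: pd.DataFrame, score_name: str,
                   threshold: float) -> ScoreDistributionSummary:
    """Threshold position in population-sigma units above the corpus mean.

    Extreme positive z-positions indicate the classifier fires only on the
    far upper tail of the score distribution.
    """
    if len(score_table) < 2:
        raise ValueError("need at least two documents")
    values = score_table[score_name].to_numpy(dtype=float)
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if sigma == 0:
        warnings.warn(f"zero variance for {score_name!r}; sigma position undefined")
        return ScoreDistributionSummary(score_name, mu, 0.0, threshold, float("nan"), True)
    return ScoreDistributionSummary(score_name, mu, sigma, threshold, (threshold - mu) / sigma)
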