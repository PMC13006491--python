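"""Recall metrics, grid-search correctness vs exhaustive oracle, diagnostics."""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest

import regfed as rf
from conftest import random_score_table


def _labels(df, positive_ids):
    return pd.Series([i in positive_ids for i in df.index], index=df.index)


class TestRecallMetrics:
    def setup_method(self):
        self.ids = [f"d{i:04d}" for i in range(200)]
        self.df = random_score_table(np.random.default_rng(5), 200)
        self.relevant = frozenset(self.ids[:40])
        self.high = frozenset(self.ids[:10])
        self.ts = rf.TestSet(self.relevant, self.high)

    def test_all_caught_and_none_caught(self):
        assert rf.test_recall(_labels(self.df, set(self.ids)), self.ts) == 1.0
        assert rf.test_recall(_labels(self.df, set()), self.ts) == 0.0

    def test_counting_oracle(self, rng):
        caught = set(list(self.relevant)[:31])
        assert rf.test_recall(_labels(self.df, caught), self.ts) == 31 / 40
        hi_caught = set(list(self.high)[:7]) | caught
        labels = _labels(self.df, hi_caught)
        assert rf.high_priority_recall(labels, self.ts) == pytest.approx(
            len(hi_caught & self.high) / 10)

    def test_high_subset_independent_of_rest(self):
        labels = _labels(self.df, self.high)  # only high-confidence caught
        assert rf.high_priority_recall(labels, self.ts) == 1.0
        assert rf.test_recall(labels, self.ts) < 1.0

    def test_degenerate_subset_equals_test_recall(self):
        ts = rf.TestSet(self.relevant, self.relevant)
        labels = _labels(self.df, set(list(self.relevant)[:13]))
        assert rf.high_priority_recall(labels, ts) == rf.test_recall(labels, ts)

    def test_missing_test_id_fatal(self):
        ts = rf.TestSet(frozenset({"ghost"}), frozenset())
        with pytest.raises((KeyError, ValueError)):
            rf.test_recall(_labels(self.df, set()), ts)

    def test_high_ids_must_be_subset(self):
        with pytest.raises(ValueError):
            rf.TestSet(frozenset({"a"}), frozenset({"b"}))


def _brute_force_grid_search(df, ts, templates, grid):
    """Exhaustive pure-Python re-evaluation of every grid point."""
    reports = []
    for tmpl in templates:
        grids = [list(grid.thresholds(n)) for n in tmpl.score_names]
        for combo in product(*grids):
            cfg = tmpl.bind(combo)
            labels = pd.Series(
                [any(df.loc[i, n] >= t for n, t in cfg.clauses) for i in df.index],
                index=df.index)
            tr = sum(labels[i] for i in ts.relevant_ids) / len(ts.relevant_ids)
            if tr < grid.min_test_recall:
                continue
            reports.append(rf.EvaluationReport(
                config=cfg, test_recall=tr,
                high_priority_recall=sum(labels[i] for i in ts.high_confidence_ids)
                / len(ts.high_confidence_ids),
                positive_rate=labels.sum() / len(labels),
            ))
    return sorted(reports, key=lambda r: (
        r.positive_rate, -r.high_priority_recall, -r.test_recall,
        len(r.config.clauses), r.config.canonical()))


class TestGridSearch:
    def _setup(self, n=120, seed=11):
        rng = np.random.default_rng(seed)
        df = random_score_table(rng, n)
        ids = list(df.index)
        ts = rf.TestSet(frozenset(ids[:30]), frozenset(ids[:8]))
        return df, ts

    def test_matches_exhaustive_oracle_including_tie_order(self):
        """Optimizer ranking equals brute-force enumeration on a 2x21 grid."""
        df, ts = self._setup()
        templates = [rf.ConfigTemplate(("ai_keyword_combined_score", "avg_ref_score")),
                     rf.ConfigTemplate(("ai_keyword_combined_score",)),
                     rf.ConfigTemplate(("avg_ref_score",))]
        grid = rf.GridSpec(default_grid=(0.0, 1.0, 0.05), min_test_recall=0.70)
        got = rf.grid_search(df, ts, templates, grid)
        expected = _brute_force_grid_search(df, ts, templates, grid)
        assert len(got) == len(expected) > 0
        for g, e in zip(got, expected):
            assert g.config.clauses == e.config.clauses
            assert g.test_recall == pytest.approx(e.test_recall)
            assert g.high_priority_recall == pytest.approx(e.high_priority_recall)
            assert g.positive_rate == pytest.approx(e.positive_rate)

    def test_unconstrained_limit_returns_global_minimum_positive_rate(self):
        df, ts = self._setup()
        grid = rf.GridSpec(default_grid=(0.0, 1.0, 0.1), min_test_recall=0.0)
        best = rf.grid_search(df, ts, [rf.ConfigTemplate(("ideal_score",))], grid)[0]
        rates = [rf.classify_corpus(df, rf.ConfigTemplate(("ideal_score",)).bind([t])).positive_rate
                 for t in grid.thresholds("ideal_score")]
        assert best.positive_rate == min(rates)

    def test_infeasible_bound_yields_empty_ranking_with_warning(self):
        df, ts = self._setup()
        grid = rf.GridSpec(default_grid=(0.0, 1.0, 0.5), min_test_recall=1.01)
        with pytest.warns(UserWarning, match="constraint"):
            assert rf.grid_search(df, ts, [rf.ConfigTemplate(("ideal_score",))], grid) == []

    def test_enumeration_order_invariance(self):
        df, ts = self._setup()
        grid = rf.GridSpec(default_grid=(0.0, 1.0, 0.1), min_test_recall=0.5)
        t1 = [rf.ConfigTemplate(("ai_keyword_combined_score", "avg_ref_score"))]
        t2 = [rf.ConfigTemplate(("avg_ref_score", "ai_keyword_combined_score"))]
        r1 = rf.grid_search(df, ts, t1, grid)
        r2 = rf.grid_search(df, ts, t2, grid)
        assert [sorted(r.config.clauses) for r in r1] == [sorted(r.config.clauses) for r in r2]

    def test_returned_metrics_recompute_exactly(self):
        df, ts = self._setup()
        grid = rf.GridSpec(default_grid=(0.0, 1.0, 0.05), min_test_recall=0.70)
        best = rf.grid_search(df, ts, [rf.ConfigTemplate(
            ("ai_keyword_combined_score", "avg_ref_score"))], grid)[0]
        res = rf.classify_corpus(df, best.config)
        assert rf.test_recall(res.labels, ts) == best.test_recall
        assert rf.high_priority_recall(res.labels, ts) == best.high_priority_recall
        assert res.positive_rate == best.positive_rate

    def test_empty_grid_fatal(self):
        df, ts = self._setup()
        grid = rf.GridSpec(grids={"ideal_score": (0.0, 1.0, -0.1)})
        with pytest.raises(ValueError):
            rf.grid_search(df, ts, [rf.ConfigTemplate(("ideal_score",))], grid)


class TestErrorCorrelation:
    def _mk(self, df, ts, miss_sets):
        return {name: _labels(df, set(df.index) - set(misses))
                for name, misses in miss_sets.items()}

    def test_identical_methods_correlate_perfectly(self):
        df = random_score_table(np.random.default_rng(1), 60)
        ids = list(df.index)
        ts = rf.TestSet(frozenset(ids[:20]), frozenset(ids[:5]))
        labels = self._mk(df, ts, {"m1": ids[:7], "m2": ids[:7]})
        mat = rf.error_correlation(labels, ts)
        assert mat.loc["m1", "m2"] == pytest.approx(1.0)
        assert (np.diag(mat) == 1.0).all()

    def test_independent_errors_correlate_near_zero(self):
        rng = np.random.default_rng(99)
        n = 10_000
        ids = [f"d{i}" for i in range(n)]
        ts = rf.TestSet(frozenset(ids), frozenset(ids[:10]))
        df = pd.DataFrame(index=pd.Index(ids, name="doc_id"))
        labels = {
            "m1": pd.Series(rng.random(n) > 0.3, index=df.index),
            "m2": pd.Series(rng.random(n) > 0.3, index=df.index),
        }
        r = rf.error_correlation(labels, ts).loc["m1", "m2"]
        assert abs(r) < 3.0 / np.sqrt(n)  # three sigma of the null

    def test_phi_matches_contingency_table_closed_form(self):
        # hand-built 2x2 table over 20 test docs: a=4 both miss, b=6, c=2, d=8
        ids = [f"d{i}" for i in range(20)]
        ts = rf.TestSet(frozenset(ids), frozenset(ids[:2]))
        m1_miss = set(ids[:10])            # misses: first 10
        m2_miss = set(ids[:4]) | set(ids[10:12])
        labels = {
            "m1": pd.Series([i not in m1_miss for i in ids], index=ids),
            "m2": pd.Series([i not in m2_miss for i in ids], index=ids),
        }
        a = len(m1_miss & m2_miss)
        b = len(m1_miss - m2_miss)
        c = len(m2_miss - m1_miss)
        d = 20 - a - b - c
        phi = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
        got = rf.error_correlation(labels, ts).loc["m1", "m2"]
        assert got == pytest.approx(phi, abs=1e-12)

    def test_zero_variance_flagged_nan(self):
        ids = [f"d{i}" for i in range(10)]
        ts = rf.TestSet(frozenset(ids), frozenset(ids[:1]))
        labels = {
            "m1": pd.Series(True, index=ids),   # no errors at all
            "m2": pd.Series([i not in ids[:3] for i in ids], index=ids),
        }
        with pytest.warns(UserWarning, match="zero-variance"):
            mat = rf.error_correlation(labels, ts)
        assert np.isnan(mat.loc["m1", "m2"])


class TestSigmaPosition:
    def test_two_point_distribution(self):
        df = pd.DataFrame({"ideal_score": [0.0, 1.0]},
                          index=pd.Index(["a", "b"], name="doc_id"))
        s = rf.sigma_position(df, "ideal_score", 1.0)
        assert (s.mean, s.std, s.z_position) == (0.5, 0.5, 1.0)

    def test_degenerate_all_equal_flagged(self):
        df = pd.DataFrame({"ideal_score": [0.3] * 5},
                          index=pd.Index(list("abcde"), name="doc_id"))
        with pytest.warns(UserWarning):
            s = rf.sigma_position(df, "ideal_score", 0.5)
        assert s.undefined and np.isnan(s.z_position)

    def test_normal_sample_two_sigma_threshold(self, rng):
        x = rng.normal(0.4, 0.1, size=5000)
        df = pd.DataFrame({"avg_ref_score": x},
                          index=pd.Index([f"d{i}" for i in range(5000)], name="doc_id"))
        theta = float(x.mean() + 2 * x.std(ddof=0))
        s = rf.sigma_position(df, "avg_ref_score", theta)
        assert s.z_position == pytest.approx(2.0, abs=1e-9)
        assert s.mean == pytest.approx(float(x.mean()), abs=1e-12)
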