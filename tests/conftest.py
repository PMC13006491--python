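"""Shared fixtures: one small scored synthetic corpus reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

import regfed as rf


@pytest.fixture(scope="session")
def backend() -> rf.HashedEmbeddingBackend:
    return rf.HashedEmbeddingBackend()


@pytest.fixture(scope="session")
def refs(backend) -> rf.ReferenceSet:
    return rf.ReferenceSet.build(
        rf.generate_reference_documents(), rf.DEFAULT_TAXONOMY, backend
    )


@pytest.fixture(scope="session")
def labeled_corpus() -> rf.LabeledCorpus:
    return rf.generate_corpus(rf.GeneratorParams(n_docs=600, seed=7))


@pytest.fixture(scope="session")
def score_table(labeled_corpus, refs, backend):
    return rf.score_corpus(labeled_corpus.corpus, refs, rf.DEFAULT_TAXONOMY, backend)


@pytest.fixture(scope="session")
def truth_test_set(labeled_corpus) -> rf.TestSet:
    rel = labeled_corpus.relevant_ids
    high = frozenset(labeled_corpus.explicit_ids & rel) or rel
    return rf.TestSet(rel, high)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def random_score_table(rng: np.random.Generator, n: int):
    """A random but valid score table (invariants respected)."""
    import pandas as pd

    sims = rng.uniform(-0.2, 0.9, size=(n, 5))
    kw = rng.uniform(0, 1, size=(n, 3))
    df = pd.DataFrame({
        "avg_ref_score": sims.mean(axis=1),
        "max_ref_score": sims.max(axis=1),
        "ideal_score": rng.uniform(-0.5, 1.0, size=n),
        "kw_ai": kw[:, 0],
        "kw_legal": kw[:, 1],
        "kw_biomed": kw[:, 2],
        "ai_keyword_combined_score": kw.mean(axis=1),
    }, index=pd.Index([f"d{i:04d}" for i in range(n)], name="doc_id"))
    return df
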