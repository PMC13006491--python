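"""Per-document scoring: embedding similarity to a reference set and
keyword-taxonomy coverage.

Two complementary signals drive AI-relevance triage of regulatory text:

* **Semantic similarity** — each document is embedded and compared (cosine)
  against a curated reference set of exemplar AI-regulatory documents plus
  one synthetic "ideal" document built by concatenating the whole keyword
  taxonomy. The reference set yields an average and a maximum similarity;
  the ideal document yields a separate score.
* **Keyword coverage** — saturating weighted coverage of three terminology
  domains (AI, legal/regulatory, biomedical), combined into a single
  ``ai_keyword_combined_score`` on [0, 1].

The embedding backend is pluggable behind a determinism contract (same text,
same vector). The default backend hashes token unigrams/bigrams into a fixed
vector space (sub-linear tf, L2-normalised) — fully deterministic, no model
download, and fast enough to score 1e5-document corpora on one CPU. A
transformer sentence-embedding backend can be registered through the same
protocol where higher semantic fidelity is wanted.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.feature_extraction.text import HashingVectorizer

from .corpus_io import Corpus, Document

SCORE_COLUMNS = (
    "avg_ref_score",
    "max_ref_score",
    "ideal_score",
    "kw_ai",
    "kw_legal",
    "kw_biomed",
    "ai_keyword_combined_score",
)

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Normalise (NFKC, lowercase, strip punctuation) and whitespace-tokenize."""
    text = unicodedata.normalize("NFKC", text).lower()
    return [t for t in _TOKEN_RE.split(text) if t]


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddingVector:
    """A unit-norm embedding. ``is_zero`` flags the degenerate empty-text case."""

    values: sp.csr_matrix  # shape (1, dim)
    dim: int
    is_zero: bool = False

    def toarray(self) -> np.ndarray:
        return np.asarray(self.values.todense()).ravel()


class EmbeddingBackend(Protocol):
    name: str
    dim: int
    deterministic: bool

    def embed_many(self, texts: Sequence[str]) -> sp.csr_matrix: ...


class HashedEmbeddingBackend:
    """Deterministic hashed token/bigram embeddings.

    Token unigrams and bigrams are hashed into ``dim`` buckets, counts are
    sub-linearly scaled (1 + log tf) and the vector L2-normalised, so cosine
    similarity behaves like a per-document TF weighting without any
    corpus-level state — the same text always maps to the same vector.
    Long documents are truncated to the first ``max_tokens`` tokens.
    """

    deterministic = True

    def __init__(self, dim: int = 2**18, ngram_range: tuple[int, int] = (1, 2),
                 max_tokens: int = 5000):
        self.name = f"hashed-{dim}"
        self.dim = dim
        self.max_tokens = max_tokens
        self._vec = HashingVectorizer(
            n_features=dim,
            ngram_range=ngram_range,
            alternate_sign=False,
            norm=None,
            tokenizer=tokenize,
            preprocessor=lambda x: x,
            token_pattern=None,
        )

    def _truncate(self, text: str) -> str:
        toks = tokenize(text)
        return " ".join(toks[: self.max_tokens])

    def embed_many(self, texts: Sequence[str]) -> sp.csr_matrix:
        mat = self._vec.transform([self._truncate(t) for t in texts]).tocsr()
        mat.data = 1.0 + np.log(mat.data)
        norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=1)).ravel())
        inv = np.divide(1.0, norms, out=np.zeros_like(norms), where=norms > 0)
        return sp.diags(inv) @ mat


def embed(text: str, backend: EmbeddingBackend) -> EmbeddingVector:
    """Embed one text; empty text yields a flagged zero vector."""
    if not tokenize(text):
        return EmbeddingVector(sp.csr_matrix((1, backend.dim)), backend.dim, is_zero=True)
    try:
        row = backend.embed_many([text])
    except Exception as exc:  # pragma: no cover - backend failure path
        raise RuntimeError(f"embedding backend {backend.name!r} failed: {exc}") from exc
    return EmbeddingVector(row, backend.dim, is_zero=False)


def cosine_similarity(a: EmbeddingVector, b: EmbeddingVector) -> float:
    if a.dim != b.dim:
        raise ValueError(f"embedding dimension mismatch: {a.dim} != {b.dim}")
    return float((a.values @ b.values.T)[0, 0])


# ---------------------------------------------------------------------------
# Keyword taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeywordTaxonomy:
    """Three weighted term lists: AI, legal/regulatory, biomedical.

    Terms are lowercase phrases (one or more tokens); weights default to 1.
    """

    ai_terms: tuple[tuple[str, float], ...]
    legal_regulatory_terms: tuple[tuple[str, float], ...]
    biomedical_terms: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for name, terms in self.domains().items():
            if not terms:
                raise ValueError(f"taxonomy domain {name!r} is empty")
            phrases = [t for t, _ in terms]
            if len(set(phrases)) != len(phrases):
                raise ValueError(f"duplicate terms in domain {name!r}")
            if any(w <= 0 for _, w in terms):
                raise ValueError(f"non-positive weight in domain {name!r}")

    def domains(self) -> dict[str, tuple[tuple[str, float], ...]]:
        return {
            "ai": self.ai_terms,
            "legal": self.legal_regulatory_terms,
            "biomed": self.biomedical_terms,
        }

    @classmethod
    def from_lists(cls, ai: Iterable[str], legal: Iterable[str], biomed: Iterable[str]) -> "KeywordTaxonomy":
        mk = lambda terms: tuple((t.lower(), 1.0) for t in terms)
        return cls(mk(ai), mk(legal), mk(biomed))

    def all_phrases(self) -> list[str]:
        out = []
        for terms in (self.ai_terms, self.legal_regulatory_terms, self.biomedical_terms):
            out.extend(t for t, _ in terms)
        return out


#: Default terminology domains for AI-relevance triage of regulatory text.
DEFAULT_TAXONOMY = KeywordTaxonomy.from_lists(
    ai=[
        "artificial intelligence",
        "machine learning",
        "deep learning",
        "neural network",
        "algorithm",
        "algorithmic transparency",
        "natural language processing",
        "large language model",
        "generative model",
        "predictive model",
        "computer vision",
        "supervised learning",
        "unsupervised learning",
        "reinforcement learning",
        "training data",
        "model drift",
    ],
    legal=[
        "guidance",
        "regulation",
        "regulatory",
        "compliance",
        "framework",
        "policy",
        "oversight",
        "authorisation",
        "legislation",
        "directive",
        "statutory",
        "enforcement",
        "submission",
        "accountability",
        "harmonisation",
        "good practice",
    ],
    biomed=[
        "drug",
        "therapeutic",
        "clinical trial",
        "pharmacovigilance",
        "biologic",
        "medicinal product",
        "patient safety",
        "manufacturing",
        "medical device",
        "pharmaceutical",
        "dosage",
        "efficacy",
        "adverse event",
        "biomarker",
        "clinical development",
        "quality control",
    ],
)


def _count_phrase(tokens: list[str], positions: dict[str, list[int]], phrase: tuple[str, ...]) -> int:
    """Non-overlapping occurrences of a token phrase in a token sequence."""
    if len(phrase) == 1:
        return len(positions.get(phrase[0], ()))
    starts = positions.get(phrase[0], ())
    count = 0
    next_free = -1
    n = len(tokens)
    k = len(phrase)
    for i in starts:
        if i < next_free or i + k > n:
            continue
        if tuple(tokens[i:i + k]) == phrase:
            count += 1
            next_free = i + k
    return count


def keyword_counts(text: str, terms: Sequence[tuple[str, float]]) -> dict[str, int]:
    """Per-term non-overlapping case-insensitive match counts in normalized text."""
    tokens = tokenize(text)
    positions: dict[str, list[int]] = {}
    for i, t in enumerate(tokens):
        positions.setdefault(t, []).append(i)
    return {term: _count_phrase(tokens, positions, tuple(term.split())) for term, _ in terms}


def keyword_domain_score(text: str, domain_terms: Sequence[tuple[str, float]],
                         cap: int = 3) -> float:
    """Saturating weighted coverage of one terminology domain.

    score = sum_t w_t * min(c_t, C) / C  /  sum_t w_t, with c_t the
    non-overlapping match count of term t and C the saturation cap. Bounded
    on [0, 1], monotone in every count, and saturating — a single term
    repeated many times cannot dominate the domain.
    """
    if not domain_terms:
        raise ValueError("empty keyword domain")
    counts = keyword_counts(text, domain_terms)
    wsum = sum(w for _, w in domain_terms)
    return sum(w * min(counts[t], cap) / cap for t, w in domain_terms) / wsum


def combined_keyword_score(text: str, taxonomy: KeywordTaxonomy,
                           domain_weights: Sequence[float] = (1.0, 1.0, 1.0),
                           cap: int = 3) -> float:
    """Weighted mean of the three domain scores (AI, legal, biomedical)."""
    if len(domain_weights) != 3:
        raise ValueError("domain_weights must have exactly three entries")
    if sum(domain_weights) == 0:
        raise ValueError("domain_weights must not all be zero")
    scores = [
        keyword_domain_score(text, taxonomy.ai_terms, cap),
        keyword_domain_score(text, taxonomy.legal_regulatory_terms, cap),
        keyword_domain_score(text, taxonomy.biomedical_terms, cap),
    ]
    w = np.asarray(domain_weights, dtype=float)
    return float(np.dot(w, scores) / w.sum())


# ---------------------------------------------------------------------------
# Reference set
# ---------------------------------------------------------------------------

def build_synthetic_reference(taxonomy: KeywordTaxonomy,
                              doc_id: str = "synthetic-ideal") -> Document:
    """Construct the synthetic "ideal" anchor document.

    Its text is the deterministic concatenation of every taxonomy term in
    domain order (AI, legal/regulatory, biomedical; list order within each),
    acting as a generalized concept anchor for similarity scoring.
    """
    text = " ".join(taxonomy.all_phrases())
    return Document(
        doc_id=doc_id,
        agency="OTHER",
        title="Synthetic ideal reference (taxonomy concatenation)",
        category="synthetic",
        text=text,
    )


@dataclass
class ReferenceSet:
    """Exemplar documents (with precomputed embeddings) anchoring similarity.

    ``real_refs`` are curated agency documents; ``ideal_ref`` is the single
    synthetic taxonomy-concatenation document, never a member of
    ``real_refs``. Average/maximum reference similarity is computed over the
    real references only; the ideal contributes the separate ``ideal_score``.
    """

    real_refs: list[Document]
    ideal_ref: Document
    backend_name: str
    real_matrix: sp.csr_matrix
    ideal_vector: sp.csr_matrix
    version: str = "v1"

    def __post_init__(self) -> None:
        if not self.real_refs:
            raise ValueError("reference set needs at least one real reference")
        ids = [d.doc_id for d in self.real_refs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference doc_id")
        if self.ideal_ref.doc_id in ids:
            raise ValueError("ideal_ref must not appear among real_refs")

    def __len__(self) -> int:
        return len(self.real_refs)

    @classmethod
    def build(cls, real_refs: Sequence[Document], taxonomy: KeywordTaxonomy,
              backend: EmbeddingBackend, version: str = "v1") -> "ReferenceSet":
        ideal = build_synthetic_reference(taxonomy)
        mat = backend.embed_many([d.text for d in real_refs])
        ivec = backend.embed_many([ideal.text])
        return cls(list(real_refs), ideal, backend.name, mat, ivec, version)


def reference_scores(doc_vec: EmbeddingVector, refs: ReferenceSet) -> tuple[float, float, float]:
    """(average, maximum) cosine similarity to the real references and the
    similarity to the synthetic ideal."""
    if doc_vec.dim != refs.real_matrix.shape[1]:
        raise ValueError("embedding backend mismatch between document and reference set")
    sims = np.asarray((refs.real_matrix @ doc_vec.values.T).todense()).ravel()
    ideal = float((refs.ideal_vector @ doc_vec.values.T)[0, 0])
    return float(sims.mean()), float(sims.max()), ideal


# ---------------------------------------------------------------------------
# Corpus scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreVector:
    """All per-document scores the classifier consumes."""

    doc_id: str
    avg_ref_score: float
    max_ref_score: float
    ideal_score: float
    kw_ai: float
    kw_legal: float
    kw_biomed: float
    ai_keyword_combined_score: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SCORE_COLUMNS}


def score_corpus(corpus: Corpus, refs: ReferenceSet, taxonomy: KeywordTaxonomy,
                 backend: EmbeddingBackend,
                 domain_weights: Sequence[float] = (1.0, 1.0, 1.0),
                 cap: int = 3) -> pd.DataFrame:
    """Score every document; returns a DataFrame indexed by doc_id with
    columns :data:`SCORE_COLUMNS`. Deterministic given a deterministic
    backend and independent of corpus order (rows follow corpus order but
    per-id values do not depend on it)."""
    ids = corpus.doc_ids
    if not ids:
        return pd.DataFrame(columns=list(SCORE_COLUMNS)).rename_axis("doc_id")
    texts = [d.text for d in corpus]
    mat = backend.embed_many(texts)
    if mat.shape[1] != refs.real_matrix.shape[1]:
        raise ValueError("embedding backend mismatch between corpus and reference set")
    sims = (mat @ refs.real_matrix.T).toarray()  # n_docs x n_real
    ideal = np.asarray((mat @ refs.ideal_vector.T).todense()).ravel()

    w = np.asarray(domain_weights, dtype=float)
    if w.sum() == 0:
        raise ValueError("domain_weights must not all be zero")
    rows = []
    for i, doc in enumerate(corpus):
        try:
            ka = keyword_domain_score(doc.text, taxonomy.ai_terms, cap)
            kl = keyword_domain_score(doc.text, taxonomy.legal_regulatory_terms, cap)
            kb = keyword_domain_score(doc.text, taxonomy.biomedical_terms, cap)
        except Exception as exc:
            raise RuntimeError(f"keyword scoring failed for doc {doc.doc_id!r}: {exc}") from exc
        combined = float(np.dot(w, [ka, kl, kb]) / w.sum())
        rows.append((sims[i].mean(), sims[i].max(), ideal[i], ka, kl, kb, combined))
    df = pd.DataFrame(rows, index=pd.Index(ids, name="doc_id"), columns=list(SCORE_COLUMNS))
    return df


def score_vector(df: pd.DataFrame, doc_id: str) -> ScoreVector:
    row = df.loc[doc_id]
    return ScoreVector(doc_id, *(float(row[c]) for c in SCORE_COLUMNS))


def save_scores(df: pd.DataFrame, path) -> None:
    df.reset_index().to_json(path, orient="records", lines=True)


def load_scores(path) -> pd.DataFrame:
    return pd.read_json(path, orient="records", lines=True).set_index("doc_id")
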