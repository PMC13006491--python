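"""Labeled synthetic corpora with the statistical structure rare-event
regulatory triage assumes.

Real agency corpora are huge, undeposited, and expensive to label, so every
other module is exercised against generated corpora built from a token-
mixture model over four vocabulary pools:

* **regulatory boilerplate** — procedural/legal phrasing (overlapping the
  default legal/regulatory taxonomy domain),
* **biomedical filler** — therapeutic-area phrasing (overlapping the
  biomedical domain),
* **explicit AI terms** — the default AI taxonomy domain itself, so keyword
  scoring can fire,
* **contextual AI phrases** — AI discussed without canonical terminology;
  this pool is deliberately disjoint from the taxonomy, so such documents
  are invisible to keyword scoring and detectable only through reference
  similarity. This asymmetry is what makes OR-ensemble synergy reproducible
  by design.

Pool weights are set by the truth label (irrelevant / relevant-explicit /
relevant-implicit) with per-document Dirichlet jitter so score
distributions have realistic spread. A per-agency *style shift* swaps
boilerplate and contextual vocabulary for parallel "shifted-style" variants
at a given rate, emulating one agency's distinct drafting conventions — the
mechanism behind cross-agency classifier bias.

Everything is deterministic given the seed: same parameters, same corpus,
byte for byte.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import Corpus, Document
from .monitoring import SitemapSnapshot, SnapshotDiff, SnapshotEntry
from .optimization_evaluation import TestSet
from .scoring_engine import DEFAULT_TAXONOMY, KeywordTaxonomy, keyword_counts, tokenize

# ---------------------------------------------------------------------------
# Vocabulary pools
# ---------------------------------------------------------------------------

_LEGAL_TAXONOMY_PHRASES = tuple(t for t, _ in DEFAULT_TAXONOMY.legal_regulatory_terms)
_BIOMED_TAXONOMY_PHRASES = tuple(t for t, _ in DEFAULT_TAXONOMY.biomedical_terms)

REGULATORY_BOILERPLATE: tuple[str, ...] = _LEGAL_TAXONOMY_PHRASES + (
    "procedure", "annex", "applicant", "committee", "assessment", "consultation",
    "stakeholder", "public register", "inspection", "dossier", "variation",
    "renewal", "referral", "scientific opinion", "agenda", "meeting minutes",
    "publication", "revision", "draft document", "final version", "scope",
    "requirements", "documentation", "certificate", "application form",
)

BIOMEDICAL_FILLER: tuple[str, ...] = _BIOMED_TAXONOMY_PHRASES + (
    "formulation", "excipient", "batch release", "stability study", "indication",
    "posology", "contraindication", "immunogenicity", "bioequivalence",
    "pharmacokinetics", "toxicology", "sterility", "active substance",
    "orphan designation", "paediatric plan", "shelf life",
)

EXPLICIT_AI_TERMS: tuple[str, ...] = tuple(t for t, _ in DEFAULT_TAXONOMY.ai_terms)

#: AI discussed without canonical AI terminology — no phrase here matches a
#: term of the AI taxonomy domain, so keyword scoring cannot see these
#: documents as AI-related. Individual legal/biomedical tokens (compliance,
#: oversight, pharmacovigilance, ...) do occur, as they would in real
#: contextual AI regulatory prose, keeping the non-AI keyword profile of
#: implicit documents comparable to ordinary regulatory text.
CONTEXTUAL_AI_PHRASES: tuple[str, ...] = (
    "adaptive computational oversight", "data driven compliance analytics",
    "in silico efficacy prediction", "automated decision support",
    "self improving software", "computational pharmacovigilance screening",
    "digital triage of submission dossiers", "autonomous screening of adverse event reports",
    "pattern recognition in manufacturing", "computationally derived evidence",
    "continuously retrained enforcement tooling", "software that adapts its regulatory behaviour",
    "opaque computational pipelines", "automated signal detection for patient safety",
    "intelligent document processing for compliance", "emergent software behaviour under oversight",
)

#: Parallel shifted-style variants (index-aligned), emulating another
#: jurisdiction's drafting conventions.
REGULATORY_BOILERPLATE_SHIFTED: tuple[str, ...] = tuple(
    f"union {p}" if " " not in p else p.replace(" ", " harmonised ")
    for p in REGULATORY_BOILERPLATE
)
CONTEXTUAL_AI_SHIFTED: tuple[str, ...] = (
    "self calibrating oversight informatics", "calculation based compliance review",
    "in silico benefit risk estimation", "computerised decision assistance",
    "self optimising informatics", "informatic pharmacovigilance surveillance",
    "digital sorting of submission files", "autonomous review of adverse event notifications",
    "pattern matching in manufacturing", "computation derived evidence",
    "continuously updated enforcement informatics", "software adjusting its regulatory conduct",
    "non transparent computation chains", "automated vigilance for patient safety",
    "informatic dossier handling for compliance", "emergent informatic conduct under oversight",
)

_POOLS = (REGULATORY_BOILERPLATE, BIOMEDICAL_FILLER, EXPLICIT_AI_TERMS,
          CONTEXTUAL_AI_PHRASES)
_SHIFTED = {0: REGULATORY_BOILERPLATE_SHIFTED, 3: CONTEXTUAL_AI_SHIFTED}

#: Base pool weights (boilerplate, biomedical, explicit AI, contextual AI).
#: Irrelevant documents carry a trace of both AI pools (stray mentions of
#: "algorithm" or automation occur in mundane regulatory text); relevant
#: documents split into explicit-terminology and contextual-phrasing styles.
MIX_IRRELEVANT = (0.549, 0.43, 0.001, 0.02)
MIX_EXPLICIT = (0.34, 0.20, 0.26, 0.20)
MIX_IMPLICIT = (0.42, 0.30, 0.0, 0.28)

_DIRICHLET_CONCENTRATION = 60.0


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for a generated corpus.

    Defaults emulate a filtered multi-agency regulatory collection: ~3%
    AI-relevance prevalence, 60% of relevant documents using explicit AI
    terminology (the rest only contextual phrasing), an FDA-heavy agency
    mixture, English-dominant language metadata, and a 2019-2025 (July)
    publication window.
    """

    n_docs: int = 1000
    prevalence: float = 0.03
    frac_explicit: float = 0.6
    agency_weights: tuple[tuple[str, float], ...] = (("FDA", 0.72), ("EMA", 0.23), ("WHO", 0.05))
    style_shift: tuple[tuple[str, float], ...] = ()
    date_min: _dt.date = _dt.date(2019, 1, 1)
    date_max: _dt.date = _dt.date(2025, 7, 31)
    language_mix: tuple[tuple[str, float], ...] = (("en", 0.92), ("fr", 0.04), ("de", 0.04))
    category_mix: tuple[tuple[str, float], ...] = (
        ("guidance", 0.30), ("report", 0.25), ("notice", 0.20),
        ("administrative notice", 0.15), ("press release", 0.10),
    )
    length_range: tuple[int, int] = (140, 260)  # phrase draws per document
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 0:
            raise ValueError("n_docs must be non-negative")
        if not 0.0 <= self.prevalence < 1.0:
            raise ValueError("prevalence must be in [0, 1)")
        if not 0.0 <= self.frac_explicit <= 1.0:
            raise ValueError("frac_explicit must be in [0, 1]")
        for name, mix in (("agency_weights", self.agency_weights),
                          ("language_mix", self.language_mix),
                          ("category_mix", self.category_mix)):
            weights = [w for _, w in mix]
            if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must be non-negative and sum to 1")
        for agency, rate in self.style_shift:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"style_shift rate for {agency} must be in [0, 1]")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")

    @property
    def frac_implicit(self) -> float:
        return 1.0 - self.frac_explicit


@dataclass
class LabeledCorpus:
    """A generated corpus with ground truth and the parameters that made it."""

    corpus: Corpus
    truth: dict[str, str]  # doc_id -> "irrelevant" | "relevant"
    explicit_ids: frozenset[str]  # relevant docs carrying explicit AI terms
    params: GeneratorParams

    @property
    def relevant_ids(self) -> frozenset[str]:
        return frozenset(d for d, label in self.truth.items() if label == "relevant")

    @property
    def implicit_ids(self) -> frozenset[str]:
        return self.relevant_ids - self.explicit_ids


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _sample_mix(rng: np.random.Generator, mix: Sequence[tuple[str, float]], n: int) -> list[str]:
    names = [k for k, _ in mix]
    probs = np.array([w for _, w in mix], dtype=float)
    return [names[i] for i in rng.choice(len(names), size=n, p=probs / probs.sum())]


def _jitter(rng: np.random.Generator, base: Sequence[float]) -> np.ndarray:
    """Dirichlet jitter over the non-zero components of a base mixture."""
    base = np.asarray(base, dtype=float)
    out = np.zeros_like(base)
    nz = base > 0
    out[nz] = rng.dirichlet(base[nz] * _DIRICHLET_CONCENTRATION)
    return out


def _doc_text(rng: np.random.Generator, base_mix: Sequence[float], length: int,
              shift_rate: float) -> str:
    w = _jitter(rng, base_mix)
    pool_ids = rng.choice(4, size=length, p=w)
    phrases: list[str] = []
    for pid in pool_ids:
        pool = _POOLS[pid]
        j = int(rng.integers(len(pool)))
        phrase = pool[j]
        if pid in _SHIFTED:
            # draw unconditionally so documents of unshifted agencies are
            # byte-identical whatever other agencies' shift rates are
            if rng.random() < shift_rate:
                phrase = _SHIFTED[pid][j]
        phrases.append(phrase)
    return " ".join(phrases)


def generate_corpus(params: GeneratorParams) -> LabeledCorpus:
    """Draw a labeled corpus under the given study conditions.

    Deterministic given ``params.seed``: two calls with identical parameters
    produce byte-identical documents.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_docs
    shift = dict(params.style_shift)

    relevant_mask = rng.random(n) < params.prevalence
    explicit_mask = rng.random(n) < params.frac_explicit
    agencies = _sample_mix(rng, params.agency_weights, n)
    languages = _sample_mix(rng, params.language_mix, n)
    categories = _sample_mix(rng, params.category_mix, n)
    span_days = (params.date_max - params.date_min).days
    offsets = rng.integers(0, span_days + 1, size=n)
    lengths = rng.integers(params.length_range[0], params.length_range[1] + 1, size=n)

    docs: list[Document] = []
    truth: dict[str, str] = {}
    explicit_ids: set[str] = set()
    for i in range(n):
        doc_id = f"doc-{params.seed}-{i:06d}"
        if relevant_mask[i]:
            mix = MIX_EXPLICIT if explicit_mask[i] else MIX_IMPLICIT
            truth[doc_id] = "relevant"
            if explicit_mask[i]:
                explicit_ids.add(doc_id)
        else:
            mix = MIX_IRRELEVANT
            truth[doc_id] = "irrelevant"
        agency = agencies[i]
        text = _doc_text(rng, mix, int(lengths[i]), shift.get(agency, 0.0))
        docs.append(Document(
            doc_id=doc_id,
            agency=agency,
            url=f"https://example.org/{agency.lower()}/{doc_id}",
            title=f"{categories[i]} {doc_id}",
            publication_date=params.date_min + _dt.timedelta(days=int(offsets[i])),
            language=languages[i],
            category=categories[i],
            text=text,
        ))
    corpus = Corpus(docs, provenance=f"synthetic seed={params.seed} n={n}")
    return LabeledCorpus(corpus, truth, frozenset(explicit_ids), params)


# ---------------------------------------------------------------------------
# Test sets and reference documents
# ---------------------------------------------------------------------------

def explicit_term_density(text: str, taxonomy: KeywordTaxonomy = DEFAULT_TAXONOMY) -> float:
    """Occurrences of explicit AI taxonomy terms per document token."""
    tokens = tokenize(text)
    if not tokens:
        return 0.0
    counts = keyword_counts(text, taxonomy.ai_terms)
    return sum(counts.values()) / len(tokens)


def generate_test_set(lc: LabeledCorpus, n_relevant: int = 127, n_high: int = 38,
                      seed: int = 0, exclude_ids: Sequence[str] = (),
                      taxonomy: KeywordTaxonomy = DEFAULT_TAXONOMY) -> TestSet:
    """Sample a labeled test set from the generated truth.

    ``n_relevant`` relevant documents are sampled (excluding any reference
    ids) and the ``n_high`` among them with the highest explicit-AI term
    density are marked high-confidence — mirroring a two-tier manual review
    in which unambiguous documents use canonical terminology.
    """
    if n_high > n_relevant:
        raise ValueError("n_high cannot exceed n_relevant")
    pool = sorted(lc.relevant_ids - set(exclude_ids))
    if len(pool) < n_relevant:
        raise ValueError(f"only {len(pool)} relevant documents available, need {n_relevant}")
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=n_relevant, replace=False)]
    density = {d: explicit_term_density(lc.corpus.get(d).text, taxonomy) for d in chosen}
    high = sorted(chosen, key=lambda d: (-density[d], d))[:n_high]
    return TestSet(frozenset(chosen), frozenset(high))


def generate_reference_documents(n: int = 34, seed: int = 1234,
                                 style_agency: str = "FDA",
                                 style_shift_rate: float = 0.0) -> list[Document]:
    """Generate exemplar reference documents for similarity anchoring.

    Half are explicit-terminology heavy and half contextual-phrasing heavy,
    so reference similarity covers both ways AI surfaces in regulatory text.
    ``style_shift_rate`` applies the shifted-style vocabulary, for building
    exemplars in another agency's drafting conventions.
    """
    rng = np.random.default_rng(seed)
    docs = []
    for i in range(n):
        mix = MIX_EXPLICIT if i % 2 == 0 else MIX_IMPLICIT
        length = int(rng.integers(180, 320))
        text = _doc_text(rng, mix, length, style_shift_rate)
        docs.append(Document(
            doc_id=f"ref-{style_agency.lower()}-{seed}-{i:03d}",
            agency=style_agency,
            title=f"reference exemplar {i}",
            category="reference",
            text=text,
        ))
    return docs


def generate_snapshot_pair(lc: LabeledCorpus, n_new: int, n_updated: int,
                           seed: int = 0, source: str = "synthetic",
                           ) -> tuple[SitemapSnapshot, SitemapSnapshot, SnapshotDiff]:
    """Before/after sitemap snapshots with a diff known by construction.

    ``n_new`` documents are absent from the old snapshot; ``n_updated`` of
    the rest get a bumped last-modified timestamp in the new one.
    """
    ids = lc.corpus.doc_ids
    if n_new + n_updated > len(ids):
        raise ValueError("n_new + n_updated exceeds corpus size")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    new_ids = set(order[:n_new])
    updated_ids = set(order[n_new:n_new + n_updated])
    url = {d: lc.corpus.get(d).url for d in ids}

    old_entries = [SnapshotEntry(url[d], "2025-01-01T00:00:00") for d in ids if d not in new_ids]
    new_entries = [
        SnapshotEntry(url[d], "2025-02-01T00:00:00" if (d in updated_ids or d in new_ids)
                      else "2025-01-01T00:00:00")
        for d in ids
    ]
    old = SitemapSnapshot.from_entries(source, "2025-01-01T00:00:00", old_entries)
    new = SitemapSnapshot.from_entries(source, "2025-02-01T00:00:00", new_entries)
    expected = SnapshotDiff(frozenset(url[d] for d in new_ids),
                            frozenset(url[d] for d in updated_ids),
                            frozenset())
    return old, new, expected
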