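"""The inference cascade: retrieve K candidates, optionally expand with
prior known mappings, score pairs, threshold, pick a winner.

Mapping a variable proceeds in stages:

1. The query sentence (name + description) is embedded and the K reference
   terms nearest in Euclidean distance are retrieved (exact scan; CDMs are
   ~10^3 terms, no index needed).
2. Optionally, the comparison set is *enriched* with every prior known
   mapping (alias) of each candidate term: a new cohort's "cdr_sb" may look
   nothing like "Clinical Dementia Rating Scale Sum of Boxes (CDRSB)" but a
   lot like another cohort's "CDR_SOB".
3. The pair classifier scores (query, item) for every entry and enrichment;
   items below the probability threshold are eliminated.
4. Among survivors the winner maximizes ``W1 * probability +
   W2 * string_similarity`` (similarity of the query *name* against the
   candidate term or alias *name*). Ties go to the smaller embedding
   distance, then the lexicographically smaller term_id. A winning alias is
   resolved to its parent reference term by reversing the known mapping.
   No survivors means no match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cdm import CDM
from .config import HarmonizationConfig
from .fuzzy import normalized_similarity
from .models import PairClassifier, TripletEmbedder
from .text import build_sentence, embed_reference_terms

__all__ = [
    "CandidateRanking",
    "MatchResult",
    "get_candidates",
    "expand_with_prior_knowledge",
    "select_winner",
    "harmonize_variable",
    "harmonize_dictionary",
    "Harmonizer",
]


@dataclass
class CandidateRanking:
    """K candidate terms ordered by embedding distance, plus optional
    alias enrichments (alias sentence, alias name, parent term_id)."""

    query_sentence: str
    entries: list[tuple[str, float]]
    enrichments: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        dists = [d for _, d in self.entries]
        if any(b < a for a, b in zip(dists, dists[1:])):
            raise ValueError("ranking entries must be sorted by nondecreasing distance")

    @property
    def term_ids(self) -> list[str]:
        return [tid for tid, _ in self.entries]


@dataclass
class MatchResult:
    """Outcome of harmonizing one variable."""

    input_name: str
    input_description: str
    winner: str | None
    probability: float | None
    combined_score: float | None
    candidates: CandidateRanking | None
    status: str  # matched | no_match | error

    def __post_init__(self) -> None:
        if (self.status == "matched") != (self.winner is not None):
            raise ValueError("status 'matched' iff a winner is present")


def get_candidates(
    query: np.ndarray, term_vectors: dict[str, np.ndarray], K: int, query_sentence: str = ""
) -> CandidateRanking:
    """Exact K-nearest reference terms by Euclidean distance.

    Equivalent to a brute-force full sort; ties broken by lexicographic
    term_id. Returns min(K, number of terms) entries.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not term_vectors:
        raise RuntimeError("empty reference-term vector table")
    tids = sorted(term_vectors)
    M = np.vstack([term_vectors[t] for t in tids])
    dists = np.linalg.norm(M - np.asarray(query)[None, :], axis=1)
    order = sorted(range(len(tids)), key=lambda i: (dists[i], tids[i]))[:K]
    return CandidateRanking(
        query_sentence=query_sentence,
        entries=[(tids[i], float(dists[i])) for i in order],
    )


def expand_with_prior_knowledge(ranking: CandidateRanking, cdm: CDM) -> CandidateRanking:
    """Enrich a ranking with every prior known mapping (alias) of each
    candidate term. Entries are unchanged; the comparison set grows from K
    to K + Σ aliases."""
    enrichments = [
        (build_sentence(v.name, v.description), v.name, tid)
        for tid in ranking.term_ids
        for v in cdm.aliases_of(tid)
    ]
    return CandidateRanking(
        query_sentence=ranking.query_sentence,
        entries=list(ranking.entries),
        enrichments=enrichments,
    )


def select_winner(
    query_sentence: str,
    ranking: CandidateRanking,
    classifier: PairClassifier,
    cdm: CDM,
    config: HarmonizationConfig,
    query_name: str | None = None,
    query_description: str = "",
    encoder=None,
) -> MatchResult:
    """Threshold on match probability, blend with string similarity, pick
    the winner (see module docstring for the full rule)."""
    if not ranking.entries:
        raise ValueError("ranking must contain at least one candidate")
    name = query_name if query_name is not None else query_sentence

    # comparison items: (sentence, display name, parent term_id, embedding distance)
    items: list[tuple[str, str, str, float]] = [
        (build_sentence(cdm.terms[tid].name, cdm.terms[tid].description),
         cdm.terms[tid].name, tid, dist)
        for tid, dist in ranking.entries
    ]
    if ranking.enrichments:
        qvec = encoder.encode(query_sentence) if encoder is not None else None
        for sent, alias_name, parent in ranking.enrichments:
            dist = (
                float(np.linalg.norm(qvec - encoder.encode(sent)))
                if qvec is not None
                else np.inf
            )
            items.append((sent, alias_name, parent, dist))

    probs = classifier.score_pairs([query_sentence] * len(items), [s for s, *_ in items])

    # ties in combined score: lexicographic term_id, then smaller embedding
    # distance — matching the string baseline's tie rule so the degenerate
    # configuration (W1=0, W2=1, threshold 0, K=|terms|) reproduces it exactly
    best = None
    for (sent, disp, tid, dist), p in zip(items, probs):
        if p < config.threshold:
            continue
        combined = config.W1 * float(p) + config.W2 * normalized_similarity(name, disp)
        key = (-combined, tid, dist)
        if best is None or key < best[0]:
            best = (key, tid, float(p), combined)

    if best is None:
        return MatchResult(
            input_name=name,
            input_description=query_description,
            winner=None,
            probability=None,
            combined_score=None,
            candidates=ranking,
            status="no_match",
        )
    _, tid, p, combined = best
    return MatchResult(
        input_name=name,
        input_description=query_description,
        winner=tid,
        probability=p,
        combined_score=combined,
        candidates=ranking,
        status="matched",
    )


class Harmonizer(BaseEstimator):
    """End-to-end variable harmonizer against a common data model.

    ``fit(cdm)`` trains the pair classifier on generated positive/negative
    pairs and the triplet embedder on the CDM's mapping clusters, then
    caches the reference-term embedding index. ``predict`` maps variable
    names (plus optional descriptions) to reference term_ids;
    ``harmonize`` returns full :class:`MatchResult` objects.

    Parameters mirror :class:`~lexmap.config.HarmonizationConfig`; pass
    ``config=...`` or individual overrides.
    """

    def __init__(
        self,
        config: HarmonizationConfig | None = None,
        encoder=None,
        classifier: PairClassifier | None = None,
        embedder: TripletEmbedder | None = None,
    ):
        self.config = config
        self.encoder = encoder
        self.classifier = classifier
        self.embedder = embedder

    # -- fitting -----------------------------------------------------------

    def fit(self, cdm: CDM, y=None) -> "Harmonizer":
        from .pairs import (
            assign_class_weights,
            generate_negative_pairs,
            generate_positive_pairs,
            split_dataset,
        )

        cdm.validate()
        cfg = self.config or HarmonizationConfig()
        self.config_ = cfg
        self.cdm_ = cdm

        if self.classifier is not None and hasattr(self.classifier, "head_"):
            self.classifier_ = self.classifier
        else:
            positives = generate_positive_pairs(cdm, "all_combinations")
            negatives = generate_negative_pairs(cdm, len(positives), seed=cfg.seed)
            pairs = assign_class_weights(positives + negatives)
            split = split_dataset(pairs, seed=cfg.seed)
            clf = self.classifier or PairClassifier(
                encoder=self.encoder, d=cfg.embedding_dim, seed=cfg.seed
            )
            self.classifier_ = clf.fit(split.train)

        if self.embedder is not None and hasattr(self.embedder, "W_"):
            self.embedder_ = self.embedder
        else:
            emb = self.embedder or TripletEmbedder(
                base=self.encoder, d=cfg.embedding_dim, seed=cfg.seed
            )
            self.embedder_ = emb.fit(cdm)

        self.term_vectors_ = embed_reference_terms(cdm, self.embedder_)
        return self

    def with_config(self, config: HarmonizationConfig) -> "Harmonizer":
        """A harmonizer sharing this one's fitted models and index but using
        a different inference configuration (K, weights, threshold, prior
        knowledge). Training-time settings of ``config`` are ignored."""
        check_is_fitted(self, "term_vectors_")
        other = Harmonizer(config=config)
        other.config_ = config
        other.cdm_ = self.cdm_
        other.classifier_ = self.classifier_
        other.embedder_ = self.embedder_
        other.term_vectors_ = self.term_vectors_
        return other

    # -- inference ---------------------------------------------------------

    def harmonize(self, name: str, description: str = "") -> MatchResult:
        """Map one variable to a reference term (or no_match)."""
        check_is_fitted(self, "term_vectors_")
        if not name:
            raise ValueError("variable name must be non-empty")
        cfg = self.config_
        sentence = build_sentence(name, description)
        ranking = get_candidates(
            self.embedder_.encode(sentence), self.term_vectors_, cfg.K, sentence
        )
        if cfg.use_prior_knowledge:
            ranking = expand_with_prior_knowledge(ranking, self.cdm_)
        return select_winner(
            sentence,
            ranking,
            self.classifier_,
            self.cdm_,
            cfg,
            query_name=name,
            query_description=description,
            encoder=self.embedder_,
        )

    def harmonize_all(self, rows: Iterable[tuple[str, str]]) -> list[MatchResult]:
        """Harmonize a data dictionary; one result per row, order preserved.
        Rows with an empty name get an error-status result instead of
        aborting the batch."""
        out = []
        for name, description in rows:
            if not name:
                out.append(
                    MatchResult(
                        input_name="",
                        input_description=description,
                        winner=None,
                        probability=None,
                        combined_score=None,
                        candidates=None,
                        status="error",
                    )
                )
            else:
                out.append(self.harmonize(name, description))
        return out

    def predict(self, X: Sequence) -> list[str | None]:
        """Winner term_ids (None for no_match) for names or (name,
        description) rows."""
        rows = [(x, "") if isinstance(x, str) else (x[0], x[1]) for x in X]
        return [r.winner for r in self.harmonize_all(rows)]


def harmonize_variable(
    name: str,
    description: str,
    cdm: CDM,
    encoder,
    classifier: PairClassifier,
    config: HarmonizationConfig,
) -> MatchResult:
    """Functional form of :meth:`Harmonizer.harmonize` with pre-fitted
    components (``encoder`` is the fitted embedding model)."""
    h = Harmonizer(config=config, classifier=classifier, embedder=encoder)
    h.config_, h.cdm_ = config, cdm
    h.classifier_, h.embedder_ = classifier, encoder
    h.term_vectors_ = embed_reference_terms(cdm, encoder)
    return h.harmonize(name, description)


def harmonize_dictionary(
    rows: Sequence[tuple[str, str]],
    cdm: CDM,
    encoder,
    classifier: PairClassifier,
    config: HarmonizationConfig,
) -> list[MatchResult]:
    """Functional batch form of :meth:`Harmonizer.harmonize_all`."""
    if not rows:
        raise ValueError("rows must be non-empty")
    h = Harmonizer(config=config, classifier=classifier, embedder=encoder)
    h.config_, h.cdm_ = config, cdm
    h.classifier_, h.embedder_ = classifier, encoder
    h.term_vectors_ = embed_reference_terms(cdm, encoder)
    return h.harmonize_all(rows)
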