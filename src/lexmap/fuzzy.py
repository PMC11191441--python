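"""Levenshtein fuzzy matching and the string-matching baseline.

Cohort variable names often differ from reference terms only by case,
punctuation, or small spelling variations ("AGE" vs "age_at_visit"), so a
normalized edit-distance similarity is a useful signal on its own and as
the W2 component of the blended score. Distances are computed with edlib;
comparison is case-insensitive (names differ mainly by case and underscore
conventions) and per Unicode code point, with similarity normalized by the
longer string's length.
"""

from __future__ import annotations

import edlib

from .cdm import CDM

__all__ = [
    "levenshtein_distance",
    "normalized_similarity",
    "combine_scores",
    "string_match_baseline",
]


def levenshtein_distance(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions turning ``a`` into ``b``. Case-sensitive; empty strings
    allowed."""
    if not a or not b:
        return len(a) + len(b)
    return edlib.align(a, b, task="distance")["editDistance"]


def normalized_similarity(a: str, b: str) -> float:
    """Case-insensitive similarity 1 - d(lower(a), lower(b)) / max(|a|, |b|).

    Equals 1 iff the case-folded strings are equal (including both empty),
    0 when exactly one string is empty.
    """
    a, b = a.lower(), b.lower()
    if not a and not b:
        return 1.0
    return 1.0 - levenshtein_distance(a, b) / max(len(a), len(b))


def combine_scores(p_model: float, s_string: float, W1: float, W2: float) -> float:
    """Blend of classifier probability and string similarity:
    ``W1 * p_model + W2 * s_string``."""
    for name, v in (("p_model", p_model), ("s_string", s_string), ("W1", W1), ("W2", W2)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return W1 * p_model + W2 * s_string


def string_match_baseline(name: str, cdm: CDM, use_aliases: bool = False):
    """Naive baseline: map ``name`` to the reference term whose name (or, when
    ``use_aliases``, any alias name, resolved to its parent) maximizes
    :func:`normalized_similarity`. Never abstains. Ties go to the higher
    similarity, then the lexicographically smaller term_id.
    """
    from .retrieval import CandidateRanking, MatchResult  # local: avoid cycle

    if not name:
        raise ValueError("name must be non-empty")
    if not cdm.terms:
        raise ValueError("CDM has no reference terms")

    best_tid, best_sim = None, -1.0
    scored: list[tuple[str, float]] = []
    for tid in sorted(cdm.terms):
        sim = normalized_similarity(name, cdm.terms[tid].name)
        if use_aliases:
            for alias in cdm.aliases_of(tid):
                sim = max(sim, normalized_similarity(name, alias.name))
        scored.append((tid, 1.0 - sim))  # dissimilarity, so the ranking sorts ascending
        if sim > best_sim:
            best_tid, best_sim = tid, sim

    ranking = CandidateRanking(
        query_sentence=name,
        entries=sorted(scored, key=lambda ts: (ts[1], ts[0])),
    )
    return MatchResult(
        input_name=name,
        input_description="",
        winner=best_tid,
        probability=None,
        combined_score=best_sim,
        candidates=ranking,
        status="matched",
    )
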