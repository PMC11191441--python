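"""Candidate retrieval, prior-knowledge expansion, winner selection."""

import numpy as np
import pytest

from lexmap import (
    CandidateRanking,
    HarmonizationConfig,
    expand_with_prior_knowledge,
    get_candidates,
    select_winner,
    string_match_baseline,
)


def brute_force_ranking(query, table, K):
    scored = sorted(
        ((tid, float(np.linalg.norm(np.asarray(v) - np.asarray(query)))) for tid, v in table.items()),
        key=lambda td: (td[1], td[0]),
    )
    return scored[:K]


class StubClassifier:
    """Fixed probabilities per candidate sentence."""

    def __init__(self, probs: dict[str, float], default: float = 0.0):
        self.probs = probs
        self.default = default

    def score_pairs(self, queries, candidates):
        return np.array([self.probs.get(c, self.default) for c in candidates])


def test_get_candidates_worked_example():
    table = {"A": np.array([0.0, 0.0]), "B": np.array([1.0, 0.0]), "C": np.array([0.0, 2.0])}
    r = get_candidates(np.array([0.9, 0.0]), table, K=2)
    assert r.term_ids == ["B", "A"]
    assert r.entries[0][1] == pytest.approx(0.1)
    assert r.entries[1][1] == pytest.approx(0.9)


def test_get_candidates_equals_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(2, 60))
        table = {f"T{i:03d}": rng.normal(size=8) for i in range(n)}
        query = rng.normal(size=8)
        for K in (1, 3, n, n + 10):
            got = get_candidates(query, table, K).entries
            expected = brute_force_ranking(query, table, K)
            assert [t for t, _ in got] == [t for t, _ in expected]
            np.testing.assert_allclose([d for _, d in got], [d for _, d in expected])


def test_get_candidates_tie_rule_and_errors():
    v = np.array([1.0, 1.0])
    table = {"B": v.copy(), "A": v.copy()}
    assert get_candidates(v, table, K=2).term_ids == ["A", "B"]
    with pytest.raises(RuntimeError):
        get_candidates(v, {}, K=1)
    with pytest.raises(ValueError):
        get_candidates(v, table, K=0)


def test_ranking_rejects_unsorted_entries():
    with pytest.raises(ValueError):
        CandidateRanking(query_sentence="q", entries=[("A", 0.5), ("B", 0.1)])


def test_expansion_counts(toy_cdm):
    # CDRSB has 3 aliases, AGE has 3: entries unchanged, enrichment = all aliases
    ranking = CandidateRanking(query_sentence="q", entries=[("CDRSB", 0.1), ("AGE", 0.2)])
    expanded = expand_with_prior_knowledge(ranking, toy_cdm)
    assert expanded.entries == ranking.entries
    assert len(expanded.enrichments) == 6
    parents = {p for *_, p in expanded.enrichments}
    assert parents == {"CDRSB", "AGE"}


def test_expansion_with_zero_aliases():
    from lexmap import CDM, ReferenceTerm

    cdm = CDM()
    cdm.add_term(ReferenceTerm(term_id="A", name="Age", modality="D"))
    ranking = CandidateRanking(query_sentence="q", entries=[("A", 0.0)])
    assert expand_with_prior_knowledge(ranking, cdm).enrichments == []


def _cfg(**kw):
    return HarmonizationConfig(**kw)


def test_select_winner_thresholds_then_picks_max(toy_cdm):
    ranking = CandidateRanking(
        query_sentence="q", entries=[("AGE", 0.1), ("EDU", 0.2), ("MMSE", 0.3)]
    )
    probs = {
        "Age Age of the participant in years": 0.8,
        "Years of Education Total years of formal schooling": 0.6,
        "Mini-Mental State Examination (MMSE) Mini mental state exam total": 0.3,
    }
    r = select_winner("q", ranking, StubClassifier(probs), toy_cdm, _cfg(W1=1.0, W2=0.0, threshold=0.5))
    assert r.winner == "AGE"
    assert r.probability == pytest.approx(0.8)
    assert r.status == "matched"


def test_select_winner_no_survivors(toy_cdm):
    ranking = CandidateRanking(query_sentence="q", entries=[("AGE", 0.1)])
    r = select_winner("q", ranking, StubClassifier({}, default=0.2), toy_cdm, _cfg(threshold=0.5))
    assert r.status == "no_match"
    assert r.winner is None and r.probability is None


def test_select_winner_reverse_maps_alias(toy_cdm):
    """A winning enrichment ('cdr_sb' alias) resolves to its parent CDRSB."""
    ranking = expand_with_prior_knowledge(
        CandidateRanking(query_sentence="cdr_sb", entries=[("CDRSB", 0.4), ("AGE", 0.5)]),
        toy_cdm,
    )
    probs = {"cdr_sb sum of boxes": 0.95}  # the alias sentence scores highest
    r = select_winner(
        "cdr_sb", ranking, StubClassifier(probs, default=0.6), toy_cdm, _cfg(threshold=0.5)
    )
    assert r.winner == "CDRSB"
    assert r.probability == pytest.approx(0.95)


def test_harmonize_identity_input(fitted_harmonizer, synthetic_cdm):
    """A reference term fed back as its own name+description maps to itself."""
    tid = sorted(synthetic_cdm.terms)[0]
    term = synthetic_cdm.terms[tid]
    r = fitted_harmonizer.harmonize(term.name, term.description)
    assert r.winner == tid
    assert r.candidates.entries[0][1] == pytest.approx(0.0, abs=1e-9)


def test_harmonize_determinism(fitted_harmonizer):
    r1 = fitted_harmonizer.harmonize("hippocampus volume left", "")
    r2 = fitted_harmonizer.harmonize("hippocampus volume left", "")
    assert (r1.winner, r1.probability, r1.combined_score) == (r2.winner, r2.probability, r2.combined_score)


def test_harmonize_rejects_empty_name(fitted_harmonizer):
    with pytest.raises(ValueError):
        fitted_harmonizer.harmonize("", "desc")


def test_harmonize_dictionary_order_and_error_rows(fitted_harmonizer):
    rows = [("age", ""), ("", "orphan description"), ("age", "")]
    results = fitted_harmonizer.harmonize_all(rows)
    assert len(results) == 3
    assert results[1].status == "error"
    assert results[0].winner == results[2].winner  # duplicated row, identical result
    assert results[0].probability == results[2].probability


def test_degenerate_weights_match_baseline(fitted_harmonizer, synthetic_cdm):
    """W1=0, W2=1, threshold 0, K=|terms|, no prior knowledge reproduces the
    string-matching baseline winner exactly."""
    cfg = HarmonizationConfig(
        K=len(synthetic_cdm.terms), W1=0.0, W2=1.0, threshold=0.0, seed=11, embedding_dim=64
    )
    degenerate = fitted_harmonizer.with_config(cfg)
    for name in ["mmse", "L_hippo_vol", "educ_yrs", "csf ab42"]:
        assert degenerate.harmonize(name).winner == string_match_baseline(name, synthetic_cdm).winner


def test_prior_knowledge_noop_without_aliases():
    from lexmap import CDM, Harmonizer, ReferenceTerm

    cdm = CDM()
    for i, (name, mod) in enumerate(
        [("Age", "D"), ("Sex", "D"), ("MMSE total", "C"), ("CDR sum", "C")]
    ):
        cdm.add_term(ReferenceTerm(term_id=f"T{i}", name=name, description="", modality=mod))
    # no aliases at all: classifier training impossible, so inject stubs
    cfg_on = HarmonizationConfig(K=2, threshold=0.0, use_prior_knowledge=True, embedding_dim=32)
    cfg_off = cfg_on.model_copy(update={"use_prior_knowledge": False})
    from lexmap import NgramEncoder, embed_reference_terms

    enc = NgramEncoder(d=32).fit()
    stub = StubClassifier({}, default=0.7)
    results = {}
    for label, cfg in [("on", cfg_on), ("off", cfg_off)]:
        h = Harmonizer(config=cfg)
        h.config_, h.cdm_, h.classifier_, h.embedder_ = cfg, cdm, stub, enc
        h.term_vectors_ = embed_reference_terms(cdm, enc)
        results[label] = [h.harmonize(q).winner for q in ["age", "sex", "mmse", "cdr"]]
    assert results["on"] == results["off"]
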