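"""Pair classifier and triplet embedder training contracts."""

import string

import numpy as np
import pytest

from lexmap import (
    DatasetSplit,
    LabeledPair,
    NgramEncoder,
    PairClassifier,
    TripletEmbedder,
    load_model,
    save_model,
    train_embedder,
    train_pair_classifier,
)
from lexmap.synthetic import SyntheticSpec, generate_cohort_variants, generate_reference_terms
from lexmap.text import build_sentence


def separable_pairs() -> list[LabeledPair]:
    """Positives duplicate a string; negatives join disjoint alphabets."""
    rng = np.random.default_rng(0)
    pos, neg = [], []
    for _ in range(20):
        s = "".join(rng.choice(list(string.ascii_lowercase[:10]), size=8))
        pos.append(LabeledPair(s, s, 1))
        a = "".join(rng.choice(list("abcde"), size=8))
        b = "".join(rng.choice(list("vwxyz"), size=8))
        neg.append(LabeledPair(a, b, 0))
    return pos + neg


def test_classifier_separates_toy_data():
    pairs = separable_pairs()
    clf = PairClassifier(d=128, seed=0).fit(pairs)
    acc = (clf.predict(pairs) == np.array([p.label for p in pairs])).mean()
    assert acc >= 0.95


def test_classifier_scores_in_unit_interval():
    clf = PairClassifier(d=64, seed=1).fit(separable_pairs())
    for a, b in [("age", "age"), ("age", "zzz"), ("Lhippo", "Rhippo")]:
        assert 0.0 <= clf.score(a, b) <= 1.0


def test_classifier_rejects_single_class_and_empty():
    ones = [LabeledPair(f"a{i}", f"b{i}", 1) for i in range(5)]
    with pytest.raises(ValueError):
        PairClassifier(d=32).fit(ones)
    with pytest.raises(ValueError):
        PairClassifier(d=32).fit([])


def test_classifier_uses_loss_weights():
    """Upweighting positives shifts the fit toward them: weighted log-loss on
    the positive class must not get worse."""
    rng = np.random.default_rng(3)
    pairs = []
    for i in range(30):
        s = f"var_{i:02d}"
        pairs.append(LabeledPair(s, s + "x", 1, 1.0))
        pairs.append(LabeledPair(s, f"other_{rng.integers(1000)}", 0, 1.0))
    heavy = [LabeledPair(p.sentence_a, p.sentence_b, p.label, 5.0 if p.label else 0.1) for p in pairs]
    clf_flat = PairClassifier(d=64, seed=0).fit(pairs)
    clf_heavy = PairClassifier(d=64, seed=0).fit(heavy)
    pos = [p for p in pairs if p.label == 1]
    assert clf_heavy.weighted_log_loss(pos) <= clf_flat.weighted_log_loss(pos) + 1e-9


def test_train_pair_classifier_wrapper():
    pairs = separable_pairs()
    split = DatasetSplit(train=pairs, test=[], validation=[])
    clf = train_pair_classifier(split)
    assert hasattr(clf, "head_")


def _margin(embedder, cdm, rng) -> float:
    """mean d(alias, other same-modality term) - mean d(alias, own term)."""
    term_sent = {tid: build_sentence(t.name, t.description) for tid, t in cdm.terms.items()}
    by_mod: dict[str, list[str]] = {}
    for tid in sorted(cdm.terms):
        by_mod.setdefault(cdm.terms[tid].modality, []).append(tid)
    own, other = [], []
    for tid in sorted(cdm.terms):
        peers = [t for t in by_mod[cdm.terms[tid].modality] if t != tid]
        if not peers:
            continue
        tvec = embedder.encode(term_sent[tid])
        for v in cdm.aliases_of(tid):
            avec = embedder.encode(build_sentence(v.name, v.description))
            own.append(np.linalg.norm(avec - tvec))
            ovec = embedder.encode(term_sent[peers[rng.integers(len(peers))]])
            other.append(np.linalg.norm(avec - ovec))
    return float(np.mean(other) - np.mean(own))


@pytest.mark.parametrize("seed", range(5))
def test_embedder_margin_positive_across_seeds(seed):
    """After training, aliases sit closer to their own term than to random
    same-modality competitors."""
    spec = SyntheticSpec(n_terms=50, n_cohorts=4, lateralized_fraction=0.2, seed=seed)
    cdm = generate_cohort_variants(generate_reference_terms(spec), spec)
    emb = TripletEmbedder(d=128, seed=seed).fit(cdm)
    assert _margin(emb, cdm, np.random.default_rng(seed)) > 0


def test_embedder_improves_on_init(synthetic_cdm):
    """Triplet training must not degrade the retrieval margin of the raw
    n-gram space, and the loss curve must be non-increasing overall."""
    init = TripletEmbedder(d=128, epochs=0, seed=11).fit(synthetic_cdm)
    trained = TripletEmbedder(d=128, epochs=30, seed=11).fit(synthetic_cdm)
    rng = np.random.default_rng(11)
    assert _margin(trained, synthetic_cdm, rng) >= _margin(init, synthetic_cdm, np.random.default_rng(11))
    assert trained.loss_curve_[-1] <= trained.loss_curve_[0]


def test_embedder_zero_epochs_is_identity(toy_cdm):
    emb = TripletEmbedder(d=64, epochs=0, seed=0).fit(toy_cdm)
    base = NgramEncoder(d=64, seed=0)
    for text in ["age", "MMSE Mini mental state exam total"]:
        np.testing.assert_array_equal(emb.encode(text), base.encode(text))


def test_embedder_seed_determinism(toy_cdm):
    e1 = TripletEmbedder(d=64, seed=5).fit(toy_cdm)
    e2 = TripletEmbedder(d=64, seed=5).fit(toy_cdm)
    np.testing.assert_array_equal(e1.W_, e2.W_)


def test_embedder_needs_two_terms():
    from lexmap import CDM, ReferenceTerm

    cdm = CDM()
    cdm.add_term(ReferenceTerm(term_id="A", name="Age", modality="D"))
    with pytest.raises(ValueError):
        train_embedder(cdm)


def test_model_archive_round_trip(tmp_path, toy_cdm):
    clf = PairClassifier(d=64, seed=2).fit(separable_pairs())
    emb = TripletEmbedder(d=64, seed=2).fit(toy_cdm)
    path = tmp_path / "model.zip"
    save_model(path, clf, emb)
    clf2, emb2 = load_model(path)
    assert clf2.score("age", "PTAGE") == pytest.approx(clf.score("age", "PTAGE"))
    np.testing.assert_array_equal(emb2.encode("age"), emb.encode("age"))
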