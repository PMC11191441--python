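"""Training-pair generation: positives, hard negatives, weights, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexmap import (
    CapacityError,
    LabeledPair,
    assign_class_weights,
    generate_negative_pairs,
    generate_positive_pairs,
    split_dataset,
)


def _cluster_sizes(cdm):
    return {tid: 1 + len(cdm.aliases_of(tid)) for tid in cdm.terms}


def test_positive_pair_counts(age_cdm):
    # one pair per mapping edge vs every unordered pair in {term} ∪ aliases
    assert len(generate_positive_pairs(age_cdm, "ref_to_variable")) == 4
    allc = generate_positive_pairs(age_cdm, "all_combinations")
    assert len(allc) == 10  # C(5, 2)
    assert all(p.label == 1 for p in allc)
    assert len({p.key for p in allc}) == 10


def test_positive_pairs_use_sentences(toy_cdm):
    pairs = generate_positive_pairs(toy_cdm, "ref_to_variable")
    sentences = {p.sentence_a for p in pairs} | {p.sentence_b for p in pairs}
    assert "PTAGE Age at baseline" in sentences  # name + ' ' + description


def test_zero_alias_term_yields_no_pairs():
    from lexmap import CDM, ReferenceTerm

    cdm = CDM()
    cdm.add_term(ReferenceTerm(term_id="A", name="Age", modality="Demographics"))
    assert generate_positive_pairs(cdm, "ref_to_variable") == []
    assert generate_positive_pairs(cdm, "all_combinations") == []


def test_negatives_respect_modality_and_term(toy_cdm):
    negatives = generate_negative_pairs(toy_cdm, 20, seed=3)
    assert len(negatives) == 20
    positives = {p.key for p in generate_positive_pairs(toy_cdm, "all_combinations")}

    # map every sentence back to (term, modality)
    sentence_info = {}
    from lexmap.pairs import _term_items

    for tid in toy_cdm.terms:
        for s in _term_items(toy_cdm, tid):
            sentence_info[s] = (tid, toy_cdm.terms[tid].modality)
    for n in negatives:
        ta, ma = sentence_info[n.sentence_a]
        tb, mb = sentence_info[n.sentence_b]
        assert ta != tb, "negative joins two items of the same reference term"
        assert ma == mb, "negative crosses modalities"
        assert n.key not in positives
        assert n.label == 0


def test_lateralized_pair_is_eligible_negative(toy_cdm):
    # exhaust the pool: the L/R hippocampus confusion pair must be drawable
    try:
        all_neg = generate_negative_pairs(toy_cdm, 10**6, seed=0)
    except CapacityError as exc:
        all_neg = generate_negative_pairs(toy_cdm, exc.available, seed=0)
    keys = {n.key for n in all_neg}
    assert any(
        any("Lhippo_FS_adj" in s for s in k) and any("Rhippo_FS_adj" in s for s in k)
        for k in keys
    )


def test_negative_capacity_error(age_cdm):
    # single term per modality: no valid negative exists
    with pytest.raises(CapacityError) as exc:
        generate_negative_pairs(age_cdm, 1, seed=0)
    assert exc.value.available == 0


def test_negative_determinism(synthetic_cdm):
    a = generate_negative_pairs(synthetic_cdm, 100, seed=5)
    b = generate_negative_pairs(synthetic_cdm, 100, seed=5)
    c = generate_negative_pairs(synthetic_cdm, 100, seed=6)
    assert a == b
    assert a != c


def test_class_weights():
    pairs = [LabeledPair("a", "b", 1), LabeledPair("c", "d", 0)]
    weighted = assign_class_weights(pairs)
    assert [p.weight for p in weighted] == [0.9, 0.1]
    unit = assign_class_weights(pairs, 1.0, 1.0)
    assert all(p.weight == 1.0 for p in unit)
    assert assign_class_weights([]) == []
    with pytest.raises(ValueError):
        assign_class_weights(pairs, 0.0, 0.9)


@pytest.mark.parametrize(
    "n,expected",
    [(100, (80, 4, 16)), (25, (20, 1, 4)), (0, (0, 0, 0))],
)
def test_split_sizes(n, expected):
    pairs = [LabeledPair(f"a{i}", f"b{i}", i % 2) for i in range(n)]
    split = split_dataset(pairs, (0.80, 0.04, 0.16), seed=1)
    assert (len(split.train), len(split.test), len(split.validation)) == expected


def test_split_bad_fractions():
    with pytest.raises(ValueError):
        split_dataset([], (0.5, 0.4, 0.2), seed=0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(n=st.integers(0, 200), seed=st.integers(0, 2**16))
def test_split_is_seeded_partition(n, seed):
    pairs = [LabeledPair(f"a{i}", f"b{i}", 1) for i in range(n)]
    s1 = split_dataset(pairs, seed=seed)
    s2 = split_dataset(pairs, seed=seed)
    assert [p.sentence_a for p in s1.train] == [p.sentence_a for p in s2.train]
    parts = [s1.train, s1.test, s1.validation]
    ids = [p.sentence_a for part in parts for p in part]
    assert sorted(ids) == sorted(f"a{i}" for i in range(n))  # partition, no loss
    assert len(set(ids)) == n


def test_pair_validation():
    with pytest.raises(ValueError):
        LabeledPair("a", "b", 2)
    with pytest.raises(ValueError):
        LabeledPair("", "b", 1)
    with pytest.raises(ValueError):
        LabeledPair("a", "b", 1, weight=0.0)
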