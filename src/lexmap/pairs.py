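"""Training-pair generation for the binary match-classification task.

The classifier learns to decide whether two variable sentences denote the
same measured concept. Positives join items (the reference term and its
aliases) that map to one another; hard negatives join items from the *same
modality* but *different* reference terms, because variables within a
modality share naming conventions and are the confusable cases — the model
must learn that "Lhippo_FS_adj" and "Rhippo_FS_adj" are different measures.

Class weights default to 0.1 for negatives and 0.9 for positives, and the
negative set is drawn to the same size as the positive set, giving a
balanced corpus with asymmetric loss.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .cdm import CDM
from .text import build_sentence

__all__ = [
    "LabeledPair",
    "DatasetSplit",
    "CapacityError",
    "generate_positive_pairs",
    "generate_negative_pairs",
    "assign_class_weights",
    "split_dataset",
    "pairs_to_csv",
]

DEFAULT_SPLIT_FRACTIONS = (0.80, 0.04, 0.16)  # train / test / validation
DEFAULT_WEIGHT_NEGATIVE = 0.1
DEFAULT_WEIGHT_POSITIVE = 0.9


class CapacityError(ValueError):
    """Not enough distinct eligible pairs to satisfy a request."""

    def __init__(self, requested: int, available: int):
        super().__init__(
            f"requested {requested} negative pairs but only {available} "
            f"distinct eligible pairs exist"
        )
        self.requested = requested
        self.available = available


@dataclass(frozen=True)
class LabeledPair:
    """Two variable sentences with a binary match label and a loss weight."""

    sentence_a: str
    sentence_b: str
    label: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if not self.sentence_a or not self.sentence_b:
            raise ValueError("pair sentences must be non-empty")

    @property
    def key(self) -> frozenset[str]:
        """Unordered sentence-pair identity used for deduplication."""
        return frozenset((self.sentence_a, self.sentence_b))


@dataclass
class DatasetSplit:
    """Disjoint train/test/validation partition of a pair corpus."""

    train: list[LabeledPair]
    test: list[LabeledPair]
    validation: list[LabeledPair]

    def __iter__(self):
        yield from (self.train, self.test, self.validation)


def _canonical(a: str, b: str, label: int) -> LabeledPair:
    # lexicographic emission order for determinism
    a, b = sorted((a, b))
    return LabeledPair(a, b, label)


def _term_items(cdm: CDM, term_id: str) -> list[str]:
    """Sentences of a term and all its aliases (the term's mapping cluster)."""
    term = cdm.terms[term_id]
    items = [build_sentence(term.name, term.description)]
    items += [build_sentence(v.name, v.description) for v in cdm.aliases_of(term_id)]
    return items


def generate_positive_pairs(
    cdm: CDM, mode: Literal["ref_to_variable", "all_combinations"] = "all_combinations"
) -> list[LabeledPair]:
    """Build label-1 pairs from the CDM's mapping clusters.

    ``ref_to_variable`` emits one (term, variable) pair per mapping edge;
    ``all_combinations`` emits every unordered pair within each term's
    cluster {term} ∪ aliases — C(1+|aliases|, 2) pairs per term.
    """
    pairs: list[LabeledPair] = []
    for tid in sorted(cdm.terms):
        items = _term_items(cdm, tid)
        if len(items) < 2:
            continue
        if mode == "ref_to_variable":
            ref = items[0]
            pairs += [_canonical(ref, alias, 1) for alias in items[1:]]
        elif mode == "all_combinations":
            pairs += [
                _canonical(items[i], items[j], 1)
                for i in range(len(items))
                for j in range(i + 1, len(items))
            ]
        else:
            raise ValueError(f"unknown positive-pair mode {mode!r}")
    return pairs


def generate_negative_pairs(cdm: CDM, n_required: int, seed: int = 0) -> list[LabeledPair]:
    """Sample label-0 hard negatives: same modality, different reference term.

    Sampling is uniform without replacement within each modality, with the
    per-modality quota proportional to that modality's positive-pair count
    (largest-remainder allocation, spillover when a modality's capacity is
    exhausted). No emitted negative duplicates a positive as an unordered
    sentence pair. Raises :class:`CapacityError` when fewer than
    ``n_required`` distinct eligible pairs exist.
    """
    if n_required == 0:
        return []
    positive_keys = {p.key for p in generate_positive_pairs(cdm, "all_combinations")}

    by_modality: dict[str, list[tuple[str, str]]] = {}  # modality -> [(term_id, sentence)]
    for tid in sorted(cdm.terms):
        m = cdm.terms[tid].modality
        for s in _term_items(cdm, tid):
            by_modality.setdefault(m, []).append((tid, s))

    # eligible pairs per modality: cross-term, not shadowing a positive
    eligible: dict[str, list[tuple[str, str]]] = {}
    for m, items in sorted(by_modality.items()):
        seen: set[frozenset[str]] = set()
        pool: list[tuple[str, str]] = []
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                t1, s1 = items[i]
                t2, s2 = items[j]
                if t1 == t2 or s1 == s2:
                    continue
                key = frozenset((s1, s2))
                if key in positive_keys or key in seen:
                    continue
                seen.add(key)
                pool.append(tuple(sorted((s1, s2))))
        if pool:
            eligible[m] = sorted(pool)

    total_capacity = sum(len(p) for p in eligible.values())
    if total_capacity < n_required:
        raise CapacityError(n_required, total_capacity)

    # per-modality positive counts drive the quota
    pos_counts = {}
    for tid in sorted(cdm.terms):
        k = len(_term_items(cdm, tid))
        m = cdm.terms[tid].modality
        pos_counts[m] = pos_counts.get(m, 0) + k * (k - 1) // 2
    modalities = sorted(eligible)
    weights = np.array([max(pos_counts.get(m, 0), 1) for m in modalities], dtype=float)
    raw = n_required * weights / weights.sum()
    quotas = np.floor(raw).astype(int)
    # largest remainders, ties by modality order
    order = np.argsort(-(raw - quotas), kind="stable")
    for idx in order[: n_required - quotas.sum()]:
        quotas[idx] += 1
    # clip to capacity and spill the shortfall round-robin
    caps = np.array([len(eligible[m]) for m in modalities])
    quotas = np.minimum(quotas, caps)
    while quotas.sum() < n_required:
        room = np.where(quotas < caps)[0]
        quotas[room[0]] += 1

    rng = np.random.default_rng(seed)
    out: list[LabeledPair] = []
    for m, q in zip(modalities, quotas):
        pool = eligible[m]
        chosen = rng.choice(len(pool), size=int(q), replace=False)
        out += [LabeledPair(*pool[i], 0) for i in sorted(chosen)]
    return out


def assign_class_weights(
    pairs: Iterable[LabeledPair],
    w_neg: float = DEFAULT_WEIGHT_NEGATIVE,
    w_pos: float = DEFAULT_WEIGHT_POSITIVE,
) -> list[LabeledPair]:
    """Set each pair's loss weight by class: ``w_neg`` for label 0, ``w_pos``
    for label 1."""
    if w_neg <= 0 or w_pos <= 0:
        raise ValueError("class weights must be positive")
    return [replace(p, weight=w_pos if p.label == 1 else w_neg) for p in pairs]


def split_dataset(
    pairs: Sequence[LabeledPair],
    fractions: tuple[float, float, float] = DEFAULT_SPLIT_FRACTIONS,
    seed: int = 0,
) -> DatasetSplit:
    """Random train/test/validation partition.

    Part sizes are floor(fraction * n) with the remainder assigned to
    train; the same seed always reproduces the same split.
    """
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be non-negative and sum to 1, got {fractions}")
    n = len(pairs)
    n_test = int(np.floor(fractions[1] * n))
    n_val = int(np.floor(fractions[2] * n))
    n_train = n - n_test - n_val  # floor(train·n) + remainder
    perm = np.random.default_rng(seed).permutation(n)
    take = lambda idx: [pairs[i] for i in idx]
    return DatasetSplit(
        train=take(perm[:n_train]),
        test=take(perm[n_train : n_train + n_test]),
        validation=take(perm[n_train + n_test :]),
    )


def pairs_to_csv(pairs: Iterable[LabeledPair], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sentence_a", "sentence_b", "label", "weight"])
        for p in pairs:
            writer.writerow([p.sentence_a, p.sentence_b, p.label, p.weight])
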