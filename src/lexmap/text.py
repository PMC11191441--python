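"""Sentence construction and the hashed character-n-gram encoder.

Variables and reference terms are turned into *sentences* by concatenating
the name with its description when one exists ("MMSE Mini mental state exam
total"); a sentence is what gets embedded and what the pair classifier
compares.

The default offline encoder embeds a sentence by hashing its lowercased
character 3-gram multiset into ``d`` buckets and L2-normalizing. This is a
deliberately simple bag-of-subwords representation: surface-similar names
("Lhippo_FS_adj" vs "Rhippo_FS_adj") land close in Euclidean space, and the
shared description words dominate when descriptions are present. Any encoder
exposing ``encode``/``transform`` with a fixed output dimension can stand in
behind the same contract (e.g. a mean-pooled biomedical transformer).
"""

from __future__ import annotations

import hashlib

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cdm import CDM

__all__ = ["build_sentence", "NgramEncoder", "baseline_encode", "embed_reference_terms"]


def build_sentence(name: str, description: str = "") -> str:
    """Concatenate a variable/term name with its description.

    A whitespace-only description counts as absent, mirroring curated
    tables that mark missing descriptions with a dash.
    """
    if not name:
        raise ValueError("name must be non-empty")
    description = (description or "").strip()
    return f"{name} {description}" if description else name


class NgramEncoder(BaseEstimator, TransformerMixin):
    """Hashed character-3-gram sentence encoder.

    Parameters
    ----------
    d : int
        Embedding dimension (number of hash buckets), default 768.
    n : int
        Character n-gram order. Texts shorter than ``n`` contribute a
        single n-gram equal to the whole text.
    seed : int
        Salts the hash function; two encoders with the same (d, n, seed)
        produce identical vectors for identical texts.

    The encoder is stateless: ``fit`` records the dimension and returns
    self, and ``encode`` is a pure function of (text, d, n, seed).
    """

    def __init__(self, d: int = 768, n: int = 3, seed: int = 0):
        self.d = d
        self.n = n
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    @property
    def dimension(self) -> int:
        return self.d

    def fit(self, X=None, y=None) -> "NgramEncoder":
        self.n_features_in_ = 1
        return self

    def _bucket(self, gram: str) -> int:
        h = hashlib.blake2b(
            gram.encode("utf-8"), digest_size=8, salt=str(self.seed).encode()[:16]
        )
        return int.from_bytes(h.digest(), "little") % self.d

    def encode(self, text: str) -> np.ndarray:
        if not text:
            raise ValueError("cannot encode empty text")
        cached = self._cache.get(text)
        if cached is not None:
            return cached
        low = text.lower()
        grams = (
            [low[i : i + self.n] for i in range(len(low) - self.n + 1)]
            if len(low) >= self.n
            else [low]
        )
        vec = np.zeros(self.d, dtype=np.float64)
        for g in grams:
            vec[self._bucket(g)] += 1.0
        vec /= np.linalg.norm(vec)
        vec.setflags(write=False)
        self._cache[text] = vec
        return vec

    def transform(self, X) -> np.ndarray:
        return np.vstack([self.encode(t) for t in X])


def baseline_encode(text: str, d: int = 768, seed: int = 0) -> np.ndarray:
    """One-shot hashed n-gram embedding (see :class:`NgramEncoder`)."""
    return NgramEncoder(d=d, seed=seed).encode(text)


def embed_reference_terms(cdm: CDM, encoder) -> dict[str, np.ndarray]:
    """Embed every reference term's sentence; the retrieval index.

    Returns a term_id -> vector table, one entry per term, built from
    ``build_sentence(term.name, term.description)``.
    """
    return {
        tid: encoder.encode(build_sentence(t.name, t.description))
        for tid, t in cdm.terms.items()
    }
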