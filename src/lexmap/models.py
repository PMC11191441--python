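"""Trainable components of the cascade: the pairwise match classifier and
the metric-learning embedder.

The cascade separates two roles. The *embedder* (retrieval role) places
sentences in a Euclidean space where a variable lies close to its reference
term, so nearest-neighbour search produces a short candidate list. The
*pair classifier* (reranking role) looks at one (query, candidate) pair at a
time and outputs a match probability used for elimination and winner
selection.

Offline stand-ins for the transformer models:

* :class:`PairClassifier` — logistic regression on the pair feature
  ``[|a - b|, a ⊙ b]`` of the two sentence embeddings, trained with the
  per-pair loss weights. The feed-forward-head shape without a transformer.
* :class:`TripletEmbedder` — a linear map ``W`` (initialized at identity)
  over a base encoder, fitted by minimizing the Euclidean triplet loss
  ``max(0, margin + d(Wa, Wp) - d(Wa, Wn))`` over (alias, own term,
  same-modality other term) triplets. This directly optimizes the retrieval
  criterion: aliases end up closer to their own reference term than to
  confusable neighbours.

Both are scikit-learn estimators; fitted state lives in trailing-underscore
attributes and both can be serialized with :func:`save_model` /
:func:`load_model`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence
import zipfile

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .cdm import CDM
from .pairs import DatasetSplit, LabeledPair
from .text import NgramEncoder, build_sentence

__all__ = [
    "PairClassifier",
    "TripletEmbedder",
    "train_pair_classifier",
    "train_embedder",
    "save_model",
    "load_model",
]

ARCHIVE_VERSION = "lexmap-model-1"


def _pair_features(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.hstack([np.abs(A - B), A * B])


class PairClassifier(BaseEstimator, ClassifierMixin):
    """Binary match classifier over sentence pairs.

    Parameters
    ----------
    encoder : object, optional
        Sentence encoder with ``encode``/``transform``; defaults to a
        :class:`~lexmap.text.NgramEncoder` of dimension ``d``.
    d : int
        Encoder dimension when no encoder is supplied.
    C : float
        Inverse L2 regularization strength of the logistic head.
    seed : int
        Seeds the solver and the default encoder's hash salt.
    """

    def __init__(self, encoder=None, d: int = 768, C: float = 10.0, max_iter: int = 2000, seed: int = 0):
        self.encoder = encoder
        self.d = d
        self.C = C
        self.max_iter = max_iter
        self.seed = seed

    def _encoder(self):
        return self.encoder if self.encoder is not None else NgramEncoder(d=self.d, seed=self.seed)

    def fit(self, pairs: Sequence[LabeledPair], y=None) -> "PairClassifier":
        pairs = list(pairs)
        if not pairs:
            raise ValueError("cannot fit on an empty pair set")
        labels = np.array([p.label for p in pairs])
        if len(set(labels.tolist())) < 2:
            raise ValueError("training data must contain both classes")
        self.encoder_ = self._encoder().fit()
        A = self.encoder_.transform([p.sentence_a for p in pairs])
        B = self.encoder_.transform([p.sentence_b for p in pairs])
        X = _pair_features(A, B)
        w = np.array([p.weight for p in pairs])
        self.head_ = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.seed
        ).fit(X, labels, sample_weight=w)
        return self

    # -- pair scoring ------------------------------------------------------

    def score_pairs(self, queries: Sequence[str], candidates: Sequence[str]) -> np.ndarray:
        """Match probabilities for aligned (query, candidate) sentence pairs."""
        check_is_fitted(self, "head_")
        A = self.encoder_.transform(queries)
        B = self.encoder_.transform(candidates)
        pos = list(self.head_.classes_).index(1)
        return self.head_.predict_proba(_pair_features(A, B))[:, pos]

    def score(self, sentence_a: str, sentence_b: str) -> float:  # type: ignore[override]
        """Probability in [0, 1] that the two sentences are a semantic match."""
        return float(self.score_pairs([sentence_a], [sentence_b])[0])

    def predict(self, pairs: Sequence[LabeledPair]) -> np.ndarray:
        p = self.score_pairs([q.sentence_a for q in pairs], [q.sentence_b for q in pairs])
        return (p >= 0.5).astype(int)

    def weighted_log_loss(self, pairs: Sequence[LabeledPair]) -> float:
        """Per-pair-weighted cross-entropy of the fitted head on ``pairs``."""
        p = np.clip(
            self.score_pairs([q.sentence_a for q in pairs], [q.sentence_b for q in pairs]),
            1e-12,
            1 - 1e-12,
        )
        y = np.array([q.label for q in pairs])
        w = np.array([q.weight for q in pairs])
        return float(-(w * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum() / w.sum())


class TripletEmbedder(BaseEstimator, TransformerMixin):
    """Linear metric-learning encoder fitted with a Euclidean triplet loss.

    Wraps a base encoder and learns ``W`` (d x d, identity-initialized) so
    that for each training alias the mapped vector sits at least ``margin``
    closer to its own reference term than to a randomly drawn other term of
    the same modality. With ``epochs=0`` the embedder is exactly the base
    encoder.

    Parameters
    ----------
    base : encoder, optional
        Initial embedding (default hashed n-gram encoder of dimension ``d``).
    margin : float
        Triplet margin in embedding-distance units, default 1.0.
    epochs, lr : int, float
        Full-batch gradient-descent schedule.
    seed : int
        Seeds negative draws (and the default base encoder).
    """

    def __init__(
        self,
        base=None,
        d: int = 768,
        margin: float = 1.0,
        epochs: int = 30,
        lr: float = 0.5,
        seed: int = 0,
    ):
        self.base = base
        self.d = d
        self.margin = margin
        self.epochs = epochs
        self.lr = lr
        self.seed = seed

    def _base(self):
        return self.base if self.base is not None else NgramEncoder(d=self.d, seed=self.seed)

    @property
    def dimension(self) -> int:
        return self.base_.dimension if hasattr(self, "base_") else self._base().dimension

    @staticmethod
    def _triplets(cdm: CDM, rng: np.random.Generator) -> tuple[list[str], list[str], list[str]]:
        """(anchor alias, own term, other same-modality term) sentences."""
        term_sentence = {
            tid: build_sentence(t.name, t.description) for tid, t in cdm.terms.items()
        }
        by_modality: dict[str, list[str]] = {}
        for tid in sorted(cdm.terms):
            by_modality.setdefault(cdm.terms[tid].modality, []).append(tid)
        anchors, positives, negatives = [], [], []
        for tid in sorted(cdm.terms):
            peers = [t for t in by_modality[cdm.terms[tid].modality] if t != tid]
            if not peers:
                continue
            for alias in cdm.aliases_of(tid):
                other = peers[rng.integers(len(peers))]
                anchors.append(build_sentence(alias.name, alias.description))
                positives.append(term_sentence[tid])
                negatives.append(term_sentence[other])
        return anchors, positives, negatives

    def fit(self, cdm: CDM, y=None) -> "TripletEmbedder":
        if len(cdm.terms) < 2:
            raise ValueError("need at least two reference terms to fit the embedder")
        self.base_ = self._base().fit()
        d = self.base_.dimension
        rng = np.random.default_rng(self.seed)
        anchors, positives, negatives = self._triplets(cdm, rng)
        W = np.eye(d)
        self.loss_curve_ = []
        if anchors:
            A = self.base_.transform(anchors)
            P = self.base_.transform(positives)
            N = self.base_.transform(negatives)
            dAP, dAN = A - P, A - N
            for _ in range(self.epochs):
                MP, MN = dAP @ W.T, dAN @ W.T
                dp = np.linalg.norm(MP, axis=1)
                dn = np.linalg.norm(MN, axis=1)
                viol = self.margin + dp - dn
                active = viol > 0
                self.loss_curve_.append(float(np.maximum(viol, 0).mean()))
                if not active.any():
                    break
                eps = 1e-12
                gp = (MP[active] / (dp[active, None] + eps)).T @ dAP[active]
                gn = (MN[active] / (dn[active, None] + eps)).T @ dAN[active]
                W -= self.lr * (gp - gn) / len(A)
        self.W_ = W
        return self

    def encode(self, text: str) -> np.ndarray:
        check_is_fitted(self, "W_")
        return self.W_ @ self.base_.encode(text)

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "W_")
        return self.base_.transform(X) @ self.W_.T


# -- functional wrappers ---------------------------------------------------


def train_pair_classifier(split: DatasetSplit, config=None, encoder=None) -> PairClassifier:
    """Fit a :class:`PairClassifier` on the train part of ``split``."""
    kw = {}
    if config is not None:
        kw = {"d": config.embedding_dim, "seed": config.seed}
    return PairClassifier(encoder=encoder, **kw).fit(split.train)


def train_embedder(cdm: CDM, init=None, config=None, **kwargs) -> TripletEmbedder:
    """Fit a :class:`TripletEmbedder` on a CDM, starting from ``init``."""
    kw = dict(kwargs)
    if config is not None:
        kw.setdefault("d", config.embedding_dim)
        kw.setdefault("seed", config.seed)
    return TripletEmbedder(base=init, **kw).fit(cdm)


# -- serialization ---------------------------------------------------------


def save_model(path: str | Path, classifier: PairClassifier, embedder: TripletEmbedder) -> None:
    """Persist both fitted models into a single zip archive with a version tag.

    Only n-gram-based encoders are serializable; a custom encoder backend
    must be re-attached after loading.
    """
    check_is_fitted(classifier, "head_")
    check_is_fitted(embedder, "W_")
    meta = {
        "version": ARCHIVE_VERSION,
        "classifier": classifier.get_params(deep=False) | {"encoder": None},
        "embedder": embedder.get_params(deep=False) | {"base": None},
        "classes": classifier.head_.classes_.tolist(),
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        with zf.open("arrays.npz", "w") as fh:
            np.savez(
                fh,
                coef=classifier.head_.coef_,
                intercept=classifier.head_.intercept_,
                W=embedder.W_,
            )


def load_model(path: str | Path) -> tuple[PairClassifier, TripletEmbedder]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("version") != ARCHIVE_VERSION:
            raise ValueError(f"unsupported model archive version {meta.get('version')!r}")
        with zf.open("arrays.npz") as fh:
            arrays = np.load(fh)
            coef, intercept, W = arrays["coef"], arrays["intercept"], arrays["W"]
    clf = PairClassifier(**meta["classifier"])
    clf.encoder_ = clf._encoder().fit()
    head = LogisticRegression(C=clf.C, max_iter=clf.max_iter, random_state=clf.seed)
    head.classes_ = np.array(meta["classes"])
    head.coef_, head.intercept_ = coef, intercept
    clf.head_ = head
    emb = TripletEmbedder(**meta["embedder"])
    emb.base_ = emb._base().fit()
    emb.W_ = W
    return clf, emb
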