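"""Topic embeddings for documents and AUC/AUK classification evaluation.

A fitted topic model turns each document into a C-vector: either the full
P(T|D) row, or — for a more inspectable feature set — the aggregated
probabilities of the topic's top-n words that actually occur in the
document.  Out-of-fold logistic-regression scores are then summarized by
the area under the ROC curve (AUC) and the area under the Cohen's-kappa
curve (AUK); the latter corrects for chance agreement, which makes it more
sensitive than AUC when the classes are heavily imbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .corpus_io import Corpus
from .fuzzy_topics import TopicModel, top_n_indices

__all__ = [
    "TopicEmbedding",
    "PredictionScores",
    "KappaCurve",
    "embed_full",
    "embed_topn",
    "crossval_predict",
    "roc_auc",
    "kappa_curve_auk",
]


@dataclass
class TopicEmbedding:
    """N x C document features derived from a topic model."""

    features: np.ndarray
    mode: str  # "full" or "topn"
    n_words: int | None = None


@dataclass
class PredictionScores:
    """Out-of-fold classifier scores with fold assignments and labels."""

    scores: np.ndarray  # in [0, 1], one per document
    folds: np.ndarray  # test-fold index per document
    labels: np.ndarray


@dataclass
class KappaCurve:
    """Cohen's kappa swept against false-positive rate over score thresholds."""

    fpr: np.ndarray
    kappa: np.ndarray
    thresholds: np.ndarray
    auk: float


def embed_full(model: TopicModel) -> TopicEmbedding:
    """Use the full topic distribution P(T|D) as the document embedding."""
    return TopicEmbedding(features=model.ptd.copy(), mode="full")


def embed_topn(
    model: TopicModel, corpus: Corpus, n: int = 20, token_weighted: bool = False
) -> TopicEmbedding:
    """Embed documents by their overlap with each topic's top-n words.

    features[j, k] sums P(w|T_k) over the distinct words w that appear both
    in document j and in topic k's top-n list.  ``token_weighted`` instead
    multiplies each probability by the word's occurrence count in the
    document.  A document disjoint from every top list gets a zero row.
    """
    idx, probs = top_n_indices(model, n)
    C = model.C
    features = np.zeros((corpus.n_docs, C))
    # sparse lookup: word index -> list of (topic, probability)
    lookup: dict[int, list[tuple[int, float]]] = {}
    for k in range(C):
        for i, p in zip(idx[k], probs[k]):
            lookup.setdefault(int(i), []).append((k, float(p)))
    for j, doc in enumerate(corpus.docs):
        counts: dict[int, int] = {}
        for tok in doc:
            i = corpus.word_index(tok)
            counts[i] = counts.get(i, 0) + 1
        for i, c in counts.items():
            for k, p in lookup.get(i, ()):
                features[j, k] += p * (c if token_weighted else 1)
    return TopicEmbedding(features=features, mode="topn", n_words=n)


def crossval_predict(
    embedding: TopicEmbedding,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> PredictionScores:
    """Out-of-fold logistic-regression scores under stratified K-fold CV.

    Folds are stratified (the violence outcome is ~10:1 imbalanced, so
    unstratified folds risk near-empty positive sets) and shuffled with the
    given seed; the classifier is ridge-penalized logistic regression with
    fixed strength.  Every document is scored exactly once, by the model
    trained without its fold.
    """
    labels = np.asarray(labels, dtype=int)
    X = np.asarray(embedding.features, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if len(labels) < folds:
        raise ValueError("need at least one document per fold")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(labels))
    fold_of = np.empty(len(labels), dtype=int)
    for f, (train, test) in enumerate(skf.split(X, labels)):
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(X[train], labels[train])
        scores[test] = clf.predict_proba(X[test])[:, 1]
        fold_of[test] = f
    return PredictionScores(scores=scores, folds=fold_of, labels=labels)


def roc_auc(scores: PredictionScores) -> float:
    """Area under the ROC curve: P(random positive outranks random negative),
    ties counting one half."""
    if len(np.unique(scores.labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(scores.labels, scores.scores))


def kappa_curve_auk(scores: PredictionScores) -> KappaCurve:
    """Sweep thresholds, plot Cohen's kappa against FPR, integrate.

    Thresholds run from +inf (nothing predicted positive) down through every
    distinct score; at each, kappa = (p_o - p_e) / (1 - p_e) from the
    confusion matrix.  AUK is the trapezoidal area of kappa over FPR.
    Constant scores give a two-point all-zero curve and AUK 0.
    """
    y = np.asarray(scores.labels, dtype=int)
    s = np.asarray(scores.scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n = len(y)
    n_pos = int(y.sum())
    n_neg = n - n_pos
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    fpr = np.empty(len(thresholds))
    kappa = np.empty(len(thresholds))
    for t_i, t in enumerate(thresholds):
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = n_pos - tp
        tn = n_neg - fp
        fpr[t_i] = fp / n_neg
        p_o = (tp + tn) / n
        p_e = ((tp + fp) * n_pos + (fn + tn) * n_neg) / (n * n)
        kappa[t_i] = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    auk = float(np.trapezoid(kappa, fpr))
    return KappaCurve(fpr=fpr, kappa=kappa, thresholds=thresholds, auk=auk)
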