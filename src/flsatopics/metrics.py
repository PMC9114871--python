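"""Topic interpretability metrics: c_v coherence, diversity, and their product.

Coherence follows the c_v recipe: word and word-pair probabilities are
estimated from a boolean sliding window over the corpus, pairwise NPMI
values form one vector per top word, and each word's confirmation is the
cosine between its vector and the topic's summed vector (one-set
segmentation).  Scores are averaged over words and then topics.

Diversity is the fraction of distinct words among all topics' top-n lists.
The interpretability index is the product coherence × diversity: a model is
only considered interpretable when its topics are internally coherent *and*
cover different themes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import Corpus
from .fuzzy_topics import TopicModel, top_n_indices

__all__ = [
    "CoherenceConfig",
    "CoherenceStats",
    "EvaluationReport",
    "window_stats",
    "npmi_pair",
    "topic_coherences",
    "cv_coherence",
    "diversity",
    "interpretability",
    "evaluate_model",
]


@dataclass
class CoherenceConfig:
    """Knobs of the c_v pipeline.

    epsilon guards the logarithms against zero probabilities; gamma is the
    exponent applied to each NPMI value; n_top is the number of words that
    represent a topic; window is the sliding-window width in tokens.
    """

    epsilon: float = 1e-12
    gamma: float = 1.0
    n_top: int = 20
    window: int = 110

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_top < 2:
            raise ValueError("n_top must be at least 2")


@dataclass
class CoherenceStats:
    """Boolean sliding-window occurrence statistics for a tracked word set.

    ``word_count[i]`` is the number of windows containing ``words[i]`` at
    least once; ``pair_count[i, i']`` the number of windows containing both
    (the diagonal repeats ``word_count``).  Probabilities divide by the
    total window count.
    """

    words: list[str]
    word_count: np.ndarray
    pair_count: np.ndarray
    n_windows: int
    window_size: int
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {w: i for i, w in enumerate(self.words)}

    def p_word(self, w: str) -> float:
        i = self._index.get(w)
        return 0.0 if i is None else float(self.word_count[i]) / self.n_windows

    def p_pair(self, wi: str, wj: str) -> float:
        i, j = self._index.get(wi), self._index.get(wj)
        if i is None or j is None:
            return 0.0
        return float(self.pair_count[i, j]) / self.n_windows


def window_stats(
    corpus: Corpus, window: int = 110, track: Iterable[str] | None = None
) -> CoherenceStats:
    """Count word and word-pair occurrences over all sliding windows.

    Every contiguous span of ``window`` tokens within a document is one
    virtual document; a document shorter than the window contributes a
    single window (the whole document).  Windows never cross document
    boundaries.  ``track`` restricts counting to a word subset — for
    coherence only the topics' top words are needed, which keeps the pair
    matrix small.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if corpus.n_docs == 0:
        raise ValueError("empty corpus")
    words = list(dict.fromkeys(track)) if track is not None else list(corpus.vocab)
    index = {w: i for i, w in enumerate(words)}
    m = len(words)
    wc = np.zeros(m, dtype=np.int64)
    pc = np.zeros((m, m), dtype=np.int64)
    n_windows = 0
    for doc in corpus.docs:
        L = len(doc)
        if L == 0:
            continue
        nw = max(1, L - window + 1)
        n_windows += nw
        if m == 0:
            continue
        occ = np.zeros((L + 1, m), dtype=np.int32)
        for pos, tok in enumerate(doc):
            i = index.get(tok)
            if i is not None:
                occ[pos + 1, i] = 1
        cum = np.cumsum(occ, axis=0)
        if L <= window:
            present = (cum[L] > 0)[None, :]
        else:
            present = (cum[window:] - cum[:-window]) > 0
        b = present.astype(np.int64)
        wc += b.sum(axis=0)
        pc += b.T @ b
    return CoherenceStats(words, wc, pc, n_windows, window)


def npmi_pair(
    stats: CoherenceStats, wi: str, wj: str, cfg: CoherenceConfig | None = None
) -> float:
    """Normalized pointwise mutual information of a word pair, raised to gamma.

    NPMI = log((P(wi,wj)+eps) / (P(wi) P(wj))) / (-log(P(wi,wj)+eps)),
    clipped into [-1, 1].  When a marginal is zero the product in the
    denominator is floored at eps, so unseen words yield 0 rather than a
    division error.
    """
    cfg = cfg or CoherenceConfig()
    p_i, p_j = stats.p_word(wi), stats.p_word(wj)
    p_ij = stats.p_pair(wi, wj)
    eps = cfg.epsilon
    num = np.log((p_ij + eps) / max(p_i * p_j, eps))
    den = -np.log(p_ij + eps)
    if den == 0.0:
        return 0.0
    val = float(np.clip(num / den, -1.0, 1.0))
    return float(np.sign(val) * np.abs(val) ** cfg.gamma) if cfg.gamma != 1.0 else val


def _topic_npmi_matrix(
    stats: CoherenceStats, top_words: Sequence[str], cfg: CoherenceConfig
) -> np.ndarray:
    n = len(top_words)
    mat = np.empty((n, n))
    for a in range(n):
        for b in range(a, n):
            mat[a, b] = mat[b, a] = npmi_pair(stats, top_words[a], top_words[b], cfg)
    return mat


def topic_coherences(
    model: TopicModel, stats: CoherenceStats, cfg: CoherenceConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-topic c_v scores, returned as (clipped, raw) arrays.

    For each top word w the NPMI vector v(w) against all top words is
    compared by cosine with the topic vector sum(v(w')); the topic score is
    the mean confirmation.  Negative confirmations are clipped to 0 in the
    first array so the aggregate respects the [0, 1] coherence range; the
    second keeps raw cosines.
    """
    cfg = cfg or CoherenceConfig()
    if model.vocab is None:
        raise ValueError("model has no vocabulary attached")
    idx, _ = top_n_indices(model, cfg.n_top)
    clipped = np.empty(model.C)
    raw = np.empty(model.C)
    for k in range(model.C):
        words = [model.vocab[i] for i in idx[k]]
        mat = _topic_npmi_matrix(stats, words, cfg)
        ref = mat.sum(axis=0)
        ref_norm = np.linalg.norm(ref)
        confirmations = np.zeros(len(words))
        if ref_norm > 0:
            norms = np.linalg.norm(mat, axis=1)
            ok = norms > 0
            confirmations[ok] = (mat[ok] @ ref) / (norms[ok] * ref_norm)
        raw[k] = confirmations.mean()
        clipped[k] = np.clip(confirmations, 0.0, None).mean()
    return clipped, raw


def cv_coherence(
    model: TopicModel, stats: CoherenceStats, cfg: CoherenceConfig | None = None
) -> float:
    """Model-level c_v coherence: arithmetic mean of per-topic scores, in [0, 1]."""
    clipped, _ = topic_coherences(model, stats, cfg)
    return float(clipped.mean())


def diversity(top_words: Sequence[Sequence[str]]) -> float:
    """Fraction of distinct words across all topics' top-n lists.

    D = |W*| / (n C): 1 means no two topics share a word, 1/C means all
    topics list the same n words.
    """
    if not top_words:
        raise ValueError("need at least one topic")
    n = len(top_words[0])
    if any(len(lst) != n for lst in top_words):
        raise ValueError("all topics must list the same number of words")
    distinct = {w for lst in top_words for w in lst}
    return len(distinct) / (n * len(top_words))


def interpretability(coherence: float, diversity_score: float) -> float:
    """Interpretability index: the exact product coherence × diversity."""
    return coherence * diversity_score


@dataclass
class EvaluationReport:
    """Interpretability summary of one fitted model."""

    coherence: float
    diversity: float
    interpretability: float
    per_topic_coherence: np.ndarray
    per_topic_coherence_raw: np.ndarray

    def to_dict(self) -> dict:
        return {
            "coherence": self.coherence,
            "diversity": self.diversity,
            "interpretability": self.interpretability,
            "per_topic_coherence": list(map(float, self.per_topic_coherence)),
            "per_topic_coherence_raw": list(map(float, self.per_topic_coherence_raw)),
        }


def evaluate_model(
    model: TopicModel,
    corpus: Corpus,
    cfg: CoherenceConfig | None = None,
    stats: CoherenceStats | None = None,
) -> EvaluationReport:
    """Compute coherence, diversity and interpretability for one model.

    Window statistics are computed over the model's own top words unless a
    precomputed ``stats`` (covering them) is supplied.
    """
    cfg = cfg or CoherenceConfig()
    if model.vocab is None:
        raise ValueError("model has no vocabulary attached")
    idx, _ = top_n_indices(model, cfg.n_top)
    top_lists = [[model.vocab[i] for i in row] for row in idx]
    if stats is None:
        tracked = {w for lst in top_lists for w in lst}
        stats = window_stats(corpus, window=cfg.window, track=sorted(tracked))
    clipped, raw = topic_coherences(model, stats, cfg)
    coh = float(clipped.mean())
    div = diversity(top_lists)
    return EvaluationReport(coh, div, interpretability(coh, div), clipped, raw)
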