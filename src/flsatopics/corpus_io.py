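"""Corpus reading, preprocessing, filtering and matrix encoding.

The pipeline mirrors common clinical-NLP practice for long free-text notes:
lowercase, strip diacritics, drop stop words and single characters, discard
very short documents, and encode the survivors as a (sparse) document-term
matrix with an optional tf-idf weighting.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite

__all__ = [
    "Corpus",
    "DocumentTermMatrix",
    "preprocess",
    "filter_min_length",
    "build_dtm",
    "apply_weighting",
    "read_text_dir",
    "read_jsonl",
    "read_csv",
    "write_vocab",
    "write_dtm_mtx",
]

_PUNCT_RE = re.compile(r"[^\w\s]|_", flags=re.UNICODE)


@dataclass
class Corpus:
    """Tokenized documents with a shared vocabulary and optional binary labels.

    Attributes
    ----------
    docs : list of token lists, one per document.
    vocab : ordered list of the unique words, first-appearance order.
    doc_ids : one identifier per document.
    labels : optional 0/1 outcome per document.
    """

    docs: list[list[str]]
    vocab: list[str]
    doc_ids: list[str]
    labels: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {w: i for i, w in enumerate(self.vocab)}
        if len(self.doc_ids) != len(self.docs):
            raise ValueError("doc_ids and docs must have the same length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.docs),):
                raise ValueError("labels must have one entry per document")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary (0/1)")

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    @property
    def n_words(self) -> int:
        return len(self.vocab)

    def word_index(self, word: str) -> int:
        return self._index[word]


@dataclass
class DocumentTermMatrix:
    """Bag-of-words counts and their weighted counterpart.

    ``counts[j, i]`` is the number of occurrences of ``vocab[i]`` in document
    ``j``; ``weighted`` is the matrix the factorization methods consume.
    Both are scipy CSR, so iterating nonzeros never materializes N x M cells.
    """

    counts: sp.csr_matrix
    weighted: sp.csr_matrix
    scheme: str = "none"

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def _strip_accents(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def tokenize(text: str) -> list[str]:
    """Lowercase, strip accents and punctuation, split on whitespace."""
    text = _strip_accents(text.lower())
    text = _PUNCT_RE.sub(" ", text)
    return text.split()


def preprocess(
    raw_texts: Sequence[str],
    stopwords: Iterable[str] = (),
    doc_ids: Sequence[str] | None = None,
    labels: Sequence[int] | None = None,
) -> Corpus:
    """Tokenize raw strings into a :class:`Corpus`.

    Tokens are lowercased, diacritics are reduced to their base letters,
    stop words and single-character tokens are removed.  A document whose
    tokens all disappear stays in the corpus as an empty token list; the
    length filter deals with it downstream.
    """
    if len(raw_texts) == 0:
        raise ValueError("raw_texts must be non-empty")
    stop = {s.lower() for s in stopwords}
    docs: list[list[str]] = []
    vocab: list[str] = []
    seen: dict[str, int] = {}
    for text in raw_texts:
        tokens = [t for t in tokenize(text) if len(t) > 1 and t not in stop]
        for t in tokens:
            if t not in seen:
                seen[t] = len(vocab)
                vocab.append(t)
        docs.append(tokens)
    if doc_ids is None:
        doc_ids = [f"doc{j}" for j in range(len(docs))]
    lab = None if labels is None else np.asarray(labels, dtype=int)
    return Corpus(docs=docs, vocab=vocab, doc_ids=list(doc_ids), labels=lab)


def filter_min_length(corpus: Corpus, min_words: int = 101) -> Corpus:
    """Keep documents with at least ``min_words`` tokens.

    The default drops documents of fewer than 101 words, the conventional
    cut-off for admission-period notes that are too short to model.
    """
    if min_words < 1:
        raise ValueError("min_words must be >= 1")
    keep = [j for j, d in enumerate(corpus.docs) if len(d) >= min_words]
    if not keep:
        raise ValueError("no documents survive the length filter")
    docs = [corpus.docs[j] for j in keep]
    ids = [corpus.doc_ids[j] for j in keep]
    labels = None if corpus.labels is None else corpus.labels[keep]
    # rebuild the vocabulary so it covers exactly the surviving tokens
    vocab: list[str] = []
    seen: set[str] = set()
    for d in docs:
        for t in d:
            if t not in seen:
                seen.add(t)
                vocab.append(t)
    return Corpus(docs=docs, vocab=vocab, doc_ids=ids, labels=labels)


def build_dtm(corpus: Corpus) -> DocumentTermMatrix:
    """Count word occurrences into a sparse N x M document-term matrix."""
    if corpus.n_docs == 0 or corpus.n_words == 0:
        raise ValueError("corpus must have documents and a vocabulary")
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for j, doc in enumerate(corpus.docs):
        counts: dict[int, int] = {}
        for t in doc:
            i = corpus.word_index(t)
            counts[i] = counts.get(i, 0) + 1
        rows.extend([j] * len(counts))
        cols.extend(counts.keys())
        vals.extend(counts.values())
    counts_mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(corpus.n_docs, corpus.n_words), dtype=np.int64
    )
    return DocumentTermMatrix(counts=counts_mat, weighted=counts_mat.astype(float), scheme="none")


def apply_weighting(dtm: DocumentTermMatrix, scheme: str = "tfidf") -> DocumentTermMatrix:
    """Weight the counts; ``none`` keeps raw counts, ``tfidf`` uses tf * ln(N/df).

    The tf-idf variant is raw term frequency times the natural-log inverse
    document frequency, unsmoothed and unnormalized, so a word present in
    every document is weighted to zero.
    """
    if scheme == "none":
        return DocumentTermMatrix(dtm.counts, dtm.counts.astype(float), "none")
    if scheme != "tfidf":
        raise ValueError(f"unknown weighting scheme: {scheme!r}")
    counts = dtm.counts.tocsr()
    n_docs = counts.shape[0]
    df = np.asarray((counts > 0).sum(axis=0)).ravel()
    idf = np.zeros_like(df, dtype=float)
    nz = df > 0
    idf[nz] = np.log(n_docs / df[nz])
    weighted = counts.astype(float).multiply(sp.csr_matrix(idf)).tocsr()
    return DocumentTermMatrix(counts, weighted, "tfidf")


# ---------------------------------------------------------------------------
# Readers / writers


def read_text_dir(path: str | Path) -> tuple[list[str], list[str]]:
    """Read one document per ``*.txt`` file; returns (texts, ids)."""
    files = sorted(Path(path).glob("*.txt"))
    if not files:
        raise FileNotFoundError(f"no .txt files under {path}")
    return [f.read_text(encoding="utf-8") for f in files], [f.stem for f in files]


def read_jsonl(path: str | Path) -> tuple[list[str], list[str], list[int] | None]:
    """Read JSONL records with ``id``, ``text`` and optional ``label`` fields."""
    texts, ids, labels = [], [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            ids.append(str(rec["id"]))
            texts.append(rec["text"])
            if "label" in rec and rec["label"] is not None:
                labels.append(int(rec["label"]))
    if labels and len(labels) != len(texts):
        raise ValueError("labels present for only some documents")
    return texts, ids, (labels or None)


def read_csv(path: str | Path) -> tuple[list[str], list[str], list[int] | None]:
    """Read a headered CSV with ``id``, ``text`` and optional ``label`` columns."""
    texts, ids, labels = [], [], []
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            ids.append(str(rec["id"]))
            texts.append(rec["text"])
            if rec.get("label") not in (None, ""):
                labels.append(int(rec["label"]))
    if labels and len(labels) != len(texts):
        raise ValueError("labels present for only some documents")
    return texts, ids, (labels or None)


def write_vocab(corpus: Corpus, path: str | Path) -> None:
    Path(path).write_text("\n".join(corpus.vocab) + "\n", encoding="utf-8")


def write_dtm_mtx(dtm: DocumentTermMatrix, path: str | Path, which: str = "counts") -> None:
    mat = dtm.counts if which == "counts" else dtm.weighted
    mmwrite(str(path), sp.coo_matrix(mat))
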