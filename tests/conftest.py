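import numpy as np
import pytest
import scipy.sparse as sp

from flsatopics import CorpusParams, apply_weighting, build_dtm, generate_corpus
from flsatopics.corpus_io import Corpus, DocumentTermMatrix


def dtm_from_dense(arr) -> DocumentTermMatrix:
    """Wrap a dense array as a DocumentTermMatrix (counts == weighted)."""
    arr = np.asarray(arr, dtype=float)
    return DocumentTermMatrix(
        counts=sp.csr_matrix(arr.astype(np.int64)),
        weighted=sp.csr_matrix(arr),
        scheme="none",
    )


def make_corpus(docs: list[list[str]], labels=None) -> Corpus:
    vocab: list[str] = []
    seen: set[str] = set()
    for d in docs:
        for t in d:
            if t not in seen:
                seen.add(t)
                vocab.append(t)
    return Corpus(
        docs=docs,
        vocab=vocab,
        doc_ids=[f"d{i}" for i in range(len(docs))],
        labels=labels,
    )


@pytest.fixture(scope="session")
def planted_small():
    """A small planted-topic corpus (3 disjoint topics) plus tf-idf DTM."""
    corpus, truth = generate_corpus(
        CorpusParams(C=3, M=90, N=80, doc_length=60), seed=7
    )
    dtm = apply_weighting(build_dtm(corpus), "tfidf")
    return corpus, truth, dtm


@pytest.fixture(scope="session")
def planted_default():
    """The generator's default study-shape corpus (C=5, N=500, L=200)."""
    corpus, truth = generate_corpus(seed=11)
    dtm = apply_weighting(build_dtm(corpus), "tfidf")
    return corpus, truth, dtm
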