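"""Fuzzy topic models: FLSA, FLSA-W, FLSA-V, plus LSI and NMF baselines.

All fitters return a :class:`TopicModel` with the two probability matrices a
topic model must supply: ``pwt`` with rows P(W|T_k) over the vocabulary and
``ptd`` with rows P(T|D_j) over the topics, both row-stochastic.

The FLSA family shares a three-stage skeleton:

1. project the weighted document-term matrix to a low-dimensional space
   (truncated SVD, or a co-occurrence stress embedding for FLSA-V);
2. fuzzily cluster the projected items — documents for FLSA, words for
   FLSA-W/FLSA-V — with fuzzy c-means or Gustafson–Kessel clustering;
3. recombine the fuzzy memberships with empirical document/word frequencies
   through Bayes' theorem into P(W|T) and P(T|D).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import svds
from scipy.spatial.distance import cdist
from sklearn.manifold import smacof

from .corpus_io import DocumentTermMatrix

__all__ = [
    "ClusteringConfig",
    "ProjectionMatrices",
    "PartitionMatrix",
    "TopicModel",
    "svd_project",
    "fcm_cluster",
    "gk_cluster",
    "word_cooccurrence",
    "cooc_embedding",
    "fit_flsa",
    "fit_flsa_w",
    "fit_flsa_v",
    "fit_lsi_baseline",
    "fit_nmf_baseline",
    "top_n_words",
    "top_n_indices",
    "save_model",
    "load_model",
]


@dataclass
class ClusteringConfig:
    """Fuzzy clustering hyper-parameters.

    ``m`` is the fuzzifier (> 1; 2 is the conventional default), ``tol`` the
    maximum center shift accepted as convergence, ``seed`` drives the
    k-means++-style center initialization.  ``n_init`` independent seeded
    starts are run and the partition with the lowest objective kept —
    fuzzy clustering objectives have local minima (notably axis-aligned
    splits of elongated clusters) that a single start can land in.
    """

    method: str = "fcm"
    m: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0
    n_init: int = 4

    def __post_init__(self) -> None:
        if self.method not in ("fcm", "gk"):
            raise ValueError(f"unknown clustering method: {self.method!r}")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


@dataclass
class ProjectionMatrices:
    """Truncated SVD factors A ≈ U diag(Sigma) V^T."""

    U: np.ndarray  # N x S document projection
    Sigma: np.ndarray  # S singular values, descending
    V: np.ndarray  # M x S word projection

    @property
    def S(self) -> int:
        return len(self.Sigma)


@dataclass
class PartitionMatrix:
    """Fuzzy memberships of clustered items; rows sum to one."""

    memberships: np.ndarray  # items x C
    centers: np.ndarray  # C x S
    objective: float
    objective_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


@dataclass
class TopicModel:
    """P(W|T) and P(T|D) for a fitted topic model."""

    pwt: np.ndarray  # C x M, rows P(W|T_k)
    ptd: np.ndarray  # N x C, rows P(T|D_j)
    algorithm: str
    C: int
    vocab: list[str] | None = None
    meta: dict = field(default_factory=dict)


def _row_normalize(mat: np.ndarray, fallback_uniform: bool = True) -> np.ndarray:
    """Normalize rows to sum 1; all-zero rows become uniform when asked."""
    mat = np.asarray(mat, dtype=float)
    sums = mat.sum(axis=1, keepdims=True)
    zero = sums.ravel() <= 0
    out = np.divide(mat, sums, out=np.zeros_like(mat), where=sums > 0)
    if fallback_uniform and zero.any():
        out[zero] = 1.0 / mat.shape[1]
    return out


def svd_project(dtm: DocumentTermMatrix, S: int) -> ProjectionMatrices:
    """Rank-S truncated SVD of the weighted document-term matrix.

    By Eckart–Young the returned factors give the best rank-S approximation
    in Frobenius norm.  A fixed Lanczos start vector keeps the factorization
    deterministic and equivariant under row/column permutations.
    """
    A = dtm.weighted
    n, m = A.shape
    if not (1 <= S <= min(n, m)):
        raise ValueError(f"S must be in [1, {min(n, m)}], got {S}")
    if S >= min(n, m) - 1:
        U, sig, Vt = np.linalg.svd(np.asarray(A.todense()), full_matrices=False)
        U, sig, Vt = U[:, :S], sig[:S], Vt[:S]
    else:
        U, sig, Vt = svds(sp.csr_matrix(A, dtype=float), k=S, v0=np.ones(min(n, m)))
        order = np.argsort(sig)[::-1]
        U, sig, Vt = U[:, order], sig[order], Vt[order]
    # canonical signs: the largest-|V| entry of each component is positive,
    # so the factorization is reproducible and permutation-equivariant
    flip = np.sign(Vt[np.arange(S), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return ProjectionMatrices(U=U * flip, Sigma=sig, V=(Vt * flip[:, None]).T)


# ---------------------------------------------------------------------------
# Fuzzy clustering


def _kmeanspp_centers(points: np.ndarray, C: int, rng: np.random.Generator) -> np.ndarray:
    # selection runs over lexicographically sorted points, so the seeded init
    # depends on the point *set* only and relabeling items permutes the fit
    pts = points[np.lexsort(points.T[::-1])]
    n = pts.shape[0]
    centers = [pts[rng.integers(n)]]
    for _ in range(1, C):
        d2 = np.min(cdist(pts, np.asarray(centers), "sqeuclidean"), axis=1)
        total = d2.sum()
        if total <= 0:  # all points coincide with existing centers
            centers.append(pts[rng.integers(n)])
            continue
        centers.append(pts[rng.choice(n, p=d2 / total)])
    return np.asarray(centers, dtype=float)


def _memberships_from_d2(d2: np.ndarray, m: float) -> np.ndarray:
    """Standard FCM membership update from squared distances.

    A point exactly coincident with a center gets membership 1 to that
    cluster (first such cluster on ties).
    """
    zero_rows = (d2 <= 0).any(axis=1)
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
    u = np.zeros_like(d2)
    ok = ~zero_rows
    u[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
    for x in np.flatnonzero(zero_rows):
        u[x, int(np.argmax(d2[x] <= 0))] = 1.0
    return u


def _restart_seeds(cfg: ClusteringConfig) -> list[int]:
    if cfg.n_init == 1:
        return [cfg.seed]
    return [int(s) for s in np.random.default_rng(cfg.seed).integers(2**31, size=cfg.n_init)]


def _best_of_restarts(single_run, cfg: ClusteringConfig) -> PartitionMatrix:
    best: PartitionMatrix | None = None
    for s in _restart_seeds(cfg):
        part = single_run(s)
        if best is None or part.objective < best.objective:
            best = part
    return best


def fcm_cluster(points: np.ndarray, C: int, cfg: ClusteringConfig | None = None) -> PartitionMatrix:
    """Bezdek fuzzy c-means with Euclidean distances.

    Alternates membership and center updates until the largest center shift
    drops below ``cfg.tol``; the objective J = sum u^m d^2 is non-increasing
    across iterations.  The best of ``cfg.n_init`` seeded starts is returned.
    """
    cfg = cfg or ClusteringConfig()
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < C:
        raise ValueError("need at least C points of equal dimension")
    return _best_of_restarts(lambda s: _fcm_single(points, C, cfg, s), cfg)


def _fcm_single(points: np.ndarray, C: int, cfg: ClusteringConfig, seed: int) -> PartitionMatrix:
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_centers(points, C, rng)
    history: list[float] = []
    converged = False
    u = _memberships_from_d2(cdist(points, centers, "sqeuclidean"), cfg.m)
    it = 0
    for it in range(1, cfg.max_iter + 1):
        um = u**cfg.m
        new_centers = (um.T @ points) / um.sum(axis=0)[:, None]
        d2 = cdist(points, new_centers, "sqeuclidean")
        history.append(float((um * d2).sum()))
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        u = _memberships_from_d2(d2, cfg.m)
        if shift < cfg.tol:
            converged = True
            break
    return PartitionMatrix(u, centers, history[-1], history, it, converged)


def _fuzzy_covariances(
    points: np.ndarray, centers: np.ndarray, um: np.ndarray, rho: float
) -> np.ndarray:
    """Per-cluster fuzzy covariances, blended with a scaled identity.

    Regularization F_k <- (1-rho) F_k + rho det(F0)^(1/S) I (F0 the overall
    covariance) keeps every norm-inducing matrix invertible.
    """
    n, S = points.shape
    C = centers.shape[0]
    f0 = np.cov(points, rowvar=False).reshape(S, S) + 1e-12 * np.eye(S)
    scale = float(np.exp(np.linalg.slogdet(f0)[1] / S))
    covs = np.empty((C, S, S))
    for k in range(C):
        diff = points - centers[k]
        fk = (um[:, k, None, None] * (diff[:, :, None] * diff[:, None, :])).sum(axis=0)
        fk /= um[:, k].sum()
        covs[k] = (1 - rho) * fk + rho * scale * np.eye(S)
    return covs


def _gk_distances(points: np.ndarray, centers: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Mahalanobis-type distances d^2 = (x-v)^T det(F)^(1/S) F^-1 (x-v)."""
    S = points.shape[1]
    d2 = np.empty((points.shape[0], centers.shape[0]))
    for k in range(centers.shape[0]):
        fk = covs[k]
        sign, logdet = np.linalg.slogdet(fk)
        if sign <= 0:  # regularization failed to fix it; fall back to identity
            fk = np.eye(S)
            logdet = 0.0
        diff = points - centers[k]
        sol = np.linalg.solve(fk, diff.T).T
        d2[:, k] = np.exp(logdet / S) * np.einsum("ij,ij->i", diff, sol)
    return np.maximum(d2, 0.0)


def gk_cluster(
    points: np.ndarray, C: int, cfg: ClusteringConfig | None = None, rho: float = 1e-4
) -> PartitionMatrix:
    """Gustafson–Kessel clustering: FCM with cluster-adaptive Mahalanobis norms.

    Each cluster carries a fuzzy covariance matrix, so elongated clusters are
    captured where plain FCM would slice them; covariances are regularized
    toward a scaled identity so singular geometry never crashes the fit.
    The best of ``cfg.n_init`` seeded starts is returned.
    """
    cfg = cfg or ClusteringConfig(method="gk")
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < C:
        raise ValueError("need at least C points of equal dimension")
    return _best_of_restarts(lambda s: _gk_single(points, C, cfg, s, rho), cfg)


def _gk_single(
    points: np.ndarray, C: int, cfg: ClusteringConfig, seed: int, rho: float
) -> PartitionMatrix:
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_centers(points, C, rng)
    u = _memberships_from_d2(cdist(points, centers, "sqeuclidean"), cfg.m)
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        um = u**cfg.m
        new_centers = (um.T @ points) / um.sum(axis=0)[:, None]
        covs = _fuzzy_covariances(points, new_centers, um, rho)
        d2 = _gk_distances(points, new_centers, covs)
        history.append(float((um * d2).sum()))
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        u = _memberships_from_d2(d2, cfg.m)
        if shift < cfg.tol:
            converged = True
            break
    return PartitionMatrix(u, centers, history[-1], history, it, converged)


def _cluster(points: np.ndarray, C: int, cfg: ClusteringConfig) -> PartitionMatrix:
    if cfg.method == "gk":
        return gk_cluster(points, C, cfg)
    return fcm_cluster(points, C, cfg)


# ---------------------------------------------------------------------------
# Bayes recombination


def _unit_rows(points: np.ndarray) -> np.ndarray:
    """Scale rows to unit Euclidean norm; all-zero rows stay at the origin.

    Similarity in an SVD projection is directional (cosine), while row
    magnitudes mostly encode document length / word frequency; clustering
    unit-normalized rows therefore groups by direction, which is what topic
    structure lives in.
    """
    norms = np.linalg.norm(points, axis=1, keepdims=True)
    return np.divide(points, norms, out=np.zeros_like(points), where=norms > 0)


def _pwd(dtm: DocumentTermMatrix) -> np.ndarray:
    """P(W_i|D_j): row-normalized raw counts (empty docs give zero rows)."""
    counts = np.asarray(dtm.counts.todense(), dtype=float)
    return _row_normalize(counts, fallback_uniform=False)


def fit_flsa(
    dtm: DocumentTermMatrix,
    C: int,
    S: int | None = None,
    cfg: ClusteringConfig | None = None,
    vocab: list[str] | None = None,
    normalize_projection: bool = True,
) -> TopicModel:
    """FLSA: cluster *documents* in the SVD space.

    Document memberships are read as P(T|D).  With the document prior P(D)
    proportional to document token totals, Bayes' theorem yields
    P(D|T) = P(T|D) P(D) / P(T) and P(W|T) = sum_j P(W|D_j) P(D_j|T).
    Documents left empty by preprocessing carry zero prior mass.
    Projection rows are unit-normalized before clustering by default so
    clusters form by direction rather than document length.
    """
    cfg = cfg or ClusteringConfig()
    S = C if S is None else S
    proj = svd_project(dtm, S)
    points = _unit_rows(proj.U) if normalize_projection else proj.U
    part = _cluster(points, C, cfg)
    ptd = part.memberships  # N x C
    doc_totals = np.asarray(dtm.counts.sum(axis=1), dtype=float).ravel()
    pd = doc_totals / doc_totals.sum()
    pt = ptd.T @ pd  # C
    pdt = (ptd * pd[:, None]).T / np.maximum(pt[:, None], 1e-300)  # C x N
    pwt = pdt @ _pwd(dtm)  # C x M
    return TopicModel(
        pwt=_row_normalize(pwt),
        ptd=_row_normalize(ptd),
        algorithm=f"flsa_{cfg.method}",
        C=C,
        vocab=vocab,
        meta={"S": S, "seed": cfg.seed, "clustering": cfg.method, "objective": part.objective},
    )


def _recombine_word_memberships(
    ptw: np.ndarray, dtm: DocumentTermMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Shared FLSA-W/FLSA-V step: word memberships P(T|W) -> (pwt, ptd).

    P(W) is proportional to corpus word totals; Bayes gives
    P(W|T) = P(T|W) P(W) / P(T) and P(T|D) = sum_i P(T|W_i) P(W_i|D).
    """
    word_totals = np.asarray(dtm.counts.sum(axis=0), dtype=float).ravel()
    pw = word_totals / word_totals.sum()
    pt = ptw.T @ pw  # C
    pwt = (ptw * pw[:, None]).T / np.maximum(pt[:, None], 1e-300)  # C x M
    ptd = _pwd(dtm) @ ptw  # N x C
    return _row_normalize(pwt), _row_normalize(ptd)


def fit_flsa_w(
    dtm: DocumentTermMatrix,
    C: int,
    S: int | None = None,
    cfg: ClusteringConfig | None = None,
    vocab: list[str] | None = None,
    normalize_projection: bool = True,
) -> TopicModel:
    """FLSA-W: cluster *words* in the SVD space.

    Since topics are distributions over words, clustering the word projection
    (the V factor) targets topic structure directly; memberships are P(T|W)
    and Bayes recombination produces both output matrices.  Projection rows
    are unit-normalized before clustering by default — word frequency scales
    the row magnitude, whereas topic identity lives in the direction.
    """
    cfg = cfg or ClusteringConfig()
    S = C if S is None else S
    proj = svd_project(dtm, S)
    points = _unit_rows(proj.V) if normalize_projection else proj.V
    part = _cluster(points, C, cfg)
    pwt, ptd = _recombine_word_memberships(part.memberships, dtm)
    return TopicModel(
        pwt=pwt,
        ptd=ptd,
        algorithm=f"flsa_w_{cfg.method}",
        C=C,
        vocab=vocab,
        meta={"S": S, "seed": cfg.seed, "clustering": cfg.method, "objective": part.objective},
    )


def word_cooccurrence(dtm: DocumentTermMatrix) -> sp.csr_matrix:
    """Symmetric M x M document-level co-occurrence counts.

    Entry (i, i') is the number of documents containing both words; the
    diagonal holds document frequencies.
    """
    presence = (dtm.counts > 0).astype(np.int64)
    return (presence.T @ presence).tocsr()


def cooc_embedding(
    cooc: sp.spmatrix | np.ndarray, proj_dim: int = 2, seed: int = 0
) -> np.ndarray:
    """Stress-minimizing word map from a co-occurrence matrix.

    Similarities use the association strength s_ij = c_ij / (c_i c_j), which
    normalizes away word frequency; dissimilarities 1/(1+s) are embedded by
    SMACOF stress majorization.  Disconnected co-occurrence components are
    embedded independently and offset along the first axis (with a warning),
    since no data constrains their relative placement.
    """
    cooc = sp.csr_matrix(cooc, dtype=float)
    M = cooc.shape[0]
    if cooc.shape[0] != cooc.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    asym = abs(cooc - cooc.T)
    if asym.nnz and asym.max() > 1e-9 * (1.0 + abs(cooc).max()):
        raise ValueError("co-occurrence matrix must be symmetric")
    if cooc.nnz and cooc.min() < 0:
        raise ValueError("co-occurrence matrix must be non-negative")
    off = cooc - sp.diags(cooc.diagonal())
    n_comp, labels = connected_components(off > 0, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"co-occurrence graph has {n_comp} disconnected components; "
            "embedding each independently",
            stacklevel=2,
        )
    coords = np.zeros((M, proj_dim))
    offset = 0.0
    dense = np.asarray(off.todense())
    totals = np.maximum(dense.sum(axis=1), 1e-300)
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        if len(idx) == 1:
            coords[idx, 0] = offset
            offset += 1.0
            continue
        sub = dense[np.ix_(idx, idx)]
        strength = sub / np.outer(totals[idx], totals[idx])
        strength *= sub.sum()
        dis = 1.0 / (1.0 + strength)
        np.fill_diagonal(dis, 0.0)
        emb, _ = smacof(
            dis,
            n_components=proj_dim,
            random_state=seed + comp,
            n_init=1,
            normalized_stress=False,
        )
        emb = emb - emb.min(axis=0)
        coords[idx] = emb
        coords[idx, 0] += offset
        offset = float(coords[idx, 0].max()) + 2.0 * max(1.0, float(np.ptp(emb)))
    return coords


def fit_flsa_v(
    dtm: DocumentTermMatrix,
    C: int,
    cfg: ClusteringConfig | None = None,
    proj_dim: int = 2,
    cooc: sp.spmatrix | np.ndarray | None = None,
    vocab: list[str] | None = None,
) -> TopicModel:
    """FLSA-V: cluster words on a co-occurrence stress embedding.

    Instead of trusting the SVD projection to place related words together,
    words are mapped so that frequently co-occurring words end up close;
    from the clustering step onward this is identical to FLSA-W.  A custom
    ``cooc`` matrix (e.g. windowed counts) can replace the default
    document-level one.
    """
    cfg = cfg or ClusteringConfig()
    if cooc is None:
        cooc = word_cooccurrence(dtm)
    coords = cooc_embedding(cooc, proj_dim=proj_dim, seed=cfg.seed)
    part = _cluster(coords, C, cfg)
    pwt, ptd = _recombine_word_memberships(part.memberships, dtm)
    return TopicModel(
        pwt=pwt,
        ptd=ptd,
        algorithm=f"flsa_v_{cfg.method}",
        C=C,
        vocab=vocab,
        meta={
            "proj_dim": proj_dim,
            "seed": cfg.seed,
            "clustering": cfg.method,
            "objective": part.objective,
        },
    )


# ---------------------------------------------------------------------------
# Baselines


def fit_lsi_baseline(
    dtm: DocumentTermMatrix, C: int, vocab: list[str] | None = None
) -> TopicModel:
    """LSI read as a topic model: top-C SVD factors, |.|-normalized to rows.

    SVD factors carry arbitrary signs, so probability rows are obtained by
    normalizing absolute values — a baseline convention, not part of SVD.
    """
    proj = svd_project(dtm, C)
    ptd = _row_normalize(np.abs(proj.U))
    pwt = _row_normalize(np.abs(proj.V.T))
    return TopicModel(pwt=pwt, ptd=ptd, algorithm="lsi", C=C, vocab=vocab, meta={})


def fit_nmf_baseline(
    dtm: DocumentTermMatrix,
    C: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    vocab: list[str] | None = None,
) -> TopicModel:
    """Multiplicative-update NMF on the weighted matrix, A ≈ W H.

    Lee–Seung updates keep the Frobenius loss non-increasing; the loss trace
    is kept in ``meta['loss_history']``.  W columns are rescaled by H row
    sums before normalization so P(T|D) reflects each topic's total mass.
    """
    A = np.asarray(dtm.weighted.todense(), dtype=float)
    if (A < 0).any():
        raise ValueError("NMF requires a non-negative matrix")
    n, m = A.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(A.mean(), 1e-12) / C)
    W = scale * rng.random((n, C)) + 1e-6
    H = scale * rng.random((C, m)) + 1e-6
    eps = 1e-12
    losses = [float(np.linalg.norm(A - W @ H) ** 2)]
    for _ in range(max_iter):
        H *= (W.T @ A) / (W.T @ W @ H + eps)
        W *= (A @ H.T) / (W @ (H @ H.T) + eps)
        loss = float(np.linalg.norm(A - W @ H) ** 2)
        losses.append(loss)
        if losses[-2] - loss <= tol * max(losses[0], 1.0):
            break
    h_mass = H.sum(axis=1)
    ptd = _row_normalize(W * h_mass)
    pwt = _row_normalize(H)
    return TopicModel(
        pwt=pwt,
        ptd=ptd,
        algorithm="nmf",
        C=C,
        vocab=vocab,
        meta={"loss_history": losses, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Topic inspection & serialization


def top_n_indices(model: TopicModel, n: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Per-topic indices and probabilities of the n most probable words.

    Ties break toward the lower vocabulary index, so output is deterministic.
    Returns (C x n indices, C x n probabilities), probabilities descending.
    """
    C, M = model.pwt.shape
    if n > M:
        raise ValueError(f"n={n} exceeds vocabulary size {M}")
    idx = np.empty((C, n), dtype=int)
    for k in range(C):
        order = np.lexsort((np.arange(M), -model.pwt[k]))
        idx[k] = order[:n]
    probs = np.take_along_axis(model.pwt, idx, axis=1)
    return idx, probs


def top_n_words(model: TopicModel, n: int = 20) -> list[list[tuple[str, float]]]:
    """Per-topic list of (word, probability), the usual topic summary."""
    if model.vocab is None:
        raise ValueError("model has no vocabulary attached")
    idx, probs = top_n_indices(model, n)
    return [
        [(model.vocab[i], float(p)) for i, p in zip(row, prow)]
        for row, prow in zip(idx, probs)
    ]


def save_model(model: TopicModel, directory: str | Path) -> None:
    """Write pwt/ptd as MatrixMarket files plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "pwt.mtx"), sp.coo_matrix(model.pwt))
    mmwrite(str(directory / "ptd.mtx"), sp.coo_matrix(model.ptd))
    meta = {
        "algorithm": model.algorithm,
        "C": model.C,
        "vocab": model.vocab,
        "meta": {k: v for k, v in model.meta.items() if not isinstance(v, np.ndarray)},
    }
    (directory / "model.json").write_text(json.dumps(meta), encoding="utf-8")


def load_model(directory: str | Path) -> TopicModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text(encoding="utf-8"))
    pwt = np.asarray(mmread(str(directory / "pwt.mtx")).todense())
    ptd = np.asarray(mmread(str(directory / "ptd.mtx")).todense())
    return TopicModel(
        pwt=pwt,
        ptd=ptd,
        algorithm=meta["algorithm"],
        C=meta["C"],
        vocab=meta["vocab"],
        meta=meta["meta"],
    )
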