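"""SVD projection, fuzzy clustering, and the topic-model fitters."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from flsatopics import (
    ClusteringConfig,
    apply_weighting,
    build_dtm,
    diversity,
    fcm_cluster,
    fit_flsa,
    fit_flsa_v,
    fit_flsa_w,
    fit_lsi_baseline,
    fit_nmf_baseline,
    gk_cluster,
    svd_project,
)
from flsatopics.corpus_io import Corpus
from flsatopics.fuzzy_topics import (
    TopicModel,
    cooc_embedding,
    load_model,
    save_model,
    top_n_indices,
    top_n_words,
    word_cooccurrence,
)

from conftest import dtm_from_dense, make_corpus


def corpus_word_frequencies(dtm):
    totals = np.asarray(dtm.counts.sum(axis=0), dtype=float).ravel()
    return totals / totals.sum()


class TestSvdProject:
    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        a = rng.random((4, 4))
        proj = svd_project(dtm_from_dense(a), 4)
        assert np.allclose(proj.U @ np.diag(proj.Sigma) @ proj.V.T, a, atol=1e-8)

    def test_sigma_descending_nonnegative(self):
        rng = np.random.default_rng(1)
        proj = svd_project(dtm_from_dense(rng.random((10, 7))), 3)
        assert (np.diff(proj.Sigma) <= 0).all() and (proj.Sigma >= 0).all()

    def test_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.random((8, 6))
        proj = svd_project(dtm_from_dense(a), 3)
        expected = np.linalg.svd(a, compute_uv=False)[:3]
        assert np.allclose(proj.Sigma, expected, atol=1e-8)

    def test_rank_limit(self):
        with pytest.raises(ValueError):
            svd_project(dtm_from_dense(np.ones((3, 5))), 4)


class TestFcm:
    def test_separated_clouds(self):
        rng = np.random.default_rng(0)
        pts = np.vstack(
            [rng.normal(0, 0.05, (20, 2)), rng.normal(10, 0.05, (20, 2))]
        )
        part = fcm_cluster(pts, 2, ClusteringConfig(seed=0))
        own = part.memberships.max(axis=1)
        assert (own > 0.99).all()
        # both clouds end up in different clusters
        assert part.memberships[:20].argmax(1).std() == 0
        assert part.memberships[:20, 0].mean() != pytest.approx(
            part.memberships[20:, 0].mean(), abs=0.5
        )

    def test_equidistant_point_gets_half_half(self):
        pts = np.array(
            [[-2.0, 0], [-2, 1], [-2, -1], [2, 0], [2, 1], [2, -1], [0.0, 0.0]]
        )
        part = fcm_cluster(pts, 2, ClusteringConfig(seed=1, tol=1e-12))
        assert np.allclose(part.memberships[-1], [0.5, 0.5], atol=1e-3)

    def test_point_on_center_tie_rule(self):
        pts = np.array([[0.0, 0], [0, 0], [0, 0], [5, 5], [5, 5], [5, 5]])
        part = fcm_cluster(pts, 2, ClusteringConfig(seed=0))
        assert np.allclose(np.sort(part.memberships[0]), [0.0, 1.0])

    def test_rows_sum_to_one_and_objective_monotone(self):
        rng = np.random.default_rng(5)
        pts = rng.random((30, 3))
        part = fcm_cluster(pts, 4, ClusteringConfig(seed=2))
        assert np.allclose(part.memberships.sum(axis=1), 1.0, atol=1e-8)
        hist = part.objective_history
        assert all(hist[i + 1] <= hist[i] + 1e-9 for i in range(len(hist) - 1))

    def test_beats_random_restart_oracle(self):
        """Converged objective is at least as good as 200 random memberships
        pushed through a single center/membership update."""
        rng = np.random.default_rng(7)
        pts = rng.random((20, 2))
        part = fcm_cluster(pts, 3, ClusteringConfig(seed=3))
        m = 2.0
        best = np.inf
        for _ in range(200):
            u = rng.dirichlet(np.ones(3), size=20)
            um = u**m
            centers = (um.T @ pts) / um.sum(axis=0)[:, None]
            d2 = cdist(pts, centers, "sqeuclidean")
            inv = np.maximum(d2, 1e-300) ** (-1.0 / (m - 1.0))
            u2 = inv / inv.sum(axis=1, keepdims=True)
            best = min(best, float(((u2**m) * d2).sum()))
        assert part.objective <= best + 1e-9


class TestGk:
    def test_reduces_to_fcm_on_spherical_clusters(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(5, 0.1, (30, 2))])
        uf = fcm_cluster(pts, 2, ClusteringConfig(seed=1)).memberships
        ug = gk_cluster(pts, 2, ClusteringConfig(method="gk", seed=1)).memberships
        diff = min(
            np.abs(uf - ug).max(), np.abs(uf - ug[:, ::-1]).max()
        )  # cluster labels may swap
        assert diff < 0.05

    def test_recovers_elongated_clusters_where_fcm_fails(self):
        """Two thin parallel stripes: Euclidean FCM splits across the
        elongation, the adaptive Mahalanobis norm follows it."""
        rng = np.random.default_rng(0)
        n = 40
        stripe1 = np.c_[rng.uniform(0, 10, n), rng.normal(0, 0.05, n)]
        stripe2 = np.c_[rng.uniform(0, 10, n), rng.normal(2.0, 0.05, n)]
        pts = np.vstack([stripe1, stripe2])
        fcm_lab = fcm_cluster(pts, 2, ClusteringConfig(seed=0)).memberships.argmax(1)
        fcm_acc = max(
            ((fcm_lab[:n] == 0).mean() + (fcm_lab[n:] == 1).mean()) / 2,
            ((fcm_lab[:n] == 1).mean() + (fcm_lab[n:] == 0).mean()) / 2,
        )
        assert fcm_acc < 0.9
        gk = gk_cluster(pts, 2, ClusteringConfig(method="gk", seed=0)).memberships
        own = max(
            min(gk[:n, 0].min(), gk[n:, 1].min()),
            min(gk[:n, 1].min(), gk[n:, 0].min()),
        )
        assert own >= 0.9

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        pts = rng.random((25, 3))
        part = gk_cluster(pts, 3, ClusteringConfig(method="gk", seed=0))
        assert np.allclose(part.memberships.sum(axis=1), 1.0, atol=1e-8)

    def test_degenerate_geometry_does_not_crash(self):
        # all points on a line: raw covariances are singular
        pts = np.c_[np.linspace(0, 1, 20), np.zeros(20)]
        part = gk_cluster(pts, 2, ClusteringConfig(method="gk", seed=0))
        assert np.isfinite(part.memberships).all()


class TestFlsaFitters:
    def test_single_topic_collapse(self, planted_small):
        _, _, dtm = planted_small
        freq = corpus_word_frequencies(dtm)
        for fit in (fit_flsa, fit_flsa_w):
            model = fit(dtm, 1, cfg=ClusteringConfig(seed=0))
            assert np.allclose(model.ptd, 1.0)
            assert np.allclose(model.pwt[0], freq, atol=1e-8)
        model = fit_flsa_v(dtm, 1, cfg=ClusteringConfig(seed=0))
        assert np.allclose(model.ptd, 1.0)
        assert np.allclose(model.pwt[0], freq, atol=1e-8)

    def test_planted_topic_recovery(self, planted_small):
        corpus, truth, dtm = planted_small
        model = fit_flsa_w(dtm, 3, cfg=ClusteringConfig(seed=7), vocab=corpus.vocab)
        idx, _ = top_n_indices(model, 10)
        planted = truth.top_words(10)
        overlap = np.array(
            [[len(set(idx[a]) & set(planted[b])) for b in range(3)] for a in range(3)]
        )
        rows, cols = linear_sum_assignment(-overlap)
        assert (overlap[rows, cols] >= 8).all()

    def test_flsa_document_recovery(self, planted_small):
        """FLSA's document clustering assigns single-topic documents to
        matching clusters."""
        corpus, truth, dtm = planted_small
        model = fit_flsa(dtm, 3, cfg=ClusteringConfig(seed=1), vocab=corpus.vocab)
        dominant = truth.true_ptd.argmax(axis=1)
        pure = truth.true_ptd.max(axis=1) > 0.9
        fitted = model.ptd.argmax(axis=1)
        # best topic relabeling
        agree = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                agree[a, b] = np.sum((fitted == a) & (dominant == b) & pure)
        rows, cols = linear_sum_assignment(-agree)
        assert agree[rows, cols].sum() / pure.sum() >= 0.8

    def test_vocab_swap_equivariance(self, planted_small):
        corpus, _, dtm = planted_small
        m1 = fit_flsa_w(dtm, 3, cfg=ClusteringConfig(seed=5), vocab=corpus.vocab)
        perm = np.arange(corpus.n_words)
        perm[[2, 50]] = [50, 2]
        vocab2 = [corpus.vocab[i] for i in perm]
        swapped = Corpus(docs=corpus.docs, vocab=vocab2, doc_ids=corpus.doc_ids)
        dtm2 = apply_weighting(build_dtm(swapped), "tfidf")
        m2 = fit_flsa_w(dtm2, 3, cfg=ClusteringConfig(seed=5), vocab=vocab2)
        assert np.allclose(m2.pwt, m1.pwt[:, perm], atol=1e-6)
        assert np.allclose(m2.ptd, m1.ptd, atol=1e-6)

    def test_same_seed_reproducible(self, planted_small):
        corpus, _, dtm = planted_small
        a = fit_flsa_w(dtm, 3, cfg=ClusteringConfig(seed=9))
        b = fit_flsa_w(dtm, 3, cfg=ClusteringConfig(seed=9))
        assert np.array_equal(a.pwt, b.pwt) and np.array_equal(a.ptd, b.ptd)


class TestFlsaV:
    def test_never_cooccurring_groups_are_separated(self):
        docs = [["a", "b", "c", "d", "e"]] * 5 + [["f", "g", "h", "i", "j"]] * 5
        corpus = make_corpus(docs)
        cooc = word_cooccurrence(build_dtm(corpus))
        with pytest.warns(UserWarning, match="disconnected"):
            emb = cooc_embedding(cooc, 2, seed=0)
        g1, g2 = emb[:5], emb[5:]
        within = max(cdist(g1, g1).max(), cdist(g2, g2).max())
        assert cdist(g1, g2).min() > within

    def test_asymmetric_cooc_rejected(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            cooc_embedding(bad)


class TestBaselines:
    def test_lsi_rank_one(self):
        a = np.outer([1, 2, 3.0], [4, 5.0, 6, 7])
        model = fit_lsi_baseline(dtm_from_dense(a), 1)
        assert np.allclose(model.ptd, 1.0)
        assert np.allclose(model.pwt.sum(axis=1), 1.0, atol=1e-8)

    def test_lsi_sigma_matches_dense_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.random((9, 7))
        model = fit_lsi_baseline(dtm_from_dense(a), 3)
        proj = svd_project(dtm_from_dense(a), 3)
        assert np.allclose(proj.Sigma, np.linalg.svd(a, compute_uv=False)[:3], atol=1e-8)
        assert model.pwt.shape == (3, 7) and model.ptd.shape == (9, 3)

    def test_nmf_recovers_exact_factorization(self):
        rng = np.random.default_rng(1)
        a = rng.random((6, 2)) @ rng.random((2, 8))
        model = fit_nmf_baseline(dtm_from_dense(a), 2, max_iter=2000, tol=0.0, seed=0)
        assert model.meta["loss_history"][-1] < 1e-4

    def test_nmf_loss_monotone(self):
        rng = np.random.default_rng(2)
        a = rng.random((10, 12))
        model = fit_nmf_baseline(dtm_from_dense(a), 3, max_iter=100, seed=1)
        hist = model.meta["loss_history"]
        assert all(hist[i + 1] <= hist[i] + 1e-9 for i in range(len(hist) - 1))

    def test_nmf_rejects_negative_input(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_nmf_baseline(dtm_from_dense(np.array([[1.0, -1.0]])), 1)

    def test_nmf_agrees_with_sklearn_reference(self):
        """Reconstruction quality is comparable to sklearn's MU solver."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(3)
        a = rng.random((12, 9))
        mine = fit_nmf_baseline(dtm_from_dense(a), 3, max_iter=500, tol=0.0, seed=0)
        ref = NMF(3, solver="mu", max_iter=500, init="random", random_state=0).fit(a)
        ref_loss = np.linalg.norm(a - ref.transform(a) @ ref.components_) ** 2
        assert mine.meta["loss_history"][-1] <= ref_loss * 1.5


class TestTopWords:
    def test_direct_sort(self):
        model = TopicModel(
            pwt=np.array([[0.5, 0.3, 0.2]]),
            ptd=np.ones((1, 1)),
            algorithm="x",
            C=1,
            vocab=["a", "b", "c"],
        )
        assert [w for w, _ in top_n_words(model, 2)[0]] == ["a", "b"]

    def test_tie_breaks_to_lower_index(self):
        model = TopicModel(
            pwt=np.array([[0.25, 0.5, 0.25]]),
            ptd=np.ones((1, 1)),
            algorithm="x",
            C=1,
            vocab=["a", "b", "c"],
        )
        assert [w for w, _ in top_n_words(model, 3)[0]] == ["b", "a", "c"]

    def test_full_sort_matches_oracle(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(15))
        model = TopicModel(
            pwt=probs[None, :],
            ptd=np.ones((1, 1)),
            algorithm="x",
            C=1,
            vocab=[f"w{i}" for i in range(15)],
        )
        idx, vals = top_n_indices(model, 15)
        expected = sorted(range(15), key=lambda i: (-probs[i], i))
        assert idx[0].tolist() == expected
        assert (np.diff(vals[0]) <= 0).all()


def test_model_serialization_roundtrip(tmp_path, planted_small):
    corpus, _, dtm = planted_small
    model = fit_flsa_w(dtm, 3, cfg=ClusteringConfig(seed=0), vocab=corpus.vocab)
    save_model(model, tmp_path / "m")
    loaded = load_model(tmp_path / "m")
    assert np.allclose(loaded.pwt, model.pwt, atol=1e-12)
    assert np.allclose(loaded.ptd, model.ptd, atol=1e-12)
    assert loaded.vocab == corpus.vocab and loaded.algorithm == model.algorithm


def test_flsa_w_disjoint_vocabulary_diversity(planted_small):
    corpus, _, dtm = planted_small
    model = fit_flsa_w(dtm, 3, cfg=ClusteringConfig(seed=7), vocab=corpus.vocab)
    assert diversity([[w for w, _ in t] for t in top_n_words(model, 20)]) == 1.0
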