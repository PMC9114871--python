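"""Grid experiments: algorithm × topic-count × repetition sweeps.

Enumerates every (algorithm, k, repetition) combination with a derived seed,
fits each model, scores interpretability (coherence, diversity, product)
and predictive performance (AUC/AUK under both embedding modes), and
collects one tidy row per run for downstream aggregation or plotting.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus_io import Corpus, apply_weighting, build_dtm
from .embed_classify import crossval_predict, embed_full, embed_topn, kappa_curve_auk, roc_auc
from .fuzzy_topics import (
    ClusteringConfig,
    TopicModel,
    fit_flsa,
    fit_flsa_v,
    fit_flsa_w,
    fit_lsi_baseline,
    fit_nmf_baseline,
)
from .metrics import CoherenceConfig, evaluate_model

__all__ = ["GridConfig", "RunSpec", "reference_grid", "enumerate_grid", "run_grid",
           "aggregate_grid", "fit_algorithm", "FITTERS"]

METRIC_COLUMNS = [
    "coherence", "diversity", "interpretability",
    "auc_20", "auc_all", "auk_20", "auk_all",
]


@dataclass(frozen=True)
class GridConfig:
    """An experiment grid over algorithms, topic counts and repetitions.

    ``hdp_like`` algorithms choose their own number of topics and are run
    once per repetition outside the k sweep.
    """

    algorithms: tuple[str, ...]
    k_values: tuple[int, ...]
    repetitions: int = 10
    hdp_like: tuple[str, ...] = ()
    base_seed: int = 0

    def __post_init__(self) -> None:
        algs = list(self.algorithms) + list(self.hdp_like)
        if len(set(algs)) != len(algs):
            raise ValueError("duplicate algorithm names in grid")
        ks = list(self.k_values)
        if ks != sorted(ks) or len(set(ks)) != len(ks) or (ks and ks[0] < 1):
            raise ValueError("k_values must be strictly increasing positive")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass(frozen=True)
class RunSpec:
    algorithm: str
    k: int | None  # None for algorithms that pick their own topic count
    rep: int
    seed: int


def reference_grid(base_seed: int = 0) -> GridConfig:
    """The reference study layout: 16 gridded algorithms over k = 5..100 in
    steps of 5, ten repetitions each, plus one k-free algorithm — 3,210 runs.

    Only the fuzzy/dimensionality-reduction algorithms are runnable here;
    the remaining names make the enumeration faithful to the study layout.
    """
    algorithms = (
        "lda", "neural_lda", "prodlda", "nmf", "ctm", "etm", "lsi",
        "flsa_fcm", "flsa_gk", "flsa_fstpso",
        "flsa_w_fcm", "flsa_w_gk", "flsa_w_fstpso",
        "flsa_v_fcm", "flsa_v_gk", "flsa_v_fstpso",
    )
    return GridConfig(
        algorithms=algorithms,
        k_values=tuple(range(5, 101, 5)),
        repetitions=10,
        hdp_like=("hdp",),
        base_seed=base_seed,
    )


def derive_seed(base_seed: int, algorithm: str, k: int | None, rep: int) -> int:
    """Stable per-run seed below 2^31, independent across runs."""
    key = f"{base_seed}|{algorithm}|{k}|{rep}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def enumerate_grid(cfg: GridConfig) -> list[RunSpec]:
    """All runs of the grid in deterministic order, with derived seeds."""
    runs: list[RunSpec] = []
    for alg in cfg.algorithms:
        for k in cfg.k_values:
            for rep in range(cfg.repetitions):
                runs.append(RunSpec(alg, k, rep, derive_seed(cfg.base_seed, alg, k, rep)))
    for alg in cfg.hdp_like:
        for rep in range(cfg.repetitions):
            runs.append(RunSpec(alg, None, rep, derive_seed(cfg.base_seed, alg, None, rep)))
    return runs


def _flsa_fitter(variant: str, method: str):
    def fit(dtm, k, seed, vocab):
        cfg = ClusteringConfig(method=method, seed=seed)
        if variant == "flsa":
            return fit_flsa(dtm, k, cfg=cfg, vocab=vocab)
        if variant == "flsa_w":
            return fit_flsa_w(dtm, k, cfg=cfg, vocab=vocab)
        return fit_flsa_v(dtm, k, cfg=cfg, vocab=vocab)

    return fit


FITTERS = {
    "lsi": lambda dtm, k, seed, vocab: fit_lsi_baseline(dtm, k, vocab=vocab),
    "nmf": lambda dtm, k, seed, vocab: fit_nmf_baseline(dtm, k, seed=seed, vocab=vocab),
    **{
        f"{variant}_{method}": _flsa_fitter(variant, method)
        for variant in ("flsa", "flsa_w", "flsa_v")
        for method in ("fcm", "gk")
    },
}


def fit_algorithm(name: str, dtm, k: int, seed: int, vocab: list[str]) -> TopicModel:
    """Dispatch a fit by algorithm name; unknown names raise KeyError."""
    if name not in FITTERS:
        raise KeyError(f"unknown or unavailable algorithm: {name!r}")
    return FITTERS[name](dtm, k, seed, vocab)


@dataclass
class RunResult:
    spec: RunSpec
    metrics: dict[str, float]
    error: str | None = None


def run_grid(
    cfg: GridConfig,
    corpus: Corpus,
    labels: np.ndarray,
    weighting: str = "tfidf",
    coherence_cfg: CoherenceConfig | None = None,
    embed_n: int = 20,
    folds: int = 10,
) -> pd.DataFrame:
    """Execute every run of the grid and return one row per run.

    Columns: algorithm, k, rep, seed, the three interpretability metrics,
    and AUC/AUK for the top-n ("_20") and full-distribution ("_all")
    embeddings.  A failing run is recorded with NaN metrics and its error
    message rather than aborting the sweep.
    """
    coherence_cfg = coherence_cfg or CoherenceConfig()
    dtm = apply_weighting(build_dtm(corpus), weighting)
    rows = []
    for spec in enumerate_grid(cfg):
        row: dict = {"algorithm": spec.algorithm, "k": spec.k, "rep": spec.rep,
                     "seed": spec.seed, "error": None}
        try:
            model = fit_algorithm(spec.algorithm, dtm, spec.k, spec.seed, corpus.vocab)
            report = evaluate_model(model, corpus, coherence_cfg)
            row["coherence"] = report.coherence
            row["diversity"] = report.diversity
            row["interpretability"] = report.interpretability
            for tag, emb in (
                ("20", embed_topn(model, corpus, n=embed_n)),
                ("all", embed_full(model)),
            ):
                scores = crossval_predict(emb, labels, folds=folds, seed=spec.seed)
                row[f"auc_{tag}"] = roc_auc(scores)
                row[f"auk_{tag}"] = kappa_curve_auk(scores).auk
        except Exception as exc:  # noqa: BLE001 - grid must survive a bad run
            row.update({c: np.nan for c in METRIC_COLUMNS})
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics per (algorithm, k) over repetitions."""
    return (
        results.groupby(["algorithm", "k"], dropna=False)[METRIC_COLUMNS]
        .mean()
        .reset_index()
    )


def interpretability_performance_correlation(
    results: pd.DataFrame, performance: str = "auc_20", method: str = "pearson"
) -> pd.DataFrame:
    """Per-algorithm correlation between interpretability and a performance
    column — the lens for asking whether interpretable models also predict."""
    out = []
    for alg, grp in results.dropna(subset=["interpretability", performance]).groupby("algorithm"):
        if len(grp) >= 3:
            corr = grp["interpretability"].corr(grp[performance], method=method)
            out.append({"algorithm": alg, "correlation": corr, "n_runs": len(grp)})
    return pd.DataFrame(out)
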