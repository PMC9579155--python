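"""End-to-end orchestration: reduce -> fuse -> tune -> train -> evaluate.

Given two feature blocks for the same samples (from files or the synthetic
generator), the pipeline splits them into train/test, fits PCA per block and
CCA across blocks on the training split only, fuses the selected canonical
pairs, tunes (C, g, gamma) of the mixed-kernel SVM with the improved PSO
using stratified 5-fold CV on the fused training features, trains the final
model at the tuned parameters, and evaluates on the untouched test split.
Every stage draws its randomness from a child of one root seed, so a rerun
with the same configuration reproduces the report bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from . import fusion, ipso, metrics, mkl_svm
from .synthetic import FeatureGenSpec, gen_feature_pair

__all__ = ["RunConfig", "run_pipeline", "compare_optimizers"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``pca_dims`` is clamped to the number of available components when the
    input blocks are narrower than the default (which matches the
    98-dimension working point of the deep-feature study).
    """

    seed: int = 0
    train_fraction: float = 0.8
    pca_dims: int = 98
    rho_min: float = 0.8
    fusion_mode: str = "concat"
    n_particles: int = 20
    n_iterations: int = 200
    cv_folds: int = 5
    svm_tol: float = 1e-4
    early_stop_fitness: float | None = None
    feature_spec: FeatureGenSpec | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.pca_dims < 1:
            raise ValueError("pca_dims must be >= 1")

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _child_seeds(root: int, n: int) -> list[int]:
    """Derive independent per-stage seeds (< 2**31) from one root seed."""
    ss = np.random.SeedSequence(root)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: RunConfig,
                 blocks: tuple[fusion.FeatureBlock, fusion.FeatureBlock, np.ndarray] | None = None,
                 ) -> dict:
    """Execute the full flow and return a JSON-serializable report.

    ``blocks`` is (M, N, labels); when omitted, features are generated from
    ``config.feature_spec`` (or its defaults) with a seed derived from the
    run seed.
    """
    seeds = _child_seeds(config.seed, 4)
    if blocks is None:
        spec = config.feature_spec or FeatureGenSpec()
        spec = FeatureGenSpec(**{**asdict(spec), "seed": seeds[0]})
        blocks = gen_feature_pair(spec)
    m_block, n_block, labels = blocks
    labels = np.asarray(labels)

    idx = np.arange(labels.shape[0])
    idx_train, idx_test = train_test_split(
        idx, train_size=config.train_fraction, random_state=seeds[1],
        shuffle=True, stratify=labels)
    m_tr, m_te = m_block.matrix[idx_train], m_block.matrix[idx_test]
    n_tr, n_te = n_block.matrix[idx_train], n_block.matrix[idx_test]
    y_tr, y_te = labels[idx_train], labels[idx_test]

    # PCA fitted on the training split only
    pca_m = fusion.pca_fit(fusion.FeatureBlock(m_tr))
    pca_n = fusion.pca_fit(fusion.FeatureBlock(n_tr))
    d_m = min(config.pca_dims, pca_m.n_components)
    d_n = min(config.pca_dims, pca_n.n_components)
    m_tr_r = fusion.pca_transform(pca_m, m_tr, d_m)
    m_te_r = fusion.pca_transform(pca_m, m_te, d_m)
    n_tr_r = fusion.pca_transform(pca_n, n_tr, d_n)
    n_te_r = fusion.pca_transform(pca_n, n_te, d_n)

    # CCA fusion, also train-only
    cca = fusion.cca_fit(m_tr_r, n_tr_r)
    l1 = fusion.select_pairs(cca, config.rho_min)
    if l1 == 0:  # fall back to the single strongest pair
        l1 = 1
    fused_tr = fusion.fuse(cca, m_tr_r, n_tr_r, mode=config.fusion_mode, n_pairs=l1)
    fused_te = fusion.fuse(cca, m_te_r, n_te_r, mode=config.fusion_mode, n_pairs=l1)

    # IPSO hyperparameter search on the fused training features
    fitness = ipso.make_cv_fitness(fused_tr, y_tr, n_folds=config.cv_folds,
                                   fold_seed=seeds[2], tol=config.svm_tol)
    pso_cfg = ipso.PsoConfig(n_particles=config.n_particles,
                             n_iterations=config.n_iterations,
                             seed=seeds[3],
                             early_stop_fitness=config.early_stop_fitness)
    result = ipso.optimize(fitness, pso_cfg)
    best_params = ipso.decode_position(result.best_position)

    model = mkl_svm.svm_train(fused_tr, y_tr, best_params, tol=1e-4,
                              max_iter=200_000)
    pred, dec = mkl_svm.svm_predict(model, fused_te)
    counts = metrics.confusion(y_te, pred)
    sc = metrics.scores(counts)
    roc = metrics.roc_auc(y_te, dec)

    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_train": int(idx_train.size),
        "n_test": int(idx_test.size),
        "pca_dims": [int(d_m), int(d_n)],
        "canonical_correlations": [round(float(r), 10) for r in cca.rho[:l1]],
        "selected_pairs": int(l1),
        "fused_dim": int(fused_tr.n_features),
        "fusion_mode": config.fusion_mode,
        "best_params": {"C": best_params.C, "g": best_params.g,
                        "gamma": best_params.gamma, "d": best_params.d},
        "cv_fitness": float(result.best_fitness),
        "fitness_trace": [round(float(v), 10) for v in result.trace],
        "n_fitness_evaluations": int(result.n_evaluations),
        "test_metrics": {**sc.as_dict(), "auc": roc.auc},
        "confusion": {"tp": counts.tp, "tn": counts.tn,
                      "fp": counts.fp, "fn": counts.fn},
    }


def compare_optimizers(config: RunConfig,
                       blocks: tuple[fusion.FeatureBlock, fusion.FeatureBlock, np.ndarray] | None = None,
                       ) -> dict:
    """RBF-SVM+PSO vs MKL-SVM+PSO vs MKL-SVM+IPSO on one synthetic split.

    All three methods share the same features, split, CV folds and swarm
    budget (identical fitness-evaluation counts), differing only in the
    kernel (pure RBF forces gamma = 0) and the swarm strategy (baseline PSO
    uses a linearly decaying inertia weight with c1 = c2 = 2).
    """
    seeds = _child_seeds(config.seed, 4)
    if blocks is None:
        spec = config.feature_spec or FeatureGenSpec()
        spec = FeatureGenSpec(**{**asdict(spec), "seed": seeds[0]})
        blocks = gen_feature_pair(spec)
    m_block, n_block, labels = blocks
    labels = np.asarray(labels)

    idx = np.arange(labels.shape[0])
    idx_train, idx_test = train_test_split(
        idx, train_size=config.train_fraction, random_state=seeds[1],
        shuffle=True, stratify=labels)
    pca_m = fusion.pca_fit(fusion.FeatureBlock(m_block.matrix[idx_train]))
    pca_n = fusion.pca_fit(fusion.FeatureBlock(n_block.matrix[idx_train]))
    d_m = min(config.pca_dims, pca_m.n_components)
    d_n = min(config.pca_dims, pca_n.n_components)
    m_tr = fusion.pca_transform(pca_m, m_block.matrix[idx_train], d_m)
    m_te = fusion.pca_transform(pca_m, m_block.matrix[idx_test], d_m)
    n_tr = fusion.pca_transform(pca_n, n_block.matrix[idx_train], d_n)
    n_te = fusion.pca_transform(pca_n, n_block.matrix[idx_test], d_n)
    cca = fusion.cca_fit(m_tr, n_tr)
    l1 = max(fusion.select_pairs(cca, config.rho_min), 1)
    fused_tr = fusion.fuse(cca, m_tr, n_tr, mode=config.fusion_mode, n_pairs=l1)
    fused_te = fusion.fuse(cca, m_te, n_te, mode=config.fusion_mode, n_pairs=l1)
    y_tr, y_te = labels[idx_train], labels[idx_test]

    fitness = ipso.make_cv_fitness(fused_tr, y_tr, n_folds=config.cv_folds,
                                   fold_seed=seeds[2], tol=config.svm_tol)

    def rbf_only_fitness(position: np.ndarray) -> float:
        pos = position.copy()
        pos[2] = 0.0  # gamma = 0 -> pure RBF kernel
        return fitness(pos)

    methods = {
        "rbf_svm_pso": (rbf_only_fitness, "linear", (2.0, 2.0), True),
        "mkl_svm_pso": (fitness, "linear", (2.0, 2.0), False),
        "mkl_svm_ipso": (fitness, "adaptive", "dynamic", False),
    }
    table: dict[str, dict] = {}
    for name, (fit_fn, inertia, factors, rbf_only) in methods.items():
        cfg = ipso.PsoConfig(n_particles=config.n_particles,
                             n_iterations=config.n_iterations,
                             inertia=inertia, factors=factors, seed=seeds[3])
        res = ipso.optimize(fit_fn, cfg)
        pos = res.best_position.copy()
        if rbf_only:
            pos[2] = 0.0
        params = ipso.decode_position(pos)
        model = mkl_svm.svm_train(fused_tr, y_tr, params, tol=1e-4,
                                  max_iter=200_000)
        pred, dec = mkl_svm.svm_predict(model, fused_te)
        sc = metrics.scores(metrics.confusion(y_te, pred))
        roc = metrics.roc_auc(y_te, dec)
        table[name] = {**sc.as_dict(), "auc": roc.auc,
                       "cv_fitness": float(res.best_fitness),
                       "n_fitness_evaluations": int(res.n_evaluations)}
    return {"config_hash": config.config_hash(), "seed": config.seed,
            "fused_dim": int(fused_tr.n_features), "methods": table}
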