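"""PCA reduction and CCA-based fusion of two deep-feature blocks.

Two extractors produce feature matrices M (n x p) and N (n x q) for the same
samples.  Each block is first reduced by PCA (keeping components by
cumulative variance contribution), then canonical correlation analysis finds
paired projection directions W_m, W_n maximizing the correlation rho between
the projected variates.  Only pairs whose correlation clears a threshold
(rho >= rho_min) are retained, and the selected variates are combined either
serially (concatenation, 2*l1 columns) or in parallel (elementwise sum, l1
columns).  Models are always fitted on training data and applied unchanged
to held-out data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.decomposition import PCA

__all__ = [
    "FeatureBlock",
    "PcaModel",
    "CcaModel",
    "pca_fit",
    "pca_transform",
    "cca_fit",
    "select_pairs",
    "fuse",
    "load_feature_block",
    "save_feature_block",
]


@dataclass
class FeatureBlock:
    """A samples x features real matrix with a provenance tag."""

    matrix: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("feature block must be 2-D (samples x features)")
        if m.shape[0] < 2:
            raise ValueError("feature block needs at least 2 samples")
        if not np.all(np.isfinite(m)):
            raise ValueError("feature block contains non-finite entries")
        object.__setattr__(self, "matrix", m)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def _as_matrix(x) -> np.ndarray:
    return x.matrix if isinstance(x, FeatureBlock) else np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaModel:
    """Fitted PCA: mean, orthonormal components (columns) and spectrum."""

    mean: np.ndarray
    components: np.ndarray          # p x k, orthonormal columns
    eigenvalues: np.ndarray         # descending, >= 0
    cumulative_contribution: np.ndarray  # nondecreasing, ends at 1

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def pca_fit(x) -> PcaModel:
    """Fit PCA on the full spectrum of a feature block (centering only).

    ``cumulative_contribution[j]`` is the fraction of total variance carried
    by the first j+1 components — the cumulative variance contribution rate
    used to decide how many dimensions to retain.
    """
    m = _as_matrix(x)
    if m.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if np.allclose(m.var(axis=0), 0.0):
        raise ValueError("PCA undefined for an all-constant block")
    p = PCA(n_components=min(m.shape[0], m.shape[1]), svd_solver="full")
    p.fit(m)
    ev = p.explained_variance_
    return PcaModel(
        mean=p.mean_,
        components=p.components_.T,
        eigenvalues=ev,
        cumulative_contribution=np.cumsum(ev) / ev.sum(),
    )


def pca_transform(model: PcaModel, x, d: int) -> FeatureBlock:
    """Project a block onto the first ``d`` principal components."""
    m = _as_matrix(x)
    if not 1 <= d <= model.n_components:
        raise ValueError(f"d must lie in [1, {model.n_components}], got {d}")
    if m.shape[1] != model.mean.shape[0]:
        raise ValueError("feature dimension mismatch with the fitted model")
    scores = (m - model.mean) @ model.components[:, :d]
    prov = x.provenance if isinstance(x, FeatureBlock) else ""
    return FeatureBlock(matrix=scores, provenance=f"{prov}|pca{d}".lstrip("|"))


# ---------------------------------------------------------------------------
# CCA

@dataclass
class CcaModel:
    """Fitted CCA: projection directions, canonical correlations, selection."""

    w_m: np.ndarray                 # p x k
    w_n: np.ndarray                 # q x k
    rho: np.ndarray                 # descending, in [0, 1]
    mean_m: np.ndarray
    mean_n: np.ndarray
    selected_pairs: int | None = None
    fusion_mode: str = "concat"

    @property
    def n_pairs(self) -> int:
        return self.rho.shape[0]


def cca_fit(m_block, n_block, ridge: float = 1e-12) -> CcaModel:
    """Canonical correlation analysis of two blocks over the same samples.

    Solves the whitened SVD form of the CCA eigenproblem: with centered
    blocks Mc, Nc and covariance matrices S_mm, S_nn, S_mn, the canonical
    directions are W_m = S_mm^{-1/2} U and W_n = S_nn^{-1/2} V where
    U S V^T is the SVD of S_mm^{-1/2} S_mn S_nn^{-1/2}.  A small ridge
    ``ridge * trace(S)/dim`` is added to each auto-covariance so nearly
    collinear deep features stay well conditioned; the default is small
    enough that the canonical correlations remain invariant (to ~1e-6)
    under invertible linear transforms of either block.  Directions are scaled so
    canonical variates have unit sample variance (ddof=1), and signs are
    fixed so the first nonzero loading of each W_m column is positive.
    """
    m = _as_matrix(m_block)
    n = _as_matrix(n_block)
    if m.shape[0] != n.shape[0]:
        raise ValueError("blocks must share the sample dimension")
    n_samp = m.shape[0]
    if n_samp < 3:
        raise ValueError("CCA needs at least 3 samples")
    mean_m, mean_n = m.mean(axis=0), n.mean(axis=0)
    mc, nc = m - mean_m, n - mean_n
    denom = n_samp - 1
    s_mm = mc.T @ mc / denom
    s_nn = nc.T @ nc / denom
    s_mn = mc.T @ nc / denom
    for s in (s_mm, s_nn):
        s[np.diag_indices_from(s)] += ridge * np.trace(s) / s.shape[0]

    l_m = linalg.cholesky(s_mm, lower=True)
    l_n = linalg.cholesky(s_nn, lower=True)
    k_mat = linalg.solve_triangular(l_m, s_mn, lower=True)
    k_mat = linalg.solve_triangular(l_n, k_mat.T, lower=True).T
    u, sv, vt = linalg.svd(k_mat, full_matrices=False)

    k = min(m.shape[1], n.shape[1], n_samp - 1)
    u, sv, vt = u[:, :k], sv[:k], vt[:k]
    w_m = linalg.solve_triangular(l_m, u, lower=True, trans="T")
    w_n = linalg.solve_triangular(l_n, vt.T, lower=True, trans="T")

    # deterministic sign: first nonzero loading of each W_m column positive;
    # W_n flips jointly so each rho keeps its (nonnegative) sign.
    for j in range(k):
        col = w_m[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            w_m[:, j] *= -1
            w_n[:, j] *= -1
    return CcaModel(w_m=w_m, w_n=w_n, rho=np.clip(sv, 0.0, 1.0),
                    mean_m=mean_m, mean_n=mean_n)


def select_pairs(model: CcaModel, rho_min: float) -> int:
    """Count (and record) canonical pairs with rho >= rho_min (inclusive)."""
    l1 = int(np.sum(model.rho >= rho_min))
    model.selected_pairs = l1
    return l1


def fuse(model: CcaModel, m_block, n_block, mode: str = "concat",
         n_pairs: int | None = None) -> FeatureBlock:
    """Combine the selected canonical variates of two blocks.

    ``concat`` stacks M* then N* column-wise (n x 2*l1); ``sum`` adds them
    elementwise (n x l1).  ``n_pairs`` defaults to the count recorded by
    :func:`select_pairs`.
    """
    if mode not in ("concat", "sum"):
        raise ValueError(f"mode must be 'concat' or 'sum', got {mode!r}")
    l1 = model.selected_pairs if n_pairs is None else n_pairs
    if l1 is None:
        raise ValueError("no pair count: call select_pairs first or pass n_pairs")
    if not 1 <= l1 <= model.n_pairs:
        raise ValueError(f"n_pairs must lie in [1, {model.n_pairs}], got {l1}")
    m = _as_matrix(m_block)
    n = _as_matrix(n_block)
    m_star = (m - model.mean_m) @ model.w_m[:, :l1]
    n_star = (n - model.mean_n) @ model.w_n[:, :l1]
    fused = np.hstack([m_star, n_star]) if mode == "concat" else m_star + n_star
    model.fusion_mode = mode
    return FeatureBlock(matrix=fused, provenance=f"cca-{mode}-{l1}")


# ---------------------------------------------------------------------------
# delimited-text I/O for feature blocks

def save_feature_block(block: FeatureBlock, path: str | Path,
                       labels: np.ndarray | None = None) -> None:
    """Write a block as CSV (one row per sample, optional label column)."""
    df = pd.DataFrame(block.matrix, columns=[f"f{j}" for j in range(block.n_features)])
    if labels is not None:
        df["label"] = labels
    df.to_csv(path, index=False)


def load_feature_block(path: str | Path, provenance: str = "") -> tuple[FeatureBlock, np.ndarray | None]:
    """Read a CSV feature block; a ``label`` column, if present, is split off."""
    df = pd.read_csv(path)
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy()
    return FeatureBlock(matrix=df.to_numpy(float), provenance=provenance or str(path)), labels
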