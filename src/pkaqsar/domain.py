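"""Applicability domain: global leverage index and local Tanimoto index.

The global index is Boolean: a query is inside the domain when its
leverage h = x (XᵀX)⁻¹ xᵀ (computed on training-centered features) does
not exceed h* = multiplier × p/n, the classical hat-value cutoff.  The
local index is continuous in [0, 1]: the mean Jaccard–Tanimoto
similarity of the k most similar training fingerprints, accompanied by a
similarity-weighted accuracy estimate derived from the neighbors'
residuals (or, absent training predictions, the weighted spread of their
experimental values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ADParams",
    "ADResult",
    "GlobalAD",
    "global_ad",
    "tanimoto_similarity",
    "local_ad",
]


@dataclass
class ADParams:
    k_neighbors: int = 5
    leverage_threshold_multiplier: float = 3.0
    similarity_floor: float = 0.0  # neighbors below this similarity are ignored
    pca_variance: float = 0.95  # retained variance when p > n

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.leverage_threshold_multiplier <= 0:
            raise ValueError("leverage multiplier must be positive")


@dataclass
class ADResult:
    global_inside: bool | None = None
    leverage: float | None = None
    local_index: float | None = None
    accuracy_estimate: float | None = None
    neighbor_keys: list = field(default_factory=list)
    neighbor_similarities: list = field(default_factory=list)


class GlobalAD:
    """Leverage-based global domain fit on a training design matrix.

    When the feature count exceeds the training size, leverage is
    computed on a PCA projection retaining ``pca_variance`` of the
    variance so XᵀX stays well-conditioned.
    """

    def __init__(self, train_features: np.ndarray, params: ADParams | None = None):
        self.params = params or ADParams()
        X = np.asarray(train_features, dtype=float)
        if X.ndim != 2:
            raise ValueError("train_features must be 2-D")
        self.n = X.shape[0]
        self.center = X.mean(axis=0)
        Xc = X - self.center
        self.projection: np.ndarray | None = None
        if X.shape[1] >= self.n:
            # PCA via SVD of the centered design
            U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
            var = s**2
            frac = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
            ncomp = int(np.searchsorted(frac, self.params.pca_variance) + 1)
            ncomp = min(ncomp, self.n - 1) if self.n > 1 else 1
            self.projection = Vt[:ncomp].T
            Xc = Xc @ self.projection
        self.p = int(np.linalg.matrix_rank(Xc)) if Xc.size else 0
        self.gram_inv = np.linalg.pinv(Xc.T @ Xc)
        self._train_proj = Xc

    @property
    def h_star(self) -> float:
        return self.params.leverage_threshold_multiplier * self.p / self.n

    def leverage(self, query: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(query, dtype=float)) - self.center
        if self.projection is not None:
            q = q @ self.projection
        return np.einsum("ij,jk,ik->i", q, self.gram_inv, q)

    def training_leverages(self) -> np.ndarray:
        return np.einsum(
            "ij,jk,ik->i", self._train_proj, self.gram_inv, self._train_proj
        )

    def check(self, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.leverage(query)
        return h <= self.h_star, h


def global_ad(
    train_features: np.ndarray,
    query_features: np.ndarray,
    params: ADParams | None = None,
) -> tuple[bool | np.ndarray, float | np.ndarray]:
    """(inside, leverage) for one query row or a batch."""
    ad = GlobalAD(train_features, params)
    q = np.asarray(query_features, dtype=float)
    single = q.ndim == 1
    inside, h = ad.check(q)
    if single:
        return bool(inside[0]), float(h[0])
    return inside, h


def tanimoto_similarity(fp_a, fp_b) -> float:
    """|a∧b| / |a∨b| for binary vectors; two all-zero vectors → 1."""
    a = np.asarray(fp_a)
    b = np.asarray(fp_b)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    a = a.astype(bool)
    b = b.astype(bool)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _tanimoto_matrix(train_fps: np.ndarray, query_fp: np.ndarray) -> np.ndarray:
    T = np.asarray(train_fps).astype(bool)
    q = np.asarray(query_fp).astype(bool)
    inter = np.logical_and(T, q).sum(axis=1)
    union = np.logical_or(T, q).sum(axis=1)
    sims = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    return sims.astype(float)


def local_ad(
    train_fps: np.ndarray,
    train_pka: np.ndarray,
    query_fp: np.ndarray,
    params: ADParams | None = None,
    train_predicted: np.ndarray | None = None,
    train_keys=None,
) -> ADResult:
    """Local domain index and accuracy estimate for one query.

    ``local_index`` is the mean Tanimoto similarity of the k nearest
    training fingerprints.  The accuracy estimate (pKa units) is the
    similarity-weighted mean absolute residual of those neighbors when
    ``train_predicted`` is given, else the similarity-weighted standard
    deviation of their experimental values.
    """
    params = params or ADParams()
    T = np.asarray(train_fps)
    y = np.asarray(train_pka, dtype=float)
    n = T.shape[0]
    if params.k_neighbors > n:
        raise ValueError(f"k_neighbors={params.k_neighbors} exceeds training size {n}")
    sims = _tanimoto_matrix(T, query_fp)
    order = np.argsort(-sims, kind="stable")[: params.k_neighbors]
    s = sims[order]
    keep = s >= params.similarity_floor
    idx = order[keep] if keep.any() else order
    s = sims[idx]
    local_index = float(s.mean())

    w = s if s.sum() > 0 else np.ones_like(s)
    if train_predicted is not None:
        res = np.abs(y[idx] - np.asarray(train_predicted, dtype=float)[idx])
        acc = float(np.average(res, weights=w))
    else:
        mean = float(np.average(y[idx], weights=w))
        acc = float(np.sqrt(np.average((y[idx] - mean) ** 2, weights=w)))

    keys = [train_keys[i] for i in idx] if train_keys is not None else list(map(int, idx))
    return ADResult(
        local_index=local_index,
        accuracy_estimate=acc,
        neighbor_keys=keys,
        neighbor_similarities=[float(v) for v in s],
    )
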