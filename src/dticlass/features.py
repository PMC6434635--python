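"""Univariate feature selection and locally linear embedding.

Selection ranks features by a two-sample t-test (pooled variance by
default) and keeps the D smallest p-values.  Dimensionality is then
reduced from D to d with locally linear embedding (LLE): each point is
reconstructed from its k nearest neighbors with weights summing to one,
and the embedding is given by the bottom nontrivial eigenvectors of
(I - W)^T (I - W).  Held-out subjects are mapped into the trained
embedding with the standard weight-based out-of-sample extension: find
the new point's k nearest training points, compute the same constrained
reconstruction weights, and take the weighted combination of their
embedding coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .cohort import CohortTable

__all__ = [
    "SelectionResult",
    "LLEModel",
    "ttest_scores",
    "select_top_features",
    "lle_fit",
    "lle_transform",
]


# --------------------------------------------------------------------------
# t-test selection
# --------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Per-feature t statistics / p-values and the selected index set."""

    t: np.ndarray
    p: np.ndarray
    selected: np.ndarray  # indices, ranked best-first
    zero_variance_flagged: bool = False

    @property
    def n_selected(self) -> int:
        return self.selected.size


def ttest_scores(X: np.ndarray, y: np.ndarray, equal_var: bool = True):
    """Two-sample t per feature, patients (y=1) minus controls (y=0).

    Pooled-variance by default; ``equal_var=False`` gives Welch's t.
    Features where both groups are constant with identical means get
    t = 0, p = 1 by convention (flagged via the returned mask).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    g1 = X[y == 1]
    g0 = X[y == 0]
    if g1.shape[0] < 2 or g0.shape[0] < 2:
        raise ValueError("need at least 2 subjects per class for a t-test")
    n1, n0 = g1.shape[0], g0.shape[0]
    m1 = g1.mean(axis=0)
    m0 = g0.mean(axis=0)
    v1 = g1.var(axis=0, ddof=1)
    v0 = g0.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        dof = np.full(X.shape[1], n1 + n0 - 2, dtype=float)
    else:
        a, b = v1 / n1, v0 / n0
        se = np.sqrt(a + b)
        with np.errstate(invalid="ignore", divide="ignore"):
            dof = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n0 - 1))
        dof = np.nan_to_num(dof, nan=n1 + n0 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m0) / se
    degenerate = se == 0
    t = np.where(degenerate, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(degenerate, 1.0, p)
    return t, p, degenerate


def select_top_features(t: np.ndarray, p: np.ndarray, D: int,
                        p_cap: float | None = None,
                        degenerate: np.ndarray | None = None
                        ) -> SelectionResult:
    """Indices of the D smallest p-values.

    Ties on p are broken by larger |t|, then by lower feature index, so
    the outcome is deterministic.  ``p_cap`` optionally discards
    selected features whose p exceeds it.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if D <= 0:
        raise ValueError("D must be positive")
    if D > p.size:
        raise ValueError(f"D={D} exceeds the {p.size} available features")
    order = np.lexsort((np.arange(p.size), -np.abs(t), p))
    selected = order[:D]
    if p_cap is not None:
        selected = selected[p[selected] <= p_cap]
    flagged = bool(degenerate.any()) if degenerate is not None else False
    return SelectionResult(t=t, p=p, selected=selected,
                           zero_variance_flagged=flagged)


def ttest_select(table: CohortTable, D: int,
                 equal_var: bool = True) -> SelectionResult:
    """Convenience wrapper: score a cohort table and take the top D."""
    t, p, degenerate = ttest_scores(table.X, table.y, equal_var=equal_var)
    return select_top_features(t, p, D, degenerate=degenerate)


# --------------------------------------------------------------------------
# locally linear embedding
# --------------------------------------------------------------------------

@dataclass
class LLEModel:
    """Trained LLE: training points, weights, and embedding coordinates."""

    X: np.ndarray  # (n, D) training points
    k: int
    d: int
    reg: float
    W: np.ndarray  # (n, n) row-stochastic reconstruction weights
    embedding: np.ndarray  # (n, d), unit-norm eigenvector columns
    eigenvalues: np.ndarray  # the d retained eigenvalues (ascending)


def _reconstruction_weights(Z: np.ndarray, reg: float) -> np.ndarray:
    """Constrained weights for one point: Z is (k, D) of neighbor offsets.

    Minimizes ||sum_j w_j z_j||^2 subject to sum w = 1 via the
    Tikhonov-regularized local Gram system (G + alpha I) w = 1.
    """
    k = Z.shape[0]
    G = Z @ Z.T
    tr = np.trace(G)
    alpha = reg * (tr / k) if tr > 0 else reg
    w = np.linalg.solve(G + alpha * np.eye(k), np.ones(k))
    return w / w.sum()


def _knn_indices(D2: np.ndarray, k: int, exclude_self: bool) -> np.ndarray:
    """k nearest neighbors per row of a squared-distance matrix.

    Stable argsort so exact ties resolve to the lower index.
    """
    order = np.argsort(D2, axis=1, kind="stable")
    if exclude_self:
        n = D2.shape[0]
        out = np.empty((n, k), dtype=int)
        for i in range(n):
            row = order[i]
            out[i] = row[row != i][:k]
        return out
    return order[:, :k]


def lle_fit(X: np.ndarray, k: int = 12, d: int = 10,
            reg: float = 1e-3) -> LLEModel:
    """Standard LLE with dense eigen-decomposition.

    Neighbors by Euclidean distance; per-point weights from the
    regularized local Gram matrix (alpha = reg * trace(G)/k); embedding
    = eigenvectors 2..d+1 (ascending eigenvalues) of (I-W)^T (I-W),
    each column's sign fixed so its largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    if n < d + 1:
        raise ValueError(f"need at least d+1={d + 1} points, got {n}")
    if d >= k:
        warnings.warn(
            f"d={d} >= k={k}: embedding dimension at or above the "
            "neighborhood size is poorly constrained",
            stacklevel=2,
        )
    D2 = cdist(X, X, "sqeuclidean")
    nbrs = _knn_indices(D2, k, exclude_self=True)

    # batched weight solve
    Z = X[nbrs] - X[:, None, :]  # (n, k, D)
    G = Z @ np.swapaxes(Z, 1, 2)  # (n, k, k)
    tr = np.trace(G, axis1=1, axis2=2)
    dup = tr <= 1e-300
    if dup.any():
        warnings.warn(
            "duplicate points produced singular local Gram matrices; "
            "regularization carries the solve",
            stacklevel=2,
        )
    alpha = np.where(tr > 0, reg * tr / k, reg)
    G = G + alpha[:, None, None] * np.eye(k)[None]
    w = np.linalg.solve(G, np.ones((n, k, 1)))[:, :, 0]
    w = w / w.sum(axis=1, keepdims=True)

    W = np.zeros((n, n))
    np.put_along_axis(W, nbrs, w, axis=1)

    IW = np.eye(n) - W
    M = IW.T @ IW
    vals, vecs = np.linalg.eigh(M)
    emb = vecs[:, 1:d + 1]
    # sign convention: largest-|entry| positive per column
    sign_ref = emb[np.argmax(np.abs(emb), axis=0), np.arange(d)]
    emb = emb * np.where(sign_ref < 0, -1.0, 1.0)
    return LLEModel(X=X, k=k, d=d, reg=reg, W=W, embedding=emb,
                    eigenvalues=vals[1:d + 1])


def lle_transform(model: LLEModel, x_new: np.ndarray) -> np.ndarray:
    """Out-of-sample mapping of new points into the trained embedding.

    Each new point is reconstructed from its k nearest training points
    with the same constrained weights used in fitting, and mapped to the
    identical weighted combination of their embedding coordinates.  A
    point coinciding exactly with a training point returns that point's
    embedding.  Accepts a single (D,) vector or an (m, D) batch.
    """
    x = np.asarray(x_new, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"dimension mismatch: model expects {model.X.shape[1]} "
            f"features, got {x.shape[1]}"
        )
    D2 = cdist(x, model.X, "sqeuclidean")
    nbrs = _knn_indices(D2, model.k, exclude_self=False)
    out = np.empty((x.shape[0], model.d))
    scale = float(np.mean(np.sum(model.X**2, axis=1))) or 1.0
    for i in range(x.shape[0]):
        exact = np.nonzero(D2[i] <= 1e-24 * scale)[0]
        if exact.size:
            out[i] = model.embedding[exact].mean(axis=0)
            continue
        idx = nbrs[i]
        w = _reconstruction_weights(model.X[idx] - x[i], model.reg)
        out[i] = w @ model.embedding[idx]
    return out[0] if single else out
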