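"""Baseline correspondence scores: fixed metrics and a learned linear metric.

All baselines share the correspondence-matrix contract: given cells (C x G')
and atlas positions (P x G') in [0,1], produce S in [0,1]^(C x P) where a
distance of zero maps to similarity 1.  Distances are converted to
similarities by S = 1 - d / d_max with d_max the global maximum over all
cell-position pairs (per-cell scaling available behind a flag).

The learned baseline is a push-only variant of large-margin nearest
neighbors: each atlas position is its own sole target (at distance zero) and
every other position is an imposter, so fitting maximizes pairwise
separation under a linear transform T via the hinge objective

    f(T) = sum_{i != j} max(0, D - ||T (x_i - x_j)||^2)

with margin D equal to the input dimensionality.  For very wide matrices a
50-component PCA reduction is applied before fitting and scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .io_prep import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "BASELINE_KINDS",
    "LinearMetric",
    "fixed_metric_scores",
    "percent_difference",
    "fit_lmnn",
    "lmnn_scores",
]

BASELINE_KINDS = ("two_norm", "inf_norm", "percent_diff")


def _to_similarity(d: np.ndarray, per_cell: bool = False) -> np.ndarray:
    if per_cell:
        d_max = d.max(axis=1, keepdims=True)
        d_max = np.where(d_max > 0, d_max, 1.0)
    else:
        m = float(d.max())
        d_max = m if m > 0 else 1.0
    return 1.0 - d / d_max


def percent_difference(cells: np.ndarray, atlas: np.ndarray) -> np.ndarray:
    """Mean over genes of |c-p| / ((c+p)/2), with 0/0 terms defined as 0."""
    C, G = cells.shape
    P = atlas.shape[0]
    d = np.empty((C, P))
    # chunk over cells: the C x P x G intermediate can be large
    chunk = max(1, int(2e7) // max(P * G, 1))
    for s in range(0, C, chunk):
        c = cells[s:s + chunk, None, :]      # b x 1 x G
        p = atlas[None, :, :]                # 1 x P x G
        num = np.abs(c - p)
        den = (c + p) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        d[s:s + chunk] = term.mean(axis=2)
    return d


def fixed_metric_scores(
    cells: np.ndarray,
    atlas: np.ndarray,
    kind: str = "two_norm",
    per_cell_scaling: bool = False,
) -> np.ndarray:
    """Correspondence scores from a fixed metric in common-gene space."""
    cells = np.atleast_2d(np.asarray(cells, float))
    atlas = np.atleast_2d(np.asarray(atlas, float))
    if cells.size == 0 or atlas.size == 0:
        raise InputError("empty input matrix")
    if cells.shape[1] != atlas.shape[1]:
        raise InputError("cells and atlas must share the gene dimension")
    if kind == "two_norm":
        d = cdist(cells, atlas, metric="euclidean")
    elif kind == "inf_norm":
        d = cdist(cells, atlas, metric="chebyshev")
    elif kind == "percent_diff":
        d = percent_difference(cells, atlas)
    else:
        raise InputError(f"unknown baseline kind {kind!r}; one of {BASELINE_KINDS}")
    return _to_similarity(d, per_cell=per_cell_scaling)


@dataclass
class LinearMetric:
    """A linear transform defining the distance d(x, y) = ||T (x - y)||_2."""

    transform: np.ndarray
    fitted_dim: int
    objective_history: list[float] | None = None
    reducer_basis: np.ndarray | None = None  # original-dim x 50 PCA basis
    reducer_mean: np.ndarray | None = None

    def reduce(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if self.reducer_basis is not None:
            X = (X - self.reducer_mean) @ self.reducer_basis
        if X.shape[1] != self.fitted_dim:
            raise InputError(
                f"expected dimension {self.fitted_dim}, got {X.shape[1]}"
            )
        return X

    def distance(self, cells: np.ndarray, atlas: np.ndarray) -> np.ndarray:
        c = self.reduce(np.atleast_2d(cells)) @ self.transform.T
        p = self.reduce(np.atleast_2d(atlas)) @ self.transform.T
        return cdist(c, p, metric="euclidean")


def _push_objective(T: np.ndarray, diffs: np.ndarray, margin: float) -> tuple[float, np.ndarray]:
    """Hinge objective and its gradient over all ordered position pairs."""
    proj = diffs @ T.T                     # K x d
    sq = np.einsum("kd,kd->k", proj, proj)
    slack = margin - sq
    active = slack > 0
    f = float(slack[active].sum())
    if not np.any(active):
        return f, np.zeros_like(T)
    da = diffs[active]
    # grad of -||T delta||^2 summed over active pairs = -2 T (sum delta delta^T)
    G = -2.0 * T @ (da.T @ da)
    return f, G


def fit_lmnn(
    atlas: np.ndarray,
    margin: float | None = None,
    max_iter: int = 200,
    step_size: float = 1e-3,
    tol: float = 1e-10,
    pca_threshold: int = 50,
    seed: int = 0,
) -> LinearMetric:
    """Fit the push-only linear metric on atlas positions.

    Gradient descent with backtracking from the identity transform.  The
    margin defaults to the (possibly reduced) input dimensionality.  If the
    objective has not reached zero after ``max_iter`` iterations the best
    iterate is returned with a warning.  Coincident positions can never be
    separated; their irreducible contribution is reported in the history.
    """
    X = np.atleast_2d(np.asarray(atlas, float))
    P, D0 = X.shape
    if P < 2:
        raise InputError("need at least 2 positions to fit a metric")
    reducer_basis = reducer_mean = None
    if D0 > pca_threshold:
        pca = PCA(n_components=min(pca_threshold, P - 1, D0), svd_solver="full")
        pca.fit(X)
        reducer_basis = pca.components_.T
        reducer_mean = pca.mean_
        X = (X - reducer_mean) @ reducer_basis
    d = X.shape[1]
    if margin is None:
        margin = float(d)

    iu, ju = np.triu_indices(P, k=1)
    diffs = X[iu] - X[ju]                 # unordered pairs; ordered = 2x
    T = np.eye(d)
    f, G = _push_objective(T, diffs, margin)
    history = [2.0 * f]
    step = step_size
    for _ in range(max_iter):
        if f <= tol:
            break
        accepted = False
        for _ in range(30):
            T_new = T - step * (2.0 * G)  # ordered-pair gradient
            f_new, G_new = _push_objective(T_new, diffs, margin)
            if f_new < f:
                T, f, G = T_new, f_new, G_new
                step *= 1.2
                accepted = True
                break
            step *= 0.5
        history.append(2.0 * f)
        if not accepted:
            break
    if f > tol:
        n_coincident = int(np.sum(np.einsum("kd,kd->k", diffs, diffs) == 0))
        logger.warning(
            "push-only LMNN objective %.4g > 0 after %d iterations "
            "(%d coincident position pairs can never separate); "
            "returning best iterate", 2.0 * f, max_iter, n_coincident,
        )
    return LinearMetric(
        transform=T,
        fitted_dim=d,
        objective_history=history,
        reducer_basis=reducer_basis,
        reducer_mean=reducer_mean,
    )


def lmnn_scores(
    metric: LinearMetric,
    cells: np.ndarray,
    atlas: np.ndarray,
    per_cell_scaling: bool = False,
) -> np.ndarray:
    """Correspondence scores under the learned metric (global [0,1] scaling)."""
    d = metric.distance(cells, atlas)
    return _to_similarity(d, per_cell=per_cell_scaling)
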