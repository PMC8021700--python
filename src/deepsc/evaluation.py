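"""Evaluation frameworks for correspondence-scoring methods.

Two complementary measures are implemented, both method-agnostic: any
callable producing a C x P correspondence matrix in [0,1] can be evaluated.

1. **Performance score E** on self-mapped atlases.  The atlas's own
   positions serve as simulated cells with known origins (cell i <-> position
   i).  Per cell, three penalties in [0,1] are combined:

       E_i = 1 - (1/3) * (accuracy_i + precision_i + robustness_i)

   accuracy_i = 1 - S_ii; precision_i = |1 - sum_j S_ij| / (P - 1);
   robustness_i = (1 - sigma*_i)^4, where sigma*_i is the smallest Gaussian
   noise level (sd on [0,1]-scaled inputs) that raises the mean of the
   accuracy and precision penalties by 0.1 over their noise-free values,
   capped at 1.  E = mean over cells; E = 1 is an ideal mapping.

2. **Predictive reproducibility** by k-fold gene dropout.  Common genes are
   split into k folds; each gene is predicted from scores computed without
   its fold, as a score-weighted average over positions (cell direction) or
   cells (atlas direction).  One minus the mean absolute prediction error,
   computed separately over zero-valued and positive-valued entries, gives
   R_sc_zero, R_sc_nonzero, R_atlas_zero and R_atlas_nonzero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .io_prep import AlignedPair, InputError, SpatialAtlas

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringMethod",
    "PerformanceBreakdown",
    "ReproducibilityReport",
    "accuracy_penalty",
    "precision_penalty",
    "sigma_star",
    "performance_score",
    "kfold_gene_split",
    "predict_cell_expression",
    "predict_atlas_expression",
    "reproducibility",
    "DEFAULT_NOISE_GRID",
]

DEFAULT_NOISE_GRID = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))


@dataclass
class ScoringMethod:
    """A named (cells, atlas) -> correspondence-matrix callable.

    ``func`` receives a C x G' cell matrix and a P x G' atlas matrix (both in
    [0,1]) and must return a finite C x P matrix in [0,1].  Methods that need
    fitting do it inside the callable (so gene-subset re-scoring refits), or
    are pre-fitted and frozen by their factory.
    """

    func: Callable[[np.ndarray, np.ndarray], np.ndarray]
    label: str = "method"

    def __call__(self, cells: np.ndarray, atlas: np.ndarray) -> np.ndarray:
        S = np.asarray(self.func(cells, atlas), dtype=float)
        if S.shape != (np.atleast_2d(cells).shape[0], np.atleast_2d(atlas).shape[0]):
            raise InputError(
                f"{self.label}: scorer returned shape {S.shape}, expected "
                f"({np.atleast_2d(cells).shape[0]}, {np.atleast_2d(atlas).shape[0]})"
            )
        if not np.all(np.isfinite(S)):
            raise InputError(f"{self.label}: non-finite correspondence scores")
        if S.min() < -1e-9 or S.max() > 1 + 1e-9:
            raise InputError(f"{self.label}: scores outside [0,1]")
        return np.clip(S, 0.0, 1.0)


@dataclass
class PerformanceBreakdown:
    accuracy_penalty: np.ndarray
    precision_penalty: np.ndarray
    sigma_star: np.ndarray
    robustness_penalty: np.ndarray
    per_cell_score: np.ndarray
    score: float
    noise_grid: tuple
    replicates: int
    label: str = "method"

    def per_position_table(self, atlas: SpatialAtlas | None = None) -> pd.DataFrame:
        """Per-position penalty table (heatmap-ready when coordinates exist)."""
        df = pd.DataFrame({
            "accuracy_penalty": self.accuracy_penalty,
            "precision_penalty": self.precision_penalty,
            "sigma_star": self.sigma_star,
            "robustness_penalty": self.robustness_penalty,
            "performance": self.per_cell_score,
        })
        if atlas is not None:
            df.insert(0, "position", atlas.position_ids)
            for k, name in enumerate(("x", "y", "z")[: atlas.coordinates.shape[1]]):
                df.insert(1 + k, name, atlas.coordinates[:, k])
        return df


def accuracy_penalty(S: np.ndarray) -> np.ndarray:
    """Per-cell 1 - S_ii on exact-copy simulated cells (cell i <-> position i)."""
    S = np.asarray(S, float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InputError(
            "accuracy penalty requires a square matrix (C = P exact-copy cells)"
        )
    return 1.0 - np.diag(S)


def precision_penalty(S: np.ndarray, off_diagonal_mean: bool = False) -> np.ndarray:
    """Per-cell |1 - sum_j S_ij| / (P - 1).

    ``off_diagonal_mean=True`` selects the alternative reading (mean score
    over the P-1 non-self positions); both coincide at the ideal one-hot row
    and the all-ones worst case.
    """
    S = np.asarray(S, float)
    P = S.shape[1]
    if P < 2:
        raise InputError("precision penalty requires P >= 2 positions")
    if off_diagonal_mean:
        if S.shape[0] != P:
            raise InputError("off-diagonal reading requires a square matrix")
        return (S.sum(axis=1) - np.diag(S)) / (P - 1)
    return np.abs(1.0 - S.sum(axis=1)) / (P - 1)


def _mean_penalty(S: np.ndarray, off_diagonal_mean: bool) -> np.ndarray:
    return 0.5 * (accuracy_penalty(S) + precision_penalty(S, off_diagonal_mean))


def sigma_star(
    method: ScoringMethod,
    atlas_matrix: np.ndarray,
    noise_grid=DEFAULT_NOISE_GRID,
    replicates: int = 5,
    rng: np.random.Generator | None = None,
    jump: float = 0.1,
    off_diagonal_mean: bool = False,
    baseline_S: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell noise level at which the mean accuracy+precision penalty jumps.

    Exact-copy cells are perturbed with Gaussian(0, sigma^2) (clipped to
    [0,1]) for each sigma in the grid, re-scored, and penalties averaged over
    replicates; sigma*_i is the smallest grid sigma whose penalty exceeds the
    noise-free value by ``jump``, or 1 if none does.
    """
    grid = np.asarray(noise_grid, float)
    if grid.size == 0:
        raise InputError("noise grid must be non-empty")
    if replicates < 1:
        raise InputError("need at least one replicate")
    rng = rng or np.random.default_rng(0)
    X = np.asarray(atlas_matrix, float)
    if baseline_S is None:
        baseline_S = method(X, X)
    m0 = _mean_penalty(baseline_S, off_diagonal_mean)
    P = X.shape[0]
    sig = np.ones(P)
    undecided = np.ones(P, dtype=bool)
    for s in np.sort(grid):
        pen = np.zeros(P)
        for _ in range(replicates):
            noisy = np.clip(X + rng.normal(0.0, s, size=X.shape), 0.0, 1.0)
            pen += _mean_penalty(method(noisy, X), off_diagonal_mean)
        pen /= replicates
        hit = undecided & (pen - m0 >= jump - 1e-12)
        sig[hit] = s
        undecided &= ~hit
        if not undecided.any():
            break
    return sig


def performance_score(
    method: ScoringMethod,
    atlas: SpatialAtlas | np.ndarray,
    noise_grid=DEFAULT_NOISE_GRID,
    replicates: int = 5,
    seed: int = 0,
    off_diagonal_mean: bool = False,
) -> PerformanceBreakdown:
    """Full accuracy/precision/robustness evaluation on exact-copy cells."""
    X = atlas.expression if isinstance(atlas, SpatialAtlas) else np.asarray(atlas, float)
    S0 = method(X, X)
    acc = accuracy_penalty(S0)
    prec = precision_penalty(S0, off_diagonal_mean)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7369]))
    sig = sigma_star(
        method, X, noise_grid=noise_grid, replicates=replicates, rng=rng,
        off_diagonal_mean=off_diagonal_mean, baseline_S=S0,
    )
    robust = (1.0 - sig) ** 4
    E_i = 1.0 - (acc + prec + robust) / 3.0
    return PerformanceBreakdown(
        accuracy_penalty=acc,
        precision_penalty=prec,
        sigma_star=sig,
        robustness_penalty=robust,
        per_cell_score=E_i,
        score=float(E_i.mean()),
        noise_grid=tuple(np.asarray(noise_grid, float)),
        replicates=replicates,
        label=method.label,
    )


# ---------------------------------------------------------------------------
# predictive reproducibility
# ---------------------------------------------------------------------------

def kfold_gene_split(gene_ids: list[str], k: int, seed: int = 0) -> np.ndarray:
    """Seeded balanced partition of genes into k folds (sizes differ by <= 1).

    Returns the fold label of each gene, aligned with ``gene_ids``.  The same
    seed yields the same split, so every method can be evaluated on an
    identical fold assignment.
    """
    n = len(gene_ids)
    if k < 1 or k > n:
        raise InputError(f"k must lie in [1, {n}], got {k}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x666f6c64]))
    folds = np.empty(n, dtype=int)
    folds[rng.permutation(n)] = np.arange(n) % k
    return folds


def _weighted_prediction(weights: np.ndarray, values: np.ndarray, axis_name: str) -> np.ndarray:
    totals = weights.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        logger.warning(
            "%d %s with all-zero score weights; predicting 0", int(zero.sum()), axis_name
        )
    safe = np.where(zero, 1.0, totals)
    out = (weights @ values) / safe
    out[zero] = 0.0
    return out


def predict_cell_expression(S_k: np.ndarray, atlas_gene: np.ndarray) -> np.ndarray:
    """Score-weighted average of an atlas gene over positions, per cell."""
    S_k = np.atleast_2d(np.asarray(S_k, float))
    return _weighted_prediction(S_k, np.asarray(atlas_gene, float), "cells")


def predict_atlas_expression(S_k: np.ndarray, cell_gene: np.ndarray) -> np.ndarray:
    """Score-weighted average of a cell gene over cells, per position."""
    S_k = np.atleast_2d(np.asarray(S_k, float))
    return _weighted_prediction(S_k.T, np.asarray(cell_gene, float), "positions")


@dataclass
class ReproducibilityReport:
    per_gene: pd.DataFrame
    R_sc_zero: float
    R_sc_nonzero: float
    R_atlas_zero: float
    R_atlas_nonzero: float
    fold_assignment: np.ndarray
    k: int
    seed: int
    label: str = "method"

    def summary(self) -> dict:
        return {
            "method": self.label,
            "k": self.k,
            "seed": self.seed,
            "R_sc_zero": self.R_sc_zero,
            "R_sc_nonzero": self.R_sc_nonzero,
            "R_atlas_zero": self.R_atlas_zero,
            "R_atlas_nonzero": self.R_atlas_nonzero,
        }


def _r_value(pred: np.ndarray, true: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        return np.nan
    return 1.0 - float(np.abs(pred[mask] - true[mask]).sum()) / int(mask.sum())


def reproducibility(
    method: ScoringMethod,
    aligned: AlignedPair | tuple[np.ndarray, np.ndarray],
    k: int = 4,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> ReproducibilityReport:
    """k-fold gene-dropout predictive reproducibility of a scoring method.

    For each fold, scores are recomputed with that fold's genes removed (the
    method callable refits on the reduced gene set as it sees fit).  Each
    held-out gene is then predicted in both directions; per-gene R values are
    one minus the mean absolute error over the zero-valued and
    positive-valued index sets (a value is undefined, and excluded from the
    aggregate, when its index set is empty).
    """
    if isinstance(aligned, AlignedPair):
        cells = aligned.cell_matrix()
        atlas = aligned.atlas_matrix()
        gene_ids = aligned.gene_ids
    else:
        cells, atlas = (np.atleast_2d(np.asarray(m, float)) for m in aligned)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(cells.shape[1])]
    if cells.max() > 1 or cells.min() < 0:
        raise InputError("cell expression must lie in [0,1] for reproducibility")
    folds = kfold_gene_split(gene_ids, k, seed=seed)

    records = []
    for f in range(k):
        keep = folds != f
        S_f = method(cells[:, keep], atlas[:, keep])
        for g in np.flatnonzero(folds == f):
            c_true = cells[:, g]
            p_true = atlas[:, g]
            c_hat = predict_cell_expression(S_f, p_true)
            p_hat = predict_atlas_expression(S_f, c_true)
            records.append({
                "gene": gene_ids[g],
                "fold": f,
                "R_sc_zero": _r_value(c_hat, c_true, c_true == 0),
                "R_sc_nonzero": _r_value(c_hat, c_true, c_true > 0),
                "R_atlas_zero": _r_value(p_hat, p_true, p_true == 0),
                "R_atlas_nonzero": _r_value(p_hat, p_true, p_true > 0),
                "n_sc_zero": int((c_true == 0).sum()),
                "n_sc_nonzero": int((c_true > 0).sum()),
                "n_atlas_zero": int((p_true == 0).sum()),
                "n_atlas_nonzero": int((p_true > 0).sum()),
            })
    per_gene = pd.DataFrame.from_records(records)
    agg = {
        col: float(np.nanmean(per_gene[col])) if per_gene[col].notna().any() else np.nan
        for col in ("R_sc_zero", "R_sc_nonzero", "R_atlas_zero", "R_atlas_nonzero")
    }
    return ReproducibilityReport(
        per_gene=per_gene,
        fold_assignment=folds,
        k=k,
        seed=seed,
        label=method.label,
        **agg,
    )
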