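"""Factories producing :class:`~deepsc.evaluation.ScoringMethod` objects.

Two flavors exist for the trainable methods:

* **frozen** — fitted once on a given atlas, then applied unchanged.  This is
  what the performance-score noise sweep needs: the model must not retrain
  between noise levels.
* **refit** — the callable fits on whatever (cells, atlas) matrices it is
  handed.  This is what gene-dropout reproducibility needs: removing a fold
  changes the gene set, so the feature space (and network, for the learned
  method) is re-fitted per fold.

Fixed-metric baselines need no fitting and behave identically either way.
"""

from __future__ import annotations

import numpy as np

from .baselines import BASELINE_KINDS, fit_lmnn, fixed_metric_scores, lmnn_scores
from .core import NetworkParams, TrainingConfig, score_cells, train
from .evaluation import ScoringMethod
from .io_prep import FeatureSpace, InputError, fit_feature_space, project

__all__ = [
    "baseline_method",
    "lmnn_frozen",
    "lmnn_refit",
    "deepsc_frozen",
    "deepsc_refit",
    "deepsc_scores",
    "external_method",
]


def baseline_method(kind: str, per_cell_scaling: bool = False) -> ScoringMethod:
    """A fixed-metric baseline (two_norm, inf_norm or percent_diff)."""
    if kind not in BASELINE_KINDS:
        raise InputError(f"kind must be one of {BASELINE_KINDS}")

    def _score(cells: np.ndarray, atlas: np.ndarray) -> np.ndarray:
        return fixed_metric_scores(cells, atlas, kind=kind, per_cell_scaling=per_cell_scaling)

    return ScoringMethod(func=_score, label=kind)


def lmnn_frozen(atlas_matrix: np.ndarray, **fit_kwargs) -> ScoringMethod:
    """Push-only LMNN fitted once on ``atlas_matrix`` and frozen."""
    metric = fit_lmnn(atlas_matrix, **fit_kwargs)

    def _score(cells: np.ndarray, atlas: np.ndarray) -> np.ndarray:
        return lmnn_scores(metric, cells, atlas)

    return ScoringMethod(func=_score, label="lmnn")


def lmnn_refit(**fit_kwargs) -> ScoringMethod:
    """Push-only LMNN refitted on the atlas passed to every call."""

    def _score(cells: np.ndarray, atlas: np.ndarray) -> np.ndarray:
        metric = fit_lmnn(atlas, **fit_kwargs)
        return lmnn_scores(metric, cells, atlas)

    return ScoringMethod(func=_score, label="lmnn")


def deepsc_scores(
    params: NetworkParams,
    space: FeatureSpace,
    cells: np.ndarray,
    atlas: np.ndarray,
) -> np.ndarray:
    """Score raw gene-space matrices through a fitted feature space and network."""
    atlas_feats = project(atlas, space, side="atlas")
    cell_feats = project(cells, space, side="cells")
    return score_cells(params, cell_feats, atlas_feats)


def deepsc_frozen(
    atlas_matrix: np.ndarray,
    config: TrainingConfig | None = None,
    n_components: int = 8,
) -> ScoringMethod:
    """Feature space + network fitted once on ``atlas_matrix`` and frozen.

    Cell-side projection reuses the atlas scale so that scoring is a pure
    function of the cell matrix (no data-dependent rescaling between calls
    of the noise sweep).
    """
    space = fit_feature_space(atlas_matrix, n_components=n_components, share_scale=True)
    params, _ = train(project(atlas_matrix, space, side="atlas"), config)

    def _score(cells: np.ndarray, atlas: np.ndarray) -> np.ndarray:
        return deepsc_scores(params, space, cells, atlas)

    return ScoringMethod(func=_score, label="deepsc")


def deepsc_refit(
    config: TrainingConfig | None = None,
    n_components: int = 8,
) -> ScoringMethod:
    """Feature space and network refitted on the atlas passed to every call."""

    def _score(cells: np.ndarray, atlas: np.ndarray) -> np.ndarray:
        space = fit_feature_space(atlas, n_components=n_components, share_scale=True)
        params, _ = train(project(atlas, space, side="atlas"), config)
        return deepsc_scores(params, space, cells, atlas)

    return ScoringMethod(func=_score, label="deepsc")


def external_method(S: np.ndarray, label: str = "external") -> ScoringMethod:
    """Wrap a precomputed correspondence matrix (clipped to [0,1] with a warning)."""
    S = np.asarray(S, float)
    if S.min() < 0 or S.max() > 1:
        import logging

        logging.getLogger(__name__).warning(
            "external scores outside [0,1]; clipping"
        )
        S = np.clip(S, 0.0, 1.0)

    def _score(cells: np.ndarray, atlas: np.ndarray) -> np.ndarray:
        if S.shape != (np.atleast_2d(cells).shape[0], np.atleast_2d(atlas).shape[0]):
            raise InputError("external score matrix shape mismatch")
        return S

    return ScoringMethod(func=_score, label=label)
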