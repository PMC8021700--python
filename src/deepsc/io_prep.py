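"""Input handling and shared feature-space construction.

Reads gene-expression tables (dense delimited or matrix-market triplets)
and spatial reference atlases, aligns the two on their common genes,
normalizes expression to [0,1], and fits a single linear projection
(PCA of the atlas) used to embed both atlas positions and cells as
feature vectors in [0,1]^N.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "GeneExpressionTable",
    "SpatialAtlas",
    "AlignedPair",
    "FeatureSpace",
    "FeatureMatrix",
    "read_expression_table",
    "read_atlas",
    "write_expression_table",
    "write_coordinates",
    "intersect_genes",
    "normalize_cells",
    "fit_feature_space",
    "project",
    "binarize_atlas",
    "continuize_atlas",
]


class InputError(ValueError):
    """Raised when an input file or matrix violates the format contract."""


@dataclass
class GeneExpressionTable:
    """A genes x samples matrix of nonnegative expression values.

    Rows are genes, columns are samples (cells). Values may be raw counts
    or normalized expression; they must be finite and >= 0.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise InputError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InputError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.values)):
            raise InputError("expression values must be finite")
        if np.any(self.values < 0):
            raise InputError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SpatialAtlas:
    """A spatial reference atlas: P positions x G genes in [0,1] plus coordinates.

    ``expression[j, g]`` is the (binary or continuous) expression of gene g
    at position j; ``coordinates`` holds the 2-D or 3-D location of each
    position.
    """

    expression: np.ndarray
    gene_ids: list[str]
    coordinates: np.ndarray
    position_ids: list[str] | None = None
    is_binary: bool = False

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.expression.ndim != 2:
            raise InputError("atlas expression must be a 2-D matrix")
        P, G = self.expression.shape
        if P < 2:
            raise InputError("atlas must contain at least 2 positions")
        if G != len(self.gene_ids):
            raise InputError("gene dimension inconsistent with gene_ids")
        if self.position_ids is None:
            self.position_ids = [f"pos{j}" for j in range(P)]
        self.position_ids = [str(p) for p in self.position_ids]
        if len(self.position_ids) != P:
            raise InputError("position_ids inconsistent with expression rows")
        if self.coordinates.shape[0] != P or self.coordinates.shape[1] not in (2, 3):
            raise InputError("coordinates must be positions x 2 or positions x 3")
        if not np.all(np.isfinite(self.coordinates)):
            raise InputError("coordinates must be finite")
        if not np.all(np.isfinite(self.expression)):
            raise InputError("atlas expression must be finite")
        if self.expression.min() < 0 or self.expression.max() > 1:
            raise InputError(
                "atlas expression must lie in [0,1]; normalize explicitly first"
            )
        if self.is_binary and not np.all(np.isin(self.expression, (0.0, 1.0))):
            raise InputError("atlas flagged binary but contains non-{0,1} values")

    @property
    def n_positions(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]


@dataclass
class AlignedPair:
    """Atlas and cells restricted to the same genes in the same order."""

    atlas: SpatialAtlas
    cells: GeneExpressionTable

    def __post_init__(self) -> None:
        if self.atlas.gene_ids != self.cells.gene_ids:
            raise InputError("atlas and cells must share an identical gene sequence")
        if len(self.atlas.gene_ids) < 1:
            raise InputError("aligned pair needs at least one common gene")

    @property
    def gene_ids(self) -> list[str]:
        return self.atlas.gene_ids

    def cell_matrix(self) -> np.ndarray:
        """Cells as a C x G' matrix (transposed from gene-major storage)."""
        return self.cells.values.T.copy()

    def atlas_matrix(self) -> np.ndarray:
        """Atlas expression as a P x G' matrix."""
        return self.atlas.expression.copy()


@dataclass
class FeatureSpace:
    """Fitted linear embedding shared by atlas positions and cells.

    The map is ``z = ((x - centering) @ basis + shift) / scale`` followed by
    clipping to [0,1].  ``shift`` places the fitting atlas's projections at a
    per-component minimum of zero so that dividing by ``atlas_scale`` (the
    largest shifted element) lands the atlas exactly in [0,1].  Cells use
    their own global maximum (``cell_scale``) by default, or the atlas scale
    when ``share_scale`` was requested at fit time.
    """

    basis: np.ndarray
    centering: np.ndarray
    shift: np.ndarray
    atlas_scale: float
    n_components: int
    cell_scale: float | None = None
    share_scale: bool = False

    def raw_project(self, table: np.ndarray) -> np.ndarray:
        table = np.asarray(table, dtype=float)
        if table.ndim != 2 or table.shape[1] != self.basis.shape[0]:
            raise InputError(
                f"expected samples x {self.basis.shape[0]} matrix, got {table.shape}"
            )
        return (table - self.centering) @ self.basis + self.shift


@dataclass
class FeatureMatrix:
    """Samples x N feature vectors in [0,1]."""

    features: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise InputError("features must be 2-D")
        if self.features.shape[0] != len(self.sample_ids):
            raise InputError("sample_ids inconsistent with feature rows")
        if self.features.size and (
            self.features.min() < 0 or self.features.max() > 1
        ):
            raise InputError("features must lie in [0,1]")

    @property
    def n_components(self) -> int:
        return self.features.shape[1]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path,
    format: str = "dense",
    sep: str = "\t",
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> GeneExpressionTable:
    """Read a genes x samples expression table.

    ``format='dense'``: delimited text, first column gene ids, header row of
    sample ids.  ``format='mtx'``: matrix-market file with gene and sample
    identifier lists in sibling one-column files (``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` unless given explicitly).

    Duplicate gene rows are collapsed by element-wise sum with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format == "dense":
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001 - wrap any parse failure
            raise InputError(f"could not parse {path} as delimited text: {exc}") from exc
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise InputError(f"empty expression matrix in {path}")
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        sample_ids = [str(c) for c in df.columns]
    elif format == "mtx":
        genes_path = Path(genes_path) if genes_path else path.with_suffix("").with_suffix(".genes.txt")
        samples_path = Path(samples_path) if samples_path else path.with_suffix("").with_suffix(".samples.txt")
        try:
            mat = mmread(str(path))
        except Exception as exc:  # noqa: BLE001
            raise InputError(f"could not parse {path} as matrix-market: {exc}") from exc
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        gene_ids = _read_id_list(genes_path)
        sample_ids = _read_id_list(samples_path)
        if values.size == 0:
            raise InputError(f"empty expression matrix in {path}")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise InputError(
                f"matrix shape {values.shape} inconsistent with id lists "
                f"({len(gene_ids)} genes, {len(sample_ids)} samples)"
            )
    else:
        raise InputError(f"unknown format {format!r}; use 'dense' or 'mtx'")

    values, gene_ids = _collapse_duplicate_genes(values, gene_ids)
    return GeneExpressionTable(values=values, gene_ids=gene_ids, sample_ids=sample_ids)


def _read_id_list(path: Path) -> list[str]:
    if not path.exists():
        raise InputError(f"identifier file missing: {path}")
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise InputError(f"empty identifier file: {path}")
    return ids


def _collapse_duplicate_genes(
    values: np.ndarray, gene_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    if len(set(gene_ids)) == len(gene_ids):
        return values, gene_ids
    logger.warning("duplicate gene rows detected; collapsing by element-wise sum")
    order: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for g, row in zip(gene_ids, values):
        if g in rows:
            rows[g] = rows[g] + row
        else:
            rows[g] = row.astype(float)
            order.append(g)
    return np.vstack([rows[g] for g in order]), order


def read_atlas(
    expr_path: str | Path,
    coords_path: str | Path,
    sep: str = "\t",
) -> SpatialAtlas:
    """Read a spatial atlas from an expression table and a coordinate table.

    The expression file is genes x positions (same layout as any expression
    table); coordinates are one row per position: id, x, y(, z).  Values
    outside [0,1] are rejected — normalization must be an explicit step.
    """
    table = read_expression_table(expr_path, format="dense", sep=sep)
    coords_df = pd.read_csv(coords_path, sep=sep, index_col=0)
    coord_ids = [str(i) for i in coords_df.index]
    if set(coord_ids) != set(table.sample_ids):
        missing = set(table.sample_ids) ^ set(coord_ids)
        raise InputError(
            f"position ids differ between expression and coordinates: {sorted(missing)}"
        )
    coords = coords_df.loc[table.sample_ids].to_numpy(dtype=float)
    expr = table.values.T
    if expr.min() < 0 or expr.max() > 1:
        raise InputError(
            "atlas expression outside [0,1]; apply normalize_cells (or rescale) "
            "before constructing an atlas"
        )
    is_binary = bool(np.all(np.isin(expr, (0.0, 1.0))))
    return SpatialAtlas(
        expression=expr,
        gene_ids=table.gene_ids,
        coordinates=coords,
        position_ids=table.sample_ids,
        is_binary=is_binary,
    )


def write_expression_table(table: GeneExpressionTable, path: str | Path, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep, index_label="gene")


def write_coordinates(atlas: SpatialAtlas, path: str | Path, sep: str = "\t") -> None:
    cols = ["x", "y", "z"][: atlas.coordinates.shape[1]]
    pd.DataFrame(atlas.coordinates, index=atlas.position_ids, columns=cols).to_csv(
        path, sep=sep, index_label="position"
    )


# ---------------------------------------------------------------------------
# alignment and normalization
# ---------------------------------------------------------------------------

def intersect_genes(atlas: SpatialAtlas, cells: GeneExpressionTable) -> AlignedPair:
    """Restrict atlas and cells to their common genes, in atlas order."""
    cell_index = {g: i for i, g in enumerate(cells.gene_ids)}
    common = [g for g in atlas.gene_ids if g in cell_index]
    if not common:
        raise InputError("no genes shared between atlas and cells")
    atlas_idx = [atlas.gene_ids.index(g) for g in common]
    cell_idx = [cell_index[g] for g in common]
    sub_atlas = SpatialAtlas(
        expression=atlas.expression[:, atlas_idx],
        gene_ids=common,
        coordinates=atlas.coordinates,
        position_ids=atlas.position_ids,
        is_binary=atlas.is_binary,
    )
    sub_cells = GeneExpressionTable(
        values=cells.values[cell_idx, :],
        gene_ids=common,
        sample_ids=cells.sample_ids,
    )
    return AlignedPair(atlas=sub_atlas, cells=sub_cells)


def normalize_cells(
    cells: GeneExpressionTable, log_transform: bool = False
) -> GeneExpressionTable:
    """Map each gene linearly onto [0,1], optionally after log1p.

    Constant genes map to all-zero rather than to an arbitrary midpoint,
    so that a gene with no variation contributes no signal.
    """
    values = cells.values.astype(float)
    if log_transform:
        values = np.log1p(values)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(values)
    nonconst = span.ravel() > 0
    out[nonconst] = (values[nonconst] - lo[nonconst]) / span[nonconst]
    return GeneExpressionTable(
        values=out, gene_ids=list(cells.gene_ids), sample_ids=list(cells.sample_ids)
    )


# ---------------------------------------------------------------------------
# feature space
# ---------------------------------------------------------------------------

def fit_feature_space(
    atlas_common: np.ndarray,
    n_components: int = 8,
    share_scale: bool = False,
) -> FeatureSpace:
    """Fit the shared PCA feature space on the atlas expression matrix.

    The top ``n_components`` principal components of the P x G' atlas define
    the projection; components are then shifted and globally rescaled so the
    fitting atlas occupies [0,1] exactly.  ``n_components`` is reduced with a
    warning when it exceeds min(P-1, G') or the effective rank of the
    centered atlas.
    """
    X = np.asarray(atlas_common, dtype=float)
    if X.ndim != 2:
        raise InputError("atlas matrix must be 2-D")
    P, G = X.shape
    if P < 2:
        raise InputError("need at least 2 positions to fit a feature space")
    centered = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    n_eff = min(n_components, P - 1, G, max(rank, 1))
    if n_eff < n_components:
        warnings.warn(
            f"n_components reduced from {n_components} to {n_eff} "
            f"(P={P}, G'={G}, effective rank {rank})",
            stacklevel=2,
        )
    pca = PCA(n_components=n_eff, svd_solver="full")
    pca.fit(X)
    basis = pca.components_.T  # G' x N
    centering = pca.mean_
    raw = (X - centering) @ basis
    shift = -raw.min(axis=0)
    shifted = raw + shift
    atlas_scale = float(shifted.max())
    if atlas_scale <= 0:
        atlas_scale = 1.0
    return FeatureSpace(
        basis=basis,
        centering=centering,
        shift=shift,
        atlas_scale=atlas_scale,
        n_components=n_eff,
        cell_scale=atlas_scale if share_scale else None,
        share_scale=share_scale,
    )


def project(
    table: np.ndarray,
    space: FeatureSpace,
    side: str = "cells",
    sample_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Project a samples x G' matrix into the fitted feature space.

    The atlas side divides by ``atlas_scale``; the cell side divides by the
    cells' own projected maximum (computed on first use and cached on the
    space) unless the space was fitted with ``share_scale``.  Outputs are
    clipped to [0,1].
    """
    if side not in ("atlas", "cells"):
        raise InputError(f"side must be 'atlas' or 'cells', got {side!r}")
    raw = space.raw_project(table)
    if side == "atlas":
        scale = space.atlas_scale
    else:
        if space.cell_scale is None:
            m = float(np.abs(raw).max()) if raw.size else 1.0
            space.cell_scale = m if m > 0 else 1.0
        scale = space.cell_scale
    feats = np.clip(raw / scale, 0.0, 1.0)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(feats.shape[0])]
    return FeatureMatrix(features=feats, sample_ids=list(sample_ids))


# ---------------------------------------------------------------------------
# atlas transforms
# ---------------------------------------------------------------------------

def binarize_atlas(atlas: SpatialAtlas, cutoff: float = 0.2) -> SpatialAtlas:
    """Threshold a continuous atlas: expression >= cutoff becomes 'on' (1).

    The default cutoff of 0.2 is the conventional on/off threshold for
    hand-curated continuous atlases such as the hair-follicle reference.
    """
    if not 0 < cutoff < 1:
        raise InputError("cutoff must lie in (0,1)")
    binary = (atlas.expression >= cutoff).astype(float)
    return SpatialAtlas(
        expression=binary,
        gene_ids=list(atlas.gene_ids),
        coordinates=atlas.coordinates.copy(),
        position_ids=list(atlas.position_ids),
        is_binary=True,
    )


def continuize_atlas(
    atlas: SpatialAtlas,
    kernel_radius: float | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SpatialAtlas:
    """Convert a binary atlas to a continuous one by spatial smoothing.

    Each gene is replaced by a truncated-Gaussian weighted average over
    positions within ``kernel_radius`` in coordinate space (bandwidth =
    radius / 2), then Gaussian noise of standard deviation ``noise_sd`` is
    added and values are clipped to [0,1].  The default radius is 1.5x the
    median nearest-neighbor distance.
    """
    if not atlas.is_binary:
        raise InputError("continuize_atlas expects a binary atlas")
    D = squareform(pdist(atlas.coordinates))
    if kernel_radius is None:
        nn = np.where(np.eye(len(D), dtype=bool), np.inf, D).min(axis=1)
        kernel_radius = 1.5 * float(np.median(nn))
    if kernel_radius <= 0:
        raise InputError("kernel_radius must be positive")
    bw = kernel_radius / 2.0
    W = np.exp(-0.5 * (D / bw) ** 2)
    W[D > kernel_radius] = 0.0
    W /= W.sum(axis=1, keepdims=True)
    smoothed = W @ atlas.expression
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        smoothed = smoothed + rng.normal(0.0, noise_sd, size=smoothed.shape)
    smoothed = np.clip(smoothed, 0.0, 1.0)
    return SpatialAtlas(
        expression=smoothed,
        gene_ids=list(atlas.gene_ids),
        coordinates=atlas.coordinates.copy(),
        position_ids=list(atlas.position_ids),
        is_binary=False,
    )
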