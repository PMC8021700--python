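"""Synthetic spatial atlases and matched ground-truth scRNA-seq data.

The simulator produces the structures the mapping methods assume: positions
on a simple 2-D layout (grid, disk or strip), genes with smooth spatial
patterns (affine gradients, soft sinusoidal stripes, Gaussian bumps) scaled
per gene to [0,1], optional binarization, and cells generated from atlas
rows by additive clipped Gaussian noise plus dropout zeros, with spatially
unstructured decoy genes appended and the true origin of every cell
recorded.  It emulates the regimes of real systems (few-gene noisy
follicle-like atlases, binary zebrafish-like atlases, striped fly-embryo
patterns, gene-rich cortex-like data) without any external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_prep import GeneExpressionTable, InputError, SpatialAtlas

__all__ = ["SyntheticConfig", "GroundTruth", "make_atlas", "make_cells", "exact_copy_cells"]

LAYOUTS = ("grid", "disk", "strip")
PATTERNS = ("gradient", "stripe", "bump")


@dataclass
class SyntheticConfig:
    """Generation parameters for one synthetic system.

    ``P`` positions on ``layout``; ``G_spatial`` patterned atlas genes drawn
    cyclically from ``patterns``; cells get Gaussian noise of sd ``noise_sd``
    (clipped to [0,1]), dropout zeros with probability ``dropout_prob``, and
    ``G_extra`` unpatterned decoy genes.  ``binarize_cutoff`` thresholds the
    atlas after generation.
    """

    P: int = 64
    G_spatial: int = 20
    G_extra: int = 0
    layout: str = "grid"
    patterns: tuple[str, ...] = PATTERNS
    noise_sd: float = 0.05
    dropout_prob: float = 0.0
    cells_per_position: int = 1
    binarize_cutoff: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.P < 4:
            raise InputError("P must be >= 4")
        if self.G_spatial < 2:
            raise InputError("G_spatial must be >= 2")
        if self.layout not in LAYOUTS:
            raise InputError(f"layout must be one of {LAYOUTS}")
        if not set(self.patterns) <= set(PATTERNS):
            raise InputError(f"patterns must be drawn from {PATTERNS}")
        if not 0 <= self.dropout_prob <= 1:
            raise InputError("dropout_prob must lie in [0,1]")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if self.cells_per_position < 1:
            raise InputError("cells_per_position must be >= 1")
        if self.binarize_cutoff is not None and not 0 < self.binarize_cutoff < 1:
            raise InputError("binarize_cutoff must lie in (0,1)")


@dataclass
class GroundTruth:
    """True origin (atlas position index) of every simulated cell."""

    position_index: np.ndarray
    cell_ids: list[str]
    config: SyntheticConfig

    def __post_init__(self) -> None:
        if len(self.cell_ids) != self.position_index.size:
            raise InputError("cell_ids inconsistent with position_index")


def _layout_coordinates(P: int, layout: str) -> np.ndarray:
    if layout == "grid":
        rows = int(np.floor(np.sqrt(P)))
        cols = int(np.ceil(P / rows))
        xx, yy = np.meshgrid(np.linspace(0, 1, cols), np.linspace(0, 1, rows))
        coords = np.stack([xx.ravel(), yy.ravel()], axis=1)[:P]
    elif layout == "disk":
        # sunflower spiral: evenly spaced points in the unit disk
        idx = np.arange(P) + 0.5
        r = np.sqrt(idx / P)
        theta = np.pi * (1 + np.sqrt(5)) * idx
        coords = 0.5 + 0.5 * np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    else:  # strip
        coords = np.stack([np.linspace(0, 1, P), np.zeros(P)], axis=1)
    return coords


def _gene_pattern(pattern: str, coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    x, y = coords[:, 0], coords[:, 1]
    if pattern == "gradient":
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        v = direction[0] * x + direction[1] * y
    elif pattern == "stripe":
        freq = rng.integers(1, 4)
        phase = rng.uniform(0, 2 * np.pi)
        axis = x if rng.random() < 0.5 else y
        # soft threshold of a sinusoid gives sharp-but-smooth stripes
        v = 1.0 / (1.0 + np.exp(-6.0 * np.sin(2 * np.pi * freq * axis + phase)))
    else:  # bump
        center = rng.uniform(0, 1, size=2)
        width = rng.uniform(0.1, 0.3)
        d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
        v = np.exp(-d2 / (2 * width**2))
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def make_atlas(config: SyntheticConfig) -> SpatialAtlas:
    """Generate a seeded synthetic spatial reference atlas."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x61746c61]))
    coords = _layout_coordinates(config.P, config.layout)
    genes = []
    for g in range(config.G_spatial):
        pattern = config.patterns[g % len(config.patterns)]
        genes.append(_gene_pattern(pattern, coords, rng))
    expr = np.stack(genes, axis=1)  # P x G
    is_binary = False
    if config.binarize_cutoff is not None:
        expr = (expr >= config.binarize_cutoff).astype(float)
        is_binary = True
    return SpatialAtlas(
        expression=expr,
        gene_ids=[f"g{j:03d}" for j in range(config.G_spatial)],
        coordinates=coords,
        position_ids=[f"pos{j:04d}" for j in range(config.P)],
        is_binary=is_binary,
    )


def make_cells(
    atlas: SpatialAtlas, config: SyntheticConfig
) -> tuple[GeneExpressionTable, GroundTruth]:
    """Simulate cells from atlas rows: noise, dropout, decoy genes, truth labels."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x63656c6c]))
    P, G = atlas.expression.shape
    origins = np.repeat(np.arange(P), config.cells_per_position)
    C = origins.size
    cells = atlas.expression[origins].copy()
    if config.noise_sd > 0:
        cells = np.clip(cells + rng.normal(0, config.noise_sd, size=cells.shape), 0, 1)
    if config.dropout_prob > 0:
        cells[rng.random(cells.shape) < config.dropout_prob] = 0.0
    gene_ids = list(atlas.gene_ids)
    if config.G_extra > 0:
        decoys = rng.uniform(0, 1, size=(C, config.G_extra))
        cells = np.concatenate([cells, decoys], axis=1)
        gene_ids += [f"decoy{j:03d}" for j in range(config.G_extra)]
    cell_ids = [f"cell{i:05d}" for i in range(C)]
    table = GeneExpressionTable(values=cells.T, gene_ids=gene_ids, sample_ids=cell_ids)
    truth = GroundTruth(position_index=origins, cell_ids=cell_ids, config=config)
    return table, truth


def exact_copy_cells(atlas: SpatialAtlas) -> GeneExpressionTable:
    """C = P cells, each an exact copy of one atlas position (cell i <-> position i)."""
    return GeneExpressionTable(
        values=atlas.expression.T.copy(),
        gene_ids=list(atlas.gene_ids),
        sample_ids=[f"cell{i:05d}" for i in range(atlas.n_positions)],
    )
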