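# Methods

## Problem setting

A spatial reference atlas gives expression of *G* genes (binary or
continuous, in [0,1]) at *P* positions with known 2-D/3-D coordinates; an
scRNA-seq experiment gives a genes × cells matrix with no positional
information. Every mapping method here is a function
S : [0,1]^G × [0,1]^G → [0,1] scoring cell–position correspondence; a cell's
origin is the argmax of its score row. The package implements the learned
DEEPsc score, fixed-metric and learned-linear-metric baselines, and two
evaluation frameworks, all against a shared correspondence-matrix contract
so that evaluation depends on a method only through the matrices it returns.

## Data preparation

Atlas and cells are aligned on their common genes in atlas order (duplicate
gene rows in input files are collapsed by sum). Cell expression is
optionally log1p-transformed, then each gene is mapped linearly onto [0,1];
constant genes map to zero rather than an arbitrary midpoint so that a gene
with no variation contributes no signal. Atlas files whose values leave
[0,1] are rejected rather than silently rescaled.

The shared feature space is the PCA of the atlas (positions as samples),
default N = 8 components, reduced with a warning when N exceeds
min(P−1, G′) or the effective rank. Raw PCA scores are signed, so each
component is shifted so the fitting atlas's minimum is 0 and the whole
matrix is divided by its largest element; the fitting atlas then occupies
[0,1] exactly without clipping. Cells are projected with the same
coefficients and shift, divided by their own maximum by default or by the
atlas scale when `share_scale` is set (the frozen scoring path uses shared
scales so that scoring is a pure function of the cell matrix), and clipped
to [0,1] to preserve the network's input contract.

Binary↔continuous conversions: thresholding at a cutoff (default 0.2,
inclusive) binarizes; a truncated-Gaussian spatial convolution (bandwidth =
radius/2, default radius 1.5× the median nearest-neighbor distance) plus
clipped Gaussian noise (sd 0.05) continuizes a binary atlas.

## The learned score

Architecture: 2N inputs → two fully connected hidden layers of N units → 1
output, logistic sigmoid at every unit, so the output is a likelihood in
(0,1). Forward, backward and the Adam update are implemented directly in
numpy; the analytic gradient is verified against central differences in the
test suite.

Training pairs come from the atlas itself: the first N input components are
a position's feature vector acting as a simulated cell, the last N are a
(possibly different) position; the target is 1 iff the two indices match.
From the P² grid, `round(train_frac·P)` matches (sampled without
replacement) and `training_multiple` times as many non-matches form the
training set; remaining grid pairs are validation. When the request exceeds
the distinct non-match pool (small P), non-matches are drawn with
replacement and a warning is logged — drawing with replacement (rather than
consuming the pool exhaustively) keeps a usable validation set.

The objective is `Σ (yᵢ−tᵢ)²/(1.001−tᵢ)` plus an L2 penalty λ‖W‖²
(weights only, λ = 1e−4); the 1000:1 false-negative weighting prevents the
trivial all-zeros solution that the 1%-match imbalance would otherwise
produce. Gaussian noise (sd 0.10) is added to the simulated-cell half of
each training row independently with probability 0.5 per sample per epoch,
then clipped to [0,1]; the position half and all scoring-time inputs are
never perturbed. Optimization is Adam (lr 0.01, β₁ 0.9, β₂ 0.999, ε 1e−8),
data order shuffled per epoch, full-batch by default with a mini-batch
option; validation RMSE (on noise-free inputs) is checkpointed and training
stops after `patience` epochs (default 500) without improvement or at
`max_epochs` (default 50,000), returning the best-validation parameters.
Non-finite losses abort with a diagnostic. With a fixed seed the entire
pipeline — pair sampling, initialization, noise, shuffling — is
bit-reproducible; all streams derive from `TrainingConfig.seed` via
`SeedSequence` spawning.

### Convergence on small systems

The weighted objective has a strong early attractor at "score ≈ 1
everywhere" (matches outweigh non-matches ~10:1 in gradient mass until the
match outputs saturate); escaping it and carving down non-match scores is
slow and markedly initialization-sensitive on small atlases (P ≤ 50), where
an epoch contains few gradient updates. Two practical consequences, both
part of the package's recommended small-system protocol:

* mini-batches of 128 (the conventional default) rather than full batch,
  multiplying updates per epoch;
* `train_with_restarts`: R independent initializations (seeds derived from
  the top-level seed), keeping the network with the best atlas self-mapping
  recovery — the fraction of positions whose own feature vector argmax-maps
  to itself. This selection uses only the training atlas, no held-out
  information, and is deterministic given the seed. Champion-of-5 with a
  2000-epoch cap recovers ≥90% of positions on smooth, well-separated
  synthetic atlases (e.g. 6×6 grid, 40 gradient/bump genes), while single
  runs range roughly 0.3–0.97 depending on initialization.

Recovery degrades when positions are closer in feature space than the
training-noise scale (noise sd 0.1 across N=8 components has norm ≈ 0.28):
the noise layer then actively teaches neighbor confusion. This is inherent
to the method's robustness/precision trade-off, not an implementation
artifact.

## Baselines

Fixed metrics in common-gene space: Euclidean (2-norm), Chebyshev (∞-norm),
and mean percent difference `mean_g |c−p| / ((c+p)/2)` with 0/0 terms
defined as 0 (both silent ⇒ no disagreement). Distances convert to
similarities as `S = 1 − d/d_max` with a global maximum (per-cell scaling
behind a flag); zero distance always maps to S = 1, which is why all
distance baselines have exactly zero accuracy penalty on exact-copy cells.

The learned baseline is push-only LMNN: minimize
`Σ_{i≠j} max(0, D − ‖T(xᵢ−xⱼ)‖²)` over linear transforms T — every
position is its own sole target and all others are imposters with margin D
(default: the input dimensionality; squared distance against the margin,
the conventional LMNN form). Optimization is gradient descent with
backtracking from the identity, default 200 iterations; coincident
positions contribute an irreducible 2D per pair, reported in diagnostics.
Matrices wider than 50 genes are reduced to 50 PCs before fitting and
scoring. The final score is scale-invariant in T because of the global
similarity normalization, so the iteration cap is not delicate.

## Evaluation

**Performance score.** Exact-copy simulated cells (C = P) give known
origins. Per cell: accuracy penalty `1 − Sᵢᵢ`; precision penalty
`|1 − Σⱼ Sᵢⱼ|/(P−1)` (the reading under which the ideal one-hot mapping
scores zero and the all-ones mapping scores 1; the "mean off-diagonal"
alternative is available behind a flag); robustness penalty `(1 − σ*)⁴`.
σ* is found on a grid (default 0.05 to 1.0 in steps of 0.05, 5 replicates
per level): exact-copy cells are perturbed with clipped Gaussian noise,
re-scored by the *frozen* method (trainable methods are fitted once before
the sweep), and σ*ᵢ is the smallest level raising the mean
accuracy+precision penalty by an absolute 0.1, else 1. Penalties are
per-cell throughout; E is their mean. E = 1 exactly for a noise-invariant
identity oracle, and the all-ones scorer with σ* forced to 0 gives
E = 1/3 — both identities are asserted in the tests.

**Predictive reproducibility.** Genes are partitioned into k seeded folds
of near-equal size (k = 4 or 5 in typical use); the same split serves every
method. For each fold the method re-scores on the reduced gene set — the
callable refits whatever it needs, so DEEPsc refits its feature space and
network per fold (not per gene, bounding cost) and fixed metrics simply
recompute distances. Each held-out gene is predicted as the score-weighted
average over positions (cell direction) or cells (atlas direction);
all-zero weight rows predict 0 with a warning. R values are
`1 − mean |prediction − truth|` over the zero-valued and positive-valued
index sets separately, per gene; genes with an empty index set are excluded
from that aggregate (NaN if no gene defines it).

## Synthetic data

Layouts: near-square grid, sunflower-spiral disk, or 1-D strip, scaled to
the unit square. Gene patterns cycle through affine gradients (random
direction), soft-thresholded sinusoid stripes (frequency 1–3, random phase
and axis), and Gaussian bumps (random center, width 0.1–0.3), each min-max
scaled to [0,1]; optional binarization at a cutoff. Cells copy their
origin's row, add clipped Gaussian noise (default sd 0.05), apply dropout
zeros (default off), and append spatially unstructured decoy genes that
exist to exercise gene intersection and bookkeeping, not biology. Counts,
library-size effects and doublets are deliberately not simulated: all
methods operate on [0,1]-normalized values, so the additive-noise model
matches the evaluation's own perturbation model. Passing tests on this
generator therefore demonstrates correctness of the algorithms and their
contracts, not performance on raw count data.

Default problem sizes in the tests and acceptance script (64-position,
20-gene atlases; 36-position training runs; 2000-epoch caps) were chosen so
the full suite completes in a few minutes on one CPU while remaining in the
regime the methods target.

## Known limitations

* Argmax recovery of the learned score on small atlases is
  initialization-sensitive (see above); restarts mitigate but do not
  guarantee convergence.
* The precision term's typeset form is ambiguous in its source; both
  candidate readings coincide on the ideal and worst cases, and the choice
  is documented above.
* External (precomputed) score matrices are accepted as-is with a
  clip-to-[0,1] warning; how third-party scores were originally scaled is
  the caller's responsibility.
* The spatial-distance-weighted precision variant and the published
  third-party mapping methods are out of scope; the evaluation accepts
  their score matrices through the external-method wrapper instead.
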