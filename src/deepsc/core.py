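"""The DEEPsc network: self-supervised training on atlas positions and scoring.

The model is a small fully connected network S(c, p) -> (0,1) that scores how
likely cell c (an N-dim feature vector) originated from atlas position p
(another N-dim feature vector).  It is trained without any labelled cells:
the atlas's own position feature vectors act as simulated cells, paired with
every position, with target 1 for the exact match and 0 otherwise.  Class
imbalance (P matches vs P^2-P non-matches) is countered twice — by the
weighted objective

    L(Y, T) = sum_i (y_i - t_i)^2 / (1.001 - t_i)

which penalizes a false negative ~1000x more than a false positive, and by
sparsifying the training set to round(train_frac*P) matches plus
training_multiple times as many non-matches.  A Gaussian noise layer perturbs
the simulated-cell half of each input during training so the network cannot
simply memorize exact matches.

The architecture (2N inputs, two hidden layers of N logistic-sigmoid units,
one sigmoid output) is small enough that forward, backward and the Adam
update are written directly against numpy arrays.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_prep import FeatureMatrix, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "NetworkParams",
    "PairDataset",
    "TrainingHistory",
    "build_pair_datasets",
    "forward",
    "weighted_loss",
    "weighted_loss_grad",
    "apply_training_noise",
    "train",
    "train_with_restarts",
    "score_cells",
    "assign_origins",
    "save_params",
    "load_params",
]


@dataclass
class TrainingConfig:
    """Hyperparameters for training a correspondence network.

    Defaults follow the reference training recipe: sigmoid MLP trained by
    full-batch gradient descent with Adam (lr 0.01, beta1 0.9, beta2 0.999,
    eps 1e-8), L2 weight penalty lambda=1e-4, input noise sd 0.10 applied
    with probability 0.5 per simulated cell per epoch, train_frac=0.9 and
    training_multiple=99 sparsification, and a 50,000-epoch cap with
    patience-based early stopping on validation RMSE.
    """

    noise_sd: float = 0.10
    noise_prob: float = 0.5
    train_frac: float = 0.9
    training_multiple: int = 99
    learning_rate: float = 0.01
    max_epochs: int = 50_000
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    l2_lambda: float = 0.0001
    seed: int = 0
    patience: int = 500
    batch_size: int | None = None  # None = full batch

    def __post_init__(self) -> None:
        if not 0 < self.train_frac <= 1:
            raise InputError("train_frac must lie in (0,1]")
        if self.training_multiple < 1:
            raise InputError("training_multiple must be >= 1")
        if not 0 <= self.noise_prob <= 1:
            raise InputError("noise_prob must lie in [0,1]")


@dataclass
class PairDataset:
    """Concatenated [simulated-cell | position] feature pairs with 0/1 targets."""

    inputs: np.ndarray  # M x 2N
    targets: np.ndarray  # M, in {0,1}
    match_flags: np.ndarray  # M, bool
    pair_indices: np.ndarray  # M x 2 (cell position index, atlas position index)

    def __len__(self) -> int:
        return self.inputs.shape[0]


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    stop_reason: str = ""
    best_epoch: int = 0


class NetworkParams:
    """Weights and biases of the 2N -> N -> N -> 1 sigmoid network."""

    def __init__(self, W1, b1, W2, b2, W3, b3):
        self.W1, self.b1 = np.asarray(W1, float), np.asarray(b1, float)
        self.W2, self.b2 = np.asarray(W2, float), np.asarray(b2, float)
        self.W3, self.b3 = np.asarray(W3, float), np.asarray(b3, float)
        if self.W1.shape[0] != 2 * self.W1.shape[1] or self.W2.shape[0] != self.W2.shape[1]:
            raise InputError("layer shapes must be 2N x N, N x N, N x 1")

    @property
    def n_features(self) -> int:
        return self.W1.shape[1]

    @classmethod
    def glorot_init(cls, n_features: int, rng: np.random.Generator) -> "NetworkParams":
        """Glorot-uniform weights, zero biases."""
        def glorot(fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        N = n_features
        return cls(
            glorot(2 * N, N), np.zeros(N),
            glorot(N, N), np.zeros(N),
            glorot(N, 1), np.zeros(1),
        )

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.W1.copy(), self.b1.copy(),
            self.W2.copy(), self.b2.copy(),
            self.W3.copy(), self.b3.copy(),
        )

    def as_list(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def forward_batch(self, X: np.ndarray, return_cache: bool = False):
        """Vectorized forward pass over an M x 2N batch."""
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 2 * self.n_features:
            raise InputError(
                f"expected M x {2 * self.n_features} inputs, got {X.shape}"
            )
        a1 = _sigmoid(X @ self.W1 + self.b1)
        a2 = _sigmoid(a1 @ self.W2 + self.b2)
        y = _sigmoid(a2 @ self.W3 + self.b3).ravel()
        if return_cache:
            return y, (X, a1, a2)
        return y

    def backward_batch(self, dLdy: np.ndarray, cache, y: np.ndarray):
        """Gradients of the loss w.r.t. every parameter, given dL/dy."""
        X, a1, a2 = cache
        d3 = (dLdy * y * (1.0 - y))[:, None]           # M x 1
        gW3 = a2.T @ d3
        gb3 = d3.sum(axis=0)
        d2 = (d3 @ self.W3.T) * a2 * (1.0 - a2)        # M x N
        gW2 = a1.T @ d2
        gb2 = d2.sum(axis=0)
        d1 = (d2 @ self.W2.T) * a1 * (1.0 - a1)        # M x N
        gW1 = X.T @ d1
        gb1 = d1.sum(axis=0)
        return [gW1, gb1, gW2, gb2, gW3, gb3]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# training-set construction
# ---------------------------------------------------------------------------

def build_pair_datasets(
    atlas_features: FeatureMatrix | np.ndarray,
    config: TrainingConfig,
) -> tuple[PairDataset, PairDataset]:
    """Split the P^2 pair grid into a sparsified training set and validation set.

    The training set holds m = round(train_frac * P) exact-match pairs sampled
    without replacement plus m * training_multiple non-match pairs, so matches
    are exactly 1/(1+training_multiple) of it.  Non-matches are drawn without
    replacement while distinct pairs remain; if more are requested than exist
    (small P), they are drawn with replacement instead, with a warning.  The
    validation set is every grid pair not placed in training.
    """
    F = atlas_features.features if isinstance(atlas_features, FeatureMatrix) else np.asarray(atlas_features, float)
    P, N = F.shape
    if P < 2:
        raise InputError("need at least 2 positions to build pair datasets")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7061]))
    m = int(round(config.train_frac * P))
    m = max(m, 1)
    n_non = m * config.training_multiple

    match_pool = rng.permutation(P)[:m]
    # ordered non-match pairs, flattened index i*P+j with i != j
    all_non = np.flatnonzero(~np.eye(P, dtype=bool).ravel())
    A = all_non.size
    if n_non > A:
        logger.warning(
            "requested %d non-match pairs but only %d distinct exist; "
            "sampling with replacement", n_non, A,
        )
        non_idx = rng.choice(all_non, size=n_non, replace=True)
    else:
        non_idx = rng.choice(all_non, size=n_non, replace=False)

    train_pairs = np.concatenate([
        np.stack([match_pool, match_pool], axis=1),
        np.stack([non_idx // P, non_idx % P], axis=1),
    ])
    used = np.zeros(P * P, dtype=bool)
    used[match_pool * P + match_pool] = True
    used[non_idx] = True
    val_flat = np.flatnonzero(~used)
    val_pairs = np.stack([val_flat // P, val_flat % P], axis=1)

    def _make(pairs: np.ndarray) -> PairDataset:
        ci, pj = pairs[:, 0], pairs[:, 1]
        inputs = np.concatenate([F[ci], F[pj]], axis=1)
        flags = ci == pj
        return PairDataset(
            inputs=inputs,
            targets=flags.astype(float),
            match_flags=flags,
            pair_indices=pairs,
        )

    return _make(train_pairs), _make(val_pairs)


# ---------------------------------------------------------------------------
# loss and noise
# ---------------------------------------------------------------------------

def weighted_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Imbalance-weighted squared error: sum of (y-t)^2 / (1.001 - t).

    A false negative (y=0 at t=1) costs 1/0.001 = 1000, a false positive
    (y=1 at t=0) costs 1/1.001, a ratio of 1001.
    """
    y = np.asarray(predictions, float)
    t = np.asarray(targets, float)
    if not np.all(np.isin(t, (0.0, 1.0))):
        raise InputError("targets must be 0 or 1")
    return float(np.sum((y - t) ** 2 / (1.001 - t)))


def weighted_loss_grad(predictions: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """dL/dy for :func:`weighted_loss`."""
    y = np.asarray(predictions, float)
    t = np.asarray(targets, float)
    return 2.0 * (y - t) / (1.001 - t)


def apply_training_noise(
    batch_inputs: np.ndarray,
    noise_sd: float,
    noise_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturb the simulated-cell half (first N columns) of selected rows.

    Each row is selected independently with probability ``noise_prob``;
    selected rows get i.i.d. Gaussian(0, noise_sd^2) added to their first N
    columns and are clipped back to [0,1].  The position half is never
    touched.
    """
    X = np.asarray(batch_inputs, float)
    if noise_sd <= 0 or noise_prob <= 0:
        return X
    N = X.shape[1] // 2
    out = X.copy()
    mask = rng.random(X.shape[0]) < noise_prob
    n_sel = int(mask.sum())
    if n_sel:
        noise = rng.normal(0.0, noise_sd, size=(n_sel, N))
        out[mask, :N] = np.clip(out[mask, :N] + noise, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, shapes, lr, b1, b2, eps):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: NetworkParams, grads) -> None:
        self.t += 1
        arrays = params.as_list()
        for i, (a, g) in enumerate(zip(arrays, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            a -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    atlas_features: FeatureMatrix | np.ndarray,
    config: TrainingConfig | None = None,
) -> tuple[NetworkParams, TrainingHistory]:
    """Train a correspondence network on the atlas's own feature vectors.

    Glorot-initialized parameters are optimized with Adam on
    ``weighted_loss + l2_lambda * sum(W^2)`` (weights only), data order
    shuffled each epoch, training noise applied per
    :func:`apply_training_noise`.  Validation RMSE is monitored on the
    noise-free held-out pairs; training stops at ``max_epochs`` or after
    ``patience`` epochs without improvement, returning the parameters from
    the best validation epoch.
    """
    if config is None:
        config = TrainingConfig()
    F = atlas_features.features if isinstance(atlas_features, FeatureMatrix) else np.asarray(atlas_features, float)
    if F.shape[0] < 2:
        raise InputError("need at least 2 positions to train")
    N = F.shape[1]

    ss = np.random.SeedSequence([config.seed, 0x646565])
    rng_init, rng_noise, rng_shuffle = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    train_set, val_set = build_pair_datasets(F, config)
    has_val = len(val_set) > 0
    if not has_val:
        logger.warning("validation set is empty; early stopping disabled")

    params = NetworkParams.glorot_init(N, rng_init)
    opt = _Adam(
        [a.shape for a in params.as_list()],
        config.learning_rate, config.adam_beta1, config.adam_beta2, config.adam_eps,
    )
    history = TrainingHistory()
    best_rmse = np.inf
    best_params = params.copy()
    best_epoch = 0
    M = len(train_set)
    batch = config.batch_size or M

    for epoch in range(1, config.max_epochs + 1):
        order = rng_shuffle.permutation(M)
        X_ep = apply_training_noise(
            train_set.inputs[order], config.noise_sd, config.noise_prob, rng_noise
        )
        t_ep = train_set.targets[order]
        epoch_loss = 0.0
        for start in range(0, M, batch):
            Xb, tb = X_ep[start:start + batch], t_ep[start:start + batch]
            y, cache = params.forward_batch(Xb, return_cache=True)
            loss = weighted_loss(y, tb) + config.l2_lambda * sum(
                float(np.sum(W * W)) for W in (params.W1, params.W2, params.W3)
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or noise level"
                )
            grads = params.backward_batch(weighted_loss_grad(y, tb), cache, y)
            for gi, W in zip((0, 2, 4), (params.W1, params.W2, params.W3)):
                grads[gi] = grads[gi] + 2.0 * config.l2_lambda * W
            opt.step(params, grads)
            epoch_loss += loss
        history.train_loss.append(epoch_loss)

        if has_val:
            y_val = params.forward_batch(val_set.inputs)
            rmse = float(np.sqrt(np.mean((y_val - val_set.targets) ** 2)))
            history.val_rmse.append(rmse)
            if rmse < best_rmse - 1e-12:
                best_rmse = rmse
                best_params = params.copy()
                best_epoch = epoch
            elif epoch - best_epoch >= config.patience:
                history.stopped_epoch = epoch
                history.stop_reason = (
                    f"validation RMSE stalled for {config.patience} epochs"
                )
                break
    else:
        history.stopped_epoch = config.max_epochs
        history.stop_reason = "max_epochs reached"

    if not history.stopped_epoch:
        history.stopped_epoch = len(history.train_loss)
        history.stop_reason = history.stop_reason or "max_epochs reached"
    if has_val:
        history.best_epoch = best_epoch
        return best_params, history
    history.best_epoch = history.stopped_epoch
    return params, history


def train_with_restarts(
    atlas_features: FeatureMatrix | np.ndarray,
    config: TrainingConfig | None = None,
    n_restarts: int = 5,
) -> tuple[NetworkParams, TrainingHistory, float]:
    """Train several networks from independent initializations, keep the best.

    Convergence of the imbalance-weighted objective is initialization-
    sensitive on small atlases, so each restart trains with a seed derived
    from ``config.seed`` and the champion is the network that best self-maps
    the atlas (fraction of positions whose own feature vector argmax-scores
    to themselves — a training-set quantity requiring no held-out labels).
    Returns the champion's parameters, history, and self-mapping recovery.
    """
    if config is None:
        config = TrainingConfig()
    F = atlas_features.features if isinstance(atlas_features, FeatureMatrix) else np.asarray(atlas_features, float)
    P = F.shape[0]
    best: tuple[float, NetworkParams, TrainingHistory] | None = None
    for r in range(n_restarts):
        sub_seed = int(
            np.random.SeedSequence([config.seed, r]).generate_state(1)[0] % (2**31)
        )
        sub_config = replace(config, seed=sub_seed)
        params, history = train(F, sub_config)
        S = score_cells(params, F, F)
        recovery = float((assign_origins(S) == np.arange(P)).mean())
        logger.info("restart %d/%d: self-mapping recovery %.3f", r + 1, n_restarts, recovery)
        if best is None or recovery > best[0]:
            best = (recovery, params, history)
    assert best is not None
    return best[1], best[2], best[0]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def forward(
    params: NetworkParams,
    cell_feature: np.ndarray,
    position_feature: np.ndarray,
) -> float:
    """Likelihood in (0,1) that one cell originated from one position."""
    c = np.asarray(cell_feature, float).ravel()
    p = np.asarray(position_feature, float).ravel()
    if c.size != params.n_features or p.size != params.n_features:
        raise InputError(
            f"feature vectors must have length {params.n_features}"
        )
    return float(params.forward_batch(np.concatenate([c, p])[None, :])[0])


def score_cells(
    params: NetworkParams,
    cell_features: FeatureMatrix | np.ndarray,
    atlas_features: FeatureMatrix | np.ndarray,
    chunk: int = 512,
) -> np.ndarray:
    """Score every cell against every position: S[i, j] = S(c_i, p_j)."""
    C_feat = cell_features.features if isinstance(cell_features, FeatureMatrix) else np.asarray(cell_features, float)
    P_feat = atlas_features.features if isinstance(atlas_features, FeatureMatrix) else np.asarray(atlas_features, float)
    if C_feat.shape[1] != P_feat.shape[1]:
        raise InputError("cells and atlas must share the feature dimension")
    C, P = C_feat.shape[0], P_feat.shape[0]
    S = np.empty((C, P))
    for start in range(0, C, chunk):
        block = C_feat[start:start + chunk]
        b = block.shape[0]
        X = np.concatenate(
            [np.repeat(block, P, axis=0), np.tile(P_feat, (b, 1))], axis=1
        )
        S[start:start + chunk] = params.forward_batch(X).reshape(b, P)
    return S


def assign_origins(S: np.ndarray) -> np.ndarray:
    """Per-cell argmax position; ties break to the lowest index with a warning."""
    S = np.asarray(S, float)
    if S.size == 0:
        raise InputError("empty correspondence matrix")
    idx = np.argmax(S, axis=1)
    n_ties = int(np.sum(np.sum(S == S.max(axis=1, keepdims=True), axis=1) > 1))
    if n_ties:
        logger.warning("%d cells had tied maximal scores; lowest index chosen", n_ties)
    return idx


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_params(params: NetworkParams, path: str | Path) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "n_features": params.n_features,
        "arrays": {
            name: arr.tolist()
            for name, arr in zip(
                ("W1", "b1", "W2", "b2", "W3", "b3"), params.as_list()
            )
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_params(path: str | Path) -> NetworkParams:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _FORMAT_VERSION:
        raise InputError(f"unsupported model file version in {path}")
    a = payload["arrays"]
    return NetworkParams(a["W1"], a["b1"], a["W2"], a["b2"], a["W3"], a["b3"])
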