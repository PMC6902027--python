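"""The block-scoring network and its training loop.

Architecture (variant ``full``): an association block enters as a binary
matrix X (M features x N SNPs). Layer 1 applies K kernels, each a length-M
weight vector, as a width-1 one-dimensional convolution across SNP columns:

    c1[k, n] = sum_m W[k, m] * X[m, n]
    H[k, n]  = ReLU(c1[k, n] + b[k])

Layer 2 linearly combines the K pattern scores of each SNP with a single
weight vector and squashes to a probability:

    o[n] = sigmoid(sum_k w2[k] * H[k, n] + b2)

The block score is max-pooled over SNPs, max_n o[n]: the block is scored by
the SNP whose annotation profile best matches a shared pattern. Training
minimizes the mean negative log-likelihood of block labels (true block = 1,
shuffled block = 0) by mini-batch gradient descent with classical momentum,
with layer-1 weights optionally pre-trained as a tied-weight autoencoder
over SNP columns, and early stopping on validation NLL.

Ablation variants: ``linear`` scores o[n] = sigmoid(v . X[:, n] + c)
directly (one layer, no ReLU mixing); ``lead_only`` is the full
architecture applied to the lead SNP column alone (N = 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import BlockFeatureMatrix
from .util import catalog_hash, rng_from

SCORE_EPS = 1e-12          # clamp inside the log for numerical safety
DEFAULT_K = 50
DEFAULT_BATCH_SIZE = 100
DEFAULT_LEARNING_RATE = 0.1
DEFAULT_MOMENTUM = 0.9
DEFAULT_MAX_EPOCHS = 200
DEFAULT_PATIENCE = 10
DEFAULT_PRETRAIN_EPOCHS = 50
DEFAULT_PRETRAIN_LR = 0.5
PRETRAIN_ACTIVATION_QUANTILE = 0.9  # kernels activate on ~10% of columns at init
DEFAULT_SPLIT = (0.6, 0.2, 0.2)
INIT_SCALE = 0.05

VARIANTS = ("full", "linear", "lead_only")


@dataclass
class ModelParams:
    """All trainable parameters plus the variant tag and catalog hash.

    For ``linear`` the single weight vector is stored as W with shape
    (1, M) and its bias as b of length 1; w2/b2 are unused.
    """

    W: np.ndarray                 # (K, M)
    b: np.ndarray                 # (K,)
    w2: np.ndarray | None         # (K,)
    b2: float | None
    variant: str = "full"
    catalog: str = ""             # hash of the feature catalog trained on

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.w2 is not None:
            self.w2 = np.asarray(self.w2, dtype=float)
        for arr in (self.W, self.b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite parameter values")

    @property
    def K(self) -> int:
        return self.W.shape[0]

    @property
    def M(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "ModelParams":
        return ModelParams(
            W=self.W.copy(),
            b=self.b.copy(),
            w2=None if self.w2 is None else self.w2.copy(),
            b2=self.b2,
            variant=self.variant,
            catalog=self.catalog,
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "variant": self.variant,
            "catalog": self.catalog,
            "W": self.W.tolist(),
            "b": self.b.tolist(),
            "w2": None if self.w2 is None else self.w2.tolist(),
            "b2": self.b2,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            W=np.array(payload["W"], dtype=float),
            b=np.array(payload["b"], dtype=float),
            w2=None if payload["w2"] is None else np.array(payload["w2"], dtype=float),
            b2=payload["b2"],
            variant=payload["variant"],
            catalog=payload["catalog"],
        )


@dataclass
class TrainConfig:
    K: int = DEFAULT_K
    batch_size: int = DEFAULT_BATCH_SIZE
    learning_rate: float = DEFAULT_LEARNING_RATE
    momentum: float = DEFAULT_MOMENTUM
    max_epochs: int = DEFAULT_MAX_EPOCHS
    patience: int = DEFAULT_PATIENCE
    pretrain_epochs: int = DEFAULT_PRETRAIN_EPOCHS
    seed: int = 0
    split_fractions: tuple[float, float, float] = DEFAULT_SPLIT

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Forward pass


def conv1_forward(X: np.ndarray, params: ModelParams) -> np.ndarray:
    """Layer 1: H[k, n] = ReLU(sum_m W[k, m] X[m, n] + b[k])."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != params.M:
        raise ValueError(
            f"input has {X.shape[0]} feature rows but kernels expect {params.M}"
        )
    return np.maximum(0.0, params.W @ X + params.b[:, None])


def conv2_forward(H: np.ndarray, params: ModelParams) -> np.ndarray:
    """Layer 2: o[n] = sigmoid(sum_k w2[k] H[k, n] + b2)."""
    H = np.asarray(H, dtype=float)
    if H.shape[0] != params.K:
        raise ValueError(f"H has {H.shape[0]} kernel rows but model has {params.K}")
    return sigmoid(params.w2 @ H + params.b2)


def snp_scores(X: np.ndarray, params: ModelParams) -> np.ndarray:
    """Per-SNP prediction scores o[n] for one block under any variant."""
    if params.variant == "linear":
        X = np.asarray(X, dtype=float)
        if X.shape[0] != params.M:
            raise ValueError(
                f"input has {X.shape[0]} feature rows but weights expect {params.M}"
            )
        return sigmoid(params.W[0] @ X + params.b[0])
    return conv2_forward(conv1_forward(X, params), params)


def block_score(o: np.ndarray) -> float:
    """Max-pooling over per-SNP scores; the block's best-matching SNP."""
    o = np.asarray(o, dtype=float)
    if o.size == 0:
        raise ValueError("cannot pool an empty score vector")
    return float(np.max(o))


def nll_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of block labels given block scores."""
    f = np.clip(np.asarray(scores, dtype=float), SCORE_EPS, 1.0 - SCORE_EPS)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(y * np.log(f) + (1.0 - y) * np.log(1.0 - f)))


def _block_view(block: BlockFeatureMatrix, variant: str) -> np.ndarray:
    if variant == "lead_only":
        if block.lead_index is None:
            raise ValueError(f"block {block.block_id} has no lead annotation")
        return block.X[:, [block.lead_index]]
    return block.X


def batch_forward(
    blocks: list[BlockFeatureMatrix], params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Block scores and labels for a list of blocks."""
    scores = np.array(
        [block_score(snp_scores(_block_view(b, params.variant), params)) for b in blocks]
    )
    labels = np.array([b.label for b in blocks], dtype=float)
    return scores, labels


def batch_nll(blocks: list[BlockFeatureMatrix], params: ModelParams) -> float:
    scores, labels = batch_forward(blocks, params)
    return nll_loss(scores, labels)


# ---------------------------------------------------------------------------
# Backward pass (exact gradients of the mean NLL over a mini-batch)


def backward(
    blocks: list[BlockFeatureMatrix], params: ModelParams
) -> dict[str, np.ndarray | float]:
    """Gradients of batch_nll with respect to every parameter group.

    ReLU subgradient at exactly 0 is 0; the max-pool routes gradient to the
    argmax SNP only, ties broken to the lowest column index (np.argmax).
    """
    S = len(blocks)
    if S == 0:
        raise ValueError("empty batch")
    dW = np.zeros_like(params.W)
    db = np.zeros_like(params.b)
    dw2 = None if params.w2 is None else np.zeros_like(params.w2)
    db2 = 0.0

    # Group blocks of equal width so the heavy path is a single einsum.
    by_width: dict[int, list[BlockFeatureMatrix]] = {}
    for blk in blocks:
        X = _block_view(blk, params.variant)
        by_width.setdefault(X.shape[1], []).append(blk)

    for width, group in by_width.items():
        Xs = np.stack(
            [_block_view(b, params.variant).astype(float) for b in group]
        )  # (S', M, N)
        y = np.array([b.label for b in group], dtype=float)
        if params.variant == "linear":
            Z = np.einsum("m,smn->sn", params.W[0], Xs) + params.b[0]
            O = sigmoid(Z)                                 # (S', N)
            nstar = np.argmax(O, axis=1)
            f = O[np.arange(len(group)), nstar]
            fc = np.clip(f, SCORE_EPS, 1.0 - SCORE_EPS)
            dfdl = -(y / fc - (1.0 - y) / (1.0 - fc)) / S  # dL/df per block
            dz = dfdl * f * (1.0 - f)                      # through sigmoid
            Xc = Xs[np.arange(len(group)), :, nstar]       # (S', M)
            dW[0] += dz @ Xc
            db[0] += dz.sum()
        else:
            Z1 = np.einsum("km,smn->skn", params.W, Xs) + params.b[None, :, None]
            H = np.maximum(0.0, Z1)                        # (S', K, N)
            O = sigmoid(np.einsum("k,skn->sn", params.w2, H) + params.b2)
            nstar = np.argmax(O, axis=1)
            idx = np.arange(len(group))
            f = O[idx, nstar]
            fc = np.clip(f, SCORE_EPS, 1.0 - SCORE_EPS)
            dfdl = -(y / fc - (1.0 - y) / (1.0 - fc)) / S
            dz2 = dfdl * f * (1.0 - f)                     # (S',)
            Hc = H[idx, :, nstar]                          # (S', K)
            Z1c = Z1[idx, :, nstar]
            Xc = Xs[idx, :, nstar]                         # (S', M)
            dw2 += dz2 @ Hc
            db2 += float(dz2.sum())
            dZ1 = (dz2[:, None] * params.w2[None, :]) * (Z1c > 0)  # (S', K)
            dW += dZ1.T @ Xc
            db += dZ1.sum(axis=0)

    grads: dict[str, np.ndarray | float] = {"W": dW, "b": db}
    if params.variant != "linear":
        grads["w2"] = dw2
        grads["b2"] = db2
    return grads


@dataclass
class Velocity:
    W: np.ndarray
    b: np.ndarray
    w2: np.ndarray | None = None
    b2: float = 0.0

    @classmethod
    def zeros_like(cls, params: ModelParams) -> "Velocity":
        return cls(
            W=np.zeros_like(params.W),
            b=np.zeros_like(params.b),
            w2=None if params.w2 is None else np.zeros_like(params.w2),
            b2=0.0,
        )


def sgd_momentum_step(
    params: ModelParams,
    grads: dict[str, np.ndarray | float],
    velocity: Velocity,
    learning_rate: float,
    momentum: float,
) -> None:
    """Classical momentum update in place: v <- mu v - lr g; theta <- theta + v."""
    velocity.W = momentum * velocity.W - learning_rate * grads["W"]
    velocity.b = momentum * velocity.b - learning_rate * grads["b"]
    params.W = params.W + velocity.W
    params.b = params.b + velocity.b
    if params.w2 is not None and "w2" in grads:
        velocity.w2 = momentum * velocity.w2 - learning_rate * grads["w2"]
        velocity.b2 = momentum * velocity.b2 - learning_rate * grads["b2"]
        params.w2 = params.w2 + velocity.w2
        params.b2 = params.b2 + velocity.b2


# ---------------------------------------------------------------------------
# Autoencoder pre-training of layer 1


def pretrain_autoencoder(
    columns: np.ndarray,
    K: int,
    epochs: int = DEFAULT_PRETRAIN_EPOCHS,
    learning_rate: float = DEFAULT_PRETRAIN_LR,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Tied-weight single-hidden-layer autoencoder over SNP feature columns.

    Encoder h = sigmoid(W x + b); decoder x_hat = sigmoid(W^T h + c); binary
    cross-entropy reconstruction loss, full-batch gradient descent. Returns
    (W, b, per-epoch losses); W and b initialize convolution layer 1.
    """
    rng = rng_from(seed)
    X = np.asarray(columns, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one feature column to pretrain on")
    n, M = X.shape
    W = rng.uniform(-INIT_SCALE, INIT_SCALE, size=(K, M))
    b = np.zeros(K)
    c = np.zeros(M)
    losses: list[float] = []
    for _ in range(epochs):
        Henc = sigmoid(X @ W.T + b)                 # (n, K)
        Xhat = sigmoid(Henc @ W + c)                # (n, M)
        Xc = np.clip(Xhat, SCORE_EPS, 1 - SCORE_EPS)
        loss = float(-np.mean(np.sum(X * np.log(Xc) + (1 - X) * np.log(1 - Xc), axis=1)))
        losses.append(loss)
        dZdec = (Xhat - X) / n                      # (n, M)
        dc = dZdec.sum(axis=0)
        dW = Henc.T @ dZdec                         # decoder contribution (K, M)
        dH = dZdec @ W.T                            # (n, K)
        dZenc = dH * Henc * (1 - Henc)
        dW += dZenc.T @ X
        db = dZenc.sum(axis=0)
        W -= learning_rate * dW
        b -= learning_rate * db
        c -= learning_rate * dc
    return W, b, losses


# ---------------------------------------------------------------------------
# Dataset splitting and the training loop


def split_dataset(
    blocks: list[BlockFeatureMatrix],
    fractions: tuple[float, float, float] = DEFAULT_SPLIT,
    seed: int = 0,
) -> tuple[list[BlockFeatureMatrix], list[BlockFeatureMatrix], list[BlockFeatureMatrix]]:
    """Train/validation/test split at the source-block level.

    A true block and all negatives shuffled from it share a source id and
    always land in the same partition, so label stratification follows from
    the fixed negatives-per-true ratio. Counts use largest-remainder
    rounding; deterministic under seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    groups: dict[str, list[BlockFeatureMatrix]] = {}
    for blk in blocks:
        groups.setdefault(blk.source_id, []).append(blk)
    keys = sorted(groups)
    rng = rng_from(seed)
    rng.shuffle(keys)
    n = len(keys)
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainders = np.array(raw) - np.array(counts)
    for i in np.argsort(-remainders)[: n - sum(counts)]:
        counts[int(i)] += 1
    parts: list[list[BlockFeatureMatrix]] = []
    start = 0
    for cnt in counts:
        part: list[BlockFeatureMatrix] = []
        for key in keys[start : start + cnt]:
            part.extend(groups[key])
        parts.append(part)
        start += cnt
    train, val, test = parts
    for name, part in zip(("train", "validation", "test"), parts):
        if part and not any(b.label == 1 for b in part):
            import warnings

            warnings.warn(f"{name} partition has zero positive blocks")
    return train, val, test


@dataclass
class TrainResult:
    params: ModelParams
    log: list[dict]                       # epoch, train_nll, val_nll
    train_blocks: list[BlockFeatureMatrix] = field(default_factory=list)
    val_blocks: list[BlockFeatureMatrix] = field(default_factory=list)
    test_blocks: list[BlockFeatureMatrix] = field(default_factory=list)


def calibrate_pretrained_kernels(
    W: np.ndarray,
    columns: np.ndarray,
    quantile: float = PRETRAIN_ACTIVATION_QUANTILE,
) -> tuple[np.ndarray, np.ndarray]:
    """Orient and sparsify pretrained kernels for use as ReLU detectors.

    The autoencoder fixes each hidden unit's direction only up to sign and
    offset, but convolution layer 1 needs detectors that fire rarely and
    positively on the columns they match. Each kernel is flipped so its
    column-score distribution is right-skewed (rare-high), and its bias is
    recentered so only the top (1 - quantile) fraction of training columns
    yields a positive pre-activation.
    """
    W = W.copy()
    scores = columns @ W.T                     # (n columns, K)
    skew = scores.mean(axis=0) - np.median(scores, axis=0)
    flip = skew < 0
    W[flip] *= -1
    scores[:, flip] *= -1
    # tiny slack below the quantile keeps tied top columns strictly above
    # the ReLU threshold (exact ties are common on small discrete inputs
    # and would otherwise dead-end the subgradient-at-zero convention)
    span = scores.max(axis=0) - scores.min(axis=0)
    b = -(np.quantile(scores, quantile, axis=0) - 1e-6 * (1.0 + span))
    return W, b


def init_params(
    M: int,
    config: TrainConfig,
    variant: str,
    rng: np.random.Generator,
    pretrain_columns: np.ndarray | None = None,
    base_rate: float | None = None,
) -> ModelParams:
    """Seeded initialization; layer 1 optionally from the autoencoder.

    The second layer starts with non-negative weights so that any kernel
    selective for a shared column pattern raises — never lowers — the
    per-SNP score, which keeps the max-pool argmax informative from the
    first epochs. When the training label base rate is known, the output
    bias starts at its logit, so early epochs refine pattern detectors
    instead of drifting every score toward the class prior.
    """
    prior = (
        float(np.log(base_rate / (1.0 - base_rate)))
        if base_rate is not None and 0 < base_rate < 1
        else float(rng.uniform(-INIT_SCALE, INIT_SCALE))
    )
    if variant == "linear":
        return ModelParams(
            W=rng.uniform(-INIT_SCALE, INIT_SCALE, size=(1, M)),
            b=np.array([prior]),
            w2=None,
            b2=None,
            variant=variant,
        )
    if pretrain_columns is not None and config.pretrain_epochs > 0:
        W, _, _ = pretrain_autoencoder(
            pretrain_columns, config.K, epochs=config.pretrain_epochs, seed=rng
        )
        W, b = calibrate_pretrained_kernels(W, pretrain_columns)
    else:
        W = rng.uniform(-INIT_SCALE, INIT_SCALE, size=(config.K, M))
        b = np.zeros(config.K)
    return ModelParams(
        W=W,
        b=b,
        w2=rng.uniform(0.0, 2 * INIT_SCALE, size=config.K),
        b2=prior,
        variant=variant,
    )


def train(
    blocks: list[BlockFeatureMatrix],
    config: TrainConfig,
    variant: str = "full",
    pretrain: bool = True,
) -> TrainResult:
    """Mini-batch momentum SGD with early stopping on validation NLL."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    labels = {b.label for b in blocks}
    if labels != {0, 1}:
        raise ValueError("training data must contain both labels")
    rng = rng_from(config.seed)
    train_blocks, val_blocks, test_blocks = split_dataset(
        blocks, config.split_fractions, seed=config.seed
    )
    M = blocks[0].n_features
    pretrain_cols = None
    if pretrain and variant != "linear" and config.pretrain_epochs > 0:
        cols = [
            _block_view(b, variant).T for b in train_blocks if b.label == 1
        ]
        if cols:
            pretrain_cols = np.concatenate(cols, axis=0).astype(float)
    base_rate = float(np.mean([b.label for b in train_blocks])) if train_blocks else None
    params = init_params(
        M, config, variant, rng, pretrain_columns=pretrain_cols, base_rate=base_rate
    )
    params.catalog = catalog_hash(blocks[0].feature_ids)
    velocity = Velocity.zeros_like(params)

    best = params.copy()
    best_val = np.inf
    stall = 0
    log: list[dict] = []
    order = np.arange(len(train_blocks))
    for epoch in range(config.max_epochs):
        rng.shuffle(order)
        for lo in range(0, len(order), config.batch_size):
            batch = [train_blocks[i] for i in order[lo : lo + config.batch_size]]
            grads = backward(batch, params)
            sgd_momentum_step(
                params, grads, velocity, config.learning_rate, config.momentum
            )
        train_nll = batch_nll(train_blocks, params)
        val_nll = batch_nll(val_blocks, params) if val_blocks else train_nll
        if not np.isfinite(train_nll) or not np.isfinite(val_nll):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: NLL is not finite "
                f"(learning rate {config.learning_rate} may be too high)"
            )
        log.append({"epoch": epoch, "train_nll": train_nll, "val_nll": val_nll})
        if val_nll < best_val - 1e-9:
            best_val = val_nll
            best = params.copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    return TrainResult(
        params=best,
        log=log,
        train_blocks=train_blocks,
        val_blocks=val_blocks,
        test_blocks=test_blocks,
    )
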