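"""Pairwise convolutional network for dispersal estimation.

The model never sees the full genotype matrix at once.  Instead it loops over
all C(n, 2) pairs of individuals; a shared "extractor" (conv blocks with a
kernel spanning two SNPs and average pooling over ten SNPs, then one dense
layer) turns each pair's genotype slab plus the pair's Euclidean distance into
a fixed-width feature vector.  The features of all pairs are stacked in a
canonical order and a single linear unit (the "head") maps them to the
dispersal estimate.

Training supports gradient gating: only k_extract randomly chosen pairs
contribute gradients to the extractor weights, while every pair contributes to
the forward pass, to the loss, and to the head-layer gradients.  On GPU
implementations this caps memory; the semantics are reproduced here exactly.

Everything is plain NumPy: the forward pass, backpropagation and the Adam
optimizer are implemented explicitly so the gating rule is under our control
and testable against finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, InvalidParameterError
from .io import GenotypeMatrix, LocationsTable, pairwise_distances


def enumerate_pairs(n: int) -> np.ndarray:
    """All unordered sample pairs (i, j), i < j, in lexicographic order.

    This order is canonical: the head layer has one weight per (pair,
    feature) slot, so the order must be identical at training and prediction.
    """
    if n < 2:
        raise InvalidParameterError(f"need at least 2 samples, got {n}")
    return np.array([(i, j) for i in range(n - 1) for j in range(i + 1, n)],
                    dtype=np.int64)


def n_pairs(n: int) -> int:
    return n * (n - 1) // 2


@dataclass
class NetworkSpec:
    """Architecture hyperparameters.

    ``conv_kernel_snps`` and ``pool_width`` default to the published values
    (kernel spanning 2 SNPs, pooling over 10).  Block depth and filter counts
    are free hyperparameters: by default conv+pool blocks are repeated until
    the SNP axis drops below ``pool_width`` (3 blocks for m = 5000), with
    filter counts doubling from 32.
    """

    n: int
    m: int
    phased: bool = False
    conv_kernel_snps: int = 2
    pool_width: int = 10
    filters_per_block: tuple = None  # type: ignore[assignment]
    pair_feature_width: int = 128
    k_extract: int | None = None  # None = all pairs

    def __post_init__(self):
        if self.conv_kernel_snps < 1 or self.pool_width < 1:
            raise InvalidParameterError("conv_kernel_snps and pool_width must be >= 1")
        if self.n < 2:
            raise InvalidParameterError("need n >= 2")
        if self.filters_per_block is None:
            depth = len(self._plan_lengths(auto=True))
            self.filters_per_block = tuple(32 * 2**b for b in range(depth))
        else:
            self.filters_per_block = tuple(self.filters_per_block)
        if not self.filters_per_block:
            raise InvalidParameterError("need at least one conv block")
        if any(l < 1 for l in self.block_lengths()):
            raise ConfigurationError(
                f"SNP axis vanishes: m={self.m} cannot support "
                f"{len(self.filters_per_block)} conv/pool blocks"
            )
        if self.k_extract is not None and not (1 <= self.k_extract <= n_pairs(self.n)):
            raise InvalidParameterError(
                f"k_extract must be in [1, {n_pairs(self.n)}], got {self.k_extract}"
            )

    def _plan_lengths(self, auto: bool = False) -> list[int]:
        lengths, L = [], self.m
        n_blocks = None if auto else len(self.filters_per_block)
        while True:
            L = (L - self.conv_kernel_snps + 1) // self.pool_width
            if L < 1:
                break
            lengths.append(L)
            if auto and L < self.pool_width:
                break
            if n_blocks is not None and len(lengths) == n_blocks:
                break
        return lengths or [0]

    def block_lengths(self) -> list[int]:
        """SNP-axis length after each conv+pool block."""
        lengths, L = [], self.m
        for _ in self.filters_per_block:
            L = (L - self.conv_kernel_snps + 1) // self.pool_width
            lengths.append(L)
        return lengths

    @property
    def in_channels(self) -> int:
        return 4 if self.phased else 2

    @property
    def n_pairs(self) -> int:
        return n_pairs(self.n)

    @property
    def flat_width(self) -> int:
        return self.filters_per_block[-1] * self.block_lengths()[-1]

    def to_dict(self) -> dict:
        return {
            "n": self.n, "m": self.m, "phased": self.phased,
            "conv_kernel_snps": self.conv_kernel_snps, "pool_width": self.pool_width,
            "filters_per_block": list(self.filters_per_block),
            "pair_feature_width": self.pair_feature_width,
            "k_extract": self.k_extract,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["filters_per_block"] = tuple(d["filters_per_block"])
        return cls(**d)


@dataclass
class ModelWeights:
    """Trained parameters plus the metadata needed to reuse them.

    One extractor parameter set exists regardless of the pair count (weights
    are shared across pairs); only the head grows with C(n, 2).  The target
    normalization constants and the distance scale travel with the weights so
    a prediction can invert them.
    """

    spec: NetworkSpec
    conv_W: list  # block b: (filters_b, channels_{b-1}, kernel)
    conv_b: list
    dense_W: np.ndarray  # (pair_feature_width, flat_width + 1); last col = distance
    dense_b: np.ndarray
    head_W: np.ndarray  # (n_pairs * pair_feature_width,)
    head_b: float
    target_mean: float = 0.0
    target_sd: float = 1.0
    distance_scale: float = 1.0

    @classmethod
    def initialize(cls, spec: NetworkSpec, rng_seed: int = 0) -> "ModelWeights":
        """He-style initialization, reproducible under the seed."""
        rng = np.random.default_rng(rng_seed)
        conv_W, conv_b = [], []
        c_in = spec.in_channels
        for f in spec.filters_per_block:
            fan_in = c_in * spec.conv_kernel_snps
            conv_W.append(rng.normal(0, np.sqrt(2.0 / fan_in),
                                     size=(f, c_in, spec.conv_kernel_snps)))
            conv_b.append(np.zeros(f))
            c_in = f
        flat = spec.flat_width
        dense_W = rng.normal(0, np.sqrt(2.0 / (flat + 1)),
                             size=(spec.pair_feature_width, flat + 1))
        dense_b = np.zeros(spec.pair_feature_width)
        head_in = spec.n_pairs * spec.pair_feature_width
        head_W = rng.normal(0, np.sqrt(1.0 / head_in), size=head_in)
        return cls(spec=spec, conv_W=conv_W, conv_b=conv_b,
                   dense_W=dense_W, dense_b=dense_b,
                   head_W=head_W, head_b=0.0)

    # -- parameter plumbing ------------------------------------------------
    def param_list(self) -> list:
        """Mutable references to every parameter array (head_b is wrapped)."""
        return [*self.conv_W, *self.conv_b, self.dense_W, self.dense_b, self.head_W]

    def extractor_param_count(self) -> int:
        B = len(self.conv_W)
        return int(sum(w.size for w in self.param_list()[: 2 * B + 2]))

    def astype(self, dtype) -> "ModelWeights":
        """Cast all parameter arrays (e.g. float32 for faster CPU training)."""
        return ModelWeights(
            spec=self.spec,
            conv_W=[w.astype(dtype) for w in self.conv_W],
            conv_b=[b.astype(dtype) for b in self.conv_b],
            dense_W=self.dense_W.astype(dtype), dense_b=self.dense_b.astype(dtype),
            head_W=self.head_W.astype(dtype), head_b=float(self.head_b),
            target_mean=self.target_mean, target_sd=self.target_sd,
            distance_scale=self.distance_scale,
        )

    def copy(self) -> "ModelWeights":
        return ModelWeights(
            spec=self.spec,
            conv_W=[w.copy() for w in self.conv_W],
            conv_b=[b.copy() for b in self.conv_b],
            dense_W=self.dense_W.copy(), dense_b=self.dense_b.copy(),
            head_W=self.head_W.copy(), head_b=float(self.head_b),
            target_mean=self.target_mean, target_sd=self.target_sd,
            distance_scale=self.distance_scale,
        )

    def save(self, path: str | Path) -> None:
        meta = dict(self.spec.to_dict(), target_mean=self.target_mean,
                    target_sd=self.target_sd, distance_scale=self.distance_scale,
                    head_b=float(self.head_b), n_blocks=len(self.conv_W))
        arrays = {"dense_W": self.dense_W, "dense_b": self.dense_b, "head_W": self.head_W}
        for i, (w, b) in enumerate(zip(self.conv_W, self.conv_b)):
            arrays[f"conv_W{i}"] = w
            arrays[f"conv_b{i}"] = b
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelWeights":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            nb = meta.pop("n_blocks")
            head_b = meta.pop("head_b")
            tm, ts, ds = (meta.pop("target_mean"), meta.pop("target_sd"),
                          meta.pop("distance_scale"))
            spec = NetworkSpec.from_dict(meta)
            return cls(spec=spec,
                       conv_W=[z[f"conv_W{i}"] for i in range(nb)],
                       conv_b=[z[f"conv_b{i}"] for i in range(nb)],
                       dense_W=z["dense_W"], dense_b=z["dense_b"],
                       head_W=z["head_W"], head_b=float(head_b),
                       target_mean=tm, target_sd=ts, distance_scale=ds)


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding windows as stacked channel blocks: (N, L, C) -> (N, L-k+1, k*C).

    Channels-last layout keeps every matmul a single large contiguous GEMM.
    """
    L_out = x.shape[1] - k + 1
    return np.concatenate([x[:, j : j + L_out, :] for j in range(k)], axis=2)


def _weight_matrix(W: np.ndarray) -> np.ndarray:
    """(F, C, k) parameter tensor as the (k*C, F) GEMM operand."""
    return np.concatenate([W[:, :, j] for j in range(W.shape[2])], axis=1).T


def _conv1d(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 1-D convolution over the SNP axis. x: (N, L, C) -> (N, L-k+1, F)."""
    xw = _im2col(x, W.shape[2])
    return xw @ _weight_matrix(W) + b


def _conv1d_backward(x, W, dz):
    """Gradients of a valid conv: returns (dW, db, dx); dz is (N, L_out, F)."""
    F, C, k = W.shape
    L_out = dz.shape[1]
    xw = _im2col(x, k)
    dWm = np.tensordot(dz, xw, axes=([0, 1], [0, 1]))  # (F, k*C)
    dW = np.stack([dWm[:, j * C : (j + 1) * C] for j in range(k)], axis=2)
    dxw = dz @ _weight_matrix(W).T  # (N, L_out, k*C)
    dx = np.zeros_like(x)
    for j in range(k):
        dx[:, j : j + L_out, :] += dxw[:, :, j * C : (j + 1) * C]
    db = dz.sum(axis=(0, 1))
    return dW, db, dx


def _avgpool(a: np.ndarray, p: int) -> np.ndarray:
    """Non-overlapping average pooling over the SNP axis (axis 1); the
    trailing remainder is dropped."""
    N, L, F = a.shape
    Lp = L // p
    return a[:, : Lp * p, :].reshape(N, Lp, p, F).mean(axis=2)


def _avgpool_backward(da: np.ndarray, p: int, L_in: int) -> np.ndarray:
    N, Lp, F = da.shape
    dx = np.zeros((N, L_in, F))
    dx[:, : Lp * p, :] = np.broadcast_to(
        (da / p)[:, :, None, :], (N, Lp, p, F)
    ).reshape(N, Lp * p, F)
    return dx


def build_pair_slabs(g: GenotypeMatrix, pairs: np.ndarray) -> np.ndarray:
    """Genotype slabs for each pair: (P, 2, m) unphased or (P, 4, m) phased.

    Within a pair the lower-index individual's rows come first (the canonical
    within-pair order frozen at training time).
    """
    c = g.counts.astype(np.float64)
    if g.phased:
        rows_i = np.stack([c[2 * pairs[:, 0]], c[2 * pairs[:, 0] + 1]], axis=1)
        rows_j = np.stack([c[2 * pairs[:, 1]], c[2 * pairs[:, 1] + 1]], axis=1)
        return np.concatenate([rows_i, rows_j], axis=1)
    return np.stack([c[pairs[:, 0]], c[pairs[:, 1]]], axis=1)


def _extractor_forward(weights: ModelWeights, slabs: np.ndarray, d_scaled: np.ndarray):
    """Run the shared extractor on a stack of pair slabs.

    slabs: (N, C, m); d_scaled: (N,).  Returns (features (N, fw), cache).
    """
    spec = weights.spec
    # channels-last internally: (N, C, m) -> (N, m, C)
    h = np.ascontiguousarray(np.transpose(slabs, (0, 2, 1)))
    cache_blocks = []
    for W, b in zip(weights.conv_W, weights.conv_b):
        z = _conv1d(h, W, b)
        a = np.maximum(z, 0.0)
        pooled = _avgpool(a, spec.pool_width)
        cache_blocks.append((h, z))
        h = pooled
    # flatten position-major: (position, filter) index order
    flat = h.reshape(h.shape[0], -1)
    x = np.concatenate([flat, d_scaled[:, None]], axis=1)
    u = x @ weights.dense_W.T + weights.dense_b
    feats = np.maximum(u, 0.0)
    cache = {"blocks": cache_blocks, "x": x, "u": u, "flat_shape": h.shape}
    return feats, cache


def _extractor_backward(weights: ModelWeights, dfeats: np.ndarray, cache):
    """Backprop through the extractor. Returns grad dict (+ d_input unused)."""
    spec = weights.spec
    du = dfeats * (cache["u"] > 0)
    dW_dense = du.T @ cache["x"]
    db_dense = du.sum(axis=0)
    dx = du @ weights.dense_W
    dflat = dx[:, :-1]  # last column is the distance input
    dh = dflat.reshape(cache["flat_shape"])
    d_conv_W, d_conv_b = [None] * len(weights.conv_W), [None] * len(weights.conv_W)
    for bidx in range(len(weights.conv_W) - 1, -1, -1):
        h_in, z = cache["blocks"][bidx]
        da = _avgpool_backward(dh, spec.pool_width, z.shape[1])
        dz = da * (z > 0)
        dW, db, dh = _conv1d_backward(h_in, weights.conv_W[bidx], dz)
        d_conv_W[bidx], d_conv_b[bidx] = dW, db
    return {"conv_W": d_conv_W, "conv_b": d_conv_b,
            "dense_W": dW_dense, "dense_b": db_dense}


def extract_pair_features(g_pair: np.ndarray, d_ij: float, weights: ModelWeights) -> np.ndarray:
    """Feature vector for a single pair slab (2 x m, or 4 x m phased)."""
    g_pair = np.asarray(g_pair, dtype=np.float64)
    if g_pair.ndim != 2 or g_pair.shape != (weights.spec.in_channels, weights.spec.m):
        raise ConfigurationError(
            f"pair slab shape {g_pair.shape} incompatible with spec "
            f"({weights.spec.in_channels} x {weights.spec.m})"
        )
    d_scaled = np.array([d_ij / weights.distance_scale])
    feats, _ = _extractor_forward(weights, g_pair[None], d_scaled)
    return feats[0]


def forward_batch(weights: ModelWeights, slabs: np.ndarray, dists: np.ndarray):
    """Vectorized forward pass over a batch of datasets.

    slabs: (B, P, C, m); dists: (B, P) raw distances.
    Returns (sigma_hat (B,), yhat_norm (B,), cache).
    """
    B, P = slabs.shape[0], slabs.shape[1]
    spec = weights.spec
    if P != spec.n_pairs:
        raise ConfigurationError(f"{P} pairs but spec expects {spec.n_pairs}")
    flat_slabs = slabs.reshape(B * P, slabs.shape[2], slabs.shape[3])
    d_scaled = (dists / weights.distance_scale).reshape(B * P)
    feats, cache = _extractor_forward(weights, flat_slabs, d_scaled)
    stacked = feats.reshape(B, P * spec.pair_feature_width)
    yhat_norm = stacked @ weights.head_W + weights.head_b
    sigma_hat = yhat_norm * weights.target_sd + weights.target_mean
    cache["stacked"] = stacked
    cache["B"], cache["P"] = B, P
    return sigma_hat, yhat_norm, cache


def forward(g: GenotypeMatrix, loc: LocationsTable, weights: ModelWeights) -> float:
    """Dispersal estimate for one dataset.

    Features are extracted from ALL pairs; the result does not depend on
    k_extract, which only gates gradients during training.
    """
    if g.n != loc.n:
        raise ConfigurationError(f"genotypes have {g.n} samples, locations {loc.n}")
    if g.n != weights.spec.n or g.m != weights.spec.m or g.phased != weights.spec.phased:
        raise ConfigurationError(
            f"dataset (n={g.n}, m={g.m}, phased={g.phased}) incompatible with "
            f"spec (n={weights.spec.n}, m={weights.spec.m}, phased={weights.spec.phased})"
        )
    pairs = enumerate_pairs(g.n)
    slabs = build_pair_slabs(g, pairs)[None]
    dists = pairwise_distances(loc, pairs)[None]
    sigma_hat, _, _ = forward_batch(weights, slabs, dists)
    return float(sigma_hat[0])


def permutation_indices(n: int, perm: np.ndarray, phased: bool = False):
    """Pair reindexing induced by relabelling individuals with ``perm``.

    Relabelling leaves a dataset physically identical but permutes the
    canonical pair order and may swap the two individuals within a pair;
    used as a training augmentation so the position-specific head cannot
    overfit arbitrary slot identities.  Returns (pair_perm, channel_idx)
    such that ``aug[:, p] = slabs[:, pair_perm[p], channel_idx[p]]``.
    """
    pairs = enumerate_pairs(n)
    pos = {(i, j): p for p, (i, j) in enumerate(map(tuple, pairs))}
    P = len(pairs)
    pair_perm = np.empty(P, dtype=np.int64)
    swap = np.zeros(P, dtype=bool)
    for p, (i, j) in enumerate(pairs):
        a, b = int(perm[i]), int(perm[j])
        if a > b:
            a, b = b, a
            swapped = True
        else:
            swapped = False
        pair_perm[pos[(a, b)]] = p
        swap[pos[(a, b)]] = swapped
    C = 4 if phased else 2
    base = np.arange(C)
    flipped = np.array([2, 3, 0, 1]) if phased else np.array([1, 0])
    channel_idx = np.where(swap[:, None], flipped[None, :], base[None, :])
    return pair_perm, channel_idx


def apply_permutation(slabs: np.ndarray, dists: np.ndarray, pair_perm, channel_idx):
    """Apply a relabelling to batched slabs (B, P, C, m) and distances (B, P)."""
    out = slabs[:, pair_perm]
    out = np.take_along_axis(out, channel_idx[None, :, :, None], axis=2)
    return out, dists[:, pair_perm]


def select_extract_pairs(pairs: np.ndarray, k_extract: int, rng_seed: int) -> np.ndarray:
    """Uniform subset of pair indices used to optimise the extractor weights."""
    P = len(pairs)
    if not 1 <= k_extract <= P:
        raise InvalidParameterError(f"k_extract must be in [1, {P}], got {k_extract}")
    rng = np.random.default_rng(rng_seed)
    return np.sort(rng.choice(P, size=k_extract, replace=False))


def backward_batch(weights: ModelWeights, cache, dy_norm: np.ndarray,
                   selected_pairs: np.ndarray | None):
    """Gradients of a scalar loss given dL/d(yhat_norm).

    Head gradients flow through every pair; extractor gradients only through
    the selected pairs (``None`` selects all).  This is the k_extract gate.
    """
    B, P = cache["B"], cache["P"]
    fw = weights.spec.pair_feature_width
    d_head_W = cache["stacked"].T @ dy_norm
    d_head_b = float(dy_norm.sum())
    dstacked = np.outer(dy_norm, weights.head_W)  # (B, P*fw)
    dfeats = dstacked.reshape(B, P, fw)
    if selected_pairs is not None and len(selected_pairs) < P:
        # unselected pairs contribute exactly zero to the extractor
        # gradient, so restrict the backward pass to the selected rows —
        # this is where the gate saves computation (memory, on GPU stacks)
        sel = np.asarray(selected_pairs)
        flat_idx = (np.arange(B)[:, None] * P + sel[None, :]).ravel()
        sub_cache = {
            "blocks": [(h[flat_idx], z[flat_idx]) for h, z in cache["blocks"]],
            "x": cache["x"][flat_idx],
            "u": cache["u"][flat_idx],
            "flat_shape": (len(flat_idx),) + cache["flat_shape"][1:],
        }
        dfeats_sel = dfeats[:, sel, :].reshape(len(flat_idx), fw)
        grads = _extractor_backward(weights, dfeats_sel, sub_cache)
    else:
        grads = _extractor_backward(weights, dfeats.reshape(B * P, fw), cache)
    grads["head_W"] = d_head_W
    grads["head_b"] = d_head_b
    return grads


class AdamState:
    """Adam optimizer state over a ModelWeights parameter set."""

    def __init__(self, weights: ModelWeights, learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        arrays = weights.param_list()
        shapes = [(w.shape, w.dtype) for w in arrays] + [((), np.float64)]
        self.m = [np.zeros(s, dtype=d) for s, d in shapes]
        self.v = [np.zeros(s, dtype=d) for s, d in shapes]

    @staticmethod
    def _grad_list(grads: dict) -> list:
        return [*grads["conv_W"], *grads["conv_b"], grads["dense_W"],
                grads["dense_b"], grads["head_W"], grads["head_b"]]

    def step(self, weights: ModelWeights, grads: dict) -> None:
        self.t += 1
        params = weights.param_list()
        glist = self._grad_list(grads)
        for i, g in enumerate(glist):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * np.asarray(g)
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * np.square(g)
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            upd = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if i < len(params):
                params[i] -= upd
            else:
                weights.head_b = float(weights.head_b - upd)


def gated_training_step(slabs, dists, y_norm, weights: ModelWeights,
                        selected_pairs, adam: AdamState):
    """One MSE/Adam update with the k_extract gradient gate.

    slabs: (B, P, C, m); dists: (B, P); y_norm: (B,) normalized targets.
    Returns the batch loss (computed from ALL pairs).
    """
    if selected_pairs is not None and len(selected_pairs) == 0:
        raise InvalidParameterError("selected_pairs must not be empty")
    _, yhat_norm, cache = forward_batch(weights, slabs, dists)
    resid = yhat_norm - y_norm
    loss = float(np.mean(resid**2))
    dy = 2.0 * resid / len(resid)
    grads = backward_batch(weights, cache, dy, selected_pairs)
    adam.step(weights, grads)
    return loss
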