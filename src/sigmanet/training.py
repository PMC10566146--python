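"""Training loop, target normalization, and evaluation metrics.

Training minimizes mean squared error on z-scored targets with Adam
(learning rate 1e-4 by default), using the gated step from
:mod:`sigmanet.network`.  The best-validation-loss checkpoint is kept and
restored.  Evaluation reports the three benchmark metrics: mean relative
absolute error (MRAE), root mean squared error (RMSE), and the squared
Pearson correlation between true and predicted dispersal rates.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigurationError,
    DegenerateTrainingSetError,
    DivergenceError,
    EmptyInputError,
    InvalidParameterError,
)
from .io import DatasetStore, GenotypeMatrix, LocationsTable, pairwise_distances
from .network import (
    AdamState,
    ModelWeights,
    NetworkSpec,
    apply_permutation,
    build_pair_slabs,
    enumerate_pairs,
    forward,
    forward_batch,
    gated_training_step,
    permutation_indices,
    select_extract_pairs,
)


@dataclass
class TrainingConfig:
    """Optimization settings.  The published defaults are MSE + Adam at
    learning rate 1e-4; desk-scale runs typically raise the rate."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10
    k_extract: int | None = None
    seed: int = 0
    validation_fraction: float = 0.15
    #: "tail" holds out the last fraction of the store — simulation-disjoint
    #: when the store was written simulation-major; "random" shuffles first
    validation_split: str = "tail"
    #: compute precision for the fit; float32 roughly halves CPU time
    dtype: str = "float32"
    #: per-batch random relabelling of individuals (a symmetry of the data):
    #: stops the position-specific head from overfitting pair-slot identities
    augment_relabel: bool = True
    #: halve the learning rate after this many epochs without validation
    #: improvement (None disables the schedule)
    lr_patience: int | None = 8
    lr_decay: float = 0.5
    min_lr: float = 1e-5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise InvalidParameterError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise InvalidParameterError("batch_size must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise InvalidParameterError("validation_fraction must be in (0, 1)")
        if self.validation_split not in ("tail", "random"):
            raise InvalidParameterError("validation_split must be 'tail' or 'random'")


@dataclass
class MetricsReport:
    """Benchmark metrics over an evaluation set."""

    mrae: float
    rmse: float
    r2: float
    n_eval: int
    undefined_fraction: float = 0.0

    def __str__(self):
        return (f"MRAE={self.mrae:.3f}  RMSE={self.rmse:.3f}  r2={self.r2:.3f}  "
                f"(n={self.n_eval}, undefined={100 * self.undefined_fraction:.1f}%)")


def normalize_targets(sigmas) -> tuple[np.ndarray, tuple[float, float]]:
    """Z-score targets over the training set; returns (normalized, (mean, sd))."""
    s = np.asarray(sigmas, dtype=float)
    if np.any(s <= 0):
        raise InvalidParameterError("all sigma targets must be > 0")
    mean, sd = float(s.mean()), float(s.std())
    if sd == 0:
        raise DegenerateTrainingSetError("targets have zero variance")
    return (s - mean) / sd, (mean, sd)


def compute_metrics(sigma_true, sigma_hat) -> MetricsReport:
    """MRAE, RMSE and squared Pearson correlation of true vs. predicted."""
    t = np.asarray(sigma_true, dtype=float)
    p = np.asarray(sigma_hat, dtype=float)
    if t.size == 0:
        raise EmptyInputError("empty evaluation set")
    mrae = float(np.mean(np.abs(p - t) / t))
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    if t.size < 2 or np.std(t) == 0 or np.std(p) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(t, p)[0, 1] ** 2)
    return MetricsReport(mrae=mrae, rmse=rmse, r2=r2, n_eval=int(t.size))


def load_arrays(store: DatasetStore):
    """Materialize a store as (slabs (N,P,C,m), dists (N,P), sigmas (N,))."""
    if store.count == 0:
        raise EmptyInputError(f"store {store.path} is empty")
    pairs = enumerate_pairs(store.n)
    slabs, dists, sigmas = [], [], []
    for g, loc, sigma_true, _sf in store:
        slabs.append(build_pair_slabs(g, pairs))
        dists.append(pairwise_distances(loc, pairs))
        sigmas.append(sigma_true)
    return np.asarray(slabs), np.asarray(dists), np.asarray(sigmas)


def _batched_predictions(weights, slabs, dists, chunk=64,
                         symmetrize: int = 1, seed: int = 0) -> np.ndarray:
    """Predictions for stacked datasets; ``symmetrize > 1`` averages the
    estimate over that many random relabellings of the individuals (a
    symmetry of the data the position-specific head does not share), which
    removes slot-assignment noise from the estimator."""
    reps = [None]
    if symmetrize > 1:
        rng = np.random.default_rng(seed)
        spec = weights.spec
        reps = [None] + [
            permutation_indices(spec.n, rng.permutation(spec.n), phased=spec.phased)
            for _ in range(symmetrize - 1)
        ]
    acc = np.zeros(len(slabs))
    for rep in reps:
        for k in range(0, len(slabs), chunk):
            s_chunk = slabs[k : k + chunk]
            d_chunk = dists[k : k + chunk]
            if rep is not None:
                s_chunk, d_chunk = apply_permutation(s_chunk, d_chunk, *rep)
            s, _, _ = forward_batch(weights, s_chunk, d_chunk)
            acc[k : k + len(s)] += s
    return acc / len(reps)


def train(store: DatasetStore, spec: NetworkSpec, cfg: TrainingConfig):
    """Train on a dataset store; returns (best ModelWeights, history dict).

    The store is split into training and validation datasets; targets are
    z-scored on the training split and the constants frozen into the weights;
    the checkpoint with the best validation loss is restored at the end.
    """
    if store.n != spec.n or store.m != spec.m or store.phased != spec.phased:
        raise ConfigurationError(
            f"store (n={store.n}, m={store.m}, phased={store.phased}) does not "
            f"match spec (n={spec.n}, m={spec.m}, phased={spec.phased})"
        )
    slabs, dists, sigmas = load_arrays(store)
    N = len(sigmas)
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.validation_fraction * N)))
    if n_val >= N:
        raise ConfigurationError("validation split leaves no training data")
    if cfg.validation_split == "tail":
        # stores are written simulation-major, so a tail split keeps the
        # validation simulations disjoint from the training ones
        val_idx, tr_idx = np.arange(N - n_val, N), np.arange(N - n_val)
    else:
        perm = rng.permutation(N)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

    y_norm = np.empty(N)
    y_norm[tr_idx], (mean, sd) = normalize_targets(sigmas[tr_idx])
    y_norm[val_idx] = (sigmas[val_idx] - mean) / sd
    y_norm = y_norm.astype(np.dtype(cfg.dtype))

    dtype = np.dtype(cfg.dtype)
    slabs = slabs.astype(dtype)
    dists = dists.astype(dtype)
    weights = ModelWeights.initialize(
        spec, rng_seed=int(rng.integers(2**31 - 1))
    ).astype(dtype)
    weights.target_mean, weights.target_sd = mean, sd
    weights.distance_scale = max(float(dists[tr_idx].max()), 1e-12)

    adam = AdamState(weights, learning_rate=cfg.learning_rate)
    k_extract = cfg.k_extract if cfg.k_extract is not None else spec.k_extract
    pairs = enumerate_pairs(spec.n)

    def val_loss():
        _, yh, _ = forward_batch(weights, slabs[val_idx], dists[val_idx])
        return float(np.mean((yh - y_norm[val_idx]) ** 2))

    history = {"train_loss": [], "val_loss": [], "epoch_seconds": [], "lr": []}
    best = {"loss": val_loss(), "weights": weights.copy(), "epoch": -1}
    step = 0
    since_best = 0
    since_decay = 0
    for epoch in range(cfg.max_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(tr_idx)
        losses = []
        for k in range(0, len(order), cfg.batch_size):
            idx = order[k : k + cfg.batch_size]
            batch_slabs, batch_dists = slabs[idx], dists[idx]
            if cfg.augment_relabel:
                perm = rng.permutation(spec.n)
                pair_perm, channel_idx = permutation_indices(
                    spec.n, perm, phased=spec.phased
                )
                batch_slabs, batch_dists = apply_permutation(
                    batch_slabs, batch_dists, pair_perm, channel_idx
                )
            selected = None
            if k_extract is not None:
                # the gated subset is re-drawn for every batch
                selected = select_extract_pairs(
                    pairs, k_extract, rng_seed=int(rng.integers(2**31 - 1))
                )
            loss = gated_training_step(
                batch_slabs, batch_dists, y_norm[idx], weights, selected, adam
            )
            if not np.isfinite(loss):
                raise DivergenceError("non-finite training loss", step=step)
            losses.append(loss)
            step += 1
        vloss = val_loss()
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(vloss)
        history["epoch_seconds"].append(time.perf_counter() - t0)
        history["lr"].append(adam.lr)
        if vloss < best["loss"]:
            best = {"loss": vloss, "weights": weights.copy(), "epoch": epoch}
            since_best = 0
            since_decay = 0
        else:
            since_best += 1
            since_decay += 1
            if since_best > cfg.patience:
                break
            if (cfg.lr_patience is not None and since_decay > cfg.lr_patience
                    and adam.lr > cfg.min_lr):
                adam.lr = max(cfg.min_lr, adam.lr * cfg.lr_decay)
                since_decay = 0
    history["best_epoch"] = best["epoch"]
    history["best_val_loss"] = best["loss"]
    return best["weights"], history


def predict(weights: ModelWeights, g: GenotypeMatrix, loc: LocationsTable) -> float:
    """Dispersal estimate for one dataset."""
    return forward(g, loc, weights)


def predict_store(weights: ModelWeights, store: DatasetStore,
                  symmetrize: int = 8) -> np.ndarray:
    slabs, dists, _ = load_arrays(store)
    return _batched_predictions(weights, slabs, dists, symmetrize=symmetrize)


def evaluate(weights: ModelWeights, store: DatasetStore,
             symmetrize: int = 8) -> MetricsReport:
    """Metrics of the trained network over every record of a store."""
    slabs, dists, sigmas = load_arrays(store)
    preds = _batched_predictions(weights, slabs, dists, symmetrize=symmetrize)
    return compute_metrics(sigmas, preds)


def constant_mean_metrics(train_sigmas, eval_sigmas) -> MetricsReport:
    """Baseline that always predicts the training-set mean sigma."""
    mu = float(np.mean(np.asarray(train_sigmas, dtype=float)))
    return compute_metrics(eval_sigmas, np.full(len(eval_sigmas), mu))


# ---------------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------------


class PairwiseDispersalNet:
    """The pairwise-extractor dispersal model, statsmodels-style.

    Build from a training store (or an explicit NetworkSpec), call
    :meth:`fit`, and use the returned results object for prediction,
    evaluation and the summary table.
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec

    @classmethod
    def from_store(cls, store: DatasetStore, **spec_kw) -> "PairwiseDispersalNet":
        return cls(NetworkSpec(n=store.n, m=store.m, phased=store.phased, **spec_kw))

    def fit(self, store: DatasetStore, config: TrainingConfig | None = None,
            n_members: int = 1):
        """Train the network; ``n_members > 1`` fits an ensemble of
        independently seeded runs whose predictions are averaged — the
        standard remedy for trajectory-to-trajectory variance when training
        sets are small."""
        from dataclasses import replace as dc_replace

        cfg = config or TrainingConfig()
        members, histories = [], []
        for j in range(n_members):
            cfg_j = dc_replace(cfg, seed=cfg.seed + 9973 * j)
            weights, history = train(store, self.spec, cfg_j)
            members.append(weights)
            histories.append(history)
        return DispersalFitResults(self, members, histories, cfg)


class DispersalFitResults:
    """Fitted pairwise network: weights, history, prediction and metrics.

    Holds one or more trained parameter sets (an ensemble); predictions are
    averaged over members.
    """

    def __init__(self, model: PairwiseDispersalNet, weights, history, config):
        self.members = list(weights) if isinstance(weights, (list, tuple)) else [weights]
        self.histories = (list(history) if isinstance(history, (list, tuple))
                          else [history])
        self.model = model
        self.config = config

    @property
    def weights(self) -> ModelWeights:
        return self.members[0]

    @property
    def history(self) -> dict:
        return self.histories[0]

    def predict(self, g: GenotypeMatrix, loc: LocationsTable) -> float:
        return float(np.mean([predict(w, g, loc) for w in self.members]))

    def predict_store(self, store: DatasetStore, symmetrize: int = 8) -> np.ndarray:
        slabs, dists, _ = load_arrays(store)
        preds = [_batched_predictions(w, slabs, dists, symmetrize=symmetrize)
                 for w in self.members]
        return np.mean(preds, axis=0)

    def evaluate(self, store: DatasetStore, symmetrize: int = 8) -> MetricsReport:
        slabs, dists, sigmas = load_arrays(store)
        preds = [_batched_predictions(w, slabs, dists, symmetrize=symmetrize)
                 for w in self.members]
        return compute_metrics(sigmas, np.mean(preds, axis=0))

    def summary(self) -> str:
        s = self.model.spec
        lines = [
            "Pairwise dispersal network — fit summary",
            "=" * 48,
            f"samples per dataset (n):      {s.n}",
            f"SNPs per dataset (m):         {s.m}",
            f"phased:                       {s.phased}",
            f"pairs per dataset:            {s.n_pairs}",
            f"conv blocks (filters):        {list(s.filters_per_block)}",
            f"kernel / pool widths:         {s.conv_kernel_snps} / {s.pool_width}",
            f"pair feature width:           {s.pair_feature_width}",
            f"k_extract:                    {self.config.k_extract or s.k_extract or 'all'}",
            f"learning rate / batch:        {self.config.learning_rate} / {self.config.batch_size}",
            f"ensemble members:             {len(self.members)}",
            f"epochs run (first member):    {len(self.history['train_loss'])}",
            f"best epoch / val loss:        {self.history['best_epoch']} / "
            f"{self.history['best_val_loss']:.4f}",
            f"target mean / sd (map units): {self.weights.target_mean:.3f} / "
            f"{self.weights.target_sd:.3f}",
            f"distance scale (map units):   {self.weights.distance_scale:.3f}",
        ]
        return "\n".join(lines)

    def plot_history(self, path=None):
        """Loss curves; written to ``path`` if given (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(self.history["train_loss"], label="train")
        ax.plot(self.history["val_loss"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE (normalized σ)")
        ax.legend(frameon=False)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig
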