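"""Multi-scale kernel Transformer with a Gaussian-process parameterization head.

The architecture maps a standardized clinical sequence (T x d) through

  1. an affine embedding to d' dimensions,
  2. a bank of kernel Gram matrices (linear / polynomial / RBF / Matern)
     over the embedded time steps, stacked to N x T x T,
  3. a per-time-step flattening of the N kernel similarity profiles,
     projected to the encoder width d'' with sinusoidal position codes,
  4. a stack of Transformer encoder blocks (multi-head self-attention,
     feed-forward, residual + layer norm),
  5. output heads: a scalar point prediction and a Gaussian-process head
     producing the predictive mean path M(t) (ml) and, through a softplus
     link with a 1e-6 floor, the strictly positive variance path Sigma(t).

Training minimizes the negative log-likelihood -sum log(L + delta) of
observed volumes under N(M(t), Sigma(t)), with an optional point-prediction
term, by minibatch gradient descent (plain SGD by default; momentum and
Adam behind config flags), early stopping on validation NLL, and optional
k-fold cross-validation. Everything is reproducible under a seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import KFold

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .crossing import (
    CrossingResult,
    TimeGrid,
    VolumeProcess,
    crossing_probability,
    expansion_threshold,
)
from .kernels import (
    KernelSpec,
    KernelStack,
    default_kernel_specs,
    kernel_gram,
    median_lengthscale,
    stack_kernels,
)

__all__ = [
    "SequenceBatch",
    "EncoderConfig",
    "TrainingConfig",
    "GPPrediction",
    "MSKTModel",
    "embed",
    "kernels_to_sequence",
    "negative_log_likelihood",
    "train",
    "cross_validate",
    "predict_expansion_probability",
    "save_checkpoint",
    "load_checkpoint",
    "TrainingDivergence",
]

VARIANCE_FLOOR = 1e-6


class TrainingDivergence(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceBatch:
    """One patient's standardized feature sequence plus baseline volume."""

    features: np.ndarray  # (T, d)
    timestamps: np.ndarray  # (T,) hours
    patient_id: object
    baseline_volume: float

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=float)
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "timestamps", ts)
        if feats.ndim != 2 or feats.shape[0] < 2:
            raise ValueError("features must be T x d with T >= 2")
        if not np.all(np.isfinite(feats)):
            raise ValueError("features must be finite (preprocessing contract)")
        if ts.shape != (feats.shape[0],):
            raise ValueError("timestamps must have length T")


@dataclass(frozen=True)
class EncoderConfig:
    n_heads: int = 4
    key_dim: int = 16
    model_dim: int = 64
    ffn_dim: int = 128
    n_layers: int = 2
    dropout: float = 0.1

    def __post_init__(self):
        if min(self.n_heads, self.key_dim, self.model_dim, self.ffn_dim, self.n_layers) < 1:
            raise ValueError("all encoder dimensions must be >= 1")
        if self.model_dim % self.n_heads != 0:
            raise ValueError("model_dim must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.05
    stability_const: float = 1e-6  # delta added to the likelihood inside the log
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    n_folds: int = 0  # 0 disables cross-validation
    seed: int = 0
    optimizer: str = "sgd"  # 'sgd' | 'momentum' | 'adam'
    momentum: float = 0.9
    point_loss_weight: float = 0.1
    val_fraction: float = 0.15  # used when no explicit validation set is given
    lr_decay: float = 0.5  # multiply the learning rate on validation plateau
    lr_patience: int = 20  # plateau length (epochs) triggering a decay
    min_lr: float = 1e-5
    warmup_epochs: int = 0  # epochs of fixed-unit-variance (squared-error) fitting

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.stability_const < 0:
            raise ValueError("stability_const must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.n_folds and self.n_folds < 2:
            raise ValueError("n_folds must be >= 2 when cross-validation is enabled")
        if self.optimizer not in ("sgd", "momentum", "adam"):
            raise ValueError("optimizer must be 'sgd', 'momentum' or 'adam'")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")


@dataclass(frozen=True)
class GPPrediction:
    """Per-time-step predictive Gaussian plus the scalar point prediction."""

    mean_path: np.ndarray  # (T,) ml
    variance_path: np.ndarray  # (T,) ml^2, strictly positive
    point_prediction: float = np.nan

    def __post_init__(self):
        if self.mean_path.shape != self.variance_path.shape:
            raise ValueError("mean and variance paths must have equal length")
        if np.any(self.variance_path <= 0):
            raise ValueError("variance path must be strictly positive")


# -- free-standing operations ---------------------------------------------

def embed(features: np.ndarray, out_dim: int, seed: int) -> np.ndarray:
    """Seeded affine per-time-step map of a T x d sequence to T x d'."""
    feats = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(feats)):
        raise ValueError("features must be finite")
    rng = np.random.default_rng(seed)
    W = nn.glorot(rng, feats.shape[-1], out_dim)
    return feats @ W


def kernels_to_sequence(
    stack: KernelStack,
    model_dim: int,
    projection: Optional[np.ndarray] = None,
    positional: bool = True,
) -> np.ndarray:
    """Turn an N x T x T kernel stack into a T x d'' sequence.

    For each time step t the N kernel rows indexed by t (the multi-scale
    similarity profiles of that step) are concatenated into a length-N*T
    vector and projected to ``model_dim``; sinusoidal position codes are
    added unless disabled. With ``projection=None`` an identity-truncation
    (or zero-padded identity) matrix is used.
    """
    if model_dim <= 0:
        raise ValueError("model_dim must be positive")
    arr = stack.stacked  # (N, T, T)
    N, T, _ = arr.shape
    per_step = arr.transpose(1, 0, 2).reshape(T, N * T)
    if projection is None:
        projection = np.eye(N * T, model_dim)
    out = per_step @ projection
    if positional:
        out = out + nn.positional_encoding(T, model_dim)
    return out


def negative_log_likelihood(
    observations: Sequence[tuple],
    prediction: GPPrediction,
    delta: float = 1e-6,
    timestamps: Optional[np.ndarray] = None,
) -> float:
    """-sum_k log(L_k + delta) with L_k the Gaussian density of the observed
    volume under the predicted N(M(t_k), Sigma(t_k)).

    ``observations`` is a sequence of (time, volume) pairs; each time must
    match a grid timestamp (the prediction index when ``timestamps`` is
    omitted). ``delta > 0`` keeps the loss finite when the density
    underflows.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    T = prediction.mean_path.shape[0]
    if timestamps is None:
        timestamps = np.arange(T, dtype=float)
    total = 0.0
    for t, v in observations:
        idx = np.flatnonzero(np.isclose(timestamps, t))
        if idx.size == 0:
            raise AlignmentError(f"observation time {t} is not on the prediction grid")
        i = int(idx[0])
        dens = norm.pdf(v, loc=prediction.mean_path[i], scale=np.sqrt(prediction.variance_path[i]))
        total -= np.log(dens + delta)
    return float(total)


# -- model -----------------------------------------------------------------

class MSKTModel(nn.Module):
    """Multi-scale kernel Transformer over fixed-length hourly sequences.

    Parameters
    ----------
    n_features:
        Input width d of the standardized feature sequence.
    seq_len:
        Number of hourly steps T; the kernel-profile flattening ties the
        projection weights to this length.
    embed_dim:
        Embedding width d'.
    encoder:
        Transformer encoder configuration.
    kernel_specs:
        The kernel bank (defaults to linear / polynomial / RBF / Matern 1.5).
    separate_trunks:
        When True the variance head gets its own encoder trunk (the
        two-network reading of the personalized mean/variance mappings);
        default is one shared trunk with two output heads.
    """

    def __init__(
        self,
        n_features: int,
        seq_len: int,
        embed_dim: int = 32,
        encoder: EncoderConfig = EncoderConfig(),
        kernel_specs: Optional[List[KernelSpec]] = None,
        seed: int = 0,
        use_positional: bool = True,
        separate_trunks: bool = False,
    ):
        super().__init__()
        self.n_features = n_features
        self.seq_len = seq_len
        self.embed_dim = embed_dim
        self.encoder_config = encoder
        self.kernel_specs = kernel_specs if kernel_specs is not None else default_kernel_specs()
        self.seed = seed
        self.use_positional = use_positional
        self.separate_trunks = separate_trunks
        self.rng = np.random.default_rng(seed)
        rng = self.rng

        N = len(self.kernel_specs)
        d2 = encoder.model_dim
        self.embedding = nn.Linear(n_features, embed_dim, rng)
        # nonzero embedding bias: every kernel in the bank is even under a
        # global sign flip of centred embeddings, so a zero bias would make
        # linear (odd) feature effects unidentifiable from the Gram entries
        self.embedding.b.data = rng.normal(0.0, 1.0, size=embed_dim)
        # the per-step vector fuses the N kernel similarity profiles with the
        # embedded step itself (skip path): similarity profiles alone cannot
        # express general per-step linear effects
        self.seq_proj = nn.Linear(N * seq_len + embed_dim, d2, rng)
        self.blocks = [
            nn.EncoderBlock(d2, encoder.n_heads, encoder.key_dim,
                            encoder.ffn_dim, encoder.dropout, rng)
            for _ in range(encoder.n_layers)
        ]
        if separate_trunks:
            self.var_blocks = [
                nn.EncoderBlock(d2, encoder.n_heads, encoder.key_dim,
                                encoder.ffn_dim, encoder.dropout, rng)
                for _ in range(encoder.n_layers)
            ]
        else:
            self.var_blocks = []
        self.mean_head = nn.Linear(d2, 1, rng)
        self.var_head = nn.Linear(d2, 1, rng)
        self.point_head = nn.Linear(d2, 1, rng)
        self._pos = nn.positional_encoding(seq_len, d2)
        self.lengthscales: List[Optional[float]] = [None] * N
        # per-kernel scalar scales fitted on the training embedding; kernel
        # families live on very different numeric ranges and the projection
        # needs them commensurate (a constant rescaling keeps all structure)
        self.kernel_scales: Optional[List[float]] = None
        # target normalization fitted from training volumes
        self.y_loc = 0.0
        self.y_scale = 1.0

    # -- configuration ----------------------------------------------------
    def fit_lengthscales(self, X: np.ndarray) -> List[Optional[float]]:
        """Resolve unset RBF/Matern lengthscales by the median pairwise
        distance of the training embedding (the standard heuristic)."""
        emb = self.embed(np.asarray(X, dtype=float))
        ell = median_lengthscale(emb)
        self.lengthscales = [
            spec.lengthscale if spec.lengthscale is not None
            else (ell if spec.family in ("rbf", "matern") else None)
            for spec in self.kernel_specs
        ]
        sample = Tensor(emb[:64] if emb.ndim == 3 else emb)
        self.kernel_scales = []
        for spec, l in zip(self.kernel_specs, self.lengthscales):
            sd = float(kernel_gram(sample, spec, l).data.std())
            self.kernel_scales.append(1.0 / sd if sd > 0 else 1.0)
        return self.lengthscales

    def set_target_scaling(self, volumes: np.ndarray) -> None:
        vals = np.asarray(volumes, dtype=float)
        vals = vals[np.isfinite(vals)]
        self.y_loc = float(vals.mean()) if vals.size else 0.0
        self.y_scale = float(vals.std()) if vals.size and vals.std() > 0 else 1.0

    # -- forward ----------------------------------------------------------
    def embed(self, X: np.ndarray) -> np.ndarray:
        """Per-time-step affine embedding, (..., T, d) -> (..., T, d')."""
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("model input must be finite")
        return self._embed_tensor(Tensor(X)).data

    def _embed_tensor(self, X: Tensor) -> Tensor:
        return self.embedding(X)

    def stack_kernels(self, embedded: np.ndarray) -> KernelStack:
        """Kernel bank over one embedded sequence (NumPy front-end)."""
        return stack_kernels(embedded, self.kernel_specs, self.lengthscales)

    def _encode(self, X: Tensor, blocks) -> Tensor:
        B, T, _ = X.shape
        emb = self._embed_tensor(X)
        scales = self.kernel_scales or [1.0] * len(self.kernel_specs)
        mats = [
            kernel_gram(emb, spec, ell) * sc
            for spec, ell, sc in zip(self.kernel_specs, self.lengthscales, scales)
        ]
        # per step t: rows of every kernel matrix, then the embedded step
        profiles = nn.concat(mats + [emb], axis=-1)
        z = self.seq_proj(profiles)
        if self.use_positional:
            z = z + Tensor(self._pos)
        e = z
        for block in blocks:
            e = block(e)
        return e

    def forward(self, X: np.ndarray) -> Dict[str, Tensor]:
        """Full forward pass on a batch (B, T, d) of sequences."""
        Xt = Tensor(np.asarray(X, dtype=float))
        if Xt.ndim == 2:
            Xt = Tensor(Xt.data[None])
        e = self._encode(Xt, self.blocks)
        e_var = self._encode(Xt, self.var_blocks) if self.separate_trunks else e
        B, T, _ = e.shape
        mean_n = self.mean_head(e).reshape((B, T))
        raw_var = self.var_head(e_var).reshape((B, T))
        var_n = ad.softplus(raw_var) + VARIANCE_FLOOR
        point_n = self.point_head(ad.tmean(e, axis=1)).reshape((B,))
        mean = mean_n * self.y_scale + self.y_loc
        var = var_n * (self.y_scale**2)
        point = point_n * self.y_scale + self.y_loc
        return {"mean": mean, "variance": var, "point": point, "encoded": e}

    def predict_head(self, encoded: Tensor | np.ndarray) -> np.ndarray:
        """Point-prediction head on an encoded sequence (B, T, d'')."""
        e = encoded if isinstance(encoded, Tensor) else Tensor(np.asarray(encoded, float))
        out = self.point_head(ad.tmean(e, axis=1))
        return (out.data * self.y_scale + self.y_loc).reshape(-1)

    def map_to_gp(self, encoded: Tensor | np.ndarray) -> GPPrediction:
        """GP parameterization head: mean path and softplus-floored variance."""
        e = encoded if isinstance(encoded, Tensor) else Tensor(np.asarray(encoded, float))
        if e.ndim == 2:
            e = Tensor(e.data[None])
        mean = self.mean_head(e).data[..., 0] * self.y_scale + self.y_loc
        var = (np.logaddexp(0.0, self.var_head(e).data[..., 0]) + VARIANCE_FLOOR) * self.y_scale**2
        point = self.predict_head(e)
        return GPPrediction(mean[0], var[0], float(point[0]))

    def predict(self, X: np.ndarray) -> List[GPPrediction]:
        """Eval-mode GP predictions for a batch of sequences."""
        self.set_training(False)
        out = self.forward(X)
        means, variances, points = out["mean"].data, out["variance"].data, out["point"].data
        return [
            GPPrediction(means[i], variances[i], float(points[i]))
            for i in range(means.shape[0])
        ]


# -- training ---------------------------------------------------------------

def _nll_loss(out: Dict[str, Tensor], volumes: np.ndarray, delta: float,
              point_weight: float, fixed_variance: bool = False) -> tuple[Tensor, float]:
    """Masked mean of -log(L + delta) plus the point-prediction term.

    ``volumes`` is (B, T) with NaN marking unobserved grid points; the point
    target is each patient's last observed volume. ``fixed_variance`` freezes
    the likelihood at unit variance (a squared-error warm-up objective) so
    that an early inflated variance head cannot stall the mean fit.
    """
    mask = np.isfinite(volumes)
    if not mask.any():
        raise ValueError("no observed volumes in batch")
    v = np.where(mask, volumes, 0.0)
    w = mask.astype(float)
    mean, var = out["mean"], out["variance"]
    resid = Tensor(v) - mean
    if fixed_variance:
        unit = Tensor(np.ones_like(v))
        log_dens = -0.5 * np.log(2 * np.pi) - (resid * resid) / 2.0
        var = unit
    else:
        log_dens = (
            -0.5 * np.log(2 * np.pi)
            - 0.5 * ad.log(var)
            - (resid * resid) / (2.0 * var)
        )
    if delta > 0:
        nll_terms = -ad.log(ad.exp(log_dens) + delta)
    else:
        nll_terms = -log_dens
    nll = ad.tsum(nll_terms * Tensor(w)) * (1.0 / w.sum())
    loss = nll
    if point_weight > 0:
        last_idx = mask.shape[1] - 1 - np.argmax(mask[:, ::-1], axis=1)
        target = volumes[np.arange(mask.shape[0]), last_idx]
        perr = out["point"] - Tensor(target)
        loss = loss + point_weight * ad.tmean(perr * perr)
    return loss, float(nll.data)


class _Optimizer:
    def __init__(self, params, config: TrainingConfig):
        self.params = params
        self.cfg = config
        self.lr = config.learning_rate
        self.state = [
            {"m": np.zeros_like(p.data), "v": np.zeros_like(p.data)} for p in params
        ]
        self.t = 0

    def decay(self):
        self.lr = max(self.lr * self.cfg.lr_decay, self.cfg.min_lr)

    def step(self):
        cfg = self.cfg
        self.t += 1
        for p, st in zip(self.params, self.state):
            if p.grad is None:
                continue
            g = p.grad
            if cfg.optimizer == "sgd":
                p.data = p.data - self.lr * g
            elif cfg.optimizer == "momentum":
                st["m"] = cfg.momentum * st["m"] + g
                p.data = p.data - self.lr * st["m"]
            else:  # adam
                b1, b2, eps = 0.9, 0.999, 1e-8
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = b2 * st["v"] + (1 - b2) * g**2
                mhat = st["m"] / (1 - b1**self.t)
                vhat = st["v"] / (1 - b2**self.t)
                p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _evaluate_nll(model: MSKTModel, X, volumes, delta, point_weight, batch_size=256):
    model.set_training(False)
    total, n = 0.0, 0
    for start in range(0, X.shape[0], batch_size):
        xb = X[start : start + batch_size]
        vb = volumes[start : start + batch_size]
        out = model.forward(xb)
        _, nll = _nll_loss(out, vb, delta, 0.0)
        k = np.isfinite(vb).sum()
        total += nll * k
        n += k
    return total / max(n, 1)


def train(
    model: MSKTModel,
    X: np.ndarray,
    volumes: np.ndarray,
    config: TrainingConfig,
    X_val: Optional[np.ndarray] = None,
    volumes_val: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Fit the model by minibatch gradient descent on the NLL.

    ``X`` is (n, T, d) and ``volumes`` (n, T) with NaN for unobserved points.
    When no validation arrays are given, a seeded ``val_fraction`` of the
    patients is held out. Stops early after ``patience`` epochs without
    validation improvement and restores the best weights. Returns the
    per-epoch history.
    """
    rng = np.random.default_rng(config.seed)
    drop_rng = np.random.default_rng(config.seed + 1)  # shared dropout stream
    for mod in model.modules():
        if isinstance(mod, nn.Dropout):
            mod.rng = drop_rng
    X = np.asarray(X, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if X_val is None:
        n = X.shape[0]
        n_val = max(1, int(round(n * config.val_fraction))) if n > 4 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_val, volumes_val = X[val_idx], volumes[val_idx]
        X, volumes = X[tr_idx], volumes[tr_idx]

    if model.kernel_scales is None or any(
        ell is None and spec.family in ("rbf", "matern")
        for spec, ell in zip(model.kernel_specs, model.lengthscales)
    ):
        model.fit_lengthscales(X)
    model.set_target_scaling(volumes)

    params = model.parameters()
    opt = _Optimizer(params, config)
    history = []
    best_val = np.inf
    best_state = model.state_dict()
    stale = 0
    n = X.shape[0]
    have_val = X_val is not None and X_val.shape[0] > 0

    for epoch in range(config.max_epochs):
        model.set_training(True)
        order = rng.permutation(n)
        epoch_nll = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            out = model.forward(X[idx])
            loss, nll = _nll_loss(
                out, volumes[idx], config.stability_const, config.point_loss_weight,
                fixed_variance=epoch < config.warmup_epochs,
            )
            if not np.isfinite(loss.data):
                raise TrainingDivergence(epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_nll.append(nll)
        row = {"epoch": epoch, "train_nll": float(np.mean(epoch_nll))}
        if have_val and epoch >= config.warmup_epochs:
            val_nll = _evaluate_nll(
                model, X_val, volumes_val, config.stability_const, 0.0
            )
            row["val_nll"] = val_nll
            if val_nll < best_val - 1e-9:
                best_val = val_nll
                best_state = model.state_dict()
                stale = 0
            else:
                stale += 1
                if config.lr_decay < 1.0 and stale and stale % config.lr_patience == 0:
                    opt.decay()
        row["lr"] = opt.lr if have_val else config.learning_rate
        history.append(row)
        if have_val and epoch >= config.warmup_epochs and stale > config.patience:
            break
    if have_val:
        model.load_state_dict(best_state)
    model.set_training(False)
    return pd.DataFrame(history)


def cross_validate(
    model_factory,
    X: np.ndarray,
    volumes: np.ndarray,
    config: TrainingConfig,
) -> pd.DataFrame:
    """k-fold cross-validation; returns one row of metrics per fold."""
    if config.n_folds < 2:
        raise ValueError("config.n_folds must be >= 2 for cross-validation")
    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    rows = []
    for fold, (tr, va) in enumerate(kf.split(X)):
        model = model_factory()
        hist = train(model, X[tr], volumes[tr], config, X[va], volumes[va])
        rows.append(
            {
                "fold": fold,
                "n_train": tr.size,
                "n_val": va.size,
                "epochs": len(hist),
                "val_nll": float(hist["val_nll"].min()),
            }
        )
    return pd.DataFrame(rows)


def predict_expansion_probability(
    model: MSKTModel,
    batch: SequenceBatch,
    horizon: Optional[float] = None,
) -> tuple[GPPrediction, CrossingResult]:
    """Compose the GP head with the crossing framework for one patient.

    The predicted mean/variance paths define the volume process on the
    batch's hourly grid; the baseline volume sets the expansion threshold;
    the Poisson crossing approximation turns both into P_j.
    """
    model.set_training(False)
    pred = model.predict(batch.features[None])[0]
    T = batch.features.shape[0]
    if horizon is None:
        step = float(np.median(np.diff(batch.timestamps))) if T > 1 else 1.0
        horizon = step * T
    grid = TimeGrid(float(batch.timestamps[0]), horizon, T)
    process = VolumeProcess(grid, pred.mean_path, pred.variance_path)
    threshold = expansion_threshold(batch.baseline_volume)
    return pred, crossing_probability(process, threshold)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: MSKTModel, path: str | Path) -> None:
    """Single-archive checkpoint: config, seed and weights."""
    config = {
        "n_features": model.n_features,
        "seq_len": model.seq_len,
        "embed_dim": model.embed_dim,
        "encoder": asdict(model.encoder_config),
        "kernel_specs": [asdict(s) for s in model.kernel_specs],
        "seed": model.seed,
        "use_positional": model.use_positional,
        "separate_trunks": model.separate_trunks,
        "lengthscales": model.lengthscales,
        "kernel_scales": model.kernel_scales,
        "y_loc": model.y_loc,
        "y_scale": model.y_scale,
    }
    buf = io.BytesIO()
    np.savez(buf, **{k: v for k, v in model.state_dict().items()})
    Path(path).write_bytes(
        json.dumps(config).encode() + b"\n---WEIGHTS---\n" + buf.getvalue()
    )


def load_checkpoint(path: str | Path) -> MSKTModel:
    raw = Path(path).read_bytes()
    head, blob = raw.split(b"\n---WEIGHTS---\n", 1)
    config = json.loads(head.decode())
    model = MSKTModel(
        n_features=config["n_features"],
        seq_len=config["seq_len"],
        embed_dim=config["embed_dim"],
        encoder=EncoderConfig(**config["encoder"]),
        kernel_specs=[KernelSpec(**s) for s in config["kernel_specs"]],
        seed=config["seed"],
        use_positional=config["use_positional"],
        separate_trunks=config["separate_trunks"],
    )
    model.lengthscales = config["lengthscales"]
    model.kernel_scales = config.get("kernel_scales")
    model.y_loc = config["y_loc"]
    model.y_scale = config["y_scale"]
    with np.load(io.BytesIO(blob)) as weights:
        model.load_state_dict({k: weights[k] for k in weights.files})
    return model
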