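"""Multi-scale kernel layer: Gram matrices over time-step embeddings.

Each kernel measures similarity between the rows of an embedded sequence
(T x d'), producing a T x T Gram matrix. A bank of kernels at different
scales — linear, polynomial, RBF, Matern — exposes linear structure,
polynomial dependencies, smooth short-range fluctuation and rougher local
variation side by side; the stack is the input representation for the
Transformer encoder.

All computations are expressed with autodiff tensors so that gradients flow
back into the embedding; thin NumPy wrappers are provided for direct use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

FAMILIES = ("linear", "polynomial", "rbf", "matern")
MATERN_SMOOTHNESS = (0.5, 1.5, 2.5)


class KernelConfigError(ValueError):
    pass


@dataclass(frozen=True)
class KernelSpec:
    """Configuration of one kernel in the multi-scale bank.

    ``lengthscale=None`` (rbf/matern) means "resolve by the median pairwise
    distance heuristic on the training embedding" at model fit time.
    """

    family: str
    degree: int = 2
    offset: float = 1.0
    lengthscale: float | None = None
    smoothness: float = 1.5

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise KernelConfigError(
                f"unknown kernel family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family == "polynomial":
            if int(self.degree) != self.degree or self.degree < 1:
                raise KernelConfigError("polynomial degree must be an integer >= 1")
            if self.offset < 0:
                raise KernelConfigError("polynomial offset must be >= 0")
        if self.family in ("rbf", "matern"):
            if self.lengthscale is not None and not self.lengthscale > 0:
                raise KernelConfigError("lengthscale must be > 0")
        if self.family == "matern" and self.smoothness not in MATERN_SMOOTHNESS:
            raise KernelConfigError(
                f"matern smoothness must be one of {MATERN_SMOOTHNESS}"
            )


def default_kernel_specs() -> list[KernelSpec]:
    """Default bank: linear, polynomial(degree 2), RBF, Matern(nu=1.5)."""
    return [
        KernelSpec("linear"),
        KernelSpec("polynomial", degree=2, offset=1.0),
        KernelSpec("rbf"),
        KernelSpec("matern", smoothness=1.5),
    ]


@dataclass(frozen=True)
class KernelStack:
    """N Gram matrices of shape T x T, stacked to (N, T, T) in spec order."""

    matrices: tuple
    stacked: np.ndarray


def _pairwise_sqdist(x: Tensor) -> Tensor:
    """Squared Euclidean distances between trailing-axis rows, (..., T, T)."""
    sq = ad.tsum(x * x, axis=-1, keepdims=True)  # (..., T, 1)
    cross = x @ ad.swapaxes(x, -1, -2)
    r2 = sq + ad.swapaxes(sq, -1, -2) - 2.0 * cross
    return ad.relu(r2)  # clip tiny negative round-off


def kernel_gram(x: Tensor, spec: KernelSpec, lengthscale: float | None = None) -> Tensor:
    """Gram matrix of ``spec`` over the rows of ``x`` (batched, differentiable)."""
    if spec.family == "linear":
        return x @ ad.swapaxes(x, -1, -2)
    if spec.family == "polynomial":
        base = x @ ad.swapaxes(x, -1, -2) + spec.offset
        out = base
        for _ in range(int(spec.degree) - 1):
            out = out * base
        return out
    ell = spec.lengthscale if spec.lengthscale is not None else lengthscale
    if ell is None or not ell > 0:
        raise KernelConfigError(
            f"{spec.family} kernel needs a positive lengthscale (got {ell!r})"
        )
    r2 = _pairwise_sqdist(x)
    if spec.family == "rbf":
        return ad.exp(r2 * (-0.5 / ell**2))
    # Matern; the 1e-18 jitter keeps sqrt differentiable at zero distance.
    r = ad.sqrt(r2 + 1e-18)
    if spec.smoothness == 0.5:
        return ad.exp(r * (-1.0 / ell))
    if spec.smoothness == 1.5:
        s = r * (np.sqrt(3.0) / ell)
        return (1.0 + s) * ad.exp(-s)
    s = r * (np.sqrt(5.0) / ell)
    return (1.0 + s + s * s * (1.0 / 3.0)) * ad.exp(-s)


def compute_kernel(
    embedded: np.ndarray, spec: KernelSpec, lengthscale: float | None = None
) -> np.ndarray:
    """NumPy front-end: Gram matrix (T x T) of ``spec`` over a T x d' embedding."""
    embedded = np.asarray(embedded, dtype=float)
    if embedded.ndim != 2:
        raise ValueError("embedded must be a T x d' matrix")
    return kernel_gram(Tensor(embedded), spec, lengthscale).data


def stack_kernels(
    embedded: np.ndarray,
    specs: Sequence[KernelSpec],
    lengthscales: Sequence[float | None] | None = None,
) -> KernelStack:
    """Evaluate every kernel in ``specs`` and stack to (N, T, T), order kept."""
    if len(specs) == 0:
        raise KernelConfigError("at least one kernel spec is required")
    if lengthscales is None:
        lengthscales = [None] * len(specs)
    mats = tuple(
        compute_kernel(embedded, spec, ell) for spec, ell in zip(specs, lengthscales)
    )
    return KernelStack(mats, np.stack(mats, axis=0))


def median_lengthscale(embedded: np.ndarray) -> float:
    """Median pairwise Euclidean distance between rows (pooled over batches).

    The standard heuristic for RBF/Matern lengthscales; zero distances are
    excluded, and a degenerate all-equal embedding falls back to 1.0.
    """
    x = np.asarray(embedded, dtype=float)
    if x.ndim == 2:
        x = x[None]
    rows = x.reshape(-1, x.shape[-1])
    if rows.shape[0] > 2000:  # subsample for cost; deterministic stride
        rows = rows[:: rows.shape[0] // 2000 + 1]
    sq = np.sum(rows**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * rows @ rows.T
    d = np.sqrt(np.clip(d2, 0, None))
    vals = d[np.triu_indices_from(d, k=1)]
    vals = vals[vals > 0]
    return float(np.median(vals)) if vals.size else 1.0
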