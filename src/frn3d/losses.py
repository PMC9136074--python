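"""Training objective: binary cross-entropy plus a down-weighted inter-class
orthogonality penalty on the support pools.

The auxiliary term normalises every support feature row onto the unit sphere
and sums, over all ordered pairs of distinct classes, the squared Frobenius
norm of the cross-class Gram matrix ‖Ŝ_i Ŝ_jᵀ‖²; it is zero exactly when
features of different classes are mutually orthogonal.  It enters the total
loss scaled by 0.03.
"""

from __future__ import annotations

import warnings

import numpy as np

from .autograd import Tensor, concatenate
from .frn import SupportPool

__all__ = [
    "AUX_WEIGHT",
    "cross_entropy",
    "aux_orthogonality_loss",
    "total_loss",
    "aux_orthogonality_loss_t",
    "nll_from_log_probs",
]

AUX_WEIGHT = 0.03
_EPS = 1e-12


def cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy, −(1/N)Σ[yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)].

    ``p`` holds class-1 probabilities and is clamped to [1e-12, 1−1e-12]
    before the logarithms so confident mistakes stay finite.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty input to cross_entropy")
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _normalized_rows(matrix: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1)
    keep = norms >= _EPS
    if not keep.all():
        warnings.warn(f"skipping {int((~keep).sum())} near-zero support rows "
                      "in the orthogonality loss", stacklevel=3)
    return matrix[keep] / norms[keep, None]


def aux_orthogonality_loss(pools: list[SupportPool | np.ndarray]) -> float:
    """Σ_{i≠j} ‖Ŝ_i Ŝ_jᵀ‖² over ordered class pairs, rows unit-normalised."""
    if len(pools) < 2:
        raise ValueError("orthogonality loss needs at least two classes")
    mats = [_normalized_rows(np.asarray(p.matrix if isinstance(p, SupportPool) else p,
                                        dtype=np.float64)) for p in pools]
    total = 0.0
    for i, si in enumerate(mats):
        for j, sj in enumerate(mats):
            if i != j:
                total += float(np.sum((si @ sj.T) ** 2))
    return total


def total_loss(ce: float, aux: float) -> float:
    """Cross-entropy plus the auxiliary term scaled by 0.03."""
    if not (np.isfinite(ce) and np.isfinite(aux)):
        raise ValueError("non-finite loss components")
    return float(ce + AUX_WEIGHT * aux)


# -- differentiable versions used by the training loop ------------------------

def aux_orthogonality_loss_t(pools: list[Tensor]) -> Tensor:
    """Tensor version of the orthogonality penalty (no row skipping: pools
    produced by the backbone are generically non-degenerate)."""
    normed = []
    for s in pools:
        norms = ((s * s).sum(axis=1, keepdims=True) + _EPS).sqrt()
        normed.append(s / norms)
    terms = []
    for i, si in enumerate(normed):
        for j, sj in enumerate(normed):
            if i != j:
                g = si @ sj.T
                terms.append((g * g).sum().reshape(1))
    return concatenate(terms).sum()


def nll_from_log_probs(log_probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of the true class, from (n, C) log-probs."""
    n = log_probs.shape[0]
    picked = log_probs[np.arange(n), np.asarray(labels, dtype=int)]
    return picked.sum() * (-1.0 / n)
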