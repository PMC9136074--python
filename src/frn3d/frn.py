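"""Feature-map reconstruction classification head.

A query volume's feature map Q (r×d) is classified by how well it can be
reconstructed as a weighted sum of support feature vectors of each class.
All feature-map rows of the k support images of class c are pooled into
S_c (kr×d); the optimal reconstruction weights solve a ridge regression

    W̄ = argmin_W ‖Q − W S_c‖² + λ‖W‖²  =  Q S_cᵀ (S_c S_cᵀ + λI)⁻¹

in closed form, the reconstruction is recalibrated as Q̄_c = ρ W̄ S_c, and the
class score is the mean squared reconstruction error ⟨Q, Q̄_c⟩ = ‖Q − Q̄_c‖²/r.
Class probabilities are a softmax over −γ⟨Q, Q̄_c⟩.  The three scalars are
learned in log-space: λ = (kr/d)·e^α, ρ = e^β, γ = e^g, with α = β = g = 0 at
initialisation.

Because Q enters the reconstruction linearly, each class reduces to a d×d
projection matrix; the solve uses whichever Gram matrix is smaller (kr×kr
when kr ≤ d, d×d otherwise — the two forms are algebraically identical by the
push-through identity) and always goes through a Cholesky factorisation,
never an explicit inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from . import nn
from .autograd import Tensor, concatenate, posdef_solve
from .backbone import FeatureMap

__all__ = [
    "SupportPool",
    "ReconHeadParams",
    "ReconResult",
    "pool_support",
    "ridge_weights",
    "reconstruct",
    "effective_lambda",
    "effective_rho",
    "class_probabilities",
    "classify",
    "FRNHead",
]


@dataclass
class SupportPool:
    """kr×d matrix pooling all feature-map rows of k images of one class."""

    matrix: np.ndarray
    class_id: int
    k: int
    r: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.k * self.r:
            raise ValueError(
                f"support pool must be (k*r)×d = {self.k * self.r}×d, got {self.matrix.shape}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("support pool contains non-finite values")

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ReconHeadParams:
    """The head's three scalars: λ = (kr/d)·e^alpha, ρ = e^beta, temperature gamma."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class ReconResult:
    reconstruction: np.ndarray  # r×d
    distance: float
    weights: np.ndarray | None = None  # r×kr, retained on request


def pool_support(maps: list[FeatureMap], class_id: int) -> SupportPool:
    """Concatenate the rows of k feature maps (input order preserved)."""
    if not maps:
        raise ValueError("cannot pool an empty list of feature maps")
    r, d = maps[0].r, maps[0].d
    for m in maps[1:]:
        if m.r != r or m.d != d:
            raise ValueError(f"all feature maps must share r={r}, d={d}; got {m.r}×{m.d}")
    matrix = np.concatenate([m.values for m in maps], axis=0)
    return SupportPool(matrix=matrix, class_id=class_id, k=len(maps), r=r)


def ridge_weights(q: np.ndarray, s: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge regression weights W̄ = Q Sᵀ (S Sᵀ + λI)⁻¹.

    Minimises ‖Q − W S‖² + λ‖W‖²; computed by a Cholesky solve of the kr×kr
    system, never by forming the inverse.
    """
    q = np.asarray(q, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if lam <= 0:
        raise ValueError("ridge penalty lam must be positive")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(s))):
        raise ValueError("non-finite inputs to ridge_weights")
    a = s @ s.T + lam * np.eye(s.shape[0])
    factor = cho_factor(a, lower=True, check_finite=False)
    # (S Sᵀ + λI)⁻¹ S Qᵀ, transposed
    return cho_solve(factor, s @ q.T, check_finite=False).T


def effective_lambda(params: ReconHeadParams, k: int, r: int, d: int) -> float:
    """λ = (kr/d)·e^alpha."""
    if min(k, r, d) < 1:
        raise ValueError("k, r, d must all be >= 1")
    return (k * r / d) * math.exp(params.alpha)


def effective_rho(params: ReconHeadParams) -> float:
    """ρ = e^beta."""
    return math.exp(params.beta)


def _projection_matrix(s: np.ndarray, lam: float) -> np.ndarray:
    """d×d matrix P with Q̄ = ρ·Q·P; kr×kr or d×d solve, whichever is smaller."""
    kr, d = s.shape
    if kr <= d:
        a = s @ s.T + lam * np.eye(kr)
        factor = cho_factor(a, lower=True, check_finite=False)
        return s.T @ cho_solve(factor, s, check_finite=False)
    g = s.T @ s
    factor = cho_factor(g + lam * np.eye(d), lower=True, check_finite=False)
    return cho_solve(factor, g, check_finite=False)


def reconstruct(q: FeatureMap | np.ndarray, pool: SupportPool,
                params: ReconHeadParams, *, retain_weights: bool = False) -> ReconResult:
    """Reconstruct a query map from one class pool; returns Q̄_c and the
    deflated squared error (1/r)·‖Q − Q̄_c‖²."""
    qm = q.values if isinstance(q, FeatureMap) else np.asarray(q, dtype=np.float64)
    r, d = qm.shape
    lam = effective_lambda(params, pool.k, pool.r, d)
    rho = effective_rho(params)
    qbar = rho * (qm @ _projection_matrix(pool.matrix, lam))
    distance = float(np.sum((qm - qbar) ** 2) / r)
    weights = None
    if retain_weights:
        weights = ridge_weights(qm, pool.matrix, lam)
    return ReconResult(reconstruction=qbar, distance=distance, weights=weights)


def class_probabilities(distances, gamma: float) -> np.ndarray:
    """Softmax over −γ·distance (max-subtracted for overflow safety)."""
    d = np.asarray(distances, dtype=np.float64)
    if d.size < 2:
        raise ValueError("need at least two classes")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    z = -gamma * d
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def classify(q: FeatureMap | np.ndarray, pools: list[SupportPool],
             params: ReconHeadParams) -> tuple[int, np.ndarray, np.ndarray]:
    """Predict the class whose pool reconstructs the query best.

    Returns (predicted class index, probabilities, distances).  Ties go to
    the lower class index (argmin takes the first minimum), which is also
    the argmax of the probabilities.
    """
    if len(pools) < 2:
        raise ValueError("need at least two class pools")
    d0 = pools[0].d
    qm = q.values if isinstance(q, FeatureMap) else np.asarray(q)
    if qm.shape[1] != d0 or any(p.d != d0 for p in pools):
        raise ValueError("query and all pools must share the channel dimension d")
    distances = np.array([reconstruct(q, p, params).distance for p in pools])
    probs = class_probabilities(distances, params.gamma)
    return int(np.argmin(distances)), probs, distances


class FRNHead(nn.Module):
    """Differentiable head: α, β and g (γ = e^g) are trainable scalars,
    all initialised to zero so that λ = kr/d, ρ = 1, γ = 1 at the start."""

    def __init__(self):
        super().__init__()
        self.alpha = nn.Parameter(0.0)
        self.beta = nn.Parameter(0.0)
        self.log_gamma = nn.Parameter(0.0)

    def params(self) -> ReconHeadParams:
        return ReconHeadParams(alpha=float(self.alpha.data),
                               beta=float(self.beta.data),
                               gamma=float(np.exp(self.log_gamma.data)))

    def _projection(self, s: Tensor, k: int, r: int) -> Tensor:
        kr, d = s.shape
        lam = (k * r / d) * self.alpha.exp()
        if kr <= d:
            a = Tensor(np.eye(kr)) * lam + s @ s.T
            return s.T @ posdef_solve(a, s)
        g = s.T @ s
        return posdef_solve(Tensor(np.eye(d)) * lam + g, g)

    def distances(self, queries: Tensor, r: int, pools: list[tuple[Tensor, int]]) -> Tensor:
        """Per-query, per-class deflated reconstruction errors.

        ``queries`` stacks n_q feature maps as an (n_q·r)×d matrix; each pool
        is (kr×d tensor, k).  Returns an (n_q, C) tensor.
        """
        nq = queries.shape[0] // r
        rho = self.beta.exp()
        cols = []
        for s, k in pools:
            qbar = (queries @ self._projection(s, k, r)) * rho
            diff = queries - qbar
            per_query = (diff * diff).reshape(nq, r, diff.shape[1]).sum(axis=(1, 2)) * (1.0 / r)
            cols.append(per_query.reshape(nq, 1))
        return concatenate(cols, axis=1)

    def log_probabilities(self, dist: Tensor) -> Tensor:
        """Row-wise log-softmax of −γ·distance (max-subtracted)."""
        z = dist * (-self.log_gamma.exp())
        z = z - Tensor(z.data.max(axis=1, keepdims=True))  # constant shift
        lse = z.exp().sum(axis=1, keepdims=True).log()
        return z - lse
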