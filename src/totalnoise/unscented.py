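"""Scaled unscented transform (UT) for propagating parameter distributions.

Given an L-dimensional Gaussian input N(theta_bar, Sigma), the scaled UT
places 2L+1 deterministic sigma points

    chi_0 = theta_bar
    chi_i = theta_bar + col_i( sqrt((L+lambda) Sigma) ),   i = 1..L
    chi_{i+L} = theta_bar - col_i( sqrt((L+lambda) Sigma) )

with lambda = alpha^2 (L + kappa) - L, mean weights W^m_0 = lambda/(L+lambda),
W^m_i = 1/(2(L+lambda)), and covariance weights identical except
W^c_0 = W^m_0 + (1 - alpha^2 + beta).  Pushing the points through a mapping g
and re-weighting reconstructs the output mean and covariance accurately to
second order in g's Taylor expansion — at the cost of exactly 2L+1 mapping
evaluations, linear in the number of extrinsic factors.

Defaults alpha = 1, beta = 2 (Gaussian-optimal), kappa = 3 - L (matches the
fourth moment of a Gaussian).  A log-normal mode builds the points in log
space from the moment-matched log-space Gaussian and exponentiates, which
guarantees strictly positive parameter values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "ParameterDistribution",
    "UTConfig",
    "SigmaPointSet",
    "sigma_points",
    "lognormal_sigma_points",
    "ut_propagate",
]


@dataclass
class ParameterDistribution:
    """Multivariate distribution over parameters / initial-condition symbols.

    ``mean`` and ``cov`` are always on the natural (linear) scale; with
    ``scale="lognormal"`` they are interpreted as the natural-scale mean and
    covariance of a log-normal vector (the log-space Gaussian is derived by
    moment matching).
    """

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    scale: str = "normal"

    def __post_init__(self):
        self.names = tuple(self.names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        L = len(self.names)
        if self.mean.shape != (L,) or self.cov.shape != (L, L):
            raise ValueError("mean/cov shapes inconsistent with names")
        if not np.allclose(self.cov, self.cov.T, rtol=1e-10, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        tr = max(np.trace(self.cov), 0.0)
        if np.any(linalg.eigvalsh(self.cov) < -1e-10 * max(tr, 1.0)):
            raise ValueError("covariance must be positive semidefinite")
        if self.scale not in ("normal", "lognormal"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def L(self) -> int:
        return len(self.names)

    @classmethod
    def from_cv(cls, names, mean, a: float, scale: str = "normal"):
        """Independent parameters with a common coefficient of variation."""
        from .extrinsic import diagonal_cov

        mean = np.asarray(mean, dtype=float)
        return cls(tuple(names), mean, diagonal_cov(mean, a), scale)


@dataclass
class UTConfig:
    """Spread/weighting constants of the scaled UT.

    ``kappa=None`` resolves to 3 - L at use, so L + lambda = 3 for alpha = 1.
    """

    alpha: float = 1.0
    beta: float = 2.0
    kappa: float | None = None

    def resolve(self, L: int) -> tuple[float, float, float, float]:
        kappa = (3.0 - L) if self.kappa is None else float(self.kappa)
        lam = self.alpha**2 * (L + kappa) - L
        if L + lam <= 0:
            raise ValueError(
                f"invalid UT config: L + lambda = {L + lam} must be positive"
            )
        return self.alpha, self.beta, kappa, lam


@dataclass
class SigmaPointSet:
    """2L+1 sigma points with their mean and covariance weights."""

    points: np.ndarray  # (2L+1, L)
    mean_weights: np.ndarray
    cov_weights: np.ndarray
    config: UTConfig = field(default_factory=UTConfig)

    @property
    def L(self) -> int:
        return self.points.shape[1]

    def __len__(self):
        return self.points.shape[0]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.points, columns=[f"x{i}" for i in range(self.L)])
        df.insert(0, "w_mean", self.mean_weights)
        df.insert(1, "w_cov", self.cov_weights)
        return df


def _sqrt_columns(M: np.ndarray) -> np.ndarray:
    """Symmetric PSD matrix square root (eigendecomposition).

    Unlike a Cholesky factor this square root is permutation-equivariant —
    reordering parameters reorders sigma-point coordinates without changing
    the point set — and it handles semidefinite input natively (negative
    round-off eigenvalues are clipped to zero).
    """
    w, V = linalg.eigh(M)
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ V.T


def _weights(L: int, lam: float, alpha: float, beta: float):
    wm = np.full(2 * L + 1, 1.0 / (2 * (L + lam)))
    wc = wm.copy()
    wm[0] = lam / (L + lam)
    wc[0] = lam / (L + lam) + (1 - alpha**2 + beta)
    return wm, wc


def sigma_points(
    dist: ParameterDistribution, config: UTConfig | None = None
) -> SigmaPointSet:
    """Deterministic sigma points of a normal-scale distribution.

    Warns when a point acquires a non-positive coordinate (kinetic rates are
    positive); the sanctioned remedy is ``scale="lognormal"`` via
    :func:`lognormal_sigma_points` — no silent clipping is performed.
    """
    if dist.scale != "normal":
        raise ValueError("sigma_points requires scale='normal'")
    config = config or UTConfig()
    L = dist.L
    alpha, beta, _, lam = config.resolve(L)
    root = _sqrt_columns((L + lam) * dist.cov)
    pts = np.empty((2 * L + 1, L))
    pts[0] = dist.mean
    for i in range(L):
        pts[1 + i] = dist.mean + root[:, i]
        pts[1 + L + i] = dist.mean - root[:, i]
    wm, wc = _weights(L, lam, alpha, beta)
    if np.any(dist.cov) and np.any(pts <= 0) and np.all(dist.mean > 0):
        warnings.warn(
            "sigma points contain non-positive coordinates for a positive-mean "
            "distribution; consider scale='lognormal'",
            stacklevel=2,
        )
    return SigmaPointSet(pts, wm, wc, config)


def lognormal_sigma_points(
    dist: ParameterDistribution, config: UTConfig | None = None
) -> SigmaPointSet:
    """Sigma points of a log-normal distribution, strictly positive.

    The natural-scale (mean, cov) are moment-matched to a log-space Gaussian
    (m, S) via S_ij = log(1 + cov_ij/(mean_i mean_j)), m_i = log(mean_i) -
    S_ii/2; points are built in log space and exponentiated componentwise.
    """
    if dist.scale != "lognormal":
        raise ValueError("lognormal_sigma_points requires scale='lognormal'")
    if np.any(dist.mean <= 0):
        raise ValueError("log-normal mode requires strictly positive means")
    config = config or UTConfig()
    L = dist.L
    alpha, beta, _, lam = config.resolve(L)
    S_log = np.log1p(dist.cov / np.outer(dist.mean, dist.mean))
    S_log = (S_log + S_log.T) / 2
    m = np.log(dist.mean) - 0.5 * np.diag(S_log)
    root = _sqrt_columns((L + lam) * S_log)
    pts = np.empty((2 * L + 1, L))
    pts[0] = m
    for i in range(L):
        pts[1 + i] = m + root[:, i]
        pts[1 + L + i] = m - root[:, i]
    wm, wc = _weights(L, lam, alpha, beta)
    return SigmaPointSet(np.exp(pts), wm, wc, config)


def make_sigma_points(
    dist: ParameterDistribution, config: UTConfig | None = None
) -> SigmaPointSet:
    """Dispatch on ``dist.scale``."""
    if dist.scale == "lognormal":
        return lognormal_sigma_points(dist, config)
    return sigma_points(dist, config)


def ut_propagate(
    sigma_set: SigmaPointSet,
    mapping: Callable[[np.ndarray], Sequence[float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Push sigma points through ``mapping`` and reconstruct (mean, cov).

    mu_y = sum_i W^m_i g(chi_i);  Sigma_y = sum_i W^c_i (g(chi_i) - mu_y)(.)^T
    (symmetrized).  Mapping failures are re-raised naming the sigma-point
    index and coordinates.
    """
    outs = []
    for i, chi in enumerate(sigma_set.points):
        try:
            outs.append(np.atleast_1d(np.asarray(mapping(chi), dtype=float)))
        except Exception as exc:
            raise RuntimeError(
                f"mapping failed at sigma point {i} with values {chi}: {exc}"
            ) from exc
    Y = np.vstack(outs)
    mu = sigma_set.mean_weights @ Y
    D = Y - mu
    cov = (sigma_set.cov_weights * D.T) @ D
    cov = (cov + cov.T) / 2
    return mu, cov
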