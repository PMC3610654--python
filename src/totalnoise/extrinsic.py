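"""Parameter covariance construction for extrinsic variability.

Extrinsic cell-to-cell variability enters the framework as a covariance
matrix over kinetic parameters and initial conditions.  This module builds
the three families used in the circuit screens: CV-scaled diagonal matrices
(independent parameters, diagonal entries (a * theta_i)^2), sign-patterned
correlation matrices (the favourable / unfavourable patterns for the
transcriptional and post-transcriptional circuits in parameter order
(k_R, k_P, gamma_R, gamma_P)), and random correlation matrices with uniform
off-diagonals projected to validity by Higham's alternating-projection
nearest-correlation algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "CorrelationMatrix",
    "SignPattern",
    "SIGN_PATTERNS",
    "diagonal_cov",
    "nearest_correlation",
    "random_correlation",
    "signed_correlation",
    "corr_to_cov",
    "cov_to_corr",
]

#: Canonical parameter order of the shipped sign patterns.
PATTERN_ORDER = ("k_R", "k_P", "gamma_R", "gamma_P")


@dataclass(frozen=True)
class CorrelationMatrix:
    """A valid correlation matrix: symmetric, unit diagonal, PSD (to 1e-8)."""

    values: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", M)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(M, M.T, rtol=0, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.all(np.diag(M) == 1.0):
            raise ValueError("correlation matrix diagonal must be exactly 1")
        if linalg.eigvalsh(M).min() < -1e-8:
            raise ValueError("correlation matrix must be PSD (min eig >= -1e-8)")

    @property
    def shape(self):
        return self.values.shape

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class SignPattern:
    """Symmetric {+1, -1} off-diagonal sign pattern (diagonal ignored)."""

    signs: np.ndarray
    order: tuple[str, ...] = PATTERN_ORDER

    def __post_init__(self):
        S = np.asarray(self.signs, dtype=float)
        object.__setattr__(self, "signs", S)
        if S.shape[0] != S.shape[1] or not np.array_equal(S, S.T):
            raise ValueError("sign pattern must be square and symmetric")
        off = S[~np.eye(S.shape[0], dtype=bool)]
        if not np.all(np.isin(off, (-1.0, 1.0))):
            raise ValueError("off-diagonal signs must be +1 or -1")


def _pattern(pairs_positive):
    S = -np.ones((4, 4))
    np.fill_diagonal(S, 1.0)
    idx = {name: i for i, name in enumerate(PATTERN_ORDER)}
    for a, b in pairs_positive:
        S[idx[a], idx[b]] = S[idx[b], idx[a]] = 1.0
    return SignPattern(S)


#: Favourable patterns: ``transcriptional`` correlates (k_R,k_P) and
#: (gamma_R,gamma_P) and anti-correlates everything else;
#: ``post_transcriptional`` correlates k_P with each of k_R, gamma_R, gamma_P.
SIGN_PATTERNS = {
    "transcriptional": _pattern([("k_R", "k_P"), ("gamma_R", "gamma_P")]),
    "post_transcriptional": _pattern(
        [("k_R", "k_P"), ("k_P", "gamma_R"), ("k_P", "gamma_P")]
    ),
}


def diagonal_cov(theta_mean, a: float) -> np.ndarray:
    """Diagonal covariance with per-parameter coefficient of variation ``a``:
    entries (a * theta_i)^2, zero off-diagonals (independent parameters)."""
    if a < 0:
        raise ValueError(f"coefficient of variation must be >= 0, got {a}")
    theta_mean = np.atleast_1d(np.asarray(theta_mean, dtype=float))
    if np.any(theta_mean <= 0):
        raise ValueError("theta_mean must be strictly positive")
    return np.diag((a * theta_mean) ** 2)


def _proj_psd(M):
    w, V = linalg.eigh(M)
    return (V * np.clip(w, 0.0, None)) @ V.T


def nearest_correlation(
    M, tol: float = 1e-8, max_iter: int = 1000
) -> CorrelationMatrix:
    """Nearest valid correlation matrix by alternating projections.

    Higham's algorithm: alternate projection onto the PSD cone and the
    unit-diagonal affine set with a Dykstra correction, until the Frobenius
    change falls below ``tol``.  A valid input is a fixed point.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(M, M.T, rtol=0, atol=1e-12):
        raise ValueError("input must be symmetric")
    if not np.allclose(np.diag(M), 1.0, atol=1e-12):
        raise ValueError("input must have unit diagonal")
    Y = M.copy()
    dS = np.zeros_like(M)
    for _ in range(max_iter):
        R = Y - dS
        X = _proj_psd(R)
        dS = X - R
        Y_new = X.copy()
        np.fill_diagonal(Y_new, 1.0)
        if np.linalg.norm(Y_new - Y, "fro") <= tol * max(
            np.linalg.norm(Y_new, "fro"), 1.0
        ):
            Y = Y_new
            break
        Y = Y_new
    else:
        raise RuntimeError(
            f"nearest_correlation did not converge in {max_iter} iterations"
        )
    Y = (Y + Y.T) / 2
    np.fill_diagonal(Y, 1.0)
    # final polish: the alternating-projection fixed point is approached only
    # to tol, so the smallest eigenvalue can sit marginally below zero; clip
    # and renormalize the diagonal (changes entries at the tol scale only)
    if linalg.eigvalsh(Y).min() < -1e-8:
        Y = _proj_psd(Y)
        d = np.sqrt(np.diag(Y))
        Y = Y / np.outer(d, d)
        Y = (Y + Y.T) / 2
        np.fill_diagonal(Y, 1.0)
    return CorrelationMatrix(Y)


def random_correlation(
    L: int, seed: int, offdiag_range=(-1.0, 1.0)
) -> CorrelationMatrix:
    """Random symmetric unit-diagonal draw with uniform off-diagonals,
    projected to the nearest valid correlation matrix."""
    if L < 2:
        raise ValueError("L must be >= 2")
    lo, hi = offdiag_range
    if not hi >= lo:
        raise ValueError(f"degenerate off-diagonal range {offdiag_range}")
    rng = np.random.default_rng(seed)
    M = np.eye(L)
    iu = np.triu_indices(L, 1)
    vals = rng.uniform(lo, hi, size=len(iu[0]))
    M[iu] = vals
    M[(iu[1], iu[0])] = vals
    return nearest_correlation(M)


def signed_correlation(
    pattern: SignPattern | str, seed: int, magnitude_range=(0.0, 1.0)
) -> CorrelationMatrix:
    """Correlation matrix with prescribed off-diagonal signs.

    Magnitudes are uniform on ``magnitude_range``, signs from ``pattern``;
    the draw is projected by :func:`nearest_correlation`.  If projection
    flips any sign a warning names the flipped entries (projection is
    unconstrained by design).
    """
    if isinstance(pattern, str):
        pattern = SIGN_PATTERNS[pattern]
    S = pattern.signs
    L = S.shape[0]
    rng = np.random.default_rng(seed)
    M = np.eye(L)
    iu = np.triu_indices(L, 1)
    mags = rng.uniform(*magnitude_range, size=len(iu[0]))
    M[iu] = mags * S[iu]
    M[(iu[1], iu[0])] = M[iu]
    R = nearest_correlation(M)
    flipped = [
        (pattern.order[i], pattern.order[j])
        for i, j in zip(*iu)
        if M[i, j] != 0 and np.sign(R.values[i, j]) not in (0.0, np.sign(M[i, j]))
    ]
    if flipped:
        warnings.warn(
            f"nearest-correlation projection flipped the sign of entries {flipped}",
            stacklevel=2,
        )
    return R


def corr_to_cov(R, sds) -> np.ndarray:
    """Scale a correlation matrix by standard deviations:
    Sigma_ij = R_ij * sd_i * sd_j."""
    R = np.asarray(R, dtype=float)
    sds = np.atleast_1d(np.asarray(sds, dtype=float))
    if R.shape != (len(sds), len(sds)):
        raise ValueError(
            f"dimension mismatch: correlation {R.shape} vs {len(sds)} sds"
        )
    if np.any(sds <= 0):
        raise ValueError("standard deviations must be positive")
    return R * np.outer(sds, sds)


def cov_to_corr(Sigma) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`corr_to_cov`; returns (correlation, sds)."""
    Sigma = np.asarray(Sigma, dtype=float)
    sds = np.sqrt(np.diag(Sigma))
    if np.any(sds <= 0):
        raise ValueError("covariance diagonal must be positive")
    return Sigma / np.outer(sds, sds), sds
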