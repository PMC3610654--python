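"""Linear noise approximation (system-size expansion) moment equations.

For a network with stoichiometry S and propensity vector f, the macroscopic
means phi obey dphi/dt = S f(phi), and the covariance C of the fluctuations
around phi obeys

    dC/dt = A C + C A^T + B,

with drift A = d(S f)/dphi evaluated along the macroscopic trajectory and
diffusion B = S diag(f) S^T.  The mean equations do not depend on C
(one-way coupling), and the pair (phi, C) approximates the first two moments
of the chemical master equation.  Everything here is carried in molecule
numbers (system size Omega = 1 by default).

Steady states are found by integrating the mean ODE until the right-hand
side is numerically zero, polishing with a Newton root solve, verifying the
drift is Hurwitz-stable, and solving the continuous Lyapunov equation
A C + C A^T + B = 0 for the stationary covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, linalg, optimize

from .network import ReactionNetwork, _compiled

__all__ = [
    "MomentState",
    "MomentTrajectory",
    "macroscopic_rhs",
    "drift_matrix",
    "diffusion_matrix",
    "integrate_lna",
    "steady_state_lna",
    "SteadyStateError",
]


class SteadyStateError(RuntimeError):
    """Steady-state search failed to converge or found an unstable point."""


@dataclass
class MomentState:
    """Mean vector and fluctuation covariance at one time point.

    ``time`` is ``math.inf`` for stationary states.  ``cov`` is symmetric
    (molecule^2); ``mean`` is the macroscopic molecule-count vector.
    """

    time: float
    mean: np.ndarray
    cov: np.ndarray
    species: tuple[str, ...]

    def mean_of(self, name: str) -> float:
        return float(self.mean[self.species.index(name)])

    def var_of(self, name: str) -> float:
        i = self.species.index(name)
        return float(self.cov[i, i])

    def cov_of(self, a: str, b: str) -> float:
        return float(self.cov[self.species.index(a), self.species.index(b)])


@dataclass
class MomentTrajectory:
    """Ordered sequence of :class:`MomentState` at strictly increasing times."""

    states: list[MomentState]

    def __post_init__(self):
        times = [s.time for s in self.states]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self):
        return len(self.states)

    def __getitem__(self, i) -> MomentState:
        return self.states[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    @property
    def species(self) -> tuple[str, ...]:
        return self.states[0].species

    def to_frame(self):
        """Tidy table: time, mean.<sp>..., cov.<a>.<b> (upper triangle)."""
        import pandas as pd

        sp = self.species
        rows = []
        for st in self.states:
            row = {"time": st.time}
            for i, a in enumerate(sp):
                row[f"mean.{a}"] = st.mean[i]
            for i, a in enumerate(sp):
                for j in range(i, len(sp)):
                    row[f"cov.{a}.{sp[j]}"] = st.cov[i, j]
            rows.append(row)
        return pd.DataFrame(rows)


def macroscopic_rhs(
    net: ReactionNetwork, phi, theta: Mapping[str, float] | None = None
) -> np.ndarray:
    """dphi/dt = S f(phi, theta)."""
    phi = np.asarray(phi, dtype=float)
    c = net.constants_vector(theta)
    f_fn, _ = _compiled(net)
    f = np.asarray(f_fn(phi, c), dtype=float)
    return net.stoichiometry @ f


def drift_matrix(
    net: ReactionNetwork, phi, theta: Mapping[str, float] | None = None
) -> np.ndarray:
    """Jacobian A of S f with respect to phi (symbolic, cached per network)."""
    phi = np.asarray(phi, dtype=float)
    c = net.constants_vector(theta)
    _, jac_fn = _compiled(net)
    A = np.asarray(jac_fn(phi, c), dtype=float)
    if not np.all(np.isfinite(A)):
        # finite-difference fallback for rate laws that are non-smooth at phi
        A = _fd_jacobian(net, phi, c)
    return A


def _fd_jacobian(net: ReactionNetwork, phi: np.ndarray, c: np.ndarray) -> np.ndarray:
    f_fn, _ = _compiled(net)
    S = net.stoichiometry

    def g(x):
        return S @ np.asarray(f_fn(x, c), dtype=float)

    n = len(phi)
    A = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(1.0, abs(phi[j]))
        e = np.zeros(n)
        e[j] = h
        A[:, j] = (g(phi + e) - g(phi - e)) / (2 * h)
    return A


def diffusion_matrix(
    net: ReactionNetwork, phi, theta: Mapping[str, float] | None = None
) -> np.ndarray:
    """B = S diag(f) S^T, symmetric PSD by construction."""
    phi = np.asarray(phi, dtype=float)
    c = net.constants_vector(theta)
    f_fn, _ = _compiled(net)
    f = np.asarray(f_fn(phi, c), dtype=float)
    S = net.stoichiometry
    return (S * f) @ S.T


# -- packing helpers ------------------------------------------------------

def _tri_indices(n: int):
    return np.triu_indices(n)


def _pack(C: np.ndarray, idx) -> np.ndarray:
    return C[idx]


def _unpack(v: np.ndarray, n: int, idx) -> np.ndarray:
    C = np.zeros((n, n))
    C[idx] = v
    C = C + C.T
    C[np.diag_indices(n)] /= 2
    return C


def integrate_lna(
    net: ReactionNetwork,
    theta: Mapping[str, float] | None = None,
    init_mean=None,
    init_cov=None,
    t_grid: Sequence[float] = (0.0, 1.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> MomentTrajectory:
    """Jointly integrate the mean and covariance ODEs over ``t_grid``.

    ``init_mean`` defaults to the network's initial conditions and
    ``init_cov`` to the zero matrix (deterministic initial counts).
    Returned covariances are symmetrized at each output point.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    n = net.n_species
    consts, ic_over = net.split_theta(theta)
    phi0 = (
        np.asarray(init_mean, dtype=float)
        if init_mean is not None
        else net.initial_state(ic_over)
    )
    if init_cov is None:
        C0 = np.zeros((n, n))
    else:
        C0 = np.asarray(init_cov, dtype=float)
        if C0.shape != (n, n) or not np.allclose(C0, C0.T, rtol=1e-10, atol=1e-12):
            raise ValueError("init_cov must be a symmetric (n, n) matrix")
        if np.any(linalg.eigvalsh(C0) < -1e-8 * max(np.trace(C0), 1.0)):
            raise ValueError("init_cov must be positive semidefinite")
    c = net.constants_vector(consts)
    f_fn, jac_fn = _compiled(net)
    S = net.stoichiometry
    idx = _tri_indices(n)

    def rhs(t, y):
        phi = y[:n]
        C = _unpack(y[n:], n, idx)
        f = np.asarray(f_fn(phi, c), dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            A = np.asarray(jac_fn(phi, c), dtype=float)
        if not np.all(np.isfinite(A)):
            A = _fd_jacobian(net, phi, c)
        B = (S * f) @ S.T
        dC = A @ C + C @ A.T + B
        return np.concatenate([S @ f, _pack(dC, idx)])

    y0 = np.concatenate([phi0, _pack(C0, idx)])
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    if t1 == t0:
        sol_y = y0[:, None]
    else:
        sol = integrate.solve_ivp(
            rhs, (t0, t1), y0, t_eval=t_grid, method=method, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"moment integration failed at t={sol.t[-1]}: {sol.message}")
        sol_y = sol.y
    states = []
    for k, t in enumerate(t_grid):
        phi = sol_y[:n, k]
        C = _unpack(sol_y[n:, k], n, idx)
        C = (C + C.T) / 2
        states.append(MomentState(float(t), phi.copy(), C, net.species))
    return MomentTrajectory(states)


def _find_fixed_point(net, c, phi0, tol):
    f_fn, jac_fn = _compiled(net)
    S = net.stoichiometry

    def g(x):
        return S @ np.asarray(f_fn(x, c), dtype=float)

    def jac(x):
        return np.asarray(jac_fn(x, c), dtype=float)

    sol = optimize.root(g, phi0, jac=jac, method="hybr", tol=1e-13)
    phi = sol.x
    ok = sol.success and np.linalg.norm(g(phi), np.inf) <= tol * max(
        1.0, np.linalg.norm(phi, np.inf)
    )
    return phi, ok


def steady_state_lna(
    net: ReactionNetwork,
    theta: Mapping[str, float] | None = None,
    guess=None,
    tol: float = 1e-9,
    seed_integration: bool = True,
) -> MomentState:
    """Stationary mean and covariance of the moment model.

    Solves S f(phi*) = 0 (Newton polish seeded by a long mean-ODE
    integration, or directly from ``guess``), verifies the drift matrix is
    stable (all eigenvalues with negative real part), and solves the
    continuous Lyapunov equation for the stationary covariance.
    """
    consts, ic_over = net.split_theta(theta)
    c = net.constants_vector(consts)
    f_fn, jac_fn = _compiled(net)
    S = net.stoichiometry
    n = net.n_species

    phi = None
    if guess is not None:
        cand, ok = _find_fixed_point(net, c, np.asarray(guess, dtype=float), tol)
        if ok and np.all(cand >= -tol):
            A = np.asarray(jac_fn(cand, c), dtype=float)
            if np.all(np.real(linalg.eigvals(A)) < 0):
                phi = cand
    if phi is None:
        if not seed_integration and guess is not None:
            raise SteadyStateError("root solve from guess failed")
        # integrate the mean ODE with doubling horizons until stationary
        x = net.initial_state(ic_over) if guess is None else np.asarray(guess, float)

        def rhs(t, y):
            return S @ np.asarray(f_fn(y, c), dtype=float)

        T, converged = 10.0, False
        for _ in range(24):
            try:
                sol = integrate.solve_ivp(
                    rhs, (0.0, T), x, method="LSODA", rtol=1e-10, atol=1e-12
                )
            except (ValueError, OverflowError) as exc:
                raise SteadyStateError(f"mean integration diverged: {exc}") from exc
            if not sol.success:
                raise SteadyStateError(f"mean integration failed: {sol.message}")
            x = sol.y[:, -1]
            if not np.all(np.isfinite(x)):
                raise SteadyStateError("mean integration diverged to non-finite values")
            if np.linalg.norm(rhs(0.0, x), np.inf) <= tol * max(
                1.0, np.linalg.norm(x, np.inf)
            ):
                converged = True
                break
            T *= 2.0
        phi, ok = _find_fixed_point(net, c, x, tol)
        if not ok:
            if converged:
                phi = x  # integration itself reached the tolerance
            else:
                raise SteadyStateError("steady-state search did not converge")
    phi = np.where(np.abs(phi) < 1e-12, 0.0, phi)
    if np.any(phi < 0):
        raise SteadyStateError(f"negative steady-state mean: {phi}")
    A = np.asarray(jac_fn(phi, c), dtype=float)
    eig = linalg.eigvals(A)
    if np.any(np.real(eig) >= 0):
        raise SteadyStateError(
            f"fixed point is not stable (drift eigenvalues {eig})"
        )
    f = np.asarray(f_fn(phi, c), dtype=float)
    B = (S * f) @ S.T
    C = linalg.solve_continuous_lyapunov(A, -B)
    C = (C + C.T) / 2
    return MomentState(math.inf, phi, C, net.species)
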