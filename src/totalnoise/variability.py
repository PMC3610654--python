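"""Total-variability analysis: intrinsic + extrinsic moment decomposition.

The output distribution of a circuit whose parameters theta themselves vary
across cells is a mixture of the per-theta intrinsic (LNA) Gaussians.  By the
law of total variance its first two moments are

    total mean = E_theta[ mu(theta) ]
    total cov  = E_theta[ Sigma_int(theta) ] + Cov_theta[ mu(theta) ]
                 \-- intrinsic component --/   \-- extrinsic component --/

Here the expectation over theta is evaluated with the scaled unscented
transform: each sigma point is mapped through the LNA (steady state or a
transient time point), intrinsic covariances are averaged with the mean
weights, and the scatter of the per-point means weighted by the covariance
weights gives the extrinsic part.  A sampling-based oracle
(:func:`mixture_sample`) estimates the same moments by brute force without
the UT, and stays free of stochastic simulation.

Variability is summarised as the squared coefficient of variation
CV^2 = var/mean^2, and relative to the matched no-feedback circuit as
CV^2_r = CV^2(test)/CV^2(reference); CV^2_r < 1 means the feedback
suppresses variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import linalg, stats

from .lna import MomentState, integrate_lna, steady_state_lna
from .network import ReactionNetwork
from .unscented import (
    ParameterDistribution,
    SigmaPointSet,
    UTConfig,
    make_sigma_points,
)

__all__ = [
    "TotalVariabilityResult",
    "EllipseGeometry",
    "total_moments",
    "mixture_sample",
    "cv2",
    "relative_cv2",
    "ellipse_contour",
]


@dataclass
class TotalVariabilityResult:
    """Decomposed output moments at one time point (or steady state).

    ``total_cov`` is by construction exactly ``intrinsic_cov +
    extrinsic_cov``.  Per-sigma-point means and covariances are retained for
    audit.
    """

    when: float | str
    species: tuple[str, ...]
    total_mean: np.ndarray
    intrinsic_cov: np.ndarray
    extrinsic_cov: np.ndarray
    total_cov: np.ndarray
    sigma_means: np.ndarray | None = None
    sigma_covs: np.ndarray | None = None
    sigma_set: SigmaPointSet | None = field(default=None, repr=False)

    def _i(self, name: str) -> int:
        return self.species.index(name)

    def mean_of(self, name: str) -> float:
        return float(self.total_mean[self._i(name)])

    def var_of(self, name: str, component: str = "total") -> float:
        i = self._i(name)
        return float(getattr(self, f"{component}_cov")[i, i])

    def cv2_of(self, name: str, component: str = "total") -> float:
        return cv2(self.mean_of(name), self.var_of(name, component))

    def to_dict(self) -> dict:
        """JSON-serializable decomposition with per-sigma-point audit block."""
        d = {
            "when": self.when if isinstance(self.when, str) else float(self.when),
            "species": list(self.species),
            "total_mean": self.total_mean.tolist(),
            "intrinsic_cov": self.intrinsic_cov.tolist(),
            "extrinsic_cov": self.extrinsic_cov.tolist(),
            "total_cov": self.total_cov.tolist(),
        }
        if self.sigma_means is not None:
            d["sigma_points"] = {
                "means": self.sigma_means.tolist(),
                "covs": self.sigma_covs.tolist(),
                "mean_weights": self.sigma_set.mean_weights.tolist(),
                "cov_weights": self.sigma_set.cov_weights.tolist(),
            }
        return d


class _SteadyMapper:
    """Fast theta -> stationary (mean, cov) map for tight sampling loops.

    Newton iteration on S f(phi) = 0 warm-started from the previous solution
    plus a direct Lyapunov solve; falls back to the robust
    :func:`steady_state_lna` whenever Newton stalls or lands on an unstable
    or negative fixed point.
    """

    def __init__(self, net: ReactionNetwork, names, base_theta=None):
        from .network import _compiled

        self.net = net
        self.f_fn, self.jac_fn = _compiled(net)
        self.S = net.stoichiometry
        self.base_theta = dict(base_theta or {})
        consts, _ = net.split_theta(self.base_theta)
        self.c0 = net.constants_vector(consts)
        cname = {n: i for i, n in enumerate(net.constant_names)}
        self.idx = []
        for j, name in enumerate(names):
            if name not in cname:
                raise KeyError(
                    f"{name!r} is not a parameter of this network (species "
                    "initial conditions need the generic path)"
                )
            self.idx.append((j, cname[name]))
        self.names = tuple(names)

    def __call__(self, theta_vec, guess):
        c = self.c0.copy()
        for j, k in self.idx:
            c[k] = theta_vec[j]
        phi = np.asarray(guess, dtype=float).copy()
        ok = False
        for _ in range(50):
            g = self.S @ np.asarray(self.f_fn(phi, c), dtype=float)
            if np.linalg.norm(g, np.inf) <= 1e-10 * max(
                1.0, np.linalg.norm(phi, np.inf)
            ):
                ok = True
                break
            A = np.asarray(self.jac_fn(phi, c), dtype=float)
            try:
                step = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            phi = phi + step
        if ok and np.all(phi >= -1e-9):
            phi = np.clip(phi, 0.0, None)
            A = np.asarray(self.jac_fn(phi, c), dtype=float)
            if np.all(np.real(np.linalg.eigvals(A)) < 0):
                f = np.asarray(self.f_fn(phi, c), dtype=float)
                B = (self.S * f) @ self.S.T
                C = linalg.solve_continuous_lyapunov(A, -B)
                return phi, (C + C.T) / 2
        theta = dict(self.base_theta)
        theta.update(zip(self.names, theta_vec))
        st = steady_state_lna(self.net, theta)
        return st.mean, st.cov


def _lna_at(net, theta, init_spec, when, guess=None) -> MomentState:
    if when == "steady_state":
        return steady_state_lna(net, theta, guess=guess)
    t = float(when)
    consts, ic_over = net.split_theta(theta)
    init = dict(init_spec or {})
    init.update(ic_over)
    x0 = net.initial_state(init)
    grid = [0.0, t] if t > 0 else [0.0]
    traj = integrate_lna(net, theta=consts, init_mean=x0, t_grid=grid)
    return traj[-1]


def total_moments(
    net: ReactionNetwork,
    dist: ParameterDistribution | None = None,
    init_spec: Mapping[str, float] | None = None,
    when: float | str = "steady_state",
    ut_config: UTConfig | None = None,
    theta: Mapping[str, float] | None = None,
) -> TotalVariabilityResult:
    """Total/intrinsic/extrinsic moment decomposition via the UT over the LNA.

    ``dist`` names parameters and/or initial-condition symbols of ``net``;
    ``theta`` supplies fixed overrides for everything not in ``dist`` (e.g.
    the feedback strength of the current sweep cell).  ``dist=None`` gives
    the intrinsic-only (fixed-theta) result with zero extrinsic component.
    """
    base = dict(theta or {})
    if dist is None or not np.any(dist.cov):
        pt_theta = dict(base)
        if dist is not None:
            pt_theta.update(zip(dist.names, dist.mean))
        st = _lna_at(net, pt_theta, init_spec, when)
        zero = np.zeros_like(st.cov)
        return TotalVariabilityResult(
            when, net.species, st.mean.copy(), st.cov.copy(), zero,
            st.cov.copy(),
        )
    sigma = make_sigma_points(dist, ut_config)
    means, covs = [], []
    guess = None
    for i, chi in enumerate(sigma.points):
        pt_theta = dict(base)
        pt_theta.update(zip(dist.names, chi))
        try:
            st = _lna_at(net, pt_theta, init_spec, when, guess=guess)
        except Exception as exc:
            raise RuntimeError(
                f"LNA evaluation failed at sigma point {i} ({dict(zip(dist.names, chi))}): {exc}"
            ) from exc
        if guess is None and when == "steady_state":
            guess = st.mean
        means.append(st.mean)
        covs.append(st.cov)
    M = np.vstack(means)
    total_mean = sigma.mean_weights @ M
    D = M - total_mean
    extrinsic = (sigma.cov_weights * D.T) @ D
    extrinsic = (extrinsic + extrinsic.T) / 2
    intrinsic = np.tensordot(sigma.mean_weights, np.array(covs), axes=1)
    intrinsic = (intrinsic + intrinsic.T) / 2
    return TotalVariabilityResult(
        when,
        net.species,
        total_mean,
        intrinsic,
        extrinsic,
        intrinsic + extrinsic,
        sigma_means=M,
        sigma_covs=np.array(covs),
        sigma_set=sigma,
    )


def _sample_thetas(dist: ParameterDistribution, n: int, rng) -> np.ndarray:
    """Draw parameter vectors; Gaussian draws are rejection-sampled to stay
    positive, log-normal draws are positive by construction."""
    if dist.scale == "lognormal":
        S_log = np.log1p(dist.cov / np.outer(dist.mean, dist.mean))
        S_log = (S_log + S_log.T) / 2
        m = np.log(dist.mean) - 0.5 * np.diag(S_log)
        Z = rng.multivariate_normal(m, S_log, size=n, method="eigh")
        return np.exp(Z)
    out = np.empty((n, dist.L))
    got, attempts, accepted = 0, 0, 0
    while got < n:
        batch = max(n - got, 128)
        draws = rng.multivariate_normal(dist.mean, dist.cov, size=batch, method="eigh")
        attempts += batch
        keep = draws[np.all(draws > 0, axis=1)]
        accepted += len(keep)
        take = min(len(keep), n - got)
        out[got : got + take] = keep[:take]
        got += take
        if attempts >= max(2 * n, 256) and accepted < attempts / 2:
            raise RuntimeError(
                "positivity rejection rate exceeds 50%; distribution too wide "
                "— use scale='lognormal'"
            )
    return out


def mixture_sample(
    net: ReactionNetwork,
    dist: ParameterDistribution,
    init_spec: Mapping[str, float] | None = None,
    when: float | str = "steady_state",
    n: int = 1000,
    seed: int = 0,
    theta: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Sample species values from the intrinsic/extrinsic mixture.

    For each of ``n`` draws: sample theta from ``dist``, run the LNA to
    ``when``, and draw one multivariate-normal deviate from the conditional
    (mu(theta), Sigma_int(theta)).  The empirical moments of the returned
    (n, n_species) array estimate the total mean and covariance — an
    SSA-free brute-force oracle for :func:`total_moments`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    thetas = _sample_thetas(dist, n, rng)
    base = dict(theta or {})
    out = np.empty((n, net.n_species))
    mapper = None
    if when == "steady_state" and not (set(dist.names) & set(net.species)):
        mapper = _SteadyMapper(net, dist.names, base)
        guess = steady_state_lna(
            net, {**base, **dict(zip(dist.names, dist.mean))}
        ).mean
        for k in range(n):
            mean, cov = mapper(thetas[k], guess)
            guess = mean
            out[k] = rng.multivariate_normal(mean, cov, method="eigh")
        return out
    guess = None
    for k in range(n):
        pt_theta = dict(base)
        pt_theta.update(zip(dist.names, thetas[k]))
        st = _lna_at(net, pt_theta, init_spec, when, guess=guess)
        if guess is None and when == "steady_state":
            guess = st.mean
        out[k] = rng.multivariate_normal(st.mean, st.cov, method="eigh")
    return out


def cv2(mean: float, variance: float) -> float:
    """Squared coefficient of variation, variance / mean^2 (mean > 0)."""
    if mean <= 0:
        raise ValueError(f"cv2 requires a positive mean, got {mean}")
    return variance / mean**2


def relative_cv2(
    test: TotalVariabilityResult,
    reference: TotalVariabilityResult,
    species: str,
    component: str = "total",
) -> float:
    """CV^2 of ``test`` normalized by the matched no-feedback ``reference``.

    The reference must be the same circuit with only the feedback element
    removed (strength 0), identical remaining parameters and identical
    extrinsic distribution; values below 1 mean the feedback suppresses
    variability.
    """
    ref = reference.cv2_of(species, component)
    if ref == 0:
        raise ZeroDivisionError("reference CV^2 is zero")
    return test.cv2_of(species, component) / ref


@dataclass
class EllipseGeometry:
    """Equal-probability contour of a bivariate normal.

    Axis directions are the eigenvectors of the 2x2 covariance; half-lengths
    are r * sqrt(eigenvalue).  In confidence mode r^2 is the chi-square(2)
    quantile at level p, so the ellipse contains probability mass p.
    """

    center: np.ndarray
    axes: np.ndarray  # columns are unit eigenvectors
    half_lengths: np.ndarray
    r: float
    confidence: float | None = None

    @property
    def angle(self) -> float:
        """Orientation of the major axis, radians in (-pi/2, pi/2]."""
        i = int(np.argmax(self.half_lengths))
        v = self.axes[:, i]
        return float(math.atan2(v[1], v[0]))

    def contains(self, points) -> np.ndarray:
        """Boolean mask: which points lie inside (or on) the contour."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        z = (pts - self.center) @ self.axes
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (z / self.half_lengths) ** 2
        q = np.where(np.isnan(q), np.where(z == 0, 0.0, np.inf), q)
        return q.sum(axis=1) <= 1.0

    def boundary(self, num: int = 200) -> np.ndarray:
        """(num, 2) points tracing the contour, for plotting."""
        t = np.linspace(0, 2 * np.pi, num)
        circ = np.vstack([np.cos(t), np.sin(t)])
        return (self.axes @ (self.half_lengths[:, None] * circ)).T + self.center


def ellipse_contour(
    mean2, cov2, r: float | None = None, confidence: float | None = None
) -> EllipseGeometry:
    """Ellipse of a 2D Gaussian, either at raw scale ``r`` (default 1) or at
    confidence level ``confidence`` (mass-p contour, r^2 = chi2(2).ppf(p))."""
    mean2 = np.asarray(mean2, dtype=float)
    cov2 = np.asarray(cov2, dtype=float)
    if mean2.shape != (2,) or cov2.shape != (2, 2):
        raise ValueError("ellipse_contour is for 2-dimensional distributions")
    if not np.allclose(cov2, cov2.T, atol=1e-12):
        raise ValueError("covariance must be symmetric")
    w, V = linalg.eigh(cov2)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("covariance must be positive semidefinite")
    w = np.clip(w, 0.0, None)
    if confidence is not None:
        if r is not None:
            raise ValueError("give either r or confidence, not both")
        if not 0 < confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        r_eff = math.sqrt(stats.chi2.ppf(confidence, df=2))
    else:
        r_eff = 1.0 if r is None else float(r)
        if r_eff < 0:
            raise ValueError("r must be non-negative")
    return EllipseGeometry(
        center=mean2,
        axes=V,
        half_lengths=r_eff * np.sqrt(w),
        r=r_eff,
        confidence=confidence,
    )
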