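"""Exact stochastic simulation (Gillespie direct method) and ensembles.

The SSA samples the jump process defined by a network's propensities
exactly, and serves as the ground-truth oracle for the moment-based
machinery: per-run trajectories (:func:`gillespie_run`), fixed-parameter
ensemble moments (:func:`ensemble_moments`), and the brute-force total
variability oracle in which every run draws its own parameter vector from
the extrinsic distribution (:func:`mixture_ensemble`).

Ensemble kernels are generated as Python source per network (propensity
expressions inlined) and JIT-compiled with numba; per-run seeds are derived
from the master seed through ``numpy.random.SeedSequence`` so identical
(seed, inputs) give bitwise-identical summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import sympy

from .network import ReactionNetwork, NetworkSpecError
from .unscented import ParameterDistribution
from .variability import _sample_thetas

try:  # pragma: no cover - numba is expected to be present
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "SSAEnsembleSummary",
    "gillespie_run",
    "ensemble_moments",
    "mixture_ensemble",
]


@dataclass
class SSAEnsembleSummary:
    """Per-time-point empirical moments of an SSA ensemble.

    ``mean`` has shape (n_times, n_species); ``cov`` (n_times, n_species,
    n_species) with denominator n-1; ``se_mean`` is the standard error of the
    mean and ``se_var`` the (normal-approximation) standard error of the
    variance, var * sqrt(2/(n-1)).
    """

    times: np.ndarray
    species: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    se_mean: np.ndarray
    se_var: np.ndarray
    n_runs: int
    seed: int

    def _i(self, name):
        return self.species.index(name)

    def mean_of(self, name: str, t_index: int = -1) -> float:
        return float(self.mean[t_index, self._i(name)])

    def var_of(self, name: str, t_index: int = -1) -> float:
        i = self._i(name)
        return float(self.cov[t_index, i, i])

    def to_frame(self):
        import pandas as pd

        sp = self.species
        rows = []
        for k, t in enumerate(self.times):
            row = {"time": t}
            for i, a in enumerate(sp):
                row[f"mean.{a}"] = self.mean[k, i]
                row[f"se.mean.{a}"] = self.se_mean[k, i]
            for i, a in enumerate(sp):
                for j in range(i, len(sp)):
                    row[f"cov.{a}.{sp[j]}"] = self.cov[k, i, j]
            rows.append(row)
        return pd.DataFrame(rows)


# -- kernel code generation ------------------------------------------------

def _propensity_exprs(net: ReactionNetwork) -> list[str]:
    """Propensity source strings over locals x_<i> (species) and c_<j>."""
    subs = {sympy.Symbol(s): sympy.Symbol(f"x_{i}") for i, s in enumerate(net.species)}
    subs.update(
        {sympy.Symbol(c): sympy.Symbol(f"c_{j}") for j, c in enumerate(net.constant_names)}
    )
    subs[sympy.Symbol("Omega")] = sympy.Float(net.system_size)
    out = []
    for law in net.rate_laws:
        expr = law.expression.xreplace(subs)
        out.append(sympy.printing.pycode(expr))
    return out


def _kernel_source(net: ReactionNetwork) -> str:
    """Source of ``kernel(x0, consts, t_grid, seeds, out)``.

    x0: (n_runs, n_species) float64 initial counts; consts: (n_runs,
    n_const); out: (n_runs, n_grid, n_species).  Records the pre-jump state
    at every grid time passed, so out[r, g] is the state at time t_grid[g].
    """
    n_sp, n_rx = net.n_species, net.n_reactions
    props = _propensity_exprs(net)
    L = ["def kernel(x0, consts, t_grid, seeds, out):"]
    L.append("    n_runs = seeds.shape[0]")
    L.append("    n_grid = t_grid.shape[0]")
    L.append("    for r in range(n_runs):")
    L.append("        np.random.seed(seeds[r])")
    for j in range(len(net.constant_names)):
        L.append(f"        c_{j} = consts[r, {j}]")
    for i in range(n_sp):
        L.append(f"        x_{i} = x0[r, {i}]")
    L.append("        t = 0.0")
    L.append("        gi = 0")
    L.append("        while gi < n_grid:")
    for j, p in enumerate(props):
        L.append(f"            a_{j} = {p}")
    tot = " + ".join(f"a_{j}" for j in range(n_rx))
    L.append(f"            a_tot = {tot}")
    L.append("            if a_tot <= 0.0:")
    L.append("                while gi < n_grid:")
    for i in range(n_sp):
        L.append(f"                    out[r, gi, {i}] = x_{i}")
    L.append("                    gi += 1")
    L.append("                break")
    L.append("            t_new = t - np.log(np.random.random()) / a_tot")
    L.append("            while gi < n_grid and t_grid[gi] <= t_new:")
    for i in range(n_sp):
        L.append(f"                out[r, gi, {i}] = x_{i}")
    L.append("                gi += 1")
    L.append("            if gi >= n_grid:")
    L.append("                break")
    L.append("            t = t_new")
    L.append("            u = np.random.random() * a_tot")
    acc = []
    for j in range(n_rx):
        acc.append(f"a_{j}")
        cond = " + ".join(acc)
        kw = "if" if j == 0 else "elif"
        if j < n_rx - 1:
            L.append(f"            {kw} u < {cond}:")
        else:
            L.append("            else:")
        for i in range(n_sp):
            dn = int(net.stoichiometry[i, j])
            if dn:
                L.append(f"                x_{i} += {dn}.0")
        if all(net.stoichiometry[i, j] == 0 for i in range(n_sp)):
            L.append("                pass")
    return "\n".join(L) + "\n"


def _ensemble_kernel(net: ReactionNetwork):
    if "ssa_kernel" in net._cache:
        return net._cache["ssa_kernel"]
    src = _kernel_source(net)
    ns: dict = {"np": np}
    exec(compile(src, "<ssa-kernel>", "exec"), ns)
    fn = ns["kernel"]
    if _HAVE_NUMBA:
        fn = numba.njit(fn, cache=False)
    net._cache["ssa_kernel"] = fn
    return fn


# -- single run ------------------------------------------------------------

def gillespie_run(
    net: ReactionNetwork,
    theta: Mapping[str, float] | None = None,
    init_counts=None,
    t_end: float = 1.0,
    seed: int = 0,
    max_events: int = 10_000_000,
):
    """One exact SSA trajectory: (event_times, states) with states integer,
    piecewise constant between events; row 0 is the initial condition at t=0.
    Reproducible given ``seed``."""
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    consts, ic_over = net.split_theta(theta)
    c = net.constants_vector(consts)
    x = (
        np.asarray(init_counts, dtype=float)
        if init_counts is not None
        else net.initial_state(ic_over)
    )
    if np.any(x < 0) or np.any(x != np.round(x)):
        raise ValueError("init_counts must be non-negative integers")
    from .network import _compiled

    f_fn, _ = _compiled(net)
    S = net.stoichiometry.astype(float)
    rng = np.random.default_rng(seed)
    times, states = [0.0], [x.copy()]
    t = 0.0
    for _ in range(max_events):
        a = np.asarray(f_fn(x, c), dtype=float)
        if np.any(a < -1e-12):
            j = int(np.argmin(a))
            raise NetworkSpecError(
                f"negative propensity for reaction {j} at state {x}"
            )
        a = np.clip(a, 0.0, None)
        a_tot = a.sum()
        if a_tot <= 0:
            break
        t += rng.exponential(1.0 / a_tot)
        if t > t_end:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.random() * a_tot, side="right"))
        j = min(j, len(a) - 1)
        x = x + S[:, j]
        times.append(t)
        states.append(x.copy())
    else:
        raise RuntimeError(f"exceeded max_events={max_events} before t_end")
    return np.array(times), np.array(states, dtype=np.int64)


# -- ensembles -------------------------------------------------------------

def _run_seeds(seed: int, n_runs: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_runs).astype(np.int64)


def _summarize(times, species, states, n_runs, seed) -> SSAEnsembleSummary:
    mean = states.mean(axis=0)
    n_t, n_sp = mean.shape
    cov = np.empty((n_t, n_sp, n_sp))
    for k in range(n_t):
        cov[k] = np.cov(states[:, k, :], rowvar=False, ddof=1).reshape(n_sp, n_sp)
    var = np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0)
    se_mean = np.sqrt(var / n_runs)
    se_var = var * np.sqrt(2.0 / (n_runs - 1))
    return SSAEnsembleSummary(
        np.asarray(times, dtype=float), species, mean, cov, se_mean, se_var,
        n_runs, seed,
    )


def _check_grid(t_points):
    t = np.asarray(t_points, dtype=float)
    if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValueError("t_points must be non-negative and strictly increasing")
    return t


def ensemble_moments(
    net: ReactionNetwork,
    theta: Mapping[str, float] | None = None,
    init_counts=None,
    t_points: Sequence[float] = (0.0, 1.0),
    n_runs: int = 1000,
    seed: int = 0,
) -> SSAEnsembleSummary:
    """Sample moments across ``n_runs`` independent SSA runs at ``t_points``."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    t = _check_grid(t_points)
    consts, ic_over = net.split_theta(theta)
    c = net.constants_vector(consts)
    x0 = (
        np.asarray(init_counts, dtype=float)
        if init_counts is not None
        else np.round(net.initial_state(ic_over))
    )
    kernel = _ensemble_kernel(net)
    seeds = _run_seeds(seed, n_runs)
    consts_mat = np.tile(c, (n_runs, 1))
    x0_mat = np.tile(x0.astype(float), (n_runs, 1))
    out = np.empty((n_runs, len(t), net.n_species))
    kernel(x0_mat, consts_mat, t, seeds, out)
    return _summarize(t, net.species, out, n_runs, seed)


def mixture_ensemble(
    net: ReactionNetwork,
    dist: ParameterDistribution,
    init_spec: Mapping[str, float] | None = None,
    t_points: Sequence[float] = (0.0, 1.0),
    n_runs: int = 1000,
    seed: int = 0,
    theta: Mapping[str, float] | None = None,
) -> SSAEnsembleSummary:
    """Total-variability oracle: each run draws its own theta from ``dist``.

    Normal-scale draws are rejection-sampled to positivity (error if the
    rejection rate exceeds 50%); sampled initial-condition species are
    rounded to integer counts.  The summary estimates the moments of the
    intrinsic/extrinsic mixture by brute force.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    t = _check_grid(t_points)
    rng = np.random.default_rng(seed)
    thetas = _sample_thetas(dist, n_runs, rng)
    consts, ic_over = net.split_theta(theta)
    c0 = net.constants_vector(consts)
    x0_base = np.round(net.initial_state({**(init_spec or {}), **ic_over}))
    const_idx = {name: i for i, name in enumerate(net.constant_names)}
    consts_mat = np.tile(c0, (n_runs, 1))
    x0_mat = np.tile(x0_base.astype(float), (n_runs, 1))
    for j, name in enumerate(dist.names):
        if name in const_idx:
            consts_mat[:, const_idx[name]] = thetas[:, j]
        elif name in net.species:
            x0_mat[:, net.species_index(name)] = np.round(thetas[:, j])
        else:
            raise KeyError(f"distribution names unknown symbol {name!r}")
    kernel = _ensemble_kernel(net)
    seeds = _run_seeds(seed + 1, n_runs)
    out = np.empty((n_runs, len(t), net.n_species))
    kernel(x0_mat, consts_mat, t, seeds, out)
    return _summarize(t, net.species, out, n_runs, seed)
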