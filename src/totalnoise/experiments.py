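"""Design-principle screens: feedback sweeps, topology comparisons,
covariance screens, and a config-file pipeline runner.

Every screen reduces to the same cell computation: build a circuit, set its
feedback strength, compute the total-variability decomposition (UT over the
LNA) and normalize the output-protein CV^2 by the matched no-feedback
reference (strength 0, identical remaining parameters and identical
extrinsic distribution).  Failures in individual cells are recorded and
never abort a sweep.

Default strength grids are logarithmic; transient evaluation times default
to fractions of the slowest relaxation time.  Both are repository
conventions, overridable everywhere.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import circuits as _circuits
from .extrinsic import (
    PATTERN_ORDER,
    SIGN_PATTERNS,
    SignPattern,
    corr_to_cov,
    diagonal_cov,
    random_correlation,
    signed_correlation,
)
from .network import ReactionNetwork
from .unscented import ParameterDistribution, UTConfig
from .variability import cv2, total_moments

__all__ = [
    "SweepResult",
    "CovarianceScreenResult",
    "feedback_sweep",
    "topology_compare",
    "covariance_screen",
    "run_config",
    "default_strength_grid",
]

#: circuit families known to the sweep machinery
FAMILIES = {
    "transcriptional": dict(builder="transcriptional_autoreg", strength="s_fb"),
    "post_transcriptional_same": dict(builder="post_transcriptional", strength="k_b"),
    "post_transcriptional_separate": dict(
        builder="post_transcriptional", strength="k_b"
    ),
    "hill_mirna": dict(builder="post_transcriptional_hill", strength="s_m"),
}


def default_strength_grid(
    lo: float = 1e-5, hi: float = 1.0, per_decade: int = 6
) -> np.ndarray:
    """Logarithmic feedback-strength grid, ``per_decade`` points per decade."""
    decades = math.log10(hi / lo)
    return np.logspace(math.log10(lo), math.log10(hi), int(round(decades * per_decade)) + 1)


def _build_family(family: str, hill, theta, circuit_kwargs) -> ReactionNetwork:
    if family not in FAMILIES:
        raise KeyError(f"unknown circuit family {family!r}; choose from {sorted(FAMILIES)}")
    kwargs = dict(circuit_kwargs or {})
    if family == "transcriptional":
        return _circuits.circuit_transcriptional_autoreg(
            theta, n=hill if hill is not None else 2, K=kwargs.pop("K", 1.0), **kwargs
        )
    if family == "hill_mirna":
        return _circuits.circuit_post_transcriptional_hill(
            theta, n_m=hill if hill is not None else 1, K_m=kwargs.pop("K_m", 1.0), **kwargs
        )
    mode = "same" if family.endswith("same") else "separate"
    return _circuits.circuit_post_transcriptional(theta, transcript_mode=mode, **kwargs)


def resolve_extrinsic(
    net: ReactionNetwork,
    spec,
    theta: Mapping[str, float] | None = None,
) -> ParameterDistribution | None:
    """Normalize an extrinsic-variability spec to a ParameterDistribution.

    Accepted forms: ``None`` (intrinsic only), a ready distribution, a
    mapping ``{param: cv}`` (independent, per-parameter coefficient of
    variation around the circuit's current value), or a tuple
    ``(names, cov)`` with an explicit covariance matrix.
    """
    if spec is None:
        return None
    if isinstance(spec, ParameterDistribution):
        return spec
    defaults = {**net.parameters, **net.initial_conditions, **(theta or {})}
    if isinstance(spec, Mapping):
        names = tuple(spec)
        mean = np.array([float(defaults[k]) for k in names])
        sds = np.array([float(spec[k]) * m for k, m in zip(names, mean)])
        return ParameterDistribution(names, mean, np.diag(sds**2))
    if isinstance(spec, tuple) and len(spec) == 2:
        names, cov = spec
        mean = np.array([float(defaults[k]) for k in names])
        return ParameterDistribution(tuple(names), mean, np.asarray(cov, dtype=float))
    raise TypeError(f"cannot interpret extrinsic spec {spec!r}")


@dataclass
class SweepResult:
    """Grid of relative-variability results, one row per sweep cell.

    Columns: family, hill, strength, extrinsic, when, cv2r, mean, var_total,
    var_intrinsic, var_extrinsic, cv2, status, reason.
    """

    table: pd.DataFrame
    species: str = "P"

    def ok(self) -> pd.DataFrame:
        return self.table[self.table.status == "ok"]

    def curve(self, **filters) -> pd.DataFrame:
        df = self.ok()
        for k, v in filters.items():
            df = df[df[k] == v]
        return df.sort_values("strength")

    def min_cv2r(self, **filters) -> float:
        return float(self.curve(**filters).cv2r.min())


def _sweep_cell(net, dist, strength_param, s, when, ut_config, base_theta, ref):
    theta = dict(base_theta or {})
    theta[strength_param] = float(s)
    res = total_moments(net, dist, when=when, ut_config=ut_config, theta=theta)
    out = net.meta.get("output", "P")
    c = res.cv2_of(out)
    return {
        "cv2r": c / ref,
        "mean": res.mean_of(out),
        "var_total": res.var_of(out),
        "var_intrinsic": res.var_of(out, "intrinsic"),
        "var_extrinsic": res.var_of(out, "extrinsic"),
        "cv2": c,
    }


def feedback_sweep(
    circuit_family: str,
    strength_grid: Sequence[float] | None = None,
    hill_values: Sequence[float] | None = None,
    extrinsic_specs: Mapping[str, object] | None = None,
    when: float | str = "steady_state",
    theta: Mapping[str, float] | None = None,
    ut_config: UTConfig | None = None,
    circuit_kwargs: Mapping | None = None,
) -> SweepResult:
    """CV^2_r of the output protein over a (hill x strength x extrinsic) grid.

    ``extrinsic_specs`` maps a label to a spec accepted by
    :func:`resolve_extrinsic`; ``None``/missing means intrinsic only.  The
    no-feedback reference (strength 0) is computed once per (extrinsic,
    when) cell — it does not depend on the Hill coefficient or strength.
    Per-cell failures are recorded with a reason; the sweep continues.
    """
    grid = (
        np.asarray(strength_grid, dtype=float)
        if strength_grid is not None
        else default_strength_grid()
    )
    if np.any(grid < 0):
        raise ValueError("feedback strengths must be >= 0")
    fam = FAMILIES[circuit_family] if circuit_family in FAMILIES else None
    if fam is None:
        raise KeyError(f"unknown circuit family {circuit_family!r}")
    strength_param = fam["strength"]
    hills = list(hill_values) if hill_values is not None else [None]
    specs = dict(extrinsic_specs) if extrinsic_specs else {"intrinsic": None}
    rows = []
    for hill in hills:
        net = _build_family(circuit_family, hill, theta, circuit_kwargs)
        out = net.meta.get("output", "P")
        refs = {}
        for label, spec in specs.items():
            dist = resolve_extrinsic(net, spec, theta)
            if dist is not None and strength_param in dist.names:
                raise ValueError(
                    f"extrinsic spec {label!r} must not vary the strength parameter"
                )
            try:
                ref_res = total_moments(
                    net, dist, when=when, ut_config=ut_config,
                    theta={**(theta or {}), strength_param: 0.0},
                )
                refs[label] = (dist, ref_res.cv2_of(out))
            except Exception as exc:
                refs[label] = (dist, exc)
        for label, (dist, ref) in refs.items():
            for s in grid:
                row = {
                    "family": circuit_family,
                    "hill": hill,
                    "strength": float(s),
                    "extrinsic": label,
                    "when": when,
                }
                if isinstance(ref, Exception):
                    row.update(status="failed", reason=f"reference: {ref}")
                    rows.append(row)
                    continue
                try:
                    row.update(
                        _sweep_cell(net, dist, strength_param, s, when, ut_config, theta, ref)
                    )
                    row.update(status="ok", reason="")
                except Exception as exc:
                    row.update(status="failed", reason=str(exc))
                rows.append(row)
    return SweepResult(pd.DataFrame(rows))


def topology_compare(
    circuit_specs: Mapping[str, Mapping],
    strength_grid: Sequence[float],
    extrinsic_specs: Mapping[str, object] | None = None,
    when: float | str = "steady_state",
    ut_config: UTConfig | None = None,
) -> dict[str, SweepResult]:
    """Paired sweeps over an identical strength grid for several topologies.

    ``circuit_specs`` maps a label to a dict with keys ``family`` and
    optionally ``hill``, ``theta``, ``circuit_kwargs``.  All results share
    the given grid so curves are directly comparable.
    """
    grid = np.asarray(strength_grid, dtype=float)
    out = {}
    for label, spec in circuit_specs.items():
        spec = dict(spec)
        family = spec.pop("family")
        out[label] = feedback_sweep(
            family,
            grid,
            hill_values=[spec.pop("hill", None)],
            extrinsic_specs=extrinsic_specs,
            when=when,
            theta=spec.pop("theta", None),
            ut_config=ut_config,
            circuit_kwargs=spec.pop("circuit_kwargs", None),
        )
        if spec:
            raise TypeError(f"unknown keys in circuit spec {label!r}: {sorted(spec)}")
    return out


@dataclass
class CovarianceScreenResult:
    """Sweeps under a family of extrinsic covariance matrices.

    ``results`` holds one SweepResult per matrix id (``diagonal``,
    ``pattern:<name>``, ``pattern:<name>:opposite``, ``random:<i>``);
    ``spread`` is the per-strength max-min range of CV^2_r across the random
    matrices.
    """

    results: dict[str, SweepResult]
    spread: pd.DataFrame
    correlations: dict[str, np.ndarray] = field(default_factory=dict)


def covariance_screen(
    circuit_family: str,
    strength_grid: Sequence[float],
    n_matrices: int = 10,
    sds: Mapping[str, float] | Sequence[float] | float = 0.1,
    seed: int = 0,
    hill: float | None = 2,
    pattern: str | SignPattern | None = None,
    when: float | str = "steady_state",
    theta: Mapping[str, float] | None = None,
    ut_config: UTConfig | None = None,
    circuit_kwargs: Mapping | None = None,
) -> CovarianceScreenResult:
    """Screen total variability across extrinsic correlation structures.

    The varied parameters are the four shared kinetic rates (k_R, k_P,
    gamma_R, gamma_P).  ``sds`` gives their standard deviations — a scalar is
    a common coefficient of variation, a sequence or mapping explicit sds.
    Screened matrices: the diagonal (independent) reference, the family's
    favourable sign pattern and its opposite, and ``n_matrices`` random
    correlation matrices.
    """
    if n_matrices < 1:
        raise ValueError("n_matrices must be >= 1")
    net = _build_family(circuit_family, hill, theta, circuit_kwargs)
    defaults = {**net.parameters, **net.initial_conditions, **(theta or {})}
    names = PATTERN_ORDER
    mean = np.array([float(defaults[k]) for k in names])
    if isinstance(sds, Mapping):
        sd = np.array([float(sds[k]) for k in names])
    elif np.isscalar(sds):
        sd = float(sds) * mean
    else:
        sd = np.asarray(sds, dtype=float)
    if pattern is None:
        pattern = (
            "transcriptional"
            if circuit_family == "transcriptional"
            else "post_transcriptional"
        )
    if isinstance(pattern, str):
        pat_name, pat = pattern, SIGN_PATTERNS[pattern]
    else:
        pat_name, pat = "custom", pattern
    corrs: dict[str, np.ndarray] = {"diagonal": np.eye(len(names))}
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_matrices + 2)
    corrs[f"pattern:{pat_name}"] = signed_correlation(pat, int(rng_seeds[0])).values
    opposite = SignPattern(
        np.where(np.eye(len(names), dtype=bool), 1.0, -pat.signs), pat.order
    )
    corrs[f"pattern:{pat_name}:opposite"] = signed_correlation(
        opposite, int(rng_seeds[1])
    ).values
    for i in range(n_matrices):
        corrs[f"random:{i}"] = random_correlation(
            len(names), int(rng_seeds[2 + i])
        ).values
    results = {}
    for label, R in corrs.items():
        dist = ParameterDistribution(names, mean, corr_to_cov(R, sd))
        results[label] = feedback_sweep(
            circuit_family,
            strength_grid,
            hill_values=[hill],
            extrinsic_specs={label: dist},
            when=when,
            theta=theta,
            ut_config=ut_config,
            circuit_kwargs=circuit_kwargs,
        )
    rand = [results[k].ok()[["strength", "cv2r"]] for k in corrs if k.startswith("random:")]
    if rand:
        cat = pd.concat(rand).groupby("strength").cv2r.agg(["min", "max"])
        spread = (cat["max"] - cat["min"]).rename("spread").reset_index()
    else:  # pragma: no cover
        spread = pd.DataFrame(columns=["strength", "spread"])
    return CovarianceScreenResult(results, spread, corrs)


# -- config-driven runner --------------------------------------------------

def _cfg_error(path: str, msg: str):
    raise ValueError(f"config error at {path}: {msg}")


def _parse_grid(spec, path) -> np.ndarray:
    if isinstance(spec, (list, tuple, np.ndarray)):
        return np.asarray(spec, dtype=float)
    if isinstance(spec, Mapping):
        try:
            lo, hi = float(spec["start"]), float(spec["stop"])
            num = int(spec.get("num", 13))
        except KeyError as exc:
            _cfg_error(path, f"grid missing key {exc}")
        if spec.get("log", True):
            return np.logspace(math.log10(lo), math.log10(hi), num)
        return np.linspace(lo, hi, num)
    _cfg_error(path, f"cannot interpret grid spec {spec!r}")


def run_config(path, out_dir=None, seed: int | None = None) -> dict:
    """Execute the experiments described in a YAML config file.

    Writes one CSV per experiment plus ``manifest.json`` (config hash, seed,
    per-experiment timings) and a plain-text log to ``out_dir`` (defaults to
    the config's directory).  Returns the manifest.  Schema violations are
    reported with their field path.
    """
    import os

    import yaml

    with open(path) as fh:
        raw = fh.read()
    cfg = yaml.safe_load(raw)
    if not isinstance(cfg, Mapping) or "experiments" not in cfg:
        _cfg_error("<root>", "config must be a mapping with an 'experiments' list")
    out_dir = out_dir or os.path.dirname(os.path.abspath(path))
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    manifest = {
        "config": os.path.abspath(path),
        "config_sha256": hashlib.sha256(raw.encode()).hexdigest(),
        "seed": seed,
        "outputs": [],
    }
    log_lines = []
    for i, exp in enumerate(cfg["experiments"]):
        p = f"experiments[{i}]"
        if not isinstance(exp, Mapping):
            _cfg_error(p, "experiment must be a mapping")
        kind = exp.get("kind")
        name = exp.get("name", f"exp{i}")
        t0 = time.time()
        if kind == "total":
            circuit = exp.get("circuit", "single_gene")
            if circuit not in _circuits.CIRCUITS:
                _cfg_error(f"{p}.circuit", f"unknown circuit {circuit!r}")
            net = _circuits.build_circuit(
                circuit, exp.get("theta"), **(exp.get("circuit_kwargs") or {})
            )
            dist = resolve_extrinsic(net, exp.get("extrinsic"), exp.get("theta"))
            res = total_moments(net, dist, when=exp.get("when", "steady_state"))
            out_path = os.path.join(out_dir, f"{name}.json")
            with open(out_path, "w") as fh:
                json.dump(res.to_dict(), fh, indent=1)
        elif kind == "moments":
            circuit = exp.get("circuit", "single_gene")
            if circuit not in _circuits.CIRCUITS:
                _cfg_error(f"{p}.circuit", f"unknown circuit {circuit!r}")
            from .lna import integrate_lna

            net = _circuits.build_circuit(
                circuit, exp.get("theta"), **(exp.get("circuit_kwargs") or {})
            )
            t_grid = _parse_grid(exp.get("t_grid", {"start": 1e-3, "stop": 100.0}), f"{p}.t_grid")
            traj = integrate_lna(net, t_grid=np.concatenate([[0.0], t_grid]))
            out_path = os.path.join(out_dir, f"{name}.csv")
            traj.to_frame().to_csv(out_path, index=False)
        elif kind == "ssa":
            from .ssa import ensemble_moments

            circuit = exp.get("circuit", "single_gene")
            if circuit not in _circuits.CIRCUITS:
                _cfg_error(f"{p}.circuit", f"unknown circuit {circuit!r}")
            net = _circuits.build_circuit(
                circuit, exp.get("theta"), **(exp.get("circuit_kwargs") or {})
            )
            t_pts = _parse_grid(exp.get("t_points", [1.0, 10.0]), f"{p}.t_points")
            summ = ensemble_moments(
                net, t_points=t_pts, n_runs=int(exp.get("n_runs", 1000)), seed=seed
            )
            out_path = os.path.join(out_dir, f"{name}.csv")
            summ.to_frame().to_csv(out_path, index=False)
        elif kind == "sweep":
            family = exp.get("circuit_family", "transcriptional")
            if family not in FAMILIES:
                _cfg_error(f"{p}.circuit_family", f"unknown family {family!r}")
            res = feedback_sweep(
                family,
                _parse_grid(exp.get("strengths", {"start": 1e-5, "stop": 1.0}), f"{p}.strengths"),
                hill_values=exp.get("hill"),
                extrinsic_specs=exp.get("extrinsic"),
                when=exp.get("when", "steady_state"),
                theta=exp.get("theta"),
                circuit_kwargs=exp.get("circuit_kwargs"),
            )
            out_path = os.path.join(out_dir, f"{name}.csv")
            res.table.to_csv(out_path, index=False)
        elif kind == "cov_screen":
            family = exp.get("circuit_family", "transcriptional")
            if family not in FAMILIES:
                _cfg_error(f"{p}.circuit_family", f"unknown family {family!r}")
            scr = covariance_screen(
                family,
                _parse_grid(exp.get("strengths", {"start": 1e-5, "stop": 1.0}), f"{p}.strengths"),
                n_matrices=int(exp.get("n_matrices", 5)),
                sds=exp.get("sds", 0.1),
                seed=seed,
                hill=exp.get("hill", 2),
                when=exp.get("when", "steady_state"),
                theta=exp.get("theta"),
            )
            cat = pd.concat(
                [r.table.assign(matrix=k) for k, r in scr.results.items()]
            )
            out_path = os.path.join(out_dir, f"{name}.csv")
            cat.to_csv(out_path, index=False)
        else:
            _cfg_error(f"{p}.kind", f"unknown experiment kind {kind!r}")
        dt = time.time() - t0
        manifest["outputs"].append({"name": name, "kind": kind, "path": out_path, "seconds": round(dt, 3)})
        log_lines.append(f"{name} ({kind}): wrote {out_path} in {dt:.2f}s")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return manifest
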