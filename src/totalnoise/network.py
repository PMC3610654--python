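"""Reaction-network definition and validation.

A :class:`ReactionNetwork` bundles the pieces every downstream analysis
consumes: an ordered species list, an integer stoichiometry matrix (one row
per species, one column per reaction), one rate law per reaction, positive
parameter defaults, and non-negative initial conditions.  Rate laws are
arithmetic expressions over declared symbols with a single built-in,
``hill_repress(x, K, n) = 1 / (1 + (x/K)**n)``, the quasi-steady-state
repressing Hill term.

Units follow the molecule-number convention: zeroth-order rates in
molecules/s, first-order in 1/s, second-order in 1/(molecule*s).  The system
size Omega defaults to 1 so means and covariances are carried directly in
molecule numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy
from sympy.parsing.sympy_parser import parse_expr


class NetworkSpecError(ValueError):
    """A network definition violates a structural invariant."""


def _hill_repress(x, K, n):
    # expands immediately during parsing; kept as the only "builtin"
    return 1 / (1 + (x / K) ** n)


@dataclass(frozen=True)
class RateLaw:
    """A reaction propensity: a sympy expression plus its source text."""

    expression: sympy.Expr
    source: str

    @classmethod
    def parse(cls, text: str | sympy.Expr, allowed: Iterable[str]) -> "RateLaw":
        """Parse ``text`` allowing only the declared symbol names.

        Raises :class:`NetworkSpecError` naming the first undeclared symbol.
        """
        allowed = set(allowed)
        if isinstance(text, sympy.Expr):
            expr, source = text, str(text)
        else:
            local = {name: sympy.Symbol(name) for name in allowed}
            local["hill_repress"] = _hill_repress
            # restricted globals: undeclared names become plain Symbols
            # instead of resolving to sympy's module namespace
            globs = {
                "Symbol": sympy.Symbol,
                "Integer": sympy.Integer,
                "Float": sympy.Float,
                "Rational": sympy.Rational,
            }
            try:
                expr = parse_expr(
                    text, local_dict=local, global_dict=globs, evaluate=True
                )
            except Exception as exc:  # pragma: no cover - sympy message varies
                raise NetworkSpecError(f"cannot parse rate law {text!r}: {exc}") from exc
            source = text
        expr = sympy.sympify(expr)
        for sym in sorted(expr.free_symbols, key=str):
            if str(sym) not in allowed:
                raise NetworkSpecError(
                    f"rate law {source!r} references undeclared symbol {str(sym)!r}"
                )
        return cls(expr, source)

    def __str__(self) -> str:
        return self.source


@dataclass
class ReactionNetwork:
    """A validated reaction network in molecule-number units.

    Attributes
    ----------
    species : tuple of str
        Canonical species order; rows of ``stoichiometry``.
    stoichiometry : ndarray (n_species, n_reactions) of int
        Net molecule-count change of each species per reaction firing.
    rate_laws : tuple of RateLaw
        One propensity per reaction (column).
    parameters : dict
        Positive kinetic parameter defaults.
    initial_conditions : dict
        Non-negative defaults for species counts and for declared
        initial-condition symbols (e.g. gene copy number ``D0``) that may
        appear in rate laws without being dynamic species.
    system_size : float
        Omega > 0; 1 by default (molecule-number convention).
    meta : dict
        Free-form circuit annotations (family, Hill coefficient, the name of
        the feedback-strength parameter, output species).
    """

    species: tuple[str, ...]
    stoichiometry: np.ndarray
    rate_laws: tuple[RateLaw, ...]
    parameters: dict[str, float]
    initial_conditions: dict[str, float]
    system_size: float = 1.0
    reaction_names: tuple[str, ...] | None = None
    meta: dict = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- derived views ----------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.rate_laws)

    @property
    def constant_names(self) -> tuple[str, ...]:
        """Parameter names followed by non-species initial-condition symbols."""
        extra = [k for k in self.initial_conditions if k not in self.species]
        return tuple(self.parameters) + tuple(extra)

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def constants_vector(self, theta: Mapping[str, float] | None = None) -> np.ndarray:
        """Numeric values for :attr:`constant_names`, overridden by ``theta``.

        Entries of ``theta`` naming species are ignored here (they override
        initial counts instead, see :meth:`initial_state`).
        """
        defaults = dict(self.parameters)
        for k in self.initial_conditions:
            if k not in self.species:
                defaults[k] = self.initial_conditions[k]
        if theta:
            for k, v in theta.items():
                if k in defaults:
                    defaults[k] = float(v)
                elif k not in self.species:
                    raise KeyError(f"unknown parameter {k!r}")
        missing = [k for k, v in defaults.items() if v is None]
        if missing:
            raise KeyError(f"missing parameter value(s): {missing}")
        return np.array([defaults[k] for k in self.constant_names], dtype=float)

    def initial_state(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        """Initial species counts (absent species default to 0)."""
        x0 = np.array(
            [float(self.initial_conditions.get(s, 0.0)) for s in self.species]
        )
        if overrides:
            for k, v in overrides.items():
                if k in self.species:
                    x0[self.species_index(k)] = float(v)
        if np.any(x0 < 0):
            raise NetworkSpecError("negative initial species count")
        return x0

    def split_theta(
        self, theta: Mapping[str, float] | None
    ) -> tuple[dict[str, float], dict[str, float]]:
        """Split a name->value map into (constant overrides, species-IC overrides)."""
        consts, ics = {}, {}
        if theta:
            known = set(self.constant_names)
            for k, v in theta.items():
                if k in self.species:
                    ics[k] = v
                elif k in known:
                    consts[k] = v
                else:
                    raise KeyError(f"unknown symbol {k!r} for this network")
        return consts, ics


def make_network(
    species: Sequence[str],
    stoichiometry,
    rate_laws: Sequence[str | sympy.Expr | RateLaw],
    parameters: Mapping[str, float],
    initial_conditions: Mapping[str, float] | None = None,
    system_size: float = 1.0,
    reaction_names: Sequence[str] | None = None,
    meta: Mapping | None = None,
) -> ReactionNetwork:
    """Validate the pieces and assemble a :class:`ReactionNetwork`.

    Raises
    ------
    NetworkSpecError
        On dimension mismatch, non-integer stoichiometry, undeclared rate-law
        symbols, non-positive system size, or negative initial conditions —
        each message names the offending reaction or symbol.
    """
    species = tuple(str(s) for s in species)
    if len(set(species)) != len(species):
        raise NetworkSpecError("duplicate species names")
    S = np.asarray(stoichiometry)
    if S.ndim != 2 or S.shape[0] != len(species):
        raise NetworkSpecError(
            f"stoichiometry must be (n_species={len(species)}, n_reactions); got {S.shape}"
        )
    if not np.all(np.equal(np.mod(S, 1), 0)):
        raise NetworkSpecError("stoichiometry entries must be integers")
    S = S.astype(np.int64)
    if S.shape[1] != len(rate_laws):
        raise NetworkSpecError(
            f"{S.shape[1]} stoichiometry columns but {len(rate_laws)} rate laws"
        )
    if not system_size > 0:
        raise NetworkSpecError(f"system size must be positive, got {system_size}")
    initial_conditions = dict(initial_conditions or {})
    parameters = {str(k): float(v) for k, v in parameters.items()}
    for k, v in parameters.items():
        if not v > 0:
            raise NetworkSpecError(f"parameter {k!r} must be positive, got {v}")
    for k, v in initial_conditions.items():
        if float(v) < 0:
            raise NetworkSpecError(f"initial condition {k!r} must be non-negative")
    allowed = set(species) | set(parameters) | set(initial_conditions) | {"Omega"}
    laws = []
    for j, law in enumerate(rate_laws):
        if isinstance(law, RateLaw):
            laws.append(RateLaw.parse(law.expression, allowed))
        else:
            try:
                laws.append(RateLaw.parse(law, allowed))
            except NetworkSpecError as exc:
                raise NetworkSpecError(f"reaction {j}: {exc}") from None
    names = tuple(reaction_names) if reaction_names is not None else None
    if names is not None and len(names) != len(laws):
        raise NetworkSpecError("reaction_names length mismatch")
    return ReactionNetwork(
        species=species,
        stoichiometry=S,
        rate_laws=tuple(laws),
        parameters=parameters,
        initial_conditions={str(k): float(v) for k, v in initial_conditions.items()},
        system_size=float(system_size),
        reaction_names=names,
        meta=dict(meta or {}),
    )


# -- symbolic compilation -------------------------------------------------

def _compiled(net: ReactionNetwork):
    """Lambdified propensity vector and drift Jacobian, cached per network.

    Returns (f, jac) with signature ``f(x, c) -> (n_reactions,)`` and
    ``jac(x, c) -> (n_species, n_species)`` where ``x`` is the species vector
    and ``c`` the :meth:`ReactionNetwork.constants_vector`.
    """
    key = "compiled"
    if key in net._cache:
        return net._cache[key]
    xs = [sympy.Symbol(s) for s in net.species]
    cs = [sympy.Symbol(c) for c in net.constant_names]
    omega = sympy.Symbol("Omega")
    subs = {omega: net.system_size}
    f_vec = sympy.Matrix([law.expression.subs(subs) for law in net.rate_laws])
    S = sympy.Matrix(net.stoichiometry)
    drift = (S * f_vec).jacobian(xs)
    f_fn = sympy.lambdify((xs, cs), list(f_vec), modules="numpy")
    jac_fn = sympy.lambdify((xs, cs), drift, modules="numpy")
    net._cache[key] = (f_fn, jac_fn)
    return net._cache[key]


def evaluate_propensities(
    net: ReactionNetwork, state, theta: Mapping[str, float] | None = None
) -> np.ndarray:
    """Evaluate all reaction propensities at ``state``.

    ``state`` is a non-negative species-value vector in canonical order;
    ``theta`` optionally overrides parameter / initial-condition-symbol values.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (net.n_species,):
        raise NetworkSpecError(
            f"state must have shape ({net.n_species},), got {x.shape}"
        )
    if np.any(x < 0):
        bad = net.species[int(np.argmin(x))]
        raise NetworkSpecError(f"negative state component for species {bad!r}")
    c = net.constants_vector(theta)
    f_fn, _ = _compiled(net)
    return np.asarray(f_fn(x, c), dtype=float)


# -- config-file loading --------------------------------------------------

def network_from_config(source) -> ReactionNetwork:
    """Build a network from a YAML/JSON config file, path, or parsed dict.

    Schema::

        species: [R, P]
        reactions:
          - name: transcription
            stoich: {R: 1}
            rate: "k_R * D0"
        parameters: {k_R: 1.0, ...}
        initial_conditions: {D0: 1, R: 0, P: 0}
        system_size: 1.0
    """
    import io
    import os

    import yaml

    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    elif isinstance(source, str):
        cfg = yaml.safe_load(io.StringIO(source))
    elif isinstance(source, Mapping):
        cfg = dict(source)
    else:
        raise NetworkSpecError(f"cannot interpret network config source {source!r}")
    for field_name in ("species", "reactions", "parameters"):
        if field_name not in cfg:
            raise NetworkSpecError(f"config missing required key {field_name!r}")
    species = list(cfg["species"])
    rxns = cfg["reactions"]
    S = np.zeros((len(species), len(rxns)), dtype=np.int64)
    laws, names = [], []
    for j, rxn in enumerate(rxns):
        if "rate" not in rxn:
            raise NetworkSpecError(f"reactions[{j}] missing 'rate'")
        for sp, dn in (rxn.get("stoich") or {}).items():
            if sp not in species:
                raise NetworkSpecError(
                    f"reactions[{j}].stoich references unknown species {sp!r}"
                )
            S[species.index(sp), j] = int(dn)
        laws.append(str(rxn["rate"]))
        names.append(str(rxn.get("name", f"r{j}")))
    return make_network(
        species,
        S,
        laws,
        cfg["parameters"],
        cfg.get("initial_conditions") or {},
        float(cfg.get("system_size", 1.0)),
        reaction_names=names,
        meta=cfg.get("meta") or {},
    )
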