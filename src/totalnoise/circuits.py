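"""The gene-circuit library: five self-repression topologies.

All circuits express a protein P from an mRNA R transcribed off D0 gene
copies, and differ in how (and whether) the output feeds back on its own
expression:

* ``single_gene`` — no feedback; the reference for every relative measure.
* ``transcriptional_autoreg`` — P represses its own transcription through a
  repressing Hill function with cooperativity n and dissociation constant K.
  Feedback strength is conventionally s = 1/K, stored as the rate-law
  parameter ``s_fb`` so s = 0 reduces the propensities exactly to the
  single-gene circuit.
* ``post_transcriptional`` — a miRNA M binds R into a complex C_RM which can
  unbind or undergo miRNA-induced mRNA degradation at rate g_c (mRNA
  destroyed, miRNA recycled).  Feedback strength is the binding rate k_b.
  ``transcript_mode`` chooses whether R and M are co-produced on one
  transcript or transcribed independently.
* ``post_transcriptional_hill`` — a coarse-grained miRNA model: M represses
  translation through a Hill function with cooperativity n_m and constant
  K_m (strength s_m = 1/K_m); no explicit complex.

Default rates keep steady-state counts in the tens-to-thousands where the
linear noise approximation is accurate; all are overridable per call.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .network import ReactionNetwork, make_network

#: Repository default kinetic parameters (molecule-number units).
DEFAULT_THETA: dict[str, float] = {
    "k_R": 1.0,      # transcription, molecules/s
    "k_P": 1.0,      # translation, 1/s
    "gamma_R": 0.1,  # mRNA degradation, 1/s
    "gamma_P": 0.01, # protein degradation, 1/s
    "gamma_M": 0.1,  # free-miRNA degradation, 1/s
    "k_b": 0.01,     # miRNA-mRNA binding, 1/(molecule*s)
    "k_u": 1.0,      # complex unbinding, 1/s
    "k_M": 1.0,      # miRNA transcription (separate-transcript mode), molecules/s
    "g_c": 0.1,      # miRNA-induced mRNA degradation, 1/s
    "D0": 1.0,       # gene copy number (initial-condition symbol)
}


def _theta(theta: Mapping[str, float] | None, keys) -> dict[str, float]:
    merged = {k: DEFAULT_THETA[k] for k in keys}
    if theta:
        for k, v in theta.items():
            if k in merged:
                merged[k] = float(v)
    missing = [k for k in keys if k not in merged]
    if missing:
        raise KeyError(f"missing circuit parameter(s): {missing}")
    return merged


def circuit_single_gene(theta: Mapping[str, float] | None = None) -> ReactionNetwork:
    """Constitutive two-stage gene expression: transcription, translation,
    first-order mRNA and protein degradation."""
    th = _theta(theta, ("k_R", "k_P", "gamma_R", "gamma_P", "D0"))
    d0 = th.pop("D0")
    return make_network(
        species=("R", "P"),
        stoichiometry=[[1, 0, -1, 0], [0, 1, 0, -1]],
        rate_laws=["k_R * D0", "k_P * R", "gamma_R * R", "gamma_P * P"],
        parameters=th,
        initial_conditions={"D0": d0, "R": 0.0, "P": 0.0},
        reaction_names=("transcription", "translation", "mRNA_deg", "protein_deg"),
        meta={"family": "single_gene", "output": "P"},
    )


def circuit_transcriptional_autoreg(
    theta: Mapping[str, float] | None = None,
    n: float = 2,
    K: float = 100.0,
) -> ReactionNetwork:
    """Single gene with transcriptional self-repression.

    Transcription propensity k_R * D0 * hill_repress(P, K, n); the feedback
    strength s = 1/K is stored as the parameter ``s_fb`` (s = 0 <=> K = inf
    recovers the single-gene circuit propensity-by-propensity).
    """
    if not n > 0:
        raise ValueError(f"Hill coefficient must be positive, got {n}")
    if not K > 0:
        raise ValueError(f"dissociation constant must be positive, got {K}")
    th = _theta(theta, ("k_R", "k_P", "gamma_R", "gamma_P", "D0"))
    d0 = th.pop("D0")
    s = 0.0 if math.isinf(K) else 1.0 / K
    n = int(n) if float(n).is_integer() else float(n)
    net = make_network(
        species=("R", "P"),
        stoichiometry=[[1, 0, -1, 0], [0, 1, 0, -1]],
        rate_laws=[
            f"k_R * D0 / (1 + (s_fb * P)**{n})",
            "k_P * R",
            "gamma_R * R",
            "gamma_P * P",
        ],
        parameters={**th, "s_fb": max(s, 1.0)},
        initial_conditions={"D0": d0, "R": 0.0, "P": 0.0},
        reaction_names=("transcription", "translation", "mRNA_deg", "protein_deg"),
        meta={
            "family": "transcriptional_autoreg",
            "hill": n,
            "strength_param": "s_fb",
            "output": "P",
        },
    )
    # the strength may legitimately be 0 (no feedback) but make_network
    # enforces positive parameters; set the true value afterwards
    net.parameters["s_fb"] = s
    net._cache.clear()
    return net


def circuit_post_transcriptional(
    theta: Mapping[str, float] | None = None,
    transcript_mode: str = "same",
    g_c: float | None = None,
) -> ReactionNetwork:
    """Mechanistic miRNA repression with explicit miRNA-mRNA complex.

    Species (R, M, C_RM, P).  The complex is not translated and has no
    spontaneous decay; it either unbinds (k_u) or degrades its mRNA while
    recycling the miRNA (g_c).  In ``same`` transcript mode R and M are
    produced by one reaction (correlated bursts); in ``separate`` mode by two
    independent reactions (k_R and k_M).
    """
    if transcript_mode not in ("same", "separate"):
        raise ValueError(f"unknown transcript_mode {transcript_mode!r}")
    keys = ["k_R", "k_P", "gamma_R", "gamma_P", "gamma_M", "k_b", "k_u", "g_c", "D0"]
    if transcript_mode == "separate":
        keys.append("k_M")
    th = _theta(theta, keys)
    if g_c is not None:
        if g_c < 0:
            raise ValueError(f"g_c must be non-negative, got {g_c}")
        th["g_c"] = float(g_c)
    d0 = th.pop("D0")
    species = ("R", "M", "C_RM", "P")
    cols = {  # (dR, dM, dC_RM, dP) per reaction
        "binding": ([-1, -1, 1, 0], "k_b * R * M"),
        "unbinding": ([1, 1, -1, 0], "k_u * C_RM"),
        "induced_deg": ([0, 1, -1, 0], "g_c * C_RM"),
        "mRNA_deg": ([-1, 0, 0, 0], "gamma_R * R"),
        "miRNA_deg": ([0, -1, 0, 0], "gamma_M * M"),
        "translation": ([0, 0, 0, 1], "k_P * R"),
        "protein_deg": ([0, 0, 0, -1], "gamma_P * P"),
    }
    if transcript_mode == "same":
        head = {"transcription": ([1, 1, 0, 0], "k_R * D0")}
    else:
        head = {
            "transcription_R": ([1, 0, 0, 0], "k_R * D0"),
            "transcription_M": ([0, 1, 0, 0], "k_M * D0"),
        }
    rxns = {**head, **cols}
    S = np.array([c for c, _ in rxns.values()]).T
    # k_b (the feedback strength) and g_c may legitimately be zero; keep them
    # out of make_network's positivity check and reinsert afterwards.
    gc_val = th.pop("g_c")
    kb_val = th.pop("k_b")
    if gc_val < 0 or kb_val < 0:
        raise ValueError("k_b and g_c must be non-negative")
    net = make_network(
        species=species,
        stoichiometry=S,
        rate_laws=[r for _, r in rxns.values()],
        parameters={**th, "k_b": max(kb_val, 1.0), "g_c": max(gc_val, 1.0)},
        initial_conditions={"D0": d0, "R": 0.0, "M": 0.0, "C_RM": 0.0, "P": 0.0},
        reaction_names=tuple(rxns),
        meta={
            "family": f"post_transcriptional_{transcript_mode}",
            "strength_param": "k_b",
            "output": "P",
        },
    )
    net.parameters["k_b"] = float(kb_val)
    net.parameters["g_c"] = float(gc_val)
    net._cache.clear()
    return net


def circuit_post_transcriptional_hill(
    theta: Mapping[str, float] | None = None,
    n_m: float = 1,
    K_m: float = 100.0,
    transcript_mode: str = "same",
) -> ReactionNetwork:
    """Hill-function miRNA repression of translation (no explicit complex).

    Species (R, M, P); translation propensity k_P * R * hill_repress(M, K_m,
    n_m); linear degradations.  The default ``same`` transcript mode
    co-produces R and M in one reaction at k_R * D0, the coarse-grained
    counterpart of the same-transcript self-repression design; ``separate``
    transcribes M independently at k_M * D0 (which removes the feedback and
    leaves only open-loop repression).  Strength s_m = 1/K_m; s_m = 0
    reduces to the single gene plus an uncoupled miRNA birth-death process.
    """
    if not n_m > 0:
        raise ValueError(f"Hill coefficient must be positive, got {n_m}")
    if not K_m > 0:
        raise ValueError(f"K_m must be positive, got {K_m}")
    if transcript_mode not in ("same", "separate"):
        raise ValueError(f"unknown transcript_mode {transcript_mode!r}")
    keys = ["k_R", "k_P", "gamma_R", "gamma_M", "gamma_P", "D0"]
    if transcript_mode == "separate":
        keys.insert(1, "k_M")
    th = _theta(theta, keys)
    d0 = th.pop("D0")
    s = 0.0 if math.isinf(K_m) else 1.0 / K_m
    n_m = int(n_m) if float(n_m).is_integer() else float(n_m)
    translation = f"k_P * R / (1 + (s_m * M)**{n_m})"
    if transcript_mode == "same":
        head_S = [[1], [1], [0]]
        head_rates, head_names = ["k_R * D0"], ["transcription"]
    else:
        head_S = [[1, 0], [0, 1], [0, 0]]
        head_rates = ["k_R * D0", "k_M * D0"]
        head_names = ["transcription_R", "transcription_M"]
    tail_S = [[0, -1, 0, 0], [0, 0, -1, 0], [1, 0, 0, -1]]
    S = np.hstack([np.array(head_S), np.array(tail_S)])
    net = make_network(
        species=("R", "M", "P"),
        stoichiometry=S,
        rate_laws=head_rates
        + [translation, "gamma_R * R", "gamma_M * M", "gamma_P * P"],
        parameters={**th, "s_m": max(s, 1.0)},
        initial_conditions={"D0": d0, "R": 0.0, "M": 0.0, "P": 0.0},
        reaction_names=tuple(
            head_names + ["translation", "mRNA_deg", "miRNA_deg", "protein_deg"]
        ),
        meta={
            "family": "post_transcriptional_hill",
            "hill": n_m,
            "strength_param": "s_m",
            "output": "P",
        },
    )
    net.parameters["s_m"] = s
    net._cache.clear()
    return net


#: Circuit constructors addressable by name (config files, CLI).
CIRCUITS = {
    "single_gene": circuit_single_gene,
    "transcriptional_autoreg": circuit_transcriptional_autoreg,
    "post_transcriptional": circuit_post_transcriptional,
    "post_transcriptional_hill": circuit_post_transcriptional_hill,
}


def build_circuit(name: str, theta: Mapping[str, float] | None = None, **kwargs) -> ReactionNetwork:
    """Build a library circuit by name with parameter overrides."""
    if name not in CIRCUITS:
        raise KeyError(
            f"unknown circuit {name!r}; available: {sorted(CIRCUITS)}"
        )
    return CIRCUITS[name](theta, **kwargs)
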