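"""Gene-expression rate laws: promoter logic, transcription and translation.

Each gene j carries an mRNA balance dm/dt = rT*u + lambda - (mu + theta_m) m
and a protein balance dp/dt = rX - (mu + theta_p) p, where the kinetic
transcription limit rT and translation rate rX are corrected by the ratio of
a characteristic sequence length to the gene's own length, and the promoter
control term u in [0, 1] is the weighted fraction of promoter configurations
that produce expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .network import GeneRecord, GlobalParameters, NetworkModel

__all__ = [
    "hill_transfer",
    "promoter_control",
    "ControlEvaluation",
    "transcription_kinetic_limit",
    "constitutive_rate",
    "translation_rate",
    "expression_rhs",
]


def hill_transfer(x, K: float, eta: float):
    """Hill transfer function x^eta / (K^eta + x^eta), in [0, 1].

    ``x`` is an effector concentration (nM), ``K`` the half-saturation
    constant (nM) and ``eta`` the cooperativity.  Monotone nondecreasing in
    ``x``; 0 at x = 0 and 1/2 at x = K for any eta.
    """
    if K <= 0:
        raise ValueError("half-saturation K must be > 0")
    if eta <= 0:
        raise ValueError("cooperativity eta must be > 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("effector concentration must be >= 0")
    # compute in ratio form for numerical stability at large x
    with np.errstate(over="ignore"):
        r = (x / K) ** eta
    out = np.where(np.isinf(r), 1.0, r / (1.0 + r))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ControlEvaluation:
    """Promoter-control term of one gene, with its weighted transfer terms."""

    target: str
    numerator_terms: list[tuple[float, float]]    # (weight, transfer value)
    denominator_terms: list[tuple[float, float]]  # (weight, transfer value)
    value: float


def promoter_control(
    gene: str,
    regulator_levels: Mapping[str, float],
    model: NetworkModel,
) -> ControlEvaluation:
    """Evaluate the promoter-occupancy control term u_j for one gene.

    u_j = (W_basal + sum_n W_n f_n) / (1 + W_basal + sum_n W_n f_n
    + sum_d W_d f_d) where n runs over activation edges and d over repression
    edges.  A gene with no declared regulators is constitutive: u_j = 1.
    ``regulator_levels`` maps effector names (gene protein or activated
    species) to concentrations in nM.
    """
    record = model.gene(gene)
    edges = model.regulators_of(gene)
    if not edges:
        return ControlEvaluation(gene, [], [], 1.0)
    num_terms: list[tuple[float, float]] = []
    den_terms: list[tuple[float, float]] = []
    for e in edges:
        if e.effector not in regulator_levels:
            raise KeyError(
                f"no level supplied for regulator {e.effector!r} of gene {gene!r}")
        f = hill_transfer(regulator_levels[e.effector], e.half_saturation, e.cooperativity)
        if e.sign == "activation":
            num_terms.append((e.weight, f))
            den_terms.append((e.weight, f))
        else:
            den_terms.append((e.weight, f))
    w0 = record.basal_weight
    num = w0 + sum(w * f for w, f in num_terms)
    den = 1.0 + w0 + sum(w * f for w, f in den_terms)
    return ControlEvaluation(gene, num_terms, den_terms, num / den)


def transcription_kinetic_limit(gene: GeneRecord, params: GlobalParameters) -> float:
    """Kinetic limit of transcription, copies/hr.

    rT_bar = kT * R1 * (L_T0 / L_Tj) * (G_j / (K_T + G_j)); zero for a
    knocked-out gene (G_j = 0).
    """
    v_max = params.k_T * params.rnap_copies
    return v_max * (params.L_T0 / gene.gene_length_nt) * (
        gene.gene_copies / (params.K_T + gene.gene_copies))


def constitutive_rate(gene: GeneRecord, params: GlobalParameters) -> float:
    """Constitutive expression rate lambda_j = rT_bar * W_basal/(1 + W_basal)."""
    w0 = gene.basal_weight
    return transcription_kinetic_limit(gene, params) * w0 / (1.0 + w0)


def translation_rate(gene: GeneRecord, mrna: float, params: GlobalParameters) -> float:
    """Translation rate rX = kX * R2 * (L_X0/L_Xj) * m/(K_X + m), copies/hr."""
    if np.any(np.asarray(mrna) < 0):
        raise ValueError("mRNA abundance must be >= 0")
    v_max = params.k_X * params.ribosome_copies
    return v_max * (params.L_X0 / gene.transcript_length_nt) * mrna / (params.K_X + mrna)


def expression_rhs(
    state: Mapping[str, float] | np.ndarray,
    model: NetworkModel,
    signals: Mapping[str, float],
) -> np.ndarray:
    """Time derivatives of all mRNA and protein balances at ``state``.

    ``state`` is either a full state vector ordered per ``model.state_index``
    (activated-species slots ignored in favour of ``signals``) or a mapping
    of state names to values; ``signals`` supplies the activated-species
    levels (nM) that feed the promoter transfer functions.

    This is the reference (per-gene, dictionary-driven) evaluation used for
    validation; the integrator uses a vectorized equivalent
    (:mod:`atranet.simulate`).
    """
    genes = model.genes
    G = len(genes)
    if isinstance(state, Mapping):
        m = np.array([state[f"{g.name}_mRNA"] for g in genes], dtype=float)
        p = np.array([state[f"{g.name}_protein"] for g in genes], dtype=float)
    else:
        arr = np.asarray(state, dtype=float)
        m, p = arr[:G].copy(), arr[G:2 * G].copy()
    if np.any(np.isnan(m)) or np.any(np.isnan(p)):
        raise ValueError("NaN in state vector")
    params = model.parameters

    levels = {g.name: p[i] * params.nM_per_copy for i, g in enumerate(genes)}
    levels.update(signals)

    dm = np.empty(G)
    dp = np.empty(G)
    for i, g in enumerate(genes):
        u = promoter_control(g.name, levels, model).value
        r_t = transcription_kinetic_limit(g, params) * u
        lam = constitutive_rate(g, params)
        dm[i] = r_t + lam - (params.mu + params.theta_m) * max(m[i], 0.0)
        r_x = translation_rate(g, max(m[i], 0.0), params)
        dp[i] = r_x - (params.mu + params.theta_p) * max(p[i], 0.0)
    return np.concatenate([dm, dp])
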