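"""Signal-initiation layer: ATRA sensing, signalsome and cRaf-pS621 kinetics.

ATRA above a critical threshold activates the Trigger (RAR/RXR) complex with
gain alpha; the signalsome (tracked by BLR1 protein abundance) drives
cRaf-S621 phosphorylation, and activated cRaf in turn feeds back onto the
BLR1 promoter.  Deactivation (phosphatase) reactions are neglected: activated
species are removed only by dilution (mu) and non-specific decay
(k_d = 0.1 mu), so the pseudo-steady-state (PSS) closure is
x* = r+ / (mu + k_d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import GlobalParameters, NetworkModel, SIGNAL_SPECIES

__all__ = [
    "SignalingState",
    "trigger_activation",
    "inhibitor_control",
    "craf_generation_rate",
    "integrate_rule",
    "signaling_generation_rates",
    "pss_solve",
    "PSSConvergenceError",
]


@dataclass(frozen=True)
class SignalingState:
    """Activated-species concentrations (nM) plus the applied inputs."""

    activated_trigger: float
    signalsome: float
    craf_ps621: float
    atra: float          # uM
    inhibitor: float     # nM

    def as_dict(self) -> dict[str, float]:
        return {
            "Trigger_active": self.activated_trigger,
            "signalsome": self.signalsome,
            "cRaf_pS621": self.craf_ps621,
        }


def trigger_activation(trigger_protein: float, atra: float, params: GlobalParameters) -> float:
    """Activated Trigger level (nM) given total Trigger protein (nM) and ATRA (uM).

    Zero below the differentiation threshold; above it,
    x_a = x_u * alpha*A / (1 + alpha*A).  Always <= trigger_protein.
    """
    if trigger_protein < 0 or atra < 0:
        raise ValueError("trigger protein and ATRA must be >= 0")
    if atra < params.atra_threshold:
        return 0.0
    a = params.alpha_gain * atra
    return trigger_protein * a / (1.0 + a)


def inhibitor_control(inhibitor: float, K_D: float) -> float:
    """MAPK-inhibitor control factor v = 1 - I/(K_D + I), in [0, 1]."""
    if inhibitor < 0 or K_D < 0:
        raise ValueError("inhibitor concentration and K_D must be >= 0")
    return 1.0 - inhibitor / (K_D + inhibitor)


def craf_generation_rate(
    signalsome: float,
    craf_protein: float,
    inhibitor: float,
    params: GlobalParameters,
) -> float:
    """Generation rate of cRaf-pS621 (nM/hr).

    r = k+ * x_s * x_cRaf/(K+ + x_cRaf) * (1 - I/(K_D + I)).  ``craf_protein``
    is the total cRaf protein level (nM).
    """
    if signalsome < 0 or craf_protein < 0:
        raise ValueError("signalsome and cRaf protein must be >= 0")
    kinetic = params.k_act_craf * signalsome * craf_protein / (
        params.K_act_craf + craf_protein)
    return kinetic * inhibitor_control(inhibitor, params.K_D)


def integrate_rule(values: Sequence[float], rule: str) -> float:
    """Combine transfer-function outputs into one control value.

    ``rule`` is ``"min"`` or ``"max"``; a process with no modifying factors
    has control value 1.
    """
    if rule not in ("min", "max"):
        raise ValueError(f"rule must be 'min' or 'max', got {rule!r}")
    vals = list(values)
    if not vals:
        return 1.0
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError("transfer values must lie in [0, 1]")
    return min(vals) if rule == "min" else max(vals)


def signaling_generation_rates(
    x: Mapping[str, float],
    protein_nM: Mapping[str, float],
    atra: float,
    inhibitor: float,
    params: GlobalParameters,
) -> dict[str, float]:
    """Generation rates r+ (nM/hr) of the activated species at state ``x``.

    The activated-Trigger balance is slaved directly to total Trigger protein
    (its generation rate is written so its PSS equals the activation law);
    signalsome formation is first order in BLR1 protein; cRaf-pS621 formation
    follows the signalsome-driven saturation kinetics with inhibitor control.
    """
    decay = params.mu + params.k_d
    r_trig = decay * trigger_activation(protein_nM["Trigger"], atra, params)
    r_sig = params.k_signalsome * protein_nM["BLR1"]
    r_craf = craf_generation_rate(
        x["signalsome"], protein_nM["cRaf"], inhibitor, params)
    return {"Trigger_active": r_trig, "signalsome": r_sig, "cRaf_pS621": r_craf}


class PSSConvergenceError(RuntimeError):
    """Fixed-point iteration for the PSS closure failed to converge."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"PSS fixed point not converged after {iterations} iterations "
            f"(residual {residual:.3e})")


def pss_solve(
    model: NetworkModel,
    protein_nM: Mapping[str, float],
    atra: float,
    inhibitor: float = 0.0,
    *,
    tol: float = 1e-10,
    max_iter: int = 500,
    damping: float = 0.5,
    x0: Mapping[str, float] | None = None,
) -> SignalingState:
    """Solve the pseudo-steady-state closure x* = r+(x)/(mu + k_d).

    Damped fixed-point iteration from ``x0`` (default: the origin) to
    relative tolerance ``tol``.  Raises :class:`PSSConvergenceError` on
    non-convergence; callers may then fall back to full-ODE mode.
    """
    params = model.parameters
    decay = params.mu + params.k_d
    x = {s: 0.0 for s in SIGNAL_SPECIES}
    if x0 is not None:
        x.update(x0)
    residual = np.inf
    for it in range(max_iter):
        rates = signaling_generation_rates(x, protein_nM, atra, inhibitor, params)
        target = {s: rates[s] / decay for s in SIGNAL_SPECIES}
        residual = max(
            abs(target[s] - x[s]) / max(abs(target[s]), 1.0) for s in SIGNAL_SPECIES)
        x = {s: (1.0 - damping) * target[s] + damping * x[s] for s in SIGNAL_SPECIES}
        if residual <= tol:
            return SignalingState(
                activated_trigger=x["Trigger_active"],
                signalsome=x["signalsome"],
                craf_ps621=x["cRaf_pS621"],
                atra=atra,
                inhibitor=inhibitor,
            )
    raise PSSConvergenceError(residual, max_iter)
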