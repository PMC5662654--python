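"""Simulation engine: coupled gene-expression/signaling integration,
steady-state and phase-plane (nullcline/bistability) analysis.

Two evaluation modes are supported.  In the default ``pss`` mode the
activated signaling species (activated Trigger, signalsome, cRaf-pS621) are
closed algebraically at their pseudo-steady state, so the ODE state is the
mRNA/protein vector only; in ``full_ode`` mode the activated species carry
their own balances dx/dt = r+ - (mu + k_d) x and relax toward the same fixed
point.  Treatment protocols are piecewise-constant ATRA/inhibitor schedules;
schedule switches are integration restarts, never interpolated across.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import (
    NetworkModel,
    SIGNAL_SPECIES,
    apply_connection_knockout,
    apply_gene_knockout,
)

__all__ = [
    "SimulationProtocol",
    "Trajectory",
    "SteadyState",
    "ModelArrays",
    "pretreatment_steady_state",
    "simulate",
    "find_steady_states",
    "nullclines",
    "washout_experiment",
    "dose_sweep",
]


# ---------------------------------------------------------------------------
# precompiled arrays
# ---------------------------------------------------------------------------

class ModelArrays:
    """Vectorized view of a :class:`NetworkModel` for fast RHS evaluation.

    Levels vector layout: protein concentrations (nM) for every gene in
    roster order, followed by the three activated species.
    """

    def __init__(self, model: NetworkModel):
        self.model = model
        p = model.parameters
        self.params = p
        genes = model.genes
        self.G = len(genes)
        self.names = [g.name for g in genes]
        g_idx = {g.name: i for i, g in enumerate(genes)}

        v_t = p.k_T * p.rnap_copies
        self.rT_bar = np.array([
            v_t * (p.L_T0 / g.gene_length_nt) * (g.gene_copies / (p.K_T + g.gene_copies))
            for g in genes])
        self.w0 = np.array([g.basal_weight for g in genes])
        self.lam = self.rT_bar * self.w0 / (1.0 + self.w0)
        self.vX = np.array([
            p.k_X * p.ribosome_copies * (p.L_X0 / g.transcript_length_nt)
            for g in genes])
        self.nM_per_copy = p.nM_per_copy
        self.decay_m = p.mu + p.theta_m
        self.decay_p = p.mu + p.theta_p
        self.decay_x = p.mu + p.k_d

        sig_idx = {s: self.G + i for i, s in enumerate(SIGNAL_SPECIES)}
        edges = model.interactions
        self.n_edges = len(edges)
        self.eff_idx = np.array(
            [g_idx.get(e.effector, sig_idx.get(e.effector)) for e in edges], dtype=int)
        self.tgt_idx = np.array([g_idx[e.target] for e in edges], dtype=int)
        self.W = np.array([e.weight for e in edges])
        self.K = np.array([e.half_saturation for e in edges])
        self.eta = np.array([e.cooperativity for e in edges])
        self.act = np.array([e.sign == "activation" for e in edges], dtype=bool)
        self.regulated = np.zeros(self.G, dtype=bool)
        self.regulated[self.tgt_idx] = True

        self.i_trigger = g_idx.get("Trigger")
        self.i_blr1 = g_idx.get("BLR1")
        self.i_craf = g_idx.get("cRaf")

    # --- promoter logic ----------------------------------------------------
    def control_terms(self, levels: np.ndarray) -> np.ndarray:
        """u_j for every gene given the levels vector (nM)."""
        x = np.maximum(levels[self.eff_idx], 0.0)
        with np.errstate(over="ignore", divide="ignore"):
            r = (x / self.K) ** self.eta
        f = np.where(np.isinf(r), 1.0, r / (1.0 + r))
        wf = self.W * f
        num = self.w0.copy()
        den = 1.0 + self.w0
        np.add.at(num, self.tgt_idx[self.act], wf[self.act])
        np.add.at(den, self.tgt_idx, wf)
        u = num / den
        u[~self.regulated] = 1.0
        return u

    # --- signaling ---------------------------------------------------------
    def trigger_active(self, p_trig_nM: float, atra: float) -> float:
        p = self.params
        if atra < p.atra_threshold:
            return 0.0
        a = p.alpha_gain * atra
        return p_trig_nM * a / (1.0 + a)

    def signals_pss(self, prot_nM: np.ndarray, atra: float, inhibitor: float) -> np.ndarray:
        """Activated-species PSS levels (nM) given protein levels.

        The closure is an acyclic cascade: activated Trigger from total
        Trigger protein, signalsome from BLR1 protein, cRaf-pS621 from the
        signalsome, so the fixed point is explicit.  A network without the
        initiation genes has no signaling layer: all levels are zero.
        """
        p = self.params
        if None in (self.i_trigger, self.i_blr1, self.i_craf):
            return np.zeros(len(SIGNAL_SPECIES))
        x_a = self.trigger_active(prot_nM[self.i_trigger], atra)
        x_s = p.k_signalsome * prot_nM[self.i_blr1] / self.decay_x
        p_craf = prot_nM[self.i_craf]
        v_i = 1.0 - inhibitor / (p.K_D + inhibitor)
        x_c = (p.k_act_craf * x_s * p_craf / (p.K_act_craf + p_craf)) * v_i / self.decay_x
        return np.array([x_a, x_s, x_c])

    def signal_generation(self, x: np.ndarray, prot_nM: np.ndarray,
                          atra: float, inhibitor: float) -> np.ndarray:
        """Generation rates r+ (nM/hr) of the activated species."""
        p = self.params
        if None in (self.i_trigger, self.i_blr1, self.i_craf):
            return np.zeros(len(SIGNAL_SPECIES))
        r_a = self.decay_x * self.trigger_active(prot_nM[self.i_trigger], atra)
        r_s = p.k_signalsome * prot_nM[self.i_blr1]
        p_craf = prot_nM[self.i_craf]
        v_i = 1.0 - inhibitor / (p.K_D + inhibitor)
        r_c = p.k_act_craf * max(x[1], 0.0) * p_craf / (p.K_act_craf + p_craf) * v_i
        return np.array([r_a, r_s, r_c])

    # --- right-hand sides --------------------------------------------------
    def rhs_pss(self, t: float, y: np.ndarray, atra: float, inhibitor: float) -> np.ndarray:
        G = self.G
        m = np.maximum(y[:G], 0.0)
        prot = np.maximum(y[G:2 * G], 0.0)
        prot_nM = prot * self.nM_per_copy
        sig = self.signals_pss(prot_nM, atra, inhibitor)
        levels = np.concatenate([prot_nM, sig])
        u = self.control_terms(levels)
        dm = self.rT_bar * u + self.lam - self.decay_m * m
        dp = self.vX * m / (self.params.K_X + m) - self.decay_p * prot
        return np.concatenate([dm, dp])

    def rhs_full(self, t: float, y: np.ndarray, atra: float, inhibitor: float) -> np.ndarray:
        G = self.G
        m = np.maximum(y[:G], 0.0)
        prot = np.maximum(y[G:2 * G], 0.0)
        x = np.maximum(y[2 * G:], 0.0)
        prot_nM = prot * self.nM_per_copy
        levels = np.concatenate([prot_nM, x])
        u = self.control_terms(levels)
        dm = self.rT_bar * u + self.lam - self.decay_m * m
        dp = self.vX * m / (self.params.K_X + m) - self.decay_p * prot
        dx = self.signal_generation(x, prot_nM, atra, inhibitor) - self.decay_x * x
        return np.concatenate([dm, dp, dx])

    # --- gene-expression quasi-steady state --------------------------------
    def expression_qss(self, x_s: float, x_craf: float, atra: float,
                       tol: float = 1e-12, max_iter: int = 500) -> np.ndarray:
        """Protein levels (nM) with mRNA/protein balances at their fixed
        point for frozen (signalsome, cRaf-pS621) and the ATRA input.

        Activated Trigger is recomputed from Trigger protein each sweep, so
        the returned levels are self-consistent with the activation law.
        """
        prot_nM = np.zeros(self.G)
        m = np.zeros(self.G)
        for _ in range(max_iter):
            x_a = self.trigger_active(prot_nM[self.i_trigger], atra)
            levels = np.concatenate([prot_nM, [x_a, x_s, x_craf]])
            u = self.control_terms(levels)
            m_new = (self.rT_bar * u + self.lam) / self.decay_m
            p_new = self.vX * m_new / (self.params.K_X + m_new) / self.decay_p
            p_new_nM = p_new * self.nM_per_copy
            err = np.max(np.abs(p_new_nM - prot_nM) / np.maximum(np.abs(p_new_nM), 1.0))
            m, prot_nM = m_new, p_new_nM
            if err <= tol:
                break
        return prot_nM


# ---------------------------------------------------------------------------
# protocols and trajectories
# ---------------------------------------------------------------------------

@dataclass
class SimulationProtocol:
    """Treatment protocol: duration, output grid, piecewise-constant
    ATRA (uM) and MAPK-inhibitor (nM) schedules, knockouts, and mode."""

    duration: float
    output_times: Sequence[float] | None = None
    atra_schedule: Sequence[tuple[float, float]] = field(default_factory=lambda: [(0.0, 0.0)])
    inhibitor_schedule: Sequence[tuple[float, float]] = field(default_factory=lambda: [(0.0, 0.0)])
    gene_knockouts: frozenset = frozenset()
    edge_knockouts: tuple = ()
    mode: str = "pss"

    def __post_init__(self):
        if self.mode not in ("pss", "full_ode"):
            raise ValueError(f"mode must be 'pss' or 'full_ode', got {self.mode!r}")
        if self.output_times is None:
            self.output_times = np.linspace(0.0, self.duration, 73)
        self.output_times = np.asarray(sorted(self.output_times), dtype=float)
        if self.output_times[0] < 0 or self.output_times[-1] > self.duration + 1e-9:
            raise ValueError("output_times must lie within [0, duration]")
        for name, sched in (("atra", self.atra_schedule), ("inhibitor", self.inhibitor_schedule)):
            times = [t for t, _ in sched]
            if times != sorted(times):
                raise ValueError(f"{name}_schedule must be sorted by time")

    def value_at(self, schedule, t: float) -> float:
        v = 0.0
        for t_i, v_i in schedule:
            if t >= t_i - 1e-12:
                v = v_i
        return v

    def segments(self):
        """Yield (t0, t1, atra, inhibitor) integration segments."""
        switch = {0.0, float(self.duration)}
        switch |= {float(t) for t, _ in self.atra_schedule if 0.0 < t < self.duration}
        switch |= {float(t) for t, _ in self.inhibitor_schedule if 0.0 < t < self.duration}
        pts = sorted(switch)
        for t0, t1 in zip(pts[:-1], pts[1:]):
            yield t0, t1, self.value_at(self.atra_schedule, t0), \
                self.value_at(self.inhibitor_schedule, t0)


@dataclass
class Trajectory:
    """Simulated time course over the full state roster.

    ``states`` has one column per entry of the model ``state_index``
    (mRNA/protein in copies/cell, activated species in nM); ``baseline`` is
    the pre-treatment (t = 0-) state and ``fold_changes`` the states
    normalized to it (columns with zero baseline are left as NaN).
    """

    times: np.ndarray
    states: np.ndarray
    baseline: np.ndarray
    state_names: list[str]

    @property
    def fold_changes(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = self.states / self.baseline
        fc[:, self.baseline <= 0.0] = np.nan
        return fc

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    def series(self, name: str, fold_change: bool = False) -> np.ndarray:
        col = self.index(name)
        return (self.fold_changes if fold_change else self.states)[:, col]


def _apply_knockouts(model: NetworkModel, protocol: SimulationProtocol) -> NetworkModel:
    out = model
    if protocol.gene_knockouts:
        out = apply_gene_knockout(out, protocol.gene_knockouts)
    if protocol.edge_knockouts:
        out = apply_connection_knockout(out, protocol.edge_knockouts)
    return out


# ---------------------------------------------------------------------------
# pre-treatment steady state
# ---------------------------------------------------------------------------

def pretreatment_steady_state(
    model: NetworkModel | ModelArrays,
    *,
    atra: float = 0.0,
    inhibitor: float = 0.0,
    guess: np.ndarray | None = None,
    settle_hours: float = 500.0,
    rtol: float = 1e-7,
) -> np.ndarray:
    """Proliferative steady state before treatment, as an [m, p] vector.

    Integrates from small positive seeds (or ``guess``) for ``settle_hours``
    and refines by root-finding on the PSS-mode RHS.  With the default ATRA-
    free input and near-zero seeds this lands on the inactive (low) branch.
    """
    arrays = model if isinstance(model, ModelArrays) else ModelArrays(model)
    y0 = np.full(2 * arrays.G, 1e-3) if guess is None else np.asarray(guess, float)
    if guess is None or settle_hours > 0:
        sol = solve_ivp(
            arrays.rhs_pss, (0.0, settle_hours), y0, args=(atra, inhibitor),
            method="LSODA", rtol=rtol, atol=1e-9, dense_output=False)
        if not sol.success:
            raise RuntimeError(f"pre-treatment settling failed: {sol.message}")
        y0 = sol.y[:, -1]
    res = root(lambda y: arrays.rhs_pss(0.0, y, atra, inhibitor), y0, method="hybr",
               options={"xtol": 1e-12})
    y_ss = res.x if res.success and np.all(res.x > -1e-9) else y0
    return np.maximum(y_ss, 0.0)


def _full_state(arrays: ModelArrays, y: np.ndarray, atra: float, inhibitor: float,
                mode: str) -> np.ndarray:
    """Extend an ODE state to the full roster (appending PSS signals if needed)."""
    G = arrays.G
    if mode == "full_ode" and y.size == 2 * G + 3:
        return y
    prot_nM = np.maximum(y[G:2 * G], 0.0) * arrays.nM_per_copy
    sig = arrays.signals_pss(prot_nM, atra, inhibitor)
    return np.concatenate([y[:2 * G], sig])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(
    model: NetworkModel,
    protocol: SimulationProtocol,
    initial_state: np.ndarray | None = None,
    *,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    baseline_state: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the coupled system under a treatment protocol.

    The default initial condition is the pre-treatment steady state of the
    (knocked-out) model at ATRA = 0.  Fold changes are referenced to the
    t = 0- state.  ``initial_state`` and ``baseline_state`` are [m, p]
    vectors in copies/cell.
    """
    worked = _apply_knockouts(model, protocol)
    arrays = ModelArrays(worked)
    G = arrays.G
    if initial_state is None:
        initial_state = pretreatment_steady_state(arrays)
    y = np.asarray(initial_state, dtype=float)
    if y.size != 2 * G:
        raise ValueError(f"initial_state must have {2 * G} entries (mRNA+protein)")
    base = y if baseline_state is None else np.asarray(baseline_state, float)
    baseline_full = _full_state(arrays, base, 0.0, 0.0, "pss")

    rhs = arrays.rhs_pss if protocol.mode == "pss" else arrays.rhs_full
    if protocol.mode == "full_ode":
        # seed the activated species at their pre-treatment (ATRA = 0) PSS
        prot_nM = np.maximum(y[G:2 * G], 0.0) * arrays.nM_per_copy
        i0 = protocol.value_at(protocol.inhibitor_schedule, 0.0)
        y = np.concatenate([y, arrays.signals_pss(prot_nM, 0.0, i0)])

    out_t = protocol.output_times
    rows: dict[float, np.ndarray] = {}
    for t0, t1, atra, inhib in protocol.segments():
        seg_mask = (out_t >= t0 - 1e-9) & (out_t <= t1 + 1e-9)
        t_eval = np.unique(np.append(np.clip(out_t[seg_mask], t0, t1), t1))
        sol = solve_ivp(rhs, (t0, t1), y, args=(atra, inhib), method="LSODA",
                        rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"integration failed at t = {sol.t[-1]:.3f} hr: {sol.message}")
        keep = set(np.round(out_t[seg_mask], 9))
        for tk, yk in zip(sol.t, sol.y.T):
            if round(float(tk), 9) in keep:
                rows[round(float(tk), 9)] = _full_state(arrays, yk, atra, inhib, protocol.mode)
        y = sol.y[:, -1]

    times = np.array(sorted(rows))
    states = np.vstack([rows[t] for t in times])
    return Trajectory(times=times, states=states, baseline=baseline_full,
                      state_names=list(worked.state_index))


# ---------------------------------------------------------------------------
# steady states / phase plane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyState:
    """One root of the reduced (signalsome, cRaf-pS621) system."""

    signalsome: float
    craf_ps621: float
    stability: str              # "stable" | "unstable"
    leading_eigenvalue: float   # largest real part


def _reduced_field(arrays: ModelArrays, x_s: float, x_craf: float,
                   atra: float, inhibitor: float = 0.0) -> np.ndarray:
    """Rates (dx_s/dt, dx_craf/dt) with gene expression at quasi-steady state."""
    p = arrays.params
    prot_nM = arrays.expression_qss(max(x_s, 0.0), max(x_craf, 0.0), atra)
    v_i = 1.0 - inhibitor / (p.K_D + inhibitor)
    p_craf = prot_nM[arrays.i_craf]
    f1 = p.k_signalsome * prot_nM[arrays.i_blr1] - arrays.decay_x * x_s
    f2 = (p.k_act_craf * max(x_s, 0.0) * p_craf / (p.K_act_craf + p_craf)) * v_i \
        - arrays.decay_x * x_craf
    return np.array([f1, f2])


def find_steady_states(
    model: NetworkModel,
    atra: float,
    n_starts: int = 20,
    seed: int | None = 0,
    *,
    inhibitor: float = 0.0,
    span: tuple[float, float] = (1e-3, 1e5),
    merge_rtol: float = 1e-4,
) -> list[SteadyState]:
    """Multistart root search on the reduced (x_s, cRaf-pS621) plane.

    Roots are deduplicated at relative distance ``merge_rtol`` and classified
    by the eigenvalues of a central finite-difference Jacobian of the reduced
    vector field (relative step 1e-6).
    """
    if n_starts < 10:
        raise ValueError("n_starts must be >= 10")
    arrays = ModelArrays(model)
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(span[0]), np.log10(span[1])
    starts = 10 ** rng.uniform(lo, hi, size=(n_starts, 2))
    starts[0] = [span[0], span[0]]  # always probe the origin region

    # The signalsome nullcline is an explicit function x_s(x_craf) (BLR1
    # protein does not depend on x_s), so sign changes of the cRaf balance
    # evaluated along it bracket every intersection, including saddles the
    # random multistart tends to miss; add one start per bracket.
    p = arrays.params
    xc_grid = np.concatenate([[0.0], 10 ** np.linspace(lo, hi, 80)])
    prot0 = arrays.expression_qss(0.0, 0.0, atra)
    p_craf = prot0[arrays.i_craf]
    v_i = 1.0 - inhibitor / (p.K_D + inhibitor)
    slope = p.k_act_craf * p_craf / (p.K_act_craf + p_craf) * v_i / arrays.decay_x
    xs_null = np.array([
        p.k_signalsome * arrays.expression_qss(0.0, xc, atra)[arrays.i_blr1]
        / arrays.decay_x for xc in xc_grid])
    g = slope * xs_null - xc_grid
    flips = np.nonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)[0]
    brackets = [[0.5 * (xs_null[i] + xs_null[i + 1]),
                 0.5 * (xc_grid[i] + xc_grid[i + 1])] for i in flips]
    if brackets:
        starts = np.vstack([starts, brackets])

    roots: list[np.ndarray] = []
    for s in starts:
        res = root(lambda z: _reduced_field(arrays, z[0], z[1], atra, inhibitor),
                   s, method="hybr", options={"xtol": 1e-12})
        if not res.success:
            continue
        z = np.maximum(res.x, 0.0)
        fz = _reduced_field(arrays, z[0], z[1], atra, inhibitor)
        if np.max(np.abs(fz)) > 1e-6 * max(1.0, arrays.decay_x * max(z.max(), 1.0)):
            continue
        if any(np.linalg.norm(z - r) <= merge_rtol * max(1.0, np.linalg.norm(r))
               for r in roots):
            continue
        roots.append(z)

    out = []
    for z in roots:
        jac = np.empty((2, 2))
        for j in range(2):
            h = 1e-6 * max(abs(z[j]), 1e-3)
            zp, zm = z.copy(), z.copy()
            zp[j] += h
            zm[j] = max(zm[j] - h, 0.0)
            df = (_reduced_field(arrays, zp[0], zp[1], atra, inhibitor)
                  - _reduced_field(arrays, zm[0], zm[1], atra, inhibitor))
            jac[:, j] = df / (zp[j] - zm[j])
        lead = float(np.max(np.linalg.eigvals(jac).real))
        label = "stable" if lead < -1e-6 else "unstable"
        out.append(SteadyState(float(z[0]), float(z[1]), label, lead))
    return sorted(out, key=lambda s: s.craf_ps621)


def nullclines(
    model: NetworkModel,
    atra: float,
    grid: np.ndarray,
    *,
    inhibitor: float = 0.0,
) -> dict[str, np.ndarray]:
    """Trace the two nullclines of the reduced system over ``grid``.

    The signalsome nullcline is traced as x_s against a cRaf-pS621 grid
    (dx_s/dt = 0), the cRaf nullcline as cRaf-pS621 against a signalsome
    grid (dx_craf/dt = 0); for x_s = 0 the cRaf nullcline passes through
    the origin.  Returns arrays of (x_s, x_craf) points for each curve.
    """
    grid = np.asarray(grid, float)
    if np.any(grid < 0):
        raise ValueError("grid bounds must be non-negative")
    arrays = ModelArrays(model)
    p = arrays.params
    v_i = 1.0 - inhibitor / (p.K_D + inhibitor)

    sig_curve = np.empty((grid.size, 2))
    for i, xc in enumerate(grid):
        prot = arrays.expression_qss(0.0, xc, atra)  # p_BLR1 is x_s-independent
        sig_curve[i] = [p.k_signalsome * prot[arrays.i_blr1] / arrays.decay_x, xc]

    prot0 = arrays.expression_qss(0.0, 0.0, atra)
    p_craf = prot0[arrays.i_craf]
    slope = p.k_act_craf * p_craf / (p.K_act_craf + p_craf) * v_i / arrays.decay_x
    craf_curve = np.column_stack([grid, slope * grid])
    return {"signalsome": sig_curve, "craf": craf_curve}


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def washout_experiment(
    model: NetworkModel,
    pulse_hours: float,
    total_hours: float,
    *,
    dose: float = 1.0,
    mode: str = "pss",
    gene_knockouts: frozenset = frozenset(),
    output_times: Sequence[float] | None = None,
) -> Trajectory:
    """Pulsed-ATRA washout: ATRA = ``dose`` for t < pulse_hours, then 0."""
    if pulse_hours >= total_hours:
        raise ValueError("pulse_hours must be < total_hours")
    sched = [(0.0, dose), (float(pulse_hours), 0.0)] if pulse_hours > 0 else [(0.0, 0.0)]
    protocol = SimulationProtocol(
        duration=total_hours,
        output_times=output_times if output_times is not None
        else np.unique(np.concatenate([np.linspace(0, total_hours, 145), [pulse_hours]])),
        atra_schedule=sched, gene_knockouts=gene_knockouts, mode=mode)
    return simulate(model, protocol)


def dose_sweep(
    model: NetworkModel,
    atra_grid: Sequence[float],
    direction: str = "up",
    *,
    settle_hours: float = 400.0,
) -> np.ndarray:
    """Continuation sweep of steady activated levels across ATRA doses.

    Each dose is settled starting from the previous dose's steady state
    (inactive branch for the up sweep start, activated branch for down).
    Returns rows (atra, signalsome, cRaf-pS621).
    """
    grid = list(atra_grid)
    if grid != sorted(grid):
        raise ValueError("atra_grid must be sorted ascending")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    arrays = ModelArrays(model)
    if direction == "up":
        y = pretreatment_steady_state(arrays)
        order = grid
    else:
        y = pretreatment_steady_state(arrays, atra=max(grid[-1], 1.0))
        order = grid[::-1]
    out = []
    for dose in order:
        sol = solve_ivp(arrays.rhs_pss, (0.0, settle_hours), y, args=(dose, 0.0),
                        method="LSODA", rtol=1e-8, atol=1e-9)
        y = np.maximum(sol.y[:, -1], 0.0)
        sig = arrays.signals_pss(y[arrays.G:] * arrays.nM_per_copy, dose, 0.0)
        out.append([dose, sig[1], sig[2]])
    rows = np.array(out)
    return rows[np.argsort(rows[:, 0])]
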