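"""Ensemble parameter estimation against fold-change measurement series.

The residual for one observable j combines three terms: a *scale* term (the
squared mismatch of the absolute pre-treatment level), a *fold-change* term
(squared per-time-point mismatch of the series normalized to the
pre-treatment value) and a *shape* term (squared mismatch of the min-max
scaled series).  The total residual, summed over observables, is minimized
by a covariance matrix adaptation evolution strategy under box constraints,
and every downhill step is archived for ensemble calculations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._cmaes import cma_es_minimize
from .network import NetworkModel
from .simulate import SimulationProtocol, Trajectory, simulate

__all__ = [
    "MeasurementSeries",
    "read_measurements",
    "write_measurements",
    "ParameterSpace",
    "default_initiation_space",
    "default_protocols",
    "EnsembleArchive",
    "minmax_scale",
    "objective_component",
    "total_objective",
    "EnsembleFitter",
    "fit",
    "select_top",
    "select_ensemble",
    "PENALTY_OBJECTIVE",
]

#: finite penalty assigned to failed simulations (never archived as downhill)
PENALTY_OBJECTIVE = 1e9


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementSeries:
    """Fold-change time series for one observable.

    ``values`` are fold changes relative to the pre-treatment level;
    ``pretreatment_scale`` is the absolute level at t = 0- in the model's
    units for that observable (copies/cell for mRNA, nM for proteins and
    activated species).  ``replicate_sd`` optionally carries per-point
    replicate standard deviations.
    """

    observable: str
    times: np.ndarray
    values: np.ndarray
    pretreatment_scale: float
    replicate_sd: np.ndarray | None = None
    protocol_key: str = "treatment"
    n_replicates: int = 1

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("fold-change values must be > 0")
        if self.pretreatment_scale <= 0:
            raise ValueError("pretreatment_scale must be > 0")


def read_measurements(path: str | Path) -> list[MeasurementSeries]:
    """Read a long-form measurement table.

    Columns: observable, time_hr, fold_change, replicate, and
    pretreatment_scale (constant per observable).  Replicates are averaged
    per time point; their standard deviation is retained.
    """
    df = pd.read_csv(path)
    required = {"observable", "time_hr", "fold_change", "pretreatment_scale"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    if "protocol" not in df.columns:
        df = df.assign(protocol="treatment")
    out = []
    for (obs, key), grp in df.groupby(["observable", "protocol"], sort=True):
        agg = grp.groupby("time_hr")["fold_change"].agg(
            ["mean", "std", "count"]).reset_index()
        out.append(MeasurementSeries(
            observable=obs,
            times=agg["time_hr"].to_numpy(),
            values=agg["mean"].to_numpy(),
            pretreatment_scale=float(grp["pretreatment_scale"].iloc[0]),
            replicate_sd=np.nan_to_num(agg["std"].to_numpy()),
            protocol_key=key,
            n_replicates=int(agg["count"].min()),
        ))
    return out


def write_measurements(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# free-parameter space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreeParameter:
    """One free parameter addressed into the model structure.

    ``kind`` is one of ``weight | half_saturation | cooperativity`` (with
    ``edge`` = (effector, target, sign)), ``basal`` (with ``gene``), or
    ``global`` (with ``attr`` naming a GlobalParameters field).
    """

    name: str
    lower: float
    upper: float
    kind: str
    edge: tuple[str, str, str] | None = None
    gene: str | None = None
    attr: str | None = None


class ParameterSpace:
    """Ordered set of free parameters with box bounds.

    ``apply(model, x)`` returns a model copy with the vector written into the
    addressed promoter-logic / global parameters; ``extract(model)`` reads
    the current values (e.g. the generator's ground truth).
    """

    def __init__(self, parameters: Sequence[FreeParameter]):
        self.parameters = list(parameters)
        if not self.parameters:
            raise ValueError("parameter space must contain at least one free parameter")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate free-parameter names")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parameters]

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [(p.lower, p.upper) for p in self.parameters]

    def __len__(self) -> int:
        return len(self.parameters)

    def _edge_index(self, model: NetworkModel, spec: tuple[str, str, str]) -> int:
        eff, tgt, sign = spec
        for i, e in enumerate(model.interactions):
            if (e.effector, e.target, e.sign) == (eff, tgt, sign):
                return i
        raise KeyError(f"no interaction {eff}->{tgt} ({sign}) in model")

    def apply(self, model: NetworkModel, x: Sequence[float]) -> NetworkModel:
        x = np.asarray(x, float)
        if x.size != len(self):
            raise ValueError(f"expected {len(self)} values, got {x.size}")
        out = model.copy()
        for p, v in zip(self.parameters, x):
            if p.kind in ("weight", "half_saturation", "cooperativity"):
                i = self._edge_index(out, p.edge)
                out.interactions[i] = replace(out.interactions[i], **{p.kind: float(v)})
            elif p.kind == "basal":
                j = out.gene_index(p.gene)
                out.genes[j] = replace(out.genes[j], basal_weight=float(v))
            elif p.kind == "global":
                out.parameters = replace(out.parameters, **{p.attr: float(v)})
            else:
                raise ValueError(f"unknown parameter kind {p.kind!r}")
        return out

    def extract(self, model: NetworkModel) -> np.ndarray:
        vals = []
        for p in self.parameters:
            if p.kind in ("weight", "half_saturation", "cooperativity"):
                vals.append(getattr(model.interactions[self._edge_index(model, p.edge)], p.kind))
            elif p.kind == "basal":
                vals.append(model.gene(p.gene).basal_weight)
            else:
                vals.append(getattr(model.parameters, p.attr))
        return np.array(vals, float)


def default_initiation_space() -> ParameterSpace:
    """Free promoter-logic parameters of the signal-initiation feedback.

    The two activating inputs of the BLR1 promoter (activated Trigger;
    cRaf-pS621) with their full Hill parameterization — the parameters that
    set the bistability of the initiation module.  The constitutive weight
    W0 is kept at its configured value: in fold-change data it acts purely
    as a normalization of the pre-treatment baseline, so freeing it opens a
    sloppy ridge in which it rescales every fold change and absorbs genuine
    promoter-weight differences.
    """
    t_edge = ("Trigger_active", "BLR1", "activation")
    c_edge = ("cRaf_pS621", "BLR1", "activation")
    return ParameterSpace([
        FreeParameter("W_Trigger_BLR1", 0.0, 100.0, "weight", edge=t_edge),
        FreeParameter("K_Trigger_BLR1", 0.01, 1000.0, "half_saturation", edge=t_edge),
        FreeParameter("eta_Trigger_BLR1", 0.1, 4.0, "cooperativity", edge=t_edge),
        FreeParameter("W_cRaf_BLR1", 0.0, 100.0, "weight", edge=c_edge),
        FreeParameter("K_cRaf_BLR1", 0.01, 1000.0, "half_saturation", edge=c_edge),
        FreeParameter("eta_cRaf_BLR1", 0.1, 4.0, "cooperativity", edge=c_edge),
    ])


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def minmax_scale(series: Sequence[float]) -> np.ndarray:
    """Min-max scale a series to [0, 1]; constant series map to zeros."""
    v = np.asarray(series, float)
    if v.size < 2:
        raise ValueError("series must have length >= 2")
    span = v.max() - v.min()
    if span == 0.0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def objective_component(
    sim: Trajectory,
    data: MeasurementSeries,
    model: NetworkModel,
) -> float:
    """Three-term residual E_j for one observable (scale + fold + shape)."""
    col = sim.index(data.observable)
    t_lo, t_hi = sim.times[0], sim.times[-1]
    if data.times[0] < t_lo - 1e-9 or data.times[-1] > t_hi + 1e-9:
        raise ValueError(
            f"simulation [{t_lo}, {t_hi}] hr does not cover data times for "
            f"{data.observable}")
    baseline = sim.baseline[col]
    scale_term = (data.pretreatment_scale - baseline) ** 2

    sim_fold = np.interp(data.times, sim.times, sim.fold_changes[:, col])
    fold_term = float(np.sum((data.values - sim_fold) ** 2))

    shape_term = float(np.sum((minmax_scale(data.values) - minmax_scale(sim_fold)) ** 2))
    return float(scale_term + fold_term + shape_term)


def default_protocols() -> dict[str, SimulationProtocol]:
    """Protocols matching the training panels: continuous 1 uM ATRA
    ('treatment') and a 24-hr 1 uM pulse followed by washout ('washout')."""
    return {
        "treatment": SimulationProtocol(duration=72.0, atra_schedule=[(0.0, 1.0)]),
        "washout": SimulationProtocol(
            duration=144.0,
            output_times=np.linspace(0.0, 144.0, 145),
            atra_schedule=[(0.0, 1.0), (24.0, 0.0)]),
        "inhibitor": SimulationProtocol(
            duration=72.0,
            atra_schedule=[(0.0, 1.0)],
            inhibitor_schedule=[(0.0, 90.0)]),
    }


def total_objective(
    x: Sequence[float],
    space: ParameterSpace,
    model: NetworkModel,
    datasets: Sequence[MeasurementSeries],
    protocol: SimulationProtocol | dict[str, SimulationProtocol],
    *,
    initial_state: np.ndarray | None = None,
) -> float:
    """Sum of per-observable residuals for candidate parameter vector ``x``.

    ``protocol`` is either one protocol applied to every dataset or a
    mapping of protocol keys; one simulation is run per required protocol.
    Simulation failures yield the finite :data:`PENALTY_OBJECTIVE` so the
    search can continue; such evaluations are never archived as downhill.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    if isinstance(protocol, SimulationProtocol):
        protocols = {d.protocol_key: protocol for d in datasets}
    else:
        protocols = dict(protocol)
    try:
        candidate = space.apply(model, x)
        if initial_state is None:
            # the ATRA-free baseline is protocol-independent; compute once
            from .simulate import ModelArrays, pretreatment_steady_state
            initial_state = pretreatment_steady_state(ModelArrays(candidate))
        trajs: dict[str, Trajectory] = {}
        total = 0.0
        for d in datasets:
            if d.protocol_key not in trajs:
                trajs[d.protocol_key] = simulate(
                    candidate, protocols[d.protocol_key], initial_state=initial_state)
            total += objective_component(trajs[d.protocol_key], d, candidate)
        return total
    except (RuntimeError, FloatingPointError, ValueError):
        return PENALTY_OBJECTIVE


# ---------------------------------------------------------------------------
# ensemble archive and fitter
# ---------------------------------------------------------------------------

@dataclass
class EnsembleArchive:
    """Archived downhill parameter vectors, sorted ascending by objective.

    ``restarts`` records which identification run produced each entry, so an
    ensemble can be drawn across independent runs rather than from the tail
    of a single converged trace.
    """

    names: list[str]
    vectors: list[np.ndarray] = field(default_factory=list)
    objectives: list[float] = field(default_factory=list)
    restarts: list[int] = field(default_factory=list)

    def append_downhill(self, x: np.ndarray, f: float, restart: int = 0) -> None:
        self.vectors.append(np.asarray(x, float).copy())
        self.objectives.append(float(f))
        self.restarts.append(int(restart))

    def sorted(self) -> "EnsembleArchive":
        order = sorted(range(len(self.objectives)), key=lambda i: (self.objectives[i], i))
        return EnsembleArchive(
            names=self.names,
            vectors=[self.vectors[i] for i in order],
            objectives=[self.objectives[i] for i in order],
            restarts=[self.restarts[i] for i in order])

    def __len__(self) -> int:
        return len(self.vectors)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(np.array(self.vectors).reshape(len(self), -1), columns=self.names)
        df.insert(0, "objective", self.objectives)
        df.insert(1, "restart", self.restarts)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnsembleArchive":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("objective", "restart")]
        restarts = (df["restart"].astype(int).tolist() if "restart" in df.columns
                    else [0] * len(df))
        return cls(names=names,
                   vectors=[row.to_numpy(float) for _, row in df[names].iterrows()],
                   objectives=df["objective"].tolist(),
                   restarts=restarts)


def select_top(archive: EnsembleArchive, n: int) -> list[np.ndarray]:
    """The n best archived vectors (ties broken by insertion order)."""
    if len(archive) == 0:
        raise ValueError("archive is empty")
    return archive.sorted().vectors[:min(n, len(archive))]


def select_ensemble(archive: EnsembleArchive, n: int) -> list[np.ndarray]:
    """The n best parameter sets, at most one per identification run.

    Takes the best entry of each restart (ascending objective), then fills
    any remainder with the next-best entries overall.  With one converged
    run this reduces to :func:`select_top`; with several runs it yields an
    ensemble whose spread reflects run-to-run identification variability
    instead of the last few steps of a single trace.
    """
    srt = archive.sorted()
    picked: list[np.ndarray] = []
    seen_runs: set[int] = set()
    used: set[int] = set()
    for i, (v, r) in enumerate(zip(srt.vectors, srt.restarts)):
        if r not in seen_runs:
            picked.append(v)
            seen_runs.add(r)
            used.add(i)
            if len(picked) == n:
                return picked
    for i, v in enumerate(srt.vectors):
        if i not in used:
            picked.append(v)
            if len(picked) == n:
                break
    return picked


class EnsembleFitter:
    """Direct-search fit of free promoter-logic parameters to measurements.

    Scikit-learn-style estimator: construct with settings, call
    :meth:`fit` with the measurement series, then read the fitted attributes
    ``archive_``, ``best_vector_``, ``best_objective_`` and ``best_model_``.
    """

    def __init__(
        self,
        model: NetworkModel,
        space: ParameterSpace | None = None,
        protocol: SimulationProtocol | None = None,
        n_iterations: int = 100,
        popsize: int | None = None,
        sigma0: float = 0.25,
        seed: int | None = None,
        n_restarts: int = 1,
        n_bootstrap: int = 0,
    ):
        self.model = model
        self.space = space if space is not None else default_initiation_space()
        self.protocol = protocol if protocol is not None else default_protocols()
        self.n_iterations = n_iterations
        self.popsize = popsize
        self.sigma0 = sigma0
        self.seed = seed
        self.n_restarts = n_restarts
        self.n_bootstrap = n_bootstrap

    def get_params(self) -> dict:
        return {k: getattr(self, k) for k in (
            "model", "space", "protocol", "n_iterations", "popsize",
            "sigma0", "seed", "n_restarts", "n_bootstrap")}

    def set_params(self, **kwargs) -> "EnsembleFitter":
        for k, v in kwargs.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, datasets: Sequence[MeasurementSeries]) -> "EnsembleFitter":
        if not datasets:
            raise ValueError("at least one dataset is required")
        archive = EnsembleArchive(names=self.space.names)
        eval_model = self._evaluation_model(datasets)

        def objective(x: np.ndarray) -> float:
            return total_objective(x, self.space, eval_model, datasets, self.protocol)

        best = None
        n_eval = 0
        n_runs = max(1, self.n_restarts) + max(0, self.n_bootstrap)
        for r in range(n_runs):
            is_bootstrap = r >= max(1, self.n_restarts)
            run_data = datasets
            if is_bootstrap:
                rng = np.random.default_rng(
                    None if self.seed is None else self.seed + 7000 + r)
                run_data = _resample_series(datasets, rng)

            def run_objective(x: np.ndarray, _d=run_data) -> float:
                return total_objective(x, self.space, eval_model, _d, self.protocol)

            run_best = [np.inf]

            def on_downhill(x: np.ndarray, f: float, _rb=run_best, _r=r) -> None:
                if f < PENALTY_OBJECTIVE and f < _rb[0]:
                    _rb[0] = f
                    archive.append_downhill(x, f, restart=_r)

            seed_r = None if self.seed is None else self.seed + 1000 * r
            result = cma_es_minimize(
                run_objective, self.space.bounds, seed=seed_r,
                max_iter=self.n_iterations, popsize=self.popsize,
                sigma0=self.sigma0, archive_callback=on_downhill)
            n_eval += result.n_evaluations
            # point estimates come from the runs on the original data only
            if not is_bootstrap and (best is None or result.fun < best.fun):
                best = result

        self.archive_ = archive.sorted()
        self.best_vector_ = best.x
        self.best_objective_ = best.fun
        self.best_model_ = self.space.apply(self.model, best.x)
        self.n_evaluations_ = n_eval
        return self

    def _evaluation_model(self, datasets) -> NetworkModel:
        """Model used inside the objective.

        When every observable and every free parameter lives in the
        signal-initiation subsystem, candidates are simulated on that
        subsystem alone — its trajectories equal the full model's (there is
        no feedback from downstream transcription factors) at a fraction of
        the cost.  Falls back to the full model otherwise.
        """
        try:
            from .network import initiation_submodel
            sub = initiation_submodel(self.model)
            observables = {d.observable for d in datasets}
            if not observables <= set(sub.state_index):
                return self.model
            self.space.extract(sub)  # raises if a free parameter is absent
            return sub
        except (ValueError, KeyError):
            return self.model


def _resample_series(
    datasets: Sequence[MeasurementSeries],
    rng: np.random.Generator,
) -> list[MeasurementSeries]:
    """Parametric bootstrap of replicate-averaged fold-change series.

    Each point is perturbed multiplicatively by the standard error of its
    replicate mean (lognormal scatter assumed, CV = replicate_sd / value),
    giving identification runs whose optima spread like the sampling
    distribution of the estimator.  Noise-free series pass through
    unchanged.
    """
    out = []
    for d in datasets:
        if d.replicate_sd is None or not np.any(d.replicate_sd > 0):
            out.append(d)
            continue
        cv = np.where(d.values > 0, d.replicate_sd / d.values, 0.0)
        se_log = cv / np.sqrt(max(d.n_replicates, 1))
        values = d.values * np.exp(se_log * rng.standard_normal(d.values.size))
        out.append(MeasurementSeries(
            observable=d.observable, times=d.times, values=values,
            pretreatment_scale=d.pretreatment_scale,
            replicate_sd=d.replicate_sd, protocol_key=d.protocol_key,
            n_replicates=d.n_replicates))
    return out


def fit(
    model: NetworkModel,
    datasets: Sequence[MeasurementSeries],
    n_iterations: int,
    seed: int | None,
    *,
    space: ParameterSpace | None = None,
    protocol: SimulationProtocol | None = None,
) -> EnsembleArchive:
    """Functional wrapper over :class:`EnsembleFitter`; returns the archive."""
    fitter = EnsembleFitter(model, space=space, protocol=protocol,
                            n_iterations=n_iterations, seed=seed)
    return fitter.fit(datasets).archive_
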