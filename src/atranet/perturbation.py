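"""Systematic knockout analysis: displacement matrices, SVD modes, mutant tables.

Pairwise gene knockouts (and pairwise promoter-edge deletions) are simulated
under ATRA treatment for each member of a fitted parameter ensemble.  The
response is encoded as a normalized state-displacement matrix — one row per
perturbation, one column per state, each entry the relative l2-norm of the
difference between the perturbed and nominal trajectory — averaged
element-wise over the ensemble and decomposed by singular values to rank
response modes and the regulators that dominate them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .network import NetworkModel, apply_gene_knockout
from .simulate import ModelArrays, SimulationProtocol, pretreatment_steady_state, simulate

__all__ = [
    "DisplacementMatrix",
    "ModeSummary",
    "default_knockout_protocol",
    "table_roster",
    "state_displacement",
    "knockout_scan",
    "svd_modes",
    "mutant_fold_change_table",
]

log = logging.getLogger(__name__)


@dataclass
class DisplacementMatrix:
    """Perturbation x state matrix of normalized trajectory displacements."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    n_ensemble: int = 1
    failed_rows: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


@dataclass
class ModeSummary:
    """SVD mode spectrum of a displacement matrix."""

    singular_values: np.ndarray
    variance_fractions: np.ndarray
    cumulative_fractions: np.ndarray
    mode_state_loadings: np.ndarray          # (k, n_states), sign-fixed
    mode_perturbation_loadings: np.ndarray   # (k, n_perturbations), sign-fixed
    col_labels: list[str]
    row_labels: list[str]

    def top_states(self, mode: int, n: int = 5) -> list[str]:
        order = np.argsort(-np.abs(self.mode_state_loadings[mode]))[:n]
        return [self.col_labels[i] for i in order]

    def top_perturbations(self, mode: int, n: int = 5) -> list[str]:
        order = np.argsort(-np.abs(self.mode_perturbation_loadings[mode]))[:n]
        return [self.row_labels[i] for i in order]


def default_knockout_protocol(duration: float = 72.0) -> SimulationProtocol:
    """72 hr of 1 uM ATRA from t = 0, 1-hr output resolution."""
    return SimulationProtocol(
        duration=duration,
        output_times=np.arange(0.0, duration + 0.5, 1.0),
        atra_schedule=[(0.0, 1.0)])


def _simulate_perturbed(model, protocol, nominal_baseline):
    """Trajectory of a perturbed model from its own pre-treatment state.

    The perturbed baseline is refined from the nominal baseline (knockouts
    only weaken the inactive branch, so the root refinement stays on it).
    """
    arrays = ModelArrays(model)
    y0 = pretreatment_steady_state(arrays, guess=nominal_baseline, settle_hours=50.0)
    return simulate(model, replace_protocol_knockouts(protocol), initial_state=y0)


def replace_protocol_knockouts(protocol: SimulationProtocol) -> SimulationProtocol:
    """Protocol copy with knockouts cleared (they are baked into the model)."""
    return SimulationProtocol(
        duration=protocol.duration, output_times=protocol.output_times,
        atra_schedule=protocol.atra_schedule,
        inhibitor_schedule=protocol.inhibitor_schedule, mode=protocol.mode)


def _displacement_row(nominal: np.ndarray, perturbed: np.ndarray) -> np.ndarray:
    """Per-state relative l2-norm displacement between two trajectories."""
    diff = np.linalg.norm(perturbed - nominal, axis=0)
    ref = np.linalg.norm(nominal, axis=0)
    return np.where(ref > 0.0, diff / np.where(ref > 0, ref, 1.0), diff)


def state_displacement(
    model: NetworkModel,
    perturbation: Sequence[str] | Sequence[int],
    protocol: SimulationProtocol | None = None,
    *,
    kind: str = "gene_pairs",
    nominal=None,
    endpoint_only: bool = False,
) -> np.ndarray:
    """Normalized displacement row for a single perturbation.

    ``perturbation`` is a set of gene names (``kind='gene_pairs'``) or of
    indices into the model's table edges (``kind='edge_pairs'``).  With
    ``endpoint_only`` the norm runs over the final state instead of the
    whole trajectory.
    """
    protocol = protocol if protocol is not None else default_knockout_protocol()
    base = pretreatment_steady_state(ModelArrays(model))
    if nominal is None:
        nominal = simulate(model, protocol, initial_state=base)
    perturbed_model = _perturb(model, perturbation, kind)
    traj = _simulate_perturbed(perturbed_model, protocol, base)
    nom = nominal.states[-1:] if endpoint_only else nominal.states
    per = traj.states[-1:] if endpoint_only else traj.states
    return _displacement_row(nom, per)


def _perturb(model: NetworkModel, perturbation, kind: str) -> NetworkModel:
    if kind == "gene_pairs":
        return apply_gene_knockout(model, set(perturbation))
    if kind == "edge_pairs":
        table_idx = [i for i, e in enumerate(model.interactions) if e.source == "table"]
        out = model.copy()
        for j in set(perturbation):
            i = table_idx[j]
            out.interactions[i] = replace(out.interactions[i], weight=0.0)
        return out
    raise ValueError(f"kind must be 'gene_pairs' or 'edge_pairs', got {kind!r}")


def table_roster(model: NetworkModel) -> list[str]:
    """Genes of the connectivity table: every table-edge target or effector,
    with the activated-Trigger input mapped back to the Trigger gene."""
    names: set[str] = set()
    for e in model.table_edges():
        names.add(e.target)
        names.add("Trigger" if e.effector == "Trigger_active" else e.effector)
    return sorted(names & set(model.gene_names))


def _pair_labels(model: NetworkModel, kind: str):
    """Canonical (sorted) unordered pairs including self-pairs (= singles)."""
    if kind == "gene_pairs":
        items = table_roster(model)
        pairs = list(itertools.combinations_with_replacement(items, 2))
        labels = [a if a == b else f"{a}+{b}" for a, b in pairs]
        perts = [{a} if a == b else {a, b} for a, b in pairs]
    elif kind == "edge_pairs":
        edges = [e for e in model.interactions if e.source == "table"]
        names = [f"{e.effector}{'+' if e.sign == 'activation' else '-'}>{e.target}"
                 for e in edges]
        idx = list(range(len(edges)))
        pairs = list(itertools.combinations_with_replacement(idx, 2))
        labels = [names[a] if a == b else f"{names[a]} & {names[b]}" for a, b in pairs]
        perts = [{a} if a == b else {a, b} for a, b in pairs]
    else:
        raise ValueError(f"kind must be 'gene_pairs' or 'edge_pairs', got {kind!r}")
    return labels, perts


def knockout_scan(
    model: NetworkModel,
    ensemble: Sequence[NetworkModel],
    kind: str = "gene_pairs",
    protocol: SimulationProtocol | None = None,
    *,
    endpoint_only: bool = False,
) -> DisplacementMatrix:
    """All pairwise perturbations, averaged element-wise over an ensemble.

    ``ensemble`` holds the parameterized models (e.g. the top-10 archive
    vectors applied to the base model); pass ``[model]`` for a single-set
    scan.  Rows whose simulation fails are excluded from the average and
    logged.
    """
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    labels, perts = _pair_labels(model, kind)
    col_labels = list(model.state_index)
    total = np.zeros((len(perts), len(col_labels)))
    counts = np.zeros(len(perts))
    failed: set[str] = set()
    protocol = protocol if protocol is not None else default_knockout_protocol()

    for member in ensemble:
        base = pretreatment_steady_state(ModelArrays(member))
        nominal = simulate(member, protocol, initial_state=base)
        nom = nominal.states[-1:] if endpoint_only else nominal.states
        for r, pert in enumerate(perts):
            try:
                traj = _simulate_perturbed(_perturb(member, pert, kind), protocol, base)
                per = traj.states[-1:] if endpoint_only else traj.states
                total[r] += _displacement_row(nom, per)
                counts[r] += 1
            except (RuntimeError, ValueError) as exc:  # pragma: no cover
                failed.add(labels[r])
                log.warning("perturbation %s failed: %s", labels[r], exc)

    with np.errstate(invalid="ignore"):
        avg = np.where(counts[:, None] > 0, total / np.maximum(counts[:, None], 1), 0.0)
    if failed:
        log.warning("%d perturbation rows excluded from averaging", len(failed))
    return DisplacementMatrix(
        row_labels=labels, col_labels=col_labels, values=avg,
        n_ensemble=len(ensemble), failed_rows=sorted(failed))


def svd_modes(matrix: DisplacementMatrix, k: int | None = None) -> ModeSummary:
    """Thin SVD of a displacement matrix with energy variance fractions.

    The variance fraction of mode i is sigma_i^2 / sum sigma^2; loadings are
    sign-fixed so the largest-magnitude state loading of each mode is
    positive.  An all-zero matrix yields zero singular values and zero
    fractions.
    """
    M = matrix.values
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float(np.sum(s ** 2))
    frac = s ** 2 / total if total > 0 else np.zeros_like(s)
    k = s.size if k is None else min(k, s.size)
    V = Vt[:k]
    Uk = U[:, :k].T
    for i in range(k):
        j = int(np.argmax(np.abs(V[i])))
        if V[i, j] < 0:
            V[i] = -V[i]
            Uk[i] = -Uk[i]
    return ModeSummary(
        singular_values=s[:k],
        variance_fractions=frac[:k],
        cumulative_fractions=np.cumsum(frac)[:k],
        mode_state_loadings=V,
        mode_perturbation_loadings=Uk,
        col_labels=matrix.col_labels,
        row_labels=matrix.row_labels)


def mutant_fold_change_table(
    model: NetworkModel,
    knockouts: Sequence[set[str]],
    t: float = 48.0,
    *,
    protocol: SimulationProtocol | None = None,
) -> pd.DataFrame:
    """Protein fold changes (mutant / wild type) at time ``t`` with bins.

    One column group per knockout set; fold changes are binned at >2, >4 and
    >8 (on the ratio for up-regulation, on the reciprocal for
    down-regulation), with the direction labeled.  A zero wild-type level is
    flagged unbounded.
    """
    protocol = protocol if protocol is not None else default_knockout_protocol(
        duration=max(t, 48.0))
    if t > protocol.duration:
        raise ValueError("t must lie within the protocol duration")
    arrays = ModelArrays(model)
    G = arrays.G
    base = pretreatment_steady_state(arrays)
    nominal = simulate(model, protocol, initial_state=base)
    it = int(np.argmin(np.abs(nominal.times - t)))
    wt = nominal.states[it, G:2 * G]

    records = []
    for ko in knockouts:
        label = "+".join(sorted(ko)) + "-/-"
        traj = _simulate_perturbed(apply_gene_knockout(model, ko), protocol, base)
        mut = traj.states[it, G:2 * G]
        for name, w, m in zip(arrays.names, wt, mut):
            if w <= 0.0:
                records.append({"knockout": label, "protein": name, "fold": np.inf,
                                "direction": "unbounded", "bin": "unbounded"})
                continue
            fold = m / w
            direction = "up" if fold >= 1.0 else "down"
            mag = fold if fold >= 1.0 else 1.0 / fold if fold > 0 else np.inf
            bin_label = (">8" if mag > 8 else ">4" if mag > 4 else
                         ">2" if mag > 2 else "-")
            records.append({"knockout": label, "protein": name, "fold": fold,
                            "direction": direction, "bin": bin_label})
    return pd.DataFrame.from_records(records)
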