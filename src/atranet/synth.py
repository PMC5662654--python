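"""Seeded synthetic measurement generation from a known ground truth.

The generator emulates the statistical structure of fold-change-normalized,
densitometry-style protein/mRNA measurements: sparse sampling times, few
biological replicates, and multiplicative lognormal noise (strictly
positive, roughly constant coefficient of variation).  Observations are
normalized to the simulated pre-treatment value, mirroring how Western-blot
series are normalized to an untreated control lane.  G0-arrest fractions
are derived from the simulated p21/E2F trajectory through the polynomial
arrest model with known coefficients, then perturbed with additive
truncated Gaussian noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .arrest import ArrestModel
from .network import GeneRecord, GlobalParameters, NetworkModel, RegulatoryInteraction
from .simulate import ModelArrays, SimulationProtocol, pretreatment_steady_state, simulate

__all__ = ["SyntheticDesign", "SyntheticDataset", "generate", "write_fixtures"]

#: transcription-factor panel reported as a 48-hr endpoint (protein fold change)
DEFAULT_TF_PANEL = (
    "PPARG", "PU1", "CEBPa", "IRF1", "Oct1", "Oct4",
    "AP1", "E2F", "Egr1", "AhR", "Gfi1", "p21",
)


@dataclass
class SyntheticDesign:
    """Study design of the synthetic measurement set."""

    observables: tuple[str, ...] = (
        "BLR1_mRNA", "cRaf_pS621", "CD38_protein", "CD11b_protein")
    tf_panel: tuple[str, ...] = DEFAULT_TF_PANEL
    sample_times: tuple[float, ...] = (0.0, 4.0, 8.0, 16.0, 24.0, 48.0, 72.0)
    replicates: int = 3
    noise_sigma: float = 0.1
    seed: int = 0
    atra_dose: float = 1.0
    arrest_coefficients: tuple[float, ...] = (0.10, 0.04, 0.025, 0.001)
    arrest_noise_sd: float = 0.03
    # pulsed-exposure (washout) panel: pulse length (hr), sampling times and
    # the observables followed after ATRA removal
    washout_observables: tuple[str, ...] = ("BLR1_mRNA", "cRaf_pS621")
    washout_pulse: float = 24.0
    washout_times: tuple[float, ...] = (0.0, 4.0, 8.0, 16.0, 24.0, 48.0, 72.0,
                                        96.0, 120.0, 144.0)
    # MAPK-inhibitor co-treatment panel (ATRA + kinase inhibitor), sampling
    # the feedback transfer curve at a partially inhibited operating point
    inhibitor_observables: tuple[str, ...] = ("BLR1_mRNA", "cRaf_pS621")
    inhibitor_dose: float = 90.0  # nM

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated measurements plus the ground-truth record."""

    measurements: pd.DataFrame     # observable, time_hr, fold_change, replicate, pretreatment_scale
    tf_panel: pd.DataFrame         # protein, time_hr, fold_change, replicate
    arrest: pd.DataFrame           # time_hr, fraction_G0, replicate
    truth: dict = field(default_factory=dict)


def _truth_hash(model: NetworkModel, design: SyntheticDesign) -> str:
    doc = {
        "parameters": {k: getattr(model.parameters, k)
                       for k in GlobalParameters.__dataclass_fields__},
        "genes": [[getattr(g, k) for k in GeneRecord.__dataclass_fields__]
                  for g in model.genes],
        "interactions": [[getattr(e, k) for k in RegulatoryInteraction.__dataclass_fields__]
                         for e in model.interactions],
        "design": {
            "observables": list(design.observables),
            "tf_panel": list(design.tf_panel),
            "sample_times": list(design.sample_times),
            "replicates": design.replicates,
            "noise_sigma": design.noise_sigma,
            "atra_dose": design.atra_dose,
            "arrest_coefficients": list(design.arrest_coefficients),
            "arrest_noise_sd": design.arrest_noise_sd,
            "washout_observables": list(design.washout_observables),
            "washout_pulse": design.washout_pulse,
            "washout_times": list(design.washout_times),
            "inhibitor_observables": list(design.inhibitor_observables),
            "inhibitor_dose": design.inhibitor_dose,
        },
    }
    blob = yaml.safe_dump(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def generate(design: SyntheticDesign, model: NetworkModel) -> SyntheticDataset:
    """Generate a seeded synthetic measurement set from ``model`` as truth."""
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.sample_times, float)
    protocol = SimulationProtocol(
        duration=float(times.max()),
        output_times=np.unique(np.concatenate([times, np.linspace(0, times.max(), 73)])),
        atra_schedule=[(0.0, design.atra_dose)])
    arrays = ModelArrays(model)
    base = pretreatment_steady_state(arrays)
    traj = simulate(model, protocol, initial_state=base)
    t_idx = [int(np.argmin(np.abs(traj.times - t))) for t in times]

    def noisy(fold: np.ndarray) -> np.ndarray:
        if design.noise_sigma == 0.0:
            return fold.copy()
        return fold * np.exp(design.noise_sigma * rng.standard_normal(fold.size))

    meas_rows = []
    for obs in design.observables:
        fold = traj.series(obs, fold_change=True)[t_idx]
        scale = float(traj.baseline[traj.index(obs)])
        for rep in range(1, design.replicates + 1):
            for t, v in zip(times, noisy(fold)):
                meas_rows.append({"observable": obs, "time_hr": t, "fold_change": v,
                                  "replicate": rep, "pretreatment_scale": scale,
                                  "protocol": "treatment"})

    # pulsed-exposure panel (ATRA removed after the pulse)
    if design.washout_observables:
        w_times = np.asarray(design.washout_times, float)
        w_protocol = SimulationProtocol(
            duration=float(w_times.max()),
            output_times=np.unique(np.concatenate(
                [w_times, [design.washout_pulse],
                 np.linspace(0.0, w_times.max(), 145)])),
            atra_schedule=[(0.0, design.atra_dose), (design.washout_pulse, 0.0)])
        w_traj = simulate(model, w_protocol, initial_state=base)
        w_idx = [int(np.argmin(np.abs(w_traj.times - t))) for t in w_times]
        for obs in design.washout_observables:
            fold = w_traj.series(obs, fold_change=True)[w_idx]
            scale = float(w_traj.baseline[w_traj.index(obs)])
            for rep in range(1, design.replicates + 1):
                for t, v in zip(w_times, noisy(fold)):
                    meas_rows.append({"observable": obs, "time_hr": t,
                                      "fold_change": v, "replicate": rep,
                                      "pretreatment_scale": scale,
                                      "protocol": "washout"})

    # ATRA + MAPK-inhibitor co-treatment panel
    if design.inhibitor_observables:
        i_protocol = SimulationProtocol(
            duration=float(times.max()),
            output_times=np.unique(np.concatenate(
                [times, np.linspace(0, times.max(), 73)])),
            atra_schedule=[(0.0, design.atra_dose)],
            inhibitor_schedule=[(0.0, design.inhibitor_dose)])
        i_traj = simulate(model, i_protocol, initial_state=base)
        i_idx = [int(np.argmin(np.abs(i_traj.times - t))) for t in times]
        for obs in design.inhibitor_observables:
            fold = i_traj.series(obs, fold_change=True)[i_idx]
            scale = float(i_traj.baseline[i_traj.index(obs)])
            for rep in range(1, design.replicates + 1):
                for t, v in zip(times, noisy(fold)):
                    meas_rows.append({"observable": obs, "time_hr": t,
                                      "fold_change": v, "replicate": rep,
                                      "pretreatment_scale": scale,
                                      "protocol": "inhibitor"})
    measurements = pd.DataFrame.from_records(meas_rows)

    panel_rows = []
    t48 = int(np.argmin(np.abs(traj.times - 48.0)))
    for prot in design.tf_panel:
        fold48 = traj.series(f"{prot}_protein", fold_change=True)[t48]
        for rep in range(1, design.replicates + 1):
            panel_rows.append({"protein": prot, "time_hr": 48.0,
                               "fold_change": float(noisy(np.array([fold48]))[0]),
                               "replicate": rep})
    tf_panel = pd.DataFrame.from_records(panel_rows)

    # arrest fractions from the truth arrest polynomial on simulated p21/E2F
    truth_arrest = ArrestModel(order=len(design.arrest_coefficients),
                               horizon=float(times.max()))
    truth_arrest.coefficients_ = np.asarray(design.arrest_coefficients, float)
    truth_arrest.horizon_ = float(times.max())
    nm = arrays.nM_per_copy
    p21 = traj.series("p21_protein")[t_idx] * nm
    e2f = traj.series("E2F_protein")[t_idx] * nm
    frac = truth_arrest.predict(times, p21, e2f)
    arrest_rows = []
    for rep in range(1, design.replicates + 1):
        noisy_frac = np.clip(frac + design.arrest_noise_sd * rng.standard_normal(frac.size),
                             0.0, 1.0)
        for t, v in zip(times, noisy_frac):
            arrest_rows.append({"time_hr": t, "fraction_G0": v, "replicate": rep})
    arrest = pd.DataFrame.from_records(arrest_rows)

    truth = {
        "seed": design.seed,
        "noise_sigma": design.noise_sigma,
        "replicates": design.replicates,
        "atra_dose": design.atra_dose,
        "arrest_coefficients": list(design.arrest_coefficients),
        "truth_hash": _truth_hash(model, design),
    }
    return SyntheticDataset(measurements=measurements, tf_panel=tf_panel,
                            arrest=arrest, truth=truth)


def write_fixtures(dataset: SyntheticDataset, path: str | Path) -> dict[str, Path]:
    """Write the dataset as delimited text plus a JSON manifest."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "measurements": out / "measurements.csv",
        "tf_panel": out / "tf_panel_48hr.csv",
        "arrest": out / "arrest_fractions.csv",
        "manifest": out / "manifest.json",
    }
    dataset.measurements.to_csv(files["measurements"], index=False)
    dataset.tf_panel.to_csv(files["tf_panel"], index=False)
    dataset.arrest.to_csv(files["arrest"], index=False)
    with files["manifest"].open("w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
    return files
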