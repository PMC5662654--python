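"""Shared fixtures: the default network, seeded synthetic data, and a
session-scoped fitted ensemble reused by the slower analysis tests."""

import numpy as np
import pytest

import atranet as an
from atranet import estimation as est
from atranet import synth


@pytest.fixture(scope="session")
def model():
    return an.default_network()


@pytest.fixture(scope="session")
def arrays(model):
    return an.ModelArrays(model)


@pytest.fixture(scope="session")
def baseline(arrays):
    return an.pretreatment_steady_state(arrays)


@pytest.fixture(scope="session")
def atra_trajectory(model, baseline):
    """72-hr 1 uM ATRA wild-type time course at 1-hr resolution."""
    protocol = an.SimulationProtocol(
        duration=72.0, output_times=np.arange(0.0, 73.0, 1.0),
        atra_schedule=[(0.0, 1.0)])
    return an.simulate(model, protocol, initial_state=baseline)


@pytest.fixture(scope="session")
def synthetic_dataset(model):
    """The shipped seeded synthetic measurement set (sigma = 0.1, 3 reps)."""
    design = synth.SyntheticDesign(observables=("BLR1_mRNA", "cRaf_pS621"), seed=7)
    return synth.generate(design, model)


@pytest.fixture(scope="session")
def measurement_series(synthetic_dataset, tmp_path_factory):
    path = tmp_path_factory.mktemp("synth") / "measurements.csv"
    synthetic_dataset.measurements.to_csv(path, index=False)
    return est.read_measurements(path)


@pytest.fixture(scope="session")
def fitted(model, measurement_series):
    """Ensemble fit of the initiation promoter-logic parameters to the
    shipped synthetic series: ten independent identification runs whose
    per-run bests form the analysis ensemble (shared across
    bistability/knockout tests)."""
    fitter = est.EnsembleFitter(model, n_iterations=60, seed=42,
                                n_restarts=2, n_bootstrap=8)
    return fitter.fit(measurement_series)


@pytest.fixture(scope="session")
def top10_models(model, fitted):
    space = fitted.space
    return [space.apply(model, v)
            for v in est.select_ensemble(fitted.archive_, 10)]
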