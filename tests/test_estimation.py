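"""Objective construction, archiving, and the evolution-strategy search."""

import numpy as np
import pytest

import atranet as an
from atranet._cmaes import cma_es_minimize
from atranet.estimation import (
    EnsembleArchive,
    EnsembleFitter,
    MeasurementSeries,
    default_initiation_space,
    default_protocols,
    minmax_scale,
    objective_component,
    select_top,
    total_objective,
)
from atranet.simulate import SimulationProtocol, simulate


class TestMinMaxScale:
    def test_basic_example(self):
        assert np.allclose(minmax_scale([1.0, 3.0, 2.0]), [0.0, 1.0, 0.5])

    def test_monotone_series_endpoints(self):
        v = minmax_scale([2.0, 4.0, 8.0, 16.0])
        assert v[0] == 0.0 and v[-1] == 1.0

    def test_constant_series_maps_to_zeros(self):
        assert np.allclose(minmax_scale([5.0, 5.0, 5.0]), 0.0)

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            minmax_scale([1.0])


class TestMeasurementSeries:
    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            MeasurementSeries("x", [0.0, 0.0], [1.0, 2.0], 1.0)  # ties
        with pytest.raises(ValueError):
            MeasurementSeries("x", [0.0, 1.0], [1.0, -2.0], 1.0)  # negative
        with pytest.raises(ValueError):
            MeasurementSeries("x", [0.0, 1.0], [1.0, 2.0], 0.0)  # zero scale


class TestObjectiveComponent:
    def _traj(self, model, baseline):
        protocol = SimulationProtocol(duration=72.0, atra_schedule=[(0.0, 1.0)])
        return simulate(model, protocol, initial_state=baseline)

    def test_perfect_match_is_zero(self, model, baseline):
        traj = self._traj(model, baseline)
        col = traj.index("cRaf_pS621")
        times = np.array([0.0, 24.0, 48.0])
        idx = [int(np.argmin(np.abs(traj.times - t))) for t in times]
        data = MeasurementSeries("cRaf_pS621", times,
                                 traj.fold_changes[idx, col],
                                 float(traj.baseline[col]))
        assert objective_component(traj, data, model) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_point_example(self, model, baseline):
        # data folds [1, 2] (shape [0, 1]) against a flat simulation (cRaf is
        # unregulated, so its protein fold stays 1; simulated shape scales to
        # [0, 0]) with a matching pre-treatment scale:
        # fold term (2-1)^2 + shape term (1-0)^2 = 2
        traj = self._traj(model, baseline)
        col = traj.index("cRaf_protein")
        sim_fold = np.interp([10.0, 60.0], traj.times, traj.fold_changes[:, col])
        assert np.allclose(sim_fold, 1.0, rtol=1e-6)
        data = MeasurementSeries(
            "cRaf_protein", [10.0, 60.0], [1.0, 2.0],
            float(traj.baseline[col]))
        e = objective_component(traj, data, model)
        assert e == pytest.approx(2.0, rel=1e-5)

    def test_uncovered_data_times_raise(self, model, baseline):
        traj = self._traj(model, baseline)
        data = MeasurementSeries("cRaf_pS621", [0.0, 100.0], [1.0, 2.0], 8.0)
        with pytest.raises(ValueError, match="cover"):
            objective_component(traj, data, model)


class TestTotalObjective:
    def test_truth_on_noise_free_data_is_tiny(self, model):
        from atranet import synth
        design = synth.SyntheticDesign(observables=("BLR1_mRNA", "cRaf_pS621"),
                                       noise_sigma=0.0, replicates=1, seed=0)
        ds = synth.generate(design, model)
        space = default_initiation_space()
        series = _series_from_frame(ds.measurements)
        f = total_objective(space.extract(model), space, model, series,
                            default_protocols())
        assert f < 1e-6

    def test_perturbing_a_weight_increases_objective(self, model):
        from atranet import synth
        design = synth.SyntheticDesign(observables=("BLR1_mRNA", "cRaf_pS621"),
                                       noise_sigma=0.0, replicates=1, seed=0)
        ds = synth.generate(design, model)
        space = default_initiation_space()
        series = _series_from_frame(ds.measurements)
        truth = space.extract(model)
        perturbed = truth.copy()
        perturbed[space.names.index("W_cRaf_BLR1")] *= 1.5
        f0 = total_objective(truth, space, model, series, default_protocols())
        f1 = total_objective(perturbed, space, model, series, default_protocols())
        assert f1 > f0

    def test_equals_sum_of_components(self, model, measurement_series):
        space = default_initiation_space()
        x = space.extract(model)
        protocols = default_protocols()
        total = total_objective(x, space, model, measurement_series, protocols)
        parts = 0.0
        trajs = {}
        for d in measurement_series:
            if d.protocol_key not in trajs:
                trajs[d.protocol_key] = simulate(model, protocols[d.protocol_key])
            parts += objective_component(trajs[d.protocol_key], d, model)
        assert total == pytest.approx(parts, rel=1e-9)


def _series_from_frame(df):
    from atranet.estimation import read_measurements
    import tempfile, os
    fd, path = tempfile.mkstemp(suffix=".csv")
    os.close(fd)
    try:
        df.to_csv(path, index=False)
        return read_measurements(path)
    finally:
        os.unlink(path)


class TestCMAES:
    def test_minimizes_shifted_quadratic_under_box(self):
        target = np.array([0.3, 0.7, 0.1])
        res = cma_es_minimize(lambda x: float(np.sum((x - target) ** 2)),
                              [(0.0, 1.0)] * 3, seed=0, max_iter=120)
        assert np.allclose(res.x, target, atol=1e-3)

    def test_respects_bounds(self):
        seen = []
        def fn(x):
            seen.append(x.copy())
            return float(np.sum(x ** 2))
        cma_es_minimize(fn, [(1.0, 2.0), (-3.0, -1.0)], seed=1, max_iter=30)
        pts = np.array(seen)
        assert pts[:, 0].min() >= 1.0 and pts[:, 0].max() <= 2.0
        assert pts[:, 1].min() >= -3.0 and pts[:, 1].max() <= -1.0

    def test_same_seed_is_bit_identical(self):
        fn = lambda x: float(np.sum((x - 0.4) ** 2))
        r1 = cma_es_minimize(fn, [(0.0, 1.0)] * 4, seed=7, max_iter=40)
        r2 = cma_es_minimize(fn, [(0.0, 1.0)] * 4, seed=7, max_iter=40)
        assert np.array_equal(r1.x, r2.x) and r1.fun == r2.fun


class TestFitterAndArchive:
    def test_same_seed_gives_identical_archive(self, model, measurement_series):
        def run():
            f = EnsembleFitter(model, n_iterations=8, seed=5, n_restarts=1)
            f.fit(measurement_series)
            return f.archive_
        a, b = run(), run()
        assert a.objectives == b.objectives
        assert all(np.array_equal(x, y) for x, y in zip(a.vectors, b.vectors))

    def test_archive_objectives_strictly_decreasing_downhill(
            self, model, fitted):
        # insertion order within one run is strictly downhill
        raw = fitted.archive_
        assert len(raw) > 0
        assert all(o >= raw.sorted().objectives[0] for o in raw.objectives)
        assert raw.sorted().objectives == sorted(raw.objectives)

    def test_select_top_returns_lowest_objectives(self):
        archive = EnsembleArchive(names=["a"])
        for i, f in enumerate([5.0, 3.0, 4.0, 1.0]):
            archive.append_downhill(np.array([float(i)]), f)
        top2 = select_top(archive, 2)
        assert [v[0] for v in top2] == [3.0, 1.0]
        assert len(select_top(archive, 99)) == 4

    def test_select_top_breaks_ties_by_insertion_order(self):
        archive = EnsembleArchive(names=["a"])
        archive.append_downhill(np.array([1.0]), 2.0)
        archive.append_downhill(np.array([2.0]), 2.0)
        top = select_top(archive, 1)
        assert top[0][0] == 1.0

    def test_empty_archive_raises(self):
        with pytest.raises(ValueError):
            select_top(EnsembleArchive(names=["a"]), 1)

    def test_archive_round_trips_through_csv(self, tmp_path, fitted):
        path = tmp_path / "archive.csv"
        fitted.archive_.to_csv(path)
        again = EnsembleArchive.from_csv(path)
        assert again.names == fitted.archive_.names
        assert np.allclose(again.objectives, fitted.archive_.objectives)

    def test_ensemble_band_covers_noise_free_truth(self, model, fitted):
        # the 99% confidence band over the ten best per-run parameter sets
        # must cover the noise-free truth trajectory at >= 90% of output
        # times (the identification-run ensemble includes replicate-bootstrap
        # runs, so its spread reflects sampling noise)
        from atranet.estimation import default_protocols, select_ensemble
        protocol = default_protocols()["treatment"]
        truth_traj = simulate(model, protocol)
        members = [fitted.space.apply(model, v)
                   for v in select_ensemble(fitted.archive_, 10)]
        for obs in ("BLR1_mRNA", "cRaf_pS621"):
            col = truth_traj.index(obs)
            member_folds = np.array([
                simulate(m, protocol).fold_changes[:, col] for m in members])
            mu = member_folds.mean(axis=0)
            sd = member_folds.std(axis=0, ddof=1)
            truth_fold = truth_traj.fold_changes[:, col]
            covered = np.mean((truth_fold >= mu - 2.576 * sd)
                              & (truth_fold <= mu + 2.576 * sd))
            assert covered >= 0.90

    def test_objective_is_invariant_to_fold_change_units(self, model, baseline):
        # terms 2-3 depend only on ratios: rescaling the observable's
        # absolute level while keeping the fold series perturbs only term 1
        protocol = SimulationProtocol(duration=72.0, atra_schedule=[(0.0, 1.0)])
        traj = simulate(model, protocol, initial_state=baseline)
        col = traj.index("cRaf_pS621")
        times = np.array([4.0, 24.0, 48.0])
        idx = [int(np.argmin(np.abs(traj.times - t))) for t in times]
        folds = traj.fold_changes[idx, col]
        base = float(traj.baseline[col])
        e1 = objective_component(traj, MeasurementSeries(
            "cRaf_pS621", times, folds, base), model)
        e2 = objective_component(traj, MeasurementSeries(
            "cRaf_pS621", times, folds, base * 3.0), model)
        assert e1 == pytest.approx(0.0, abs=1e-12)
        assert e2 == pytest.approx((base * 3.0 - base) ** 2, rel=1e-9)
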