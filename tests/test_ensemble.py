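"""Ensemble machinery: cost surface, annealing, harvest, statistics."""

import numpy as np
import pytest
from scipy import stats

from erkensemble.ensemble import (
    EnsembleResult,
    FitProblem,
    SamplerConfig,
    chi2_delta,
    ensemble_stats,
    metropolis_anneal,
    metropolis_harvest,
)
from erkensemble.exceptions import InsufficientEnsembleError, ValidationError

from conftest import theta_from_truth


class TestCost:
    def test_cost_vanishes_at_generating_parameters(
        self, noisefree_problem, noisefree_dataset
    ):
        _, truth = noisefree_dataset
        theta = theta_from_truth(truth)
        assert noisefree_problem.cost(theta) < 1e-6

    def test_cost_matches_independent_weighted_least_squares(
        self, default_problem, default_dataset
    ):
        """Dual route: chi2 recomputed in numpy from the predictions."""
        _, truth = default_dataset
        rng = np.random.default_rng(7)
        for _ in range(5):
            theta = theta_from_truth(truth) * rng.uniform(0.7, 1.4, size=10)
            preds = default_problem.predictions(theta)[0]
            expected = 0.0
            for ci in range(len(default_problem.conditions)):
                m = default_problem.n_pts[ci]
                r = (
                    preds[ci, :m] - default_problem.means[ci, :m]
                ) / default_problem.sems_eff[ci, :m]
                expected += float(np.sum(r * r))
            assert default_problem.cost(theta) == pytest.approx(expected, rel=1e-9)

    def test_doubling_residuals_quadruples_cost(self, noisefree_dataset):
        from erkensemble.mek_input import fit_mek_timecourse
        from erkensemble.timecourse import (
            TimeCoursePoint,
            TimeCourseDataset,
        )

        dataset, truth = noisefree_dataset
        theta = theta_from_truth(truth)
        inputs = {
            c: fit_mek_timecourse(dataset, c)
            for c in dataset.conditions_with("pERK")
        }
        problem = FitProblem(dataset, inputs)
        preds = problem.predictions(theta)[0]
        pred_of = {}
        for ci, cond in enumerate(problem.conditions):
            for j in range(problem.n_pts[ci]):
                pred_of[(cond, problem.times[ci, j])] = preds[ci, j]
        # move every pERK mean to pred + 2*(mean - pred)
        points = []
        for p in dataset.points:
            if p.readout == "pERK":
                pr = pred_of[(p.condition, p.time)]
                new_mean = max(pr + 2.0 * (p.mean - pr), 0.0)
                points.append(
                    TimeCoursePoint(
                        p.readout, p.condition, p.time, new_mean, p.sem, p.n_reps
                    )
                )
            else:
                points.append(p)
        stretched = FitProblem(TimeCourseDataset(points), inputs)
        assert stretched.cost(theta) == pytest.approx(
            4.0 * problem.cost(theta), rel=1e-6
        )

    def test_sem_floor_is_five_percent_of_max_mean(self, default_problem):
        assert default_problem.sem_floor == pytest.approx(
            0.05 * default_problem.means.max()
        )
        assert np.all(default_problem.sems_eff >= default_problem.sem_floor)

    def test_missing_input_for_condition_rejected(self, default_dataset):
        dataset, _ = default_dataset
        with pytest.raises(ValidationError, match="MEK input"):
            FitProblem(dataset, {})


QUAD_BOUNDS = np.array([[-2.0, 2.0]])  # theta in [0.01, 100]


def quad_cost(v):
    return (v[0] - 2.0) ** 2


class TestAnnealCore:
    def test_quadratic_minimum_located(self):
        cfg = SamplerConfig(n_temperatures=20, steps_per_temperature=150,
                            polish=False)
        res = metropolis_anneal(quad_cost, QUAD_BOUNDS, cfg, seed=11)
        assert res.best_params[0] == pytest.approx(2.0, abs=1e-2)

    def test_polish_refines_to_analytic_minimum(self):
        cfg = SamplerConfig(n_temperatures=20, steps_per_temperature=150)
        res = metropolis_anneal(quad_cost, QUAD_BOUNDS, cfg, seed=11)
        assert res.best_params[0] == pytest.approx(2.0, abs=1e-6)

    def test_same_seed_is_bit_identical(self):
        cfg = SamplerConfig(n_temperatures=10, steps_per_temperature=100)
        r1 = metropolis_anneal(quad_cost, QUAD_BOUNDS, cfg, seed=5)
        r2 = metropolis_anneal(quad_cost, QUAD_BOUNDS, cfg, seed=5)
        assert np.array_equal(r1.best_params, r2.best_params)
        assert r1.best_cost == r2.best_cost

    def test_constant_cost_returns_that_constant(self):
        cfg = SamplerConfig(n_temperatures=5, steps_per_temperature=50,
                            polish=False)
        res = metropolis_anneal(lambda v: 7.5, QUAD_BOUNDS, cfg, seed=1)
        assert res.best_cost == 7.5


class TestHarvestCore:
    def _harvest_quadratic(self, n=5000, seed=3):
        cfg = SamplerConfig(
            n_ensemble=n, n_temperatures=20, steps_per_temperature=150,
            decimation=10,
        )
        anneal = metropolis_anneal(quad_cost, QUAD_BOUNDS, cfg, seed=seed)
        delta = chi2_delta(cfg, 1)
        threshold = anneal.best_cost + delta
        sets, costs, acc = metropolis_harvest(
            quad_cost, QUAD_BOUNDS, anneal.best_log10,
            np.maximum(anneal.step_sizes, 0.2), threshold, cfg, seed=seed + 1,
        )
        return 10.0**sets[:, 0], costs, threshold

    def test_support_matches_brute_force_grid_scan(self):
        """The harvested region must coincide with the sub-threshold
        set found by direct grid evaluation of the cost."""
        thetas, costs, threshold = self._harvest_quadratic()
        grid = np.linspace(0.01, 100.0, 2_000_001)
        sub = grid[(grid - 2.0) ** 2 <= threshold]
        lo, hi = sub[0], sub[-1]
        width = hi - lo
        assert np.all(costs <= threshold)
        assert np.all(thetas >= lo - 1e-9) and np.all(thetas <= hi + 1e-9)
        assert abs(thetas.min() - lo) < 0.02 * width
        assert abs(thetas.max() - hi) < 0.02 * width

    def test_flat_cost_with_zero_step_gives_degenerate_ensemble(self):
        cfg = SamplerConfig(n_ensemble=50, decimation=1)
        sets, costs, _ = metropolis_harvest(
            lambda v: 1.0, QUAD_BOUNDS, np.array([0.5]), np.array([0.0]),
            threshold=2.0, config=cfg, seed=2,
        )
        assert np.all(sets == 0.5)
        assert np.ptp(costs) == 0.0


class TestEnsembleStats:
    def _result(self, param_sets, problem):
        sets = np.asarray(param_sets, dtype=float)
        return EnsembleResult(
            param_sets=sets,
            costs=np.zeros(len(sets)),
            best_cost=0.0,
            threshold=1.0,
            param_summary=None,
            trajectory_summary=None,
            seed=0,
            config_echo={},
            acceptance_rate=1.0,
        )

    def test_hand_computed_moments(self, noisefree_problem, noisefree_dataset):
        _, truth = noisefree_dataset
        base = theta_from_truth(truth)
        sets = np.vstack([base, base, base])
        sets[:, 9] = [1.0, 2.0, 3.0]  # phi column
        res = self._result(sets, noisefree_problem)
        param_summary, _ = ensemble_stats(res, noisefree_problem)
        row = param_summary.set_index("parameter").loc["phi"]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)  # sample SD, ddof=1
        assert row["cv"] == pytest.approx(0.5)

    def test_identical_sets_have_zero_spread(
        self, noisefree_problem, noisefree_dataset
    ):
        _, truth = noisefree_dataset
        base = theta_from_truth(truth)
        res = self._result(np.vstack([base, base, base]), noisefree_problem)
        param_summary, trajectory_summary = ensemble_stats(res, noisefree_problem)
        np.testing.assert_allclose(param_summary["sd"], 0.0, atol=1e-14)
        np.testing.assert_allclose(trajectory_summary["sd"], 0.0, atol=1e-14)

    def test_trajectory_mean_within_per_set_envelope(
        self, noisefree_problem, noisefree_dataset
    ):
        _, truth = noisefree_dataset
        rng = np.random.default_rng(0)
        sets = theta_from_truth(truth) * rng.uniform(0.8, 1.25, size=(5, 10))
        res = self._result(sets, noisefree_problem)
        _, traj = ensemble_stats(res, noisefree_problem)
        preds = noisefree_problem.predictions(sets)
        k = 0
        for ci in range(len(noisefree_problem.conditions)):
            m = noisefree_problem.n_pts[ci]
            for j in range(m):
                vals = preds[:, ci, j]
                assert vals.min() - 1e-12 <= traj["mean"].iloc[k] <= vals.max() + 1e-12
                k += 1

    def test_fewer_than_two_sets_rejected(
        self, noisefree_problem, noisefree_dataset
    ):
        _, truth = noisefree_dataset
        res = self._result(theta_from_truth(truth)[None, :], noisefree_problem)
        with pytest.raises(InsufficientEnsembleError):
            ensemble_stats(res, noisefree_problem)


class TestChiSquareThreshold:
    def test_delta_is_chi2_quantile_of_free_parameters(self):
        cfg = SamplerConfig()
        assert chi2_delta(cfg, 10) == pytest.approx(stats.chi2.ppf(0.95, 10))
        assert chi2_delta(SamplerConfig(delta_quantile=0.5), 1) == pytest.approx(
            stats.chi2.ppf(0.5, 1)
        )
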