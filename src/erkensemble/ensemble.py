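"""Global ensemble fitting by simulated annealing + Metropolis harvest.

Instead of reporting one best-fit parameter vector, the fitting strategy
compiles a large ensemble (default 1e4) of parameter sets that all fit
the data nearly equally well, and quantifies how tightly the data
constrain each parameter by its coefficient of variation over the
ensemble.  The procedure has two phases:

1. **Annealing** — a Metropolis random walk in log10-parameter space
   whose temperature cools geometrically; it locates the low-cost
   region and adapts per-parameter step sizes.
2. **Harvest** — a fixed-temperature Metropolis chain started from the
   best annealed vector.  Every ``decimation``-th visited state whose
   cost lies below ``best_cost + delta`` is retained, where ``delta``
   is a chi-square quantile increment (default the 95% level for the
   number of free parameters), until the target ensemble size is
   reached.

The objective is the SEM-weighted chi-square over all phospho-ERK time
courses, with the nine kinetic/scale parameters shared across every
condition and a single free phosphatase fold-factor ``phi`` applied to
all inhibitor-treated conditions (``phi = 1`` in control).  The harvest
chain accepts with probability ``exp(-(delta chi2)/T)`` at ``T = 2``,
i.e. it samples the Gaussian likelihood ``exp(-chi2/2)`` restricted to
the good-fit region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .erk_model import PARAM_NAMES, ErkModelParams
from .exceptions import (
    InsufficientEnsembleError,
    SamplerError,
    ValidationError,
)
from .mek_input import MekInputParams
from .timecourse import Condition, TimeCourseDataset
from . import _fastsim

__all__ = [
    "SamplerConfig",
    "FitProblem",
    "EnsembleResult",
    "AnnealResult",
    "cost",
    "anneal_phase",
    "harvest_ensemble",
    "ensemble_stats",
    "metropolis_anneal",
    "metropolis_harvest",
]

PENALTY_COST = 1e12
SEM_FLOOR_FRACTION = 0.05  # floor = 5% of the dataset-wide max pERK mean

#: log10 sampling bounds per parameter class
DEFAULT_BOUNDS = {name: (-4.0, 4.0) for name in PARAM_NAMES}
DEFAULT_BOUNDS["phi"] = (-1.0, 2.0)    # phi in [0.1, 100]
DEFAULT_BOUNDS["scale"] = (-2.0, 2.0)  # scale in [0.01, 100]


@dataclass(frozen=True)
class SamplerConfig:
    """All schedule constants of the two-phase sampler.

    The annealing ladder is geometric from ``t_initial`` down to
    ``t_final``; step sizes (log10 units) adapt toward a 20-40%
    acceptance rate during annealing and are frozen for harvest.
    ``delta_quantile`` sets the chi-square confidence level defining a
    "good" fit; ``harvest_temperature = 2`` samples exp(-chi2/2).
    """

    n_ensemble: int = 10_000
    n_temperatures: int = 50
    t_initial: float = 100.0
    t_final: float = 1.0
    steps_per_temperature: int = 500
    n_anneal_restarts: int = 2
    polish: bool = True
    polish_maxfev: int = 8000
    decimation: int = 10
    delta_quantile: float = 0.95
    harvest_temperature: float = 2.0
    initial_step: float = 0.5
    step_bounds: tuple[float, float] = (1e-3, 2.0)
    max_harvest_steps_factor: int = 50
    bounds_log10: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def temperature_ladder(self) -> np.ndarray:
        return np.geomspace(self.t_initial, self.t_final, self.n_temperatures)

    def to_dict(self) -> dict:
        return {
            "n_ensemble": self.n_ensemble,
            "n_temperatures": self.n_temperatures,
            "t_initial": self.t_initial,
            "t_final": self.t_final,
            "steps_per_temperature": self.steps_per_temperature,
            "n_anneal_restarts": self.n_anneal_restarts,
            "decimation": self.decimation,
            "delta_quantile": self.delta_quantile,
            "harvest_temperature": self.harvest_temperature,
            "initial_step": self.initial_step,
            "bounds_log10": {k: list(v) for k, v in self.bounds_log10.items()},
        }


class FitProblem:
    """Binds the pERK dataset, the fitted MEK inputs, and the parameter
    sharing structure (shared kinetics, one global phi for inhibited
    arms) into packed arrays for the compiled cost."""

    def __init__(
        self,
        dataset: TimeCourseDataset,
        inputs: Mapping[Condition, MekInputParams],
    ):
        conditions = dataset.conditions_with("pERK")
        if not conditions:
            raise ValidationError("dataset contains no pERK time courses")
        missing = [c for c in conditions if c not in inputs]
        if missing:
            raise ValidationError(
                f"no MEK input for condition(s): {[c.key for c in missing]}"
            )
        self.dataset = dataset
        self.conditions: list[Condition] = conditions
        self.inputs = {c: inputs[c] for c in conditions}

        n_cond = len(conditions)
        counts = []
        courses = [dataset.course("pERK", c) for c in conditions]
        max_pts = max(len(t) for t, *_ in courses)
        self.times = np.zeros((n_cond, max_pts))
        self.means = np.zeros((n_cond, max_pts))
        self.sems = np.zeros((n_cond, max_pts))
        for i, (t, m, s, _) in enumerate(courses):
            counts.append(len(t))
            self.times[i, : len(t)] = t
            self.means[i, : len(t)] = m
            self.sems[i, : len(t)] = s
        self.n_pts = np.array(counts, dtype=np.int64)
        self.phi_mask = np.array(
            [1.0 if c.treatment == "inhibited" else 0.0 for c in conditions]
        )
        self.mek_mat = np.vstack([self.inputs[c].as_array() for c in conditions])
        # floor zero/near-zero SEMs so noise-free points stay finite-weight
        self.sem_floor = SEM_FLOOR_FRACTION * float(self.means.max())
        self.sems_eff = np.maximum(self.sems, self.sem_floor)

    @property
    def n_free(self) -> int:
        return len(PARAM_NAMES)

    @property
    def n_points(self) -> int:
        return int(self.n_pts.sum())

    def cost(self, theta: np.ndarray) -> float:
        """SEM-weighted chi-square at the natural-unit parameter vector
        ``theta`` (PARAM_NAMES order); integration failures map to a
        large finite penalty so the sampler can move away."""
        theta = np.ascontiguousarray(theta, dtype=np.float64)
        return float(
            _fastsim.chi2_cost(
                theta, self.mek_mat, self.phi_mask, self.times,
                self.means, self.sems_eff, self.n_pts, PENALTY_COST,
            )
        )

    def predictions(self, thetas: np.ndarray) -> np.ndarray:
        """Predicted pERK for each row of ``thetas``; shape
        (n_sets, n_cond, max_pts), NaN where integration failed."""
        thetas = np.ascontiguousarray(np.atleast_2d(thetas), dtype=np.float64)
        return _fastsim.batch_predictions(
            thetas, self.mek_mat, self.phi_mask, self.times, self.n_pts
        )

    def bounds_array(self, config: SamplerConfig) -> np.ndarray:
        return np.array([config.bounds_log10[name] for name in PARAM_NAMES])

    def initial_log10(self, config: SamplerConfig) -> np.ndarray:
        """Deterministic, data-informed starting vector: bound centers
        for the kinetic constants, the data maximum for the scale, and
        no phosphatase upregulation (phi = 1)."""
        b = self.bounds_array(config)
        x0 = b.mean(axis=1)
        names = list(PARAM_NAMES)
        x0[names.index("scale")] = np.clip(
            np.log10(max(self.means.max(), 1e-6)), *b[names.index("scale")]
        )
        x0[names.index("phi")] = 0.0
        return x0


def cost(theta: Sequence[float], problem: FitProblem) -> float:
    """Module-level convenience wrapper around :meth:`FitProblem.cost`."""
    return problem.cost(np.asarray(theta, dtype=float))


@dataclass
class AnnealResult:
    best_params: np.ndarray        # natural units
    best_cost: float
    best_log10: np.ndarray
    step_sizes: np.ndarray         # frozen per-parameter log10 steps
    acceptance_by_temperature: np.ndarray
    n_evaluations: int


@dataclass
class EnsembleResult:
    """The harvested ensemble and its summaries.

    ``param_sets`` holds natural-unit vectors (PARAM_NAMES order);
    ``param_summary`` and ``trajectory_summary`` are tidy DataFrames.
    """

    param_sets: np.ndarray
    costs: np.ndarray
    best_cost: float
    threshold: float
    param_summary: pd.DataFrame
    trajectory_summary: pd.DataFrame
    seed: int
    config_echo: dict
    acceptance_rate: float

    @property
    def n_ensemble(self) -> int:
        return len(self.costs)

    def phi_estimate(self) -> tuple[float, float, float]:
        """(mean, sd, cv) of the phosphatase fold-factor over the ensemble."""
        row = self.param_summary.set_index("parameter").loc["phi"]
        return float(row["mean"]), float(row["sd"]), float(row["cv"])


# ---------------------------------------------------------------------------
# sampler core (cost-function agnostic; reused by the quadratic-surrogate
# tests and by the FitProblem-facing API below)
# ---------------------------------------------------------------------------


def metropolis_anneal(
    cost_fn: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    config: SamplerConfig,
    seed: int,
    x0_log10: np.ndarray | None = None,
) -> AnnealResult:
    """Simulated-annealing Metropolis walk in log10-parameter space.

    ``cost_fn`` takes a natural-unit vector.  One round-robin-chosen
    parameter is perturbed per step by a Gaussian of per-parameter step
    size; out-of-bounds proposals are rejected.  Step sizes adapt after
    each temperature block toward 20-40% acceptance.  Deterministic for
    a given seed.
    """
    bounds = np.asarray(bounds, dtype=float)
    n_dim = len(bounds)
    rng = np.random.default_rng(seed)
    x = bounds.mean(axis=1) if x0_log10 is None else np.array(x0_log10, dtype=float)
    x = np.clip(x, bounds[:, 0], bounds[:, 1])
    c = cost_fn(10.0**x)
    best_x = x.copy()
    best_c = c
    steps = np.full(n_dim, config.initial_step)
    ladder = config.temperature_ladder()
    acc_by_temp = np.zeros(len(ladder))
    n_eval = 1
    k = 0
    for ti, temp in enumerate(ladder):
        accepted = np.zeros(n_dim)
        proposed = np.zeros(n_dim)
        for _ in range(config.steps_per_temperature):
            i = k % n_dim
            k += 1
            proposed[i] += 1
            xi_new = x[i] + steps[i] * rng.standard_normal()
            if xi_new < bounds[i, 0] or xi_new > bounds[i, 1]:
                rng.random()  # keep the draw count aligned for determinism
                continue
            x_new = x.copy()
            x_new[i] = xi_new
            c_new = cost_fn(10.0**x_new)
            n_eval += 1
            if c_new <= c or rng.random() < np.exp(-(c_new - c) / temp):
                x, c = x_new, c_new
                accepted[i] += 1
                if c < best_c:
                    best_x, best_c = x.copy(), c
            else:
                pass
        rate = accepted.sum() / max(proposed.sum(), 1)
        acc_by_temp[ti] = rate
        # per-parameter adaptation toward the 20-40% window
        for i in range(n_dim):
            if proposed[i] == 0:
                continue
            ri = accepted[i] / proposed[i]
            if ri > 0.4:
                steps[i] *= 1.5
            elif ri < 0.2:
                steps[i] *= 0.6
            steps[i] = float(np.clip(steps[i], *config.step_bounds))
        if ti == len(ladder) - 1 and accepted.sum() == 0 and best_c > 0:
            raise SamplerError(
                "no proposal accepted at the final temperature; "
                "step sizes are likely pathological"
            )
    if config.polish:
        best_x, best_c, n_pol = _polish(cost_fn, bounds, best_x, best_c, config)
        n_eval += n_pol
    return AnnealResult(
        best_params=10.0**best_x,
        best_cost=best_c,
        best_log10=best_x,
        step_sizes=steps,
        acceptance_by_temperature=acc_by_temp,
        n_evaluations=n_eval,
    )


def _polish(
    cost_fn: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    x0: np.ndarray,
    c0: float,
    config: SamplerConfig,
) -> tuple[np.ndarray, float, int]:
    """Deterministic Nelder-Mead refinement of the annealed optimum in
    log10 space (out-of-bounds points get a distance-graded penalty).
    The stochastic walk locates the basin; the simplex settles its
    floor, so the good-fit threshold is anchored at the true best."""
    from scipy.optimize import minimize

    lo, hi = bounds[:, 0], bounds[:, 1]

    def f(x):
        excess = np.maximum(lo - x, 0) + np.maximum(x - hi, 0)
        if excess.any():
            return c0 + 1e6 * (1.0 + excess.sum())
        return cost_fn(10.0**x)

    res = minimize(
        f,
        x0,
        method="Nelder-Mead",
        options={
            "maxfev": config.polish_maxfev,
            "xatol": 1e-8,
            "fatol": 1e-10,
        },
    )
    if res.fun < c0:
        return np.clip(res.x, lo, hi), float(res.fun), int(res.nfev)
    return x0, c0, int(res.nfev)


def metropolis_harvest(
    cost_fn: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    start_log10: np.ndarray,
    step_sizes: np.ndarray,
    threshold: float,
    config: SamplerConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fixed-temperature Metropolis chain; records every
    ``decimation``-th visited state whose cost passes ``threshold``.

    Returns (log10 parameter sets, costs, acceptance rate).  Raises
    :class:`SamplerError` when the acceptance rate over a monitoring
    window drops below 1%, or when the chain cannot collect the target
    ensemble within ``max_harvest_steps_factor * n_ensemble *
    decimation`` steps.
    """
    bounds = np.asarray(bounds, dtype=float)
    n_dim = len(bounds)
    rng = np.random.default_rng(seed)
    x = np.clip(np.array(start_log10, dtype=float), bounds[:, 0], bounds[:, 1])
    c = cost_fn(10.0**x)
    temp = config.harvest_temperature
    kept_x: list[np.ndarray] = []
    kept_c: list[float] = []
    window = 1000
    win_acc = 0
    win_tot = 0
    total_acc = 0
    step_count = 0
    max_steps = config.max_harvest_steps_factor * config.n_ensemble * config.decimation
    k = 0
    while len(kept_x) < config.n_ensemble:
        step_count += 1
        if step_count > max_steps:
            raise SamplerError(
                f"harvest terminated early: collected {len(kept_x)} of "
                f"{config.n_ensemble} sets within {max_steps} steps"
            )
        i = k % n_dim
        k += 1
        xi_new = x[i] + step_sizes[i] * rng.standard_normal()
        win_tot += 1
        if bounds[i, 0] <= xi_new <= bounds[i, 1]:
            x_new = x.copy()
            x_new[i] = xi_new
            c_new = cost_fn(10.0**x_new)
            if c_new <= c or rng.random() < np.exp(-(c_new - c) / temp):
                x, c = x_new, c_new
                win_acc += 1
                total_acc += 1
        else:
            rng.random()
        if win_tot >= window:
            if win_acc / win_tot < 0.01:
                raise SamplerError(
                    f"harvest acceptance rate {win_acc / win_tot:.3%} < 1%; "
                    "retune step sizes"
                )
            win_acc = win_tot = 0
        if step_count % config.decimation == 0 and c <= threshold:
            kept_x.append(x.copy())
            kept_c.append(c)
    return (
        np.array(kept_x),
        np.array(kept_c),
        total_acc / step_count,
    )


# ---------------------------------------------------------------------------
# FitProblem-facing API
# ---------------------------------------------------------------------------


def anneal_phase(
    problem: FitProblem, config: SamplerConfig, seed: int
) -> AnnealResult:
    """Annealing phase on the chi-square surface of ``problem``.

    Runs ``n_anneal_restarts`` independent cooling chains (seeds derived
    deterministically from ``seed``) and keeps the best, which guards
    against a single chain freezing in a secondary basin.
    """
    n = max(config.n_anneal_restarts, 1)
    chain_seeds = (
        np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) >> 1
    )
    best: AnnealResult | None = None
    for cs in chain_seeds:
        res = metropolis_anneal(
            problem.cost,
            problem.bounds_array(config),
            config,
            int(cs),
            x0_log10=problem.initial_log10(config),
        )
        if best is None or res.best_cost < best.best_cost:
            best = res
    return best


def chi2_delta(config: SamplerConfig, n_free: int) -> float:
    """Cost increment defining a "good" fit: the ``delta_quantile``
    chi-square quantile for the number of free parameters (the
    confidence-region increment under Gaussian errors)."""
    return float(stats.chi2.ppf(config.delta_quantile, n_free))


def harvest_ensemble(
    problem: FitProblem,
    anneal: AnnealResult,
    config: SamplerConfig,
    seed: int,
) -> EnsembleResult:
    """Harvest the good-fit ensemble from the annealed optimum and
    compute per-parameter and per-trajectory summaries."""
    threshold = anneal.best_cost + chi2_delta(config, problem.n_free)
    sets_log10, costs, acc = metropolis_harvest(
        problem.cost,
        problem.bounds_array(config),
        anneal.best_log10,
        anneal.step_sizes,
        threshold,
        config,
        seed,
    )
    param_sets = 10.0**sets_log10
    result = EnsembleResult(
        param_sets=param_sets,
        costs=costs,
        best_cost=float(costs.min()),
        threshold=threshold,
        param_summary=pd.DataFrame(),
        trajectory_summary=pd.DataFrame(),
        seed=seed,
        config_echo=config.to_dict(),
        acceptance_rate=acc,
    )
    param_summary, trajectory_summary = ensemble_stats(result, problem)
    result.param_summary = param_summary
    result.trajectory_summary = trajectory_summary
    return result


def ensemble_stats(
    result: EnsembleResult, problem: FitProblem
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-parameter mean/SD/CV and per-(condition, time) ensemble
    mean/SD of the recalculated model output.

    The SD is the sample standard deviation (ddof=1); the phi row of
    the parameter summary is the analysis's headline estimate, reported
    as mean +/- SD.
    """
    sets = np.atleast_2d(result.param_sets)
    if len(sets) < 2:
        raise InsufficientEnsembleError(
            "ensemble statistics require at least 2 parameter sets"
        )
    means = sets.mean(axis=0)
    sds = sets.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means != 0, sds / means, np.nan)
    param_summary = pd.DataFrame(
        {"parameter": list(PARAM_NAMES), "mean": means, "sd": sds, "cv": cvs}
    )

    preds = problem.predictions(sets)  # (n_sets, n_cond, max_pts)
    rows = []
    for ci, cond in enumerate(problem.conditions):
        m = problem.n_pts[ci]
        for j in range(m):
            vals = preds[:, ci, j]
            rows.append(
                {
                    "dose": cond.dose_label,
                    "treatment": cond.treatment,
                    "time_min": problem.times[ci, j],
                    "mean": float(np.nanmean(vals)),
                    "sd": float(np.nanstd(vals, ddof=1)),
                }
            )
    trajectory_summary = pd.DataFrame(rows)
    return param_summary, trajectory_summary


def params_from_vector(theta: Sequence[float]) -> ErkModelParams:
    """Natural-unit vector (PARAM_NAMES order) -> :class:`ErkModelParams`."""
    return ErkModelParams.from_array(theta)
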