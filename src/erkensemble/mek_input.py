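"""Phenomenological MEK-activation input.

Upstream of ERK, the measured phospho-MEK kinetics are transient: a rise
within minutes of growth-factor stimulation followed by slow adaptation.
Rather than modeling receptor/Raf mechanism, each measured pMEK time
course is fit independently to an empirical rise-and-decay curve

    u(t) = M0 + A * (1 - exp(-t / tau_rise)) * exp(-t / tau_decay)

which then drives the ERK model as a continuous, condition-specific
input.  ``M0`` is the basal (pre-stimulation) level, ``A`` the stimulated
amplitude, and the two time constants set the rise and adaptation scales.
The functional form is deliberately kept behind :func:`eval_mek_input` so
an alternative (e.g. piecewise-linear interpolation of the data) could be
swapped in without touching the ERK stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FittingError, InsufficientDataError, ValidationError
from .timecourse import Condition, TimeCourseDataset

__all__ = ["MekInputParams", "eval_mek_input", "fit_mek_timecourse"]

_TAU_MIN = 1e-6  # minutes; lower bound keeping time constants positive


@dataclass(frozen=True)
class MekInputParams:
    """Parameters of the phenomenological pMEK(t) input for one condition.

    Units: ``m0`` and ``amplitude`` in the arbitrary units of the
    normalized readout; time constants in minutes.
    """

    m0: float
    amplitude: float
    tau_rise: float
    tau_decay: float

    def __post_init__(self) -> None:
        vals = (self.m0, self.amplitude, self.tau_rise, self.tau_decay)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError(f"MEK input parameters must be finite: {vals}")
        if self.m0 < 0 or self.amplitude < 0:
            raise ValidationError("m0 and amplitude must be non-negative")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValidationError("tau_rise and tau_decay must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.m0, self.amplitude, self.tau_rise, self.tau_decay])


def eval_mek_input(params: MekInputParams, t):
    """Evaluate u(t) at time(s) ``t`` (minutes, >= 0).

    The curve is continuous, non-negative, and bounded by ``m0 + amplitude``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    u = params.m0 + params.amplitude * (
        1.0 - np.exp(-t / params.tau_rise)
    ) * np.exp(-t / params.tau_decay)
    return u if u.ndim else float(u)


def _curve(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    m0, a, tr, td = theta
    return m0 + a * (1.0 - np.exp(-t / tr)) * np.exp(-t / td)


def _multistart_grid(times: np.ndarray, means: np.ndarray) -> list[np.ndarray]:
    """Fixed, data-driven grid of starting points (deterministic order).

    Heuristic centers: basal ~ first point, amplitude ~ excursion above
    it, rise time ~ a third of the time-to-peak, decay ~ the last time.
    Each center is bracketed by a factor of 10 either way (two decades).
    """
    floor = max(np.max(means), 1.0) * 1e-3
    m0_h = max(means[0], floor)
    a_h = max(np.max(means) - means[0], floor)
    t_peak = times[np.argmax(means)]
    tr_h = max(t_peak / 3.0, 1.0)
    td_h = max(times[-1], 1.0)
    factors = (0.1, 1.0, 10.0)
    starts = []
    for fm, fa, fr, fd in itertools.product(factors, repeat=4):
        starts.append(np.array([m0_h * fm, a_h * fa, tr_h * fr, td_h * fd]))
    return starts


def fit_mek_timecourse(
    dataset: TimeCourseDataset, condition: Condition
) -> MekInputParams:
    """Fit the pMEK time course of one condition to the rise-decay form.

    Minimizes the SEM-weighted sum of squared residuals (unweighted when
    any SEM is zero, as with noise-free synthetic data), by bounded
    trust-region least squares from a fixed multistart grid, so the
    result is deterministic for a given dataset.
    """
    times, means, sems, _ = dataset.course("pMEK", condition)
    if len(times) < 4:
        raise InsufficientDataError(
            f"pMEK fit for {condition.key} needs >= 4 time points, "
            f"got {len(times)}"
        )
    weights = None if np.any(sems == 0) else 1.0 / sems

    def residuals(theta):
        r = _curve(theta, times) - means
        return r if weights is None else r * weights

    lower = np.array([0.0, 0.0, _TAU_MIN, _TAU_MIN])
    upper = np.array([np.inf, np.inf, np.inf, np.inf])
    best = None
    best_ssr = np.inf
    for start in _multistart_grid(times, means):
        start = np.clip(start, lower + 1e-12, None)
        try:
            sol = least_squares(
                residuals, start, bounds=(lower, upper), xtol=1e-14,
                ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        ssr = float(np.sum(sol.fun**2))
        if sol.success and ssr < best_ssr - 1e-15:
            best, best_ssr = sol.x, ssr
    if best is None:
        raise FittingError(
            f"pMEK fit failed to converge from every start for {condition.key}"
        )
    # the nested flat model (A = 0) is a degenerate direction the solver
    # can stall in; check it explicitly so constant courses fit exactly
    w = np.ones_like(means) if weights is None else weights**2
    flat_m0 = float(np.sum(w * means) / np.sum(w))
    flat = np.array([flat_m0, 0.0, 1.0, float(times[-1])])
    if np.sum(residuals(flat) ** 2) <= best_ssr:
        best = flat
    m0, a, tr, td = best
    return MekInputParams(
        m0=float(m0),
        amplitude=float(a),
        tau_rise=float(max(tr, _TAU_MIN)),
        tau_decay=float(max(td, _TAU_MIN)),
    )
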