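"""Two-site distributive ERK (de)phosphorylation ODE model.

ERK is activated by MEK-catalyzed phosphorylation of two activating
sites (Thr202/Tyr204), through a mono-phosphorylated intermediate, and
deactivated by phosphatase action on the same two sites.  Total ERK is
conserved and normalized to 1, so the state is the vector of fractions

    x = (x0, x1, x2)   un-, mono-, dual-phosphorylated,  sum(x) = 1.

Each of the four (de)phosphorylation steps follows an independent
Michaelis-Menten rate law.  The kinase Vmax terms are taken proportional
to the measured phospho-MEK level, supplied as the phenomenological
input u(t); the phosphatase Vmax terms carry a condition-specific
fold-factor ``phi`` (1 in control cells, free in proteasome-inhibited
cells) modeling a uniform upregulation of ERK-directed phosphatase
activity:

    dx0/dt = -kc1 u(t) x0/(K1+x0) + phi Vp1 x1/(P1+x1)
    dx2/dt =  kc2 u(t) x1/(K2+x1) - phi Vp2 x2/(P2+x2)
    dx1/dt = -(dx0/dt + dx2/dt)

The measured pERK signal is dual-phosphorylated ERK only, so the
observable is ``scale * x2(t)`` with a fitted scale factor mapping the
dimensionless fraction to the arbitrary units of the normalized blot.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .exceptions import InitializationError, IntegrationError, ValidationError
from .mek_input import MekInputParams, eval_mek_input

__all__ = [
    "ErkModelParams",
    "erk_rhs",
    "steady_state_init",
    "simulate_erk",
    "predicted_perk",
]

#: order of the free parameters throughout the fitting machinery
PARAM_NAMES = ("kc1", "kc2", "K1", "K2", "Vp1", "Vp2", "P1", "P2", "scale", "phi")

_STATE_TOL = 1e-6


@dataclass(frozen=True)
class ErkModelParams:
    """Kinetic constants of the two-site ERK model.

    Units: ``kc1``, ``kc2`` per (a.u. x min) — kinase catalytic rates per
    unit of phospho-MEK signal; ``K1``, ``K2``, ``P1``, ``P2`` in ERK
    fraction; ``Vp1``, ``Vp2`` in fraction/min; ``phi`` dimensionless
    (phosphatase fold-factor, 1 in control); ``scale`` in a.u. per
    fraction.
    """

    kc1: float
    kc2: float
    K1: float
    K2: float
    Vp1: float
    Vp2: float
    P1: float
    P2: float
    phi: float = 1.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        positive = ("kc1", "kc2", "K1", "K2", "Vp1", "Vp2", "P1", "P2", "scale")
        for name in positive:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive and finite, got {v!r}")
        if not (np.isfinite(self.phi) and self.phi >= 0):
            raise ValidationError(f"phi must be non-negative, got {self.phi!r}")

    def with_phi(self, phi: float) -> "ErkModelParams":
        return replace(self, phi=phi)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, values) -> "ErkModelParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))


def _check_state(state: np.ndarray, tol: float = _STATE_TOL) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (3,):
        raise ValidationError(f"state must have 3 components, got {state.shape}")
    if np.any(state < -tol) or abs(state.sum() - 1.0) > tol:
        raise ValidationError(
            f"invalid ERK state {state}: components must be >= -{tol} and sum to 1"
        )
    return state


def erk_rhs(
    state, t: float, params: ErkModelParams, mek_input: MekInputParams
) -> np.ndarray:
    """Time derivative of (x0, x1, x2); the components sum to 0 exactly."""
    x0, x1, x2 = _check_state(state)
    u = eval_mek_input(mek_input, t)
    return _rhs_raw(x0, x1, x2, u, params)


def _rhs_raw(x0, x1, x2, u, params: ErkModelParams) -> np.ndarray:
    v01 = params.kc1 * u * x0 / (params.K1 + x0)
    v10 = params.phi * params.Vp1 * x1 / (params.P1 + x1)
    v12 = params.kc2 * u * x1 / (params.K2 + x1)
    v21 = params.phi * params.Vp2 * x2 / (params.P2 + x2)
    dx0 = -v01 + v10
    dx2 = v12 - v21
    dx1 = -dx0 - dx2
    return np.array([dx0, dx1, dx2])


def steady_state_init(params: ErkModelParams, basal_input: float) -> np.ndarray:
    """Pre-stimulus steady state under constant input ``u = basal_input``.

    Solves the reduced 2-D system in (x1, x2) with x0 = 1 - x1 - x2 by
    root finding; the returned state has componentwise |rhs| < 1e-10.
    With zero input the phosphatases win and the fixed point is the
    fully dephosphorylated state (1, 0, 0).
    """
    if basal_input < 0:
        raise ValueError("basal_input must be non-negative")
    if basal_input == 0:
        return np.array([1.0, 0.0, 0.0])

    def reduced(y):
        x1, x2 = y
        dx0, _, dx2 = _rhs_raw(1.0 - x1 - x2, x1, x2, basal_input, params)
        return [dx0, dx2]

    def admissible(x1, x2):
        x0 = 1.0 - x1 - x2
        state = np.array([x0, x1, x2])
        rhs = _rhs_raw(x0, x1, x2, basal_input, params)
        ok = np.all(state >= -1e-12) and np.all(state <= 1 + 1e-12)
        return (np.clip(state, 0.0, 1.0), ok and np.max(np.abs(rhs)) < 1e-10)

    starts = [(0.05, 0.05), (0.2, 0.2), (0.4, 0.1), (0.1, 0.4), (0.01, 0.01)]
    for y0 in starts:
        sol = root(reduced, y0, method="hybr", tol=1e-14)
        state, ok = admissible(*sol.x)
        if sol.success and ok:
            return state
    # direct root finding failed: relax toward the attractor by long
    # integration from the dephosphorylated corner, then polish
    relaxed = solve_ivp(
        lambda t, y: _rhs_raw(1.0 - y[0] - y[1], y[0], y[1], basal_input, params)[1:],
        (0.0, 1e6),
        [0.0, 0.0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    sol = root(reduced, relaxed.y[:, -1], method="hybr", tol=1e-14)
    state, ok = admissible(*sol.x)
    if ok:
        return state
    raise InitializationError(
        f"no admissible steady state found for basal input {basal_input}"
    )


def simulate_erk(
    params: ErkModelParams,
    mek_input: MekInputParams,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the model from its pre-stimulus steady state.

    ``times`` must be sorted with ``times[0] == 0``.  Returns an array of
    shape ``(len(times), 3)`` of states; mass conservation holds to 1e-6
    at every output time (checked).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] != 0:
        raise ValueError("times must start at 0 (pre-stimulation baseline)")

    y0 = steady_state_init(params, eval_mek_input(mek_input, 0.0))
    if len(times) == 1:
        return y0[None, :]

    def rhs(t, y):
        return _rhs_raw(y[0], y[1], y[2], eval_mek_input(mek_input, t), params)

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    traj = sol.y.T
    err = np.abs(traj.sum(axis=1) - 1.0)
    if np.max(err) > _STATE_TOL:
        raise IntegrationError(
            f"mass conservation violated: max |sum(x)-1| = {np.max(err):.2e}"
        )
    return traj


def predicted_perk(
    params: ErkModelParams, mek_input: MekInputParams, times
) -> np.ndarray:
    """Model observable: ``scale * x2(t)``, comparable to measured pERK."""
    traj = simulate_erk(params, mek_input, times)
    return params.scale * traj[:, 2]
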