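"""Concentration-time simulation for IV-infusion compartmental models.

The production path (:func:`simulate_profile`) superposes the closed-form
constant-rate-infusion solution of the 1- or 2-compartment model over the
dose events; linear PK makes the superposition exact. Writing the unit-bolus
disposition as a sum of exponentials ``C(t) = sum_i A_i exp(-lambda_i t)``,
an infusion at rate R over [0, T] contributes

    R * sum_i (A_i/lambda_i) * (1 - exp(-lambda_i t))                 t <= T
    R * sum_i (A_i/lambda_i) * (1 - exp(-lambda_i T)) * exp(-lambda_i (t-T))   t > T

For the 2-compartment model the eigenvalues are the roots of
``lambda^2 - (k10+k12+k21) lambda + k10 k21 = 0`` with micro-constants
k10 = CL/V1, k12 = Q/V1, k21 = Q/V2.

:func:`ode_profile` integrates the same mass-balance ODEs numerically
(piecewise between infusion on/off switch points) and serves as the
independent reference path for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .model import IndividualParameters
from .regimens import DoseSchedule


@dataclass
class ConcentrationProfile:
    """Total (and optionally unbound) drug concentration on a time grid."""

    subject_id: str
    time: np.ndarray  # h since birth
    total: np.ndarray  # mg/L
    unbound: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if self.time.shape != self.total.shape:
            raise ValueError("time and total grids must have the same shape")


def default_time_grid(window_h: float = 48.0, step_h: float = 0.05) -> np.ndarray:
    """Regular simulation grid over [0, window] hours."""
    n = int(round(window_h / step_h))
    return np.linspace(0.0, window_h, n + 1)


def disposition_exponentials(params: IndividualParameters) -> list[tuple[float, float]]:
    """Unit-bolus macro-coefficients ``[(A_i, lambda_i), ...]`` (central cpt)."""
    if params.q is None:
        return [(1.0 / params.v, params.cl / params.v)]
    k10 = params.cl / params.v
    k12 = params.q / params.v
    k21 = params.q / params.v2
    s = k10 + k12 + k21
    prod = k10 * k21
    disc = math.sqrt(max(s * s - 4.0 * prod, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    if lam1 - lam2 < 1e-12 * lam1:
        # repeated-eigenvalue corner (k10 == k21, Q -> 0): nudge apart; the
        # perturbation is far below the solver tolerances used in tests
        lam1 *= 1.0 + 1e-9
        lam2 *= 1.0 - 1e-9
    a1 = (lam1 - k21) / ((lam1 - lam2) * params.v)
    a2 = (k21 - lam2) / ((lam1 - lam2) * params.v)
    return [(a1, lam1), (a2, lam2)]


def simulate_profile(
    params: IndividualParameters,
    schedule: DoseSchedule,
    time_grid: np.ndarray,
) -> ConcentrationProfile:
    """Closed-form concentration profile by superposition of dose events.

    The grid must be sorted and non-negative; overlapping infusions are
    allowed (rates add). The result is linear in dose and continuous in time.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time_grid must be a non-empty 1-D array")
    if np.any(t < 0):
        raise ValueError("time_grid must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("time_grid must be sorted")

    exps = disposition_exponentials(params)
    conc = np.zeros_like(t)
    for ev in schedule.events:
        te = t - ev.start_time
        during = (te >= 0) & (te < ev.duration)
        after = te >= ev.duration
        for a, lam in exps:
            coef = ev.rate * a / lam
            conc[during] += coef * -np.expm1(-lam * te[during])
            conc[after] += coef * -np.expm1(-lam * ev.duration) * np.exp(
                -lam * (te[after] - ev.duration)
            )
    return ConcentrationProfile(schedule.subject_id, t, conc)


def ode_profile(
    params: IndividualParameters,
    schedule: DoseSchedule,
    time_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> ConcentrationProfile:
    """Reference profile by stiff-tolerance numeric integration of the
    compartmental mass-balance ODEs; same contract as :func:`simulate_profile`."""
    t = np.asarray(time_grid, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("time_grid must be sorted and non-negative")

    two_cpt = params.q is not None
    k10 = params.cl / params.v
    k12 = params.q / params.v if two_cpt else 0.0
    k21 = params.q / params.v2 if two_cpt else 0.0

    def infusion_rate(tt: float) -> float:
        return sum(
            ev.rate for ev in schedule.events if ev.start_time <= tt < ev.start_time + ev.duration
        )

    def rhs(tt: float, y: np.ndarray) -> list[float]:
        rate = infusion_rate(tt)
        if two_cpt:
            return [rate - (k10 + k12) * y[0] + k21 * y[1], k12 * y[0] - k21 * y[1]]
        return [rate - k10 * y[0]]

    # integrate piecewise between infusion switch points so the solver never
    # steps across a rate discontinuity
    breaks = {0.0, float(t[-1])}
    for ev in schedule.events:
        for b in (ev.start_time, ev.start_time + ev.duration):
            if 0.0 <= b <= t[-1]:
                breaks.add(float(b))
    breaks = sorted(breaks)

    y = np.zeros(2 if two_cpt else 1)
    amounts = np.full(t.shape, np.nan)
    if t[0] == 0.0:
        amounts[t == 0.0] = 0.0
    for left, right in zip(breaks[:-1], breaks[1:]):
        mask = (t > left) & (t <= right)
        # always evaluate the segment endpoint so the carried state is exact
        t_eval = np.unique(np.concatenate((t[mask], [right])))
        sol = solve_ivp(
            rhs,
            (left, right),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{left}, {right}]: {sol.message}")
        amounts[mask] = np.interp(t[mask], sol.t, sol.y[0])
        y = sol.y[:, -1]
    if np.any(np.isnan(amounts)):
        raise RuntimeError("ODE oracle failed to evaluate every grid point")
    return ConcentrationProfile(schedule.subject_id, t, amounts / params.v)


def batch_profile(
    cl: np.ndarray,
    v: np.ndarray,
    schedule: DoseSchedule,
    times: np.ndarray,
    q: Optional[np.ndarray] = None,
    v2: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Vectorized closed-form solution for many parameter sets on one schedule.

    Returns an ``(n_sets, n_times)`` concentration matrix; used by the
    simulation-based diagnostics, where thousands of between-subject
    variability replicates share a subject's dose history and sample times.
    """
    cl = np.atleast_1d(np.asarray(cl, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    t = np.asarray(times, dtype=float)
    if q is None:
        lams = [cl / v]
        coeffs = [1.0 / v]
    else:
        q = np.atleast_1d(np.asarray(q, dtype=float))
        v2 = np.atleast_1d(np.asarray(v2, dtype=float))
        k10, k12, k21 = cl / v, q / v, q / v2
        s = k10 + k12 + k21
        disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
        lam1 = 0.5 * (s + disc)
        lam2 = 0.5 * (s - disc)
        close = lam1 - lam2 < 1e-12 * lam1
        lam1 = np.where(close, lam1 * (1 + 1e-9), lam1)
        lam2 = np.where(close, lam2 * (1 - 1e-9), lam2)
        lams = [lam1, lam2]
        coeffs = [(lam1 - k21) / ((lam1 - lam2) * v), (k21 - lam2) / ((lam1 - lam2) * v)]

    conc = np.zeros((cl.size, t.size))
    for ev in schedule.events:
        te = t - ev.start_time
        during = (te >= 0) & (te < ev.duration)
        after = te >= ev.duration
        for a, lam in zip(coeffs, lams):
            coef = (ev.rate * a / lam)[:, None]
            lam_c = lam[:, None]
            if during.any():
                conc[:, during] += coef * -np.expm1(-lam_c * te[during])
            if after.any():
                conc[:, after] += (
                    coef * -np.expm1(-lam_c * ev.duration) * np.exp(-lam_c * (te[after] - ev.duration))
                )
    return conc
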