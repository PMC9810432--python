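"""Phase reduction of a single self-coupled neural mass and its period.

A single node with delayed self-coupling,

    dz/dt = F(z) + kappa tanh(c x(t - tau)),    lam > 0,

oscillates near the elliptical limit cycle of F.  For weak coupling its state
is captured by the phase theta on that cycle:

    dtheta/dt = omega + kappa f(theta(t), theta(t - tau)),
    f(p, q)   = -sin(p)/(a sqrt(lam)) * tanh(c a sqrt(lam) cos(q)).

The period T (smallest T with theta(T) - theta(0) = 2*pi) admits a closed
expansion for small c after approximating the delayed phase as free-running
(theta(t - tau) ~ theta - omega*tau):

    T ~ 2*pi/omega
        - pi c (a^2 c^2 lam - 4) sin(tau omega) / (4 omega^2) * kappa
        + pi c^2 ((2 a^2 c^2 lam - 3) cos(2 tau omega) - 3 a^2 c^2 lam + 6)
          / (12 omega^3) * kappa^2 + O(kappa^3, c^5),

so the sign of sin(omega*tau) decides whether weak self-coupling slows or
accelerates the oscillator, and (at tau = 0) decreasing the excitatory
parameter ``a`` lengthens the period: frequency slowing from excitatory loss.

Two leading-order (single-kappa-term) variants are exposed: the compact
form with coefficient c*pi*sin(omega tau)/(4 omega^2), and the c^1
truncation of the full expansion, c*pi*sin(omega tau)/omega^2 — the two are
inconsistent by a factor 4 and the numeric period is the referee.
Here ``omega`` is the literal angular rate, so T = 2*pi/omega at kappa = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AssumptionViolationError, ParameterError
from .neural_dynamics import _phase_kernel, simulate_selfcoupled

ANALYTIC_FORMS = ("order2", "small_tau", "leading", "leading_consistent")


@dataclass
class SelfCoupledParams:
    """Parameters of the delayed self-coupled node (omega in rad/s)."""

    omega: float = 1.0
    a: float = 1.0
    b: float = 1.0
    c: float = 1.0
    lam: float = 1.0
    kappa: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ParameterError("lam must be positive for oscillatory analysis")
        if self.a <= 0 or self.b <= 0:
            raise ParameterError("a and b must be positive")
        if self.kappa < 0 or self.tau < 0:
            raise ParameterError("kappa and tau must be nonnegative")


@dataclass
class PeriodResult:
    period: float
    method: str

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ParameterError("period must be positive")


def phase_rhs(theta_now: float, theta_delayed: float, p: SelfCoupledParams) -> float:
    """Instantaneous phase velocity omega + kappa f(theta, theta_delayed)."""
    asl = p.a * math.sqrt(p.lam)
    f = -math.sin(theta_now) / asl * math.tanh(p.c * asl * math.cos(theta_delayed))
    return p.omega + p.kappa * f


def _mean_crossing_period(t: np.ndarray, x: np.ndarray, min_cycles: int) -> float:
    """Mean interval between upward zero crossings, linearly refined."""
    up = np.nonzero((x[:-1] < 0.0) & (x[1:] >= 0.0))[0]
    if up.size < min_cycles + 1:
        raise AssumptionViolationError("too few zero crossings to estimate a period")
    frac = -x[up] / (x[up + 1] - x[up])
    times = t[up] + frac * (t[up + 1] - t[up])
    return (times[-1] - times[0]) / (times.size - 1)


def period_numeric(
    system: str,
    p: SelfCoupledParams,
    transient_cycles: int = 50,
    measure_cycles: int = 25,
    dt_factor: float = 1e-3,
) -> PeriodResult:
    """Measure the period of the full DDE or of its phase reduction.

    full:  simulate the self-coupled node, discard ``transient_cycles``, and
    average the interval between upward zero crossings of x.
    phase: simulate the phase equation and average the time per 2*pi of
    accumulated phase.  A non-increasing phase raises
    :class:`AssumptionViolationError` (the reduction assumes theta' > 0).
    """
    if system not in ("full", "phase"):
        raise ParameterError("system must be 'full' or 'phase'")
    if measure_cycles < 20:
        raise ParameterError("average over at least 20 cycles")
    t0 = 2.0 * math.pi / p.omega
    dt = dt_factor * t0
    duration = (transient_cycles + measure_cycles + 3) * t0

    if system == "full":
        t, x = simulate_selfcoupled(p, duration, dt)
        keep = t >= transient_cycles * t0
        period = _mean_crossing_period(t[keep], x[keep], measure_cycles)
        return PeriodResult(period, "full_numeric")

    tau_steps = 0 if p.tau == 0 else max(1, int(round(p.tau / dt)))
    n_steps = int(round(duration / dt))
    th = _phase_kernel(
        0.0, float(p.omega), float(p.kappa), p.a * math.sqrt(p.lam), float(p.c),
        tau_steps, dt, n_steps
    )
    if np.any(np.diff(th) <= 0.0):
        raise AssumptionViolationError("phase velocity is not strictly positive")
    t = np.arange(n_steps + 1) * dt
    skip = int(round(transient_cycles * t0 / dt))
    th0 = th[skip]
    targets = th0 + 2.0 * math.pi * np.arange(measure_cycles + 1)
    if targets[-1] > th[-1]:
        raise AssumptionViolationError("simulation too short to accumulate the phase")
    idx = np.searchsorted(th, targets)
    frac = (targets - th[idx - 1]) / (th[idx] - th[idx - 1])
    times = t[idx - 1] + frac * dt
    return PeriodResult((times[-1] - times[0]) / measure_cycles, "phase_numeric")


def period_analytic(p: SelfCoupledParams, form: str = "order2") -> PeriodResult:
    """Evaluate the closed-form period expansions exactly as written above."""
    if form not in ANALYTIC_FORMS:
        raise ParameterError(f"form must be one of {ANALYTIC_FORMS}")
    om, a, c, lam, k, tau = p.omega, p.a, p.c, p.lam, p.kappa, p.tau
    base = 2.0 * math.pi / om
    if form == "order2":
        t1 = -math.pi * c * (a**2 * c**2 * lam - 4.0) * math.sin(tau * om) / (4.0 * om**2)
        t2 = (
            math.pi
            * c**2
            * ((2.0 * a**2 * c**2 * lam - 3.0) * math.cos(2.0 * tau * om)
               - 3.0 * a**2 * c**2 * lam + 6.0)
            / (12.0 * om**3)
        )
        period = base + t1 * k + t2 * k**2
        tag = "analytic_order2"
    elif form == "small_tau":
        t1 = tau * c * math.pi * (4.0 + 1.5 * om**2 * c**2 * k**2 - a**2 * c**2 * lam) / (4.0 * om)
        t2 = c**2 * math.pi * (3.0 - a**2 * c**2 * lam) / (12.0 * om**3)
        period = base + t1 * k + t2 * k**2
        tag = "analytic_small_tau"
    elif form == "leading":
        period = base + c * math.pi * math.sin(om * tau) / (4.0 * om**2) * k
        tag = "analytic_leading"
    else:
        period = base + c * math.pi * math.sin(om * tau) / om**2 * k
        tag = "analytic_leading_consistent"
    return PeriodResult(period, tag)


def kappa_sweep(
    p: SelfCoupledParams,
    kappa_grid: Iterable[float],
    tau_list: Sequence[float],
    **numeric_kwargs,
) -> pd.DataFrame:
    """Period-vs-coupling comparison table across delays.

    Columns: tau, kappa, T_full, T_phase, T_analytic_order2, T_analytic_leading.
    """
    rows = []
    for tau in tau_list:
        for kappa in kappa_grid:
            pk = replace(p, kappa=float(kappa), tau=float(tau))
            rows.append(
                {
                    "tau": tau,
                    "kappa": kappa,
                    "T_full": period_numeric("full", pk, **numeric_kwargs).period,
                    "T_phase": period_numeric("phase", pk, **numeric_kwargs).period,
                    "T_analytic_order2": period_analytic(pk, "order2").period,
                    "T_analytic_leading": period_analytic(pk, "leading").period,
                }
            )
    return pd.DataFrame(rows)
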