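"""Plasma EPO pharmacokinetics for piecewise-constant administration rates.

The plasma EPO concentration is split into the constant endogenous level
``E_end`` and an exogenous part ``E_ex`` obeying first-order elimination,

    dE_ex/dt = u(t) / V - lam * E_ex,      E_ex(t1) = E_ex0,

where ``u(t)`` is the administration schedule in U/day, ``V`` is the plasma
distribution volume in liters (so concentrations are in U/l, numerically equal
to mU/ml), and ``lam = log(2)/T_half`` is the degradation rate.  Because the
schedule is piecewise constant the solution is available in closed form as a
sum of single-interval exponential responses; this closed form — not numerical
ODE integration — is used everywhere inside the time stepping, and its
gradient with respect to the rate vector is exact and independent of the rates
(the concentration is affine in ``u``, so the Hessian vanishes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .patients import PatientParameters

__all__ = ["ControlSchedule", "EpoTrajectory", "epo_concentration", "epo_gradient"]


@dataclass(frozen=True)
class ControlSchedule:
    """Piecewise-constant EPO rates on a strictly increasing breakpoint grid.

    ``rates[j]`` applies on the half-open interval
    ``[breakpoints[j], breakpoints[j+1])``; rates are box-constrained to
    ``[0, u_max]``.
    """

    breakpoints: tuple[float, ...]
    rates: tuple[float, ...]
    u_max: float = 1000.0

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, float)
        r = np.asarray(self.rates, float)
        if bp.ndim != 1 or bp.size != r.size + 1:
            raise ValueError("need n_u + 1 breakpoints for n_u rates")
        if not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(r < -1e-12) or np.any(r > self.u_max + 1e-12):
            raise ValueError(f"rates must lie in [0, u_max={self.u_max:g}]")

    @classmethod
    def uniform(
        cls,
        rates,
        t_start: float = 0.0,
        period: float = 1.0,
        u_max: float = 1000.0,
    ) -> "ControlSchedule":
        """Schedule with equal-length constant-rate intervals."""
        rates = tuple(float(r) for r in np.atleast_1d(rates))
        bp = tuple(t_start + period * j for j in range(len(rates) + 1))
        return cls(breakpoints=bp, rates=rates, u_max=u_max)

    @property
    def n_u(self) -> int:
        return len(self.rates)

    @property
    def span(self) -> tuple[float, float]:
        return self.breakpoints[0], self.breakpoints[-1]

    @property
    def constant_period(self) -> float:
        widths = np.diff(self.breakpoints)
        if not np.allclose(widths, widths[0]):
            raise ValueError("schedule intervals have unequal lengths")
        return float(widths[0])

    def replace_rates(self, rates) -> "ControlSchedule":
        return ControlSchedule(self.breakpoints, tuple(float(r) for r in rates), self.u_max)


def _check_span(t: np.ndarray, sched: ControlSchedule) -> None:
    lo, hi = sched.span
    if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
        raise ValueError(f"time outside the schedule span [{lo:g}, {hi:g}]")


def _sensitivity_matrix(
    t: np.ndarray, sched: ControlSchedule, lam: float, volume_l: float
) -> np.ndarray:
    """``S[m, j] = dE(t_m)/du_j`` for the closed-form concentration.

    The response of interval ``j`` at a later time ``t`` is
    ``(exp(-lam*max(t - b_{j+1}, 0)) - exp(-lam*(t - b_j))) / (V*lam)``
    and zero for ``t <= b_j``; all exponents are kept non-positive for
    numerical stability.  The matrix does not depend on the rates.
    """
    t = np.atleast_1d(np.asarray(t, float))
    bp = np.asarray(sched.breakpoints, float)
    left = bp[:-1][None, :]
    right = bp[1:][None, :]
    tt = t[:, None]
    started = tt > left
    a = np.exp(-lam * np.maximum(tt - right, 0.0))
    b = np.exp(-lam * np.maximum(tt - left, 0.0))
    return np.where(started, (a - b) / (volume_l * lam), 0.0)


def epo_concentration(
    t,
    sched: ControlSchedule,
    p: PatientParameters,
    E_ex0: float | None = None,
):
    """Plasma EPO concentration ``E(t; u)`` in U/l from the closed form.

    ``E_ex0`` is the exogenous concentration at the first breakpoint and
    defaults to the patient's ``E_ex0``.  Scalar in, scalar out.
    """
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, float))
    _check_span(t, sched)
    e0 = p.E_ex0 if E_ex0 is None else float(E_ex0)
    lam, vol = p.lam, p.plasma_volume_l
    S = _sensitivity_matrix(t, sched, lam, vol)
    E = p.E_end + np.exp(-lam * (t - sched.breakpoints[0])) * e0 + S @ np.asarray(sched.rates)
    return float(E[0]) if scalar else E


def epo_gradient(t, sched: ControlSchedule, p: PatientParameters) -> np.ndarray:
    """Gradient of ``E(t; u)`` with respect to the rate vector.

    Components of intervals starting at or after ``t`` are zero; the gradient
    does not depend on ``u`` (the map is affine, the Hessian is zero).  For
    array ``t`` the result has shape ``(len(t), n_u)``.
    """
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, float))
    _check_span(t, sched)
    S = _sensitivity_matrix(t, sched, p.lam, p.plasma_volume_l)
    return S[0] if scalar else S


@dataclass(frozen=True)
class EpoTrajectory:
    """Evaluator bundle for one schedule: ``E(t)`` with its positivity bound.

    ``E_min = E_end + exp(-lam * (T - t1)) * E_ex0`` is a strictly positive
    lower bound of the concentration over the schedule span for every
    admissible rate vector.
    """

    schedule: ControlSchedule
    patient: PatientParameters
    E_ex0: float = 0.0
    evaluator: Callable[[np.ndarray], np.ndarray] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "evaluator",
            lambda t: epo_concentration(t, self.schedule, self.patient, self.E_ex0),
        )

    @property
    def E_min(self) -> float:
        lo, hi = self.schedule.span
        return self.patient.E_end + float(np.exp(-self.patient.lam * (hi - lo))) * self.E_ex0

    def __call__(self, t):
        return self.evaluator(t)
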