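"""Forward simulation of the coupled five-class system and its observables.

Time integration uses the implicit Euler method on the Galerkin coefficient
ODEs; the five classes are solved consecutively within each step, with the
boundary influx of a class taken from the already-updated upstream class at
the new time level and the EPO concentration evaluated by its closed form at
the step end (fully implicit treatment of all coefficients).

The internal state carries densities in units of 1e8 cells per day of
maturity (``CELL_SCALE``); all public observables — total RBC population
``P`` and hemoglobin — are reported unscaled.  The discretized total
population is simply ``sqrt(w5) * y5_0`` (only the constant mode carries
mass), which also equals the quadrature of the reconstructed density.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _engine, rates as _rates
from .epo_pk import ControlSchedule, epo_concentration
from .patients import CELL_SCALE, PatientParameters
from .spectral import DEFAULT_N, AssembledOperators, operators_for, steady_state_class

__all__ = [
    "SpectralState",
    "Trajectory",
    "hgb",
    "population",
    "steady_state",
    "step_implicit_euler",
    "simulate",
    "apply_bleed",
]


def hgb(P: float, c_tbv: float, MCH: float = 29.0) -> float:
    """Hemoglobin concentration (g/dl) from the total RBC count.

    ``Hgb = P * MCH / (c_tbv * 1e10)`` with ``P`` in cells, ``MCH`` in pg and
    ``c_tbv`` in ml.
    """
    if c_tbv <= 0:
        raise ValueError("c_tbv must be positive")
    return P * MCH / (c_tbv * 1e10)


@dataclass(frozen=True)
class SpectralState:
    """Coefficient vectors of the five classes at one time instant.

    ``coeffs[i, j]`` is the j-th Legendre coefficient of class i+1, in
    1e8-cell density units.
    """

    coeffs: np.ndarray  # (5, N)
    t: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, float)
        if c.ndim != 2 or c.shape[0] != 5:
            raise ValueError("coeffs must have shape (5, N)")
        if not np.all(np.isfinite(c)):
            raise ValueError("state coefficients must be finite")
        object.__setattr__(self, "coeffs", c)

    @property
    def N(self) -> int:
        return self.coeffs.shape[1]

    def population(self, p: PatientParameters) -> float:
        """Total RBC count (cells): ``sqrt(w5) * y5_0`` unscaled."""
        return float(np.sqrt(p.geometry.widths[4]) * self.coeffs[4, 0] * CELL_SCALE)

    def hgb(self, p: PatientParameters) -> float:
        return hgb(self.population(p), p.c_tbv, p.MCH)


def population(state: SpectralState, p: PatientParameters) -> float:
    return state.population(p)


@dataclass(frozen=True)
class Trajectory:
    """Uniform-grid simulation output.

    ``t``, ``E``, ``P`` and ``hgb`` are aligned arrays (one entry per time
    node); ``final_state`` is the full coefficient state at the last node and
    ``states`` optionally the whole coefficient history (5, K+1, N).
    """

    t: np.ndarray
    E: np.ndarray
    P: np.ndarray
    hgb: np.ndarray
    final_state: SpectralState
    rate: np.ndarray | None = None
    states: np.ndarray | None = None

    def to_frame(self):
        """Tidy table (time, E, P, Hgb and, if known, the applied rate)."""
        import pandas as pd

        data = {"time_days": self.t, "epo_U_per_l": self.E, "rbc_count": self.P, "hgb_g_dl": self.hgb}
        if self.rate is not None:
            data["rate_U_per_day"] = self.rate
        return pd.DataFrame(data)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def steady_state(p: PatientParameters, E: float | None = None, N: int = DEFAULT_N) -> SpectralState:
    """Uncontrolled (or fixed-EPO) equilibrium of the whole lineage.

    Solves the time-invariant balance of each class consecutively 1 -> 5,
    chaining boundary influxes.  With ``E = E_end`` (the default) this is the
    anemic steady state used as the initial condition of every run.
    """
    if E is None:
        E = p.E_end
    ops = operators_for(p, N)
    coeffs = np.zeros((5, N))
    g = p.S0
    for i in range(5):
        coeffs[i] = steady_state_class(i + 1, E, g, p, N)
        if i < 4:
            upstream = float(ops.bvec[i] @ coeffs[i])
            g = _rates.boundary_influx(i + 2, upstream, E, p)
    return SpectralState(coeffs=coeffs, t=0.0)


# ---------------------------------------------------------------------------
# engine plumbing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _StepMatrices:
    Cm: np.ndarray  # (5, N, N): I - dt*A0
    Gm: np.ndarray  # (5, N, N): -dt*A1


_step_cache: dict[tuple, _StepMatrices] = {}


def _step_matrices(ops: AssembledOperators, dt: float) -> _StepMatrices:
    key = (ops.patient, ops.N, dt)
    hit = _step_cache.get(key)
    if hit is None:
        eye = np.eye(ops.N)
        Cm = np.stack([eye - dt * ops.A0[i] for i in range(5)])
        Gm = np.stack([-dt * ops.A1[i] for i in range(5)])
        hit = _StepMatrices(Cm=np.ascontiguousarray(Cm), Gm=np.ascontiguousarray(Gm))
        if len(_step_cache) > 32:
            _step_cache.clear()
        _step_cache[key] = hit
    return hit


def _coefficient_arrays(ops: AssembledOperators, E_nodes: np.ndarray, derivatives: bool = False):
    """Vectorized per-node scalar coefficients for the kernels."""
    p = ops.patient
    K1 = E_nodes.size
    nuv = _rates.nu(E_nodes, p)
    cvar = np.zeros((5, K1))
    cvar[1] = _rates.alpha2(E_nodes, p)
    cvar[3] = nuv
    cvar[4] = _rates.neo_factor(E_nodes, p)
    svals = np.ones((5, K1))
    svals[3] = 1.0 / nuv
    svals[4] = nuv
    if not derivatives:
        return cvar, svals, None, None
    dnuv = _rates.dnu(E_nodes, p)
    dcvar = np.zeros((5, K1))
    dcvar[1] = _rates.dalpha2(E_nodes, p)
    dcvar[3] = dnuv
    dcvar[4] = _rates.dneo_factor(E_nodes, p)
    dsrel = np.zeros((5, K1))
    dsrel[3] = -dnuv / nuv
    dsrel[4] = dnuv / nuv
    return cvar, svals, dcvar, dsrel


def _forward(
    p: PatientParameters,
    N: int,
    dt: float,
    E_nodes: np.ndarray,
    y0: np.ndarray,
):
    ops = operators_for(p, N)
    mats = _step_matrices(ops, dt)
    cvar, svals, _, _ = _coefficient_arrays(ops, E_nodes)
    Y, gout = _engine.forward_scan(
        mats.Cm, mats.Gm, cvar, svals, ops.bvec, ops.dvec, np.ascontiguousarray(y0), dt, p.S0
    )
    return Y, gout, ops, mats, cvar, svals


# ---------------------------------------------------------------------------
# public stepping / simulation
# ---------------------------------------------------------------------------


def step_implicit_euler(
    state: SpectralState,
    t: float,
    dt: float,
    u: ControlSchedule,
    p: PatientParameters,
    E_ex0: float | None = None,
    N: int | None = None,
) -> SpectralState:
    """One implicit-Euler step ``t -> t + dt`` under schedule ``u``.

    ``E_ex0`` is the exogenous EPO concentration at the schedule start.  The
    classes are solved consecutively; each class solves
    ``(I - dt*A_i(E(t+dt))) y(t+dt) = y(t) + dt*g_i(t+dt)*d_i``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    N = state.N if N is None else N
    E_nodes = np.asarray(
        [epo_concentration(t, u, p, E_ex0), epo_concentration(t + dt, u, p, E_ex0)], float
    )
    Y, _, _, _, _, _ = _forward(p, N, dt, E_nodes, state.coeffs)
    return SpectralState(coeffs=Y[:, 1, :], t=t + dt)


def simulate(
    u: ControlSchedule,
    p: PatientParameters,
    t_span: tuple[float, float] | None = None,
    y0: SpectralState | None = None,
    dt: float = 0.01,
    E_ex0: float | None = None,
    N: int = DEFAULT_N,
    store_states: bool = False,
) -> Trajectory:
    """Integrate the coupled system over ``t_span`` under schedule ``u``.

    The initial state defaults to the uncontrolled equilibrium at ``E_end``;
    the EPO concentration is evaluated by its closed form at every step end.
    ``t_span`` must lie inside the schedule span and contain an integer
    number of steps.
    """
    if t_span is None:
        t_span = u.span
    t0, tf = t_span
    if tf <= t0:
        raise ValueError("empty time span")
    K = int(round((tf - t0) / dt))
    if abs(K * dt - (tf - t0)) > 1e-9 * max(1.0, abs(tf - t0)):
        raise ValueError("t_span must contain an integer number of dt steps")
    if y0 is None:
        y0 = steady_state(p, N=N)
    t_nodes = t0 + dt * np.arange(K + 1)
    E_nodes = epo_concentration(t_nodes, u, p, E_ex0)
    Y, _, ops, _, _, _ = _forward(p, N, dt, E_nodes, y0.coeffs)
    sqw5 = np.sqrt(p.geometry.widths[4])
    P = sqw5 * Y[4, :, 0] * CELL_SCALE
    h = P * p.MCH / (p.c_tbv * 1e10)
    # rate applied on [t_m, t_m + dt): schedule lookup at node times
    idx = np.clip(
        np.searchsorted(np.asarray(u.breakpoints), t_nodes, side="right") - 1, 0, u.n_u - 1
    )
    rate = np.asarray(u.rates, float)[idx]
    return Trajectory(
        t=t_nodes,
        E=np.asarray(E_nodes, float),
        P=P,
        hgb=h,
        rate=rate,
        final_state=SpectralState(coeffs=Y[:, K, :], t=tf),
        states=Y if store_states else None,
    )


def apply_bleed(state: SpectralState, target_hgb: float, p: PatientParameters) -> SpectralState:
    """Instantaneous blood loss bringing Hgb down to ``target_hgb``.

    Bleeding removes circulating cells only: the class-5 coefficient vector
    is scaled uniformly by ``target/current`` (age-proportional loss), the
    marrow classes are untouched.
    """
    current = state.hgb(p)
    if target_hgb > current + 1e-12:
        raise ValueError(f"bleed target {target_hgb:g} g/dl exceeds current Hgb {current:.4g} g/dl")
    factor = target_hgb / current
    coeffs = state.coeffs.copy()
    coeffs[4] *= factor
    return dataclasses.replace(state, coeffs=coeffs)
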