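"""Open-loop optimal dosing on one prediction horizon.

The horizon cost balances three terms: a quadratic penalty on the rate
vector, an integral penalty on the deviation of the total RBC population
from the desired population ``P_d`` (obtained from the target Hgb), and a
terminal deviation penalty added for closed-loop stability,

    J(u) = 1/2 sum_j gamma_j |u_j|^2
         + sigma_omega/2 * int |z(t)|^2 dt  +  sigma_f/2 * |z(t_f)|^2,

where ``z(t) = r*(P(t) - P_d)`` with ``r = 2*MCH/(c_tbv*1e10)``, i.e. the
population deviation expressed on the hemoglobin scale (``z`` is twice the
Hgb deviation in g/dl).  The dimensionless weights are
``sigma_omega = 1e4 / horizon`` and ``sigma_f = 1e3``; the per-interval
regularization is ``gamma_j = c_gamma * period / horizon`` so that the same
``c_gamma`` penalizes control effort equally across rate-update periods.
Only ``c_gamma`` is chosen per patient.

Gradients follow the discretize-then-optimize route: the adjoint of the
implicit-Euler/Galerkin scheme itself is solved backward in time (classes
5 -> 1), which makes the gradient exact for the discrete cost and therefore
consistent with finite differences to solver precision.  The box-constrained
problem ``0 <= u <= u_max`` is solved with a projected BFGS method with
Armijo line search; controls are internally rescaled by ``u_max`` for
quasi-Newton conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .epo_pk import ControlSchedule, _sensitivity_matrix
from .patients import CELL_SCALE, PatientParameters
from .simulate import SpectralState, _coefficient_arrays, _forward, _step_matrices
from .spectral import DEFAULT_N, operators_for

__all__ = [
    "CostConfig",
    "OpenLoopResult",
    "cost",
    "gradient",
    "solve_open_loop",
    "projected_bfgs",
]


@dataclass(frozen=True)
class CostConfig:
    """Weights and geometry of the horizon cost.

    ``horizon_days = M * period_days`` is the prediction-horizon length; the
    rate grid has ``M`` intervals of length ``period_days``.  ``sigma_omega``
    and ``sigma_f`` default to ``1e4/horizon_days`` and ``1e3``; ``gamma``
    (per interval) is ``c_gamma * period_days / horizon_days``.
    """

    horizon_days: float
    period_days: float = 1.0
    c_gamma: float = 0.1
    target_hgb: float = 10.5
    u_max: float = 1000.0
    dt: float = 0.1
    N: int = DEFAULT_N
    sigma_omega: float | None = None
    sigma_f: float | None = None

    def __post_init__(self) -> None:
        if self.horizon_days <= 0 or self.period_days <= 0:
            raise ValueError("horizon and period must be positive")
        m = self.horizon_days / self.period_days
        if abs(m - round(m)) > 1e-9:
            raise ValueError("horizon must be an integer number of periods")
        k = self.period_days / self.dt
        if abs(k - round(k)) > 1e-9:
            raise ValueError("period must be an integer number of time steps")

    @property
    def M(self) -> int:
        return int(round(self.horizon_days / self.period_days))

    @property
    def sig_omega(self) -> float:
        return 1e4 / self.horizon_days if self.sigma_omega is None else self.sigma_omega

    @property
    def sig_f(self) -> float:
        return 1e3 if self.sigma_f is None else self.sigma_f

    @property
    def gamma(self) -> float:
        return self.c_gamma * self.period_days / self.horizon_days

    def r(self, p: PatientParameters) -> float:
        """Population-to-hemoglobin scale ``2*MCH/(c_tbv*1e10)`` (g/dl per cell, x2)."""
        return 2.0 * p.MCH / (p.c_tbv * 1e10)

    def desired_population(self, p: PatientParameters) -> float:
        return self.target_hgb * p.c_tbv * 1e10 / p.MCH


def _schedule(u: np.ndarray, t0: float, cfg: CostConfig) -> ControlSchedule:
    return ControlSchedule.uniform(u, t_start=t0, period=cfg.period_days, u_max=cfg.u_max)


def _horizon_eval(
    u: np.ndarray,
    t0: float,
    y0: SpectralState,
    E_ex0: float,
    cfg: CostConfig,
    p: PatientParameters,
    need_grad: bool,
):
    u = np.asarray(u, float)
    sched = _schedule(u, t0, cfg)
    K = int(round(cfg.horizon_days / cfg.dt))
    t_nodes = t0 + cfg.dt * np.arange(K + 1)
    SE = _sensitivity_matrix(t_nodes, sched, p.lam, p.plasma_volume_l)
    E_nodes = (
        p.E_end + np.exp(-p.lam * (t_nodes - t0)) * E_ex0 + SE @ u
    )
    Y, gout, ops, mats, cvar, svals = _forward(p, cfg.N, cfg.dt, E_nodes, y0.coeffs)

    sp = np.sqrt(p.geometry.widths[4]) * CELL_SCALE
    r = cfg.r(p)
    z = r * (sp * Y[4, :, 0] - cfg.desired_population(p))
    trapw = np.ones(K + 1)
    trapw[0] = trapw[-1] = 0.5
    gamma = cfg.gamma
    J = (
        0.5 * gamma * float(u @ u)
        + 0.5 * cfg.sig_omega * cfg.dt * float(trapw @ (z * z))
        + 0.5 * cfg.sig_f * z[-1] ** 2
    )
    if not need_grad:
        return J, None
    _, _, dcvar, dsrel = _coefficient_arrays(ops, E_nodes, derivatives=True)
    src = cfg.sig_omega * cfg.dt * trapw * z * r * sp
    src[-1] += cfg.sig_f * z[-1] * r * sp
    W = _engine.adjoint_scan(
        mats.Cm, mats.Gm, cvar, svals, dsrel, dcvar, ops.bvec, ops.dvec, Y, gout, cfg.dt, src
    )
    grad = gamma * u + SE.T @ W
    return J, grad


def cost(
    u,
    t0: float,
    y0: SpectralState,
    E_ex0: float,
    cfg: CostConfig,
    p: PatientParameters,
) -> float:
    """Horizon cost of a rate vector (tracking integral by composite trapezoid)."""
    J, _ = _horizon_eval(np.asarray(u, float), t0, y0, E_ex0, cfg, p, need_grad=False)
    return J


def gradient(
    u,
    t0: float,
    y0: SpectralState,
    E_ex0: float,
    cfg: CostConfig,
    p: PatientParameters,
) -> np.ndarray:
    """Exact gradient of the discrete cost via the backward adjoint sweep."""
    _, g = _horizon_eval(np.asarray(u, float), t0, y0, E_ex0, cfg, p, need_grad=True)
    return g


# ---------------------------------------------------------------------------
# projected BFGS with Armijo line search
# ---------------------------------------------------------------------------


@dataclass
class OpenLoopResult:
    u: np.ndarray
    cost: float
    grad_norm: float
    iterations: int
    converged: bool
    line_search_failed: bool
    history: list = field(default_factory=list)


def projected_bfgs(
    value_and_grad,
    value,
    x0: np.ndarray,
    lower: float = 0.0,
    upper: float = 1.0,
    gtol_rel: float = 1e-6,
    maxiter: int = 200,
    armijo_c1: float = 1e-4,
    backtrack: float = 0.5,
    max_backtracks: int = 40,
    ftol_rel: float = 0.0,
):
    """Box-constrained quasi-Newton minimization (projected BFGS + Armijo).

    ``value_and_grad(x) -> (f, g)`` and ``value(x) -> f`` evaluate the
    objective; iterates stay inside ``[lower, upper]^n`` via projection.  The
    inverse-Hessian approximation acts on the inactive variables only and is
    reset whenever the active set changes.  Stops when the projected gradient
    satisfies ``||pg||_inf <= gtol_rel * (1 + |f|)``, or — if ``ftol_rel > 0``
    — when the cost decrease stays below ``ftol_rel * (1 + |f|)`` on two
    consecutive accepted steps (stagnation stop for receding-horizon use,
    where the optimum is re-solved every period anyway).

    Returns ``(x, f, pg_norm, iterations, converged, ls_failed, history)``.
    """

    def proj(x):
        return np.clip(x, lower, upper)

    x = proj(np.asarray(x0, float).copy())
    f, g = value_and_grad(x)
    n = x.size
    h0 = 1.0  # running inverse-Hessian scale (s'y / y'y of the last good pair)
    H = np.eye(n)
    history = [(0, f, np.nan, np.nan)]
    act_prev = None
    ls_failed = False
    it = 0
    alpha_prev = 1.0
    stagnant = 0
    tol_edge = 1e-10 * (upper - lower)
    for it in range(1, maxiter + 1):
        pg = x - proj(x - g)
        pg_norm = float(np.max(np.abs(pg))) if n else 0.0
        if pg_norm <= gtol_rel * (1.0 + abs(f)):
            return x, f, pg_norm, it - 1, True, ls_failed, history
        active = ((x <= lower + tol_edge) & (g > 0)) | ((x >= upper - tol_edge) & (g < 0))
        if act_prev is None or not np.array_equal(active, act_prev):
            H = h0 * np.eye(n)
        act_prev = active
        free = ~active
        d = np.zeros(n)
        d[free] = -(H[np.ix_(free, free)] @ g[free])
        d[active] = -h0 * g[active]
        if float(d @ g) >= 0:  # safeguard: fall back to steepest descent
            d = -h0 * g
            H = h0 * np.eye(n)
        alpha = min(1.0, 2.0 * alpha_prev)
        accepted = False
        for _ in range(max_backtracks):
            x_new = proj(x + alpha * d)
            step = x_new - x
            if np.max(np.abs(step)) == 0.0:
                break
            f_new = value(x_new)
            if f_new <= f + armijo_c1 * float(g @ step):
                accepted = True
                break
            alpha *= backtrack
        if not accepted:
            ls_failed = True
            pg = x - proj(x - g)
            return x, f, float(np.max(np.abs(pg))), it, False, True, history
        alpha_prev = alpha
        f_old, g_old, x_old = f, g, x
        x = x_new
        f, g = value_and_grad(x)
        history.append((it, f, alpha, pg_norm))
        if ftol_rel > 0.0:
            stagnant = stagnant + 1 if f_old - f <= ftol_rel * (1.0 + abs(f)) else 0
            if stagnant >= 2:
                pg = x - proj(x - g)
                return x, f, float(np.max(np.abs(pg))), it, True, ls_failed, history
        s = x - x_old
        yk = g - g_old
        sy = float(s @ yk)
        if sy > 1e-12 * float(np.linalg.norm(s) * np.linalg.norm(yk) + 1e-300):
            h0 = sy / float(yk @ yk)
            rho = 1.0 / sy
            I = np.eye(n)
            V = I - rho * np.outer(s, yk)
            H = V @ H @ V.T + rho * np.outer(s, s)
    pg = x - proj(x - g)
    return x, f, float(np.max(np.abs(pg))), it, False, ls_failed, history


def solve_open_loop(
    t0: float,
    y0: SpectralState,
    E_ex0: float,
    cfg: CostConfig,
    p: PatientParameters,
    warm_start: np.ndarray | None = None,
    gtol_rel: float = 1e-6,
    maxiter: int = 200,
    ftol_rel: float = 0.0,
) -> OpenLoopResult:
    """Minimize the horizon cost over admissible rate vectors.

    The iterate sequence stays in ``[0, u_max]^M``; on line-search breakdown
    the best iterate is returned with ``converged=False`` (never silently).
    """
    operators_for(p, cfg.N)  # build caches up front
    M = cfg.M
    if warm_start is None:
        v0 = np.zeros(M)
    else:
        v0 = np.clip(np.asarray(warm_start, float) / cfg.u_max, 0.0, 1.0)
        if v0.size != M:
            raise ValueError(f"warm start has {v0.size} entries, horizon needs {M}")

    def fg(v):
        J, g = _horizon_eval(v * cfg.u_max, t0, y0, E_ex0, cfg, p, need_grad=True)
        return J, g * cfg.u_max

    def fval(v):
        J, _ = _horizon_eval(v * cfg.u_max, t0, y0, E_ex0, cfg, p, need_grad=False)
        return J

    x, f, pg, it, conv, lsf, hist = projected_bfgs(
        fg, fval, v0, 0.0, 1.0, gtol_rel=gtol_rel, maxiter=maxiter, ftol_rel=ftol_rel
    )
    return OpenLoopResult(
        u=x * cfg.u_max,
        cost=f,
        grad_norm=pg,
        iterations=it,
        converged=conv,
        line_search_failed=lsf,
        history=hist,
    )
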