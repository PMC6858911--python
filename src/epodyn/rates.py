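"""EPO-dependent biological rate functions of the five cell classes.

EPO acts at three points of the erythroid lineage: it suppresses apoptosis of
CFU-E cells (sigmoid ``alpha2``), accelerates maturation of marrow
reticulocytes (sigmoid ``nu``) and, below the threshold ``tau_E``, triggers
neocytolysis — selective destruction of young circulating erythrocytes —
through an age-windowed addition to the erythrocyte mortality ``alpha5``.

The neocytolysis switch ``H(tau_E - E) * min(mu8 / E**mu9, mu10)`` is
non-smooth in ``E``; gradient-based dose optimization needs differentiable
dynamics, so the Heaviside step and the min are replaced by the C^2 polynomial
smoothings :func:`heaviside_reg` and :func:`smooth_min` with a single width
``epsilon``.  Outside an ``epsilon``-band the regularized rate coincides
exactly with the non-smooth one.
"""

from __future__ import annotations

import numpy as np

from .patients import PatientParameters

__all__ = [
    "heaviside_reg",
    "dheaviside_reg",
    "smooth_min",
    "alpha2",
    "dalpha2",
    "nu",
    "dnu",
    "neo_factor",
    "dneo_factor",
    "alpha5_reg",
    "boundary_influx",
]


def heaviside_reg(s, eps: float):
    """C^2 polynomial regularization of the Heaviside step.

    Equals 0 for ``s <= 0`` and 1 for ``s >= eps``; on ``(0, eps)`` it is the
    sixth-degree polynomial ``s^4/eps^6 * (10 s^2 - 24 eps s + 15 eps^2)``,
    whose first and second derivatives vanish at both joins.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    s = np.asarray(s, float)
    mid = s**4 / eps**6 * (10.0 * s**2 - 24.0 * eps * s + 15.0 * eps**2)
    out = np.where(s <= 0.0, 0.0, np.where(s >= eps, 1.0, mid))
    return float(out) if out.ndim == 0 else out


def dheaviside_reg(s, eps: float):
    """Derivative of :func:`heaviside_reg`: ``60 s^3 (s - eps)^2 / eps^6`` inside the band."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    s = np.asarray(s, float)
    mid = 60.0 * s**3 * (s - eps) ** 2 / eps**6
    out = np.where((s <= 0.0) | (s >= eps), 0.0, mid)
    return float(out) if out.ndim == 0 else out


def smooth_min(s, tau: float, eps: float):
    """Smooth approximation of ``min(s, tau)``: ``(s - tau) * H_eps(tau - s) + tau``.

    Exact (equal to ``min``) whenever ``s >= tau`` or ``s <= tau - eps``.
    """
    s = np.asarray(s, float)
    out = (s - tau) * heaviside_reg(tau - s, eps) + tau
    return float(out) if np.ndim(out) == 0 else out


def alpha2(E, p: PatientParameters):
    """CFU-E apoptosis rate ``mu1 / (1 + exp(mu2*E - mu3))``; decreasing in E."""
    m1, m2, m3 = p.mu[0], p.mu[1], p.mu[2]
    E = np.asarray(E, float)
    with np.errstate(over="ignore"):  # exp overflow saturates the sigmoid at 0
        out = m1 / (1.0 + np.exp(m2 * E - m3))
    return float(out) if out.ndim == 0 else out


def dalpha2(E, p: PatientParameters):
    m1, m2, m3 = p.mu[0], p.mu[1], p.mu[2]
    E = np.asarray(E, float)
    with np.errstate(over="ignore"):
        ex = np.exp(m2 * E - m3)
        out = -m1 * m2 * ex / (1.0 + ex) ** 2
        out = np.where(np.isfinite(ex), out, 0.0)
    return float(out) if out.ndim == 0 else out


def nu(E, p: PatientParameters):
    """Reticulocyte maturation velocity ``(mu4-mu5)/(1+exp(-mu6*E+mu7)) + mu5``.

    Strictly increasing in E with range ``(mu5, mu4)``.
    """
    m4, m5, m6, m7 = p.mu[3], p.mu[4], p.mu[5], p.mu[6]
    E = np.asarray(E, float)
    out = (m4 - m5) / (1.0 + np.exp(-m6 * E + m7)) + m5
    return float(out) if out.ndim == 0 else out


def dnu(E, p: PatientParameters):
    m4, m5, m6, m7 = p.mu[3], p.mu[4], p.mu[5], p.mu[6]
    E = np.asarray(E, float)
    ex = np.exp(-m6 * E + m7)
    out = (m4 - m5) * m6 * ex / (1.0 + ex) ** 2
    return float(out) if out.ndim == 0 else out


def _power_term(E, p: PatientParameters):
    # mu8 / E**mu9 evaluated in log-space: stable for small E and large mu9.
    E = np.asarray(E, float)
    return np.exp(np.log(p.mu[7]) - p.mu[8] * np.log(E))


def min_band(p: PatientParameters) -> float:
    """Smoothing band of the mortality-cap min: ``min(epsilon, mu10/2)``.

    The Heaviside band ``epsilon`` lives on the EPO-concentration scale,
    while the arguments of the capped min live on the mortality-rate scale
    (per day, of order ``mu10``); capping the band at half the ceiling keeps
    the smoothing local, so the regularized rate is exact outside an
    ``O(min_band)``-neighborhood of the cap.
    """
    return min(p.epsilon, p.mu[9] / 2.0)


def neo_factor(E, p: PatientParameters):
    """Age-independent neocytolysis intensity ``H_eps(tau_E - E) * R_eps(E)``.

    ``R_eps`` is the smoothed ``min(mu8 / E**mu9, mu10)``; the factor vanishes
    identically for ``E >= tau_E`` and multiplies the indicator of the
    neocytolysis age window inside ``alpha5``.
    """
    E = np.asarray(E, float)
    out = heaviside_reg(p.tau_E - E, p.epsilon) * smooth_min(
        _power_term(E, p), p.mu[9], min_band(p)
    )
    return float(out) if np.ndim(out) == 0 else out


def dneo_factor(E, p: PatientParameters):
    """d/dE of :func:`neo_factor` (used by the adjoint gradient)."""
    E = np.asarray(E, float)
    eps, tau = p.epsilon, p.mu[9]
    epsm = min_band(p)
    rho = _power_term(E, p)
    drho = -p.mu[8] * rho / E
    h = heaviside_reg(p.tau_E - E, eps)
    dh = -dheaviside_reg(p.tau_E - E, eps)
    f = (rho - tau) * heaviside_reg(tau - rho, epsm) + tau
    df_drho = heaviside_reg(tau - rho, epsm) - (rho - tau) * dheaviside_reg(tau - rho, epsm)
    out = dh * f + h * df_drho * drho
    return float(out) if np.ndim(out) == 0 else out


def alpha5_reg(x, E, p: PatientParameters):
    """Regularized erythrocyte mortality ``alpha5_0 + chi(x) * neo_factor(E)``.

    ``chi`` is the indicator of the neocytolysis age window; outside that
    window, or for ``E >= tau_E``, the rate is exactly the baseline
    ``alpha5_0``.  Broadcasts over ``x`` and ``E``.
    """
    x = np.asarray(x, float)
    lo, hi = p.neo_window
    chi = ((x >= lo) & (x <= hi)).astype(float)
    out = p.alpha5_0 + chi * np.asarray(neo_factor(E, p))
    return float(out) if np.ndim(out) == 0 else out


def boundary_influx(i: int, upstream_value, E, p: PatientParameters):
    """Boundary influx ``g_i`` of class ``i`` (1-based).

    Class 1 receives the constant stem-cell commitment ``S0``; classes 2 and 3
    receive the upstream boundary *density* unchanged (equal unit
    velocities); class 4 divides by the maturation velocity ``nu(E)`` (flux
    continuity: density = flux / velocity) and class 5 multiplies by it
    (cells leave class 4 at rate ``nu * y4``).
    """
    if i == 1:
        return p.S0
    if i not in (2, 3, 4, 5):
        raise ValueError(f"class index must be 1..5, got {i}")
    v = nu(E, p)
    if np.any(np.asarray(v) <= 0):
        raise ValueError("maturation velocity must be positive")
    if i in (2, 3):
        return upstream_value
    if i == 4:
        return upstream_value / v
    return v * upstream_value
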