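"""Shifted-Legendre spectral Galerkin machinery for the transport equations.

Each class equation is an advection–reaction PDE on its maturity interval,
normalized to the unit interval by ``h(xi) = x_lo + w*xi``.  On the weighted
space ``L2_w(0,1)`` (inner product ``<f,g>_w = w * int f g dxi``) the basis

    e_j(xi) = L_j(-1 + 2*xi) / sqrt(w),      j = 0 .. N-1,

is orthogonal with ``||e_j||_w^2 = 1/(2j+1)``, ``e_j(1) = 1/sqrt(w)`` and
``e_j(0) = (-1)^j / sqrt(w)``.  The boundary influx enters through the
discrete delta representer ``delta_N`` (the Riesz representer of evaluation
at 0 on the span), and the approximating operator of one class is

    A_N(E) phi = -(v(E)/w) phi' + P_N(kappa(h(.); E) phi) - delta_N phi(0),

whose matrix is assembled exactly: derivatives of Legendre polynomials expand
in lower-degree Legendre polynomials, the reaction coefficient is constant in
maturity for the four marrow classes, and for circulating erythrocytes the
age-windowed neocytolysis term factorizes into a fixed indicator-projection
matrix times a scalar function of E.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

from . import rates as _rates
from .patients import PatientParameters

__all__ = [
    "legendre_eval",
    "derivative_matrix",
    "SpectralBasis",
    "delta_representer",
    "project",
    "indicator_mass_matrix",
    "AssembledOperators",
    "assemble_operator",
    "steady_state_class",
]

DEFAULT_N = 15


def legendre_eval(j: int, x):
    """Legendre polynomial ``L_j(x)`` by Bonnet's three-term recursion."""
    if j < 0:
        raise ValueError("degree must be non-negative")
    x = np.asarray(x, float)
    p_prev = np.ones_like(x)
    if j == 0:
        return float(p_prev) if p_prev.ndim == 0 else p_prev
    p = x.copy()
    for k in range(1, j):
        p, p_prev = ((2 * k + 1) * x * p - k * p_prev) / (k + 1), p
    return float(p) if p.ndim == 0 else p


def derivative_matrix(N: int) -> np.ndarray:
    """Coefficients ``C`` with ``L_j' = sum_k C[j, k] L_k``.

    Row ``j`` is the expansion of the derivative of degree ``j`` in
    lower-degree Legendre polynomials of opposite parity:
    ``L_{2m}' = sum_{v<m} (4v+3) L_{2v+1}`` and
    ``L_{2m+1}' = sum_{v<=m} (4v+1) L_{2v}``.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    C = np.zeros((N, N))
    for j in range(N):
        if j % 2 == 0:
            for v in range(j // 2):
                C[j, 2 * v + 1] = 4 * v + 3
        else:
            for v in range((j - 1) // 2 + 1):
                C[j, 2 * v] = 4 * v + 1
    return C


@dataclass(frozen=True)
class SpectralBasis:
    """Orthogonal shifted-Legendre basis of one class on ``[0, 1]``.

    Attributes
    ----------
    N : basis size (polynomial degrees 0..N-1).
    w : class width in days (the weight of the inner product).
    norms_sq : ``||e_j||_w^2 = 1/(2j+1)``.
    at_zero, at_one : boundary values ``e_j(0)``, ``e_j(1)``.
    diff : matrix ``D`` with ``e_j' = sum_k D[k, j] e_k`` (d/dxi).
    delta : delta-representer coefficients ``e_j(0) / ||e_j||_w^2``.
    """

    N: int
    w: float
    norms_sq: np.ndarray = field(init=False, repr=False, compare=False)
    at_zero: np.ndarray = field(init=False, repr=False, compare=False)
    at_one: np.ndarray = field(init=False, repr=False, compare=False)
    diff: np.ndarray = field(init=False, repr=False, compare=False)
    delta: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.N < 1 or self.w <= 0:
            raise ValueError("need N >= 1 and w > 0")
        j = np.arange(self.N)
        object.__setattr__(self, "norms_sq", 1.0 / (2 * j + 1))
        object.__setattr__(self, "at_zero", (-1.0) ** j / np.sqrt(self.w))
        object.__setattr__(self, "at_one", np.ones(self.N) / np.sqrt(self.w))
        # d/dxi L_j(-1+2xi) = 2 L_j'(-1+2xi): column j of `diff` expands e_j'.
        object.__setattr__(self, "diff", 2.0 * derivative_matrix(self.N).T)
        object.__setattr__(self, "delta", self.at_zero / self.norms_sq)

    def evaluate(self, coeffs: np.ndarray, xi) -> np.ndarray:
        """Reconstruct ``sum_j c_j e_j(xi)`` at points ``xi`` in [0, 1]."""
        xi = np.asarray(xi, float)
        V = npleg.legvander(-1.0 + 2.0 * xi, self.N - 1) / np.sqrt(self.w)
        return V @ np.asarray(coeffs, float)

    def boundary_value(self, coeffs: np.ndarray) -> float:
        """Value of the reconstruction at ``xi = 1`` (the class outlet)."""
        return float(self.at_one @ np.asarray(coeffs, float))

    def inner(self, f, g) -> float:
        """Weighted inner product ``<f, g>_w`` of two callables on [0,1]."""
        x, wq = npleg.leggauss(max(4 * self.N, 64))
        xi = 0.5 * (x + 1.0)
        return float(self.w * 0.5 * np.sum(wq * f(xi) * g(xi)))


def delta_representer(basis: SpectralBasis) -> np.ndarray:
    """Coefficients of the discrete delta at 0: ``<delta_N, phi>_w = phi(0)`` on the span."""
    return basis.delta.copy()


def project(f, basis: SpectralBasis, breaks=()) -> np.ndarray:
    """Galerkin coefficients ``<f, e_j>_w / ||e_j||_w^2`` of a function on [0,1].

    Composite Gauss–Legendre quadrature of order ``>= 2N`` per smooth
    subinterval; pass interior discontinuity locations of ``f`` (in xi
    coordinates) via ``breaks`` so each panel integrates a smooth integrand —
    polynomial-times-smooth products are then integrated essentially exactly.
    """
    edges = np.unique(np.clip(np.array([0.0, *breaks, 1.0], float), 0.0, 1.0))
    if edges.size < 2:
        raise ValueError("quadrature failed: empty integration domain")
    xg, wg = npleg.leggauss(max(2 * basis.N, 32))
    moments = np.zeros(basis.N)
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= 0:
            continue
        xi = a + (b - a) * 0.5 * (xg + 1.0)
        wq = (b - a) * 0.5 * wg
        vals = np.asarray(f(xi), float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("quadrature failed: non-finite integrand values")
        V = npleg.legvander(-1.0 + 2.0 * xi, basis.N - 1) / np.sqrt(basis.w)
        moments += basis.w * (V * (wq * vals)[:, None]).sum(axis=0)
    return moments / basis.norms_sq


def indicator_mass_matrix(basis: SpectralBasis, a: float, b: float) -> np.ndarray:
    """Matrix of ``phi -> P_N(chi_[a,b] phi)``: entries ``<chi e_j, e_i>_w / ||e_i||_w^2``.

    ``[a, b]`` is in xi coordinates; the integrand is polynomial, so a single
    Gauss panel on the window is exact.
    """
    a, b = max(0.0, a), min(1.0, b)
    if b <= a:
        return np.zeros((basis.N, basis.N))
    xg, wg = npleg.leggauss(2 * basis.N)
    xi = a + (b - a) * 0.5 * (xg + 1.0)
    wq = (b - a) * 0.5 * wg
    V = npleg.legvander(-1.0 + 2.0 * xi, basis.N - 1) / np.sqrt(basis.w)
    M = basis.w * (V * wq[:, None]).T @ V
    return M / basis.norms_sq[:, None]


class AssembledOperators:
    """Per-class Galerkin matrices of one patient, cached for fast assembly.

    The operator matrix of class ``i`` splits as ``A_i(E) = A0_i + c_i(E) * A1_i``
    with constant matrices and a scalar coefficient:

    ========  ==========================================  ============
    class     constant part ``A0``                        ``c(E)``
    ========  ==========================================  ============
    1 BFU-E   advection + ``beta1 I`` - delta             --
    2 CFU-E   advection + ``beta2 I`` - delta             ``alpha2(E)`` on ``A1 = -I``
    3 EB      advection + ``beta3 I`` - delta             --
    4 retic   ``-alpha4 I`` - delta                       ``nu(E)`` on ``A1 = -(1/w) D``
    5 RBC     advection - ``alpha5_0 I`` - delta          ``neo_factor(E)`` on ``A1 = -K``
    ========  ==========================================  ============

    where "advection" is ``-(1/w) D`` (``D`` the exact Legendre derivative
    matrix), "delta" is the rank-one boundary operator
    ``outer(delta, at_zero)``, and ``K`` is the indicator-projection matrix of
    the neocytolysis age window.
    """

    def __init__(self, p: PatientParameters, N: int = DEFAULT_N):
        p.validate()
        self.patient = p
        self.N = N
        widths = p.geometry.widths
        self.widths = np.asarray(widths)
        self.bases = [SpectralBasis(N, w) for w in widths]
        eye = np.eye(N)
        self.A0 = np.zeros((5, N, N))
        self.A1 = np.zeros((5, N, N))
        self.dvec = np.stack([b.delta for b in self.bases])
        self.bvec = np.stack([b.at_one for b in self.bases])
        self.at0 = np.stack([b.at_zero for b in self.bases])
        self.D_omega = self.bases[0].norms_sq.copy()  # 1/(2j+1), class independent

        kappa_const = [p.beta1, p.beta2, p.beta3, -p.alpha4, -p.alpha5_0]
        for i in range(5):
            b = self.bases[i]
            adv = -(1.0 / b.w) * b.diff
            dterm = np.outer(b.delta, b.at_zero)
            if i == 3:  # velocity nu(E) multiplies the advection part only
                self.A0[i] = kappa_const[i] * eye - dterm
                self.A1[i] = adv
            else:
                self.A0[i] = adv + kappa_const[i] * eye - dterm
                if i == 1:
                    self.A1[i] = -eye
                elif i == 4:
                    w5 = widths[4]
                    lo, hi = p.neo_window
                    self.A1[i] = -indicator_mass_matrix(b, lo / w5, hi / w5)

    def coeff(self, i: int, E):
        """Scalar coefficient ``c_i(E)`` multiplying ``A1`` (1-based class)."""
        p = self.patient
        if i == 2:
            return _rates.alpha2(E, p)
        if i == 4:
            return _rates.nu(E, p)
        if i == 5:
            return _rates.neo_factor(E, p)
        return np.zeros_like(np.asarray(E, float)) if np.ndim(E) else 0.0

    def dcoeff(self, i: int, E):
        """dc_i/dE, needed by the adjoint gradient."""
        p = self.patient
        if i == 2:
            return _rates.dalpha2(E, p)
        if i == 4:
            return _rates.dnu(E, p)
        if i == 5:
            return _rates.dneo_factor(E, p)
        return np.zeros_like(np.asarray(E, float)) if np.ndim(E) else 0.0

    def matrix(self, i: int, E: float) -> np.ndarray:
        """Assembled ``A_i(E)`` for 1-based class index ``i``."""
        if i not in (1, 2, 3, 4, 5):
            raise ValueError(f"class index must be 1..5, got {i}")
        return self.A0[i - 1] + float(self.coeff(i, E)) * self.A1[i - 1]


@functools.lru_cache(maxsize=16)
def _cached_operators(p: PatientParameters, N: int) -> AssembledOperators:
    return AssembledOperators(p, N)


def operators_for(p: PatientParameters, N: int = DEFAULT_N) -> AssembledOperators:
    """Cached :class:`AssembledOperators` for a (hashable) patient record."""
    return _cached_operators(p, N)


def assemble_operator(
    i: int, E: float, p: PatientParameters, N: int = DEFAULT_N
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix ``A_i(E)`` and influx vector ``d_i`` of class ``i`` (1-based)."""
    ops = operators_for(p, N)
    return ops.matrix(i, E), ops.dvec[i - 1].copy()


def steady_state_class(
    i: int, E: float, g: float, p: PatientParameters, N: int = DEFAULT_N
) -> np.ndarray:
    """Equilibrium coefficients of one class at fixed EPO level and influx.

    Solves the time-invariant balance ``0 = A_i(E) y + g d_i``.  A singular
    operator is reported, not masked.
    """
    A, d = assemble_operator(i, E, p, N)
    try:
        return np.linalg.solve(A, -g * d)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular steady-state system for class {i} at E={E:g}: {err}"
        ) from err
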