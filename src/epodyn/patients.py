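"""Patient parameter records and calibrated synthetic-patient generation.

A :class:`PatientParameters` record collects every patient-specific constant of
the erythropoiesis model: the ten sigmoid/mortality shape parameters
``mu[0..9]``, the committed stem-cell influx ``S0``, per-class proliferation
and apoptosis rates, the endogenous EPO level ``E_end``, total blood volume,
the (shortened, dialysis-typical) red-cell lifespan, and the EPO
pharmacokinetic half-life.

Real per-patient parameter sets are obtained by fitting the model to clinical
Hgb/EPO records, which is out of scope here.  Instead this module generates
*synthetic* patients: parameters are sampled inside physiologically motivated
ranges and then passed through :func:`calibrate_patient`, which enforces the
two properties every study patient must have:

(a) the *uncontrolled* steady-state Hgb (no exogenous EPO) lies in the anemic
    band of 7–9.5 g/dl, i.e. well below the 10–12 g/dl clinical target; and
(b) sustained dosing at the reference maximum rate raises the steady-state
    Hgb above 12 g/dl, so the target window is actually reachable
    (controllability).

Because the transport equations are linear in the cell densities, criterion
(a) is met exactly by rescaling ``S0``; criterion (b) is a pure check and its
violation is an explicit error, never silently repaired.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "ClassGeometry",
    "PatientParameters",
    "CalibrationError",
    "make_default_patient",
    "generate_patient",
    "calibrate_patient",
    "save_patient",
    "load_patient",
]

#: Fixed maturity boundaries (days) of the four bone-marrow classes.  Class 5
#: (circulating erythrocytes) restarts at age 0 and ends at the patient's RBC
#: lifespan.
MARROW_BOUNDS = (0.0, 3.0, 8.0, 13.0, 15.5)

#: Measured range of the shortened RBC lifespan in hemodialysis patients (days).
LIFESPAN_RANGE = (37.7, 115.8)

#: Internal scaling of the cell-count equations (densities are carried in
#: units of 1e8 cells / day of maturity).
CELL_SCALE = 1.0e8

#: Reference maximum EPO rate (U/day) used by the controllability check.
U_MAX_REFERENCE = 1000.0

PROFILES = ("high_Eend", "near_threshold", "low_Eend")
Profile = Literal["high_Eend", "near_threshold", "low_Eend"]

_SCHEMA = "epodyn-patient/1"


class CalibrationError(ValueError):
    """A patient parameter set violates one of the calibration criteria."""


@dataclass(frozen=True)
class ClassGeometry:
    """Maturity intervals of the five cell classes.

    ``lower[i] <= x <= upper[i]`` is the age range (days) of class ``i+1``;
    ``widths`` are the interval lengths used to normalize each class onto the
    unit interval for the spectral discretization.
    """

    lower: tuple[float, ...]
    upper: tuple[float, ...]

    @classmethod
    def from_lifespan(cls, rbc_lifespan: float) -> "ClassGeometry":
        lo = (MARROW_BOUNDS[0], MARROW_BOUNDS[1], MARROW_BOUNDS[2], MARROW_BOUNDS[3], 0.0)
        hi = (MARROW_BOUNDS[1], MARROW_BOUNDS[2], MARROW_BOUNDS[3], MARROW_BOUNDS[4], rbc_lifespan)
        return cls(lower=lo, upper=hi)

    @property
    def widths(self) -> tuple[float, ...]:
        return tuple(u - l for l, u in zip(self.lower, self.upper))


@dataclass(frozen=True)
class PatientParameters:
    """All patient-specific constants of the erythropoiesis model.

    Parameters
    ----------
    mu
        Ten positive shape parameters: ``mu[0..2]`` control the CFU-E
        apoptosis sigmoid ``alpha2(E)``, ``mu[3..6]`` the reticulocyte
        maturation-velocity sigmoid ``nu(E)``, and ``mu[7..9]`` the
        neocytolysis mortality term ``min(mu8 / E**mu9, mu10)``.
    S0
        Committed stem-cell influx into the BFU-E class, in 1e8 cells/day.
    beta1, beta2, beta3
        Proliferation rates (1/day) of BFU-E, CFU-E and erythroblasts.
    alpha4
        Apoptosis rate (1/day) of marrow reticulocytes.
    alpha5_0
        Baseline random mortality (1/day) of circulating erythrocytes.
    E_end
        Endogenous EPO concentration in model units (U/l, numerically equal
        to mU/ml); always positive even in dialysis patients.
    c_tbv
        Total blood volume in ml.
    rbc_lifespan
        Maximum age of circulating erythrocytes in days.
    E_ex0
        Exogenous EPO concentration at time zero (same units as ``E_end``).
    T_half
        EPO elimination half-life in days; the degradation rate is
        ``lam = log(2) / T_half``.
    tau_E
        EPO threshold below which neocytolysis (selective destruction of
        young circulating cells) is active.
    neo_window
        Closed age interval (days) of class 5 in which neocytolysis acts.
    MCH
        Mean corpuscular hemoglobin in pg.
    epsilon
        Width (in EPO units) of the smoothed Heaviside/min regularization of
        the neocytolysis switch.
    """

    mu: tuple[float, ...]
    S0: float
    beta1: float
    beta2: float
    beta3: float
    alpha4: float
    alpha5_0: float
    E_end: float
    c_tbv: float
    rbc_lifespan: float
    E_ex0: float = 0.0
    T_half: float = 0.3
    tau_E: float = 80.0
    neo_window: tuple[float, float] = (0.0, 14.0)
    MCH: float = 29.0
    epsilon: float = 1.0

    # -- derived quantities ------------------------------------------------
    @property
    def lam(self) -> float:
        """EPO degradation rate, ``log(2) / T_half`` (1/day)."""
        return math.log(2.0) / self.T_half

    @property
    def plasma_volume_l(self) -> float:
        """Blood volume in liters; EPO concentrations are carried in U/l."""
        return self.c_tbv / 1000.0

    @property
    def geometry(self) -> ClassGeometry:
        return ClassGeometry.from_lifespan(self.rbc_lifespan)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        if len(self.mu) != 10:
            raise ValueError("mu must have exactly 10 entries")
        if any(not (m > 0 and math.isfinite(m)) for m in self.mu):
            raise ValueError("all mu parameters must be positive and finite")
        if self.mu[3] <= self.mu[4]:
            raise ValueError("mu4 must exceed mu5 (velocity sigmoid bounds)")
        if not self.E_end > 0:
            raise ValueError("E_end must be positive")
        if not self.c_tbv > 0:
            raise ValueError("c_tbv must be positive")
        if not self.rbc_lifespan > 0:
            raise ValueError("rbc_lifespan must be positive")
        if not self.T_half > 0:
            raise ValueError("T_half must be positive (lam = log2/T_half > 0)")
        lo, hi = self.neo_window
        if not (0.0 <= lo < hi < self.rbc_lifespan):
            raise ValueError(
                "neo_window must be a non-empty interval strictly below the RBC lifespan"
            )
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.E_ex0 < 0:
            raise ValueError("E_ex0 must be non-negative")
        if self.S0 < 0:
            raise ValueError("S0 must be non-negative")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        """Flat key→value mapping (schema-versioned, YAML friendly)."""
        d = {"schema": _SCHEMA}
        for j, m in enumerate(self.mu, start=1):
            d[f"mu{j}"] = float(m)
        for name in (
            "S0",
            "beta1",
            "beta2",
            "beta3",
            "alpha4",
            "alpha5_0",
            "E_end",
            "c_tbv",
            "rbc_lifespan",
            "E_ex0",
            "T_half",
            "tau_E",
            "MCH",
            "epsilon",
        ):
            d[name] = float(getattr(self, name))
        d["neo_lo"], d["neo_hi"] = (float(v) for v in self.neo_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PatientParameters":
        if d.get("schema") != _SCHEMA:
            raise ValueError(f"unknown patient schema {d.get('schema')!r}, expected {_SCHEMA!r}")
        mu = tuple(float(d[f"mu{j}"]) for j in range(1, 11))
        kwargs = {
            name: float(d[name])
            for name in (
                "S0",
                "beta1",
                "beta2",
                "beta3",
                "alpha4",
                "alpha5_0",
                "E_end",
                "c_tbv",
                "rbc_lifespan",
                "E_ex0",
                "T_half",
                "tau_E",
                "MCH",
                "epsilon",
            )
        }
        return cls(mu=mu, neo_window=(float(d["neo_lo"]), float(d["neo_hi"])), **kwargs)


def save_patient(p: PatientParameters, path: str | Path) -> None:
    """Write a patient record as a flat YAML key→value file."""
    Path(path).write_text(yaml.safe_dump(p.to_dict(), sort_keys=True))


def load_patient(path: str | Path) -> PatientParameters:
    """Read a patient record written by :func:`save_patient`."""
    return PatientParameters.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# default patient and calibration
# ---------------------------------------------------------------------------

def _uncalibrated_default(E_end: float = 70.0) -> PatientParameters:
    # Shape parameters: alpha2 and nu sigmoids centered at E = 150 U/l so that
    # both retain slope over the whole reachable EPO range (~20-400 U/l);
    # neocytolysis rate mu8/E^mu9 capped at mu10 per day.
    return PatientParameters(
        mu=(1.4, 0.01, 1.5, 1.8, 0.6, 0.01, 1.5, 30.0, 2.0, 0.05),
        S0=1.0,
        beta1=0.5,
        beta2=1.0,
        beta3=0.45,
        alpha4=0.1,
        alpha5_0=0.01,
        E_end=E_end,
        c_tbv=5000.0,
        rbc_lifespan=80.0,
    )


def make_default_patient() -> PatientParameters:
    """Return the fully calibrated default synthetic patient.

    The default patient has a near-threshold endogenous EPO level
    (``E_end = 70`` against the neocytolysis threshold ``tau_E = 80``), an
    80-day RBC lifespan and an uncontrolled steady-state Hgb of 8.5 g/dl.
    The call is deterministic.
    """
    return calibrate_patient(_uncalibrated_default(), target_hgb=8.5)


def _steady_hgb(p: PatientParameters, E: float, N: int = 15) -> float:
    from .simulate import hgb as _hgb, steady_state as _steady_state

    state = _steady_state(p, E=E, N=N)
    return _hgb(state.population(p), p.c_tbv, p.MCH)


def calibrate_patient(
    p: PatientParameters,
    target_hgb: float = 8.5,
    hgb_band: tuple[float, float] = (7.0, 9.5),
    controllability_hgb: float = 12.0,
    u_max: float = U_MAX_REFERENCE,
    N: int = 15,
) -> PatientParameters:
    """Calibrate a patient record against the two study criteria.

    (a) If the uncontrolled steady-state Hgb falls outside ``hgb_band`` the
        stem-cell influx ``S0`` is rescaled (the model is linear in the cell
        densities, so this is exact) to place it at ``target_hgb``.
    (b) Sustained dosing at ``u_max`` must raise the steady-state Hgb above
        ``controllability_hgb``; a violation raises :class:`CalibrationError`.

    Returns a new record; the input is never modified.
    """
    p.validate()
    if not (hgb_band[0] <= target_hgb <= hgb_band[1]):
        raise ValueError("target_hgb must lie inside hgb_band")
    if p.S0 <= 0:
        raise CalibrationError(
            "anemic steady state unreachable: S0 = 0 gives zero cell influx and zero Hgb"
        )
    h0 = _steady_hgb(p, p.E_end, N=N)
    if not (math.isfinite(h0) and h0 > 0):
        raise CalibrationError(f"uncontrolled steady-state Hgb is degenerate ({h0!r})")
    if not (hgb_band[0] <= h0 <= hgb_band[1]):
        p = dataclasses.replace(p, S0=p.S0 * target_hgb / h0)
        h0 = _steady_hgb(p, p.E_end, N=N)
        if not (hgb_band[0] - 1e-6 <= h0 <= hgb_band[1] + 1e-6):
            raise CalibrationError(
                f"uncontrolled steady-state Hgb {h0:.3f} g/dl cannot be placed in "
                f"[{hgb_band[0]}, {hgb_band[1]}] by rescaling S0"
            )
    e_max = p.E_end + u_max / (p.plasma_volume_l * p.lam)
    h_max = _steady_hgb(p, e_max, N=N)
    if not h_max > controllability_hgb:
        raise CalibrationError(
            f"controllability violated: steady-state Hgb at the maximum rate "
            f"({u_max:g} U/day) is {h_max:.2f} g/dl <= {controllability_hgb:g} g/dl"
        )
    return p


# ---------------------------------------------------------------------------
# synthetic cohort generation
# ---------------------------------------------------------------------------

_EEND_RANGES = {
    "high_Eend": (200.0, 300.0),
    "near_threshold": (60.0, 80.0),
    "low_Eend": (20.0, 60.0),
}


def generate_patient(seed: int, profile: Profile, max_retries: int = 8) -> PatientParameters:
    """Draw a calibrated synthetic patient.

    ``profile`` selects the endogenous EPO level relative to the neocytolysis
    threshold ``tau_E = 80``: far above (``high_Eend``, 200–300), just below
    (``near_threshold``, 60–80) or clearly below (``low_Eend``, 20–60).  The
    RBC lifespan is drawn uniformly from the measured dialysis range of
    37.7–115.8 days; the remaining rates are jittered around the default
    patient.  Records that fail calibration are redrawn from the same stream,
    so the result is a deterministic function of ``(seed, profile)``.
    """
    if profile not in _EEND_RANGES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        e_lo, e_hi = _EEND_RANGES[profile]
        mu2 = rng.uniform(0.008, 0.013)
        mu6 = rng.uniform(0.008, 0.013)
        mu5 = rng.uniform(0.5, 0.7)
        candidate = PatientParameters(
            mu=(
                rng.uniform(1.1, 1.7),
                mu2,
                mu2 * rng.uniform(120.0, 180.0),
                mu5 + rng.uniform(1.0, 1.5),
                mu5,
                mu6,
                mu6 * rng.uniform(120.0, 180.0),
                rng.uniform(15.0, 45.0),
                rng.uniform(1.7, 2.3),
                rng.uniform(0.03, 0.08),
            ),
            S0=1.0,
            beta1=rng.uniform(0.35, 0.6),
            beta2=1.0,
            beta3=rng.uniform(0.3, 0.6),
            alpha4=rng.uniform(0.05, 0.15),
            alpha5_0=rng.uniform(0.005, 0.02),
            E_end=rng.uniform(e_lo, e_hi),
            c_tbv=rng.uniform(4000.0, 6000.0),
            rbc_lifespan=rng.uniform(*LIFESPAN_RANGE),
            T_half=rng.uniform(0.25, 0.35),
        )
        target = rng.uniform(7.8, 9.3)
        try:
            return calibrate_patient(candidate, target_hgb=target)
        except CalibrationError as err:  # redraw
            last_err = err
    raise CalibrationError(
        f"no calibrated patient found for seed={seed}, profile={profile!r} "
        f"after {max_retries} attempts: {last_err}"
    )
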