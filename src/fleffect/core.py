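"""Core-annulus continuum model of the Fåhræus-Lindqvist effect.

Blood flowing through tubes narrower than about 300 μm shows a progressive
drop of its apparent relative viscosity with decreasing diameter (the
Fåhræus-Lindqvist effect).  This module implements a two-fluid explanation:
red blood cells segregate into a central core of relative viscosity
``eta_c`` surrounded by a cell-poor marginal annulus of relative viscosity
``eta_A = 1 + alpha*(eta_c - 1)``, with ``alpha`` small (the classical
Haynes cell-free layer is ``alpha = 0``).  Size exclusion fixes the inlet
core radius at ``s0* = R* - a*`` where ``a*`` is roughly the red-cell
half-thickness; mass conservation between the inlet plug flow and the
developed core-annulus Poiseuille flow then pins the asymptotic core radius
``s_inf`` and hence the apparent relative viscosity

    eta_app = 1 / ( s_inf^4 (1/eta_c - 1/eta_A) + 1/eta_A ).

Sections, in the order the method runs:

1. empirical rheology laws (Charm-Kurland, Pries, Secomb);
2. the core-annulus model proper (inlet radius, asymptotic radius closed
   form + bisection oracle, velocity profile, apparent viscosity + an
   independent quadrature oracle, per-vessel prediction, curves);
3. viscosity-diameter datasets and CSV I/O;
4. bounded nonlinear least-squares fitting of (eta_c, a*, alpha);
5. synthetic dataset generation and packaged literature fixtures.

All lengths are micrometers externally and dimensionless internally; all
viscosities are relative to plasma unless an explicit plasma scale
``eta_p_mPas`` is supplied.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import quad
from scipy.stats import truncnorm

__all__ = [
    # rheology laws
    "charm_kurland_relative_viscosity",
    "charm_kurland_inverse",
    "pries_reference_viscosity_45",
    "pries_shape_exponent",
    "pries_apparent_viscosity",
    "secomb_reference_viscosity_45",
    "secomb_apparent_viscosity",
    "EMPIRICAL_LAWS",
    # core-annulus model
    "ModelParams",
    "CoreAnnulusSolution",
    "VelocityProfile",
    "ContinuumValidityWarning",
    "inlet_core_radius",
    "annulus_viscosity",
    "core_radius_closed_form",
    "core_radius_numeric",
    "velocity_profile",
    "apparent_relative_viscosity",
    "apparent_viscosity_poiseuille_oracle",
    "predict_vessel",
    "viscosity_curve",
    # datasets and I/O
    "ViscosityDataset",
    "read_viscosity_csv",
    "write_curve_csv",
    "CURVE_CSV_COLUMNS",
    "DATASET_CSV_COLUMNS",
    # fitting
    "FitBounds",
    "FitResult",
    "RecoverySummary",
    "model_residuals",
    "fit_parameters",
    "recovery_experiment",
    # synthetic data and fixtures
    "SyntheticSpec",
    "generate_dataset",
    "FixtureTable",
    "fixture",
    "FIXTURE_IDS",
]

logger = logging.getLogger("fleffect")

#: Diameter (μm) below which the continuum description is questionable:
#: vessels a few red-cell sizes wide are at the edge of applicability and
#: predictions there trigger a ContinuumValidityWarning, never an error.
CONTINUUM_THRESHOLD_UM = 30.0

#: Upper guard on hematocrit for the Charm-Kurland law.  The bracket
#: 1 - phi*f(phi) crosses zero near phi ≈ 0.78; 0.7 keeps a safety margin
#: while admitting the largest hematocrit used in practice (~0.66).
CK_PHI_MAX = 0.7

#: Fixed CSV dialects (UTF-8, comma, header required).
CURVE_CSV_COLUMNS = ("diameter_um", "eta_app_rel", "layer_thickness_um")
DATASET_CSV_COLUMNS = ("diameter_um", "eta_app_rel")

#: Numeric formatting used by every CSV writer: 12 significant digits, so
#: write -> read round-trips are lossless at that precision and identical
#: invocations produce byte-identical files.
_CSV_FLOAT_FORMAT = "%.12g"


class ContinuumValidityWarning(UserWarning):
    """Prediction requested below the continuum-validity diameter threshold."""


def _as_float_array(x, name: str) -> tuple[np.ndarray, bool]:
    """Return (array, is_scalar) for a scalar-or-array numeric argument."""
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _scalar_or_array(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


# ---------------------------------------------------------------------------
# 1. Empirical rheology laws
# ---------------------------------------------------------------------------
#
# Three in-vitro correlations from the hemorheology literature.  The
# Charm-Kurland law maps hematocrit to bulk relative viscosity at body
# temperature (the 1107/310 constant is 1107/T with T = 310 K, kept as an
# exact rational).  The Pries and Secomb laws map (tube diameter in μm,
# discharge hematocrit) to apparent relative viscosity and summarise decades
# of glass-tube viscometry.

_CK_TEMPERATURE_CONSTANT = 1107.0 / 310.0


def charm_kurland_relative_viscosity(phi):
    """Bulk relative viscosity of blood at hematocrit ``phi`` (Charm-Kurland).

    eta(phi) = [1 - phi*(0.07*exp(2.49*phi + (1107/310)*exp(-1.69*phi)))]^-1

    Equals 1 at ``phi = 0`` and increases strictly with hematocrit.  Valid
    for ``0 <= phi < 0.7``; beyond that the bracketed factor approaches zero
    (divergent packed-cell limit) and a ValueError is raised rather than
    returning a negative viscosity.
    """
    p, scalar = _as_float_array(phi, "phi")
    if np.any(p < 0.0) or np.any(p >= CK_PHI_MAX):
        raise ValueError(
            f"hematocrit must satisfy 0 <= phi < {CK_PHI_MAX}; got {phi!r}"
        )
    bracket = 1.0 - p * (
        0.07 * np.exp(2.49 * p + _CK_TEMPERATURE_CONSTANT * np.exp(-1.69 * p))
    )
    if np.any(bracket <= 0.0):
        raise ValueError(f"Charm-Kurland bracket non-positive at phi={phi!r}")
    return _scalar_or_array(1.0 / bracket, scalar)


#: Largest relative viscosity attainable within the hematocrit guard;
#: the supremum of the invertible range.
_CK_ETA_SUP = 1.0 / (
    1.0
    - (CK_PHI_MAX - 1e-12)
    * 0.07
    * math.exp(2.49 * (CK_PHI_MAX - 1e-12)
               + _CK_TEMPERATURE_CONSTANT * math.exp(-1.69 * (CK_PHI_MAX - 1e-12)))
)


def charm_kurland_inverse(eta: float) -> float:
    """Hematocrit whose Charm-Kurland relative viscosity equals ``eta``.

    Unique by strict monotonicity; found by bracketed root search on
    [0, 0.7) to absolute tolerance 1e-10.  ``eta`` must lie in the
    attainable range [1, eta(0.7-)).
    """
    eta = float(eta)
    if eta < 1.0:
        raise ValueError(f"relative viscosity must be >= 1; got {eta}")
    if eta == 1.0:
        return 0.0
    if eta >= _CK_ETA_SUP:
        raise ValueError(
            f"eta={eta} above the attainable Charm-Kurland range "
            f"(sup ≈ {_CK_ETA_SUP:.3f} at the phi<{CK_PHI_MAX} guard)"
        )
    f = lambda p: charm_kurland_relative_viscosity(p) - eta
    return float(optimize.brentq(f, 0.0, CK_PHI_MAX - 1e-12, xtol=1e-10))


def _check_positive_diameter(d) -> tuple[np.ndarray, bool]:
    arr, scalar = _as_float_array(d, "d")
    if np.any(arr <= 0.0):
        raise ValueError(f"tube diameter must be positive (μm); got {d!r}")
    return arr, scalar


def pries_reference_viscosity_45(d):
    """Pries in-vitro apparent relative viscosity at hematocrit 0.45.

    eta_45(d) = 220*exp(-1.3 d) + 3.2 - 2.44*exp(-0.06 d^0.645),
    with ``d`` the tube diameter in micrometers.  Tends to the bulk value
    3.2 as d -> infinity.
    """
    arr, scalar = _check_positive_diameter(d)
    with np.errstate(over="ignore"):
        out = 220.0 * np.exp(-1.3 * arr) + 3.2 - 2.44 * np.exp(-0.06 * arr**0.645)
    return _scalar_or_array(out, scalar)


def pries_shape_exponent(d):
    """Diameter-dependent exponent c(d) of the Pries hematocrit dependence.

    c(d) = (0.8 + exp(-0.075 d)) * (1/(1+1e-11 d^12) - 1) + 1/(1+1e-11 d^12)

    Runs from 1 at small d to -0.8 at large d, crossing zero near
    d ≈ 8.1 μm.
    """
    arr, scalar = _check_positive_diameter(d)
    with np.errstate(over="ignore"):
        g = 1.0 / (1.0 + 1e-11 * arr**12)
    out = (0.8 + np.exp(-0.075 * arr)) * (g - 1.0) + g
    return _scalar_or_array(out, scalar)


def _hematocrit_ratio(c, phi):
    """((1-phi)^c - 1)/(0.55^c - 1), continuously extended across c = 0.

    Both numerator and denominator vanish linearly in c at c = 0; the
    l'Hôpital limit is ln(1-phi)/ln(0.55).
    """
    c = np.asarray(c, dtype=float)
    phi = np.asarray(phi, dtype=float)
    small = np.abs(c) < 1e-8
    c_safe = np.where(small, 1.0, c)
    with np.errstate(invalid="ignore"):
        ratio = ((1.0 - phi) ** c_safe - 1.0) / (0.55**c_safe - 1.0)
    limit = np.log1p(-phi) / math.log(0.55)
    return np.where(small, limit, ratio)


def _check_hematocrit_sub_unit(phi) -> tuple[np.ndarray, bool]:
    arr, scalar = _as_float_array(phi, "phi")
    if np.any(arr < 0.0) or np.any(arr >= 1.0):
        raise ValueError(f"hematocrit must satisfy 0 <= phi < 1; got {phi!r}")
    return arr, scalar


def pries_apparent_viscosity(d, phi):
    """Pries in-vitro law: apparent relative viscosity at diameter ``d`` (μm)
    and discharge hematocrit ``phi``.

    eta(d, phi) = 1 + (eta_45(d) - 1) * ((1-phi)^c - 1)/(0.55^c - 1),
    c = pries_shape_exponent(d).  Identity: eta(d, 0.45) == eta_45(d).
    """
    d_arr, d_scalar = _check_positive_diameter(d)
    p_arr, p_scalar = _check_hematocrit_sub_unit(phi)
    c = pries_shape_exponent(d_arr)
    out = 1.0 + (pries_reference_viscosity_45(d_arr) - 1.0) * _hematocrit_ratio(c, p_arr)
    return _scalar_or_array(np.asarray(out), d_scalar and p_scalar)


def secomb_reference_viscosity_45(d):
    """Secomb variant of the hematocrit-0.45 reference viscosity.

    eta_45(d) = 3.2 - 2.44*exp(-0.06 d^0.645) + 6*exp(-0.085 d); also tends
    to 3.2 as d -> infinity.
    """
    arr, scalar = _check_positive_diameter(d)
    out = 3.2 - 2.44 * np.exp(-0.06 * arr**0.645) + 6.0 * np.exp(-0.085 * arr)
    return _scalar_or_array(out, scalar)


def secomb_apparent_viscosity(d, phi):
    """Secomb in-vitro law for apparent relative viscosity.

    eta(d, phi) = (d/(d-1.1))^2 * ( d^2 (eta_45(d)-1) ((1-phi)^c - 1)
                  / ((d-1.1)^2 (0.55^c - 1)) + 1 ),
    with c = pries_shape_exponent(d).  Requires ``d > 1.1`` μm (singular
    wall-exclusion factor at d = 1.1).
    """
    d_arr, d_scalar = _check_positive_diameter(d)
    if np.any(d_arr <= 1.1):
        raise ValueError(f"Secomb law requires d > 1.1 μm; got {d!r}")
    p_arr, p_scalar = _check_hematocrit_sub_unit(phi)
    c = pries_shape_exponent(d_arr)
    shrink = d_arr**2 / (d_arr - 1.1) ** 2
    inner = shrink * (secomb_reference_viscosity_45(d_arr) - 1.0) * _hematocrit_ratio(c, p_arr)
    out = shrink * (inner + 1.0)
    return _scalar_or_array(np.asarray(out), d_scalar and p_scalar)


#: Closed enumeration of the implemented empirical (d, phi) -> eta laws.
EMPIRICAL_LAWS: Mapping[str, object] = {
    "pries": pries_apparent_viscosity,
    "secomb": secomb_apparent_viscosity,
}


# ---------------------------------------------------------------------------
# 2. The core-annulus model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """The model triple (eta_c, alpha, a*) plus an optional plasma scale.

    Parameters
    ----------
    eta_c:
        Core relative viscosity (> 1); also the large-diameter (bulk) limit
        of the apparent viscosity.
    alpha:
        Marginal-layer viscosity fraction in [0, 1]:
        eta_A = 1 + alpha*(eta_c - 1).  alpha = 0 is the Haynes cell-free
        layer; physically alpha stays small (fitting default <= 0.15).
    a_star_um:
        Red-cell exclusion half-thickness (μm), the inlet marginal-gap
        width; ~1.0-1.5 μm for human blood, ~0.8 μm for rat.
    eta_p_mPas:
        Optional plasma viscosity scale (mPa·s) for dimensional output.
    phi_source:
        Set when eta_c was derived from a hematocrit through the
        Charm-Kurland law (metadata only; not used in computation).
    """

    eta_c: float
    alpha: float
    a_star_um: float
    eta_p_mPas: float | None = None
    phi_source: float | None = None

    def __post_init__(self):
        if not self.eta_c > 1.0:
            raise ValueError(f"eta_c must be > 1; got {self.eta_c}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1]; got {self.alpha}")
        if not self.a_star_um > 0.0:
            raise ValueError(f"a_star_um must be > 0; got {self.a_star_um}")
        if self.eta_p_mPas is not None and not self.eta_p_mPas > 0.0:
            raise ValueError(f"eta_p_mPas must be > 0; got {self.eta_p_mPas}")

    @classmethod
    def from_hematocrit(
        cls,
        phi: float,
        alpha: float,
        a_star_um: float,
        eta_p_mPas: float | None = None,
    ) -> "ModelParams":
        """Build parameters with eta_c estimated from hematocrit via the
        Charm-Kurland law; the hematocrit route is recorded in
        ``phi_source``."""
        eta_c = charm_kurland_relative_viscosity(phi)
        return cls(eta_c=eta_c, alpha=alpha, a_star_um=a_star_um,
                   eta_p_mPas=eta_p_mPas, phi_source=float(phi))

    @property
    def eta_A(self) -> float:
        return annulus_viscosity(self.eta_c, self.alpha)


def inlet_core_radius(D_um: float, a_star_um: float) -> float:
    """Dimensionless inlet core radius s0 = 1 - 2 a*/D from size exclusion.

    Finite red-cell size keeps cell centers at least a half-thickness
    ``a_star_um`` off the wall at the vessel entrance, so the cell-rich core
    enters with radius s0* = R* - a*.  Requires ``D_um > 2*a_star_um``
    (otherwise the continuum two-region geometry is undefined).
    """
    D_um = float(D_um)
    a_star_um = float(a_star_um)
    if a_star_um < 0.0:
        raise ValueError(f"a_star_um must be >= 0; got {a_star_um}")
    if not D_um > 2.0 * a_star_um:
        raise ValueError(
            f"diameter {D_um} μm must exceed twice the exclusion "
            f"half-thickness ({2.0 * a_star_um} μm): geometry degenerate"
        )
    return 1.0 - 2.0 * a_star_um / D_um


def annulus_viscosity(eta_c: float, alpha: float) -> float:
    """Marginal-annulus relative viscosity eta_A = 1 + alpha*(eta_c - 1)."""
    eta_c = float(eta_c)
    alpha = float(alpha)
    if not eta_c > 1.0:
        raise ValueError(f"eta_c must be > 1; got {eta_c}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1]; got {alpha}")
    return 1.0 + alpha * (eta_c - 1.0)


def _check_core_annulus_viscosities(eta_c: float, eta_A: float) -> None:
    if not eta_c > 1.0:
        raise ValueError(f"eta_c must be > 1; got {eta_c}")
    if not 1.0 <= eta_A <= eta_c:
        raise ValueError(f"eta_A must lie in [1, eta_c]; got {eta_A}")


def core_radius_closed_form(s0: float, eta_c: float, eta_A: float) -> float:
    """Asymptotic dimensionless core radius (closed form).

    s_inf = s0 / sqrt(1 + sqrt((1 - s0^2)(1 - s0^2 (1 - eta_A/eta_c))))

    The unique physically admissible root of the quartic mass-conservation
    condition; lies in (0, s0], with equality only at s0 = 1.
    """
    s0 = float(s0)
    _check_core_annulus_viscosities(eta_c, eta_A)
    if not 0.0 < s0 <= 1.0:
        raise ValueError(f"s0 must be in (0, 1]; got {s0}")
    inner = (1.0 - s0**2) * (1.0 - s0**2 * (1.0 - eta_A / eta_c))
    return s0 / math.sqrt(1.0 + math.sqrt(inner))


def core_radius_numeric(
    s0: float, eta_c: float, eta_A: float, tol: float = 1e-14
) -> float:
    """Asymptotic core radius by bracketed bisection on the quartic.

    Solves, for x = s_inf^2 in (0, 1),

        s0^2 = [x^2 (1/eta_c - 2/eta_A) + 2 x/eta_A]
               / [x^2 (1/eta_c - 1/eta_A) + 1/eta_A]

    by plain bisection to absolute tolerance ``tol`` on x.  Deliberately
    independent of the closed form; serves as its oracle.
    """
    s0 = float(s0)
    _check_core_annulus_viscosities(eta_c, eta_A)
    if not 0.0 < s0 <= 1.0:
        raise ValueError(f"s0 must be in (0, 1]; got {s0}")
    if s0 == 1.0:
        return 1.0
    target = s0**2
    inv_c, inv_A = 1.0 / eta_c, 1.0 / eta_A

    def implied_s0_sq(x: float) -> float:
        num = x**2 * (inv_c - 2.0 * inv_A) + 2.0 * x * inv_A
        den = x**2 * (inv_c - inv_A) + inv_A
        return num / den

    lo, hi = 0.0, 1.0
    f_lo = implied_s0_sq(lo) - target  # = -s0^2 < 0
    f_hi = implied_s0_sq(hi) - target  # = 1 - s0^2 > 0
    if not (f_lo < 0.0 < f_hi):
        raise ValueError(
            f"bisection bracket failed for s0={s0}, eta_c={eta_c}, eta_A={eta_A}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if implied_s0_sq(mid) - target < 0.0:
            lo = mid
        else:
            hi = mid
    return math.sqrt(0.5 * (lo + hi))


@dataclass(frozen=True)
class VelocityProfile:
    """Dimensionless developed axial velocity of the core-annulus flow.

    Callable on r in [0, 1] (radius scaled by the vessel radius, speed by
    the mean speed).  Piecewise parabolic with a knot at ``s_inf``:

        v(r) = A * [ (s_inf^2 - r^2)/eta_c + (1 - s_inf^2)/eta_A ],  r <= s_inf
        v(r) = A * (1 - r^2)/eta_A,                                  r >= s_inf

    with prefactor A = 2 / (s_inf^4/eta_c + (1 - s_inf^4)/eta_A) chosen so
    the dimensionless mean speed is one (2*int_0^1 v r dr = 1).
    """

    s_inf: float
    eta_c: float
    eta_A: float

    @property
    def prefactor(self) -> float:
        si4 = self.s_inf**4
        return 2.0 / (si4 / self.eta_c + (1.0 - si4) / self.eta_A)

    def __call__(self, r):
        arr, scalar = _as_float_array(r, "r")
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise ValueError(f"radius must lie in [0, 1]; got {r!r}")
        si2 = self.s_inf**2
        core = (si2 - arr**2) / self.eta_c + (1.0 - si2) / self.eta_A
        annulus = (1.0 - arr**2) / self.eta_A
        out = self.prefactor * np.where(arr <= self.s_inf, core, annulus)
        return _scalar_or_array(out, scalar)


def velocity_profile(s_inf: float, eta_c: float, eta_A: float) -> VelocityProfile:
    """Developed two-region Poiseuille profile with core radius ``s_inf``."""
    s_inf = float(s_inf)
    _check_core_annulus_viscosities(eta_c, eta_A)
    if not 0.0 < s_inf < 1.0:
        raise ValueError(f"s_inf must be in (0, 1); got {s_inf}")
    return VelocityProfile(s_inf=s_inf, eta_c=float(eta_c), eta_A=float(eta_A))


def apparent_relative_viscosity(s_inf: float, eta_c: float, eta_A: float) -> float:
    """Apparent relative viscosity of the developed core-annulus flow.

    eta_app = 1 / ( s_inf^4 (1/eta_c - 1/eta_A) + 1/eta_A )

    The viscosity of the homogeneous fluid delivering the same discharge
    under the same pressure gradient; strictly between eta_A and eta_c for
    s_inf in (0, 1) when eta_A < eta_c.
    """
    s_inf = float(s_inf)
    _check_core_annulus_viscosities(eta_c, eta_A)
    if not 0.0 <= s_inf <= 1.0:
        raise ValueError(f"s_inf must be in [0, 1]; got {s_inf}")
    return 1.0 / (s_inf**4 * (1.0 / eta_c - 1.0 / eta_A) + 1.0 / eta_A)


def apparent_viscosity_poiseuille_oracle(
    s_inf: float, eta_c: float, eta_A: float
) -> float:
    """Apparent viscosity recomputed from first principles by quadrature.

    Independent verification path that never touches the closed-form
    expression: for a unit pressure gradient the shear stress is
    tau(r) = r/2, so the axial speed follows from integrating
    dv/dr = -tau/eta(r) with the piecewise viscosity field, the discharge
    from integrating the speed over the cross-section, and the apparent
    viscosity from matching a homogeneous Poiseuille discharge
    (Q = pi G R^4 / (8 eta)).  Agrees with ``apparent_relative_viscosity``
    to ~1e-8 relative.
    """
    s_inf = float(s_inf)
    _check_core_annulus_viscosities(eta_c, eta_A)
    if not 0.0 <= s_inf <= 1.0:
        raise ValueError(f"s_inf must be in [0, 1]; got {s_inf}")

    def viscosity(r: float) -> float:
        return eta_c if r <= s_inf else eta_A

    def speed(r: float) -> float:
        # v(r) = int_r^1 t/(2 eta(t)) dt, split at the viscosity jump
        pieces = []
        if r < s_inf:
            pieces.append((r, s_inf, eta_c))
            pieces.append((s_inf, 1.0, eta_A))
        else:
            pieces.append((r, 1.0, eta_A))
        total = 0.0
        for lo, hi, eta in pieces:
            val, _ = quad(lambda t: t / (2.0 * eta), lo, hi, epsabs=1e-13)
            total += val
        return total

    points = [s_inf] if 0.0 < s_inf < 1.0 else None
    flux, err = quad(lambda r: speed(r) * r, 0.0, 1.0,
                     points=points, epsabs=1e-12, limit=200)
    if err > 1e-8:
        raise RuntimeError(f"flux quadrature did not converge (err={err})")
    flux *= 2.0 * math.pi
    # homogeneous Poiseuille with G = 1, R = 1: Q = pi/(8 eta)
    return math.pi / (8.0 * flux)


@dataclass(frozen=True)
class CoreAnnulusSolution:
    """Per-vessel asymptotic solution of the core-annulus model."""

    D_um: float
    s0: float
    s_inf: float
    eta_A: float
    eta_app: float
    layer_thickness_um: float
    #: dimensional apparent viscosity (mPa·s); only when a plasma scale was given
    eta_app_mPas: float | None = None
    params: ModelParams | None = None


def predict_vessel(
    D_um: float,
    params: ModelParams,
    continuum_threshold_um: float = CONTINUUM_THRESHOLD_UM,
) -> CoreAnnulusSolution:
    """Solve the model for one vessel diameter.

    Chains inlet radius -> annulus viscosity -> asymptotic core radius
    (closed form) -> apparent viscosity; the marginal-layer thickness is
    R*(1 - s_inf), i.e. the asymptotic cell-poor layer (always thicker than
    the inlet exclusion gap a*).  Below ``continuum_threshold_um`` a
    ContinuumValidityWarning is emitted (the model is at the edge of its
    continuum assumptions there) but the computation proceeds.
    """
    D_um = float(D_um)
    s0 = inlet_core_radius(D_um, params.a_star_um)
    if D_um < continuum_threshold_um:
        warnings.warn(
            f"D = {D_um} μm is below the continuum-validity threshold "
            f"({continuum_threshold_um} μm); treat predictions with caution",
            ContinuumValidityWarning,
            stacklevel=2,
        )
    eta_A = annulus_viscosity(params.eta_c, params.alpha)
    s_inf = core_radius_closed_form(s0, params.eta_c, eta_A)
    eta_app = apparent_relative_viscosity(s_inf, params.eta_c, eta_A)
    eta_dim = None if params.eta_p_mPas is None else eta_app * params.eta_p_mPas
    return CoreAnnulusSolution(
        D_um=D_um,
        s0=s0,
        s_inf=s_inf,
        eta_A=eta_A,
        eta_app=eta_app,
        layer_thickness_um=0.5 * D_um * (1.0 - s_inf),
        eta_app_mPas=eta_dim,
        params=params,
    )


def viscosity_curve(
    D_grid: Sequence[float] | np.ndarray,
    params: ModelParams,
    continuum_threshold_um: float = CONTINUUM_THRESHOLD_UM,
) -> pd.DataFrame:
    """Vectorised per-vessel prediction over a diameter grid.

    Returns a DataFrame with columns ``diameter_um, eta_app_rel,
    layer_thickness_um`` in the input order (no sorting).  Any invalid
    diameter aborts with its position reported; sub-threshold diameters
    produce a single summary ContinuumValidityWarning.
    """
    diameters = [float(d) for d in np.asarray(D_grid, dtype=float).ravel()]
    for i, d in enumerate(diameters):
        if not d > 2.0 * params.a_star_um:
            raise ValueError(
                f"invalid diameter at index {i}: {d} μm (must exceed "
                f"{2.0 * params.a_star_um} μm)"
            )
    n_small = sum(d < continuum_threshold_um for d in diameters)
    if n_small:
        warnings.warn(
            f"{n_small} of {len(diameters)} diameters lie below the "
            f"continuum-validity threshold ({continuum_threshold_um} μm)",
            ContinuumValidityWarning,
            stacklevel=2,
        )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ContinuumValidityWarning)
        for d in diameters:
            sol = predict_vessel(d, params, continuum_threshold_um)
            rows.append((sol.D_um, sol.eta_app, sol.layer_thickness_um))
    return pd.DataFrame(rows, columns=list(CURVE_CSV_COLUMNS))


# ---------------------------------------------------------------------------
# 3. Viscosity-diameter datasets and CSV I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViscosityDataset:
    """Observed (diameter, apparent relative viscosity) series for fitting.

    At least three rows (the model has three free parameters); diameters in
    μm, viscosities relative (>= 1), optional positive per-row weights.
    Rows need not be sorted or unique.
    """

    diameter_um: np.ndarray
    eta_app_rel: np.ndarray
    weight: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        d = np.atleast_1d(np.asarray(self.diameter_um, dtype=float))
        e = np.atleast_1d(np.asarray(self.eta_app_rel, dtype=float))
        object.__setattr__(self, "diameter_um", d)
        object.__setattr__(self, "eta_app_rel", e)
        if d.shape != e.shape or d.ndim != 1:
            raise ValueError("diameter_um and eta_app_rel must be equal-length 1-D")
        if len(d) < 3:
            raise ValueError(
                f"dataset needs >= 3 rows for a 3-parameter model; got {len(d)}"
            )
        if np.any(d <= 0.0):
            raise ValueError("all diameters must be positive")
        if np.any(e < 1.0):
            raise ValueError("all relative viscosities must be >= 1")
        if self.weight is not None:
            w = np.atleast_1d(np.asarray(self.weight, dtype=float))
            if w.shape != d.shape:
                raise ValueError("weight must match the data length")
            if np.any(w <= 0.0):
                raise ValueError("weights must be positive")
            object.__setattr__(self, "weight", w)

    def __len__(self) -> int:
        return len(self.diameter_um)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "diameter_um": self.diameter_um,
            "eta_app_rel": self.eta_app_rel,
        }
        if self.weight is not None:
            data["weight"] = self.weight
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "ViscosityDataset":
        weight = df["weight"].to_numpy(float) if "weight" in df.columns else None
        return cls(
            diameter_um=df["diameter_um"].to_numpy(float),
            eta_app_rel=df["eta_app_rel"].to_numpy(float),
            weight=weight,
            label=label,
        )

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "ViscosityDataset":
        return read_viscosity_csv(path, label=label)


def _coerce_numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    """Strictly numeric column; on failure name the offending row and column."""
    raw = df[col]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = coerced.isna()
    if bad.any():
        # +2: one for the header line, one for 1-based counting
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(
            f"{path}: non-numeric or missing value in column '{col}', line {row}"
        )
    return coerced.to_numpy(float)


def read_viscosity_csv(path, label: str | None = None) -> ViscosityDataset:
    """Read a dataset CSV (``diameter_um,eta_app_rel[,weight]``, UTF-8,
    comma-separated, header required); malformed input raises ValueError
    naming the offending line and column."""
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:  # unreadable / unparseable file
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in DATASET_CSV_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    d = _coerce_numeric(df, "diameter_um", path)
    e = _coerce_numeric(df, "eta_app_rel", path)
    w = _coerce_numeric(df, "weight", path) if "weight" in df.columns else None
    name = label if label is not None else str(path)
    return ViscosityDataset(diameter_um=d, eta_app_rel=e, weight=w, label=name)


def write_curve_csv(df: pd.DataFrame, path) -> None:
    """Write a curve table with the fixed dialect and 12-significant-digit
    floats (byte-identical for identical inputs)."""
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# 4. Parameter fitting
# ---------------------------------------------------------------------------

#: Canonical parameter order; also the lexicographic tie-break order.
_PARAM_ORDER = ("eta_c", "a_star_um", "alpha")

#: Residual magnitude assigned to rows with D <= 2a* during the search;
#: large but finite so bounded optimizers step back in-bounds instead of
#: dying on an exception.
_PENALTY_RESIDUAL = 1e6


@dataclass(frozen=True)
class FitBounds:
    """Box bounds for (eta_c, a*, alpha); defaults are the physically
    motivated ranges (red-cell half-thickness 1-1.5 μm for human blood,
    marginal fraction typically not exceeding 0.15)."""

    eta_c: tuple[float, float] = (1.001, 10.0)
    a_star_um: tuple[float, float] = (1.0, 1.5)
    alpha: tuple[float, float] = (0.0, 0.15)

    def __post_init__(self):
        for name in _PARAM_ORDER:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"empty bound interval for {name}: ({lo}, {hi})")
        if self.eta_c[0] < 1.0:
            raise ValueError("eta_c lower bound must be >= 1")
        if self.alpha[0] < 0.0 or self.alpha[1] > 1.0:
            raise ValueError("alpha bounds must lie in [0, 1]")
        if self.a_star_um[0] <= 0.0:
            raise ValueError("a_star_um bounds must be positive")

    def interval(self, name: str) -> tuple[float, float]:
        return getattr(self, name)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a bounded least-squares fit."""

    params: ModelParams
    loss: float
    residuals: np.ndarray
    converged: bool
    n_starts: int
    bounds_active: tuple[str, ...]


def _predict_eta_app(diameters: np.ndarray, eta_c: float, alpha: float,
                     a_star_um: float) -> np.ndarray:
    eta_A = annulus_viscosity(eta_c, alpha)
    out = np.empty_like(diameters)
    for i, d in enumerate(diameters):
        s0 = 1.0 - 2.0 * a_star_um / d
        if s0 <= 0.0:
            out[i] = np.nan
        else:
            s_inf = core_radius_closed_form(s0, eta_c, eta_A)
            out[i] = apparent_relative_viscosity(s_inf, eta_c, eta_A)
    return out


def _penalized_residuals(dataset: ViscosityDataset, eta_c: float, alpha: float,
                         a_star_um: float) -> np.ndarray:
    pred = _predict_eta_app(dataset.diameter_um, eta_c, alpha, a_star_um)
    res = (pred - dataset.eta_app_rel) / dataset.eta_app_rel
    bad = ~np.isfinite(res)
    if np.any(bad):
        # grows with the constraint violation so the optimizer has a gradient
        gap = 2.0 * a_star_um - dataset.diameter_um[bad]
        res[bad] = _PENALTY_RESIDUAL * (1.0 + np.maximum(gap, 0.0))
    if dataset.weight is not None:
        res = res * np.sqrt(dataset.weight)
    return res


def model_residuals(dataset: ViscosityDataset, params: ModelParams) -> np.ndarray:
    """Per-row relative residuals (predicted - observed)/observed,
    sqrt(weight)-scaled when the dataset carries weights.

    Relative (not absolute) residuals because tube-viscometry errors are
    multiplicative, of order 10-20%.
    """
    if np.any(dataset.diameter_um <= 2.0 * params.a_star_um):
        raise ValueError(
            "every diameter must exceed 2*a_star_um "
            f"({2.0 * params.a_star_um} μm) for residual evaluation"
        )
    return _penalized_residuals(dataset, params.eta_c, params.alpha, params.a_star_um)


def fit_parameters(
    dataset: ViscosityDataset,
    bounds: FitBounds | None = None,
    fixed: Mapping[str, float] | None = None,
    n_starts_per_axis: int = 3,
) -> FitResult:
    """Fit (eta_c, a*, alpha) to a viscosity-diameter series.

    Minimises the sum of squared relative residuals by bounded local least
    squares (scipy trust-region reflective) launched from a deterministic
    grid of starts (default 3 per free axis, interior-spaced over the
    bounds), keeping the best local optimum.  Equal-loss optima are broken
    by the lexicographically smallest (eta_c, a*, alpha), so the result is
    fully deterministic.  ``fixed`` pins a subset of parameters (the usual
    use: share a* across series and fit eta_c, alpha).
    """
    bounds = bounds if bounds is not None else FitBounds()
    fixed = dict(fixed or {})
    for name, value in fixed.items():
        if name not in _PARAM_ORDER:
            raise ValueError(f"unknown parameter {name!r}; expected {_PARAM_ORDER}")
        lo, hi = bounds.interval(name)
        if not lo <= value <= hi:
            raise ValueError(f"fixed {name}={value} outside bounds [{lo}, {hi}]")
    free = [p for p in _PARAM_ORDER if p not in fixed]

    def assemble(x: np.ndarray) -> dict[str, float]:
        vals = dict(fixed)
        vals.update(zip(free, (float(v) for v in x)))
        return vals

    def objective(x: np.ndarray) -> np.ndarray:
        v = assemble(x)
        return _penalized_residuals(dataset, v["eta_c"], v["alpha"], v["a_star_um"])

    if not free:
        v = dict(fixed)
        res = _penalized_residuals(dataset, v["eta_c"], v["alpha"], v["a_star_um"])
        params = ModelParams(eta_c=v["eta_c"], alpha=v["alpha"],
                             a_star_um=v["a_star_um"])
        return FitResult(params=params, loss=float(res @ res), residuals=res,
                         converged=True, n_starts=0, bounds_active=())

    lb = np.array([bounds.interval(p)[0] for p in free])
    ub = np.array([bounds.interval(p)[1] for p in free])
    axes = [np.linspace(lo, hi, n_starts_per_axis + 2)[1:-1]
            for lo, hi in zip(lb, ub)]
    starts = list(itertools.product(*axes))

    candidates: list[tuple[float, tuple[float, ...], optimize.OptimizeResult]] = []
    for x0 in starts:
        sol = optimize.least_squares(
            objective, np.asarray(x0), bounds=(lb, ub), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=500,
        )
        v = assemble(sol.x)
        key = tuple(v[p] for p in _PARAM_ORDER)
        candidates.append((float(2.0 * sol.cost), key, sol))

    best_loss = min(c[0] for c in candidates)
    tol = 1e-10 * (1.0 + best_loss)
    tied = [c for c in candidates if c[0] <= best_loss + tol]
    loss, key, sol = min(tied, key=lambda c: c[1])

    vals = assemble(sol.x)
    params = ModelParams(eta_c=vals["eta_c"], alpha=vals["alpha"],
                         a_star_um=vals["a_star_um"])
    residuals = objective(sol.x)
    active = tuple(
        p for p in free
        if min(vals[p] - bounds.interval(p)[0],
               bounds.interval(p)[1] - vals[p])
        <= 1e-9 * (bounds.interval(p)[1] - bounds.interval(p)[0])
    )
    converged = any(c[2].success for c in candidates)
    if not converged:
        logger.warning("no multistart converged; returning best attempt")
    return FitResult(params=params, loss=float(residuals @ residuals),
                     residuals=residuals, converged=converged,
                     n_starts=len(starts), bounds_active=active)


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo parameter-recovery summary: per-parameter bias and RMSE."""

    truth: ModelParams
    bias: Mapping[str, float]
    rmse: Mapping[str, float]
    n_replicates: int
    rel_noise_sd: float
    estimates: pd.DataFrame


def recovery_experiment(
    truth: ModelParams,
    diameters: Sequence[float],
    rel_noise_sd: float,
    n_replicates: int,
    seed: int,
    bounds: FitBounds | None = None,
    fixed: Mapping[str, float] | None = None,
) -> RecoverySummary:
    """Repeated generate -> fit cycles quantifying estimator bias and RMSE.

    Deterministic given ``seed``: replicate seeds are spawned from a
    numpy SeedSequence so replicates are independent yet reproducible.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    child_seeds = (
        np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    )
    rows = []
    for rep_seed in child_seeds:
        spec = SyntheticSpec(truth=truth, diameters=tuple(diameters),
                             rel_noise_sd=rel_noise_sd, seed=int(rep_seed))
        ds = generate_dataset(spec)
        fit = fit_parameters(ds, bounds=bounds, fixed=fixed)
        rows.append({p: getattr(fit.params, p) for p in _PARAM_ORDER})
    est = pd.DataFrame(rows)
    bias = {p: float((est[p] - getattr(truth, p)).mean()) for p in _PARAM_ORDER}
    rmse = {p: float(np.sqrt(((est[p] - getattr(truth, p)) ** 2).mean()))
            for p in _PARAM_ORDER}
    return RecoverySummary(truth=truth, bias=bias, rmse=rmse,
                           n_replicates=n_replicates,
                           rel_noise_sd=rel_noise_sd, estimates=est)


# ---------------------------------------------------------------------------
# 5. Synthetic data and literature fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic viscosity-diameter dataset.

    Observations are the exact model curve perturbed by i.i.d.
    multiplicative Gaussian noise truncated at ±3 standard deviations,
    emulating the 10-20% relative errors typical of tube viscometry
    (``rel_noise_sd`` defaults to the lower end, 0.10).  One integer seed
    fully determines the dataset (numpy PCG64 generator).
    """

    truth: ModelParams
    diameters: tuple[float, ...]
    rel_noise_sd: float = 0.10
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self):
        object.__setattr__(self, "diameters",
                           tuple(float(d) for d in self.diameters))
        if not 0.0 <= self.rel_noise_sd <= 0.5:
            raise ValueError(
                f"rel_noise_sd must be in [0, 0.5]; got {self.rel_noise_sd}"
            )
        bad = [d for d in self.diameters if d <= 2.0 * self.truth.a_star_um]
        if bad:
            raise ValueError(
                f"diameters {bad} do not exceed 2*a_star_um "
                f"({2.0 * self.truth.a_star_um} μm)"
            )


def generate_dataset(spec: SyntheticSpec) -> ViscosityDataset:
    """Draw a synthetic dataset: eta_obs_i = eta_app(D_i) * (1 + eps_i),
    eps_i ~ truncated N(0, rel_noise_sd^2) on ±3 sd.  Identical specs give
    bit-identical datasets."""
    d = np.asarray(spec.diameters, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ContinuumValidityWarning)
        curve = viscosity_curve(d, spec.truth)
    exact = curve["eta_app_rel"].to_numpy()
    if spec.rel_noise_sd > 0.0:
        rng = np.random.default_rng(spec.seed)
        eps = truncnorm.rvs(-3.0, 3.0, loc=0.0, scale=spec.rel_noise_sd,
                            size=len(d), random_state=rng)
    else:
        eps = np.zeros(len(d))
    observed = exact * (1.0 + eps)
    return ViscosityDataset(diameter_um=d, eta_app_rel=observed,
                            label=spec.label)


@dataclass(frozen=True)
class FixtureTable:
    """A read-only transcription of a published parameter configuration."""

    id: str
    citation: str
    conditions: Mapping[str, object]
    rows: tuple[Mapping[str, object], ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([dict(r) for r in self.rows])


def _freeze(d: dict) -> Mapping[str, object]:
    import types

    return types.MappingProxyType(dict(d))


# Marginal-layer thickness measurements in 30 μm rigid tubes (human blood)
# at four discharge hematocrits, with the bulk viscosities estimated from
# the Charm-Kurland law and the thicknesses printed alongside them.
_TABLE1_MAEDA = dict(
    citation="Maeda et al., marginal-layer thickness in 30 μm rigid tubes",
    conditions=dict(diameter_um=30.0, a_star_um=1.2, alpha=0.1, blood="human"),
    rows=(
        dict(phi=0.08, eta_ck=1.18, thickness_meas_um=3.9,
             thickness_meas_sd_um=1.0, thickness_printed_um=2.7),
        dict(phi=0.16, eta_ck=1.34, thickness_meas_um=3.1,
             thickness_meas_sd_um=0.5, thickness_printed_um=2.7),
        dict(phi=0.30, eta_ck=1.61, thickness_meas_um=2.3,
             thickness_meas_sd_um=0.8, thickness_printed_um=2.6),
        dict(phi=0.45, eta_ck=2.05, thickness_meas_um=1.6,
             thickness_meas_sd_um=0.5, thickness_printed_um=2.6),
    ),
)

# Cell-poor layer thickness for rat blood (red cells 25-30% smaller than
# human, hence a* = 0.8 μm) across two hematocrit series.
_TABLE2_KIM = dict(
    citation="Kim et al., cell-poor layer thickness, rat blood",
    conditions=dict(a_star_um=0.8, alpha=0.1, blood="rat"),
    rows=(
        dict(phi=0.42, eta_ck=1.94, diameter_um=72.3, thickness_meas_um=2.7,
             thickness_meas_sd_um=0.5, thickness_printed_um=3.4),
        dict(phi=0.42, eta_ck=1.94, diameter_um=49.2, thickness_meas_um=3.1,
             thickness_meas_sd_um=0.6, thickness_printed_um=2.9),
        dict(phi=0.42, eta_ck=1.94, diameter_um=45.3, thickness_meas_um=2.3,
             thickness_meas_sd_um=0.4, thickness_printed_um=2.8),
        dict(phi=0.42, eta_ck=1.94, diameter_um=30.8, thickness_meas_um=2.1,
             thickness_meas_sd_um=0.4, thickness_printed_um=2.4),
        dict(phi=0.41, eta_ck=1.90, diameter_um=71.1, thickness_meas_um=3.2,
             thickness_meas_sd_um=0.7, thickness_printed_um=3.2),
        dict(phi=0.41, eta_ck=1.90, diameter_um=60.2, thickness_meas_um=2.2,
             thickness_meas_sd_um=0.4, thickness_printed_um=3.0),
        dict(phi=0.41, eta_ck=1.90, diameter_um=54.2, thickness_meas_um=2.9,
             thickness_meas_sd_um=0.6, thickness_printed_um=2.9),
        dict(phi=0.41, eta_ck=1.90, diameter_um=51.7, thickness_meas_um=2.3,
             thickness_meas_sd_um=0.4, thickness_printed_um=2.8),
    ),
)

# Fitted model parameters for adult and infant blood viscometry series at
# three hematocrit levels.
_TABLE3_ZILOW = dict(
    citation="Zilow & Linderkamp viscometry series: fitted model parameters",
    conditions=dict(),
    rows=(
        dict(group="infant", phi=0.6, eta_c=6.4, a_star_um=1.2, alpha=0.10),
        dict(group="adult", phi=0.2, eta_c=1.7, a_star_um=1.3, alpha=0.09),
        dict(group="adult", phi=0.4, eta_c=3.5, a_star_um=1.2, alpha=0.11),
        dict(group="adult", phi=0.6, eta_c=6.0, a_star_um=1.0, alpha=0.14),
    ),
)

# Reference curve configuration: bulk viscosity 3.3, human exclusion gap,
# three marginal fractions, diameters spanning the FL-effect range.
_FIG2_CONFIG = dict(
    citation="reference viscosity-diameter curve configuration",
    conditions=dict(eta_c=3.3, a_star_um=1.2,
                    diameter_range_um=(10.0, 1000.0)),
    rows=(
        dict(alpha=0.05),
        dict(alpha=0.10),
        dict(alpha=0.15),
    ),
)

_FIXTURES: dict[str, dict] = {
    "table1_maeda": _TABLE1_MAEDA,
    "table2_kim": _TABLE2_KIM,
    "table3_zilow": _TABLE3_ZILOW,
    "fig2_config": _FIG2_CONFIG,
}

#: Closed set of packaged fixture identifiers.
FIXTURE_IDS = tuple(sorted(_FIXTURES))


def fixture(fixture_id: str) -> FixtureTable:
    """Return one of the packaged literature configurations (read-only)."""
    try:
        raw = _FIXTURES[fixture_id]
    except KeyError:
        raise KeyError(
            f"unknown fixture {fixture_id!r}; available: {FIXTURE_IDS}"
        ) from None
    return FixtureTable(
        id=fixture_id,
        citation=raw["citation"],
        conditions=_freeze(raw["conditions"]),
        rows=tuple(_freeze(r) for r in raw["rows"]),
    )
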