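"""Pressure-volume relationships of the spherical ventricle by quadrature.

The ventricular pressure follows from the work balance ``P = dW/dV`` for a
thick incompressible shell loaded by cavity pressure alone:

    P(v_hat) = -2 * int_0^Delta  (lambda_rho**2 / r_hat) * dPsi/dlambda_rho  ddelta

where the integrand is evaluated on the kinematic state at depth ``delta``
and cavity volume ratio ``v_hat``. With the exponential passive law this
yields the end-diastolic pressure-volume relationship (EDPVR)

    P_ED = 2a * int_0^Delta (1 - lambda_rho**3)/r_hat * exp(b*(I1-3)) ddelta

and with the tangential active stress the active pressure

    P_a = 2*T_a * int_0^Delta (1 - lambda0*sqrt(lambda_rho/2))/r_hat ddelta ,

the end-systolic relationship being their sum, ``P_ES = P_ED + P_a``.
``P_ED`` vanishes identically at the reference volume and is exactly
proportional to ``a``; ``P_a`` is exactly proportional to ``T_a`` and is
strictly positive for any ``lambda0 < sqrt(2)``.

The integrand is smooth, so a fixed-order Gauss-Legendre rule on
``[0, Delta]`` (64 points by default) is accurate far beyond the needs of
fitting; an adaptive scheme is available as a cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from scipy import integrate, optimize

from . import constitutive as _con
from .constitutive import ActiveLaw, PassiveLaw
from .errors import (
    BracketingError,
    ConfigurationError,
    DomainError,
    PhysiologyError,
    QuadratureError,
)
from .geometry import ShellGeometry, first_invariant, normalized_radius, radial_stretch

__all__ = [
    "ShellModel",
    "QuadratureSpec",
    "PVCurve",
    "LoopMetrics",
    "pressure_from_energy",
    "edpvr_pressure",
    "active_pressure",
    "espvr_pressure",
    "active_pressure_at_reference",
    "curve",
    "volume_at_pressure",
    "loop_metrics",
]

Branch = Literal["edpvr", "espvr"]


@dataclass(frozen=True)
class QuadratureSpec:
    """How to evaluate the transmural pressure integral.

    ``scheme='gauss'`` uses a fixed-order Gauss-Legendre rule with
    ``n_points`` nodes (deterministic, fast); ``scheme='adaptive'`` uses
    scipy's adaptive quadrature to relative tolerance ``rel_tol``.
    """

    scheme: Literal["gauss", "adaptive"] = "gauss"
    n_points: int = 64
    rel_tol: float = 1e-10

    def __post_init__(self):
        if self.n_points < 8:
            raise ConfigurationError(f"n_points must be >= 8, got {self.n_points}")
        if not 0 < self.rel_tol <= 1e-3:
            raise ConfigurationError(f"rel_tol must lie in (0, 1e-3], got {self.rel_tol}")


DEFAULT_QUAD = QuadratureSpec()


@dataclass(frozen=True)
class ShellModel:
    """Full parameter set of the spherical ventricle.

    ``geometry`` carries the wall thickness, ``passive`` the exponential
    law (a, b); ``active`` is optional and only needed for end-systolic
    quantities.
    """

    geometry: ShellGeometry
    passive: PassiveLaw
    active: Optional[ActiveLaw] = None

    @classmethod
    def from_parameters(
        cls,
        a: float,
        b: float,
        delta_wall: float,
        t_a: float | None = None,
        lambda0: float = _con.DEFAULT_LAMBDA0,
        v0: float | None = None,
    ) -> "ShellModel":
        """Build a model from the five scalar parameters (a, b, Delta, T_a, lambda0)."""
        active = None if t_a is None else ActiveLaw(t_a=t_a, lambda0=lambda0)
        return cls(ShellGeometry(delta_wall=delta_wall, v0=v0), PassiveLaw(a=a, b=b), active)

    def require_active(self) -> ActiveLaw:
        if self.active is None:
            raise ConfigurationError("this operation needs an active law (t_a, lambda0)")
        return self.active


def _integrate(f: Callable[[np.ndarray], np.ndarray], delta_wall: float, quad: QuadratureSpec) -> float:
    """Integrate a smooth vectorized integrand over depth [0, delta_wall]."""
    if quad.scheme == "gauss":
        nodes, weights = np.polynomial.legendre.leggauss(quad.n_points)
        x = 0.5 * delta_wall * (nodes + 1.0)
        return float(0.5 * delta_wall * np.dot(weights, f(x)))
    val, err = integrate.quad(
        f, 0.0, delta_wall, epsabs=0.0, epsrel=quad.rel_tol, limit=200
    )
    if err > quad.rel_tol * max(abs(val), 1e-30) * 100 and err > 1e-12:
        raise QuadratureError(
            f"adaptive quadrature did not reach rel_tol={quad.rel_tol}: value={val}, err={err}"
        )
    return float(val)


def pressure_from_energy(
    energy_derivative: Callable[[np.ndarray], np.ndarray],
    v_hat: float,
    geometry: ShellGeometry,
    quad: QuadratureSpec = DEFAULT_QUAD,
) -> float:
    """Cavity pressure (kPa) from an arbitrary energy derivative dPsi/dlambda_rho.

    Evaluates ``-2 * int_0^Delta (lambda_rho**2/r_hat) * dPsi/dlambda_rho ddelta``
    for the kinematics at volume ratio ``v_hat``; generic over any
    constitutive law given as a map ``lambda_rho -> kPa``.
    """
    if not v_hat > 0:
        raise DomainError(f"v_hat must be > 0, got {v_hat}")

    def integrand(delta):
        r = normalized_radius(delta, v_hat)
        lr = radial_stretch(delta, v_hat)
        return -2.0 * lr**2 / r * energy_derivative(lr)

    return _integrate(integrand, geometry.delta_wall, quad)


def edpvr_pressure(v_hat, model: ShellModel, quad: QuadratureSpec = DEFAULT_QUAD):
    """Passive (end-diastolic) pressure in kPa at volume ratio ``v_hat``.

    Exactly zero at ``v_hat = 1``, positive above, negative below, and
    proportional to the stiffness ``a``. Accepts a scalar or an array.
    """
    law = model.passive
    geo = model.geometry

    def one(v):
        if not v > 0:
            raise DomainError(f"v_hat must be > 0, got {v}")
        if v == 1.0:
            return 0.0  # lambda_rho == 1 across the wall

        def integrand(delta):
            r = normalized_radius(delta, v)
            lr = radial_stretch(delta, v)
            i1 = first_invariant(lr)
            return 2.0 * law.a * (1.0 - lr**3) / r * np.exp(law.b * (i1 - 3.0))

        return _integrate(integrand, geo.delta_wall, quad)

    arr = np.asarray(v_hat, dtype=float)
    if arr.ndim == 0:
        return one(float(arr))
    return np.array([one(float(v)) for v in arr])


def active_pressure(v_hat, model: ShellModel, quad: QuadratureSpec = DEFAULT_QUAD):
    """Active pressure contribution in kPa; proportional to ``T_a`` and positive."""
    act = model.require_active()
    geo = model.geometry

    def one(v):
        if not v > 0:
            raise DomainError(f"v_hat must be > 0, got {v}")
        if act.t_a == 0.0:
            return 0.0

        def integrand(delta):
            r = normalized_radius(delta, v)
            lr = radial_stretch(delta, v)
            return 2.0 * act.t_a * (1.0 - act.lambda0 * np.sqrt(lr / 2.0)) / r

        return _integrate(integrand, geo.delta_wall, quad)

    arr = np.asarray(v_hat, dtype=float)
    if arr.ndim == 0:
        return one(float(arr))
    return np.array([one(float(v)) for v in arr])


def espvr_pressure(v_hat, model: ShellModel, quad: QuadratureSpec = DEFAULT_QUAD):
    """End-systolic pressure in kPa: passive plus active, additive by construction."""
    if model.active is None or model.active.t_a == 0.0:
        return edpvr_pressure(v_hat, model, quad)
    return edpvr_pressure(v_hat, model, quad) + active_pressure(v_hat, model, quad)


def active_pressure_at_reference(t_a: float, lambda0: float, delta_wall: float) -> float:
    """Closed-form active pressure at the reference volume (v_hat = 1), kPa.

    With ``lambda_rho == 1`` and ``r_hat = 1 + delta`` the active integral
    is elementary: ``2*T_a*(1 - lambda0/sqrt(2))*ln(1 + Delta)``.
    """
    return 2.0 * t_a * (1.0 - lambda0 / math.sqrt(2.0)) * math.log1p(delta_wall)


@dataclass(frozen=True)
class PVCurve:
    """A sampled pressure-volume curve (pressures in kPa on a v_hat grid)."""

    v_hat: np.ndarray
    pressure: np.ndarray
    passive: Optional[np.ndarray] = None
    active: Optional[np.ndarray] = None

    def __post_init__(self):
        v = np.asarray(self.v_hat, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        if v.shape != p.shape:
            raise ConfigurationError("v_hat and pressure grids must have equal length")
        if np.any(np.diff(v) <= 0):
            raise ConfigurationError("v_hat grid must be strictly increasing")

    def to_dataframe(self, pressure_unit: str = "mmHg"):
        """Tabulate the curve; pressures converted to the requested unit."""
        import pandas as pd

        from .units import convert_pressure

        cols = {"v_hat": self.v_hat, "pressure": convert_pressure(self.pressure, "kPa", pressure_unit)}
        if self.passive is not None:
            cols["pressure_passive"] = convert_pressure(self.passive, "kPa", pressure_unit)
        if self.active is not None:
            cols["pressure_active"] = convert_pressure(self.active, "kPa", pressure_unit)
        df = pd.DataFrame(cols)
        df.attrs["pressure_unit"] = pressure_unit
        df.attrs["volume_axis"] = "v_hat"
        return df


def curve(
    v_hat_grid: Sequence[float],
    model: ShellModel,
    quad: QuadratureSpec = DEFAULT_QUAD,
    branch: Branch = "edpvr",
    split: bool = False,
) -> PVCurve:
    """Evaluate a PV branch on a strictly increasing volume-ratio grid.

    With ``split=True`` on the end-systolic branch the passive and active
    components are returned alongside the total (which equals their sum).
    """
    grid = np.asarray(v_hat_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ConfigurationError("v_hat_grid must be a non-empty 1-D sequence")
    if np.any(grid <= 0):
        raise DomainError("all grid volumes must be > 0")
    if np.any(np.diff(grid) <= 0):
        raise ConfigurationError("v_hat_grid must be strictly increasing")

    try:
        passive = np.asarray(edpvr_pressure(grid, model, quad))
    except DomainError as exc:  # pragma: no cover - guarded above
        raise DomainError(f"EDPVR evaluation failed on grid: {exc}") from exc

    if branch == "edpvr":
        return PVCurve(grid, passive, passive=passive if split else None,
                       active=np.zeros_like(passive) if split else None)
    act = np.asarray(active_pressure(grid, model, quad))
    total = passive + act
    if split:
        return PVCurve(grid, total, passive=passive, active=act)
    return PVCurve(grid, total)


_DEFAULT_BRACKET = (0.3, 10.0)
_MAX_BRACKET = (0.05, 100.0)


def volume_at_pressure(
    p_target: float,
    model: ShellModel,
    branch: Branch = "edpvr",
    bracket: tuple[float, float] = _DEFAULT_BRACKET,
    quad: QuadratureSpec = DEFAULT_QUAD,
) -> float:
    """Invert a PV branch: the volume ratio at which the pressure equals ``p_target`` (kPa).

    Uses Brent's method to 1e-10 in ``v_hat``. The initial bracket is
    widened automatically up to [0.05, 100]. On the end-systolic branch
    the curve can be non-monotone at small volumes for large ``T_a``; the
    largest root in the bracket is returned (the end-systolic state lies
    on the ascending limb) and a warning is emitted if several roots are
    present.
    """
    pressure = edpvr_pressure if branch == "edpvr" else espvr_pressure

    def g(v):
        return pressure(v, model, quad) - p_target

    lo, hi = bracket
    glo, ghi = g(lo), g(hi)
    # widen towards the hard limits until the target is straddled
    while glo > 0 and lo > _MAX_BRACKET[0]:
        lo = max(lo / 2.0, _MAX_BRACKET[0])
        glo = g(lo)
    while ghi < 0 and hi < _MAX_BRACKET[1]:
        hi = min(hi * 2.0, _MAX_BRACKET[1])
        ghi = g(hi)

    if branch == "edpvr":
        # the passive curve is monotone increasing: a single bracketed root
        if glo > 0 or ghi < 0:
            raise BracketingError(
                f"pressure {p_target} kPa not bracketed by EDPVR on [{lo}, {hi}]; "
                "try a wider bracket"
            )
        if glo == 0.0:
            return float(lo)
        if ghi == 0.0:
            return float(hi)
        return float(optimize.brentq(g, lo, hi, xtol=1e-10, rtol=8.9e-16))

    # scan for sign changes; ESPVR can be non-monotone near small volumes
    grid = np.geomspace(lo, hi, 65)
    vals = np.array([g(v) for v in grid])
    idx = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) <= 0)[0]
    roots = []
    for i in idx:
        if vals[i] == 0.0:
            roots.append(grid[i])
            continue
        roots.append(optimize.brentq(g, grid[i], grid[i + 1], xtol=1e-10, rtol=8.9e-16))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    if not roots:
        raise BracketingError(
            f"no volume in [{lo}, {hi}] gives pressure {p_target} kPa on {branch}; "
            "try a wider bracket"
        )
    roots = sorted(set(roots))
    if len(roots) > 1:
        warnings.warn(
            f"{branch} is non-monotone in the bracket; returning the largest of "
            f"{len(roots)} roots",
            stacklevel=2,
        )
    return float(roots[-1])


@dataclass(frozen=True)
class LoopMetrics:
    """PV-loop summary: normalised EDV, ESV, stroke volume and ejection fraction."""

    edv_hat: float
    esv_hat: float
    sv_hat: float
    ejection_fraction: float

    def to_dict(self) -> dict:
        return {
            "edv_hat": self.edv_hat,
            "esv_hat": self.esv_hat,
            "sv_hat": self.sv_hat,
            "ejection_fraction": self.ejection_fraction,
        }


def loop_metrics(
    edp: float,
    esp: float,
    model: ShellModel,
    quad: QuadratureSpec = DEFAULT_QUAD,
) -> LoopMetrics:
    """PV-loop corner volumes and ejection fraction for given pressures (kPa).

    The end-diastolic volume is read off the passive curve at filling
    pressure ``edp``; the end-systolic volume off the ESPVR at ejection
    pressure ``esp``. Since both are volume ratios, the reference volume
    cancels from the ejection fraction ``EF = (EDV - ESV)/EDV``.
    """
    if not edp > 0:
        raise DomainError(f"end-diastolic pressure must be > 0, got {edp}")
    edv = volume_at_pressure(edp, model, "edpvr", quad=quad)
    esv = volume_at_pressure(esp, model, "espvr", quad=quad)
    if esv >= edv:
        raise PhysiologyError(
            f"ESV ({esv:.4g}) >= EDV ({edv:.4g}): contractility too low for the "
            "requested pressures"
        )
    sv = edv - esv
    return LoopMetrics(edv_hat=edv, esv_hat=esv, sv_hat=sv, ejection_fraction=sv / edv)
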