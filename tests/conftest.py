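"""Shared fixtures and independent oracles.

The dense-quadrature oracle re-implements the pressure integrand from the
defining formulas (kinematics inlined, composite trapezoid at very high
panel counts) without touching the package's quadrature code path, so it
can serve as an independent check of the Gauss-Legendre evaluation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from pvshell import ShellModel


def trapezoid_pressure(
    v_hat: float,
    a: float,
    b: float,
    delta_wall: float,
    t_a: float = 0.0,
    lambda0: float = 0.85,
    n_panels: int = 1_000_000,
) -> float:
    """Brute-force composite-trapezoid evaluation of the total pressure (kPa).

    Independent of pvshell's integration code: kinematics and integrand
    are written out from scratch here.
    """
    delta = np.linspace(0.0, delta_wall, n_panels + 1)
    r = ((1.0 + delta) ** 3 + v_hat - 1.0) ** (1.0 / 3.0)
    lam_rho = (1.0 + delta) ** 2 / r**2
    i1 = lam_rho**2 + 2.0 / lam_rho
    integrand = 2.0 * a * (1.0 - lam_rho**3) / r * np.exp(b * (i1 - 3.0))
    if t_a != 0.0:
        integrand = integrand + 2.0 * t_a * (1.0 - lambda0 * np.sqrt(lam_rho / 2.0)) / r
    return float(np.trapezoid(integrand, delta))


def neo_hookean_pressure(v_hat: float, a: float, delta_wall: float,
                         n_panels: int = 2_000_000) -> float:
    """Dense-quadrature passive pressure for the b = 0 (neo-Hookean) shell."""
    return trapezoid_pressure(v_hat, a, 0.0, delta_wall, n_panels=n_panels)


def active_reference_closed_form(t_a: float, lambda0: float, delta_wall: float) -> float:
    """Closed form for the active pressure at the reference volume, written out independently."""
    return 2.0 * t_a * (1.0 - lambda0 / math.sqrt(2.0)) * math.log(1.0 + delta_wall)


@pytest.fixture(scope="session")
def base_model() -> ShellModel:
    """The healthy-human operating point used throughout: a=1.15 kPa, b=3.82,
    Delta=0.27, T_a=76.9 kPa, lambda0=0.85."""
    return ShellModel.from_parameters(a=1.15, b=3.82, delta_wall=0.27, t_a=76.9, lambda0=0.85)


@pytest.fixture(scope="session")
def passive_model() -> ShellModel:
    """Passive-only shell with the human EDPVR parameters (a=1.15, b=3.82, Delta=0.27)."""
    return ShellModel.from_parameters(a=1.15, b=3.82, delta_wall=0.27)
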