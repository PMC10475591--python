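"""Classical empirical EDPVR models and Klotz volume normalisation.

Two comparator curves for the end-diastolic pressure-volume relationship:

* exponential model  ``P = A*(exp(B*V_n) - 1)``  (also available on an
  absolute volume axis as ``A*(exp(B*(V - V0)) - 1)``),
* Klotz power law    ``P = A_n * V_n**B_n``,

both on the Klotz-normalised volume axis ``V_n = (V - V0)/(V30 - V0)``
where ``V0`` and ``V30`` are the cavity volumes at 0 and 30 mmHg. By
construction the Klotz curve passes through ``(1, A_n)``.

:func:`physics_curve_on_vn_axis` puts the physics-based shell EDPVR on the
same axis by solving for the volume ratio at 30 mmHg, which enables
like-for-like fitting and comparison of all three models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .pv import DEFAULT_QUAD, QuadratureSpec, ShellModel, edpvr_pressure, volume_at_pressure
from .units import mmhg_to_kpa

__all__ = [
    "ExponentialParams",
    "KlotzParams",
    "exponential_edpvr",
    "exponential_edpvr_absolute",
    "klotz_edpvr",
    "normalize_volume",
    "PhysicsOnVnAxis",
    "physics_curve_on_vn_axis",
]


@dataclass(frozen=True)
class ExponentialParams:
    """Exponential EDPVR parameters: amplitude ``A`` (kPa) and rate ``B`` (dimensionless)."""

    amp: float
    rate: float

    def __post_init__(self):
        if not self.amp > 0:
            raise DomainError(f"amplitude A must be > 0, got {self.amp}")
        if not self.rate > 0:
            raise DomainError(f"rate B must be > 0, got {self.rate}")


@dataclass(frozen=True)
class KlotzParams:
    """Klotz power-law parameters ``A_n`` (kPa) and ``B_n`` (dimensionless)."""

    amp_n: float
    exp_n: float

    def __post_init__(self):
        if not self.amp_n > 0:
            raise DomainError(f"A_n must be > 0, got {self.amp_n}")
        if not self.exp_n > 0:
            raise DomainError(f"B_n must be > 0, got {self.exp_n}")


def _check_vn(v_n):
    v_n = np.asarray(v_n, dtype=float)
    if np.any(v_n < 0):
        raise DomainError(f"normalized volume must be >= 0, got {v_n}")
    return v_n


def exponential_edpvr(v_n, params: ExponentialParams):
    """Exponential EDPVR on the normalised axis, ``A*(exp(B*v_n) - 1)`` in kPa."""
    v_n = _check_vn(v_n)
    out = params.amp * np.expm1(params.rate * v_n)
    return out if out.ndim else float(out)


def exponential_edpvr_absolute(v_ml, v0_ml: float, params: ExponentialParams):
    """Exponential EDPVR on an absolute mL axis, ``A*(exp(B*(V - V0)) - 1)`` in kPa."""
    v = np.asarray(v_ml, dtype=float)
    out = params.amp * np.expm1(params.rate * (v - v0_ml))
    return out if out.ndim else float(out)


def klotz_edpvr(v_n, params: KlotzParams):
    """Klotz power-law EDPVR ``A_n * v_n**B_n`` in kPa; equals ``A_n`` at ``v_n = 1``."""
    v_n = _check_vn(v_n)
    out = params.amp_n * np.power(v_n, params.exp_n)
    return out if out.ndim else float(out)


def normalize_volume(v, v0: float, v30: float, permissive: bool = False):
    """Klotz volume normalisation ``V_n = (V - V0)/(V30 - V0)``.

    Volumes below ``V0`` map to negative ``V_n`` and are rejected unless
    ``permissive=True``.
    """
    if not v30 > v0:
        raise DomainError(f"degenerate normalization: need V30 > V0, got V0={v0}, V30={v30}")
    v = np.asarray(v, dtype=float)
    out = (v - v0) / (v30 - v0)
    if not permissive and np.any(out < 0):
        raise DomainError(
            f"volume below V0={v0} maps to negative V_n; pass permissive=True to allow"
        )
    return out if out.ndim else float(out)


_P30_KPA = mmhg_to_kpa(30.0)


@dataclass(frozen=True)
class PhysicsOnVnAxis:
    """The shell EDPVR reparameterised onto the Klotz-normalised volume axis.

    ``v_hat_30`` is the volume ratio at which the passive pressure reaches
    30 mmHg; ``v_n = (v_hat - 1)/(v_hat_30 - 1)`` so that the curve passes
    through (0, 0) and (1, 30 mmHg) by construction.
    """

    model: ShellModel
    v_hat_30: float
    quad: QuadratureSpec = DEFAULT_QUAD

    def v_hat(self, v_n):
        """Map normalised volume back to a volume ratio."""
        v_n = np.asarray(v_n, dtype=float)
        out = 1.0 + v_n * (self.v_hat_30 - 1.0)
        return out if out.ndim else float(out)

    def __call__(self, v_n):
        """Pressure in kPa at normalised volume ``v_n``."""
        return edpvr_pressure(self.v_hat(_check_vn(v_n)), self.model, self.quad)


def physics_curve_on_vn_axis(
    model: ShellModel, quad: QuadratureSpec = DEFAULT_QUAD
) -> PhysicsOnVnAxis:
    """Anchor the shell EDPVR to the Klotz axis by solving P_ED(v_hat_30) = 30 mmHg."""
    v30 = volume_at_pressure(_P30_KPA, model, "edpvr", quad=quad)
    return PhysicsOnVnAxis(model=model, v_hat_30=v30, quad=quad)
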