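"""Least-squares fitting of PV models, and local sensitivity analysis.

The fitting surface follows the model/results convention of statistical
modelling packages: a model object is constructed from a
:class:`PVDataset`, its :meth:`~PVModel.fit` method minimises the mean
squared pressure error (in mmHg**2, the axis unit of published EDPVR
comparisons) over the free parameters and returns a
:class:`PVFitResults` carrying the estimates, the achieved MSE, residual
diagnostics and a ``summary()`` table. The functional core
(:class:`FitProblem` / :func:`fit`) is exposed as well.

The optimizer is a bounded derivative-free simplex (Nelder-Mead) started
from a seeded Latin-hypercube sample of the bounds: the objectives are
smooth but the shell model's quadrature makes analytic gradients awkward,
and the parameter spaces are small (<= 4 free parameters).

Sensitivity: :func:`oat_sensitivity` computes the one-at-a-time ratio

    S = [(P(theta*(1+f)) - P(theta)) / P(theta)] / f

for each model parameter at a chosen operating point; because the
pressure is exactly linear in the stiffness ``a`` (passive branch) and in
the active stress ``T_a``, S(a) = 1 identically, while |S(b)| and
|S(Delta)| stay below 1 near physiological parameters — the model output
is stable there. :func:`hessian` estimates the matrix of second partial
derivatives of the pressure with respect to (a, b, Delta, T_a) by central
finite differences; its a-row mixed entries with T_a vanish because the
passive and active contributions are additive and each linear in its own
amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from . import classic as _classic
from .classic import ExponentialParams, KlotzParams, physics_curve_on_vn_axis
from .constitutive import DEFAULT_LAMBDA0
from .errors import ConfigurationError, DomainError, FittingError
from .pv import (
    DEFAULT_QUAD,
    QuadratureSpec,
    ShellModel,
    edpvr_pressure,
    espvr_pressure,
)
from .units import convert_pressure

__all__ = [
    "PVDataset",
    "FitProblem",
    "FitResult",
    "mse",
    "fit",
    "PVModel",
    "ExponentialEDPVRModel",
    "KlotzEDPVRModel",
    "PhysicsEDPVRModel",
    "PhysicsESPVRModel",
    "PVFitResults",
    "SensitivityReport",
    "oat_sensitivity",
    "hessian",
    "DEFAULT_BOUNDS",
]

VolumeAxis = Literal["ml", "v_hat", "v_n"]
ModelId = Literal["exponential", "klotz", "physics_ed", "physics_es"]


@dataclass(frozen=True)
class PVDataset:
    """Unit-tagged pressure-volume samples.

    ``volume_axis`` declares what the volume column means: absolute mL
    (``"ml"``), volume ratio V/V0 (``"v_hat"``) or Klotz-normalised
    volume (``"v_n"``). ``pressure_unit`` is ``"kPa"`` or ``"mmHg"``.
    """

    volume: np.ndarray
    pressure: np.ndarray
    volume_axis: VolumeAxis = "v_hat"
    pressure_unit: str = "mmHg"
    meta: str = ""

    def __post_init__(self):
        v = np.asarray(self.volume, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        object.__setattr__(self, "volume", v)
        object.__setattr__(self, "pressure", p)
        if v.ndim != 1 or p.ndim != 1 or v.size != p.size:
            raise ConfigurationError("volume and pressure must be 1-D and of equal length")
        if v.size < 3:
            raise ConfigurationError(f"need at least 3 samples, got {v.size}")
        if not np.all(np.isfinite(p)) or not np.all(np.isfinite(v)):
            raise ConfigurationError("volumes and pressures must be finite")
        if self.volume_axis not in ("ml", "v_hat", "v_n"):
            raise ConfigurationError(f"unknown volume axis {self.volume_axis!r}")
        if self.volume_axis in ("v_hat", "v_n") and np.any(v < 0):
            raise ConfigurationError("normalized volumes must be non-negative")
        if self.pressure_unit not in ("kPa", "mmHg"):
            raise ConfigurationError(f"unknown pressure unit {self.pressure_unit!r}")

    def __len__(self) -> int:
        return int(self.volume.size)

    @property
    def pressure_mmhg(self) -> np.ndarray:
        return np.asarray(convert_pressure(self.pressure, self.pressure_unit, "mmHg"))

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({"volume": self.volume, "pressure": self.pressure})
        df.attrs["volume_axis"] = self.volume_axis
        df.attrs["pressure_unit"] = self.pressure_unit
        return df


def mse(dataset: PVDataset, model_curve: Callable, curve_unit: str = "kPa") -> float:
    """Mean squared pressure residual in mmHg**2.

    ``model_curve`` maps the dataset's volume column to pressures in
    ``curve_unit``; both predictions and observations are converted to
    mmHg before squaring (the convention of published EDPVR model
    comparisons).
    """
    obs = dataset.pressure_mmhg
    pred = np.empty_like(obs)
    for i, v in enumerate(dataset.volume):
        try:
            pred[i] = model_curve(v)
        except Exception as exc:
            raise type(exc)(f"model evaluation failed at point {i} (volume={v}): {exc}") from exc
    pred = np.asarray(convert_pressure(pred, curve_unit, "mmHg"))
    return float(np.mean((pred - obs) ** 2))


# ---------------------------------------------------------------------------
# model registry: parameter names, defaults, curve factories

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "a": (0.01, 50.0),       # kPa
    "b": (1e-6, 30.0),
    "delta": (0.05, 1.0),
    "t_a": (0.0, 500.0),     # kPa
    "lambda0": (0.5, 0.99),
    "amp": (1e-4, 50.0),     # kPa
    "rate": (1e-3, 30.0),
    "amp_n": (1e-4, 50.0),   # kPa
    "exp_n": (1e-3, 30.0),
}

_MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "exponential": ("amp", "rate"),
    "klotz": ("amp_n", "exp_n"),
    "physics_ed": ("a", "b", "delta"),
    "physics_es": ("a", "b", "delta", "t_a", "lambda0"),
}

# free parameters when the caller does not choose: wall thickness is kept
# fixed by default (it is weakly coupled to the others and best measured,
# not fitted), as is the sarcomere reference stretch
_DEFAULT_FREE: dict[str, tuple[str, ...]] = {
    "exponential": ("amp", "rate"),
    "klotz": ("amp_n", "exp_n"),
    "physics_ed": ("a", "b"),
    "physics_es": ("a", "b", "t_a"),
}

_PARAM_DEFAULTS: dict[str, float] = {"lambda0": DEFAULT_LAMBDA0}


def _curve_factory(model_id: ModelId, dataset: PVDataset, quad: QuadratureSpec):
    """Return params-dict -> (volume -> pressure kPa) for the given model."""
    axis = dataset.volume_axis
    if model_id == "exponential":
        if axis != "v_n":
            raise ConfigurationError("the exponential model needs a v_n volume axis")
        return lambda p: (lambda v: _classic.exponential_edpvr(v, ExponentialParams(p["amp"], p["rate"])))
    if model_id == "klotz":
        if axis != "v_n":
            raise ConfigurationError("the Klotz model needs a v_n volume axis")
        return lambda p: (lambda v: _classic.klotz_edpvr(v, KlotzParams(p["amp_n"], p["exp_n"])))
    if model_id == "physics_ed":
        if axis == "v_hat":
            def make(p):
                m = ShellModel.from_parameters(a=p["a"], b=p["b"], delta_wall=p["delta"])
                return lambda v: edpvr_pressure(v, m, quad)
            return make
        if axis == "v_n":
            def make(p):
                m = ShellModel.from_parameters(a=p["a"], b=p["b"], delta_wall=p["delta"])
                return physics_curve_on_vn_axis(m, quad)
            return make
        raise ConfigurationError("the shell EDPVR needs a v_hat or v_n volume axis")
    if model_id == "physics_es":
        if axis != "v_hat":
            raise ConfigurationError("the shell ESPVR needs a v_hat volume axis")
        def make(p):
            m = ShellModel.from_parameters(
                a=p["a"], b=p["b"], delta_wall=p["delta"],
                t_a=p["t_a"], lambda0=p["lambda0"],
            )
            return lambda v: espvr_pressure(v, m, quad)
        return make
    raise ConfigurationError(f"unknown model id {model_id!r}")


def _linear_basis_factory(model_id: ModelId, dataset: PVDataset, quad: QuadratureSpec):
    """Linear structure of a model: params-dict -> {name: basis array (kPa)}.

    Every model's prediction is a linear combination of basis curves in
    its amplitude parameters: ``A*(expm1(B*v))``, ``A_n*v**B_n``,
    ``a * P_ED[a=1]`` and ``a * P_ED[a=1] + T_a * P_a[T_a=1]``. The basis
    arrays are evaluated at the dataset volumes given the remaining
    (nonlinear) parameters, letting the fit profile the amplitudes out by
    linear least squares. Returns None when no linear structure applies
    (the shell EDPVR on the v_n axis, where the 30 mmHg anchor couples
    the amplitude to the axis itself).
    """
    axis = dataset.volume_axis
    v = dataset.volume
    if model_id == "exponential":
        return lambda p: {"amp": np.expm1(p["rate"] * v)}
    if model_id == "klotz":
        return lambda p: {"amp_n": np.power(v, p["exp_n"])}
    if model_id == "physics_ed" and axis == "v_hat":
        def basis(p):
            m = ShellModel.from_parameters(a=1.0, b=p["b"], delta_wall=p["delta"])
            return {"a": np.asarray(edpvr_pressure(v, m, quad))}
        return basis
    if model_id == "physics_es":
        def basis(p):
            mp = ShellModel.from_parameters(a=1.0, b=p["b"], delta_wall=p["delta"])
            ma = ShellModel.from_parameters(
                a=1.0, b=p["b"], delta_wall=p["delta"], t_a=1.0, lambda0=p["lambda0"]
            )
            from .pv import active_pressure

            return {
                "a": np.asarray(edpvr_pressure(v, mp, quad)),
                "t_a": np.asarray(active_pressure(v, ma, quad)),
            }
        return basis
    return None


@dataclass(frozen=True)
class FitProblem:
    """A declarative fitting task: dataset, model, free/fixed split, bounds, starts, seed."""

    dataset: PVDataset
    model_id: ModelId
    free: tuple[str, ...] = ()
    fixed: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    starts: int = 8
    seed: int = 0
    quad: QuadratureSpec = DEFAULT_QUAD

    def resolved(self) -> "FitProblem":
        """Fill in default free parameters, fixed values and bounds."""
        names = _MODEL_PARAMS[self.model_id]
        free = tuple(self.free) if self.free else _DEFAULT_FREE[self.model_id]
        for name in free:
            if name not in names:
                raise ConfigurationError(f"{name!r} is not a parameter of {self.model_id}")
        fixed = dict(self.fixed)
        overlap = set(free) & set(fixed)
        if overlap:
            raise ConfigurationError(f"parameters both free and fixed: {sorted(overlap)}")
        for name in names:
            if name in free or name in fixed:
                continue
            if name in _PARAM_DEFAULTS:
                fixed[name] = _PARAM_DEFAULTS[name]
            else:
                raise ConfigurationError(
                    f"parameter {name!r} of {self.model_id} is neither free nor fixed"
                )
        bounds = {**{k: DEFAULT_BOUNDS[k] for k in free}, **dict(self.bounds)}
        for name, (lo, hi) in bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(f"bounds for {name!r} must be finite and ordered")
        return replace(self, free=free, fixed=fixed, bounds=bounds)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit: parameter values, MSE (mmHg**2), diagnostics."""

    params: dict[str, float]
    mse: float
    converged: bool
    n_eval: int
    start_used: int
    per_start_mse: tuple[float, ...] = ()


def fit(problem: FitProblem) -> FitResult:
    """Minimise the mmHg**2 MSE over the free parameters with seeded multistarts.

    Free amplitude parameters (a, T_a, A, A_n) enter the models linearly
    and are profiled out by linear least squares at every step; the
    simplex only searches the remaining nonlinear parameters. When all
    free parameters are linear the fit is a single bounded least-squares
    solve. Deterministic for a given problem and seed. Raises
    :class:`FittingError` when every start fails.
    """
    prob = problem.resolved()
    factory = _curve_factory(prob.model_id, prob.dataset, prob.quad)
    basis_factory = _linear_basis_factory(prob.model_id, prob.dataset, prob.quad)

    obs_mmhg = prob.dataset.pressure_mmhg
    linear_free: list[str] = []
    if basis_factory is not None:
        probe_names = basis_factory(
            {**{k: DEFAULT_BOUNDS[k][0] for k in prob.free}, **prob.fixed}
        ).keys()
        linear_free = [k for k in prob.free if k in probe_names]
    nonlinear_free = [k for k in prob.free if k not in linear_free]

    n_eval = 0

    def profiled_mse(params: dict[str, float]) -> tuple[float, dict[str, float]]:
        """MSE with free amplitudes solved analytically; returns (mse, amplitudes)."""
        nonlocal n_eval
        n_eval += 1
        if linear_free:
            bases = basis_factory(params)
            target = obs_mmhg.copy()
            # fixed amplitudes contribute a known offset
            for name, col in bases.items():
                if name not in linear_free:
                    target = target - params[name] * np.asarray(
                        convert_pressure(col, "kPa", "mmHg")
                    )
            design = np.column_stack(
                [np.asarray(convert_pressure(bases[k], "kPa", "mmHg")) for k in linear_free]
            )
            coef, *_ = np.linalg.lstsq(design, target, rcond=None)
            coef = np.clip(
                coef,
                [prob.bounds[k][0] for k in linear_free],
                [prob.bounds[k][1] for k in linear_free],
            )
            params = dict(params)
            params.update(dict(zip(linear_free, map(float, coef))))
            resid = target - design @ coef
            return float(np.mean(resid**2)), {k: params[k] for k in linear_free}
        return mse(prob.dataset, factory(params)), {}

    def objective(x: np.ndarray) -> float:
        params = dict(prob.fixed)
        params.update(dict(zip(nonlinear_free, x)))
        # placeholder values for profiled amplitudes (overwritten inside)
        for k in linear_free:
            params.setdefault(k, 1.0)
        try:
            return profiled_mse(params)[0]
        except (DomainError, ConfigurationError, ArithmeticError):
            return 1e12  # infeasible candidate

    def assemble(x: np.ndarray) -> dict[str, float]:
        params = dict(prob.fixed)
        params.update(dict(zip(nonlinear_free, map(float, x))))
        for k in linear_free:
            params.setdefault(k, 1.0)
        if linear_free:
            _, amps = profiled_mse(params)
            params.update(amps)
        return params

    if not nonlinear_free:
        if not linear_free:
            raise ConfigurationError("no free parameters to fit")
        x0 = np.empty(0)
        value = objective(x0)
        if value >= 1e12:
            raise FittingError("the linear least-squares solve failed at the fixed parameters")
        return FitResult(
            params=assemble(x0), mse=value, converged=True,
            n_eval=n_eval, start_used=0, per_start_mse=(value,),
        )

    lo = np.array([prob.bounds[k][0] for k in nonlinear_free])
    hi = np.array([prob.bounds[k][1] for k in nonlinear_free])
    sampler = qmc.LatinHypercube(d=len(nonlinear_free), seed=prob.seed)
    x0s = lo + sampler.random(prob.starts) * (hi - lo)

    best = None
    per_start: list[float] = []
    failures: list[str] = []
    for i, x0 in enumerate(x0s):
        try:
            res = optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000, "maxfev": 8000},
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"start {i}: {exc}")
            per_start.append(np.inf)
            continue
        per_start.append(float(res.fun))
        if best is None or res.fun < best[1].fun:
            best = (i, res)
    if best is None:
        raise FittingError("all optimizer starts failed:\n" + "\n".join(failures))

    start_used, res = best
    return FitResult(
        params=assemble(res.x),
        mse=float(res.fun),
        converged=bool(res.success),
        n_eval=n_eval,
        start_used=start_used,
        per_start_mse=tuple(per_start),
    )


# ---------------------------------------------------------------------------
# model/results objects


class PVModel:
    """Base class: a PV model bound to a dataset, fitted by least squares.

    Subclasses set ``model_id``. Construction takes the dataset plus any
    parameters to hold fixed; :meth:`fit` chooses the free set (defaults
    to the model's conventional free parameters) and returns a
    :class:`PVFitResults`.
    """

    model_id: ModelId

    def __init__(self, dataset: PVDataset, quad: QuadratureSpec = DEFAULT_QUAD, **fixed: float):
        self.dataset = dataset
        self.quad = quad
        self.fixed = fixed
        # fail early on axis mismatches
        _curve_factory(self.model_id, dataset, quad)

    @classmethod
    def from_dataframe(cls, df, volume_axis: VolumeAxis = "v_hat",
                       pressure_unit: str = "mmHg", **fixed) -> "PVModel":
        """Build from a DataFrame with ``volume`` and ``pressure`` columns."""
        ds = PVDataset(
            volume=df["volume"].to_numpy(dtype=float),
            pressure=df["pressure"].to_numpy(dtype=float),
            volume_axis=df.attrs.get("volume_axis", volume_axis),
            pressure_unit=df.attrs.get("pressure_unit", pressure_unit),
        )
        return cls(ds, **fixed)

    def fit(
        self,
        free: Sequence[str] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        starts: int = 8,
        seed: int = 0,
    ) -> "PVFitResults":
        problem = FitProblem(
            dataset=self.dataset,
            model_id=self.model_id,
            free=tuple(free) if free else (),
            fixed=self.fixed,
            bounds=bounds or {},
            starts=starts,
            seed=seed,
            quad=self.quad,
        )
        return PVFitResults(self, fit(problem), problem.resolved())


class ExponentialEDPVRModel(PVModel):
    """Exponential EDPVR ``A*(exp(B*V_n) - 1)`` on the Klotz-normalised axis."""

    model_id = "exponential"


class KlotzEDPVRModel(PVModel):
    """Klotz power-law EDPVR ``A_n * V_n**B_n``."""

    model_id = "klotz"


class PhysicsEDPVRModel(PVModel):
    """Shell-model passive EDPVR; fit ``(a, b)`` with the wall thickness fixed."""

    model_id = "physics_ed"


class PhysicsESPVRModel(PVModel):
    """Shell-model ESPVR; contractility ``T_a`` (and optionally a, b) free."""

    model_id = "physics_es"


class PVFitResults:
    """Results of a PV model fit: parameters, MSE, residuals, summary table."""

    def __init__(self, model: PVModel, result: FitResult, problem: FitProblem):
        self.model = model
        self.result = result
        self.problem = problem
        self._curve = _curve_factory(model.model_id, model.dataset, model.quad)(result.params)

    @property
    def params(self) -> dict[str, float]:
        return dict(self.result.params)

    @property
    def mse(self) -> float:
        """Mean squared pressure error in mmHg**2."""
        return self.result.mse

    def predict(self, volume) -> np.ndarray:
        """Predicted pressure in mmHg at volumes on the dataset's axis."""
        volume = np.atleast_1d(np.asarray(volume, dtype=float))
        out = np.array([self._curve(v) for v in volume], dtype=float)
        return np.asarray(convert_pressure(out, "kPa", "mmHg"))

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.dataset.volume)

    @property
    def resid(self) -> np.ndarray:
        """Residuals (observed - fitted) in mmHg."""
        return self.model.dataset.pressure_mmhg - self.fittedvalues

    def rms_error(self) -> float:
        """Root-mean-square pressure residual in mmHg."""
        return float(np.sqrt(np.mean(self.resid**2)))

    def summary(self) -> str:
        r = self.result
        lines = [
            f"{type(self.model).__name__} fit ({self.model.model_id})",
            "=" * 54,
            f"observations: {len(self.model.dataset)}   "
            f"axis: {self.model.dataset.volume_axis}   unit: mmHg",
            f"MSE: {r.mse:.6g} mmHg^2   RMS: {self.rms_error():.6g} mmHg",
            f"converged: {r.converged}   evaluations: {r.n_eval}   "
            f"best start: {r.start_used}",
            "-" * 54,
            f"{'parameter':<12}{'value':>14}  {'status':<8}",
        ]
        for name in _MODEL_PARAMS[self.model.model_id]:
            status = "free" if name in self.problem.free else "fixed"
            lines.append(f"{name:<12}{r.params[name]:>14.6g}  {status:<8}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PVFitResults {self.model.model_id} mse={self.mse:.4g}>"


# ---------------------------------------------------------------------------
# sensitivity


_SENS_PARAMS = ("a", "b", "delta", "t_a")


def _model_with(model: ShellModel, **changes: float) -> ShellModel:
    p = {
        "a": model.passive.a,
        "b": model.passive.b,
        "delta": model.geometry.delta_wall,
        "t_a": model.active.t_a if model.active else 0.0,
        "lambda0": model.active.lambda0 if model.active else DEFAULT_LAMBDA0,
    }
    p.update(changes)
    return ShellModel.from_parameters(
        a=p["a"], b=p["b"], delta_wall=p["delta"], t_a=p["t_a"], lambda0=p["lambda0"],
        v0=model.geometry.v0,
    )


def _branch_pressure(model: ShellModel, branch: str, v_hat: float, quad: QuadratureSpec) -> float:
    if branch == "edpvr":
        return float(edpvr_pressure(v_hat, model, quad))
    if branch == "espvr":
        return float(espvr_pressure(v_hat, model, quad))
    raise ConfigurationError(f"unknown branch {branch!r}")


@dataclass(frozen=True)
class SensitivityReport:
    """One-at-a-time S ratios and (optionally) the parameter Hessian of the pressure."""

    base: dict[str, float]
    branch: str
    v_hat: float
    entries: tuple[tuple[str, float, float], ...]  # (parameter, fraction, S)
    param_names: tuple[str, ...] = _SENS_PARAMS
    hessian: Optional[np.ndarray] = None
    notes: str = ""

    def s(self, parameter: str, fraction: float) -> float:
        for name, f, s in self.entries:
            if name == parameter and np.isclose(f, fraction):
                return s
        raise KeyError(f"no entry for {parameter!r} at fraction {fraction}")

    def to_dict(self) -> dict:
        out = {
            "base": self.base,
            "branch": self.branch,
            "v_hat": self.v_hat,
            "entries": [
                {"parameter": n, "fraction": f, "S": s} for n, f, s in self.entries
            ],
            "notes": self.notes,
        }
        if self.hessian is not None:
            out["hessian"] = {
                "parameters": list(self.param_names),
                "matrix": np.asarray(self.hessian).tolist(),
            }
        return out


def oat_sensitivity(
    model: ShellModel,
    branch: str,
    v_hat: float,
    fractions: Sequence[float] = (0.01, 0.05, 0.10, 0.20),
    quad: QuadratureSpec = DEFAULT_QUAD,
    parameters: Sequence[str] | None = None,
) -> SensitivityReport:
    """One-at-a-time sensitivity of the pressure at an operating point.

    Each parameter theta in (a, b, Delta, T_a) is perturbed to
    ``theta*(1+f)`` and the ratio of relative pressure change to ``f``
    recorded. The base pressure must be nonzero (on the passive branch it
    vanishes at v_hat = 1, where S is undefined).
    """
    if parameters is None:
        parameters = _SENS_PARAMS if branch == "espvr" else ("a", "b", "delta")
    base_p = _branch_pressure(model, branch, v_hat, quad)
    if base_p == 0.0:
        raise DomainError(
            f"base pressure is zero at v_hat={v_hat} on {branch}; S is undefined there"
        )
    base = {
        "a": model.passive.a,
        "b": model.passive.b,
        "delta": model.geometry.delta_wall,
        "t_a": model.active.t_a if model.active else 0.0,
    }
    entries = []
    for name in parameters:
        theta = base[name]
        for f in fractions:
            pert = _branch_pressure(_model_with(model, **{name: theta * (1.0 + f)}), branch, v_hat, quad)
            s = ((pert - base_p) / base_p) / f
            entries.append((name, float(f), float(s)))
    return SensitivityReport(
        base=base, branch=branch, v_hat=float(v_hat), entries=tuple(entries),
        param_names=tuple(parameters),
    )


def hessian(
    model: ShellModel,
    branch: str,
    v_hat: float,
    step: float = 1e-4,
    quad: QuadratureSpec = DEFAULT_QUAD,
) -> np.ndarray:
    """Central-difference Hessian of the pressure w.r.t. (a, b, Delta, T_a).

    ``step`` is a relative step per parameter. The matrix is symmetrised;
    a warning is emitted if the raw asymmetry suggests cancellation error.
    """
    base = {
        "a": model.passive.a,
        "b": model.passive.b,
        "delta": model.geometry.delta_wall,
        "t_a": model.active.t_a if model.active else 0.0,
    }
    names = _SENS_PARAMS
    h = {n: step * abs(base[n]) if base[n] != 0.0 else step for n in names}

    def p_at(**changes):
        vals = {n: base[n] + changes.get(n, 0.0) for n in names}
        return _branch_pressure(_model_with(model, **vals), branch, v_hat, quad)

    p0 = p_at()
    H = np.empty((4, 4))
    for i, ni in enumerate(names):
        hi = h[ni]
        H[i, i] = (p_at(**{ni: hi}) - 2.0 * p0 + p_at(**{ni: -hi})) / hi**2
        for j in range(i + 1, 4):
            nj = names[j]
            hj = h[nj]
            pp = p_at(**{ni: hi, nj: hj})
            pm = p_at(**{ni: hi, nj: -hj})
            mp = p_at(**{ni: -hi, nj: hj})
            mm = p_at(**{ni: -hi, nj: -hj})
            H[i, j] = H[j, i] = (pp - pm - mp + mm) / (4.0 * hi * hj)

    scale = np.max(np.abs(H)) or 1.0
    asym = np.max(np.abs(H - H.T)) / scale
    if asym > 1e-4:  # pragma: no cover - H built symmetric; kept as guard
        warnings.warn(f"Hessian asymmetry {asym:.2e} suggests cancellation; increase step")
    return H
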