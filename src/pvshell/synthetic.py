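"""Synthetic pressure-volume datasets for validation and parameter recovery.

Published human ex vivo EDPVR compilations (~80 hearts, pressures up to
30 mmHg on the Klotz-normalised volume axis) and afterload-sweep ESPVR
measurements are not publicly deposited, so this module emulates their
shape: volumes on a stated grid or sampled uniformly over a range, truth
pressures from a chosen model, and additive zero-mean Gaussian
measurement noise in mmHg. Everything is deterministic per seed.

Defaults mirror the study conditions the emulated datasets report:
n = 80 points, pressures spanning 0-30 mmHg over V_n in [0, 1], and a
measurement noise standard deviation of 0.5 mmHg (a realistic
catheter-calibration scale, small against the 30 mmHg span).

What the generator does not emulate: inter-heart parameter variability
(points come from one truth curve, not 80 hearts), volume measurement
error, and heteroscedastic or correlated pressure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .classic import (
    ExponentialParams,
    KlotzParams,
    exponential_edpvr,
    klotz_edpvr,
    physics_curve_on_vn_axis,
)
from .errors import ConfigurationError
from .fitting import PVDataset
from .pv import (
    DEFAULT_QUAD,
    QuadratureSpec,
    ShellModel,
    edpvr_pressure,
    espvr_pressure,
)
from .units import kpa_to_mmhg

__all__ = ["SyntheticSpec", "generate_synthetic", "klotz_style_edpvr_data", "afterload_sweep_data"]

TruthModel = Union[ShellModel, ExponentialParams, KlotzParams]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic PV dataset.

    Parameters
    ----------
    truth : ShellModel | ExponentialParams | KlotzParams
        The generating model. A ShellModel is evaluated on its passive
        branch by default, or on the end-systolic branch with
        ``branch='espvr'``; the classical models require a ``v_n`` axis.
    n : int
        Sample count (>= 3); 80 matches the emulated ex vivo compilation.
    volume_axis : {'v_hat', 'v_n'}
        Axis on which volumes are drawn.
    volume_range : (float, float)
        Range of the volume axis; for ``v_n`` the default [0, 1] spans
        0-30 mmHg by the definition of the normalisation.
    noise_sd : float
        Standard deviation of additive Gaussian pressure noise, mmHg.
    seed : int
        Seed for the noise and the uniform volume sampling.
    grid : bool
        If true, volumes sit on an evenly spaced grid instead of being
        sampled uniformly.
    """

    truth: TruthModel
    n: int = 80
    volume_axis: Literal["v_hat", "v_n"] = "v_n"
    volume_range: tuple[float, float] = (0.0, 1.0)
    noise_sd: float = 0.5
    seed: int = 0
    branch: Literal["edpvr", "espvr"] = "edpvr"
    grid: bool = False
    quad: QuadratureSpec = DEFAULT_QUAD
    meta: str = field(default="synthetic")

    def __post_init__(self):
        if self.n < 3:
            raise ConfigurationError(f"n must be >= 3, got {self.n}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = self.volume_range
        if not lo < hi:
            raise ConfigurationError(f"volume_range must be increasing, got {self.volume_range}")


def _truth_curve_mmhg(spec: SyntheticSpec):
    """Map volumes on the spec's axis to noiseless pressures in mmHg."""
    truth = spec.truth
    if isinstance(truth, ExponentialParams):
        if spec.volume_axis != "v_n":
            raise ConfigurationError("exponential truth needs a v_n axis")
        return lambda v: kpa_to_mmhg(exponential_edpvr(v, truth))
    if isinstance(truth, KlotzParams):
        if spec.volume_axis != "v_n":
            raise ConfigurationError("Klotz truth needs a v_n axis")
        return lambda v: kpa_to_mmhg(klotz_edpvr(v, truth))
    if isinstance(truth, ShellModel):
        if spec.volume_axis == "v_n":
            if spec.branch != "edpvr":
                raise ConfigurationError("the v_n axis is defined for the passive branch only")
            curve = physics_curve_on_vn_axis(truth, spec.quad)
            return lambda v: kpa_to_mmhg(curve(v))
        fn = edpvr_pressure if spec.branch == "edpvr" else espvr_pressure
        return lambda v: kpa_to_mmhg(fn(v, truth, spec.quad))
    raise ConfigurationError(f"unsupported truth model {type(truth).__name__}")


def generate_synthetic(spec: SyntheticSpec) -> PVDataset:
    """Draw one synthetic dataset: truth curve plus iid Gaussian mmHg noise."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.volume_range
    if spec.grid:
        volumes = np.linspace(lo, hi, spec.n)
    else:
        volumes = np.sort(rng.uniform(lo, hi, size=spec.n))
    curve = _truth_curve_mmhg(spec)
    clean = np.array([curve(v) for v in volumes], dtype=float)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return PVDataset(
        volume=volumes,
        pressure=noisy,
        volume_axis=spec.volume_axis,
        pressure_unit="mmHg",
        meta=spec.meta,
    )


def klotz_style_edpvr_data(
    truth: TruthModel,
    n: int = 80,
    noise_sd: float = 0.5,
    seed: int = 0,
    grid: bool = False,
) -> PVDataset:
    """EDPVR data in the shape of the ex vivo human compilation.

    Pressures 0-30 mmHg over ``V_n`` in [0, 1] (the span follows from the
    Klotz normalisation itself), n points, additive mmHg noise.
    """
    spec = SyntheticSpec(
        truth=truth, n=n, volume_axis="v_n", volume_range=(0.0, 1.0),
        noise_sd=noise_sd, seed=seed, grid=grid, meta="synthetic Klotz-style EDPVR",
    )
    return generate_synthetic(spec)


def afterload_sweep_data(
    model: ShellModel,
    v_hat_range: tuple[float, float] = (0.6, 1.4),
    n: int = 12,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PVDataset:
    """End-systolic points traced by varying afterload, on the v_hat axis.

    Each afterload level leaves the ventricle at a different end-systolic
    volume; the (volume, pressure) pairs sample the ESPVR.
    """
    spec = SyntheticSpec(
        truth=model, n=n, volume_axis="v_hat", volume_range=v_hat_range,
        noise_sd=noise_sd, seed=seed, branch="espvr", grid=True,
        meta="synthetic afterload-sweep ESPVR",
    )
    return generate_synthetic(spec)
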