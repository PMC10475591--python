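"""Dataset and result I/O: PV CSV files, result JSON, run configuration.

CSV dialect: comma-separated UTF-8; a header row (``volume,pressure``) is
required on output and recognised on input (positional columns are
accepted without one); blank lines and ``#`` comments are skipped.
Volume-axis and pressure-unit tags are declared by the caller and stored
on the dataset — the reader never converts units silently.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .errors import ConfigurationError, ParseError
from .fitting import PVDataset
from .pv import PVCurve

__all__ = [
    "read_pv_csv",
    "write_pv_csv",
    "write_curve_csv",
    "write_json",
    "RunConfig",
    "load_config",
]


def read_pv_csv(path, volume_axis: str = "v_hat", pressure_unit: str = "mmHg") -> PVDataset:
    """Read a two-column (volume, pressure) CSV into a tagged PVDataset.

    The declared tags are attached as-is; values are never rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    raw = path.read_text(encoding="utf-8")
    lines = []
    for i, line in enumerate(raw.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        lines.append((i, line))
    if not lines:
        raise ParseError(f"{path}: no data rows")

    # detect an optional header row
    first = [c.strip().lower() for c in lines[0][1].split(",")]
    has_header = "volume" in first or "pressure" in first
    body = lines[1:] if has_header else lines
    if has_header:
        try:
            vi, pi = first.index("volume"), first.index("pressure")
        except ValueError as exc:
            raise ParseError(f"{path}: header must name both volume and pressure") from exc
    else:
        vi, pi = 0, 1

    volumes, pressures = [], []
    for lineno, line in body:
        cells = [c.strip() for c in line.split(",")]
        if len(cells) <= max(vi, pi):
            raise ParseError(f"{path}:{lineno}: expected at least {max(vi, pi)+1} columns")
        try:
            volumes.append(float(cells[vi]))
            pressures.append(float(cells[pi]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell: {exc}") from exc

    try:
        return PVDataset(
            volume=np.array(volumes),
            pressure=np.array(pressures),
            volume_axis=volume_axis,  # type: ignore[arg-type]
            pressure_unit=pressure_unit,
            meta=str(path),
        )
    except ConfigurationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_pv_csv(dataset: PVDataset, path) -> None:
    """Write a dataset with its axis/unit tags recorded as comment lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# volume_axis: {dataset.volume_axis}\n")
        fh.write(f"# pressure_unit: {dataset.pressure_unit}\n")
        if dataset.meta:
            fh.write(f"# meta: {dataset.meta}\n")
        fh.write("volume,pressure\n")
        for v, p in zip(dataset.volume, dataset.pressure):
            fh.write(f"{float(v)!r},{float(p)!r}\n")


def write_curve_csv(curve: PVCurve, path, pressure_unit: str = "mmHg") -> None:
    """Write a PVCurve as CSV with an explicit axis column and unit header."""
    path = Path(path)
    df = curve.to_dataframe(pressure_unit=pressure_unit)
    buf = _stdio.StringIO()
    buf.write(f"# volume_axis: v_hat\n# pressure_unit: {pressure_unit}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


def _jsonable(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    return obj


def write_json(payload: Mapping[str, Any], path) -> None:
    Path(path).write_text(
        json.dumps({k: _jsonable(v) for k, v in payload.items()}, indent=2, default=_jsonable)
        + "\n",
        encoding="utf-8",
    )


_CONFIG_KEYS = {
    "a", "b", "delta", "t_a", "lambda0", "v0",
    "quadrature", "fit", "seed", "out",
}
_QUAD_KEYS = {"scheme", "n_points", "rel_tol"}
_FIT_KEYS = {"model_id", "free", "fixed", "bounds", "starts", "volume_axis", "pressure_unit"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (model parameters, quadrature, fit spec, seed)."""

    a: float | None = None
    b: float | None = None
    delta: float | None = None
    t_a: float | None = None
    lambda0: float | None = None
    v0: float | None = None
    quadrature: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    seed: int = 0
    out: str | None = None


def load_config(path) -> RunConfig:
    """Load a YAML or JSON RunConfig, rejecting unknown keys."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    for sub, allowed in (("quadrature", _QUAD_KEYS), ("fit", _FIT_KEYS)):
        extra = set(raw.get(sub, {})) - allowed
        if extra:
            raise ConfigurationError(f"{path}: unknown {sub} keys {sorted(extra)}")
    return RunConfig(**raw)
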