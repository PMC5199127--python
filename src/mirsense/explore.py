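"""Parameter-space exploration of sensor performance.

Single-parameter sweeps report sensitivity (sensor IC50), On and Off
states and dynamic range along the sweep; the two-dimensional activator
pool x Kd landscape exposes the optimal crest where the dynamic range is
maximized at a particular ratio of the two parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .dose_response import (
    fit_hill_with_leakage,
    generate_sensor_curve,
    ic50_inverse_mapping,
    normalize_curve,
)
from .errors import ConfigurationError, DomainError, NarrowRangeWarning
from .model import (
    PRACTICAL_INPUT_DEFAULT,
    PerformanceSummary,
    SensorParameters,
    performance_summary,
)

__all__ = [
    "ScanResult",
    "LandscapeResult",
    "scan_parameter",
    "scan_landscape",
    "find_optimal_kd",
    "log_range",
]


def log_range(center: float, decades: float = 2.0, n: int = 25) -> np.ndarray:
    """Log-spaced grid of ``n`` values spanning ``+-decades`` around ``center``."""
    if center <= 0:
        raise DomainError("log_range needs a positive center")
    return np.geomspace(center / 10**decades, center * 10**decades, n)


def _robust_sensor_ic50(params: SensorParameters) -> tuple[float, str]:
    """Hill-fit IC50 with an inverse-mapping fallback on a dense curve."""
    curve = generate_sensor_curve(params)
    fit = fit_hill_with_leakage(curve)
    if fit.converged and math.isfinite(fit.b2) and fit.b2 > 0:
        return fit.b2, "hill"
    dense = normalize_curve(generate_sensor_curve(params, n_points=1000))
    return ic50_inverse_mapping(dense), "interp"


@dataclass(frozen=True)
class ScanResult:
    """One-parameter sweep: per-value performance summaries.

    ``ic50_method`` records, per grid value, whether the sensor IC50 came
    from the Hill fit ("hill") or the inverse-mapping fallback ("interp").
    """

    parameter_name: str
    parameter_values: np.ndarray
    summaries: list[PerformanceSummary]
    ic50_method: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for value, summary, method in zip(
            self.parameter_values, self.summaries, self.ic50_method
        ):
            row = {"parameter_name": self.parameter_name, "parameter_value": value}
            row.update(summary.to_dict())
            row["ic50_method"] = method
            rows.append(row)
        return pd.DataFrame(rows)


_LANDSCAPE_METRICS = ("sensor_ic50", "practical_on", "off_state", "dynamic_range_practical")


@dataclass(frozen=True)
class LandscapeResult:
    """Cartesian act_max x kd evaluation of four performance metrics."""

    act_max_values: np.ndarray
    kd_values: np.ndarray
    metric_grids: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.act_max_values):
            for j, k in enumerate(self.kd_values):
                for metric in _LANDSCAPE_METRICS:
                    rows.append(
                        {
                            "act_max": a,
                            "kd": k,
                            "metric": metric,
                            "value": self.metric_grids[metric][i, j],
                        }
                    )
        return pd.DataFrame(rows)


def _validate_axis(name: str, values: np.ndarray, minimum: int = 1) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < minimum:
        raise DomainError(f"{name} must be a 1-D axis with >= {minimum} values")
    if np.any(values <= 0):
        raise DomainError(f"{name} values must be strictly positive")
    if np.any(np.diff(values) <= 0):
        raise DomainError(f"{name} values must be strictly increasing")
    return values


def scan_parameter(
    base: SensorParameters,
    parameter_name: str,
    values,
    practical_input: float = PRACTICAL_INPUT_DEFAULT,
    compute_ic50: bool = True,
) -> ScanResult:
    """Sweep one parameter, holding the other five at the base set."""
    if parameter_name not in SensorParameters.field_names():
        raise ConfigurationError(
            f"unknown parameter {parameter_name!r}; expected one of "
            f"{SensorParameters.field_names()}"
        )
    values = _validate_axis("parameter_values", values)
    summaries: list[PerformanceSummary] = []
    methods: list[str] = []
    for value in values:
        params = base.replace(**{parameter_name: float(value)})
        ic50 = None
        method = "none"
        if compute_ic50:
            ic50, method = _robust_sensor_ic50(params)
        summaries.append(performance_summary(params, practical_input, sensor_ic50=ic50))
        methods.append(method)
    return ScanResult(
        parameter_name=parameter_name,
        parameter_values=values,
        summaries=summaries,
        ic50_method=methods,
    )


def scan_landscape(
    base: SensorParameters,
    act_max_values,
    kd_values,
    practical_input: float = PRACTICAL_INPUT_DEFAULT,
) -> LandscapeResult:
    """Evaluate the four headline metrics on the act_max x kd grid.

    Every cell is an independent :func:`performance_summary` evaluation of
    the corresponding parameter set (no state is shared across cells).
    """
    act_max_values = _validate_axis("act_max_values", act_max_values, minimum=3)
    kd_values = _validate_axis("kd_values", kd_values, minimum=3)
    shape = (len(act_max_values), len(kd_values))
    grids = {metric: np.empty(shape) for metric in _LANDSCAPE_METRICS}
    for i, act in enumerate(act_max_values):
        for j, kd in enumerate(kd_values):
            params = base.replace(act_max=float(act), kd=float(kd))
            ic50, _ = _robust_sensor_ic50(params)
            summary = performance_summary(params, practical_input, sensor_ic50=ic50)
            grids["sensor_ic50"][i, j] = ic50
            grids["practical_on"][i, j] = summary.practical_on
            grids["off_state"][i, j] = summary.off_state
            grids["dynamic_range_practical"][i, j] = summary.dynamic_range_practical
    return LandscapeResult(
        act_max_values=act_max_values, kd_values=kd_values, metric_grids=grids
    )


def find_optimal_kd(
    base: SensorParameters,
    kd_range: tuple[float, float] = (1e1, 1e7),
    practical_input: float = PRACTICAL_INPUT_DEFAULT,
    n_grid: int = 121,
) -> float:
    """Kd maximizing the practical dynamic range, to 3 significant figures.

    A dense log grid brackets the maximum; golden-section refinement on
    the log axis then localizes it (relative tolerance ~1e-3). A maximum
    sitting on a range boundary raises a :class:`NarrowRangeWarning`
    instead of an error and returns the boundary value.
    """
    lo, hi = kd_range
    if not (lo > 0 and hi > lo):
        raise DomainError("kd_range must be positive with hi > lo")
    if hi / lo < 100:
        raise DomainError("kd_range must span at least two decades")

    def dynamic_range(kd: float) -> float:
        return performance_summary(
            base.replace(kd=float(kd)), practical_input
        ).dynamic_range_practical

    grid = np.geomspace(lo, hi, n_grid)
    values = np.array([dynamic_range(k) for k in grid])
    best = int(np.argmax(values))
    if best == 0 or best == n_grid - 1:
        warnings.warn(
            f"dynamic-range maximum lies on the boundary of kd_range {kd_range}; "
            "widen the range for an interior optimum",
            NarrowRangeWarning,
            stacklevel=2,
        )
        return float(f"{grid[best]:.3g}")
    result = minimize_scalar(
        lambda t: -dynamic_range(math.exp(t)),
        bounds=(math.log(grid[best - 1]), math.log(grid[best + 1])),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(f"{math.exp(result.x):.3g}")
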