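"""Dose-response curves and sensor IC50 extraction.

Two IC50 estimators are provided. The model-oriented one fits a Hill
function with leakage, ``y = b3 + b1*x/(b2 + x)``, to an input-output curve
and reads the half-max dose ``b2`` as the sensor IC50. The data-oriented
one normalizes a curve to percent and locates the 50% crossing by linear
interpolation between the bracketing pair of points (inverse mapping),
using a three-point vicinity window around the crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigurationError, DegenerateFitError, DomainError, NoCrossingError
from .model import SensorParameters, steady_state

__all__ = [
    "CurveKind",
    "DoseResponseCurve",
    "HillFitResult",
    "generate_sensor_curve",
    "fit_hill_with_leakage",
    "sensor_ic50",
    "normalize_curve",
    "ic50_inverse_mapping",
    "DEFAULT_DOSE_MIN",
    "DEFAULT_DOSE_MAX",
    "DEFAULT_N_POINTS",
]

CurveKind = Literal["knockdown", "induction", "output_with_control"]
_CURVE_KINDS = ("knockdown", "induction", "output_with_control")

# Default sensor-curve grid: 10 points per decade over six decades.
DEFAULT_DOSE_MIN = 1e-1
DEFAULT_DOSE_MAX = 1e5
DEFAULT_N_POINTS = 61

#: Relative residual norm above which a Hill fit is flagged non-converged.
DEFAULT_RESIDUAL_CEILING = 1e-3


@dataclass(frozen=True)
class DoseResponseCurve:
    """Paired dose/response series with curve-kind semantics.

    ``curve_kind`` determines the 100% reference used by
    :func:`normalize_curve`: the maximum response for ``knockdown`` and
    ``induction`` curves, and an externally measured ``control_max`` for
    ``output_with_control`` curves.
    """

    doses: np.ndarray
    responses: np.ndarray
    curve_kind: CurveKind = "induction"
    control_max: Optional[float] = None

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        responses = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "responses", responses)
        if self.curve_kind not in _CURVE_KINDS:
            raise ConfigurationError(f"unknown curve_kind {self.curve_kind!r}")
        if doses.ndim != 1 or doses.shape != responses.shape:
            raise DomainError("doses and responses must be 1-D and equally long")
        if len(doses) < 3:
            raise DomainError("a dose-response curve needs at least 3 points")
        if np.any(doses < 0):
            raise DomainError("doses must be non-negative")
        if np.any(np.diff(doses) <= 0):
            raise DomainError("doses must be strictly increasing")
        if np.any(responses < 0):
            raise DomainError("responses must be non-negative")

    def __len__(self) -> int:
        return len(self.doses)


@dataclass(frozen=True)
class HillFitResult:
    """Least-squares estimates for ``y = b3 + b1*x/(b2 + x)``.

    ``residual_norm`` is the residual 2-norm relative to the response
    2-norm; ``converged`` is False when the optimizer failed or the
    relative residual exceeded the configured ceiling.
    """

    b1: float
    b2: float
    b3: float
    residual_norm: float
    converged: bool


def _hill_with_leakage(x: np.ndarray, b1: float, b2: float, b3: float) -> np.ndarray:
    return b3 + b1 * x / (b2 + x)


def generate_sensor_curve(
    params: SensorParameters,
    n_points: int = DEFAULT_N_POINTS,
    dose_min: float = DEFAULT_DOSE_MIN,
    dose_max: float = DEFAULT_DOSE_MAX,
) -> DoseResponseCurve:
    """Evaluate the sensor transfer function on a log-uniform input grid.

    The output rises with the input, so the result is an ``induction``
    curve spanning ``[dose_min, dose_max]`` inclusive.
    """
    if n_points < 3:
        raise DomainError(f"n_points must be >= 3, got {n_points}")
    if not (dose_min > 0 and math.isfinite(dose_min)):
        raise DomainError("dose_min must be strictly positive (log spacing)")
    if not (dose_max > dose_min and math.isfinite(dose_max)):
        raise DomainError("dose_max must exceed dose_min")
    doses = np.geomspace(dose_min, dose_max, n_points)
    responses = np.array([steady_state(params, d).output for d in doses])
    return DoseResponseCurve(doses=doses, responses=responses, curve_kind="induction")


def fit_hill_with_leakage(
    curve: DoseResponseCurve,
    residual_ceiling: float = DEFAULT_RESIDUAL_CEILING,
) -> HillFitResult:
    """Fit ``y = b3 + b1*x/(b2 + x)`` by bounded least squares.

    Initialization: ``b3`` at the minimum response, ``b1`` at the response
    span, ``b2`` at the geometric mean of the (positive) dose range; all
    three bounded below by zero. Responses are internally rescaled to a
    unit maximum before fitting, which makes the recovered ``b2``
    insensitive to linear rescaling of the responses (e.g. output-pool
    changes); ``b1`` and ``b3`` are reported on the original scale.
    """
    if len(curve) < 4:
        raise DomainError("Hill fitting needs at least 4 points")
    y = curve.responses
    span = float(np.max(y) - np.min(y))
    scale = float(np.max(y))
    if span == 0 or scale == 0:
        raise DegenerateFitError("responses are constant; Hill fit is unconstrained")
    x = curve.doses
    yn = y / scale
    positive = x[x > 0]
    b2_0 = math.sqrt(positive[0] * positive[-1]) if len(positive) else 1.0
    p0 = [float(np.max(yn) - np.min(yn)), b2_0, float(np.min(yn))]
    try:
        popt, _ = curve_fit(
            _hill_with_leakage,
            x,
            yn,
            p0=p0,
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        fit_ok = True
    except RuntimeError:
        popt, fit_ok = np.array(p0), False
    residual = np.linalg.norm(yn - _hill_with_leakage(x, *popt)) / np.linalg.norm(yn)
    return HillFitResult(
        b1=float(popt[0] * scale),
        b2=float(popt[1]),
        b3=float(popt[2] * scale),
        residual_norm=float(residual),
        converged=bool(fit_ok and residual <= residual_ceiling),
    )


def sensor_ic50(
    params: SensorParameters,
    n_points: int = DEFAULT_N_POINTS,
    dose_min: float = DEFAULT_DOSE_MIN,
    dose_max: float = DEFAULT_DOSE_MAX,
) -> float:
    """Sensor IC50: the half-max dose ``b2`` of a Hill-with-leakage fit
    to the default input-output curve."""
    curve = generate_sensor_curve(params, n_points, dose_min, dose_max)
    return fit_hill_with_leakage(curve).b2


def normalize_curve(curve: DoseResponseCurve) -> DoseResponseCurve:
    """Rescale responses to percent of the kind-appropriate reference.

    ``knockdown`` and ``induction`` curves use the maximal response as
    100%; ``output_with_control`` curves use ``control_max`` (measured in
    a separate control experiment, so no saturation assumption is made).
    Doses are unchanged.
    """
    if curve.curve_kind == "output_with_control":
        if curve.control_max is None:
            raise ConfigurationError(
                "output_with_control curves require control_max for normalization"
            )
        reference = float(curve.control_max)
    else:
        reference = float(np.max(curve.responses))
    if reference <= 0:
        raise DegenerateFitError("normalization reference is not positive")
    return replace(
        curve,
        responses=curve.responses / reference * 100.0,
        control_max=100.0 if curve.control_max is not None else None,
    )


def ic50_inverse_mapping(curve: DoseResponseCurve, threshold: float = 50.0) -> float:
    """Half-response dose by inverse mapping with linear interpolation.

    The curve must already be normalized to percent. Scanning in
    increasing dose order, the first segment whose endpoints bracket the
    threshold is located; a three-point vicinity (the bracketing pair plus
    the neighbor on the side of the endpoint closer to the threshold, so
    at least one point lies above 50% and one below) defines the local
    window, and the dose at the threshold is interpolated linearly between
    the bracketing pair.
    """
    if len(curve) < 3:
        raise DomainError("inverse mapping needs at least 3 points")
    y = curve.responses
    x = curve.doses
    for i in range(len(y) - 1):
        lo, hi = y[i] - threshold, y[i + 1] - threshold
        if lo == 0.0:
            return float(x[i])
        if lo * hi <= 0.0:
            # Three-point vicinity: the bracketing pair plus the neighbor on
            # the side of the closer endpoint. Only the bracketing pair
            # enters the interpolation, so the window carries no extra
            # numeric weight; it documents the locality of the estimate.
            t = lo / (y[i] - y[i + 1])
            return float(x[i] * (1.0 - t) + x[i + 1] * t)
    if y[-1] == threshold:
        return float(x[-1])
    raise NoCrossingError(
        f"responses never cross {threshold}% (range {y.min():.3g}-{y.max():.3g}%)"
    )
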