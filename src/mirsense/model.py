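"""Closed-form steady state of the compact proportional miRNA sensor.

The sensor is a three-stage feed-forward cascade: an input miRNA represses
a constitutively expressed transcriptional activator; the activator induces
a synthetic miRNA (miR-FF4); miR-FF4 represses the fluorescent output. Each
stage is a non-cooperative (Hill coefficient 1) relationship, so the whole
transfer function is available in closed form — no ODE integration is needed.

Concentrations are expressed in molecules per cell throughout; for a
mammalian cell 1,000 molecules/cell corresponds to roughly 1 nM, and
:func:`molecules_to_nm` / :func:`nm_to_molecules` convert between the two.

Two "On" states are distinguished. The *theoretical* On state is the
asymptotic output at infinite input, which equals the uninhibited output
pool ``out_max`` (at infinite input the activator, and hence miR-FF4,
vanish). The *practical* On state is the output at a finite input level
representative of a highly expressed endogenous miRNA, 3,000 molecules/cell
by default. Dynamic range is the ratio of an On state to the Off state
(output at zero input).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

from .errors import DomainError

__all__ = [
    "SensorParameters",
    "SensorSteadyState",
    "PerformanceSummary",
    "activator_level",
    "mirff4_level",
    "output_level",
    "steady_state",
    "performance_summary",
    "molecules_to_nm",
    "nm_to_molecules",
    "PRACTICAL_INPUT_DEFAULT",
]

#: Input level (molecules/cell) representing a highly expressed endogenous
#: miRNA, used for the "practical" On state.
PRACTICAL_INPUT_DEFAULT = 3000.0

#: Conversion factor: molecules per cell in one nanomolar, for a typical
#: mammalian cell volume.
MOLECULES_PER_NM = 1000.0

_POSITIVE_FIELDS = ("ic50_mir", "ic50_ff4", "kd")
_POOL_FIELDS = ("act_max", "mirff4_max", "out_max")


@dataclass(frozen=True)
class SensorParameters:
    """Six-parameter description of one sensor instance.

    Parameters
    ----------
    ic50_mir:
        Input-miRNA concentration eliciting half-knockdown of the
        activator (molecules/cell).
    ic50_ff4:
        miR-FF4 concentration eliciting half-knockdown of the output
        (molecules/cell).
    kd:
        Apparent dissociation constant of the activator from its cognate
        inducible promoter (molecules/cell); lower means stronger binding.
    act_max:
        Uninhibited activator pool (molecules/cell).
    mirff4_max:
        Maximal miR-FF4 expression under activator saturation
        (molecules/cell).
    out_max:
        Uninhibited output pool (molecules/cell).

    Interaction constants must be strictly positive (they appear in
    denominators); pools may be zero, describing degenerate but
    well-defined sensors.
    """

    ic50_mir: float
    ic50_ff4: float
    kd: float
    act_max: float
    mirff4_max: float
    out_max: float

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise DomainError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )
        for name in _POOL_FIELDS:
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise DomainError(
                    f"{name} must be non-negative and finite, got {value!r}"
                )

    @classmethod
    def basic(cls) -> "SensorParameters":
        """The canonical basic parameter set used for all simulations."""
        return cls(
            ic50_mir=20.0,
            ic50_ff4=20.0,
            kd=10251.0,
            act_max=9755.0,
            mirff4_max=3000.0,
            out_max=30000.0,
        )

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def replace(self, **changes: float) -> "SensorParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SensorParameters":
        unknown = set(data) - set(cls.field_names())
        if unknown:
            raise DomainError(f"unknown parameter fields: {sorted(unknown)}")
        missing = set(cls.field_names()) - set(data)
        if missing:
            raise DomainError(f"missing parameter fields: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class SensorSteadyState:
    """Steady-state species levels for one input level (molecules/cell)."""

    input_level: float
    activator: float
    mirff4: float
    output: float


@dataclass(frozen=True)
class PerformanceSummary:
    """Headline performance metrics of one parameter set.

    ``theoretical_on`` always equals ``out_max``; ``sensor_ic50`` is only
    populated when IC50 extraction has been run (see
    :mod:`mirsense.dose_response`).
    """

    off_state: float
    practical_on: float
    theoretical_on: float
    dynamic_range_practical: float
    dynamic_range_theoretical: float
    sensor_ic50: Optional[float] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_non_negative(name: str, value: float) -> None:
    if not (math.isfinite(value) and value >= 0):
        raise DomainError(f"{name} must be non-negative and finite, got {value!r}")


def activator_level(params: SensorParameters, input_level: float) -> float:
    """Steady-state activator as a function of the miRNA input.

    ``act_max * ic50_mir / (ic50_mir + input)``: strictly decreasing in the
    input, equal to ``act_max`` at zero input and vanishing asymptotically.
    """
    _check_non_negative("input_level", input_level)
    return params.act_max * params.ic50_mir / (params.ic50_mir + input_level)


def mirff4_level(params: SensorParameters, activator: float) -> float:
    """Steady-state miR-FF4 induced by a given activator level.

    ``mirff4_max * act / (kd + act)``: strictly increasing, saturating at
    ``mirff4_max``; half-saturation at ``act == kd``.
    """
    _check_non_negative("activator", activator)
    return params.mirff4_max * activator / (params.kd + activator)


def output_level(params: SensorParameters, mirff4: float) -> float:
    """Steady-state output repressed by a given miR-FF4 level.

    ``out_max * ic50_ff4 / (ic50_ff4 + mirff4)``: strictly decreasing,
    half-knockdown at ``mirff4 == ic50_ff4``.
    """
    _check_non_negative("mirff4", mirff4)
    return params.out_max * params.ic50_ff4 / (params.ic50_ff4 + mirff4)


def steady_state(params: SensorParameters, input_level: float) -> SensorSteadyState:
    """Chain the three stages for one input level.

    The cascade is feed-forward, so a single pass through the three
    closed-form relations *is* the fixed point of the system.
    """
    act = activator_level(params, input_level)
    ff4 = mirff4_level(params, act)
    out = output_level(params, ff4)
    return SensorSteadyState(
        input_level=float(input_level), activator=act, mirff4=ff4, output=out
    )


def _ratio(numerator: float, denominator: float) -> float:
    # Degenerate sensors: zero output pool gives 0/0, read as a flat
    # (unit dynamic range) sensor; a zero Off with positive On is unbounded.
    if denominator == 0:
        return 1.0 if numerator == 0 else math.inf
    return numerator / denominator


def performance_summary(
    params: SensorParameters,
    practical_input: float = PRACTICAL_INPUT_DEFAULT,
    sensor_ic50: Optional[float] = None,
) -> PerformanceSummary:
    """Off state, both On states and both dynamic ranges for one sensor.

    The Off state is the output at zero input; the theoretical On state is
    ``out_max`` (evaluated analytically, not at a large finite input).
    """
    if not (math.isfinite(practical_input) and practical_input > 0):
        raise DomainError(
            f"practical_input must be strictly positive, got {practical_input!r}"
        )
    off = steady_state(params, 0.0).output
    on_practical = steady_state(params, practical_input).output
    on_theoretical = params.out_max
    return PerformanceSummary(
        off_state=off,
        practical_on=on_practical,
        theoretical_on=on_theoretical,
        dynamic_range_practical=_ratio(on_practical, off),
        dynamic_range_theoretical=_ratio(on_theoretical, off),
        sensor_ic50=sensor_ic50,
    )


def molecules_to_nm(molecules_per_cell: float) -> float:
    """Convert molecules/cell to nM (1,000 molecules/cell ~ 1 nM)."""
    return molecules_per_cell / MOLECULES_PER_NM


def nm_to_molecules(nanomolar: float) -> float:
    """Convert nM to molecules/cell (1 nM ~ 1,000 molecules/cell)."""
    return nanomolar * MOLECULES_PER_NM
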