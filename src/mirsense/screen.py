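"""Combinatorial sensor library and synthetic screen simulation.

The default library mirrors the screened design space: 2 constitutive
activator promoters (CMV, UbC) x 2 transactivators (tTA, PIT2) x 2 input
target arrangements (3'-UTR, 5'+3'-UTR) give 8 activator constructs;
2 miR-FF4 cassettes (intron only, or intron embedded in a citrine exon)
and 2 output promoters (EF1A, UbC) x 3 miR-FF4 target arrangements (3F,
5F, 5'+3'F) complete the 96 compositions. The inducible promoter driving
the miR-FF4 cassette is implied by the transactivator (TRE for tTA, PIR
for PIT2).

Each variant acts on the model through a table of multiplicative factors
on the six sensor parameters. The default factors are calibration
stand-ins chosen to reproduce the qualitative effect of each part (e.g.
PIT2 is expressed about two orders of magnitude more strongly than tTA
but binds its promoter about 100x more weakly; 5'+3' input targets
strengthen knockdown); they are not measured quantities.

Simulated measurements are per-composition condition means (On at the
practical input, Off at zero input, and the two output-pool controls)
perturbed by multiplicative lognormal noise of configured CV, in
triplicate by default, under a mandatory seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataCompletenessError,
    DomainError,
    UnknownVariantError,
)
from .model import (
    PRACTICAL_INPUT_DEFAULT,
    SensorParameters,
    performance_summary,
    steady_state,
)

__all__ = [
    "BLOCKS",
    "CONDITIONS",
    "ComponentVariant",
    "SensorComposition",
    "ScreenRecord",
    "ScreenTable",
    "default_library",
    "enumerate_library",
    "activator_constructs",
    "compose_parameters",
    "simulate_screen",
    "normalize_to_output_pool",
    "flow_score",
]

#: Building blocks of a composition, in enumeration order.
BLOCKS = (
    "activator_promoter",
    "activator_protein",
    "activator_targets",
    "ff4_cassette",
    "output_promoter",
    "output_targets",
)

#: Measurement conditions simulated per composition.
CONDITIONS = ("on", "off", "output_only", "output_plus_ff4")

# Which parameters each block may plausibly govern.
BLOCK_PARAMETER_SCOPE: dict[str, frozenset[str]] = {
    "activator_promoter": frozenset({"act_max"}),
    "activator_protein": frozenset({"act_max", "kd"}),
    "activator_targets": frozenset({"ic50_mir"}),
    "ff4_cassette": frozenset({"mirff4_max"}),
    "output_promoter": frozenset({"out_max"}),
    "output_targets": frozenset({"ic50_ff4"}),
}

_ROW_LETTERS = "ABCDEFGH"


@dataclass(frozen=True)
class ComponentVariant:
    """One interchangeable genetic part and its effect on the parameters.

    ``multipliers`` maps sensor-parameter field names to positive factors;
    only fields within the block's scope are allowed.
    """

    block: str
    name: str
    multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ConfigurationError(f"unknown block {self.block!r}")
        scope = BLOCK_PARAMETER_SCOPE[self.block]
        for key, factor in self.multipliers.items():
            if key not in scope:
                raise ConfigurationError(
                    f"block {self.block!r} may not modify {key!r} "
                    f"(allowed: {sorted(scope)})"
                )
            if not (math.isfinite(factor) and factor > 0):
                raise ConfigurationError(
                    f"multiplier {key}={factor!r} on {self.name!r} must be positive"
                )
        object.__setattr__(self, "multipliers", dict(self.multipliers))


@dataclass(frozen=True)
class SensorComposition:
    """A choice of one variant per block, placed in a plate well."""

    activator_promoter: str
    activator_protein: str
    activator_targets: str
    ff4_cassette: str
    output_promoter: str
    output_targets: str
    composition_id: str
    well: str

    @property
    def inducible_promoter(self) -> str:
        """TRE when driven by tTA, PIR when driven by PIT2."""
        return "TRE" if self.activator_protein == "tTA" else "PIR"

    def variant_of(self, block: str) -> str:
        return getattr(self, block)

    @property
    def activator_construct(self) -> tuple[str, str, str]:
        return (self.activator_promoter, self.activator_protein, self.activator_targets)

    @property
    def output_construct(self) -> tuple[str, str]:
        return (self.output_promoter, self.output_targets)


@dataclass(frozen=True)
class ScreenRecord:
    """One simulated measurement of one composition in one condition."""

    composition_id: str
    well: str
    condition: str
    replicate: int
    raw_value: float
    normalized_value: Optional[float] = None


@dataclass(frozen=True)
class ScreenTable:
    """A full simulated screen: records plus provenance.

    Regenerating with the same seed and settings reproduces raw values
    bit-identically.
    """

    records: list[ScreenRecord]
    library: list[ComponentVariant]
    compositions: list[SensorComposition]
    seed: int
    noise_cv: float
    n_replicates: int
    practical_input: float
    control_leakage: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "composition_id": [r.composition_id for r in self.records],
                "well": [r.well for r in self.records],
                "condition": [r.condition for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "raw_value": [r.raw_value for r in self.records],
                "normalized_value": [r.normalized_value for r in self.records],
            }
        )

    def composition(self, composition_id: str) -> SensorComposition:
        for comp in self.compositions:
            if comp.composition_id == composition_id:
                return comp
        raise UnknownVariantError(composition_id)


def default_library() -> list[ComponentVariant]:
    """The default screened component library with stand-in multipliers."""
    return [
        ComponentVariant("activator_promoter", "CMV", {"act_max": 1.0}),
        ComponentVariant("activator_promoter", "UbC", {"act_max": 0.3}),
        ComponentVariant("activator_protein", "tTA", {"act_max": 1.0, "kd": 1.0}),
        ComponentVariant("activator_protein", "PIT2", {"act_max": 100.0, "kd": 100.0}),
        ComponentVariant("activator_targets", "3prime", {"ic50_mir": 1.0}),
        ComponentVariant("activator_targets", "5and3prime", {"ic50_mir": 0.3}),
        ComponentVariant("ff4_cassette", "intron_only", {"mirff4_max": 1.0}),
        ComponentVariant("ff4_cassette", "cit_embedded", {"mirff4_max": 0.3}),
        ComponentVariant("output_promoter", "EF1A", {"out_max": 1.0}),
        ComponentVariant("output_promoter", "UbC", {"out_max": 0.4}),
        ComponentVariant("output_targets", "3F", {"ic50_ff4": 1.0}),
        ComponentVariant("output_targets", "5F", {"ic50_ff4": 2.0}),
        ComponentVariant("output_targets", "5and3F", {"ic50_ff4": 1.5}),
    ]


def variants_by_block(
    variants: Iterable[ComponentVariant],
) -> dict[str, list[ComponentVariant]]:
    """Group a flat variant list by block, preserving declaration order."""
    grouped: dict[str, list[ComponentVariant]] = {block: [] for block in BLOCKS}
    for variant in variants:
        grouped[variant.block].append(variant)
    return grouped


def _composition_id(names: Sequence[str]) -> str:
    ap, prot, tgt, ff4, op, ot = names
    return f"{ap}-{prot}-{tgt}|{ff4}|{op}-{ot}"


def enumerate_library(variants: Iterable[ComponentVariant]) -> list[SensorComposition]:
    """Full Cartesian product of the library, with deterministic wells.

    Blocks iterate in :data:`BLOCKS` order (later blocks vary fastest),
    variants in declaration order. Wells follow the plate layout of the
    screen: each row (A-H) holds one activator construct; columns 1-6 use
    the first miR-FF4 cassette crossed with the six output constructs,
    columns 7-12 the second cassette. Well assignment is bijective for the
    default 8 x 12 library; other library sizes still enumerate, with
    wells labeled row-major on the same 12-column grid.
    """
    grouped = variants_by_block(variants)
    for block, members in grouped.items():
        if not members:
            raise ConfigurationError(f"library defines no variants for block {block!r}")
    names = [[v.name for v in grouped[block]] for block in BLOCKS]
    compositions = []
    for index, combo in enumerate(itertools.product(*names)):
        row, col = divmod(index, 12)
        well = f"{_ROW_LETTERS[row % len(_ROW_LETTERS)]}{col + 1}"
        compositions.append(
            SensorComposition(
                *combo, composition_id=_composition_id(combo), well=well
            )
        )
    return compositions


def activator_constructs(
    compositions: Iterable[SensorComposition],
) -> list[tuple[str, str, str]]:
    """Distinct (promoter, protein, targets) activator constructs, in order."""
    seen: dict[tuple[str, str, str], None] = {}
    for comp in compositions:
        seen.setdefault(comp.activator_construct, None)
    return list(seen)


def _variant_lookup(
    variants: Iterable[ComponentVariant],
) -> dict[tuple[str, str], ComponentVariant]:
    return {(v.block, v.name): v for v in variants}


def compose_parameters(
    base: SensorParameters,
    composition: SensorComposition,
    variants: Iterable[ComponentVariant],
) -> SensorParameters:
    """Apply the composition's multipliers to the base parameter set.

    Factors from different blocks compose multiplicatively, so the result
    is order-independent and a pure function of its inputs.
    """
    lookup = _variant_lookup(variants)
    factors = {name: 1.0 for name in SensorParameters.field_names()}
    for block in BLOCKS:
        key = (block, composition.variant_of(block))
        if key not in lookup:
            raise UnknownVariantError(
                f"variant {key[1]!r} of block {block!r} not found in library"
            )
        for param, factor in lookup[key].multipliers.items():
            factors[param] *= factor
    return base.replace(
        **{name: getattr(base, name) * factor for name, factor in factors.items()}
    )


def _condition_means(
    params: SensorParameters,
    practical_input: float,
    residual_input: float,
    control_leakage: float,
) -> dict[str, float]:
    summary = performance_summary(params, practical_input)
    off = (
        summary.off_state
        if residual_input == 0
        else steady_state(params, residual_input).output
    )
    return {
        "on": summary.practical_on,
        "off": off,
        "output_only": params.out_max,
        "output_plus_ff4": params.out_max * control_leakage,
    }


def simulate_screen(
    variants: Iterable[ComponentVariant],
    base: SensorParameters,
    seed: int,
    practical_input: float = PRACTICAL_INPUT_DEFAULT,
    noise_cv: float = 0.2,
    n_replicates: int = 3,
    residual_input: float = 0.0,
    control_leakage: float = 0.85,
) -> ScreenTable:
    """Simulate the full screen for every composition in the library.

    Noiseless condition means come from the steady-state model: On at the
    practical input, Off at zero input (or at ``residual_input`` for an
    imperfect inhibitor), and two controls per composition — the output
    construct alone (its full pool) and the output plus the miR-FF4
    cassette without activator, reduced by ``control_leakage`` to emulate
    basal leakage of the un-activated inducible promoter. Replicates draw
    independent multiplicative lognormal noise with the requested CV and
    unit mean.
    """
    if seed is None:
        raise ConfigurationError("simulate_screen requires an explicit seed")
    if noise_cv < 0:
        raise DomainError("noise_cv must be non-negative")
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    if not 0 < control_leakage <= 1:
        raise ConfigurationError("control_leakage must lie in (0, 1]")
    if residual_input < 0:
        raise DomainError("residual_input must be non-negative")
    variants = list(variants)
    compositions = enumerate_library(variants)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv**2))
    records: list[ScreenRecord] = []
    for comp in compositions:
        params = compose_parameters(base, comp, variants)
        means = _condition_means(params, practical_input, residual_input, control_leakage)
        for condition in CONDITIONS:
            mean = means[condition]
            for replicate in range(1, n_replicates + 1):
                if noise_cv == 0 or mean == 0:
                    value = mean
                else:
                    # lognormal factor with unit mean and the requested CV
                    value = mean * math.exp(rng.normal(-0.5 * sigma**2, sigma))
                records.append(
                    ScreenRecord(
                        composition_id=comp.composition_id,
                        well=comp.well,
                        condition=condition,
                        replicate=replicate,
                        raw_value=value,
                    )
                )
    return ScreenTable(
        records=records,
        library=variants,
        compositions=compositions,
        seed=seed,
        noise_cv=noise_cv,
        n_replicates=n_replicates,
        practical_input=practical_input,
        control_leakage=control_leakage,
    )


def normalize_to_output_pool(table: ScreenTable) -> ScreenTable:
    """Normalize every record to its output construct's control level.

    The reference is the mean ``output_plus_ff4`` control (output together
    with the miR-FF4 cassette, no activator) across all compositions
    sharing the same output construct — the highest output a working
    sensor could reach. Ratios within a composition (On:Off in particular)
    are unchanged by this normalization.
    """
    by_id = {comp.composition_id: comp for comp in table.compositions}
    control_values: dict[tuple[str, str], list[float]] = {}
    for record in table.records:
        if record.condition == "output_plus_ff4":
            construct = by_id[record.composition_id].output_construct
            control_values.setdefault(construct, []).append(record.raw_value)
    normalized: list[ScreenRecord] = []
    for record in table.records:
        construct = by_id[record.composition_id].output_construct
        if construct not in control_values:
            raise DataCompletenessError(
                "missing output_plus_ff4 control for output construct "
                f"{'-'.join(construct)}"
            )
        reference = float(np.mean(control_values[construct]))
        if reference <= 0:
            raise DataCompletenessError(
                f"non-positive control mean for output construct {'-'.join(construct)}"
            )
        normalized.append(replace(record, normalized_value=record.raw_value / reference))
    return replace(table, records=normalized)


def flow_score(
    mean_pos: float, freq_pos: float, mean_ctrl: float, freq_ctrl: float
) -> float:
    """Flow-cytometry fluorophore intensity in relative units.

    (mean of fluorophore-positive cells x their frequency) divided by the
    same product for the transfection control channel.
    """
    for name, value in (
        ("mean_pos", mean_pos),
        ("freq_pos", freq_pos),
        ("mean_ctrl", mean_ctrl),
        ("freq_ctrl", freq_ctrl),
    ):
        if value < 0 or not math.isfinite(value):
            raise DomainError(f"{name} must be non-negative and finite")
    denominator = mean_ctrl * freq_ctrl
    if denominator <= 0:
        raise DomainError("control score (mean_ctrl * freq_ctrl) must be positive")
    return (mean_pos * freq_pos) / denominator
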