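"""Screen-table analysis: summaries, plate heat maps, pairwise trends.

Trends are averaged effects of swapping a single building block: every
pair of compositions that differ only in the compared block contributes
the ratio metric(X)/metric(Y). Swapping the transactivator implicitly
swaps its matched inducible promoter as well, so those pairs still differ
in just one library choice. For the default 96-composition library every
two-variant comparison yields 48 pairs and the three-variant output-target
comparisons yield 32.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataCompletenessError, DomainError, LayoutError
from .screen import (
    BLOCKS,
    ComponentVariant,
    ScreenTable,
    SensorComposition,
    enumerate_library,
)

__all__ = [
    "CompositionSummary",
    "TrendResult",
    "summarize_compositions",
    "heatmap_table",
    "plot_heatmap",
    "pairwise_trends",
    "default_trend_comparisons",
    "rank_sensors",
]

logger = logging.getLogger(__name__)

Metric = Literal["on", "off", "dynamic_range"]
Normalization = Literal["absolute", "pool_normalized"]

_ROW_LETTERS = "ABCDEFGH"
_LOG_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class CompositionSummary:
    """Replicate means/SDs and dynamic range for one composition.

    SD fields are ``None`` with a single replicate; the ``*_norm`` fields
    are ``None`` when the table has not been pool-normalized.
    """

    composition_id: str
    well: str
    on_mean: float
    off_mean: float
    dynamic_range: float
    on_sd: Optional[float] = None
    off_sd: Optional[float] = None
    on_mean_norm: Optional[float] = None
    off_mean_norm: Optional[float] = None
    dynamic_range_norm: Optional[float] = None
    on_sd_norm: Optional[float] = None
    off_sd_norm: Optional[float] = None

    def metric(self, metric: Metric, normalization: Normalization = "absolute") -> float:
        key = {"on": "on_mean", "off": "off_mean", "dynamic_range": "dynamic_range"}[
            metric
        ]
        if normalization == "pool_normalized":
            value = getattr(self, key + "_norm")
            if value is None:
                raise DataCompletenessError(
                    "pool-normalized metrics requested but the table was not "
                    "normalized; run normalize_to_output_pool first"
                )
            return value
        return getattr(self, key)


@dataclass(frozen=True)
class TrendResult:
    """Averaged single-block swap effect: mean/SD of per-pair ratios."""

    comparison_label: str
    metric: Metric
    normalization: Normalization
    pair_ratios: list[float]
    mean_ratio: float
    sd_ratio: Optional[float]
    n_pairs: int
    n_excluded: int = 0
    log_ratios: bool = False


def _mean_sd(values: Sequence[float]) -> tuple[float, Optional[float]]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return mean, sd


def summarize_compositions(table: ScreenTable) -> list[CompositionSummary]:
    """Per-composition On/Off means, SDs and dynamic range.

    Dynamic range is the ratio of replicate means; it is identical for
    absolute and pool-normalized values because the normalization is a
    per-composition constant.
    """
    frame = table.to_frame()
    has_norm = frame["normalized_value"].notna().all()
    summaries = []
    for comp in table.compositions:
        rows = frame[frame["composition_id"] == comp.composition_id]
        per_condition = {}
        for condition in ("on", "off"):
            values = rows.loc[rows["condition"] == condition, "raw_value"]
            if values.empty:
                raise DataCompletenessError(
                    f"composition {comp.composition_id} has no {condition!r} records"
                )
            per_condition[condition] = values.to_numpy()
        on_mean, on_sd = _mean_sd(per_condition["on"])
        off_mean, off_sd = _mean_sd(per_condition["off"])
        dr = on_mean / off_mean if off_mean > 0 else math.inf
        norm_fields: dict[str, Optional[float]] = {}
        if has_norm:
            for condition in ("on", "off"):
                values = rows.loc[
                    rows["condition"] == condition, "normalized_value"
                ].to_numpy()
                mean, sd = _mean_sd(values)
                norm_fields[f"{condition}_mean_norm"] = mean
                norm_fields[f"{condition}_sd_norm"] = sd
            norm_fields["dynamic_range_norm"] = (
                norm_fields["on_mean_norm"] / norm_fields["off_mean_norm"]
                if norm_fields["off_mean_norm"] > 0
                else math.inf
            )
        summaries.append(
            CompositionSummary(
                composition_id=comp.composition_id,
                well=comp.well,
                on_mean=on_mean,
                on_sd=on_sd,
                off_mean=off_mean,
                off_sd=off_sd,
                dynamic_range=dr,
                **norm_fields,
            )
        )
    return summaries


def summaries_to_frame(summaries: Iterable[CompositionSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def heatmap_table(
    summaries: Iterable[CompositionSummary],
    metric: Metric = "dynamic_range",
    log_transform: bool = False,
    normalization: Normalization = "absolute",
) -> pd.DataFrame:
    """8x12 plate-layout matrix of one metric, optionally log10-scaled.

    Log transformation (used for Off states and dynamic ranges to spread
    the low end) floors values at 1e-6 of the table maximum so zeros map
    to a finite floor rather than -inf.
    """
    summaries = list(summaries)
    matrix = pd.DataFrame(
        np.nan, index=list(_ROW_LETTERS), columns=range(1, 13), dtype=float
    )
    seen: set[str] = set()
    for summary in summaries:
        if summary.well in seen:
            raise LayoutError(f"duplicate well {summary.well}")
        seen.add(summary.well)
        row, col = summary.well[0], int(summary.well[1:])
        matrix.loc[row, col] = summary.metric(metric, normalization)
    missing = [
        f"{r}{c}" for r in _ROW_LETTERS for c in range(1, 13) if f"{r}{c}" not in seen
    ]
    if missing:
        raise LayoutError(f"wells not covered by summaries: {', '.join(missing)}")
    if log_transform:
        floor = matrix.values.max() * _LOG_FLOOR_FRACTION
        matrix = np.log10(matrix.clip(lower=floor))
    return matrix


def plot_heatmap(matrix: pd.DataFrame, title: str = "", ax=None):
    """Render a plate heat map (matplotlib Axes) from a heatmap_table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    image = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns)
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    ax.set_title(title)
    ax.figure.colorbar(image, ax=ax)
    return ax


def default_trend_comparisons() -> list[tuple[str, str, str]]:
    """The six single-block comparisons reported for the default library."""
    return [
        ("activator_promoter", "UbC", "CMV"),
        ("activator_protein", "PIT2", "tTA"),
        ("activator_targets", "5and3prime", "3prime"),
        ("ff4_cassette", "cit_embedded", "intron_only"),
        ("output_promoter", "UbC", "EF1A"),
        ("output_targets", "5and3F", "3F"),
    ]


def _pair_key(comp: SensorComposition, block: str) -> tuple:
    return tuple(comp.variant_of(b) for b in BLOCKS if b != block)


def pairwise_trends(
    summaries: Iterable[CompositionSummary],
    variants: Iterable[ComponentVariant],
    comparison: tuple[str, str, str],
    metric: Metric = "dynamic_range",
    normalization: Normalization = "absolute",
    log_ratios: bool = False,
) -> TrendResult:
    """Averaged effect of swapping one building block, 'X versus Y'.

    Finds every pair of compositions identical in all blocks except the
    compared one and reports metric(X)/metric(Y) per pair (for
    transactivator swaps the matched inducible promoter changes along with
    the protein, which still counts as a single-block swap). Pairs with a
    zero denominator are excluded and counted. With ``log_ratios`` the
    mean/SD are taken over log10 of the ratios instead of the raw ratios.
    """
    block, name_x, name_y = comparison
    if block not in BLOCKS:
        raise ConfigurationError(f"unknown block {block!r}")
    variants = list(variants)
    available = {v.name for v in variants if v.block == block}
    for name in (name_x, name_y):
        if name not in available:
            raise ConfigurationError(
                f"variant {name!r} not defined for block {block!r} "
                f"(available: {sorted(available)})"
            )
    by_id = {s.composition_id: s for s in summaries}
    compositions = [
        c for c in enumerate_library(variants) if c.composition_id in by_id
    ]
    sides: dict[tuple, dict[str, SensorComposition]] = {}
    for comp in compositions:
        variant = comp.variant_of(block)
        if variant in (name_x, name_y):
            sides.setdefault(_pair_key(comp, block), {})[variant] = comp
    ratios: list[float] = []
    excluded = 0
    for members in sides.values():
        if name_x not in members or name_y not in members:
            continue
        x = by_id[members[name_x].composition_id].metric(metric, normalization)
        y = by_id[members[name_y].composition_id].metric(metric, normalization)
        if y == 0:
            excluded += 1
            continue
        ratios.append(x / y)
    if excluded:
        logger.warning(
            "%d pair(s) excluded from %s vs %s (%s) due to zero denominators",
            excluded,
            name_x,
            name_y,
            block,
        )
    if not ratios:
        raise DomainError(
            f"no comparable pairs for {name_x!r} vs {name_y!r} in block {block!r}"
        )
    values = [math.log10(r) for r in ratios] if log_ratios else ratios
    mean, sd = _mean_sd(values)
    label_block = {"activator_promoter": "Act promoter", "activator_protein": "Act",
                   "activator_targets": "Act targets", "ff4_cassette": "FF4 cassette",
                   "output_promoter": "Out promoter", "output_targets": "Out targets"}[
        block
    ]
    return TrendResult(
        comparison_label=f"{name_x} versus {name_y} ({label_block})",
        metric=metric,
        normalization=normalization,
        pair_ratios=ratios,
        mean_ratio=mean,
        sd_ratio=sd,
        n_pairs=len(ratios),
        n_excluded=excluded,
        log_ratios=log_ratios,
    )


def rank_sensors(
    summaries: Iterable[CompositionSummary],
    criterion: Metric = "dynamic_range",
    normalization: Normalization = "absolute",
) -> list[CompositionSummary]:
    """Stable ranking, best first: criterion desc, then On desc, then id."""
    summaries = list(summaries)
    if not summaries:
        raise DomainError("cannot rank an empty summary list")
    return sorted(
        summaries,
        key=lambda s: (
            -s.metric(criterion, normalization),
            -s.metric("on", normalization),
            s.composition_id,
        ),
    )
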