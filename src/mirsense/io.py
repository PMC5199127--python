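"""Reading and writing the package's plain-text formats.

Parameter sets are flat key-value YAML; component libraries are nested
YAML (block -> variant -> multipliers); dose-response curves are
two-column CSV with a JSON sidecar for curve kind and control reference;
screen tables are tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .dose_response import DoseResponseCurve
from .errors import ConfigurationError
from .model import PerformanceSummary, SensorParameters
from .screen import ComponentVariant, ScreenRecord, ScreenTable

__all__ = [
    "read_parameters",
    "write_parameters",
    "read_library",
    "write_library",
    "read_curve",
    "write_curve",
    "write_screen_table",
    "read_screen_records",
    "summary_to_json",
]


def read_parameters(path) -> SensorParameters:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a flat key-value mapping")
    return SensorParameters.from_dict(data)


def write_parameters(params: SensorParameters, path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(params.to_dict(), handle, sort_keys=False)


def read_library(path) -> list[ComponentVariant]:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected block -> variant -> multipliers")
    variants = []
    for block, members in data.items():
        if not isinstance(members, dict):
            raise ConfigurationError(f"{path}: block {block!r} must map variant names")
        for name, multipliers in members.items():
            variants.append(
                ComponentVariant(block, str(name), dict(multipliers or {}))
            )
    return variants


def write_library(variants: Iterable[ComponentVariant], path) -> None:
    data: dict[str, dict[str, dict[str, float]]] = {}
    for variant in variants:
        data.setdefault(variant.block, {})[variant.name] = dict(variant.multipliers)
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_curve(curve: DoseResponseCurve, path) -> None:
    pd.DataFrame({"dose": curve.doses, "response": curve.responses}).to_csv(
        path, index=False
    )
    meta = {"curve_kind": curve.curve_kind, "control_max": curve.control_max}
    _sidecar(path).write_text(json.dumps(meta))


def read_curve(path) -> DoseResponseCurve:
    frame = pd.read_csv(path)
    if not {"dose", "response"}.issubset(frame.columns):
        raise ConfigurationError(f"{path}: expected 'dose' and 'response' columns")
    kind, control_max = "induction", None
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kind = meta.get("curve_kind", kind)
        control_max = meta.get("control_max")
    return DoseResponseCurve(
        doses=frame["dose"].to_numpy(),
        responses=frame["response"].to_numpy(),
        curve_kind=kind,
        control_max=control_max,
    )


def write_screen_table(table: ScreenTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_screen_records(path) -> list[ScreenRecord]:
    """Read tidy screen CSV back into records (provenance not recoverable)."""
    frame = pd.read_csv(path)
    required = {"composition_id", "well", "condition", "replicate", "raw_value"}
    if not required.issubset(frame.columns):
        raise ConfigurationError(f"{path}: missing columns {required - set(frame.columns)}")
    records = []
    for row in frame.itertuples(index=False):
        normalized: Optional[float] = getattr(row, "normalized_value", None)
        if normalized is not None and pd.isna(normalized):
            normalized = None
        records.append(
            ScreenRecord(
                composition_id=row.composition_id,
                well=row.well,
                condition=row.condition,
                replicate=int(row.replicate),
                raw_value=float(row.raw_value),
                normalized_value=normalized,
            )
        )
    return records


def read_screen_table(path, variants: Iterable[ComponentVariant]) -> ScreenTable:
    """Rebuild a ScreenTable from tidy CSV plus its component library.

    Simulation provenance (seed, noise CV) is not stored in the CSV, so
    the returned table carries placeholder values for those fields; all
    analysis operations depend only on the records and compositions.
    """
    from .screen import enumerate_library

    records = read_screen_records(path)
    variants = list(variants)
    compositions = enumerate_library(variants)
    present = {r.composition_id for r in records}
    compositions = [c for c in compositions if c.composition_id in present]
    n_replicates = max((r.replicate for r in records), default=1)
    return ScreenTable(
        records=records,
        library=variants,
        compositions=compositions,
        seed=-1,
        noise_cv=float("nan"),
        n_replicates=n_replicates,
        practical_input=float("nan"),
        control_leakage=float("nan"),
    )


def summary_to_json(summary: PerformanceSummary, path=None) -> str:
    text = json.dumps(summary.to_dict(), indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
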