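"""End-to-end orchestration: config, seeded runs, full pipeline.

``run_full_pipeline`` chains parameter scans, the act_max x kd landscape,
library enumeration, screen simulation, pool normalization, composition
summaries, plate heat maps and the six default trend comparisons, writing
every artifact as CSV/JSON plus a manifest carrying the config hash and
seed. Deterministic stages are bit-identical across reruns; the seeded
screen is value-identical under the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import analysis, explore, io, screen
from .errors import ConfigurationError, MirsenseError
from .model import PRACTICAL_INPUT_DEFAULT, SensorParameters
from .screen import ComponentVariant

__all__ = ["RunConfig", "run_full_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a reproducible run depends on. The seed is mandatory."""

    seed: int
    base: SensorParameters = field(default_factory=SensorParameters.basic)
    library: list[ComponentVariant] = field(default_factory=screen.default_library)
    practical_input: float = PRACTICAL_INPUT_DEFAULT
    noise_cv: float = 0.2
    n_replicates: int = 3
    residual_input: float = 0.0
    control_leakage: float = 0.85
    out_dir: Path = Path("mirsense_run")
    # curve grid
    curve_n_points: int = 61
    curve_dose_min: float = 1e-1
    curve_dose_max: float = 1e5
    # scan / landscape grids
    scan_decades: float = 2.0
    scan_points: int = 25
    landscape_points: int = 13

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory for reproducible runs")
        self.seed = int(self.seed)
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if "seed" not in data:
            raise ConfigurationError(f"{path}: config must define a seed")
        kwargs = dict(data)
        if "base" in kwargs:
            base = kwargs["base"]
            kwargs["base"] = (
                io.read_parameters(base)
                if isinstance(base, str)
                else SensorParameters.from_dict(base)
            )
        if "library" in kwargs:
            lib = kwargs["library"]
            if isinstance(lib, str):
                lib_path = Path(lib)
                if not lib_path.exists():
                    raise ConfigurationError(f"library file not found: {lib}")
                kwargs["library"] = io.read_library(lib_path)
            else:
                kwargs["library"] = [
                    ComponentVariant(block, name, dict(mult or {}))
                    for block, members in lib.items()
                    for name, mult in members.items()
                ]
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**kwargs)

    def canonical_dict(self) -> dict:
        return {
            "seed": self.seed,
            "base": self.base.to_dict(),
            "library": [
                {"block": v.block, "name": v.name, "multipliers": dict(v.multipliers)}
                for v in self.library
            ],
            "practical_input": self.practical_input,
            "noise_cv": self.noise_cv,
            "n_replicates": self.n_replicates,
            "residual_input": self.residual_input,
            "control_leakage": self.control_leakage,
            "curve_n_points": self.curve_n_points,
            "curve_dose_min": self.curve_dose_min,
            "curve_dose_max": self.curve_dose_max,
            "scan_decades": self.scan_decades,
            "scan_points": self.scan_points,
            "landscape_points": self.landscape_points,
        }

    def config_hash(self) -> str:
        canonical = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except MirsenseError:
        logger.error("pipeline stage %r failed (inputs: %r)", name, args[:1])
        raise


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts; returns the manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    # 1. single-parameter scans
    scan_frames = []
    for name in SensorParameters.field_names():
        values = explore.log_range(
            getattr(config.base, name), config.scan_decades, config.scan_points
        )
        result = _stage(
            f"scan:{name}",
            explore.scan_parameter,
            config.base,
            name,
            values,
            config.practical_input,
        )
        scan_frames.append(result.to_frame())
    scans = pd.concat(scan_frames, ignore_index=True)
    scans.to_csv(out / "scans.csv", index=False)
    files["scans"] = "scans.csv"

    # 2. act_max x kd landscape
    landscape = _stage(
        "landscape",
        explore.scan_landscape,
        config.base,
        explore.log_range(config.base.act_max, config.scan_decades, config.landscape_points),
        explore.log_range(config.base.kd, config.scan_decades, config.landscape_points),
        config.practical_input,
    )
    landscape.to_frame().to_csv(out / "landscape.csv", index=False)
    files["landscape"] = "landscape.csv"

    # 3. library + screen simulation
    compositions = _stage("enumerate_library", screen.enumerate_library, config.library)
    pd.DataFrame(
        [dataclasses.asdict(c) for c in compositions]
    ).to_csv(out / "library.csv", index=False)
    files["library"] = "library.csv"
    table = _stage(
        "simulate_screen",
        screen.simulate_screen,
        config.library,
        config.base,
        seed=config.seed,
        practical_input=config.practical_input,
        noise_cv=config.noise_cv,
        n_replicates=config.n_replicates,
        residual_input=config.residual_input,
        control_leakage=config.control_leakage,
    )
    io.write_screen_table(table, out / "screen_raw.csv")
    files["screen_raw"] = "screen_raw.csv"

    # 4. normalization + summaries
    table = _stage("normalize_to_output_pool", screen.normalize_to_output_pool, table)
    io.write_screen_table(table, out / "screen_normalized.csv")
    files["screen_normalized"] = "screen_normalized.csv"
    summaries = _stage("summarize_compositions", analysis.summarize_compositions, table)
    analysis.summaries_to_frame(summaries).to_csv(out / "summaries.csv", index=False)
    files["summaries"] = "summaries.csv"

    # 5. heat maps (On, log Off, log dynamic range — the reported trio)
    for metric, log_transform, stem in (
        ("on", False, "heatmap_on"),
        ("off", True, "heatmap_off_log10"),
        ("dynamic_range", True, "heatmap_dynamic_range_log10"),
    ):
        matrix = _stage(
            f"heatmap:{metric}", analysis.heatmap_table, summaries, metric, log_transform
        )
        matrix.to_csv(out / f"{stem}.csv")
        files[stem] = f"{stem}.csv"

    # 6. pairwise trends for the six default comparisons
    trend_rows = []
    comparisons = analysis.default_trend_comparisons()
    for comparison in comparisons:
        for metric in ("on", "off", "dynamic_range"):
            for normalization in ("absolute", "pool_normalized"):
                trend = _stage(
                    f"trends:{comparison[0]}",
                    analysis.pairwise_trends,
                    summaries,
                    config.library,
                    comparison,
                    metric,
                    normalization,
                )
                trend_rows.append(
                    {
                        "comparison": trend.comparison_label,
                        "block": comparison[0],
                        "metric": metric,
                        "normalization": normalization,
                        "mean_ratio": trend.mean_ratio,
                        "sd_ratio": trend.sd_ratio,
                        "n_pairs": trend.n_pairs,
                        "n_excluded": trend.n_excluded,
                    }
                )
    pd.DataFrame(trend_rows).to_csv(out / "trends.csv", index=False)
    files["trends"] = "trends.csv"

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_compositions": len(compositions),
        "n_records": len(table.records),
        "trend_comparisons": [list(c) for c in comparisons],
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
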