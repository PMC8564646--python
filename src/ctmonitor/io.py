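"""Configuration, table readers/writers and report assembly.

All tables are comma-separated UTF-8 text with a header row and '.' decimal
separator; weeks are the canonical time unit throughout. Every writer's
output is readable by its paired reader without loss.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ddpcr import AssayConstants
from .simulate import CohortSimConfig

log = logging.getLogger("ctmonitor")

DROPLET_COLUMNS = [
    "patient_id",
    "timepoint",
    "mutant_positive",
    "wildtype_positive",
    "total_droplets",
]
CLINICAL_COLUMNS = [
    "patient_id",
    "pfs_weeks",
    "pfs_event",
    "os_weeks",
    "os_event",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline stages need, loadable from one YAML file."""

    assay: AssayConstants = field(default_factory=AssayConstants)
    classification_threshold: float = 0.30
    sweep_thresholds: tuple[float, ...] = (0.30, 0.40, 0.50)
    grouping_convention: str = "exclude_negative"
    dcb_threshold_weeks: float = 26.0
    candidate_weeks: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0)
    max_gap_weeks: float = 1.0
    high_level_cutoff: float | None = None
    simulation: CohortSimConfig = field(default_factory=CohortSimConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.classification_threshold < 1:
            raise ValueError("classification_threshold must lie in (0, 1)")
        if self.dcb_threshold_weeks <= 0:
            raise ValueError("dcb_threshold_weeks must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        assay = AssayConstants(**raw.pop("assay", {}))
        sim_kwargs = raw.pop("simulation", {})
        if seed is not None:
            raw["seed"] = seed
            sim_kwargs["seed"] = seed
        sim = CohortSimConfig(**sim_kwargs)
        for key in ("sweep_thresholds", "candidate_weeks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(assay=assay, simulation=sim, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonify(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonify(obj: Any) -> Any:
    """Recursively coerce numpy scalars / arrays so json.dump accepts them."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def read_droplet_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: droplet table is empty")
    missing = set(DROPLET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[
        (df["mutant_positive"] > df["total_droplets"])
        | (df["wildtype_positive"] > df["total_droplets"])
        | (df["total_droplets"] < 1)
        | (df[["mutant_positive", "wildtype_positive"]].lt(0).any(axis=1))
    ]
    if not bad.empty:
        lines = ", ".join(str(i + 2) for i in bad.index[:10])  # +2: header + 1-based
        raise ValueError(f"{path}: malformed droplet counts at line(s) {lines}")
    return df


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["pfs_weeks"] < 0).any() or (df["os_weeks"] < 0).any():
        raise ValueError(f"{path}: negative survival times")
    return df


def read_quant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"patient_id", "timepoint", "copies_per_ml", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_series_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"patient_id", "week", "copies_per_ml", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")
    return path


def write_km_curves(report: dict, out_dir: str | Path) -> list[Path]:
    """Export KM curve points as TSV (time, survival, at_risk) per group.

    ``report`` is the dict from :func:`ctmonitor.survival.stratified_endpoint_report`
    augmented with ``_curves`` entries, or a plain mapping
    name -> :class:`ctmonitor.survival.KMCurve`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, curve in report.items():
        df = pd.DataFrame(
            {
                "time_weeks": curve.times,
                "survival": curve.survival,
                "at_risk": curve.at_risk,
            }
        )
        path = out_dir / f"km_{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def assemble_report(
    config: PipelineConfig,
    quant: pd.DataFrame | None = None,
    dynamics: pd.DataFrame | None = None,
    endpoints: dict | None = None,
    concordance: dict | None = None,
    timepoint_table: pd.DataFrame | None = None,
    recommended_week: float | None = None,
) -> dict:
    """Aggregate stage outputs into one deterministic JSON-able report."""
    report: dict[str, Any] = {
        "ctmonitor_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    if quant is not None:
        report["quantification_qc"] = {
            "n_samples": int(len(quant)),
            "status_counts": quant["status"].value_counts().to_dict(),
        }
    if dynamics is not None:
        report["dynamics"] = {
            "n_patients": int(len(dynamics)),
            "category_counts": dynamics["category"].value_counts().to_dict(),
            "n_excluded": int((dynamics["category"] == "excluded").sum()),
        }
    if endpoints is not None:
        report["endpoints"] = endpoints
    if concordance is not None:
        report["concordance"] = concordance
    if timepoint_table is not None:
        report["timepoint_separation"] = timepoint_table.to_dict(orient="records")
        report["recommended_week"] = recommended_week
    return _jsonify(report)
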