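"""Run configuration: serializable bundle of geometry, cohort calibration
and analysis options, so a full run is reproducible from one file."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .cohort import CohortCalibration, ParamDist, default_calibration
from .task_design import Effector, Task, TaskGeometry


@dataclass
class AnalysisOptions:
    """Options of the analysis stages."""

    onset_threshold_fraction: float = 0.02
    include_control_level: bool = True
    fit_lapse_high: bool = True
    lapse_high_max: float = 0.15
    end_rule: str = "stillness"  # or "radius"
    n_boot: int = 1000
    bf_prior_scale: float = 0.7071067811865476  # sqrt(2)/2
    smooth: bool = True


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulate + analyze run."""

    seed: int = 0
    n_participants: int = 20
    geometry: TaskGeometry = field(default_factory=TaskGeometry)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    calibration_overrides: dict[str, Any] = field(default_factory=dict)

    def calibration(self) -> CohortCalibration:
        cal = default_calibration(self.n_participants)
        if self.calibration_overrides:
            cal = _apply_overrides(cal, self.calibration_overrides)
        return cal


def _apply_overrides(cal: CohortCalibration, overrides: dict[str, Any]) -> CohortCalibration:
    """Replace scalar calibration fields or (effector[, task])-keyed
    distribution entries from a plain dict (as read from YAML/JSON)."""
    kwargs: dict[str, Any] = {f.name: getattr(cal, f.name) for f in fields(cal)}
    for name, value in overrides.items():
        if name not in kwargs:
            raise KeyError(f"unknown calibration field: {name}")
        current = kwargs[name]
        if isinstance(current, dict) and isinstance(value, dict):
            updated = dict(current)
            for key_str, entry in value.items():
                key = _parse_key(key_str)
                updated[key] = (
                    ParamDist(**entry) if isinstance(entry, dict) else float(entry)
                )
            kwargs[name] = updated
        else:
            kwargs[name] = value
    return CohortCalibration(**kwargs)


def _parse_key(key: str):
    parts = key.split(":")
    if len(parts) == 1:
        return Effector(parts[0])
    return (Effector(parts[0]), Task(parts[1]))


def _to_plain(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = _to_plain(config)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(data, fh, sort_keys=True)
        else:
            json.dump(data, fh, indent=1, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    geometry = TaskGeometry(**data.get("geometry", {}))
    analysis = AnalysisOptions(**data.get("analysis", {}))
    return RunConfig(
        seed=int(data.get("seed", 0)),
        n_participants=int(data.get("n_participants", 20)),
        geometry=geometry,
        analysis=analysis,
        calibration_overrides=data.get("calibration_overrides", {}),
    )
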