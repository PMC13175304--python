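"""Plain-text serialization: TAC CSV/JSON bundles, YAML configs, metric tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierThresholds
from .kinetics import FrameSchedule, NoiseSpec, TAC, TracerKineticParams
from .wknn import NeighborhoodWeights

__all__ = [
    "tac_to_csv", "tac_from_csv", "tacs_to_json", "tacs_from_json",
    "save_yaml_config", "load_noise_spec", "load_tracer_params",
    "load_thresholds", "load_weights", "metrics_to_csv", "metrics_to_json",
]


def tac_to_csv(tac: TAC, path) -> None:
    pd.DataFrame(dict(frame_start=tac.schedule.frame_start,
                      frame_end=tac.schedule.frame_end,
                      value=tac.values)).to_csv(path, index=False)


def tac_from_csv(path) -> TAC:
    df = pd.read_csv(path)
    sched = FrameSchedule(df["frame_start"].to_numpy(),
                          df["frame_end"].to_numpy())
    return TAC(sched, df["value"].to_numpy())


def tacs_to_json(tacs: dict, path, *, units: str = "kBq/ml",
                 seed=None, params: dict | None = None) -> None:
    """Write a named set of TACs sharing one schedule, with metadata."""
    first = next(iter(tacs.values()))
    bundle = dict(units=units, seed=seed, params=params or {},
                  frame_start=first.schedule.frame_start.tolist(),
                  frame_end=first.schedule.frame_end.tolist(),
                  curves={k: v.values.tolist() for k, v in tacs.items()})
    Path(path).write_text(json.dumps(bundle, indent=1))


def tacs_from_json(path):
    bundle = json.loads(Path(path).read_text())
    sched = FrameSchedule(np.array(bundle["frame_start"]),
                          np.array(bundle["frame_end"]))
    curves = {k: TAC(sched, np.array(v)) for k, v in bundle["curves"].items()}
    return curves, bundle


def save_yaml_config(obj, path) -> None:
    data = asdict(obj)
    data.pop("_FACTORS", None)
    if "plasma" in data and isinstance(data["plasma"], dict):
        pass  # nested dataclass already dict-ified by asdict
    yaml.safe_dump({type(obj).__name__: data}, open(path, "w"))


def _load_section(path, name):
    data = yaml.safe_load(open(path))
    return data.get(name, data)


def load_noise_spec(path) -> NoiseSpec:
    return NoiseSpec(**_load_section(path, "NoiseSpec"))


def load_tracer_params(path) -> TracerKineticParams:
    from .kinetics import PlasmaInput
    data = _load_section(path, "TracerKineticParams")
    if isinstance(data.get("plasma"), dict):
        data["plasma"] = PlasmaInput(**data["plasma"])
    return TracerKineticParams(**data)


def load_thresholds(path) -> ClassifierThresholds:
    return ClassifierThresholds(**_load_section(path, "ClassifierThresholds"))


def load_weights(path) -> NeighborhoodWeights:
    return NeighborhoodWeights(**_load_section(path, "NeighborhoodWeights"))


def metrics_to_csv(report, path) -> None:
    """Tidy one-row-per-metric CSV from a MetricsReport."""
    pd.DataFrame(report.to_rows(),
                 columns=["class_label", "metric", "value"]).to_csv(
        path, index=False)


def metrics_to_json(report, path) -> None:
    rows = report.to_rows()
    Path(path).write_text(json.dumps(
        [dict(class_label=c, metric=m, value=v) for c, m, v in rows],
        indent=1))
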