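"""YAML configuration loading and validation for the command-line tools.

A single run-config file carries the subject's limb measurements and every
tunable of the pipeline (many of the tracker's constants — the cost weights in
particular — are deliberately user-visible):

.. code-block:: yaml

    shapes:
      left:  {r: 40, l: 260, h: 80, d: 15, r1: 50, r2: 60, s: 350}
      right: {r: 40, l: 260, h: 80, d: 15, r1: 50, r2: 60, s: 350}
    segmentation: {max_range: 1000, r_initial: 10}
    weights: {w1: 2.0, w2: 10.0}
    optimizer: {n_max: 30}
    kalman: {enabled: true}
    events: {window: 19, delta_d_min: 5}
    seed: 0

Unknown keys are rejected with an error naming the offending key.
"""

from __future__ import annotations

from dataclasses import fields
from typing import Any, Dict, Tuple

import yaml

from .gait import EventDetectorConfig
from .geometry import FootShape, ShankShape
from .segmentation import SegmentationConfig
from .synthetic import GaitScript
from .tracking import (
    CostWeights,
    KalmanConfig,
    LimbShapes,
    OptimizerConfig,
    TrackerConfig,
)

__all__ = ["ConfigError", "load_run_config", "load_script"]


class ConfigError(ValueError):
    pass


def _build(cls, data: Dict[str, Any], section: str):
    allowed = {f.name for f in fields(cls)}
    for key in data:
        if key not in allowed:
            raise ConfigError(f"unknown key '{section}.{key}'")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{section}': {exc}") from exc


def _shapes(data: Dict[str, Any]) -> Dict[str, LimbShapes]:
    out = {}
    for side in ("left", "right"):
        if side not in data:
            raise ConfigError(f"missing key 'shapes.{side}'")
        entry = dict(data[side])
        extra = set(entry) - {"r", "l", "h", "d", "r1", "r2", "s"}
        if extra:
            raise ConfigError(f"unknown key 'shapes.{side}.{extra.pop()}'")
        try:
            foot = FootShape(
                r=entry["r"], l=entry["l"], h=entry["h"], d=entry.get("d", 0.0)
            )
            shank = ShankShape(r1=entry["r1"], r2=entry["r2"], s=entry["s"])
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"invalid section 'shapes.{side}': {exc}") from exc
        out[side] = LimbShapes(foot, shank)
    return out


_SECTIONS = {
    "segmentation": SegmentationConfig,
    "weights": CostWeights,
    "optimizer": OptimizerConfig,
    "kalman": KalmanConfig,
    "events": EventDetectorConfig,
}


def load_run_config(
    path: str,
) -> Tuple[Dict[str, LimbShapes], TrackerConfig, EventDetectorConfig]:
    """Parse and validate a run config; raises :class:`ConfigError`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = set(_SECTIONS) | {"shapes", "seed", "reestimate_ground"}
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown key '{key}'")
    if "shapes" not in raw:
        raise ConfigError("missing key 'shapes'")
    shapes = _shapes(raw["shapes"])
    built = {
        name: _build(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    tracker = TrackerConfig(
        segmentation=built["segmentation"],
        weights=built["weights"],
        optimizer=built["optimizer"],
        kalman=built["kalman"],
        reestimate_ground=bool(raw.get("reestimate_ground", False)),
        seed=int(raw.get("seed", 0)),
    )
    return shapes, tracker, built["events"]


def load_script(path: str) -> GaitScript:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("script root must be a mapping")
    return _build(GaitScript, raw, "script")
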