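"""YAML configuration loading for the tracker.

Recognised keys (all optional; omitted keys keep the built-in defaults,
which are the published detector parameters)::

    cht:
      min_dist: 40
      canny_high: 180
      accumulator_threshold: 10
      min_radius: 15
      max_radius: 50
    acm:
      max_iter: 200
      tol: 0.1
      smoothing: 1
    selection:
      white_threshold: 0.60
    morphology:
      kernel_shape: ellipse
      kernel_size: 3
      erode_iterations: 1
      dilate_iterations: 1
      order: erode_first
    matching:
      use_mask: true
      method: ncc
      sim_threshold: 0.98
      sim_floor: 0.5

Precedence is: CLI flag > config file > built-in defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Optional

import yaml

from .detection import AcmConfig, ChtParams, DetectionConfig
from .preprocess import MorphologyConfig
from .tracking import MatchConfig, TrackerConfig

__all__ = ["load_tracker_config", "tracker_config_to_dict"]


def _build(cls, data: Optional[dict]):
    data = data or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_tracker_config(path: Optional[str | Path] = None) -> TrackerConfig:
    """Build a :class:`TrackerConfig` from a YAML file (or the defaults)."""
    raw: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("tracker config must be a YAML mapping")
            raw = loaded
    selection = raw.get("selection") or {}
    detection = DetectionConfig(
        cht=_build(ChtParams, raw.get("cht")),
        morph=_build(MorphologyConfig, raw.get("morphology")),
        acm=_build(AcmConfig, raw.get("acm")),
        white_threshold=float(selection.get("white_threshold", 0.60)),
    )
    return TrackerConfig(
        detection=detection, match=_build(MatchConfig, raw.get("matching"))
    )


def tracker_config_to_dict(cfg: TrackerConfig) -> dict:
    """Serialisable snapshot of a tracker configuration."""
    return {
        "cht": dataclasses.asdict(cfg.detection.cht),
        "acm": dataclasses.asdict(cfg.detection.acm),
        "morphology": dataclasses.asdict(cfg.detection.morph),
        "selection": {"white_threshold": cfg.detection.white_threshold},
        "matching": dataclasses.asdict(cfg.match),
    }
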