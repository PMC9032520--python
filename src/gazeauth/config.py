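"""YAML configuration with package defaults.

Geometry defaults match a 1680x1050 display (474 x 297 mm) viewed at
550 mm; all values are overridable from a YAML file.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .core import ScreenGeometry

DEFAULTS: dict = {
    "geometry": {
        "distance_mm": 550.0,
        "width_mm": 474.0,
        "height_mm": 297.0,
        "width_px": 1680,
        "height_px": 1050,
    },
    "ivt": {
        "fix_thresh": 100.0,
        "sac_peak_thresh": 300.0,
        "min_fix_ms": 50.0,
        "min_sac_ms": 10.0,
    },
    "attention": {
        "window_s": 0.5,
        "trim_head_s": 1.0,
        "keep_s": 14.0,
        "fovea_deg": 1.0,
    },
    "mi": {"decimate": 1, "fixation_only": False},
    "sdm": {"min_extent_px": 10.0, "drop_if": "both_short"},
    "segmentation": {"segment_s": 12.0, "usable_s": 60.0},
    "train": {
        "mode": "open_set",
        "max_steps": 2000,
        "weight_decay": 1e-4,
        "subjects_per_batch": 8,
        "samples_per_subject": 4,
        "seed": 0,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Package defaults, overlaid with a YAML file when given."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    user = yaml.safe_load(Path(path).read_text()) or {}
    return _merge(DEFAULTS, user)


def geometry_from_config(cfg: dict) -> ScreenGeometry:
    return ScreenGeometry(**cfg["geometry"])
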