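"""Pipeline configuration with documented defaults.

Every tunable parameter of the pipeline is exposed here with its
default: lumen HU range 200-500, circle-likeness threshold 0.60,
angular tolerance 10 deg, centroid-line tolerance 2 px, minimum lumen
component 50 px, slice-linking continuity limit 20 px, and minimum PAU
component 3 px.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path
from typing import Any, Optional

import yaml

log = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "hu_range": [200, 500],
    "circle_threshold": 0.60,
    "angle_tol_deg": 10.0,
    "line_tol_px": 2.0,
    "min_component_px": 50,
    "continuity_limit_px": 20.0,
    "pau_min_px": 3,
    "seeds": {},  # e.g. {"descending": [row, col]}
}


def load_config(path: Optional[str] = None) -> dict[str, Any]:
    """Merge a YAML config file over the documented defaults.

    A missing file path returns pure defaults; a config that omits
    ``hu_range`` falls back to 200-500 HU with a logged warning.
    """
    cfg = copy.deepcopy(DEFAULTS)
    if path is None:
        log.warning("no config supplied; using default HU range %s", cfg["hu_range"])
        return cfg
    with open(Path(path)) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "hu_range" not in user:
        log.warning("config omits hu_range; falling back to default %s", cfg["hu_range"])
    cfg.update(user)
    return cfg
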