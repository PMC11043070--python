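"""Run configuration: defaults, legal ranges and validation.

A single nested mapping governs every stage; :func:`validate_config` fills
defaults and range-checks numeric parameters, so downstream code can assume a
fully populated, legal configuration.
"""

from __future__ import annotations

import copy
import json
from typing import Any, Mapping

import numpy as np

from .core import ConfigError

#: full default configuration; every stage reads its section from here
DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "segmentation": {
        "threshold_method": "otsu",     # otsu | fixed
        "fixed_threshold": 0.0,         # intensity, used when method = fixed
        "min_size": 10.0,               # um^2 (2D) / um^3 (3D)
        "max_size": 1.0e5,
        "projection": "max",            # max | none
    },
    "classification": {
        "pomc_channel": "pomc",
        "statistic": "mean",
        "threshold_rule": "otsu_on_cells",  # fixed | quantile_of_negative_control | otsu_on_cells
        "fixed_threshold": 0.0,
        "quantile": 0.95,
    },
    "kde": {
        "bandwidth_rule": "scott",      # scott | silverman | fixed
        "fixed_bandwidth": 50.0,        # um per axis, used when rule = fixed
        "grid_spacing": 25.0,           # um
        "occupancy_quantile": 0.25,
    },
    "ephys_rule": {
        "delta_rmp_threshold": 2.0,     # mV
        "delta_ri_threshold_pct": 10.0, # %
        "pre_window": 30.0,             # s, ends at application onset
        "post_offset": 300.0,           # s after onset
        "post_window": 30.0,            # s
        "combine": "and",               # and | or
    },
    "cluster": {
        "n_pcs": 20,
        "knn_k": 10,
        "resolution_grid": [round(0.1 * i, 1) for i in range(1, 21)],
        "min_silhouette": 0.0,
    },
}

# (section, key) -> (low, high, low_open, high_open); None = unbounded
_RANGES: dict[tuple[str, str], tuple[float | None, float | None, bool, bool]] = {
    ("segmentation", "fixed_threshold"): (0.0, None, False, False),
    ("segmentation", "min_size"): (0.0, None, True, False),
    ("segmentation", "max_size"): (0.0, None, True, False),
    ("classification", "fixed_threshold"): (0.0, None, False, False),
    ("classification", "quantile"): (0.0, 1.0, True, True),
    ("kde", "fixed_bandwidth"): (0.0, None, True, False),
    ("kde", "grid_spacing"): (0.0, None, True, False),
    ("kde", "occupancy_quantile"): (0.0, 1.0, True, True),
    ("ephys_rule", "delta_rmp_threshold"): (0.0, None, True, False),
    ("ephys_rule", "delta_ri_threshold_pct"): (0.0, None, True, False),
    ("ephys_rule", "pre_window"): (0.0, None, True, False),
    ("ephys_rule", "post_offset"): (0.0, None, False, False),
    ("ephys_rule", "post_window"): (0.0, None, True, False),
    ("cluster", "n_pcs"): (1, None, False, False),
    ("cluster", "knn_k"): (1, None, False, False),
    ("cluster", "min_silhouette"): (-1.0, 1.0, False, False),
}

_CHOICES: dict[tuple[str, str], tuple[str, ...]] = {
    ("segmentation", "threshold_method"): ("otsu", "fixed"),
    ("segmentation", "projection"): ("max", "none"),
    ("classification", "statistic"): ("mean",),
    ("classification", "threshold_rule"):
        ("fixed", "quantile_of_negative_control", "otsu_on_cells"),
    ("kde", "bandwidth_rule"): ("scott", "silverman", "fixed"),
    ("ephys_rule", "combine"): ("and", "or"),
}


def _range_str(lo, hi, lo_open, hi_open) -> str:
    left = "(" if lo_open else "["
    right = ")" if hi_open else "]"
    return f"{left}{'-inf' if lo is None else lo}, {'inf' if hi is None else hi}{right}"


def validate_config(config: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Merge a partial configuration over the defaults and range-check it.

    Returns a fresh, fully populated dict.  Raises :class:`ConfigError`
    naming the offending parameter and its legal range.
    """
    out = copy.deepcopy(DEFAULTS)
    config = config or {}
    for section, values in config.items():
        if section == "seed":
            out["seed"] = int(values)
            continue
        if section not in out:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(values, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in out[section]:
                raise ConfigError(f"unknown parameter {section}.{key}")
            out[section][key] = val

    for (section, key), (lo, hi, lo_open, hi_open) in _RANGES.items():
        val = out[section][key]
        if not np.isscalar(val) or isinstance(val, str) or not np.isfinite(val):
            raise ConfigError(f"{section}.{key} must be a finite number")
        ok = True
        if lo is not None:
            ok &= val > lo if lo_open else val >= lo
        if hi is not None:
            ok &= val < hi if hi_open else val <= hi
        if not ok:
            raise ConfigError(
                f"{section}.{key} = {val} outside legal range "
                f"{_range_str(lo, hi, lo_open, hi_open)}"
            )
    for (section, key), choices in _CHOICES.items():
        if out[section][key] not in choices:
            raise ConfigError(
                f"{section}.{key} = {out[section][key]!r} not one of {choices}"
            )
    grid = list(out["cluster"]["resolution_grid"])
    if not grid or any(r <= 0 for r in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])):
        raise ConfigError(
            "cluster.resolution_grid must be a non-empty increasing positive sequence"
        )
    out["cluster"]["resolution_grid"] = grid
    return out


def dump_config(config: Mapping[str, Any], path: str) -> None:
    """Log the effective configuration of a run (JSON, sorted keys)."""
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
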