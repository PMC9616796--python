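"""Central configuration: package-wide defaults and YAML overrides.

Every tunable constant used by the simulation and analysis modules lives
here so that a single structured config file can override any of them.
Values are documented where the corresponding dataclass is defined
(:mod:`escapenav.arena`, :mod:`escapenav.agents`, ...); this module only
centralizes the raw defaults and the override machinery.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

#: Physical scale of one grid-world cell. The grid is a coarse abstraction
#: of arenas whose two paths total ~16 m, so one cell spans several cm.
CM_PER_CELL: float = 12.0

#: Defaults for the reward function (see arena.RewardParams).
REWARD_DEFAULTS: dict[str, Any] = {
    "goal_reward": 1.0,
    "goal_radius_cells": 3.0,       # strict "<" comparison
    "illegal_penalty": -0.1,
    "novelty_bonus": 1e-8,          # model-free agent class only
    "goal_metric": "euclidean",     # alternative: "chebyshev"
}

#: Defaults for tabular TD learning (see agents.LearningParams).
LEARNING_DEFAULTS: dict[str, Any] = {
    "alpha": 0.3,
    "gamma": 0.95,
    "epsilon": 1.0,
    "epsilon_decay": 0.985,         # multiplicative, applied per episode
}

#: DYNA-Q planning.
PLANNING_SAMPLES: int = 20

#: Influence-Zones / Instantaneous-Topological-Map parameters
#: (see agents.IZParams). Distances are in lattice-cell units.
IZ_DEFAULTS: dict[str, Any] = {
    "td_threshold_one_step": 1e-10,
    "td_threshold_n_step": 0.1,
    "itm_learning_rate": 0.2,
    "itm_max_error": 1.2,
}

#: Free-exploration training protocol.
TRAINING_DEFAULTS: dict[str, Any] = {
    "n_episodes": 250,
    "max_steps": 500,
    "n_reps": 64,
    "smoothing_window": 6,          # rolling-mean window for curves
}

#: Guided-exploration protocol.
GUIDED_DEFAULTS: dict[str, Any] = {
    "n_reps": 10,
    "success_threshold": 8,         # session succeeds if >= 8/10 reps do
}

#: Tracking post-processing (see trajectory module).
TRACKING_DEFAULTS: dict[str, Any] = {
    "median_window": 7,
    "likelihood_threshold": 0.995,
    "snap_radius_cells": 2.0,
    "speed_smoothing_frames": 5,
}

#: Escape-trial classification.
ESCAPE_DEFAULTS: dict[str, Any] = {
    "escape_window_s": 10.0,
    "arm_choice_window_s": 4.0,
    "speed_threshold_cm_s": 35.0,
}

#: Choice-probability inference.
STATS_DEFAULTS: dict[str, Any] = {
    "posterior_convention": "paper",   # or "standard"
    "n_resamples": 100,
    "bin_width_s": 300.0,
    "bin_step_s": 120.0,
    "horizon_s": 3600.0,
    "glm_k_folds": 5,
    "glm_n_repeats": 4,
    "decode_n_splits": 100,
    "decode_test_fraction": 1.0 / 3.0,
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a YAML config file; return an empty override set if ``path`` is None."""
    if path is None:
        return {}
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file must contain a mapping: {path}")
    return data


def merged(defaults: dict[str, Any], overrides: dict[str, Any] | None,
           section: str | None = None) -> dict[str, Any]:
    """Overlay the relevant section of a config dict onto ``defaults``.

    Unknown keys are rejected so typos in config files fail loudly.
    """
    out = dict(defaults)
    if not overrides:
        return out
    src = overrides.get(section, {}) if section else overrides
    for key, val in (src or {}).items():
        if key not in out:
            raise ConfigurationError(
                f"unknown config key {key!r}"
                + (f" in section {section!r}" if section else ""))
        out[key] = val
    return out


def params_from(cls, defaults: dict[str, Any], overrides: dict[str, Any] | None = None,
                section: str | None = None):
    """Instantiate a params dataclass from defaults + config overrides."""
    vals = merged(defaults, overrides, section)
    fields = {f.name for f in dataclasses.fields(cls)}
    return cls(**{k: v for k, v in vals.items() if k in fields})
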