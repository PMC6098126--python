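"""Simulation configuration: dataclass, validation, and YAML round-trip.

Config files are nested key-value YAML with five sections — ``world``,
``topology``, ``agents``, ``interventions``, ``run`` — mapping onto the
flat :class:`SimulationConfig`.  Unknown sections or keys are errors, so a
typo never silently falls back to a default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Any, Dict, Optional

import yaml

__all__ = ["SimulationConfig", "ConfigError", "load_config", "dump_config"]

RANDOM_SPATIAL = "random_spatial"
SCALE_FREE = "scale_free"


class ConfigError(ValueError):
    """Invalid configuration; ``key`` names the offending entry."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


@dataclass
class SimulationConfig:
    """All free parameters of one simulation run.

    Defaults are the baseline study conditions: 1000 agents on the random
    spatial arena with full reach (alpha=1), moderately confirmatory
    pruning (beta=1), no Socratic agents, no broadcasts, horizon 200.
    """

    # world
    mu_true: float = 0.5
    sigma_true: float = 0.25

    # topology
    topology: str = RANDOM_SPATIAL
    alpha: float = 1.0
    gamma: float = 2.5
    n_agents: int = 1000
    sf_dialect: str = "target_exponent"
    grid_side: float = 100.0

    # agents
    beta: Optional[float] = 1.0  # None means the window is unused (stochastic agents)
    socratic_fraction: float = 0.0
    overlap_k: float = 3.0
    n_init_samples: int = 5
    initial_p_h: float = 0.5
    stochastic_beta_mode: str = "ignore"  # or "random": beta ~ U(0.1, 2) each step
    belief_update_mode: str = "memory"  # or "conjugate": precision-weighted Gaussian

    # interventions
    nu: float = 0.0  # broadcast frequency; repeat period round(1/nu) steps
    broadcast_bypasses_filter: bool = True

    # run
    horizon: int = 200
    seed: int = 0
    update_order: str = "async_shuffled"  # or "synchronous"
    track_memory: bool = False
    metrics_every: int = 1
    sigma_floor: float = 1e-6
    extremist_k_sd: float = 2.0
    extremist_sigma_ref: str = "initial_belief_sd"  # or "sigma_true" / "population"

    def validate(self) -> "SimulationConfig":
        c = self
        if c.sigma_true <= 0:
            raise ConfigError("world.sigma_true", f"must be > 0, got {c.sigma_true}")
        if c.topology not in (RANDOM_SPATIAL, SCALE_FREE):
            raise ConfigError("topology.kind", f"unknown topology {c.topology!r}")
        if not (0 < c.alpha <= 1):
            raise ConfigError("topology.alpha", f"must be in (0, 1], got {c.alpha}")
        if c.gamma <= 1:
            raise ConfigError("topology.gamma", f"must be > 1, got {c.gamma}")
        if c.n_agents < 2:
            raise ConfigError("topology.n_agents", f"must be >= 2, got {c.n_agents}")
        if c.sf_dialect not in ("target_exponent", "literal_rule"):
            raise ConfigError("topology.sf_dialect", f"unknown dialect {c.sf_dialect!r}")
        if c.grid_side <= 0:
            raise ConfigError("topology.grid_side", f"must be > 0, got {c.grid_side}")
        if c.beta is not None and c.beta < 0:
            raise ConfigError("agents.beta", f"must be >= 0 or 'unused', got {c.beta}")
        if not (0 <= c.socratic_fraction <= 1):
            raise ConfigError(
                "agents.socratic_fraction", f"must be in [0, 1], got {c.socratic_fraction}"
            )
        if c.overlap_k <= 0:
            raise ConfigError("agents.overlap_k", f"must be > 0, got {c.overlap_k}")
        if c.n_init_samples < 2:
            raise ConfigError(
                "agents.n_init_samples", f"must be >= 2, got {c.n_init_samples}"
            )
        if not (0 <= c.initial_p_h <= 1):
            raise ConfigError(
                "agents.initial_p_h", f"must be in [0, 1], got {c.initial_p_h}"
            )
        if c.stochastic_beta_mode not in ("ignore", "random"):
            raise ConfigError(
                "agents.stochastic_beta_mode",
                f"must be 'ignore' or 'random', got {c.stochastic_beta_mode!r}",
            )
        if c.belief_update_mode not in ("memory", "conjugate"):
            raise ConfigError(
                "agents.belief_update_mode",
                f"must be 'memory' or 'conjugate', got {c.belief_update_mode!r}",
            )
        if c.nu < 0:
            raise ConfigError("interventions.nu", f"must be >= 0, got {c.nu}")
        if c.horizon < 0:
            raise ConfigError("run.horizon", f"must be >= 0, got {c.horizon}")
        if c.update_order not in ("async_shuffled", "synchronous"):
            raise ConfigError(
                "run.update_order",
                f"must be 'async_shuffled' or 'synchronous', got {c.update_order!r}",
            )
        if c.metrics_every < 1:
            raise ConfigError("run.metrics_every", f"must be >= 1, got {c.metrics_every}")
        if c.sigma_floor <= 0:
            raise ConfigError("run.sigma_floor", f"must be > 0, got {c.sigma_floor}")
        if c.extremist_k_sd <= 0:
            raise ConfigError(
                "run.extremist_k_sd", f"must be > 0, got {c.extremist_k_sd}"
            )
        if c.extremist_sigma_ref not in ("initial_belief_sd", "sigma_true", "population"):
            raise ConfigError(
                "run.extremist_sigma_ref",
                f"unknown mode {c.extremist_sigma_ref!r}",
            )
        return self

    @property
    def broadcast_period(self) -> Optional[int]:
        """Repeat period round(1/nu), or None when broadcasts are disabled."""
        if self.nu <= 0:
            return None
        return max(1, round(1.0 / self.nu))

    def with_overrides(self, **kwargs: Any) -> "SimulationConfig":
        return replace(self, **kwargs)


# YAML section -> {yaml key: dataclass field}
_SECTIONS: Dict[str, Dict[str, str]] = {
    "world": {"mu_true": "mu_true", "sigma_true": "sigma_true"},
    "topology": {
        "kind": "topology",
        "alpha": "alpha",
        "gamma": "gamma",
        "n_agents": "n_agents",
        "sf_dialect": "sf_dialect",
        "grid_side": "grid_side",
    },
    "agents": {
        "beta": "beta",
        "socratic_fraction": "socratic_fraction",
        "overlap_k": "overlap_k",
        "n_init_samples": "n_init_samples",
        "initial_p_h": "initial_p_h",
        "stochastic_beta_mode": "stochastic_beta_mode",
        "belief_update_mode": "belief_update_mode",
    },
    "interventions": {"nu": "nu", "broadcast_bypasses_filter": "broadcast_bypasses_filter"},
    "run": {
        "horizon": "horizon",
        "seed": "seed",
        "update_order": "update_order",
        "track_memory": "track_memory",
        "metrics_every": "metrics_every",
        "sigma_floor": "sigma_floor",
        "extremist_k_sd": "extremist_k_sd",
        "extremist_sigma_ref": "extremist_sigma_ref",
    },
}


def config_from_dict(data: Dict[str, Any]) -> SimulationConfig:
    """Build a validated config from a nested section dict; unknown keys error."""
    if not isinstance(data, dict):
        raise ConfigError("<root>", "config must be a mapping of sections")
    kwargs: Dict[str, Any] = {}
    for section, content in data.items():
        if section not in _SECTIONS:
            raise ConfigError(section, "unknown section")
        if content is None:
            continue
        if not isinstance(content, dict):
            raise ConfigError(section, "section must be a mapping")
        keymap = _SECTIONS[section]
        for key, value in content.items():
            if key not in keymap:
                raise ConfigError(f"{section}.{key}", "unknown key")
            if keymap[key] == "beta" and isinstance(value, str):
                if value.lower() != "unused":
                    raise ConfigError(
                        "agents.beta", f"must be a number or 'unused', got {value!r}"
                    )
                value = None
            kwargs[keymap[key]] = value
    return SimulationConfig(**kwargs).validate()


def config_to_dict(config: SimulationConfig) -> Dict[str, Any]:
    out: Dict[str, Any] = {}
    field_names = {f.name for f in fields(SimulationConfig)}
    for section, keymap in _SECTIONS.items():
        out[section] = {}
        for key, fname in keymap.items():
            assert fname in field_names
            value = getattr(config, fname)
            if fname == "beta" and value is None:
                value = "unused"
            out[section][key] = value
    return out


def load_config(path: str) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def dump_config(config: SimulationConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
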