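"""Run configuration: simulation parameters plus analysis constants.

Configs are flat YAML key-value files. Unknown keys and out-of-range values
are rejected with the offending key named; defaults filled in are logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields

import yaml

from .simulator import SimParams

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Simulation parameters plus the analysis constants built on them."""

    sim: SimParams = field(default_factory=SimParams)
    window: float = 500.0               # final-window length (h)
    stability_threshold: float = 3e5    # cells/mL (~95% of K)
    stability_span: float = 100.0       # h
    peak_prominence_frac: float = 0.05  # fraction of K
    peak_min_separation: float = 10.0   # h
    sigma: str = "pairwise"             # evenness-factor variant
    pdi_bin_width: float = 0.1
    idi_bin_width: float = 0.6
    seed: int | None = None

    def validate(self) -> None:
        self.sim.validate()
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.stability_threshold <= 0:
            raise ValueError("stability_threshold must be positive")
        if self.sigma not in ("pairwise", "population"):
            raise ValueError(f"sigma must be pairwise|population, got {self.sigma!r}")
        for name in ("stability_span", "peak_min_separation",
                     "pdi_bin_width", "idi_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "sim"}
        d.update(self.sim.to_dict())
        return d


_SIM_KEYS = {f.name for f in fields(SimParams)}
_TOP_KEYS = {f.name for f in fields(RunConfig)} - {"sim"}


def load_config(path: str | None = None, text: str | None = None) -> RunConfig:
    """Load a RunConfig from a flat YAML file, filling and logging defaults."""
    if text is None:
        if path is None:
            raw = {}
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of key: value pairs")

    sim_kwargs, top_kwargs = {}, {}
    for key, value in raw.items():
        if key in _SIM_KEYS:
            sim_kwargs[key] = value
        elif key in _TOP_KEYS:
            top_kwargs[key] = value
        else:
            raise ValueError(f"unknown config key: {key!r}")

    cfg = RunConfig(sim=SimParams(**sim_kwargs), **top_kwargs)
    cfg.validate()
    for name in sorted(_SIM_KEYS - set(sim_kwargs)):
        logger.debug("config default: %s = %r", name, getattr(cfg.sim, name))
    for name in sorted(_TOP_KEYS - set(top_kwargs)):
        logger.debug("config default: %s = %r", name, getattr(cfg, name))
    return cfg


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
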