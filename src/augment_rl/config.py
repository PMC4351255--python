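"""Plain-text run configuration.

INI-style files with three sections::

    [learning]
    beta = 0.15
    lambda = 0.20
    gamma = 0.90
    epsilon = 0.025
    theta = 2.5

    [architecture]
    n_regular = 3
    n_memory = 4
    n_q = 3
    init_low = -0.25
    init_high = 0.25

    [run]
    task = saccade
    mode = variable
    seed = 1
    n_networks = 10
    max_trials = 25000
    shaping = true

Every key is optional; defaults are the standard parameter set. The tag
persistence alpha is always derived as 1 - lambda * gamma and cannot be
set directly.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .params import LearningParams

_LEARNING_KEYS = {"beta", "lambda", "gamma", "epsilon", "theta"}
_ARCH_KEYS = {"n_regular", "n_memory", "n_q", "init_low", "init_high"}
_RUN_KEYS = {"task", "mode", "seed", "n_networks", "max_trials", "shaping",
             "pro_only"}

_TASKS = {"saccade", "category", "classification", "vibrotactile"}


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values."""


@dataclass
class RunConfig:
    """Everything that determines an experiment run."""

    params: LearningParams = field(default_factory=LearningParams)
    arch_overrides: dict = field(default_factory=dict)
    task: str = "saccade"
    mode: str = "variable"
    seed: int = 0
    n_networks: int = 10
    max_trials: Optional[int] = None
    shaping: bool = True
    pro_only: bool = False

    def __post_init__(self):
        if self.task not in _TASKS:
            raise ConfigError(f"unknown task {self.task!r}")
        if self.mode not in ("variable", "fixed"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.n_networks < 1:
            raise ConfigError("n_networks must be >= 1")


def load_config(path) -> RunConfig:
    """Parse a config file; unknown keys or invalid values fail loudly."""
    cp = configparser.ConfigParser()
    text = Path(path).read_text()
    cp.read_string(text)

    for section in cp.sections():
        if section not in ("learning", "architecture", "run"):
            raise ConfigError(f"unknown section [{section}]")

    learn_kw = {}
    if cp.has_section("learning"):
        for key, val in cp.items("learning"):
            if key not in _LEARNING_KEYS:
                raise ConfigError(f"unknown key {key!r} in [learning]")
            name = "lam" if key == "lambda" else key
            try:
                learn_kw[name] = float(val)
            except ValueError as exc:
                raise ConfigError(f"bad value for {key}: {val!r}") from exc
    try:
        params = LearningParams(**learn_kw)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    arch_overrides = {}
    if cp.has_section("architecture"):
        for key, val in cp.items("architecture"):
            if key not in _ARCH_KEYS:
                raise ConfigError(f"unknown key {key!r} in [architecture]")
            cast = int if key.startswith("n_") else float
            try:
                arch_overrides[key] = cast(val)
            except ValueError as exc:
                raise ConfigError(f"bad value for {key}: {val!r}") from exc

    run_kw = {}
    if cp.has_section("run"):
        sec = cp["run"]
        for key in sec:
            if key not in _RUN_KEYS:
                raise ConfigError(f"unknown key {key!r} in [run]")
        if "task" in sec:
            run_kw["task"] = sec.get("task")
        if "mode" in sec:
            run_kw["mode"] = sec.get("mode")
        for key in ("seed", "n_networks", "max_trials"):
            if key in sec:
                try:
                    run_kw[key] = sec.getint(key)
                except ValueError as exc:
                    raise ConfigError(f"bad value for {key}") from exc
        for key in ("shaping", "pro_only"):
            if key in sec:
                try:
                    run_kw[key] = sec.getboolean(key)
                except ValueError as exc:
                    raise ConfigError(f"bad value for {key}") from exc

    return RunConfig(params=params, arch_overrides=arch_overrides, **run_kw)


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to INI text (round-trips losslessly)."""
    cp = configparser.ConfigParser()
    cp["learning"] = {
        "beta": repr(cfg.params.beta),
        "lambda": repr(cfg.params.lam),
        "gamma": repr(cfg.params.gamma),
        "epsilon": repr(cfg.params.epsilon),
        "theta": repr(cfg.params.theta),
    }
    cp["architecture"] = {k: repr(v) for k, v in cfg.arch_overrides.items()}
    cp["run"] = {
        "task": cfg.task,
        "mode": cfg.mode,
        "seed": repr(cfg.seed),
        "n_networks": repr(cfg.n_networks),
        "shaping": repr(cfg.shaping).lower(),
        "pro_only": repr(cfg.pro_only).lower(),
    }
    if cfg.max_trials is not None:
        cp["run"]["max_trials"] = repr(cfg.max_trials)
    import io as _io

    buf = _io.StringIO()
    cp.write(buf)
    return buf.getvalue()
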