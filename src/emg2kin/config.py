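"""Run configuration and logging for the command-line pipeline.

A single YAML file configures every stage; all defaults equal the nominal
protocol values (100 ms windows, 10 training restarts, 0.3 s dwell, 20 s
timeout, W = 0.08, A in {0.8, 1.2, 1.4}).  Any key can be omitted; CLI
flags override file values.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .autoencoder import TrainConfig
from .fitts import (
    DEFAULT_AMPLITUDES,
    DEFAULT_DISTANCE_SCALE,
    DEFAULT_DWELL,
    DEFAULT_TIMEOUT,
    DEFAULT_WIDTH,
)
from .synthetic import SimulatedUser, SynergyGenerator

__all__ = ["RunConfig", "load_config", "get_logger"]

_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s %(message)s"


def get_logger(name: str = "emg2kin", level: int | str = logging.INFO) -> logging.Logger:
    """Package logger: per-stage timing at INFO, numeric traces at DEBUG."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


@dataclass
class TaskConfig:
    dwell: float = DEFAULT_DWELL
    timeout: float = DEFAULT_TIMEOUT
    width: float = DEFAULT_WIDTH
    a_values: tuple[float, ...] = DEFAULT_AMPLITUDES
    n_targets: int = 20
    distance_scale: float = DEFAULT_DISTANCE_SCALE


@dataclass
class FeatureConfig:
    window_seconds: float = 0.1
    sampling_rate: float = 2048.0


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with protocol defaults."""

    seed: int = 0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    user: SimulatedUser = field(default_factory=SimulatedUser)
    generator: SynergyGenerator = field(default_factory=SynergyGenerator)
    target_range: float = 1.0
    tau_quantile: float = 0.95

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"].pop("mixing", None)  # derived from the seed
        return d


_SECTIONS = {
    "features": FeatureConfig,
    "train": TrainConfig,
    "task": TaskConfig,
    "user": SimulatedUser,
    "generator": SynergyGenerator,
}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Unknown keys are rejected with the offending name so configuration typos
    fail loudly.
    """
    doc: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        doc = loaded
    doc.update(overrides)

    kwargs: dict = {}
    for key, value in doc.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            if not isinstance(value, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            valid = set(cls.__dataclass_fields__)
            bad = set(value) - valid
            if bad:
                raise ValueError(
                    f"unknown key(s) in '{key}': {sorted(bad)}"
                )
            if key == "task" and "a_values" in value:
                value = {**value, "a_values": tuple(value["a_values"])}
            kwargs[key] = cls(**value)
        elif key in ("seed", "target_range", "tau_quantile"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config key: '{key}'")
    cfg = RunConfig(**kwargs)
    # a single top-level seed propagates to stages that did not set their own
    if "seed" in doc:
        if "train" not in doc or "seed" not in doc.get("train", {}):
            cfg.train.seed = cfg.seed
        if "generator" not in doc or "seed" not in doc.get("generator", {}):
            cfg.generator = SynergyGenerator(
                **{**_generator_kwargs(cfg.generator), "seed": cfg.seed}
            )
    return cfg


def _generator_kwargs(gen: SynergyGenerator) -> dict:
    return {
        "n_channels": gen.n_channels,
        "noise_sigma": gen.noise_sigma,
        "crosstalk": gen.crosstalk,
        "rest_level": gen.rest_level,
        "seed": gen.seed,
        "frame_rate": gen.frame_rate,
    }
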