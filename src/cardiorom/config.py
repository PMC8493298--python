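"""Experiment configuration schema, YAML round-trip, and hashing.

A single :class:`ExperimentConfig` document describes one benchmark end to
end: geometry and spline space, fibers and conductivities (with parameter
hooks), ionic model, stimulation protocol, time integration and snapshot
sampling, the parameter-space design, POD compression, and network training.
Configs are validated on construction, serialize losslessly to YAML, and
hash canonically (semantically identical configs hash equal; any field
change changes the hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError

__all__ = [
    "GeometryConfig", "FiberConfig", "ConductivityConfig", "IonicConfig",
    "StimulusConfig", "TimeConfig", "DesignConfig", "PodConfig",
    "TrainingStageConfig", "ExperimentConfig",
    "load_config", "save_config", "config_hash",
]


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GeometryConfig(_Base):
    p: int = Field(ge=1)
    n_el: Tuple[int, int]
    extents: Tuple[Tuple[float, float], Tuple[float, float]]


class FiberConfig(_Base):
    rule: Literal["constant", "laplace_gradient"] = "constant"
    direction: Tuple[float, float] = (1.0, 0.0)
    markers: Tuple[str, str] = ("left", "right")


class ConductivityConfig(_Base):
    sigma_l_i: float = Field(gt=0)
    sigma_t_i: float = Field(gt=0)
    sigma_l_e: float = Field(gt=0)
    sigma_t_e: float = Field(gt=0)
    param_map: dict[str, int] = Field(default_factory=dict)


class IonicConfig(_Base):
    """Either a named preset or a full parameter dictionary."""

    preset: Optional[str] = None
    model_id: Optional[str] = None
    params: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _one_of(self):
        if (self.preset is None) == (self.model_id is None):
            raise ValueError("give exactly one of 'preset' or 'model_id'+'params'")
        return self


class StimulusConfig(_Base):
    amplitude: float
    region: Literal["half_space", "ball"]
    t_start: float = Field(ge=0)
    t_end: float
    x0: Optional[float] = None
    center: Optional[Tuple[float, float]] = None
    radius: Optional[float] = None
    compartment: Literal["intracellular", "extracellular"] = "intracellular"
    center_from_mu: Optional[Tuple[int, int]] = None


class TimeConfig(_Base):
    dt: float = Field(gt=0)
    T: float = Field(gt=0)
    n_t: int = Field(ge=1)
    window: Optional[Tuple[float, float]] = None
    ionic_mode: Literal["svi", "ici"] = "svi"


class DesignConfig(_Base):
    bounds: Tuple[Tuple[float, float], ...]
    n_train: int = Field(ge=2)
    n_test: int = Field(ge=1)
    train_rule: Literal["uniform_grid", "random"] = "uniform_grid"
    test_rule: Literal["midpoints", "random"] = "midpoints"
    train_seed: int = 0
    test_seed: int = 1


class PodConfig(_Base):
    N: int = Field(ge=1)
    oversampling: int = 10
    n_power_iter: int = 2
    seed: int = 0


class TrainingStageConfig(_Base):
    n_epochs: int = 3000
    batch_size: int = 40
    lr: float = 1e-2
    lr_final: Optional[float] = 1e-4
    patience: int = 500
    omega_h: float = Field(default=0.5, ge=0.0, le=1.0)
    val_fraction: float = 0.2
    seed: int = 0
    encoder_widths: Tuple[int, ...] = (64,)
    dfnn_widths: Tuple[int, ...] = (50, 50)
    decoder_widths: Tuple[int, ...] = (64,)
    decoder_fourier_modes: int = 8


class ExperimentConfig(_Base):
    name: str
    geometry: GeometryConfig
    fiber: FiberConfig = FiberConfig()
    conductivity: ConductivityConfig
    ionic: IonicConfig
    stimuli: Tuple[StimulusConfig, ...]
    time: TimeConfig
    design: DesignConfig
    pod: PodConfig
    training: TrainingStageConfig = TrainingStageConfig()
    channels: Tuple[str, ...] = ("u", "ue")
    latent_dim: Optional[int] = None    # default: n_mu + 1

    @model_validator(mode="after")
    def _consistent(self):
        import numpy as np
        side = int(round(np.sqrt(self.pod.N)))
        if side * side != self.pod.N:
            raise ValueError(f"pod.N={self.pod.N} must be a perfect square")
        n_mu = len(self.design.bounds)
        if self.latent_dim is not None and self.latent_dim < n_mu + 1:
            raise ValueError("latent_dim must be at least n_mu + 1")
        for i in self.conductivity.param_map.values():
            if not (0 <= i < n_mu):
                raise ValueError("conductivity param_map index outside mu")
        for s in self.stimuli:
            if s.center_from_mu is not None and any(
                not (0 <= i < n_mu) for i in s.center_from_mu
            ):
                raise ValueError("stimulus center_from_mu index outside mu")
        return self

    @property
    def n_mu(self) -> int:
        return len(self.design.bounds)

    @property
    def n(self) -> int:
        """Latent dimension: configured value or the n_mu + 1 default."""
        return self.latent_dim if self.latent_dim is not None else self.n_mu + 1


def config_hash(cfg: ExperimentConfig) -> str:
    """Canonical SHA-256 of the config (stable across YAML round-trips)."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True))


def load_config(path: str | Path) -> ExperimentConfig:
    try:
        data = yaml.safe_load(Path(path).read_text())
        return ExperimentConfig.model_validate(data)
    except Exception as exc:  # noqa: BLE001 - uniform config error surface
        raise ConfigError(f"invalid experiment config {path}: {exc}") from exc
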