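"""Run configuration and deterministic seeding.

Configurations are YAML documents validated against a strict schema
(unknown keys are rejected and errors name the offending key path). All
randomness flows from a single master seed through named, independent
streams, so that e.g. paired erosion runs can share the synaptic-noise
realization exactly while drawing different patterns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError
from .nonlinearity import Nonlinearity
from .dynamics import SimConfig
from .plasticity import HomeostasisConfig, STDPConfig

STREAM_NAMES = ("init_W", "init_x", "noise", "patterns", "stimulus", "targets")


class PhiConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["tanh", "rectified_linear", "sign", "tanh_gain"] = "tanh"
    gain: float = Field(1.0, gt=0)
    floor: float = -5.0

    def build(self) -> Nonlinearity:
        return Nonlinearity(kind=self.kind, gain=self.gain, floor=self.floor)


class NetworkConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    N: int = Field(128, ge=1)
    dt: float = Field(0.1, gt=0)
    eta: float = Field(0.01, gt=0)
    seed: int = 0
    g: float = Field(1.0, ge=0)
    density: float = Field(1.0, gt=0, le=1)
    phi: PhiConfig = PhiConfig()

    def build(self) -> SimConfig:
        return SimConfig(N=self.N, dt=self.dt, eta=self.eta, seed=self.seed,
                         phi=self.phi.build())


class STDPSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    a_P: float = Field(1.0, gt=0)
    a_D: float = Field(-1.0, lt=0)
    tau_P: float = Field(50.0, gt=0)
    tau_D: float = Field(50.0, gt=0)

    def build(self) -> STDPConfig:
        return STDPConfig(a_P=self.a_P, a_D=self.a_D, tau_P=self.tau_P,
                          tau_D=self.tau_D)


class PlasticityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rule: Literal["dissipation", "rate_control", "decorrelation", "none"] = "decorrelation"
    beta: float = Field(0.1, gt=0)
    noise_on: bool = True
    noise_variance: Optional[float] = Field(None, gt=0)
    noise_convention: Literal["per_step", "sqrt_dt"] = "per_step"
    tau_x: float = Field(20.0, gt=0)
    stdp: STDPSection = STDPSection()

    def build(self, phi0: Optional[np.ndarray] = None) -> HomeostasisConfig:
        return HomeostasisConfig(
            rule=self.rule, beta=self.beta, phi0=phi0, noise_on=self.noise_on,
            noise_variance=self.noise_variance,
            noise_convention=self.noise_convention, tau_x=self.tau_x,
        )


class ProtocolEvent(BaseModel):
    model_config = ConfigDict(extra="forbid")
    type: Literal["stimulus", "cue"]
    item_index: int = Field(0, ge=0)
    t_on: float
    t_off: float
    amplitude: float = 10.0


class OutputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dir: str = "runs"
    formats: List[Literal["hdf5", "csv", "json"]] = ["hdf5", "json"]
    snapshot_every: float = Field(10.0, gt=0)


class RunConfig(BaseModel):
    """Fully validated run configuration (defaults follow the published
    simulation parameters: N=128, dt=0.1, eta=0.01, tau=50, tau_x=20,
    beta=0.1, targets ~ U[-1, 1])."""

    model_config = ConfigDict(extra="forbid")
    network: NetworkConfig = NetworkConfig()
    plasticity: PlasticityConfig = PlasticityConfig()
    protocol: List[ProtocolEvent] = []
    output: OutputConfig = OutputConfig()
    seed: int = 0


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config; an empty file yields defaults."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigurationError(f"cannot parse {path}: {e}") from e
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in e.errors()
        )
        raise ConfigurationError(f"invalid config {path}: {locs}") from e


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def seed_streams(master_seed: int) -> Dict[str, np.random.Generator]:
    """Named independent random streams derived from one master seed.

    Streams are spawned in a fixed order, so consuming from one stream
    never changes the draws of another; paired experiments reuse the
    `noise` stream exactly while varying `patterns` or `stimulus`.
    """
    children = np.random.SeedSequence(master_seed).spawn(len(STREAM_NAMES))
    return {name: np.random.default_rng(ss) for name, ss in zip(STREAM_NAMES, children)}
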