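"""Neural state dynamics.

The network state x (synaptic input of each of N neurons) evolves as

    dx/dt = -x + W phi(x) + b(t)

integrated with explicit Euler at step dt (default 0.1, in units of the
neural time constant). W is the recurrent connectivity, b an external
input. Time is dimensionless throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .errors import ConfigurationError, IntegrationBlowupError
from .nonlinearity import Nonlinearity, apply_phi

InputFn = Optional[Callable[[float], np.ndarray]]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    N: number of neurons. dt: Euler step. eta: plasticity rate (weights
    evolve slower than activity by this factor). seed: master seed.
    phi: the rate nonlinearity.
    """

    N: int = 128
    dt: float = 0.1
    eta: float = 0.01
    seed: int = 0
    phi: Nonlinearity = field(default_factory=Nonlinearity)

    def __post_init__(self):
        if self.N < 1:
            raise ConfigurationError("network.N must be a positive integer")
        if not self.dt > 0:
            raise ConfigurationError("network.dt must be > 0")
        if not self.eta > 0:
            raise ConfigurationError("network.eta must be > 0")


@dataclass
class NetworkState:
    """Activity vector x at simulation time t."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1:
            raise ConfigurationError("state x must be a 1-D vector")


def _as_matrix(W) -> np.ndarray:
    # Accept a Connectivity or a bare ndarray.
    return np.asarray(getattr(W, "W", W), dtype=float)


def step_activity(
    state: NetworkState, W, b: Optional[np.ndarray], cfg: SimConfig
) -> NetworkState:
    """One explicit Euler step: x <- x + dt * (-x + W phi(x) + b)."""
    Wm = _as_matrix(W)
    x = state.x
    drive = Wm @ apply_phi(x, cfg.phi)
    if b is not None:
        drive = drive + b
    x_new = x + cfg.dt * (-x + drive)
    if not np.all(np.isfinite(x_new)):
        raise IntegrationBlowupError(
            f"activity became non-finite at t={state.t + cfg.dt:.3f}", state.t + cfg.dt
        )
    return NetworkState(x=x_new, t=state.t + cfg.dt)


@dataclass
class Trajectory:
    """Recorded activity time series: times (T,) and xs (T, N)."""

    times: np.ndarray
    xs: np.ndarray

    def project(self, u: np.ndarray, v: np.ndarray):
        """Overlaps p_u(t), p_v(t) with a plane, scaled by 1/sqrt(N)."""
        n = self.xs.shape[1]
        return self.xs @ u / np.sqrt(n), self.xs @ v / np.sqrt(n)


def run_trajectory(
    x0: np.ndarray,
    W,
    input_fn: InputFn,
    duration: float,
    cfg: SimConfig,
    record_every: int = 1,
) -> Trajectory:
    """Integrate for `duration` and record every `record_every` steps.

    The recording excludes the initial condition: after `duration` with
    record_every=1 there are round(duration/dt) recorded states.
    Deterministic given x0, W and input_fn.
    """
    if not duration > 0:
        raise ConfigurationError("duration must be > 0")
    if record_every < 1:
        raise ConfigurationError("record_every must be >= 1")
    state = NetworkState(x=np.array(x0, dtype=float), t=0.0)
    n_steps = int(round(duration / cfg.dt))
    times, xs = [], []
    for k in range(n_steps):
        b = input_fn(state.t) if input_fn is not None else None
        state = step_activity(state, W, b, cfg)
        if (k + 1) % record_every == 0:
            times.append(state.t)
            xs.append(state.x.copy())
    return Trajectory(times=np.asarray(times), xs=np.asarray(xs))


def default_initial_state(cfg: SimConfig, rng: np.random.Generator) -> NetworkState:
    """Small random state ~ Normal(0, 1/N): breaks symmetry without
    biasing any memory plane."""
    return NetworkState(x=rng.normal(0.0, 1.0 / np.sqrt(cfg.N), cfg.N), t=0.0)


def with_phi(cfg: SimConfig, phi: Nonlinearity) -> SimConfig:
    return replace(cfg, phi=phi)
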