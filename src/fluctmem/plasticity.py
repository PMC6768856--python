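"""Synaptic plasticity: learning and fluctuation terms.

Weights evolve as  dW/dt = eta * (Delta_L + Delta_F)  where Delta_L is the
rate-based STDP learning operator and Delta_F collects activity-independent
noise plus one of three homeostatic rules:

* dissipation:     Delta_F = xi - beta W
* rate control:    Delta_F = xi + [(phi0 - phi(x)) phi(x)^T] o W   (o = Hadamard)
* decorrelation:   Delta_F = xi + I - phi_post(x) phi_pre(x)^T

with xi_ij ~ Normal(0, 1/N) drawn freshly every weight step, independent
across synapses and time. The decorrelation rule uses phi_pre = phi(x) and
phi_post = phi(x - xbar), where xbar is a slow (tau_x = 20) average of x,
so it senses fluctuations of activity rather than its level.

The STDP operator derives from an exponential spike-timing kernel with
amplitudes a_P > 0 (potentiation) and a_D < 0 (depression) and timescales
tau_P, tau_D; in the rate picture the kernel becomes first-order low-pass
filters y_P, y_D of the rate vector phi(x):

    Delta_L = a_P phi y_P^T + a_D y_D phi^T

For tau_P = tau_D and a_D = -a_P this is purely anti-symmetric,
a_P (phi y^T - y phi^T), and can only write to the anti-symmetric
(imaginary-coded) component of W.

The plasticity rate eta multiplies the sum once, in step_weights, never
inside the individual terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError, IntegrationBlowupError
from .nonlinearity import Nonlinearity, apply_phi

_RULES = ("dissipation", "rate_control", "decorrelation", "none")
_NOISE_CONVENTIONS = ("per_step", "sqrt_dt")


@dataclass
class Connectivity:
    """N x N weight matrix; row i collects inputs to neuron i.

    An optional binary mask imposes structural sparsity: masked-out
    synapses are zero and stay zero under every update. No constraint is
    placed on the diagonal.
    """

    W: np.ndarray
    mask: Optional[np.ndarray] = None
    density: float = 1.0

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ConfigurationError("connectivity W must be square")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=float)
            if self.mask.shape != self.W.shape:
                raise ConfigurationError("mask shape must match W")
            self.W = self.W * self.mask

    @property
    def N(self) -> int:
        return self.W.shape[0]


def random_connectivity(
    rng: np.random.Generator, N: int, g: float = 1.0, density: float = 1.0
) -> Connectivity:
    """W_ij ~ Normal(0, g^2/N), optionally with a random binary mask."""
    W = rng.normal(0.0, g / np.sqrt(N), (N, N)) if g > 0 else np.zeros((N, N))
    mask = None
    if density < 1.0:
        mask = (rng.random((N, N)) < density).astype(float)
    return Connectivity(W=W, mask=mask, density=density)


@dataclass(frozen=True)
class STDPConfig:
    """Kernel parameters. Anti-symmetric iff tau_P == tau_D and a_D == -a_P."""

    a_P: float = 1.0
    a_D: float = -1.0
    tau_P: float = 50.0
    tau_D: float = 50.0

    def __post_init__(self):
        if not self.a_P > 0:
            raise ConfigurationError("stdp.a_P must be > 0")
        if not self.a_D < 0:
            raise ConfigurationError("stdp.a_D must be < 0")
        if not (self.tau_P > 0 and self.tau_D > 0):
            raise ConfigurationError("stdp timescales must be > 0")

    @property
    def is_antisymmetric(self) -> bool:
        return self.tau_P == self.tau_D and self.a_D == -self.a_P


@dataclass
class PlasticityState:
    """Low-pass traces: y_P, y_D of phi(x) and xbar of x (tau_x = 20)."""

    yP: np.ndarray
    yD: np.ndarray
    xbar: np.ndarray

    @classmethod
    def zeros(cls, N: int) -> "PlasticityState":
        return cls(yP=np.zeros(N), yD=np.zeros(N), xbar=np.zeros(N))


@dataclass(frozen=True)
class HomeostasisConfig:
    """Fluctuation-term configuration.

    rule: which homeostatic mechanism accompanies the noise.
    beta: dissipation rate. phi0: target rates (drawn U[-1, 1] once per
    run if None). noise_on / noise_variance: the white synaptic noise.
    noise_convention: 'per_step' includes the Normal(0, 1/N) draw in
    Delta_F like any other term (the published numerics); 'sqrt_dt'
    scales it by 1/sqrt(eta dt) so its integrated variance is
    discretization-independent (diffusion convention).
    """

    rule: str = "decorrelation"
    beta: float = 0.1
    phi0: Optional[np.ndarray] = None
    noise_on: bool = True
    noise_variance: Optional[float] = None  # default 1/N
    noise_convention: str = "per_step"
    tau_x: float = 20.0

    def __post_init__(self):
        if self.rule not in _RULES:
            raise ConfigurationError(
                f"plasticity.rule {self.rule!r} not in {_RULES}"
            )
        if self.noise_convention not in _NOISE_CONVENTIONS:
            raise ConfigurationError(
                f"plasticity.noise_convention {self.noise_convention!r} "
                f"not in {_NOISE_CONVENTIONS}"
            )
        if not self.beta > 0:
            raise ConfigurationError("plasticity.beta must be > 0")


def update_filters(
    ps: PlasticityState,
    x: np.ndarray,
    phi: Nonlinearity,
    stdp: STDPConfig,
    dt: float,
    tau_x: float = 20.0,
) -> PlasticityState:
    """Euler update of the first-order filters.

    y <- y + dt (phi(x) - y)/tau for each STDP trace, and analogously for
    xbar with its own timescale. At constant input each filter relaxes to
    its driving signal.
    """
    f = apply_phi(x, phi)
    yP = ps.yP + dt * (f - ps.yP) / stdp.tau_P
    yD = ps.yD + dt * (f - ps.yD) / stdp.tau_D
    xbar = ps.xbar + dt * (x - ps.xbar) / tau_x
    return PlasticityState(yP=yP, yD=yD, xbar=xbar)


def noise_term(
    rng: np.random.Generator,
    N: int,
    mask: Optional[np.ndarray] = None,
    variance: Optional[float] = None,
) -> np.ndarray:
    """Fresh i.i.d. synaptic noise, xi_ij ~ Normal(0, 1/N) by default."""
    var = 1.0 / N if variance is None else variance
    xi = rng.normal(0.0, np.sqrt(var), (N, N))
    if mask is not None:
        xi = xi * mask
    return xi


def dissipation_term(W: np.ndarray, beta: float) -> np.ndarray:
    """-beta W: every weight decays toward zero at rate beta."""
    return -beta * np.asarray(W, dtype=float)


def rate_control_term(
    x: np.ndarray, W: np.ndarray, phi0: np.ndarray, phi: Nonlinearity
) -> np.ndarray:
    """Multiplicative rate homeostasis: entry (i, j) is
    (phi0_i - phi(x_i)) * phi(x_j) * W_ij."""
    f = apply_phi(x, phi)
    return ((phi0 - f)[:, None] * f[None, :]) * np.asarray(W, dtype=float)


def decorrelation_term(
    x: np.ndarray, xbar: np.ndarray, phi: Nonlinearity
) -> np.ndarray:
    """Anti-Hebbian decorrelation: I - phi_post(x) phi_pre(x)^T with
    phi_pre = phi(x) and phi_post = phi(x - xbar)."""
    pre = apply_phi(x, phi)
    post = apply_phi(x - xbar, phi)
    return np.eye(len(x)) - np.outer(post, pre)


def stdp_term(
    phi_x: np.ndarray, ps: PlasticityState, cfg: STDPConfig
) -> np.ndarray:
    """Rate-based STDP operator a_P phi y_P^T + a_D y_D phi^T.

    Potentiation strengthens W_ij when presynaptic activity (trace y_P of
    neuron j) precedes postsynaptic firing phi_i; depression (a_D < 0)
    weakens the reverse ordering. In the anti-symmetric special case this
    equals a_P (phi y^T - y phi^T).
    """
    return cfg.a_P * np.outer(phi_x, ps.yP) + cfg.a_D * np.outer(ps.yD, phi_x)


def homeostatic_term(
    x: np.ndarray,
    W: np.ndarray,
    ps: PlasticityState,
    cfg: HomeostasisConfig,
    phi: Nonlinearity,
) -> np.ndarray:
    """The deterministic part of Delta_F for the configured rule."""
    if cfg.rule == "dissipation":
        return dissipation_term(W, cfg.beta)
    if cfg.rule == "rate_control":
        if cfg.phi0 is None:
            raise ConfigurationError("rate_control requires target rates phi0")
        return rate_control_term(x, W, cfg.phi0, phi)
    if cfg.rule == "decorrelation":
        return decorrelation_term(x, ps.xbar, phi)
    return np.zeros_like(np.asarray(W, dtype=float))


def fluctuation_term(
    x: np.ndarray,
    W: np.ndarray,
    ps: PlasticityState,
    cfg: HomeostasisConfig,
    phi: Nonlinearity,
    rng: Optional[np.random.Generator],
    dt: float,
    eta: float,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Delta_F = homeostatic term + (optional) fresh synaptic noise."""
    dF = homeostatic_term(x, W, ps, cfg, phi)
    if cfg.noise_on:
        if rng is None:
            raise ConfigurationError("noise_on requires a noise rng stream")
        xi = noise_term(rng, len(x), mask=mask, variance=cfg.noise_variance)
        if cfg.noise_convention == "sqrt_dt":
            xi = xi / np.sqrt(dt * eta)
        dF = dF + xi
    if mask is not None:
        dF = dF * mask
    return dF


def step_weights(
    W: np.ndarray,
    delta_L: Optional[np.ndarray],
    delta_F: Optional[np.ndarray],
    eta: float,
    dt: float,
    mask: Optional[np.ndarray] = None,
    t: float = float("nan"),
) -> np.ndarray:
    """W <- W + dt * eta * (Delta_L + Delta_F); masked entries stay zero."""
    W = np.asarray(W, dtype=float)
    total = np.zeros_like(W)
    if delta_L is not None:
        total = total + delta_L
    if delta_F is not None:
        total = total + delta_F
    if mask is not None:
        total = total * mask
    W_new = W + dt * eta * total
    if not np.all(np.isfinite(W_new)):
        raise IntegrationBlowupError(f"weights became non-finite at t={t}", t)
    return W_new
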