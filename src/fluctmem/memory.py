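"""Memory patterns, embeddings, stimuli and retrieval cues.

A memory item is a pair of random directions (u, v) in activity space,
entries ~ Normal(0, 1/N). A *real-coded* memory is the symmetric rank-1
perturbation u u^T (a real outlier eigenvalue, fixed-point attractor); an
*imaginary-coded* memory is rho (u v^T - v u^T), an anti-symmetric rank-2
perturbation whose conjugate eigenvalue pair +-i rho supports a limit
cycle on the plane span{u, v}. A symmetric in-plane term
gamma (u u^T + v v^T) with gamma > 1 is required for the limit cycle to
persist in continuous time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .errors import ConfigurationError


@dataclass
class MemoryItem:
    u: np.ndarray
    v: np.ndarray
    rho: float = 1.0
    gamma: float = 0.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 1:
            raise ConfigurationError("u and v must be 1-D vectors of equal length")


def sample_memory(
    rng: np.random.Generator,
    N: int,
    rho: float = 1.0,
    gamma: float = 0.0,
    orthonormalize: bool = False,
) -> MemoryItem:
    """Draw u, v with independent Normal(0, 1/N) entries.

    With `orthonormalize` the pair is Gram-Schmidt orthonormalized, which
    makes the embedded spectrum exactly {gamma +- i rho} (used by the
    analytic spectrum tests); simulations use the raw Gaussian pair.
    """
    if N < 2:
        raise ConfigurationError("N must be >= 2")
    u = rng.normal(0.0, 1.0 / np.sqrt(N), N)
    v = rng.normal(0.0, 1.0 / np.sqrt(N), N)
    if orthonormalize:
        u = u / np.linalg.norm(u)
        v = v - u * (u @ v)
        v = v / np.linalg.norm(v)
    return MemoryItem(u=u, v=v, rho=rho, gamma=gamma)


def embed_real(W: np.ndarray, u: np.ndarray) -> np.ndarray:
    """W + u u^T: a symmetric perturbation adding a real outlier."""
    return np.asarray(W, dtype=float) + np.outer(u, u)


def embed_imaginary(W: np.ndarray, item: MemoryItem) -> np.ndarray:
    """W + rho (u v^T - v u^T) + gamma (u u^T + v v^T)."""
    u, v = item.u, item.v
    dW = item.rho * (np.outer(u, v) - np.outer(v, u))
    if item.gamma != 0.0:
        dW = dW + item.gamma * (np.outer(u, u) + np.outer(v, v))
    return np.asarray(W, dtype=float) + dW


@dataclass
class MemoryBank:
    """A set of M planar memories with interleaved pattern matrix U and
    block-diagonal rotation matrix D (blocks [[0, rho_k], [-rho_k, 0]])."""

    items: List[MemoryItem]

    def __post_init__(self):
        if not self.items:
            raise ConfigurationError("memory bank must hold at least one item")
        n = len(self.items[0].u)
        if len(self.items) > n // 2:
            raise ConfigurationError("bank size M must satisfy M <= N/2")

    @property
    def M(self) -> int:
        return len(self.items)

    @property
    def U(self) -> np.ndarray:
        cols = []
        for it in self.items:
            cols.append(it.u)
            cols.append(it.v)
        return np.column_stack(cols)

    @property
    def D(self) -> np.ndarray:
        M = self.M
        D = np.zeros((2 * M, 2 * M))
        for k, it in enumerate(self.items):
            D[2 * k, 2 * k + 1] = it.rho
            D[2 * k + 1, 2 * k] = -it.rho
        return D


def sample_bank(
    rng: np.random.Generator,
    N: int,
    M: int,
    rho: float = 1.0,
    gamma: float = 0.0,
    orthonormalize: bool = False,
) -> MemoryBank:
    items = [
        sample_memory(rng, N, rho=rho, gamma=gamma, orthonormalize=orthonormalize)
        for _ in range(M)
    ]
    if orthonormalize and M > 1:
        # full Gram-Schmidt across all 2M columns for exact block spectra
        cols = []
        for it in items:
            cols.extend([it.u, it.v])
        Q, _ = np.linalg.qr(np.column_stack(cols))
        for k, it in enumerate(items):
            it.u = Q[:, 2 * k]
            it.v = Q[:, 2 * k + 1]
    return MemoryBank(items=items)


def build_bank_connectivity(bank: MemoryBank, gamma: Optional[float] = None) -> np.ndarray:
    """U D U^T, plus gamma * sum_k (u_k u_k^T + v_k v_k^T) if gamma given.

    For exactly orthogonal patterns this equals the sum of per-item
    imaginary embeddings.
    """
    U, D = bank.U, bank.D
    W = U @ D @ U.T
    if gamma is None:
        gammas = [it.gamma for it in bank.items]
    else:
        gammas = [gamma] * bank.M
    for g, it in zip(gammas, bank.items):
        if g != 0.0:
            W = W + g * (np.outer(it.u, it.u) + np.outer(it.v, it.v))
    return W


@dataclass
class StimulusSpec:
    """Planar Ornstein-Uhlenbeck drive b(t) = amplitude * (c_u(t) u + c_v(t) v)
    on [t_on, t_off); c_u, c_v are independent unit-variance OU processes
    with timescale `ou_timescale` (default 0.01, far below dt, so the
    drive is effectively white across integration steps)."""

    item: MemoryItem
    t_on: float
    t_off: float
    ou_timescale: float = 0.01
    amplitude: float = 10.0

    def __post_init__(self):
        if not self.t_off > self.t_on:
            raise ConfigurationError("stimulus requires t_off > t_on")
        if not self.ou_timescale > 0:
            raise ConfigurationError("ou_timescale must be > 0")


def ou_stimulus(
    spec: StimulusSpec, rng: np.random.Generator, dt: float
) -> Callable[[float], np.ndarray]:
    """Precompute the OU coefficient paths on the dt grid and return
    b(t); zero outside the window.

    Uses the exact OU discretization
        c <- c e^{-dt/tau} + sqrt(1 - e^{-2 dt/tau}) * Normal(0, 1),
    so the stationary variance is 1 for any dt/tau ratio.
    """
    n = int(np.ceil((spec.t_off - spec.t_on) / dt)) + 1
    a = np.exp(-dt / spec.ou_timescale)
    s = np.sqrt(1.0 - a * a)
    cu = np.empty(n)
    cv = np.empty(n)
    cu[0] = rng.normal()
    cv[0] = rng.normal()
    for k in range(1, n):
        cu[k] = cu[k - 1] * a + s * rng.normal()
        cv[k] = cv[k - 1] * a + s * rng.normal()
    u, v = spec.item.u, spec.item.v
    N = len(u)

    def b(t: float) -> np.ndarray:
        if spec.t_on <= t < spec.t_off:
            k = min(int(round((t - spec.t_on) / dt)), n - 1)
            return spec.amplitude * (cu[k] * u + cv[k] * v)
        return np.zeros(N)

    return b


@dataclass
class CueSpec:
    """Brief retrieval pulse along u: b(t) = amplitude * u for
    t in [t_cue, t_cue + duration); default amplitude 10 for 2 neural
    time constants, the associative recall cue."""

    item: MemoryItem
    t_cue: float
    duration: float = 2.0
    amplitude: float = 10.0

    def __post_init__(self):
        if not self.duration > 0:
            raise ConfigurationError("cue duration must be > 0")


def retrieval_cue(spec: CueSpec) -> Callable[[float], np.ndarray]:
    u = spec.item.u
    N = len(u)

    def b(t: float) -> np.ndarray:
        if spec.t_cue <= t < spec.t_cue + spec.duration:
            return spec.amplitude * u
        return np.zeros(N)

    return b
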