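"""Low-dimensional and baseline models used as independent oracles.

* A 2-D reduction of the single-memory limit cycle for a step-like
  nonlinearity, in the planar overlap coordinates (p_u, p_v):

      dp_u/dt = -p_u + rho q_v (+ gamma q_u)
      dp_v/dt = -p_v - rho q_u (+ gamma q_v)

  with q_v = arctan(p_v / |p_u|) and, by symmetric completion,
  q_u = arctan(p_u / |p_v|) (the completion takes the signed limits
  +-pi/2 on the axes). An exact mean-field alternative for Gaussian
  patterns and a hard sign nonlinearity, q = sqrt(2/pi) p / r, is also
  provided as a cross-check; the arctan form overestimates the in-plane
  drive and yields systematically larger orbits.

* Synchronous discrete-time dynamics x' = phi(W x) used for capacity
  runs (the continuous-time model with gamma = 0 has a globally stable
  origin; the discrete map sustains the orbit).

* The classic symmetric Hopfield model as the capacity baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .nonlinearity import Nonlinearity, SIGN, apply_phi
from .memory import MemoryItem, sample_memory, embed_imaginary

_Q_FORMS = ("arctan", "gaussian")


@dataclass
class ReducedState:
    p_u: float
    p_v: float
    rho: float
    gamma: float = 0.0


def _q_pair(p_u: float, p_v: float, form: str) -> Tuple[float, float]:
    if p_u == 0.0 and p_v == 0.0:
        return 0.0, 0.0
    if form == "arctan":
        # arctan2(y, |x|) == arctan(y/|x|) with the signed +-pi/2 limits
        return np.arctan2(p_u, abs(p_v)), np.arctan2(p_v, abs(p_u))
    if form == "gaussian":
        r = np.hypot(p_u, p_v)
        c = np.sqrt(2.0 / np.pi)
        return c * p_u / r, c * p_v / r
    raise ConfigurationError(f"unknown reduced q form {form!r}")


def reduced_step(s: ReducedState, dt: float, q_form: str = "arctan") -> ReducedState:
    """One Euler step of the reduced planar system."""
    if not dt > 0:
        raise ConfigurationError("dt must be > 0")
    q_u, q_v = _q_pair(s.p_u, s.p_v, q_form)
    dp_u = -s.p_u + s.rho * q_v + s.gamma * q_u
    dp_v = -s.p_v - s.rho * q_u + s.gamma * q_v
    return ReducedState(
        p_u=s.p_u + dt * dp_u, p_v=s.p_v + dt * dp_v, rho=s.rho, gamma=s.gamma
    )


def reduced_trajectory(
    s0: ReducedState, duration: float, dt: float, q_form: str = "arctan"
) -> np.ndarray:
    """Integrate and return the (T, 2) array of (p_u, p_v)."""
    steps = int(round(duration / dt))
    out = np.empty((steps, 2))
    s = s0
    for k in range(steps):
        s = reduced_step(s, dt, q_form)
        out[k] = (s.p_u, s.p_v)
    return out

def reduced_orbit_amplitude(
    rho: float,
    gamma: float = 0.0,
    dt: float = 0.1,
    duration: float = 200.0,
    tail: float = 50.0,
    p0: Tuple[float, float] = (0.1, 0.0),
    q_form: str = "arctan",
) -> float:
    """Mean radius over the trailing `tail` time units (the settled orbit)."""
    traj = reduced_trajectory(ReducedState(*p0, rho=rho, gamma=gamma), duration, dt, q_form)
    n_tail = int(round(tail / dt))
    r = np.hypot(traj[-n_tail:, 0], traj[-n_tail:, 1])
    return float(r.mean())


@dataclass
class DiscreteNet:
    """Synchronous discrete-time network x' = phi(W x)."""

    W: np.ndarray
    phi: Nonlinearity = field(default_factory=lambda: SIGN)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)


def discrete_step(net: DiscreteNet, x: np.ndarray) -> np.ndarray:
    return apply_phi(net.W @ np.asarray(x, dtype=float), net.phi)


def full_orbit_amplitude(
    item: MemoryItem,
    N: int,
    phi: Nonlinearity,
    dt: float = 0.1,
    duration: float = 200.0,
    tail: float = 50.0,
    x0_scale: float = 0.5,
) -> Tuple[float, bool]:
    """Orbit radius of the full Euler-integrated model with
    W = rho (u v^T - v u^T) + gamma (u u^T + v v^T).

    Returns (mean tail radius in (p_u, p_v), collapsed_to_origin flag).
    The collapse flag marks the gamma = 0 continuous-time behavior where
    the origin is globally attracting and no orbit survives.
    """
    W = embed_imaginary(np.zeros((N, N)), item)
    x = x0_scale * np.sqrt(N) * item.u
    steps = int(round(duration / dt))
    n_tail = int(round(tail / dt))
    rs = []
    sqN = np.sqrt(N)
    for k in range(steps):
        x = x + dt * (-x + W @ apply_phi(x, phi))
        if k >= steps - n_tail:
            rs.append(np.hypot(item.u @ x, item.v @ x) / sqN)
    amp = float(np.mean(rs))
    return amp, amp < 1e-3


@dataclass
class ReducedVsFullReport:
    amplitude_full: float
    amplitude_reduced: float
    relative_difference: float
    full_collapsed: bool


def reduced_vs_full(
    item: MemoryItem,
    rho: float,
    N: int,
    phi: Optional[Nonlinearity] = None,
    gamma: float = 0.0,
    dt: float = 0.1,
    duration: float = 200.0,
    discrete_time: bool = False,
    q_form: str = "arctan",
    rng: Optional[np.random.Generator] = None,
) -> ReducedVsFullReport:
    """Compare the reduced planar orbit with the full steep-nonlinearity
    model at matched rho, gamma and dt.

    With `discrete_time` the full model is the synchronous map
    x' = phi(W x) (whose orbit radius is rho-independent for a sign
    nonlinearity); otherwise the Euler-integrated continuous model.
    """
    phi = phi or SIGN
    item = MemoryItem(u=item.u, v=item.v, rho=rho, gamma=gamma)
    if discrete_time:
        W = embed_imaginary(np.zeros((N, N)), item)
        net = DiscreteNet(W=W, phi=phi)
        x = np.sqrt(N) * item.u
        if rng is not None:
            x = x + 0.1 * rng.normal(size=N)
        rs = []
        steps = int(round(duration))
        for k in range(steps):
            x = discrete_step(net, x)
            if k >= steps - min(50, steps // 2):
                rs.append(np.hypot(item.u @ x, item.v @ x) / np.sqrt(N))
        amp_full, collapsed = float(np.mean(rs)), float(np.mean(rs)) < 1e-3
    else:
        amp_full, collapsed = full_orbit_amplitude(
            item, N, phi, dt=dt, duration=duration
        )
    amp_red = reduced_orbit_amplitude(rho, gamma=gamma, dt=dt, duration=duration,
                                      q_form=q_form)
    rel = abs(amp_full - amp_red) / amp_full if amp_full > 0 else float("inf")
    return ReducedVsFullReport(
        amplitude_full=amp_full,
        amplitude_reduced=amp_red,
        relative_difference=float(rel),
        full_collapsed=collapsed,
    )


# ---------------------------------------------------------------------------
# capacity models


def binary_planar_patterns(
    rng: np.random.Generator, N: int, M: int
) -> Tuple[np.ndarray, np.ndarray]:
    """M pairs (u_k, v_k) with +-1/sqrt(N) entries: the discrete
    anti-symmetric model then restores exact patterns at the four phases
    of each cycle, the analogue of Hopfield error correction."""
    us = rng.choice([-1.0, 1.0], (M, N)) / np.sqrt(N)
    vs = rng.choice([-1.0, 1.0], (M, N)) / np.sqrt(N)
    return us, vs


def antisymmetric_net(us: np.ndarray, vs: np.ndarray) -> DiscreteNet:
    """W = sum_k (u_k v_k^T - v_k u_k^T); gamma = 0 (stable in discrete time)."""
    W = us.T @ vs - vs.T @ us
    return DiscreteNet(W=W, phi=SIGN)


def hopfield_baseline(
    N: int, M: int, rng: np.random.Generator
) -> Tuple[DiscreteNet, np.ndarray]:
    """W = (1/N) sum_k xi_k xi_k^T with +-1 patterns and zero diagonal."""
    if M < 1:
        raise ConfigurationError("M must be >= 1")
    xi = rng.choice([-1.0, 1.0], (M, N))
    W = (xi.T @ xi) / N
    np.fill_diagonal(W, 0.0)
    return DiscreteNet(W=W, phi=SIGN), xi


def _retrieval_overlap_antisym(
    rng: np.random.Generator, N: int, M: int, steps: int, avg: int
) -> float:
    us, vs = binary_planar_patterns(rng, N, M)
    net = antisymmetric_net(us, vs)
    x = np.sqrt(N) * us[0] + 0.1 * rng.normal(size=N)
    acc = []
    for s in range(steps):
        x = discrete_step(net, x)
        x[x == 0] = 1.0  # break sign ties so no unit goes silent
        if s >= steps - avg:
            acc.append(np.hypot(us[0] @ x, vs[0] @ x) / np.sqrt(N))
    return float(np.mean(acc))


def _retrieval_overlap_hopfield(
    rng: np.random.Generator, N: int, M: int, steps: int, avg: int
) -> float:
    net, xi = hopfield_baseline(N, M, rng)
    x = np.sign(xi[0] + 0.1 * rng.normal(size=N))
    acc = []
    for s in range(steps):
        x = discrete_step(net, x)
        x[x == 0] = 1.0
        if s >= steps - avg:
            acc.append(abs(xi[0] @ x) / N)
    return float(np.mean(acc))


def capacity_curve(
    model: str,
    N: int,
    loads: Sequence[float],
    trials: int = 10,
    seed: int = 0,
    steps: int = 60,
    avg: int = 30,
    success_fraction: float = 0.7,
) -> pd.DataFrame:
    """Retrieval success rate vs load.

    `loads` are 2M/N for the anti-symmetric model (each memory occupies a
    plane) and M/N for Hopfield. A trial succeeds when the time-averaged
    target overlap over the final `avg` steps exceeds `success_fraction`
    of its single-memory value (1.0 for both models with binary
    patterns). The protocol (cue = pattern plus 10% Gaussian noise,
    synchronous sign updates) is identical for both models.
    """
    if model not in ("antisymmetric", "hopfield"):
        raise ConfigurationError("model must be 'antisymmetric' or 'hopfield'")
    rows = []
    for load in loads:
        rng = np.random.default_rng(np.random.SeedSequence([seed, N, int(load * 10000)]))
        if model == "antisymmetric":
            M = max(1, int(round(load * N / 2)))
        else:
            M = max(1, int(round(load * N)))
        ok = 0
        for _ in range(trials):
            if model == "antisymmetric":
                r = _retrieval_overlap_antisym(rng, N, M, steps, avg)
            else:
                r = _retrieval_overlap_hopfield(rng, N, M, steps, avg)
            ok += r > success_fraction
        rows.append({"model": model, "N": N, "M": M, "load": load,
                     "success_rate": ok / trials})
    return pd.DataFrame(rows)


def critical_load(curve: pd.DataFrame) -> float:
    """Load at which the success rate crosses 1/2, linearly interpolated;
    the last tested load if retrieval never fails."""
    c = curve.sort_values("load")
    loads = c["load"].to_numpy()
    rates = c["success_rate"].to_numpy()
    for i in range(1, len(loads)):
        if rates[i] < 0.5 <= rates[i - 1]:
            lo, hi = loads[i - 1], loads[i]
            rlo, rhi = rates[i - 1], rates[i]
            return float(lo + (rlo - 0.5) / (rlo - rhi) * (hi - lo))
    return float(loads[-1]) if rates[-1] >= 0.5 else float(loads[0])
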