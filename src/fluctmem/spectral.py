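"""Spectral analysis of connectivity and activity.

Memory content lives in the eigenstructure of W: real outliers are
fixed-point memories, conjugate imaginary pairs are limit-cycle memories.
This module tracks eigenvalue identities through time (value + eigenvector
matching solved as an assignment problem), measures overlaps between 2-D
planes, projects activity onto memory planes, and estimates oscillation
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import periodogram

from .errors import DegenerateInputError
from .memory import MemoryItem


def sym_antisym_decompose(W: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """W = S + A with S = (W + W^T)/2 symmetric, A = (W - W^T)/2
    anti-symmetric. Symmetric parts carry real eigenvalues, anti-symmetric
    parts imaginary ones."""
    W = np.asarray(W, dtype=float)
    S = (W + W.T) / 2.0
    return S, W - S


def orthonormal_plane(u: np.ndarray, v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Gram-Schmidt orthonormal basis of span{u, v}."""
    nu = np.linalg.norm(u)
    if nu == 0:
        raise DegenerateInputError("zero-norm spanning vector u")
    e1 = u / nu
    w = v - e1 * (e1 @ v)
    nw = np.linalg.norm(w)
    if nw < 1e-12 * max(1.0, np.linalg.norm(v)):
        raise DegenerateInputError("spanning vectors are collinear")
    return e1, w / nw


@dataclass(frozen=True)
class PlaneOverlap:
    """Overlap between two 2-D planes.

    `raw` is sqrt(r_u^2 + r_v^2) where r_u, r_v are the norms of the
    projections of the first plane's orthonormal basis onto the second
    plane; it equals sqrt(2) for identical planes and 0 for orthogonal
    ones. `normalized` = raw / sqrt(2), in [0, 1].
    """

    raw: float

    @property
    def normalized(self) -> float:
        return self.raw / np.sqrt(2.0)


def plane_overlap(u1, v1, u2, v2) -> PlaneOverlap:
    """Overlap of span{u1, v1} with span{u2, v2}; each pair is
    orthonormalized before evaluation, so the result is basis-invariant."""
    a1, b1 = orthonormal_plane(np.asarray(u1, float), np.asarray(v1, float))
    a2, b2 = orthonormal_plane(np.asarray(u2, float), np.asarray(v2, float))
    r_u = np.hypot(a1 @ a2, a1 @ b2)
    r_v = np.hypot(b1 @ a2, b1 @ b2)
    return PlaneOverlap(raw=float(np.sqrt(r_u**2 + r_v**2)))


def project_onto_plane(x: np.ndarray, item: MemoryItem) -> Tuple[float, float, float]:
    """Overlaps of activity with a memory plane:
    p_u = u^T x / sqrt(N), p_v = v^T x / sqrt(N), r = sqrt(p_u^2 + p_v^2)."""
    x = np.asarray(x, dtype=float)
    sqN = np.sqrt(len(x))
    p_u = float(item.u @ x / sqN)
    p_v = float(item.v @ x / sqN)
    return p_u, p_v, float(np.hypot(p_u, p_v))


@dataclass
class SpectrumTrace:
    """Identity-matched eigenvalue trajectories.

    eigvals[t, k] follows one eigenvalue identity through time; at each
    snapshot the row is a permutation of the instantaneous spectrum.
    eigvecs[t, :, k] is the matching eigenvector when retained.
    """

    times: np.ndarray
    eigvals: np.ndarray
    eigvecs: Optional[np.ndarray] = None


def track_eigenvalues(
    snapshots: Sequence[np.ndarray],
    times: Optional[Sequence[float]] = None,
    keep_vectors: bool = False,
    vector_weight: float = 1.0,
) -> SpectrumTrace:
    """Eigendecompose each snapshot and match identities between
    consecutive snapshots by minimum-cost assignment.

    The cost of pairing trajectory i (previous snapshot) with eigenvalue j
    (current) is |lambda_i - lambda_j| / scale + w (1 - |<v_i, v_j>|),
    with `scale` the median nearest-neighbour eigenvalue spacing of the
    previous snapshot. Value-only matching swaps trajectories that cross
    in the complex plane; the eigenvector term disambiguates crossings.
    """
    snaps = [np.asarray(S, dtype=float) for S in snapshots]
    if not snaps:
        raise DegenerateInputError("need at least one snapshot")
    N = snaps[0].shape[0]
    T = len(snaps)
    if times is None:
        times = np.arange(T, dtype=float)
    vals = np.empty((T, N), dtype=complex)
    vecs = np.empty((T, N, N), dtype=complex) if keep_vectors else None

    prev_w, prev_v = None, None
    for t, S in enumerate(snaps):
        w, v = np.linalg.eig(S)
        if prev_w is None:
            order = np.lexsort((w.imag, w.real))  # deterministic start
            w, v = w[order], v[:, order]
        else:
            dist = np.abs(prev_w[:, None] - w[None, :])
            spacing = _median_spacing(prev_w)
            cost = dist / spacing
            overlap = np.abs(prev_v.conj().T @ v)  # |<v_i, v_j>|
            cost = cost + vector_weight * (1.0 - overlap)
            _, cols = linear_sum_assignment(cost)
            w, v = w[cols], v[:, cols]
        vals[t] = w
        if keep_vectors:
            vecs[t] = v
        prev_w, prev_v = w, v
    return SpectrumTrace(times=np.asarray(times, float), eigvals=vals, eigvecs=vecs)


def _median_spacing(w: np.ndarray) -> float:
    if len(w) < 2:
        return 1.0
    d = np.abs(w[:, None] - w[None, :])
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    m = float(np.median(nn))
    return m if m > 1e-12 else 1.0


@dataclass
class MemoryEigenpair:
    """Best-matching conjugate pair for a memory plane (absent if the
    spectrum is entirely real)."""

    found: bool
    eigenvalue: complex = 0.0j
    overlap: float = 0.0
    plane_u: Optional[np.ndarray] = None
    plane_v: Optional[np.ndarray] = None


def eigenplane(z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Real 2-D plane of a complex eigenvector: orthonormalized
    span{Re z, Im z}."""
    return orthonormal_plane(np.real(z), np.imag(z))


def memory_eigenpair(W: np.ndarray, item: MemoryItem) -> MemoryEigenpair:
    """Among conjugate pairs of W (taking the Im > 0 member), return the
    one whose realified eigenplane maximizes the normalized overlap with
    span{u, v}."""
    W = np.asarray(W, dtype=float)
    w, V = np.linalg.eig(W)
    best = MemoryEigenpair(found=False)
    for j in range(len(w)):
        if w[j].imag <= 1e-12:
            continue
        try:
            pu, pv = eigenplane(V[:, j])
        except DegenerateInputError:
            continue
        ov = plane_overlap(pu, pv, item.u, item.v).normalized
        if not best.found or ov > best.overlap:
            best = MemoryEigenpair(
                found=True, eigenvalue=w[j], overlap=float(ov), plane_u=pu, plane_v=pv
            )
    return best


def top_imaginary_eigenpair(W: np.ndarray) -> MemoryEigenpair:
    """The conjugate pair with the largest imaginary part (absent for a
    purely real spectrum)."""
    w, V = np.linalg.eig(np.asarray(W, dtype=float))
    j = int(np.argmax(w.imag))
    if w[j].imag <= 1e-12:
        return MemoryEigenpair(found=False)
    pu, pv = eigenplane(V[:, j])
    return MemoryEigenpair(found=True, eigenvalue=w[j], overlap=float("nan"),
                           plane_u=pu, plane_v=pv)


def dominant_frequency(
    series: np.ndarray, dt_record: float, min_length: int = 64
) -> Optional[float]:
    """Frequency of the periodogram maximum after mean removal, refined
    by parabolic interpolation around the peak. Returns None for a flat
    (or too short) series."""
    s = np.asarray(series, dtype=float)
    if len(s) < min_length:
        return None
    s = s - s.mean()
    if np.allclose(s, 0.0):
        return None
    freqs, power = periodogram(s, fs=1.0 / dt_record)
    k = int(np.argmax(power[1:])) + 1  # skip DC
    if power[k] <= 0:
        return None
    f = freqs[k]
    if 1 <= k < len(power) - 1:
        pm, p0, pp = power[k - 1], power[k], power[k + 1]
        denom = pm - 2 * p0 + pp
        if denom != 0:
            delta = 0.5 * (pm - pp) / denom
            f = f + np.clip(delta, -0.5, 0.5) * (freqs[1] - freqs[0])
    return float(f)
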