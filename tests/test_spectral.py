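import numpy as np
import pytest

from fluctmem import (
    DegenerateInputError,
    MemoryItem,
    dominant_frequency,
    memory_eigenpair,
    plane_overlap,
    project_onto_plane,
    sample_memory,
    embed_imaginary,
    sym_antisym_decompose,
    track_eigenvalues,
)

J = np.array([[0.0, 1.0], [-1.0, 0.0]])  # rotation generator, eigvals +-i


def rotation_family(scales, n_pad=4):
    """Block-diagonal family s*J (+ zero padding) with spectrum +-i*s."""
    out = []
    for s in scales:
        W = np.zeros((2 + n_pad, 2 + n_pad))
        W[:2, :2] = s * J
        out.append(W)
    return out


def test_decompose_reconstruction(rng):
    W = rng.normal(size=(10, 10))
    S, A = sym_antisym_decompose(W)
    np.testing.assert_allclose(S + A, W)
    np.testing.assert_allclose(S, S.T)
    np.testing.assert_allclose(A, -A.T)


def test_plane_overlap_identical_orthogonal(rng):
    u = rng.normal(size=20)
    v = rng.normal(size=20)
    ov = plane_overlap(u, v, u, v)
    assert abs(ov.raw - np.sqrt(2)) < 1e-12
    assert abs(ov.normalized - 1.0) < 1e-12
    e = np.eye(8)
    assert plane_overlap(e[0], e[1], e[2], e[3]).raw < 1e-12


def test_plane_overlap_basis_invariance_and_symmetry(rng):
    u1, v1 = rng.normal(size=20), rng.normal(size=20)
    u2, v2 = rng.normal(size=20), rng.normal(size=20)
    base = plane_overlap(u1, v1, u2, v2).raw
    # rotate the second plane within its own span
    for theta in rng.uniform(0, 2 * np.pi, 5):
        a = np.cos(theta) * u2 + np.sin(theta) * v2
        b = -np.sin(theta) * u2 + np.cos(theta) * v2
        assert abs(plane_overlap(u1, v1, a, b).raw - base) < 1e-10
    assert abs(plane_overlap(u2, v2, u1, v1).raw - base) < 1e-10
    # rotating plane 2 into plane 1's span gives full overlap
    assert abs(plane_overlap(u1, v1, 0.3 * u1 + 0.2 * v1, v1).raw
               - np.sqrt(2)) < 1e-10


def test_plane_overlap_degenerate_input():
    z = np.zeros(5)
    ok = np.ones(5)
    with pytest.raises(DegenerateInputError):
        plane_overlap(z, ok, ok, ok)


def test_projection_values_and_linearity(rng):
    N = 64
    item = sample_memory(rng, N, orthonormalize=True)
    x = np.sqrt(N) * item.u
    p_u, p_v, r = project_onto_plane(x, item)
    assert abs(p_u - 1.0) < 1e-12 and abs(p_v) < 1e-12 and abs(r - 1.0) < 1e-12
    y = rng.normal(size=N)
    x2 = rng.normal(size=N)
    pa = project_onto_plane(2.0 * x2 + 3.0 * y, item)
    pb = project_onto_plane(x2, item)
    pc = project_onto_plane(y, item)
    assert abs(pa[0] - (2 * pb[0] + 3 * pc[0])) < 1e-12
    perp = rng.normal(size=N)
    for w in (item.u, item.v):
        perp -= w * (w @ perp)
    assert project_onto_plane(perp, item)[2] < 1e-12


def test_tracking_constant_sequence(rng):
    W = rng.normal(size=(8, 8))
    trace = track_eigenvalues([W] * 5)
    for t in range(1, 5):
        np.testing.assert_allclose(trace.eigvals[t], trace.eigvals[0], atol=1e-12)


def test_tracking_rotating_family_matches_analytic():
    scales = np.linspace(1.0, 3.0, 21)
    trace = track_eigenvalues(rotation_family(scales))
    # the two nonzero trajectories are +-i s_k at every snapshot
    col_plus = np.argmax(trace.eigvals[0].imag)
    col_minus = np.argmin(trace.eigvals[0].imag)
    np.testing.assert_allclose(trace.eigvals[:, col_plus], 1j * scales, atol=1e-6)
    np.testing.assert_allclose(trace.eigvals[:, col_minus], -1j * scales, atol=1e-6)


def test_tracking_no_swap_at_crossing():
    # two conjugate pairs on distinct planes whose imaginary parts cross:
    # value-only matching would swap identities at the crossing
    a = np.linspace(3.0, 1.0, 31)
    b = np.linspace(1.0, 3.0, 31)
    snaps = []
    for ak, bk in zip(a, b):
        W = np.zeros((4, 4))
        W[:2, :2] = ak * J
        W[2:, 2:] = bk * J
        snaps.append(W)
    trace = track_eigenvalues(snaps)
    col_a = np.argmax(np.isclose(trace.eigvals[0].imag, 3.0, atol=1e-9))
    np.testing.assert_allclose(trace.eigvals[:, col_a].imag, a, atol=1e-6)


def test_tracking_preserves_spectrum_and_conjugacy(rng):
    N = 12
    W0 = rng.normal(0, 1 / np.sqrt(N), (N, N))
    dW = rng.normal(0, 0.01, (N, N))
    snaps = [W0 + k * dW for k in range(10)]
    trace = track_eigenvalues(snaps)
    for k, S in enumerate(snaps):
        got = np.sort_complex(trace.eigvals[k])
        ref = np.sort_complex(np.linalg.eigvals(S))
        np.testing.assert_allclose(got, ref, atol=1e-8)
        # closed under conjugation
        np.testing.assert_allclose(
            np.sort_complex(np.conj(got)), got, atol=1e-8
        )


def test_memory_eigenpair_clean_and_in_bulk():
    rng = np.random.default_rng(7)
    N = 64
    item = sample_memory(rng, N, rho=4.0, orthonormalize=True)
    W = embed_imaginary(np.zeros((N, N)), item)
    pair = memory_eigenpair(W, item)
    assert pair.found
    np.testing.assert_allclose(pair.eigenvalue, 4j, atol=1e-8)
    assert pair.overlap > 0.999
    # embedded in a random bulk of unit radius the outlier still dominates
    Wb = embed_imaginary(rng.normal(0, 1 / np.sqrt(N), (N, N)), item)
    pair_b = memory_eigenpair(Wb, item)
    assert abs(pair_b.eigenvalue.imag) > 3.0
    assert pair_b.overlap > 0.9


def test_memory_eigenpair_absent_for_symmetric():
    rng = np.random.default_rng(8)
    A = rng.normal(size=(16, 16))
    S = (A + A.T) / 2
    item = sample_memory(rng, 16)
    assert not memory_eigenpair(S, item).found


def test_dominant_frequency_sinusoid_and_flat(rng):
    dt = 0.1
    t = np.arange(0, 100, dt)
    f0 = 0.63
    f = dominant_frequency(np.sin(2 * np.pi * f0 * t), dt)
    assert abs(f - f0) < 1.0 / (len(t) * dt)  # within one bin
    assert dominant_frequency(np.ones(512), dt) is None
    assert dominant_frequency(np.ones(10), dt) is None
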