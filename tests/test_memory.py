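import numpy as np
import pytest

from fluctmem import (
    CueSpec,
    MemoryItem,
    StimulusSpec,
    build_bank_connectivity,
    embed_imaginary,
    embed_real,
    ou_stimulus,
    retrieval_cue,
    sample_bank,
    sample_memory,
    sym_antisym_decompose,
)


def test_sample_memory_concentration():
    rng = np.random.default_rng(0)
    item = sample_memory(rng, 4096)
    assert abs(item.u @ item.v) < 0.1
    assert 0.9 < np.linalg.norm(item.u) < 1.1
    assert 0.9 < np.linalg.norm(item.v) < 1.1


def test_sample_memory_deterministic():
    a = sample_memory(np.random.default_rng(42), 64)
    b = sample_memory(np.random.default_rng(42), 64)
    np.testing.assert_array_equal(a.u, b.u)
    np.testing.assert_array_equal(a.v, b.v)


def test_pattern_independence(rng):
    dots = [
        (lambda it: it.u @ it.v)(sample_memory(rng, 256)) for _ in range(1000)
    ]
    assert abs(np.mean(dots)) < 3 / np.sqrt(1000 * 256)  # ~3 sigma


def test_embed_real_rank_one_projector():
    u = np.zeros(8)
    u[0] = 1.0
    W = embed_real(np.zeros((8, 8)), u)
    vals = np.sort(np.linalg.eigvalsh(W))
    np.testing.assert_allclose(vals[-1], 1.0, atol=1e-12)
    np.testing.assert_allclose(vals[:-1], 0.0, atol=1e-12)
    np.testing.assert_allclose(W, W.T)


def test_embed_real_top_eigvec_aligned(rng):
    N = 64
    W = rng.normal(0, 1 / np.sqrt(N), (N, N))
    u = rng.normal(0, 1 / np.sqrt(N), N)
    u /= np.linalg.norm(u)
    S, _ = sym_antisym_decompose(embed_real(W, 3.0 * np.sqrt(1) * u) - W)
    vals, vecs = np.linalg.eigh(S)
    assert abs(vecs[:, -1] @ u) > 0.99


def test_embed_imaginary_spectrum():
    rng = np.random.default_rng(1)
    item = sample_memory(rng, 32, rho=4.0, gamma=0.0, orthonormalize=True)
    W = embed_imaginary(np.zeros((32, 32)), item)
    vals = np.linalg.eigvals(W)
    vals = vals[np.argsort(-np.abs(vals))]
    np.testing.assert_allclose(sorted(vals[:2].imag), [-4.0, 4.0], atol=1e-10)
    np.testing.assert_allclose(vals[2:], 0.0, atol=1e-10)
    np.testing.assert_allclose(W + W.T, 0.0, atol=1e-12)


def test_embed_imaginary_with_gamma():
    rng = np.random.default_rng(2)
    item = sample_memory(rng, 32, rho=4.0, gamma=1.5, orthonormalize=True)
    W = embed_imaginary(np.zeros((32, 32)), item)
    vals = np.linalg.eigvals(W)
    top = vals[np.argsort(-np.abs(vals))][:2]
    np.testing.assert_allclose(sorted(top.imag), [-4.0, 4.0], atol=1e-10)
    np.testing.assert_allclose(top.real, 1.5, atol=1e-10)


def test_bank_single_item_equals_embedding():
    rng = np.random.default_rng(3)
    bank = sample_bank(rng, 16, 1, rho=2.0)
    W_bank = build_bank_connectivity(bank)
    W_item = embed_imaginary(np.zeros((16, 16)), bank.items[0])
    np.testing.assert_allclose(W_bank, W_item, atol=1e-14)


def test_bank_two_items_spectrum_and_rank():
    rng = np.random.default_rng(4)
    bank = sample_bank(rng, 32, 2, rho=1.0, orthonormalize=True)
    W = build_bank_connectivity(bank)
    np.testing.assert_allclose(W + W.T, 0.0, atol=1e-12)
    vals = np.linalg.eigvals(W)
    im = np.sort(vals.imag)
    np.testing.assert_allclose(im[:2], -1.0, atol=1e-10)
    np.testing.assert_allclose(im[-2:], 1.0, atol=1e-10)
    np.testing.assert_allclose(im[2:-2], 0.0, atol=1e-10)
    assert np.linalg.matrix_rank(W, tol=1e-8) == 4


def test_bank_size_limit():
    rng = np.random.default_rng(5)
    with pytest.raises(Exception):
        sample_bank(rng, 8, 5)


def test_ou_stimulus_window_and_span(rng):
    item = sample_memory(rng, 64)
    spec = StimulusSpec(item=item, t_on=5.0, t_off=15.0, amplitude=2.0)
    b = ou_stimulus(spec, rng, dt=0.1)
    assert np.all(b(0.0) == 0.0) and np.all(b(20.0) == 0.0)
    # every in-window value lies in span{u, v}
    basis = np.linalg.qr(np.column_stack([item.u, item.v]))[0]
    for t in (5.0, 9.37, 14.9):
        val = b(t)
        resid = val - basis @ (basis.T @ val)
        assert np.linalg.norm(resid) < 1e-12 * max(np.linalg.norm(val), 1)


def test_ou_stationary_variance_and_whiteness(rng):
    # exact discretization: unit stationary variance; with tau << dt the
    # lag-1 autocorrelation is e^{-dt/tau} < e^{-10}
    item = sample_memory(rng, 8)
    spec = StimulusSpec(item=item, t_on=0.0, t_off=2000.0, ou_timescale=0.01)
    b = ou_stimulus(spec, rng, dt=0.1)
    B = np.array([b(t) for t in np.arange(0, 2000, 0.1)])
    coeffs = np.linalg.lstsq(np.column_stack([item.u, item.v]), B.T, rcond=None)[0]
    cu = coeffs[0] / spec.amplitude
    assert abs(cu.var() - 1.0) < 0.05
    lag1 = np.corrcoef(cu[:-1], cu[1:])[0, 1]
    assert abs(lag1) < 0.02  # consistent with e^{-10} plus sampling noise


def test_retrieval_cue_pulse(rng):
    item = sample_memory(rng, 32)
    spec = CueSpec(item=item, t_cue=10.0)
    b = retrieval_cue(spec)
    assert np.all(b(9.99) == 0.0)
    np.testing.assert_allclose(b(10.0), 10.0 * item.u)
    np.testing.assert_allclose(b(11.9), 10.0 * item.u)
    assert np.all(b(12.0) == 0.0)
    # the cue points along u only
    v_perp = item.v - item.u * (item.u @ item.v) / (item.u @ item.u)
    assert abs(b(10.5) @ v_perp) < 1e-12


def test_embeddings_preserve_complementary_parts(rng):
    N = 24
    W = rng.normal(size=(N, N))
    S0, A0 = sym_antisym_decompose(W)
    u = rng.normal(0, 1 / np.sqrt(N), N)
    _, A1 = sym_antisym_decompose(embed_real(W, u))
    np.testing.assert_allclose(A1, A0, atol=1e-13)
    item = sample_memory(rng, N, rho=2.0, gamma=0.0)
    S2, _ = sym_antisym_decompose(embed_imaginary(W, item))
    np.testing.assert_allclose(S2, S0, atol=1e-13)
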