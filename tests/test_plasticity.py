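import numpy as np
import pytest

from fluctmem import (
    HomeostasisConfig,
    Nonlinearity,
    PlasticityState,
    STDPConfig,
    TANH,
    decorrelation_term,
    dissipation_term,
    noise_term,
    rate_control_term,
    stdp_term,
    step_weights,
    sym_antisym_decompose,
    update_filters,
)


# ----------------------------------------------------------------- oracles
# scalar triple-loop references, deliberately naive


def rate_control_oracle(x, W, phi0):
    n = len(x)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = (phi0[i] - np.tanh(x[i])) * np.tanh(x[j]) * W[i, j]
    return out


def decorrelation_oracle(x, xbar):
    n = len(x)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = (1.0 if i == j else 0.0) - np.tanh(x[i] - xbar[i]) * np.tanh(x[j])
    return out


def stdp_oracle(phi_x, yP, yD, a_P, a_D):
    n = len(phi_x)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = a_P * phi_x[i] * yP[j] + a_D * yD[i] * phi_x[j]
    return out


@pytest.mark.parametrize("n", [4, 16])
def test_rate_control_matches_scalar_oracle(rng, n):
    x = rng.normal(size=n)
    W = rng.normal(size=(n, n))
    phi0 = rng.uniform(-1, 1, n)
    got = rate_control_term(x, W, phi0, TANH)
    np.testing.assert_allclose(got, rate_control_oracle(x, W, phi0), rtol=1e-14)


@pytest.mark.parametrize("n", [4, 16])
def test_decorrelation_matches_scalar_oracle(rng, n):
    x = rng.normal(size=n)
    xbar = rng.normal(size=n)
    got = decorrelation_term(x, xbar, TANH)
    np.testing.assert_allclose(got, decorrelation_oracle(x, xbar), rtol=1e-14)


@pytest.mark.parametrize("n", [4, 16])
def test_stdp_matches_scalar_oracle(rng, n):
    cfg = STDPConfig(a_P=1.3, a_D=-0.7, tau_P=40.0, tau_D=60.0)
    phi_x = rng.normal(size=n)
    ps = PlasticityState(yP=rng.normal(size=n), yD=rng.normal(size=n),
                         xbar=np.zeros(n))
    got = stdp_term(phi_x, ps, cfg)
    np.testing.assert_allclose(
        got, stdp_oracle(phi_x, ps.yP, ps.yD, cfg.a_P, cfg.a_D), rtol=1e-14
    )


# ------------------------------------------------------------- identities


def test_antisymmetric_stdp_is_antisymmetric(rng):
    cfg = STDPConfig(a_P=2.0, a_D=-2.0)
    assert cfg.is_antisymmetric
    phi_x = rng.normal(size=16)
    y = rng.normal(size=16)
    ps = PlasticityState(yP=y, yD=y, xbar=np.zeros(16))
    dL = stdp_term(phi_x, ps, cfg)
    np.testing.assert_allclose(dL + dL.T, 0.0, atol=1e-14)


def test_antisymmetric_stdp_vanishes_at_stationary_activity(rng):
    cfg = STDPConfig(a_P=1.0, a_D=-1.0)
    phi_x = rng.normal(size=8)
    ps = PlasticityState(yP=phi_x.copy(), yD=phi_x.copy(), xbar=np.zeros(8))
    np.testing.assert_allclose(stdp_term(phi_x, ps, cfg), 0.0, atol=1e-15)


def test_antisymmetric_updates_preserve_symmetric_part(rng):
    # sym(W) is invariant under purely anti-symmetric learning
    n = 12
    W = rng.normal(size=(n, n))
    S0, _ = sym_antisym_decompose(W)
    cfg = STDPConfig()
    for _ in range(20):
        phi_x = rng.normal(size=n)
        y = rng.normal(size=n)
        ps = PlasticityState(yP=y, yD=y, xbar=np.zeros(n))
        W = step_weights(W, stdp_term(phi_x, ps, cfg), None, eta=0.01, dt=0.1)
    S1, _ = sym_antisym_decompose(W)
    np.testing.assert_allclose(S1, S0, atol=1e-13)


def test_rate_control_zero_at_set_point(rng):
    n = 8
    phi0 = rng.uniform(-0.9, 0.9, n)
    x = np.arctanh(phi0)  # phi(x) == phi0 exactly
    W = rng.normal(size=(n, n))
    np.testing.assert_allclose(rate_control_term(x, W, phi0, TANH), 0.0, atol=1e-12)
    # and x = 0 silences the rule regardless of targets
    np.testing.assert_allclose(
        rate_control_term(np.zeros(n), W, phi0, TANH), 0.0, atol=1e-15
    )


def test_decorrelation_identity_cases(rng):
    n = 6
    np.testing.assert_allclose(
        decorrelation_term(np.zeros(n), np.zeros(n), TANH), np.eye(n)
    )
    x = rng.normal(size=n)
    np.testing.assert_allclose(decorrelation_term(x, x.copy(), TANH), np.eye(n))


def test_dissipation_term_is_linear_decay():
    np.testing.assert_allclose(dissipation_term(np.eye(3), 0.1), -0.1 * np.eye(3))


# ------------------------------------------------------------------ noise


def test_noise_statistics(rng):
    N = 100
    draws = np.stack([noise_term(rng, N) for _ in range(20)])
    assert abs(draws.mean()) < 3e-4
    assert abs(draws.var() - 1.0 / N) < 5e-4
    # half-normal mean E|xi| = sqrt(2/(pi N))
    expected = np.sqrt(2.0 / (np.pi * N))
    assert abs(np.abs(draws).mean() - expected) / expected < 0.01


def test_noise_respects_mask(rng):
    N = 40
    mask = (rng.random((N, N)) < 0.5).astype(float)
    xi = noise_term(rng, N, mask=mask)
    assert np.all(xi[mask == 0] == 0.0)
    assert np.all(xi[mask == 1] != 0.0)


# ---------------------------------------------------------------- filters


def test_filter_fixed_point():
    n = 4
    cfg = STDPConfig(tau_P=50.0, tau_D=50.0)
    ps = PlasticityState.zeros(n)
    x = np.array([0.5, -1.0, 2.0, 0.0])
    for _ in range(int(10 * 50 / 0.1)):
        ps = update_filters(ps, x, TANH, cfg, dt=0.1)
    np.testing.assert_allclose(ps.yP, np.tanh(x), atol=1e-3)
    np.testing.assert_allclose(ps.yD, np.tanh(x), atol=1e-3)


def test_filter_stays_zero_for_zero_input():
    ps = PlasticityState.zeros(3)
    for _ in range(100):
        ps = update_filters(ps, np.zeros(3), TANH, STDPConfig(), dt=0.1)
    assert np.all(ps.yP == 0) and np.all(ps.xbar == 0)


def test_filter_relaxation_timescale():
    # step input: fitted exponential timescale within 2% of tau = 50
    tau, dt = 50.0, 0.1
    cfg = STDPConfig(tau_P=tau, tau_D=tau)
    ps = PlasticityState.zeros(1)
    x = np.array([10.0])  # tanh saturates to ~1
    ts, resid = [], []
    for k in range(int(3 * tau / dt)):
        ps = update_filters(ps, x, TANH, cfg, dt=dt)
        ts.append((k + 1) * dt)
        resid.append(1.0 - ps.yP[0] / np.tanh(10.0))
    slope = np.polyfit(ts, np.log(resid), 1)[0]
    assert abs(-1.0 / slope - tau) / tau < 0.02


# ----------------------------------------------------------- weight steps


def test_step_weights_identity_and_mask(rng):
    n = 10
    W = rng.normal(size=(n, n))
    np.testing.assert_array_equal(step_weights(W, None, None, 0.01, 0.1), W)
    mask = (rng.random((n, n)) < 0.5).astype(float)
    Wm = W * mask
    out = step_weights(Wm, rng.normal(size=(n, n)), rng.normal(size=(n, n)),
                       0.01, 0.1, mask=mask)
    assert np.all(out[mask == 0] == 0.0)


def test_noise_only_weight_variance_grows_linearly(rng):
    # random-walk variance: Var[W_ij(k)] = k (dt eta)^2 / N
    N, steps, dt, eta = 24, 400, 0.1, 0.01
    W = np.zeros((N, N))
    for _ in range(steps):
        W = step_weights(W, None, noise_term(rng, N), eta, dt)
    expected = steps * (dt * eta) ** 2 / N
    measured = W.var()
    assert abs(measured - expected) / expected < 0.15


def test_dissipation_with_noise_matches_ou_variance(rng):
    # stationary per-entry variance of W <- (1 - dt eta beta) W + dt eta xi
    N, dt, eta, beta = 32, 0.1, 0.01, 0.1
    a = 1 - dt * eta * beta
    var_inf = (dt * eta) ** 2 * (1.0 / N) / (1 - a * a)
    W = np.zeros((N, N))
    burn = int(10 / (dt * eta * beta))
    acc = []
    for k in range(burn + 4000):
        W = step_weights(W, None, dissipation_term(W, beta) + noise_term(rng, N),
                         eta, dt)
        if k >= burn:
            acc.append(W.var())
    assert abs(np.mean(acc) - var_inf) / var_inf < 0.05


def test_homeostasis_config_validation():
    with pytest.raises(Exception):
        HomeostasisConfig(rule="shrinkage")
    with pytest.raises(Exception):
        STDPConfig(a_D=0.5)
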