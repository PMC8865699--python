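"""Tests of the population mean-field theory."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from engramnet.network import LIFParams
from engramnet.meanfield import (PopulationModel, cv_isi,
                                 connectivity_flow, element_rate_mean,
                                 equilibrium_indegree, equilibrium_state,
                                 input_moments, integrate_model,
                                 operating_point, siegert_rate,
                                 sigma_element)
from engramnet._mfkernel import _GLX, _GLW, _siegert_nb


# ----------------------------------------------------------------------
# Siegert transfer function
# ----------------------------------------------------------------------

def test_siegert_limits(lif):
    assert siegert_rate(-50.0, 0.5, lif) < 1e-12          # deep subthreshold
    ceiling = 1.0 / (lif.t_ref * 1e-3)
    # approach to the refractory ceiling is ~ tau_m*(V_th-V_r)/mu slow
    assert siegert_rate(2e5, 1.0, lif) == pytest.approx(ceiling, rel=1e-2)
    with pytest.raises(ValueError):
        siegert_rate(10.0, 0.0, lif)


def test_siegert_stable_for_extreme_arguments(lif):
    # (V - mu)/sigma up to +-40 must not overflow or go negative
    for mu in (-380.0, -100.0, 0.0, 100.0, 420.0):
        r = siegert_rate(mu, 10.0, lif)
        assert np.isfinite(r) and r >= 0.0


def test_siegert_compiled_path_matches_reference(lif):
    rng = np.random.default_rng(1)
    for _ in range(200):
        mu = rng.uniform(-30, 60)
        sigma = rng.uniform(0.5, 12.0)
        r_ref = siegert_rate(mu, sigma, lif)
        r_nb = _siegert_nb(mu, sigma, lif.tau_m * 1e-3, lif.t_ref * 1e-3,
                           lif.V_th, lif.V_r, _GLX, _GLW)
        assert r_nb == pytest.approx(r_ref, rel=1e-6, abs=1e-9)


from numba import njit


@njit
def _sde_isi_kernel(mu, sigma, tau, V_th, V_r, t_ref, T, dt, seed):
    np.random.seed(seed)
    n = int(T / dt)
    amp = sigma * np.sqrt(dt / tau)
    V, t_last, ref, t = V_r, 0.0, 0.0, 0.0
    isis = np.empty(int(T * 600) + 10)
    m = 0
    for _ in range(n):
        if ref > 0:
            ref -= dt
        else:
            V += (mu - V) * dt / tau + amp * np.random.standard_normal()
            if V >= V_th:
                if m < isis.shape[0]:
                    isis[m] = t - t_last
                    m += 1
                t_last, V, ref = t, V_r, t_ref
        t += dt
    return isis[1:m]


def _sde_isi_cv(mu, sigma, lif, T=400.0, dt=1e-5, seed=0):
    """Independent oracle: Euler-Maruyama simulation of the LIF SDE."""
    isis = _sde_isi_kernel(mu, sigma, lif.tau_m * 1e-3, lif.V_th, lif.V_r,
                           lif.t_ref * 1e-3, T, dt, seed)
    return isis.std() / isis.mean(), isis.size


def test_cv_statistic_matches_sde_oracle(lif):
    """The first-passage irregularity statistic equals the squared ISI
    CV of a brute-force SDE simulation at the grown-network operating
    point."""
    op = operating_point(lif)
    stat = cv_isi(op.mu_e, op.sigma_e, lif)
    cv_emp, n = _sde_isi_cv(op.mu_e, op.sigma_e, lif, T=200.0)
    assert n > 1000
    # sampling error of CV^2 ~ 2 CV^2 sqrt(2/n) plus small time-step bias
    assert stat == pytest.approx(cv_emp ** 2, abs=0.08)


def test_cv_statistic_small_in_drift_dominated_regime(lif):
    assert cv_isi(40.0, 1.0, lif) < 0.05


# ----------------------------------------------------------------------
# input moments and equilibrium
# ----------------------------------------------------------------------

def test_input_moments_external_only(lif):
    m = PopulationModel(sizes_e=np.array([100.0, 900.0]), N_I=250)
    mom = input_moments(m, np.zeros((2, 2)), np.zeros(3))
    tau = lif.tau_m * 1e-3
    assert mom.mu[0] == pytest.approx(tau * lif.J * lif.nu_ext)
    with pytest.raises(ValueError):
        input_moments(m, np.zeros((2, 2)), np.array([-1.0, 0, 0]))


def test_input_moment_scaling_with_J():
    m1 = PopulationModel(sizes_e=np.array([1000.0]), N_I=250)
    lif2 = LIFParams(J=0.2)
    m2 = PopulationModel(sizes_e=np.array([1000.0]), N_I=250, lif=lif2)
    C = np.array([[0.1]])
    r = np.array([8.0, 0.0])
    a = input_moments(m1, C, r)
    b = input_moments(m2, C, r)
    assert b.mu[0] == pytest.approx(2 * a.mu[0])
    assert b.sigma[0] ** 2 == pytest.approx(4 * a.sigma[0] ** 2)


def test_equilibrium_selfconsistency_residual(lif):
    nu = 8.0
    K = equilibrium_indegree(lif, nu)
    op = operating_point(lif, nu)
    assert siegert_rate(op.mu_e, op.sigma_e, lif) == pytest.approx(nu,
                                                                   abs=1e-6)
    assert K == pytest.approx(op.K)


def test_equilibrium_indegree_monotone_in_target(lif):
    Ks = [equilibrium_indegree(lif, nu) for nu in (2.0, 4.0, 8.0, 16.0)]
    assert np.all(np.diff(Ks) > 0)


# ----------------------------------------------------------------------
# element rates
# ----------------------------------------------------------------------

@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.floats(-30, 30), st.floats(0.01, 10))
def test_rectified_rate_identity(mu, sigma):
    cre, dele = element_rate_mean(mu, sigma)
    assert cre - dele == pytest.approx(mu, abs=1e-12 * max(1, abs(mu)))
    assert cre >= 0 and dele >= 0


def test_rectified_rate_limits():
    cre, dele = element_rate_mean(3.0, 0.0)
    assert (cre, dele) == (3.0, 0.0)
    cre0, dele0 = element_rate_mean(0.0, 2.0)
    assert cre0 == pytest.approx(2.0 / np.sqrt(2 * np.pi), rel=1e-12)
    assert cre0 == dele0 > 0      # rewiring persists at the set-point


def test_sigma_element_assembly():
    # eta * sqrt(nu/(2 tau_Ca)) / beta
    assert sigma_element(0.7, 8.0, 10.0, 2.0) == pytest.approx(
        0.7 * np.sqrt(8.0 / 20.0) / 2.0)


# ----------------------------------------------------------------------
# connectivity flow
# ----------------------------------------------------------------------

def test_flow_vanishes_on_line_attractor_without_noise():
    m = PopulationModel(sizes_e=np.array([1000.0, 9000.0]), N_I=2500,
                        eta=0.0)
    K = equilibrium_indegree(m.lif, 8.0)
    for x in (0.05, 0.0999, 0.2, 0.5):
        c12 = (K - x * 1000) / 9000
        c22 = (K / 9000 - (1000 / 9000) * (K / 9000)) + x * (1000 / 9000) ** 2
        C = np.array([[x, c12], [c12, c22]])
        dC = connectivity_flow(m, np.full(2, 8.0), C)
        assert np.abs(dC).max() < 1e-10


def test_flow_drifts_toward_entropic_point_with_noise():
    m = PopulationModel(sizes_e=np.array([1000.0, 9000.0]), N_I=2500)
    st = equilibrium_state(m)
    c = st.C[0, 0]
    K = c * 10000
    x = 2 * c
    c12 = (K - x * 1000) / 9000
    c22 = (K / 9000 - (1000 / 9000) * (K / 9000)) + x * (1000 / 9000) ** 2
    C = np.array([[x, c12], [c12, c22]])
    dC = connectivity_flow(m, st.phi, C)
    assert dC[0, 0] < 0        # engram connectivity decays ...
    assert dC[0, 1] > 0        # ... toward the homogeneous configuration
    # fixed point itself is stationary
    assert np.abs(connectivity_flow(m, st.phi, st.C)).max() < 1e-12


def test_integrator_constant_at_equilibrium():
    m = PopulationModel(sizes_e=np.array([1000.0, 9000.0]), N_I=2500)
    st = equilibrium_state(m)
    tr = integrate_model(m, [(20.0, np.ones(2))], state=st.copy())
    assert np.allclose(tr.C[-1], st.C, atol=1e-6)
    assert np.allclose(tr.r[-1], st.r, atol=1e-6)
    assert not tr.runaway


def test_integrator_matches_python_flow_over_short_horizon():
    """Compiled integrator agrees with the reference numpy flow."""
    m = PopulationModel(sizes_e=np.array([1000.0, 9000.0]), N_I=2500)
    st = equilibrium_state(m)
    C = st.C * np.array([[1.5, 0.94], [0.94, 1.0]])
    state = st.copy()
    state.C = C.copy()
    tr = integrate_model(m, [(1.0, np.ones(2))], state=state,
                         record_every_s=1.0)
    # reference: Euler with the numpy implementations (delay ~ 1 step)
    phi, Cr, r = st.phi.copy(), C.copy(), st.r.copy()
    dt = m.lif.D * 1e-3
    r_prev = r.copy()
    for _ in range(int(round(1.0 / dt))):
        mom = input_moments(m, Cr, r_prev)
        f = siegert_rate(mom.mu, mom.sigma, m.lif)
        dC = connectivity_flow(m, phi, Cr)
        r_prev = r.copy()
        r = r + dt * (f - r) / (m.tau_rate_ms * 1e-3)
        phi = phi + dt * (r[:-1] - phi) / m.tau_ca_s
        Cr = np.maximum(Cr + dt * dC, 0.0)
    assert np.allclose(tr.C[-1], Cr, rtol=1e-9, atol=1e-12)
    assert np.allclose(tr.r[-1], r, rtol=1e-7)


def test_scaled_population_model_reproduces_spiking_equilibrium(grown_scaled):
    """Mean-field equilibrium connectivity matches the connectivity the
    scaled spiking network actually grew to (matched static wiring)."""
    net = grown_scaled.net
    c_sim = net.conn.ee.mean()
    m = PopulationModel(sizes_e=np.array([100.0, 900.0]), N_I=250,
                        K_I=124, K_IE=100, tau_ca_s=1.0,
                        beta_a=0.4, beta_d=0.4)
    c_mf = equilibrium_state(m).C[0, 0]
    assert c_sim == pytest.approx(c_mf, rel=0.1)
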