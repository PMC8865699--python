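"""Tests of protocols, overlap statistics and renewal-process theory."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from engramnet.network import SpikeRecord
from engramnet.protocols import (Pattern, ProtocolError, StimulusProtocol,
                                 attach_readout, calcium_equilibrium_stats,
                                 calcium_trace, decay_time_constant,
                                 FitError, gamma_spike_train, overlap,
                                 pattern_completion_curve, population_rate,
                                 sample_ensembles)


# ----------------------------------------------------------------------
# protocol data structures
# ----------------------------------------------------------------------

def test_protocol_validation():
    ens = {"A": np.array([0, 1]), "B": np.array([2, 3])}
    p = StimulusProtocol([(1.0, {"A": 1.4})], ens)
    mult = p.multipliers({"A": 1.4}, 6)
    assert np.array_equal(mult, [1.4, 1.4, 1, 1, 1, 1])
    with pytest.raises(ProtocolError):
        StimulusProtocol([(1.0, {})], {"A": [0, 1], "B": [1, 2]})
    with pytest.raises(ProtocolError):
        StimulusProtocol([(-1.0, {})], ens)
    with pytest.raises(ProtocolError):
        StimulusProtocol([(1.0, {"C": 1.0})], ens)
    with pytest.raises(ProtocolError):
        StimulusProtocol([(1.0, {"A": -0.5})], ens)


def test_sample_ensembles_disjoint_and_sized():
    rng = np.random.default_rng(0)
    ens = sample_ensembles(1000, {"US": 0.1, "C1": 0.1, "C2": 0.1}, rng)
    all_idx = np.concatenate(list(ens.values()))
    assert all(len(v) == 100 for v in ens.values())
    assert np.unique(all_idx).size == 300


# ----------------------------------------------------------------------
# overlap
# ----------------------------------------------------------------------

def test_overlap_identities():
    pat = Pattern.from_indices([0, 1, 2], 10)
    # activity equal to the pattern -> overlap exactly 1
    rec = SpikeRecord(np.array([1.0, 2.0, 3.0]), np.array([0, 1, 2]))
    _, m = overlap(pat, rec, bin_ms=10.0, t0_ms=0.0, t1_ms=10.0)
    assert m[0] == pytest.approx(1.0)
    # silence -> overlap 0
    _, m = overlap(pat, SpikeRecord(np.empty(0), np.empty(0, int)),
                   bin_ms=10.0, t0_ms=0.0, t1_ms=10.0)
    assert m[0] == 0.0
    with pytest.raises(ProtocolError):
        overlap(Pattern(np.ones(5, bool)), rec)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(2, 40), st.integers(1, 39))
def test_overlap_one_for_exact_pattern(n, k):
    k = min(k, n - 1)
    pat = Pattern.from_indices(np.arange(k), n)
    rec = SpikeRecord(np.ones(k), np.arange(k))
    _, m = overlap(pat, rec, bin_ms=5.0, t0_ms=0.0, t1_ms=5.0)
    assert m[0] == pytest.approx(1.0)


def test_overlap_zero_mean_for_independent_activity():
    """For activity independent of the pattern E[m] = 0 (Monte Carlo)."""
    rng = np.random.default_rng(5)
    N, a, n_bins = 200, 0.2, 10000
    pat = Pattern(rng.random(N) < a)
    times, ids = [], []
    for b in range(n_bins):
        active = np.nonzero(rng.random(N) < a)[0]
        times.append(np.full(active.size, b * 10.0 + 5.0))
        ids.append(active)
    rec = SpikeRecord(np.concatenate(times), np.concatenate(ids))
    _, m = overlap(pat, rec, bin_ms=10.0, t0_ms=0.0, t1_ms=n_bins * 10.0)
    se = m.std() / np.sqrt(n_bins)
    assert abs(m.mean()) < 3 * se


def test_population_rate_integrates_to_spike_count():
    rng = np.random.default_rng(2)
    rec = SpikeRecord(np.sort(rng.uniform(0, 1000.0, 777)),
                      rng.integers(0, 50, 777))
    t, r = population_rate(rec, 50, 0.0, 1000.0, bin_ms=100.0)
    total = (r * 50 * 0.1).sum()
    assert total == pytest.approx(777)


# ----------------------------------------------------------------------
# decay fit
# ----------------------------------------------------------------------

def test_decay_fit_recovers_planted_constant():
    t = np.arange(0, 5000.0, 15.0)
    c = 0.1 + 0.05 * np.exp(-t / 3000.0)
    tau = decay_time_constant(t, c)
    assert tau == pytest.approx(3000.0, abs=1.0)


def test_decay_fit_rejects_non_decaying_series():
    t = np.arange(0, 100.0, 1.0)
    with pytest.raises(FitError):
        decay_time_constant(t, 0.1 + 0.001 * t)


# ----------------------------------------------------------------------
# renewal processes and calcium shot noise
# ----------------------------------------------------------------------

def test_gamma_train_matches_requested_cv():
    rng = np.random.default_rng(0)
    rec = gamma_spike_train(100.0, 0.7, 1000.0, rng)   # ~1e5 ISIs
    isi = np.diff(rec.times_ms) / 1000.0
    assert isi.size > 90000
    assert isi.std() / isi.mean() == pytest.approx(0.7, abs=0.01)
    assert rec.times_ms.max() < 1000.0 * 1000.0


def test_gamma_train_poisson_limit_is_exponential():
    rng = np.random.default_rng(1)
    rec = gamma_spike_train(50.0, 1.0, 400.0, rng)
    isi = np.diff(rec.times_ms) / 1000.0
    ks = stats.kstest(isi, "expon", args=(0, isi.mean()))
    assert ks.pvalue > 0.01


def test_calcium_moments_follow_campbell_theorem():
    """Empirical moments of the filtered train match mean nu and
    variance cv^2 nu / (2 tau_Ca)."""
    rng = np.random.default_rng(3)
    nu, cv, tau_ca = 20.0, 0.7, 2.0
    rec = gamma_spike_train(nu, cv, 1500.0, rng)
    phi = calcium_trace(rec, tau_ca, 0.01, 1500.0)[5000:]
    mean_th, var_th = calcium_equilibrium_stats(nu, cv, tau_ca)
    n_eff = 1450.0 / tau_ca
    assert phi.mean() == pytest.approx(mean_th,
                                       abs=4 * np.sqrt(var_th / n_eff))
    assert phi.var() == pytest.approx(var_th, rel=0.2)


def test_filtered_gamma_fits_calcium_better_than_poisson():
    """Gaussian with the Campbell variance of the cv=0.7 train has higher
    likelihood on the empirical calcium samples than the Poisson (cv=1)
    variance."""
    rng = np.random.default_rng(4)
    nu, cv, tau_ca = 8.0, 0.7, 2.0
    rec = gamma_spike_train(nu, cv, 2000.0, rng)
    phi = calcium_trace(rec, tau_ca, 0.05, 2000.0)[1000:]
    sub = phi[:: int(tau_ca / 0.05)]      # ~decorrelated samples
    ll_gamma = stats.norm.logpdf(
        sub, *_norm_params(nu, cv, tau_ca)).sum()
    ll_poisson = stats.norm.logpdf(
        sub, *_norm_params(nu, 1.0, tau_ca)).sum()
    assert ll_gamma > ll_poisson


def _norm_params(nu, cv, tau_ca):
    mean, var = calcium_equilibrium_stats(nu, cv, tau_ca)
    return mean, np.sqrt(var)


def test_gamma_train_input_validation():
    rng = np.random.default_rng(0)
    with pytest.raises(ProtocolError):
        gamma_spike_train(0.0, 0.7, 1.0, rng)
    with pytest.raises(ProtocolError):
        gamma_spike_train(10.0, 2.0, 1.0, rng)


# ----------------------------------------------------------------------
# engram probing on the scaled network
# ----------------------------------------------------------------------

def test_repeated_stimulation_strengthens_engram(engram_scaled):
    _, _, res = engram_scaled
    ends = res.cycle_end_connectivity
    assert np.all(np.diff(ends) > 0)          # strictly increasing
    assert ends[-1] > res.block_means["E2-E2"][-1]


def test_meanfield_surrogate_matches_spiking_trend(engram_scaled):
    """The scaled population model driven by the same protocol shows the
    same qualitative behavior: growing within-engram connectivity at the
    expense of cross connectivity, fixed in-degree."""
    from engramnet.meanfield import PopulationModel, integrate_model
    m = PopulationModel(sizes_e=np.array([100.0, 900.0]), N_I=250,
                        K_I=124, K_IE=100, tau_ca_s=1.0, beta_a=0.4,
                        beta_d=0.4)
    eps = []
    for _ in range(4):
        eps.append((15.0, np.array([1.1, 1.0])))
        eps.append((15.0, np.array([1.0, 1.0])))
    tr = integrate_model(m, eps)
    assert tr.C[-1, 0, 0] > tr.C[0, 0, 0]
    assert tr.C[-1, 0, 1] < tr.C[0, 0, 1]
    _, engram, res = engram_scaled
    assert res.block_means["E1-E1"][-1] > res.block_means["E1-E2"][-1]


def test_pattern_completion_recruits_unstimulated_members(engram_scaled):
    """Stimulating half of a strong engram raises the firing rate of the
    non-stimulated engram members above the non-engram population."""
    net0, engram, _ = engram_scaled
    net = net0.clone()
    rng = np.random.default_rng(8)
    half = rng.choice(engram, size=50, replace=False)
    othere = np.setdiff1d(np.arange(net.conn.N_E), engram)
    nonstim = np.setdiff1d(engram, half)
    mult = np.ones(net.conn.N)
    # the down-scaled network has ~8x weaker recurrent gain than the
    # full-scale one, so the probe stimulus is stronger to compensate
    mult[half] = 1.3
    rec = net.run_interval(10_000.0, multipliers=mult)
    r_nonstim = np.isin(rec.ids, nonstim).sum() / nonstim.size
    r_other = np.isin(rec.ids, othere).sum() / othere.size
    assert r_nonstim > 1.1 * r_other


def test_pattern_completion_curve_above_unstructured(grown_scaled,
                                                     engram_scaled):
    """The overlap-vs-stimulated-fraction curve of an encoded engram lies
    above the same curve of the unstructured grown network."""
    net_eng, engram, _ = engram_scaled
    fractions = [0.5, 0.8]
    rng = np.random.default_rng(9)
    curve_eng = pattern_completion_curve(net_eng.clone(), engram, fractions,
                                         rng, stim_amp=1.3, stim_s=5.0,
                                         n_draws=5)
    net_flat = grown_scaled.net.clone()
    from dataclasses import replace
    net_flat.plasticity = replace(net_flat.plasticity, frozen=True)
    rng = np.random.default_rng(9)
    curve_flat = pattern_completion_curve(net_flat, engram, fractions, rng,
                                          stim_amp=1.3, stim_s=5.0,
                                          n_draws=5)
    assert np.all(curve_eng > curve_flat)
    assert curve_eng[1] > curve_eng[0]
    with pytest.raises(ProtocolError):
        pattern_completion_curve(net_eng.clone(), engram, [1.5], rng)


def test_readout_prefers_encoded_engram_population_model():
    """A readout sampling 9% of all E and I neurons fires more during
    stimulation of an encoded engram than of a size-matched random
    ensemble, and more for stronger engrams.

    In the balanced network the *mean* recurrent input of such a sample
    is nearly invariant (the inhibitory population tracks total
    excitation), so the discrimination is carried by the input variance,
    which grows with the stimulated members' firing rates.  This is a
    full-scale effect; evaluated with the population model and the
    Siegert rate of the sampled input moments.
    """
    from engramnet.meanfield import (PopulationModel, equilibrium_state,
                                     integrate_model, siegert_rate)
    from engramnet.network import LIFParams
    lif = LIFParams()
    tau, J, g = lif.tau_m * 1e-3, lif.J, lif.g
    frac = 0.09
    N1, N2, NI = 1000.0, 9000.0, 2500.0

    def readout_rate(c11):
        # stationary rates during 1.1x stimulation of the first ensemble
        # (plasticity effectively frozen via huge growth parameters)
        m = PopulationModel(sizes_e=np.array([N1, N2]), N_I=int(NI),
                            beta_a=1e12, beta_d=1e12)
        st = equilibrium_state(m)
        K = st.C[0, 0] * m.N_E
        c12 = (K - c11 * N1) / N2
        c22 = (K / N2 - (N1 / N2) * (K / N2)) + c11 * (N1 / N2) ** 2
        st.C = np.array([[c11, c12], [c12, c22]])
        r = integrate_model(m, [(5.0, np.array([1.1, 1.0]))],
                            state=st).r[-1]
        mu = tau * (J * frac * (N1 * r[0] + N2 * r[1])
                    - g * J * frac * NI * r[2] + J * lif.nu_ext)
        s2 = tau * (J ** 2 * frac * (N1 * r[0] + N2 * r[1])
                    + g ** 2 * J ** 2 * frac * NI * r[2]
                    + J ** 2 * lif.nu_ext)
        return siegert_rate(mu, np.sqrt(s2), lif), mu

    r_random, mu_random = readout_rate(0.10)   # unstructured ensemble
    r_weak, _ = readout_rate(0.17)
    r_strong, mu_strong = readout_rate(0.21)
    assert r_strong > r_weak > r_random
    # the mean-input cancellation that makes this a variance effect
    assert abs(mu_strong - mu_random) < 0.1


def test_attached_readout_fires_at_predicted_rate(grown_scaled):
    """The spiking readout wired by `attach_readout` fires at the Siegert
    rate of its sampled input moments (sanity of weights and signs)."""
    net = grown_scaled.net.clone()
    from dataclasses import replace
    from engramnet.meanfield import siegert_rate
    net.plasticity = replace(net.plasticity, frozen=True)
    rng = np.random.default_rng(12)
    attach_readout(net, 0.09, rng, weight_mv=0.1)
    ridx = net.conn.N - 1
    lif = net.lif
    tau = lif.tau_m * 1e-3
    n_e, n_i = 90, 23       # 9% of 1000 E and of 250 I
    mu = tau * (lif.J * n_e * 8.0 - lif.g * lif.J * n_i * 8.0
                + lif.J * lif.nu_ext)
    s2 = tau * (lif.J ** 2 * n_e * 8.0 + lif.g ** 2 * lif.J ** 2 * n_i * 8.0
                + lif.J ** 2 * lif.nu_ext)
    pred = siegert_rate(mu, np.sqrt(s2), lif)
    c0 = int(net.counts[ridx])
    net.run_interval(20_000.0, record_spikes=False)
    emp = (int(net.counts[ridx]) - c0) / 20.0
    assert emp == pytest.approx(pred, rel=0.15)


def test_readout_silent_without_inputs(grown_scaled):
    net = grown_scaled.net.clone()
    from dataclasses import replace
    net.plasticity = replace(net.plasticity, frozen=True)
    ridx = net.conn.N - 1
    net.conn.W[:, ridx] = 0
    mult = np.ones(net.conn.N)
    mult[ridx] = 0.0
    c0 = int(net.counts[ridx])
    net.run_interval(2000.0, multipliers=mult, record_spikes=False)
    assert int(net.counts[ridx]) == c0
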