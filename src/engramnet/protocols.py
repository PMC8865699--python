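"""Stimulation experiments and analysis statistics.

Implements the standard experiment battery on top of the spiking simulator:
growing a network to its homeostatic equilibrium, classical conditioning
with paired ensembles (US, C1, C2) and a readout neuron, repeated
stimulation of a single ensemble to form an engram, pattern-completion
probing of a frozen engram, plus the supporting statistics (pattern
overlap, population rate, exponential decay fit) and the renewal-process
generators used by the spiking-noise theory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .network import (LIFParams, SpikeRecord, SpikingNetwork,
                      build_static_network)
from .plasticity import PlasticityParams, PlasticRunResult, plastic_run

__all__ = [
    "StimulusProtocol",
    "Pattern",
    "sample_ensembles",
    "grow_network",
    "GrowthResult",
    "conditioning_experiment",
    "ConditioningConfig",
    "ConditioningResult",
    "repeated_stimulation",
    "RepeatedStimulationResult",
    "attach_readout",
    "overlap",
    "population_rate",
    "pattern_completion_curve",
    "decay_time_constant",
    "gamma_spike_train",
    "calcium_equilibrium_stats",
    "calcium_trace",
]


class ProtocolError(ValueError):
    pass


@dataclass
class StimulusProtocol:
    """Timed episodes of per-ensemble external-rate multipliers.

    ``episodes`` is an ordered list of ``(duration_s, {ensemble label:
    multiplier})``; unlisted ensembles run at baseline (multiplier 1).
    Ensembles are named, pairwise disjoint index sets of excitatory
    neurons.  A protocol is pure data: replaying it with identical seeds
    is bit-reproducible.
    """

    episodes: List[Tuple[float, Dict[str, float]]]
    ensembles: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ensembles = {k: np.asarray(v, dtype=np.int64)
                          for k, v in self.ensembles.items()}
        seen: set = set()
        for label, idx in self.ensembles.items():
            s = set(idx.tolist())
            if seen & s:
                raise ProtocolError(f"ensemble {label!r} overlaps another")
            seen |= s
        for dur, stim in self.episodes:
            if dur <= 0:
                raise ProtocolError("episode durations must be positive")
            for label, m in stim.items():
                if label not in self.ensembles:
                    raise ProtocolError(f"unknown ensemble {label!r}")
                if m < 0:
                    raise ProtocolError("multipliers must be >= 0")

    def multipliers(self, stim: Dict[str, float], N: int) -> np.ndarray:
        mult = np.ones(N)
        for label, m in stim.items():
            mult[self.ensembles[label]] = m
        return mult


@dataclass
class Pattern:
    """Binary ensemble-membership vector with sparseness ``a``."""

    xi: np.ndarray

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi).astype(bool)

    @property
    def a(self) -> float:
        return float(self.xi.mean())

    @classmethod
    def from_indices(cls, indices: np.ndarray, n: int) -> "Pattern":
        xi = np.zeros(n, dtype=bool)
        xi[np.asarray(indices)] = True
        return cls(xi)


def sample_ensembles(N_E: int, fractions: Dict[str, float],
                     rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Disjoint random ensembles of excitatory neurons (without
    replacement across all ensembles)."""
    total = int(sum(round(f * N_E) for f in fractions.values()))
    if total > N_E:
        raise ProtocolError("ensemble fractions exceed the population")
    pool = rng.permutation(N_E)
    out, k = {}, 0
    for label, f in fractions.items():
        n = int(round(f * N_E))
        out[label] = np.sort(pool[k:k + n])
        k += n
    return out


# ----------------------------------------------------------------------
# growing a network
# ----------------------------------------------------------------------

@dataclass
class GrowthResult:
    net: SpikingNetwork
    history: PlasticRunResult
    converged: bool


#: static in-degrees of the down-scaled (N_E=1000, N_I=250) reference
#: network.  Plain 0.1-fraction scaling would leave inhibition too weak to
#: pull the zero-EE firing rate below the 8 Hz target (no homeostatic
#: equilibrium exists); raising the inhibitory in-degree to 124 contacts
#: restores the full-scale operating point (equilibrium EE in-degree ~100,
#: i.e. connectivity ~0.1, r_I ~ 8 Hz).  See docs/methods.md.
SCALED_K_INH = 124
SCALED_K_EXC = 100


def grow_network(N_E: int = 1000, N_I: int = 250,
                 lif: Optional[LIFParams] = None,
                 plast: Optional[PlasticityParams] = None,
                 t_growth_s: float = 100.0, seed: int = 1,
                 n_extra: int = 0, record_every_s: float = 1.0,
                 rate_tol: float = 0.05,
                 k_inh: Optional[int] = None,
                 k_exc: Optional[int] = None) -> GrowthResult:
    """Grow the EE block from scratch under baseline drive.

    Starts from random static I-involving wiring and an empty EE block and
    runs the plastic network until ``t_growth_s``.  Convergence is judged
    by the mean excitatory calcium trace (the rate estimate the controller
    itself uses) landing within ``rate_tol`` of the target rate; failure
    is reported via ``converged`` together with the full trajectory.
    """
    lif = lif or LIFParams()
    plast = plast or PlasticityParams()
    if k_inh is None and (N_E, N_I) == (1000, 250):
        k_inh, k_exc = SCALED_K_INH, SCALED_K_EXC
    conn = build_static_network(N_E, N_I, lif, seed, n_extra=n_extra,
                                k_inh=k_inh, k_exc=k_exc)
    net = SpikingNetwork(conn, lif, plast, drive_seed=seed + 1,
                         rewire_seed=seed + 2, init_seed=seed + 3)
    history = plastic_run(net, t_growth_s * 1000.0,
                          record_every_s=record_every_s)
    nu = plast.nu_target_hz
    converged = bool(t_growth_s > 0 and history.phi_hz.size
                     and abs(history.phi_hz[-1] - nu) <= rate_tol * nu)
    if not converged:
        warnings.warn("growth did not converge to the target rate; "
                      "inspect GrowthResult.history")
    return GrowthResult(net, history, converged)


# ----------------------------------------------------------------------
# conditioning
# ----------------------------------------------------------------------

@dataclass
class ConditioningConfig:
    """Classical-conditioning protocol (growth, baseline, encoding,
    decay, retrieval) with three disjoint 10% ensembles and a readout
    neuron statically wired from the US ensemble."""

    N_E: int = 1000
    N_I: int = 250
    lif: LIFParams = field(default_factory=LIFParams)
    plast: PlasticityParams = field(default_factory=lambda: PlasticityParams(
        tau_ca_s=1.0, beta_a=0.4, beta_d=0.4, delta_t_s_ms=10.0))
    t_growth_s: float = 100.0
    stim_s: float = 2.0
    relax_s: float = 48.0
    decay_s: float = 100.0
    stim_amp: float = 1.4
    ensemble_fraction: float = 0.1
    n_encoding_cycles: int = 6
    readout_weight_mv: float = 0.1   # per-US-neuron weight onto the readout
    record_every_s: float = 1.0
    seed: int = 1
    k_inh: Optional[int] = None      # static in-degrees (None: size-based)
    k_exc: Optional[int] = None


@dataclass
class ConditioningResult:
    ensembles: Dict[str, np.ndarray]
    protocol: StimulusProtocol
    block_means: Dict[str, np.ndarray]   # per episode-concatenated series
    time_s: np.ndarray
    episode_bounds: Dict[str, Tuple[float, float]]
    readout_rates: Dict[str, float]      # readout rate during each stim event
    growth: GrowthResult


def _conditioning_schedule(cfg: ConditioningConfig):
    """(label, duration_s, stim dict) tuples after growth."""
    ep = []
    for who in ("US", "C1", "C2"):       # baseline: each alone, once
        ep.append((f"baseline-{who}", cfg.stim_s, {who: cfg.stim_amp}))
        ep.append((f"baseline-{who}-relax", cfg.relax_s, {}))
    for k in range(cfg.n_encoding_cycles):
        if k % 2 == 0:                   # US+C1 paired, alternating with C2
            ep.append((f"encode-{k}-USC1", cfg.stim_s,
                       {"US": cfg.stim_amp, "C1": cfg.stim_amp}))
        else:
            ep.append((f"encode-{k}-C2", cfg.stim_s, {"C2": cfg.stim_amp}))
        ep.append((f"encode-{k}-relax", cfg.relax_s, {}))
    ep.append(("decay", cfg.decay_s, {}))
    for who in ("C1", "C2"):             # retrieval: each alone
        ep.append((f"retrieval-{who}", cfg.stim_s, {who: cfg.stim_amp}))
        ep.append((f"retrieval-{who}-relax", cfg.relax_s, {}))
    return ep


def conditioning_experiment(cfg: ConditioningConfig) -> ConditioningResult:
    """Run the full conditioning paradigm on a plastic network.

    Stimulation raises the external rate of an ensemble by ``stim_amp``
    for ``stim_s`` seconds followed by ``relax_s`` of baseline.  During
    encoding, US and C1 are always stimulated together while C2 is always
    stimulated alone.  Block connectivity means are recorded continuously;
    the readout neuron's firing rate is measured during every stimulation
    window.
    """
    growth = grow_network(cfg.N_E, cfg.N_I, cfg.lif, cfg.plast,
                          cfg.t_growth_s, cfg.seed, n_extra=1,
                          record_every_s=cfg.record_every_s,
                          k_inh=cfg.k_inh, k_exc=cfg.k_exc)
    net = growth.net
    rng = np.random.default_rng(cfg.seed + 10)
    ens = sample_ensembles(cfg.N_E, {k: cfg.ensemble_fraction
                                     for k in ("US", "C1", "C2")}, rng)
    rest = np.setdiff1d(np.arange(cfg.N_E), np.concatenate(list(ens.values())))
    blocks = dict(ens)
    blocks["bg"] = rest

    # readout neuron: static contacts from every US neuron
    readout = net.conn.N - 1
    k_contacts = max(1, int(round(cfg.readout_weight_mv / cfg.lif.J)))
    net.conn.W[ens["US"], readout] = k_contacts

    schedule = _conditioning_schedule(cfg)
    proto = StimulusProtocol(
        episodes=[(d, s) for _, d, s in schedule], ensembles=ens)

    times, series = [], {f"{a}-{b}": [] for a in blocks for b in blocks}
    bounds: Dict[str, Tuple[float, float]] = {}
    readout_rates: Dict[str, float] = {}
    t0 = net.time_ms / 1000.0
    for label, dur, stim in schedule:
        mult = proto.multipliers(stim, net.conn.N)
        mult[readout] = 0.0              # readout: no external drive
        start = net.time_ms / 1000.0
        c0 = int(net.counts[readout])
        res = plastic_run(net, dur * 1000.0, multipliers=mult,
                          ensembles=blocks,
                          record_every_s=min(cfg.record_every_s, dur))
        bounds[label] = (start - t0, start - t0 + dur)
        if stim:
            readout_rates[label] = (int(net.counts[readout]) - c0) / dur
        times.append(res.time_s + (start - t0))
        for key, vals in res.block_means.items():
            series[key].append(vals)
    return ConditioningResult(
        ensembles=ens, protocol=proto,
        block_means={k: np.concatenate(v) for k, v in series.items()},
        time_s=np.concatenate(times), episode_bounds=bounds,
        readout_rates=readout_rates, growth=growth)


# ----------------------------------------------------------------------
# repeated stimulation (engram formation)
# ----------------------------------------------------------------------

@dataclass
class RepeatedStimulationResult:
    engram: np.ndarray
    time_s: np.ndarray
    block_means: Dict[str, np.ndarray]
    cycle_end_connectivity: np.ndarray   # within-engram mean after each cycle


def repeated_stimulation(net: SpikingNetwork, engram: np.ndarray,
                         n_cycles: int = 8, stim_s: float = 150.0,
                         relax_s: float = 150.0, amp: float = 1.05,
                         record_every_s: float = 15.0,
                         freeze_after: bool = True) -> RepeatedStimulationResult:
    """Repeatedly stimulate one ensemble of a grown network.

    Each cycle raises the ensemble's external rate to ``amp * nu_ext``
    for ``stim_s`` followed by ``relax_s`` at baseline.  Connectivity
    block means are recorded every ``record_every_s``; plasticity is
    optionally frozen afterwards for non-plastic probing.
    """
    engram = np.asarray(engram, dtype=np.int64)
    rest = np.setdiff1d(np.arange(net.conn.N_E), engram)
    blocks = {"E1": engram, "E2": rest}
    mult_on = np.ones(net.conn.N)
    mult_on[engram] = amp
    times, series = [], {k: [] for k in
                         ("E1-E1", "E1-E2", "E2-E1", "E2-E2")}
    ends = []
    t0 = net.time_ms / 1000.0
    for _ in range(n_cycles):
        for mult, dur in ((mult_on, stim_s), (None, relax_s)):
            start = net.time_ms / 1000.0 - t0
            res = plastic_run(net, dur * 1000.0, multipliers=mult,
                              ensembles=blocks,
                              record_every_s=record_every_s)
            times.append(res.time_s + start)
            for k in series:
                series[k].append(res.block_means[k])
        ends.append(net.conn.block_mean(post=engram, pre=engram))
    if freeze_after and net.plasticity is not None:
        from dataclasses import replace
        net.plasticity = replace(net.plasticity, frozen=True)
    return RepeatedStimulationResult(
        engram, np.concatenate(times),
        {k: np.concatenate(v) for k, v in series.items()}, np.array(ends))


def attach_readout(net: SpikingNetwork, sample_fraction: float,
                   rng: np.random.Generator,
                   weight_mv: Optional[float] = None) -> np.ndarray:
    """Wire the spare readout neuron from a random sample of the network.

    The readout (last neuron, created with ``n_extra=1``) receives static
    contacts from ``sample_fraction`` of all excitatory and the same
    fraction of all inhibitory neurons; excitatory sampled contacts have
    weight ``+weight_mv`` and inhibitory ones ``-g*weight_mv``.  It does
    not project back into the network.  Returns the sampled indices.
    """
    if not 0 <= sample_fraction <= 1:
        raise ProtocolError("sample fraction must be in [0, 1]")
    if net.conn.n_extra < 1:
        raise ProtocolError("network was built without a readout slot")
    if weight_mv is None:
        weight_mv = net.lif.J
    k = max(1, int(round(weight_mv / net.lif.J)))
    readout = net.conn.N - 1
    N_E, N_I = net.conn.N_E, net.conn.N_I
    ne = int(round(sample_fraction * N_E))
    ni = int(round(sample_fraction * N_I))
    src_e = rng.choice(N_E, size=ne, replace=False)
    src_i = N_E + rng.choice(N_I, size=ni, replace=False)
    net.conn.W[:, readout] = 0
    net.conn.W[src_e, readout] = k
    net.conn.W[src_i, readout] = k     # inhibitory weight sign set by w_pre
    return np.concatenate([src_e, src_i])


# ----------------------------------------------------------------------
# statistics
# ----------------------------------------------------------------------

def overlap(pattern: Pattern, spikes: SpikeRecord, bin_ms: float = 10.0,
            t0_ms: float = 0.0, t1_ms: Optional[float] = None):
    """Overlap time series of binned binary activity with a pattern.

    ``s_i(t) = 1`` iff neuron ``i`` spiked in the bin;
    ``m(t) = [N a (1-a)]^-1 sum_i (xi_i - a) s_i(t)``.  The overlap is 1
    when exactly the pattern is active, 0 in expectation for activity
    independent of the pattern.
    """
    if bin_ms <= 0:
        raise ProtocolError("bin size must be positive")
    a = pattern.a
    if a <= 0.0 or a >= 1.0:
        raise ProtocolError("overlap undefined for empty or full patterns")
    N = pattern.xi.size
    if t1_ms is None:
        t1_ms = float(spikes.times_ms.max()) + bin_ms if len(spikes) else bin_ms
    edges = np.arange(t0_ms, t1_ms + bin_ms, bin_ms)
    n_bins = edges.size - 1
    m = np.empty(n_bins)
    sel = (spikes.times_ms >= t0_ms) & (spikes.times_ms < edges[-1])
    tb = np.floor((spikes.times_ms[sel] - t0_ms) / bin_ms).astype(np.int64)
    ids = spikes.ids[sel]
    norm = 1.0 / (N * a * (1.0 - a))
    xi = pattern.xi
    for b in range(n_bins):
        active = np.unique(ids[tb == b])
        active = active[active < N]
        s_sum = active.size
        s_in = xi[active].sum()
        m[b] = norm * (s_in - a * s_sum)
    centers = edges[:-1] + bin_ms / 2.0
    return centers, m


def population_rate(spikes: SpikeRecord, n_neurons: int, t0_ms: float,
                    t1_ms: float, bin_ms: float = 100.0):
    """Binned population rate (spikes/s); integrates exactly to the
    total spike count in the window."""
    edges = np.arange(t0_ms, t1_ms + bin_ms, bin_ms)
    sel = (spikes.times_ms >= t0_ms) & (spikes.times_ms < edges[-1])
    counts, _ = np.histogram(spikes.times_ms[sel], bins=edges)
    rate = counts / n_neurons / (bin_ms * 1e-3)
    return edges[:-1] + bin_ms / 2.0, rate


def pattern_completion_curve(net: SpikingNetwork, engram: np.ndarray,
                             fractions: Sequence[float],
                             rng: np.random.Generator,
                             stim_amp: float = 1.1, stim_s: float = 10.0,
                             n_draws: int = 50, bin_ms: float = 10.0,
                             discard_ms: float = 500.0) -> np.ndarray:
    """Mean engram overlap under partial stimulation (frozen network).

    For each fraction, ``n_draws`` random subsets of the engram are
    stimulated for ``stim_s`` and the overlap with the full engram is
    averaged over the window (discarding the onset transient).
    """
    if net.plasticity is not None and not net.plasticity.frozen:
        raise ProtocolError("pattern completion requires frozen plasticity")
    engram = np.asarray(engram, dtype=np.int64)
    pat = Pattern.from_indices(engram, net.conn.N_E)
    out = np.empty(len(fractions))
    for j, f in enumerate(fractions):
        if not 0 <= f <= 1:
            raise ProtocolError("fractions must lie in [0, 1]")
        vals = []
        for _ in range(n_draws):
            n_stim = int(round(f * engram.size))
            mult = np.ones(net.conn.N)
            if n_stim:
                subset = rng.choice(engram, size=n_stim, replace=False)
                mult[subset] = stim_amp
            t_start = net.time_ms
            rec = net.run_interval(stim_s * 1000.0, multipliers=mult)
            _, m = overlap(pat, rec, bin_ms,
                           t0_ms=t_start + discard_ms,
                           t1_ms=t_start + stim_s * 1000.0)
            vals.append(m.mean())
        out[j] = np.mean(vals)
    return out


class FitError(RuntimeError):
    pass


def decay_time_constant(time_s: np.ndarray, values: np.ndarray) -> float:
    """Exponential time constant of a post-overshoot connectivity decay.

    Fits ``C(t) = C_inf + A exp(-t/tau)`` by least squares from the
    series maximum onward.  Initialization: ``C_inf`` from the final 10%
    of the series, ``A`` and ``tau`` from a log-linear regression of the
    residual; refined by Levenberg-Marquardt.
    """
    time_s = np.asarray(time_s, float)
    values = np.asarray(values, float)
    i0 = int(np.argmax(values))
    t = time_s[i0:] - time_s[i0]
    v = values[i0:]
    if t.size < 4 or v[-1] >= v[0]:
        raise FitError("series does not decay after its maximum")
    c_inf0 = float(v[int(0.9 * v.size):].mean())
    resid = v - c_inf0
    pos = resid > 0
    if pos.sum() >= 2:
        slope, icpt = np.polyfit(t[pos], np.log(resid[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0])
        A0 = float(np.exp(icpt))
    else:
        tau0, A0 = t[-1] / 2.0, float(v[0] - c_inf0)
    try:
        p, _ = curve_fit(lambda t, ci, A, tau: ci + A * np.exp(-t / tau),
                         t, v, p0=[c_inf0, A0, max(tau0, 1e-6)],
                         maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"exponential fit failed: {exc}") from exc
    if p[2] <= 0:
        raise FitError("fitted time constant is not positive")
    return float(p[2])


# ----------------------------------------------------------------------
# renewal processes and calcium shot noise
# ----------------------------------------------------------------------

def gamma_spike_train(rate_hz: float, cv: float, duration_s: float,
                      rng: np.random.Generator,
                      neuron_id: int = 0) -> SpikeRecord:
    """Renewal spike train with Gamma-distributed ISIs.

    Shape ``alpha = 1/cv^2`` and mean ISI ``1/rate``; ``cv = 1`` recovers
    a Poisson process.  Used to emulate spike trains of a given rate and
    irregularity.
    """
    if rate_hz <= 0:
        raise ProtocolError("rate must be positive")
    if not 0 < cv <= 1.5:
        raise ProtocolError("cv must lie in (0, 1.5]")
    alpha = 1.0 / cv ** 2
    scale = cv ** 2 / rate_hz
    n = int(duration_s * rate_hz * 1.25) + 50
    t = np.cumsum(rng.gamma(alpha, scale, size=n))
    while t.size and t[-1] < duration_s:
        t = np.concatenate([t, t[-1] + np.cumsum(
            rng.gamma(alpha, scale, size=n))])
    t = t[t < duration_s]
    return SpikeRecord(t * 1000.0, np.full(t.size, neuron_id, dtype=np.int64))


def calcium_equilibrium_stats(rate_hz: float, cv: float,
                              tau_ca_s: float) -> Tuple[float, float]:
    """Stationary mean and variance of the filtered calcium trace.

    Campbell's theorem for the exponentially filtered renewal train:
    mean ``nu``, variance ``cv^2 * nu / (2 tau_Ca)``.
    """
    return rate_hz, cv ** 2 * rate_hz / (2.0 * tau_ca_s)


def calcium_trace(spikes: SpikeRecord, tau_ca_s: float, dt_s: float,
                  duration_s: float) -> np.ndarray:
    """Exponentially filtered spike train sampled on a regular grid."""
    n = int(round(duration_s / dt_s))
    phi = np.zeros(n)
    dec = np.exp(-dt_s / tau_ca_s)
    counts, _ = np.histogram(spikes.times_ms * 1e-3,
                             bins=np.arange(n + 1) * dt_s)
    x = 0.0
    for k in range(n):
        x = x * dec + counts[k] / tau_ca_s
        phi[k] = x
    return phi
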