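"""Clock-driven simulator of a current-based LIF network with delta synapses.

The network follows the classical sparse balanced-random-network setup:
``N_E`` excitatory and ``N_I`` inhibitory leaky integrate-and-fire neurons,
delayed delta-pulse synapses whose efficacy is ``J`` (excitatory source) or
``-g*J`` (inhibitory source) per synaptic contact, and independent external
Poisson drive of rate ``nu_ext`` to every neuron.  Synapses are counted as
integer contact numbers ``C_ij`` (multapses allowed), so a single presynaptic
spike deflects the postsynaptic membrane by ``C_ij * J`` after the delay.

Connections to and from inhibitory neurons are static with fixed in-degrees
(0.1 of the source population); the excitatory-to-excitatory block starts
empty and is rewired by the homeostatic structural-plasticity rule in
:mod:`engramnet.plasticity`.

Integration is exact for the leak between spike arrivals (exponential
propagator) because synapses are delta pulses aligned to the grid.  All
threshold crossings within one time step are processed simultaneously; the
synaptic delay makes the outcome independent of processing order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "LIFParams",
    "ConnectivityMatrix",
    "SpikeRecord",
    "NeuronState",
    "SpikingNetwork",
    "build_static_network",
    "DEFAULT_DT_MS",
]

#: default integration step (ms); divides the synaptic delay exactly
DEFAULT_DT_MS = 0.1


def _log_factorial(k: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln
    return gammaln(np.asarray(k, float) + 1.0)


class ConfigurationError(ValueError):
    """Raised for invalid network or protocol configurations."""


@dataclass(frozen=True)
class LIFParams:
    """Single-neuron and coupling parameters of the LIF network.

    Voltages are relative to the resting potential (mV), times in ms,
    rates in spikes/s.  ``tau_m`` is not fixed by the model definition and
    defaults to 20 ms, a standard value for this class of balanced networks.
    """

    tau_m: float = 20.0       # membrane time constant (ms)
    V_th: float = 20.0        # spike threshold (mV)
    V_r: float = 10.0         # reset potential (mV)
    t_ref: float = 2.0        # absolute refractory period (ms)
    D: float = 1.5            # synaptic transmission delay (ms)
    J: float = 0.1            # EPSP amplitude per contact (mV)
    g: float = 8.0            # relative strength of inhibition
    nu_ext: float = 15000.0   # external Poisson rate (spikes/s)

    def __post_init__(self) -> None:
        if not (self.V_th > self.V_r):
            raise ConfigurationError("V_th must exceed V_r")
        if self.t_ref < 0 or self.D <= 0 or self.J <= 0 or self.g <= 0:
            raise ConfigurationError("t_ref >= 0 and D, J, g > 0 required")
        if self.tau_m <= 0 or self.nu_ext < 0:
            raise ConfigurationError("tau_m > 0 and nu_ext >= 0 required")


class ConnectivityMatrix:
    """Integer synaptic-contact counts for the whole network.

    The canonical storage is ``W[j, i]`` = number of contacts from
    presynaptic neuron ``j`` onto postsynaptic neuron ``i`` (row-contiguous
    per presynaptic neuron, which makes spike delivery cache friendly).
    The conventional post-by-pre matrix ``C_ij`` is exposed as the
    :attr:`counts` view.

    Neuron indices: ``0..N_E-1`` excitatory, ``N_E..N_E+N_I-1`` inhibitory,
    optionally followed by extra read-only neurons (e.g. readout units) that
    receive input but project nowhere.
    """

    def __init__(self, N_E: int, N_I: int, n_extra: int = 0,
                 W: Optional[np.ndarray] = None):
        if N_E <= 0 or N_I <= 0:
            raise ConfigurationError("population sizes must be positive")
        self.N_E = int(N_E)
        self.N_I = int(N_I)
        self.n_extra = int(n_extra)
        N = self.N_E + self.N_I + self.n_extra
        if W is None:
            W = np.zeros((N, N), dtype=np.int32)
        if W.shape != (N, N):
            raise ConfigurationError("connectivity array has wrong shape")
        self.W = np.ascontiguousarray(W, dtype=np.int32)

    # -- views ---------------------------------------------------------
    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def counts(self) -> np.ndarray:
        """Contacts ``C[i, j]`` from presynaptic j to postsynaptic i (view)."""
        return self.W.T

    @property
    def ee(self) -> np.ndarray:
        """Plastic EE block in pre-by-post layout ``W[j, i]`` (view)."""
        return self.W[: self.N_E, : self.N_E]

    def in_degrees(self) -> np.ndarray:
        """Total synaptic in-degree ``K_in_i`` of every neuron."""
        return self.W.sum(axis=0)

    def out_degrees(self) -> np.ndarray:
        """Total synaptic out-degree ``K_out_j`` of every neuron."""
        return self.W.sum(axis=1)

    def ee_in_degrees(self) -> np.ndarray:
        return self.ee.sum(axis=0)

    def ee_out_degrees(self) -> np.ndarray:
        return self.ee.sum(axis=1)

    def block_mean(self, post: np.ndarray, pre: np.ndarray) -> float:
        """Mean contact count over an ordered (post, pre) index block."""
        return float(self.W[np.ix_(np.asarray(pre), np.asarray(post))].mean())

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(self.N_E, self.N_I, self.n_extra, self.W.copy())


def build_static_network(N_E: int, N_I: int, params: LIFParams, seed: int,
                         n_extra: int = 0,
                         k_inh: Optional[int] = None,
                         k_exc: Optional[int] = None) -> ConnectivityMatrix:
    """Construct the static (I-involving) wiring; the EE block stays empty.

    Each inhibitory neuron receives ``k_inh`` inhibitory and ``k_exc``
    excitatory contacts, each excitatory neuron receives ``k_inh``
    inhibitory contacts; the defaults are ``floor(0.1*N_I)`` and
    ``floor(0.1*N_E)``.  (Down-scaled presets raise ``k_inh`` to keep the
    full-scale operating point; see the methods note.)  Presynaptic
    partners are drawn uniformly with replacement (multapses allowed),
    self-connections excluded.
    """
    conn = ConnectivityMatrix(N_E, N_I, n_extra=n_extra)
    rng = np.random.default_rng(seed)
    K_I = int(0.1 * N_I) if k_inh is None else int(k_inh)
    K_E = int(0.1 * N_E) if k_exc is None else int(k_exc)
    W = conn.W
    exc = np.arange(N_E)
    inh = np.arange(N_E, N_E + N_I)

    def _wire(post: int, sources: np.ndarray, k: int) -> None:
        if k == 0:
            return
        pool = sources[sources != post]
        pres = rng.choice(pool, size=k, replace=True)
        np.add.at(W[:, post], pres, 1)

    for i in range(N_E):           # E neurons: inhibitory input only (static)
        _wire(i, inh, K_I)
    for i in inh:                  # I neurons: excitatory + inhibitory input
        _wire(i, exc, K_E)
        _wire(i, inh, K_I)
    return conn


@dataclass
class SpikeRecord:
    """Time-sorted spike events ``(neuron id, time in ms)``."""

    times_ms: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times_ms.shape != self.ids.shape:
            raise ConfigurationError("times and ids must have equal length")
        if self.times_ms.size and np.any(np.diff(self.times_ms) < 0):
            order = np.argsort(self.times_ms, kind="stable")
            self.times_ms = self.times_ms[order]
            self.ids = self.ids[order]

    def __len__(self) -> int:
        return self.times_ms.size

    def for_neuron(self, i: int) -> np.ndarray:
        return self.times_ms[self.ids == i]

    def min_isi(self) -> float:
        """Smallest inter-spike interval over all neurons (inf if none)."""
        best = np.inf
        for i in np.unique(self.ids):
            t = self.for_neuron(i)
            if t.size > 1:
                best = min(best, float(np.min(np.diff(t))))
        return best

    def rate(self, n_neurons: int, duration_ms: float) -> float:
        """Mean population firing rate (spikes/s)."""
        return len(self) / n_neurons / (duration_ms / 1000.0)

    def window(self, t0: float, t1: float) -> "SpikeRecord":
        m = (self.times_ms >= t0) & (self.times_ms < t1)
        return SpikeRecord(self.times_ms[m], self.ids[m])


@dataclass
class NeuronState:
    """Dynamic state of all neurons plus the plasticity counters."""

    V: np.ndarray          # membrane potentials (mV)
    ref: np.ndarray        # remaining refractory steps
    phi: np.ndarray        # calcium traces of excitatory neurons (spikes/s)
    a: np.ndarray          # continuous axonal-element counters (E only)
    d: np.ndarray          # continuous dendritic-element counters (E only)
    buf: np.ndarray        # delayed-input ring buffer (n_delay, N) in mV
    buf_pos: int = 0
    step: int = 0

    def copy(self) -> "NeuronState":
        return NeuronState(self.V.copy(), self.ref.copy(), self.phi.copy(),
                           self.a.copy(), self.d.copy(), self.buf.copy(),
                           self.buf_pos, self.step)


# ----------------------------------------------------------------------
# numba kernel
# ----------------------------------------------------------------------

@njit(cache=True)
def _seed_kernel_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _advance(n_steps, dt_ms, step0,
             V, ref, phi, a, d, W, w_pre,
             buf, buf_pos,
             lam_idx, lam_cdf, J,
             decay_v, V_th, V_r, n_ref,
             decay_ca, ca_jump,
             nu_target, inc_a, inc_d, grow_elements,
             N_E,
             record_spikes, spike_t, spike_id,
             counts):
    """Advance the network ``n_steps`` steps of length ``dt_ms``.

    Returns (number of recorded spikes, new buffer position).
    """
    N = V.shape[0]
    n_delay = buf.shape[0]
    sp = np.empty(N, dtype=np.int64)
    nrec = 0
    max_rec = spike_t.shape[0]
    for s in range(n_steps):
        m = 0
        for i in range(N):
            if ref[i] > 0:
                ref[i] -= 1
                buf[buf_pos, i] = 0.0
                continue
            v = V[i] * decay_v + buf[buf_pos, i]
            buf[buf_pos, i] = 0.0
            li = lam_idx[i]
            if li >= 0:
                # Poisson external events via inverse-CDF table lookup
                u = np.random.random()
                k = 0
                while u > lam_cdf[li, k]:
                    k += 1
                v += J * k
            if v >= V_th:
                sp[m] = i
                m += 1
                v = V_r
                ref[i] = n_ref
            V[i] = v
        for i in range(N_E):
            phi[i] *= decay_ca
        for k in range(m):
            j = sp[k]
            counts[j] += 1
            if j < N_E:
                phi[j] += ca_jump
            if record_spikes and nrec < max_rec:
                spike_t[nrec] = (step0 + s + 1) * dt_ms
                spike_id[nrec] = j
                nrec += 1
            wj = w_pre[j]
            for i in range(N):
                cji = W[j, i]
                if cji > 0:
                    buf[buf_pos, i] += cji * wj
        if grow_elements:
            for i in range(N_E):
                drive = nu_target - phi[i]
                a[i] += inc_a * drive
                d[i] += inc_d * drive
                if a[i] < 0.0:
                    a[i] = 0.0
                if d[i] < 0.0:
                    d[i] = 0.0
        buf_pos += 1
        if buf_pos == n_delay:
            buf_pos = 0
    return nrec, buf_pos


# ----------------------------------------------------------------------
# simulator front end
# ----------------------------------------------------------------------

class SpikingNetwork:
    """Stateful front end around the integration kernel.

    Random numbers come from three named streams: *construction* (wiring,
    handled by :func:`build_static_network`), *drive* (external Poisson
    events; ``drive_seed``) and *rewiring* (structural plasticity;
    ``rewire_seed``, consumed by :mod:`engramnet.plasticity`).
    """

    def __init__(self, conn: ConnectivityMatrix, lif: LIFParams,
                 plasticity=None, dt_ms: float = DEFAULT_DT_MS,
                 drive_seed: int = 1, rewire_seed: int = 2,
                 init_seed: int = 3):
        n_delay = lif.D / dt_ms
        if abs(n_delay - round(n_delay)) > 1e-9:
            raise ConfigurationError("dt must divide the synaptic delay D")
        if dt_ms > lif.t_ref + 1e-12:
            raise ConfigurationError("dt must not exceed t_ref")
        self.lif = lif
        self.conn = conn
        self.plasticity = plasticity
        self.dt_ms = float(dt_ms)
        self.n_delay = int(round(n_delay))
        self.drive_seed = int(drive_seed)
        self.rewire_rng = np.random.default_rng(rewire_seed)
        self._chunk_counter = 0

        N = conn.N
        rng = np.random.default_rng(init_seed)
        V0 = lif.V_r + (lif.V_th - lif.V_r) * rng.random(N)
        self.state = NeuronState(
            V=V0,
            ref=np.zeros(N, dtype=np.int64),
            phi=np.zeros(conn.N_E),
            a=np.zeros(conn.N_E),
            d=np.zeros(conn.N_E),
            buf=np.zeros((self.n_delay, N)),
        )
        self.w_pre = np.empty(N)
        self.w_pre[: conn.N_E] = lif.J
        self.w_pre[conn.N_E: conn.N_E + conn.N_I] = -lif.g * lif.J
        self.w_pre[conn.N_E + conn.N_I:] = lif.J
        self.counts = np.zeros(N, dtype=np.int64)

    # -- helpers -------------------------------------------------------
    def clone(self) -> "SpikingNetwork":
        """Independent deep copy (connectivity, state, RNG positions)."""
        import copy
        new = object.__new__(SpikingNetwork)
        new.__dict__ = {k: v for k, v in self.__dict__.items()}
        new.conn = self.conn.copy()
        new.state = self.state.copy()
        new.counts = self.counts.copy()
        new.rewire_rng = copy.deepcopy(self.rewire_rng)
        return new

    @property
    def time_ms(self) -> float:
        return self.state.step * self.dt_ms

    def _ext_lam(self, multipliers: Optional[np.ndarray]) -> np.ndarray:
        base = self.lif.nu_ext * self.dt_ms * 1e-3
        if multipliers is None:
            return np.full(self.conn.N, base)
        mult = np.asarray(multipliers, dtype=float)
        if mult.shape != (self.conn.N,):
            raise ConfigurationError("multiplier vector has wrong length")
        if np.any(mult < 0):
            raise ConfigurationError("external-rate multipliers must be >= 0")
        return base * mult

    @staticmethod
    def _poisson_tables(lam: np.ndarray):
        """Per-neuron inverse-CDF tables for the external event counts.

        The expected events per step are small (~1.5), so a cumulative
        table walked with one uniform per neuron-step samples the exact
        Poisson law far faster than generic generators.
        """
        vals, idx = np.unique(lam, return_inverse=True)
        kmax = int(max(40, 4 * lam.max() + 30))
        cdf = np.empty((vals.size, kmax))
        for r, lv in enumerate(vals):
            k = np.arange(kmax)
            logp = -lv + k * np.log(lv) - _log_factorial(k) if lv > 0 else \
                np.where(k == 0, 0.0, -np.inf)
            p = np.exp(logp)
            cdf[r] = np.minimum(np.cumsum(p), 1.0)
            cdf[r, -1] = 1.1  # sentinel: never exceeded
        lam_idx = idx.astype(np.int64)
        lam_idx[lam <= 0] = -1
        return lam_idx, cdf

    def advance(self, duration_ms: float, multipliers: Optional[np.ndarray] = None,
                record_spikes: bool = False,
                max_record: Optional[int] = None) -> SpikeRecord:
        """Advance without rewiring (calcium/elements still integrate)."""
        lif = self.lif
        st = self.state
        n_steps = int(round(duration_ms / self.dt_ms))
        if record_spikes:
            if max_record is None:
                # generous headroom: 100 Hz mean rate
                max_record = int(self.conn.N * duration_ms / 1000.0 * 100) + 64
            spike_t = np.empty(max_record)
            spike_id = np.empty(max_record, dtype=np.int64)
        else:
            spike_t = np.empty(0)
            spike_id = np.empty(0, dtype=np.int64)

        pl = self.plasticity
        grow = pl is not None and not getattr(pl, "frozen", False)
        tau_ca_ms = (pl.tau_ca_s * 1000.0) if grow else 1.0
        dt_s = self.dt_ms * 1e-3

        self._chunk_counter += 1
        _seed_kernel_rng(
            np.uint32((self.drive_seed * np.uint64(2654435761)
                       + np.uint64(self._chunk_counter)) & np.uint64(0xFFFFFFFF)))
        lam = self._ext_lam(multipliers)
        key = lam.tobytes()
        if getattr(self, "_lam_key", None) != key:
            self._lam_key = key
            self._lam_tables = self._poisson_tables(lam)
        lam_idx, lam_cdf = self._lam_tables
        nrec, pos = _advance(
            n_steps, self.dt_ms, st.step,
            st.V, st.ref, st.phi, st.a, st.d,
            self.conn.W, self.w_pre,
            st.buf, st.buf_pos,
            lam_idx, lam_cdf, lif.J,
            np.exp(-self.dt_ms / lif.tau_m), lif.V_th, lif.V_r,
            int(round(lif.t_ref / self.dt_ms)),
            np.exp(-self.dt_ms / tau_ca_ms) if grow else 1.0,
            (1.0 / pl.tau_ca_s) if grow else 0.0,
            pl.nu_target_hz if grow else 0.0,
            (dt_s / pl.beta_a) if grow else 0.0,
            (dt_s / pl.beta_d) if grow else 0.0,
            grow,
            self.conn.N_E,
            record_spikes, spike_t, spike_id,
            self.counts)
        st.buf_pos = pos
        st.step += n_steps
        return SpikeRecord(spike_t[:nrec], spike_id[:nrec])

    def step(self, multipliers: Optional[np.ndarray] = None) -> SpikeRecord:
        """Advance exactly one time step."""
        return self.advance(self.dt_ms, multipliers, record_spikes=True)

    def run_interval(self, duration_ms: float,
                     multipliers: Optional[np.ndarray] = None,
                     record_spikes: bool = True) -> SpikeRecord:
        """Run for ``duration_ms`` with a fixed per-neuron stimulus.

        ``multipliers`` scales the external Poisson rate per neuron
        (1 everywhere = baseline drive).  Structural rewiring is *not*
        performed here; use :func:`engramnet.plasticity.plastic_run` for
        plastic simulations.
        """
        return self.advance(duration_ms, multipliers, record_spikes)

    def ensemble_multipliers(self, stim: dict, ensembles: dict) -> np.ndarray:
        """Build a per-neuron multiplier vector from ensemble labels."""
        mult = np.ones(self.conn.N)
        for label, value in stim.items():
            mult[np.asarray(ensembles[label])] = value
        return mult
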