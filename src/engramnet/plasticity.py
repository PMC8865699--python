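"""Homeostatic structural plasticity of the excitatory-to-excitatory block.

Each excitatory neuron low-pass filters its own spike train into a calcium
trace ``phi_i`` (time constant ``tau_Ca``) and uses it as a firing-rate
proxy.  Deviations from the target rate ``nu`` drive continuous counters of
axonal (``a_i``) and dendritic (``d_i``) synaptic elements:

    beta_a * da_i/dt = nu - phi_i,      beta_d * dd_i/dt = nu - phi_i.

Every ``Delta_T_s`` of simulated time the discrete rewiring step runs:
neurons whose integer element count ``floor(a_i)`` (``floor(d_i)``) fell
below their out-degree (in-degree) delete the surplus outgoing (incoming)
contacts at random; deletion frees the bonded counterpart element on the
partner neuron.  All free axonal and free dendritic elements are then
randomly matched into ``n = min(|a+|, |d+|)`` new synaptic contacts
(self-connections rejected).  Contacts are counted per ordered pair, so
multapses both form and are deleted contact by contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .network import ConnectivityMatrix, SpikeRecord, SpikingNetwork

__all__ = [
    "PlasticityParams",
    "CalciumState",
    "ElementState",
    "update_calcium",
    "update_elements",
    "free_elements",
    "negative_elements",
    "rewire_step",
    "plastic_run",
    "PlasticRunResult",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Parameters of the homeostatic rewiring rule.

    ``delta_t_s_ms`` is the interval between rewiring steps; the default
    100 ms matches the standard slow-plasticity setup (protocol presets
    override it down to fractions of a millisecond where needed).
    Setting ``frozen=True`` disables the rule entirely (the beta -> inf
    limit), leaving a pure spiking simulation.
    """

    tau_ca_s: float = 10.0
    beta_a: float = 2.0
    beta_d: float = 2.0
    nu_target_hz: float = 8.0
    delta_t_s_ms: float = 100.0
    record_every_s: float = 1.0
    frozen: bool = False


@dataclass
class CalciumState:
    """Per-neuron calcium traces (spikes/s) with their filter constant."""

    phi: np.ndarray
    tau_ca_s: float = 10.0


@dataclass
class ElementState:
    """Continuous axonal/dendritic element counters of excitatory neurons."""

    a: np.ndarray
    d: np.ndarray
    beta_a: float = 2.0
    beta_d: float = 2.0
    nu_target_hz: float = 8.0


def update_calcium(state: CalciumState, spikes_in_step: np.ndarray,
                   dt_s: float) -> CalciumState:
    """Exact exponential update of the calcium trace over one step.

    ``phi <- phi * exp(-dt/tau_Ca) + (spike count)/tau_Ca``; the impulse
    response of the first-order filter integrates delta spikes exactly.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    phi = state.phi * np.exp(-dt_s / state.tau_ca_s)
    phi = phi + np.asarray(spikes_in_step) / state.tau_ca_s
    return CalciumState(phi, state.tau_ca_s)


def update_elements(elem: ElementState, cal: CalciumState,
                    dt_s: float) -> ElementState:
    """Integrate the homeostatic growth equations over ``dt`` seconds.

    Counters drift with ``(nu - phi)/beta`` and are floored at zero; they
    may drop below the current degree, in which case the rewiring step will
    delete the corresponding synapses.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    drive = elem.nu_target_hz - cal.phi
    a = np.maximum(elem.a + dt_s * drive / elem.beta_a, 0.0)
    d = np.maximum(elem.d + dt_s * drive / elem.beta_d, 0.0)
    return ElementState(a, d, elem.beta_a, elem.beta_d, elem.nu_target_hz)


def free_elements(elem: ElementState, conn: ConnectivityMatrix):
    """Free (unbonded) element counts ``a+ = [floor(a) - K_out]_+`` etc."""
    K_out = conn.ee_out_degrees()
    K_in = conn.ee_in_degrees()
    a_plus = np.maximum(np.floor(elem.a).astype(np.int64) - K_out, 0)
    d_plus = np.maximum(np.floor(elem.d).astype(np.int64) - K_in, 0)
    return a_plus, d_plus


def negative_elements(elem: ElementState, conn: ConnectivityMatrix):
    """Element deficits ``a- = [K_out - floor(a)]_+`` triggering deletion."""
    K_out = conn.ee_out_degrees()
    K_in = conn.ee_in_degrees()
    a_minus = np.maximum(K_out - np.floor(elem.a).astype(np.int64), 0)
    d_minus = np.maximum(K_in - np.floor(elem.d).astype(np.int64), 0)
    return a_minus, d_minus


def _delete_from(rng: np.random.Generator, vec: np.ndarray,
                 k: int) -> np.ndarray:
    """Delete ``k`` contacts uniformly from a contact-count vector in place.

    Every multapse contact is an independent deletion candidate.  Returns
    the partner indices of the deleted contacts (clipped to what exists).
    """
    nz = np.nonzero(vec)[0]
    if nz.size == 0 or k <= 0:
        return np.empty(0, dtype=np.int64)
    cands = np.repeat(nz, vec[nz])
    k = min(k, cands.size)
    picks = rng.choice(cands.size, size=k, replace=False)
    chosen = cands[picks]
    np.subtract.at(vec, chosen, 1)
    return chosen


def rewire_step(conn: ConnectivityMatrix, elem: ElementState,
                rng: np.random.Generator,
                max_fix_attempts: Optional[int] = None) -> Dict[str, int]:
    """One discrete rewiring event on the EE block (in place).

    Phase 1 deletes surplus bonded elements (axonal first, then dendritic;
    counterpart elements of deleted synapses become free automatically
    because free counts are recomputed from degrees).  Phase 2 matches the
    free axonal and dendritic element multisets uniformly at random without
    replacement; self-pairings are rejected and redrawn by local swaps, up
    to ``|a+|*|d+|`` attempts, after which remaining self-pairings are
    dropped.
    """
    W = conn.ee  # (pre, post) view
    N_E = conn.N_E
    # degrees are tracked incrementally through the deletions below; tests
    # verify they always agree with a recount from the matrix
    K_out = W.sum(axis=1)
    K_in = W.sum(axis=0)
    fa = np.floor(elem.a).astype(np.int64)
    fd = np.floor(elem.d).astype(np.int64)
    a_minus = np.maximum(K_out - fa, 0)
    d_minus = np.maximum(K_in - fd, 0)

    n_del = 0
    for j in np.nonzero(a_minus)[0]:
        posts = _delete_from(rng, W[j, :], int(a_minus[j]))
        K_out[j] -= posts.size
        np.subtract.at(K_in, posts, 1)
        n_del += posts.size
    if np.any(d_minus):
        # dendritic deficits are evaluated on the pre-deletion snapshot;
        # axonal deletions may already have removed some incoming contacts
        for i in np.nonzero(d_minus)[0]:
            k = min(int(d_minus[i]), int(K_in[i]))
            pres = _delete_from(rng, W[:, i], k)
            K_in[i] -= pres.size
            np.subtract.at(K_out, pres, 1)
            n_del += pres.size

    a_plus = np.maximum(fa - K_out, 0)
    d_plus = np.maximum(fd - K_in, 0)
    tot_a, tot_d = int(a_plus.sum()), int(d_plus.sum())
    n = min(tot_a, tot_d)
    n_new = 0
    if n > 0:
        pre = np.repeat(np.arange(N_E), a_plus)
        post = np.repeat(np.arange(N_E), d_plus)
        rng.shuffle(pre)
        rng.shuffle(post)
        if max_fix_attempts is None:
            max_fix_attempts = tot_a * tot_d
        attempts = 0
        k = 0
        while k < n:
            if pre[k] == post[k]:
                if attempts >= max_fix_attempts:
                    k += 1
                    continue
                j = int(rng.integers(post.size))
                post[k], post[j] = post[j], post[k]
                attempts += 1
                if j < k:
                    k = j  # re-check the slot we disturbed
            else:
                k += 1
        ok = pre[:n] != post[:n]
        np.add.at(W, (pre[:n][ok], post[:n][ok]), 1)
        n_new = int(ok.sum())
    return {"created": n_new, "deleted": n_del,
            "free_axonal": tot_a - n_new, "free_dendritic": tot_d - n_new}


@dataclass
class PlasticRunResult:
    """Recorded trajectories of a plastic simulation."""

    time_s: np.ndarray
    rate_hz: np.ndarray            # mean excitatory rate per record window
    phi_hz: np.ndarray             # mean excitatory calcium trace
    mean_ee: np.ndarray            # mean EE contact count (connectivity)
    block_means: Dict[str, np.ndarray] = field(default_factory=dict)
    spikes: Optional[SpikeRecord] = None


def plastic_run(net: SpikingNetwork, duration_ms: float,
                multipliers: Optional[np.ndarray] = None,
                ensembles: Optional[Dict[str, np.ndarray]] = None,
                record_every_s: Optional[float] = None,
                record_spikes: bool = False) -> PlasticRunResult:
    """Run the network with interleaved spiking and rewiring.

    Spiking, calcium and element integration advance every ``dt`` inside
    the kernel; every ``delta_t_s_ms`` the rewiring step executes.  Block
    connectivity means ``C_AB`` (contacts from ensemble B onto ensemble A),
    population rate and mean calcium are recorded at ``record_every_s``.
    """
    pl = net.plasticity
    if pl is None:
        raise ValueError("network has no plasticity parameters attached")
    frozen = pl.frozen
    dt_rw = pl.delta_t_s_ms if not frozen else duration_ms
    n_chunk_steps = int(round(dt_rw / net.dt_ms))
    if not frozen and abs(n_chunk_steps * net.dt_ms - pl.delta_t_s_ms) > 1e-9:
        raise ValueError("delta_t_s_ms must be a multiple of dt")
    n_chunks = int(round(duration_ms / dt_rw))
    if record_every_s is None:
        record_every_s = pl.record_every_s
    rec_every_ms = record_every_s * 1000.0

    elem = ElementState(net.state.a, net.state.d, pl.beta_a, pl.beta_d,
                        pl.nu_target_hz)
    times, rates, phis, means = [], [], [], []
    blocks: Dict[str, list] = {}
    if ensembles:
        for la in ensembles:
            for lb in ensembles:
                blocks[f"{la}-{lb}"] = []
    all_spikes_t, all_spikes_i = [], []
    counts0 = net.counts.copy()
    next_rec = rec_every_ms
    t_done = 0.0

    def _record(now_ms: float, window_ms: float) -> None:
        nonlocal counts0
        times.append(net.time_ms / 1000.0)
        dcount = net.counts[: net.conn.N_E] - counts0[: net.conn.N_E]
        rates.append(dcount.mean() / (window_ms / 1000.0))
        counts0 = net.counts.copy()
        phis.append(net.state.phi.mean())
        means.append(net.conn.ee.mean())
        if ensembles:
            for la, ia in ensembles.items():
                for lb, ib in ensembles.items():
                    blocks[f"{la}-{lb}"].append(
                        net.conn.block_mean(post=ia, pre=ib))

    for _ in range(n_chunks):
        rec = net.advance(dt_rw, multipliers, record_spikes=record_spikes)
        if record_spikes and len(rec):
            all_spikes_t.append(rec.times_ms)
            all_spikes_i.append(rec.ids)
        if not frozen:
            rewire_step(net.conn, elem, net.rewire_rng)
        t_done += dt_rw
        if t_done >= next_rec - 1e-9:
            _record(t_done, rec_every_ms)
            next_rec += rec_every_ms

    spikes = None
    if record_spikes:
        spikes = SpikeRecord(
            np.concatenate(all_spikes_t) if all_spikes_t else np.empty(0),
            np.concatenate(all_spikes_i) if all_spikes_i else np.empty(0, int))
    return PlasticRunResult(np.array(times), np.array(rates), np.array(phis),
                            np.array(means),
                            {k: np.array(v) for k, v in blocks.items()},
                            spikes)
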