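# engramnet

Memory-engram formation through homeostatic structural plasticity in
spiking recurrent networks.

Networks of excitatory and inhibitory leaky integrate-and-fire neurons
can store memories without any Hebbian rule: if every excitatory neuron
controls its number of synaptic elements to hold its own firing rate at a
set-point (firing-rate homeostasis), and free axonal/dendritic elements
are paired randomly into synapses, then jointly stimulated ensembles end
up more strongly wired to each other.  The wiring diagram itself becomes
the memory trace ("engram"): silent during spontaneous activity,
retrievable by partial cues, slowly forgotten by spiking noise.
`engramnet` is for computational neuroscientists who want to simulate
this mechanism, reproduce its analytic theory, or build on either.

The package provides:

- **`engramnet.network`** — a clock-driven LIF simulator with delta
  synapses, integer multapse contact counts `C_ij`, delayed spike
  delivery and independent external Poisson drive (numba-accelerated);
- **`engramnet.plasticity`** — the homeostatic rule: calcium traces
  `tau_Ca dphi/dt = -phi + S(t)`, element counters
  `beta dx/dt = nu - phi`, and the periodic random deletion/pairing
  rewiring step on the EE block;
- **`engramnet.meanfield`** — the population theory: Siegert transfer
  function `r = f(mu, sigma)`, ISI irregularity statistic, diffusion
  input moments, rectified-Gaussian element rates
  `R_sigma(mu) = (mu + mu erf(mu/sqrt2 sigma) + sqrt(2/pi) sigma
  e^{-mu^2/2sigma^2})/2`, the connectivity flow and the coupled
  rate/calcium/connectivity ODE integrator;
- **`engramnet.stability`** — line attractor `L(x)`, 9x9 Jacobian with
  its rank-one connectivity block, slow-mode eigenvalue
  `lambda_1 = -(R_a(0)+R_d(0))/(c N_E)`, oscillation boundary, critical
  engram connectivity `eps (1 + N_E2/(N_E1 j_E))`, turnover ratio;
- **`engramnet.protocols`** — growth, classical conditioning (US/C1/C2 +
  readout neuron), repeated stimulation, pattern completion, overlap
  `m = [N a (1-a)]^{-1} sum_i (xi_i - a) s_i(t)`, decay fitting, Gamma
  renewal trains and calcium shot-noise statistics;
- **`engramnet.cli` / `engramnet.io`** — YAML experiment configs with
  explicit seeds, presets, text artifact formats, and an `engramnet`
  command-line tool (`run`, `grow`, `stimulate`, `condition`, `readout`,
  `analyze`, `presets`).

## Worked example

Solve the grown equilibrium and the headline stability numbers:

```python
>>> from engramnet import LIFParams, operating_point, cv_isi
>>> from engramnet import stability as sb
>>> op = operating_point(LIFParams())          # N_E=10000, N_I=2500, 8 Hz
>>> round(op.K)                                # equilibrium EE in-degree
999
>>> round(cv_isi(op.mu_e, op.sigma_e, LIFParams()), 3)   # irregularity
0.748
>>> round(sb.slow_mode_timescale(c=0.1))       # memory lifetime (s)
5662
>>> round(100 * sb.critical_connectivity(
...     __import__("engramnet").PopulationModel(
...         sizes_e=[1000., 9000.], N_I=2500), op), 1)
27.8
```

A neuron needs 999 excitatory contacts to sustain 8 Hz; its interspike
irregularity statistic is 0.75; an encoded engram decays back to the
uniform wiring with a ~5700 s time constant; and once within-engram
connectivity exceeds ~28% the excitation-inhibition balance breaks and
the network bursts.

Encode an engram in the population model by repeated stimulation:

```python
>>> import numpy as np
>>> from engramnet import PopulationModel, integrate_model
>>> m = PopulationModel(sizes_e=np.array([1000., 9000.]), N_I=2500)
>>> eps = [(150.0, np.array([a, 1.0])) for _ in range(8)
...        for a in (1.05, 1.0)]               # 8 stim/relax cycles
>>> tr = integrate_model(m, eps, record_every_s=5.0)
>>> round(tr.C[-1, 0, 0], 3)                   # within-engram connectivity
0.218
```

Starting from the uniform 0.1, eight cycles of 5% extra drive to a 10%
ensemble more than double its internal connectivity while mean rates stay
homeostatically clamped at 8 Hz.

Run a spiking experiment from the shell:

```
engramnet run --preset repeated_stimulation_scaled -o runs
engramnet analyze stability --defaults
```

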