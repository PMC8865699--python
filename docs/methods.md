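# Methods

## Model

`engramnet` simulates a sparsely connected recurrent network of
current-based leaky integrate-and-fire (LIF) neurons whose
excitatory-to-excitatory (EE) wiring is remodeled by structural plasticity
under firing-rate homeostasis, together with the population-level theory
of the same system.

### Spiking network

Membrane potentials follow

    tau_m dV_i/dt = -V_i + tau_m * sum_j C_ij J_j S_j(t - D) + RI_i(t),

with integer contact counts `C_ij` (multapses allowed), delta-pulse
synapses of amplitude `J = 0.1 mV` per contact for excitatory and
`-g J = -0.8 mV` for inhibitory sources, a uniform delay `D = 1.5 ms`,
threshold 20 mV, reset 10 mV, refractory period 2 ms, and independent
external Poisson drive of 15 000 events/s and amplitude `J` per neuron.
The membrane time constant is not fixed by the model definition; we use
`tau_m = 20 ms`, a standard value for this network class, and expose it in
the configuration.  With this choice the self-consistent EE in-degree at
the 8 Hz target rate is 999 contacts, i.e. 10% connectivity among
10 000 excitatory neurons.

Integration is clock driven with `dt = 0.1 ms` (any divisor of `D` not
exceeding the refractory period is accepted).  The leak is propagated with
the exact exponential factor between grid points, which makes the scheme
exact for delta synapses up to the quantization of spike times to the
grid.  All threshold crossings within one step are processed together;
because every synapse is delayed by `D`, the result does not depend on
processing order.  Inputs arriving during the refractory clamp are
discarded.  External Poisson event counts per step are sampled exactly via
per-rate inverse-CDF tables (the expected count per step is ~1.5, so a
table walk with a single uniform per neuron-step reproduces the Poisson
law at a fraction of the cost of a generic generator).

Three named random streams exist: construction (static wiring and initial
membrane potentials), external drive, and rewiring, each with its own
seed.  Runs are bit-reproducible given the seed block.

### Structural plasticity

Each excitatory neuron filters its own spike train into a calcium trace
(`tau_Ca dphi/dt = -phi + S(t)`, default `tau_Ca = 10 s`) and integrates
continuous counters of axonal and dendritic synaptic elements,
`beta dx/dt = nu - phi` with target rate `nu = 8 Hz` and growth parameters
`beta_a = beta_d = 2` by default.  Counters are floored at zero and
compared against the integer degrees through `floor(x)`.  Every
`Delta_T_s` (default 100 ms) the discrete rewiring step runs:

1. neurons whose counter fell below their degree delete the surplus
   outgoing (axonal) or incoming (dendritic) contacts, chosen uniformly
   among individual contacts (a multapse loses contacts in proportion to
   its count); deletion frees the bonded counterpart element on the
   partner neuron, and those freed elements can already be re-paired in
   the same step;
2. all free axonal and dendritic elements are matched uniformly at random
   without replacement into `n = min(|a+|, |d+|)` new contacts.
   Self-pairings are rejected and locally redrawn (capped at
   `|a+| * |d+|` swap attempts, after which the offending pairings are
   dropped — in practice the cap is never reached except in adversarial
   toy states).

The per-pair increment distribution of the uniform matching is the
hypergeometric law of sampling the smaller element multiset into the
larger one; the test suite verifies it against exhaustive enumeration of
all matchings on small instances.  Deletion precedes creation within a
step, which is what the freed-counterpart correction terms of the
mean-field flow describe.

### Mean-field theory

Populations `E_1 .. E_n` (plastic) and `I` (static) are described by the
state `(phi_Y, C_YZ, r_Y)`.  Input moments are the usual diffusion
approximation; stationary rates come from the Siegert first-passage
formula, evaluated through the scaled complementary error function
`erfcx` with a closed-form `erfi` split on the positive branch (stable for
`(V - mu)/sigma` up to ±40; deeply subthreshold points use the leading
asymptotic term).  Rate dynamics are relaxational with
`tau_rate = tau_m / 2` (results are insensitive to this value as long as
it does not exceed `tau_m`); the delay enters as a one-step rate buffer at
the integration step `dt = D = 1.5 ms` (explicit Euler; calcium and
connectivity are orders of magnitude slower, so the same step is used for
them).

The connectivity flow is

    dC_YZ/dt = rho'd+_Y rho'a+_Z / rho
               - C_YZ (rho d-_Y / K_in_Y + rho a-_Z / K_out_Z),

where element creation/deletion rates are rectified-Gaussian means
`R_sigma(±(nu - phi)/beta)` with noise level
`sigma_x = eta * sqrt(nu / (2 tau_Ca)) / beta` (Campbell's theorem for
the exponentially filtered spike train, scaled by the growth parameter),
primes denote the freed-counterpart corrections, and
`rho = max(total corrected axonal, total corrected dendritic)` free-element
rate.  With `eta = 0` the rates are sharp rectifiers and every
constant-in-degree configuration is stationary (line attractor / degree
hyperplane of dimension `(n_E - 1)^2`); with `eta > 0` the only fixed
point is the homogeneous, most entropic configuration `C = K_in / N_E`,
approached along the manifold with the slow eigenvalue

    lambda_1 = -(R_a(0) + R_d(0)) / (c N_E),
    1/|lambda_1| = sqrt(4 pi tau_Ca / (eta^2 nu)) * N_E c / (1/beta_a + 1/beta_d),

about 5.7e3 s at default parameters.  The irregularity correction is
`eta = 0.7` by default, the operating-point value of the first-passage
irregularity statistic (see below).

### Irregularity statistic

`cv_isi` evaluates

    CV(mu, sigma) = 2 pi (nu_0 tau_m)^2
        int_{y_r}^{y_th} e^{x^2} int_{-inf}^x e^{y^2} (1 + erf y)^2 dy dx,

the statistic the noise theory calibrates `eta` with; at the grown
operating point it equals 0.75.  In the standard first-passage
normalization this expression is the *squared* coefficient of variation
of the ISI distribution — the conventional CV at the same point is its
square root, 0.87, which is what an ISI histogram of a long simulated
train yields.  The test suite checks `cv_isi` against the empirical
squared CV of a brute-force Euler–Maruyama simulation of the LIF SDE.
We keep the statistic in the model's own normalization because the
homeostasis noise level (`eta = 0.7`) and the resulting memory lifetime
are calibrated with it.

### Stability analysis

The 9-dimensional Jacobian of the two-population system at the grown
fixed point is assembled analytically: the connectivity block is the
rank-one matrix `c0 * u w^T` with
`c0 = eta sqrt(nu/(pi tau_Ca)) (1/beta_a + 1/beta_d) / (2 c N_E^3)`,
`u = (-N2^2, N1 N2, N1 N2, -N1^2)`, `w = (1, -1, -1, 1)` (eigenvalues 0,
0, 0 and `lambda_1 = -c0 N_E^2`, slow eigenvector tangent to the line
attractor); calcium couplings of the connectivity rows are
`(n_W - delta_YW - delta_ZW) / (beta N_E)`; the rate block carries the
effective synaptic couplings
`j_YZ = J_Z tau_m df/dmu + J_Z^2 tau_m / (2 sigma) df/dsigma`, with the
Siegert derivatives taken by Richardson-extrapolated central differences
(step 1e-4 mV).  All eigenvalues are computed numerically; finite
differences of the implemented flow cross-check every analytic block.

The oscillation boundary of the homeostatic response is located by
bisection (tolerance 1e-3 s) on the imaginary part of the least-stable
eigenvalue pair of the reduced one-population Jacobian; the boundary is
`tau_Ca ≈ 3.1 * beta_d` seconds at default couplings.  The critical
within-engram connectivity `eps (1 + N_E2/(N_E1 j_E))`, `j_E = eps N_E
j_EE`, evaluates to 27.8% and coincides with the sign change of the
reduced rate-block determinant along the line attractor.  The synapse
turnover ratio (created + deleted per day over twice the synapse count)
reduces at the set-point to `|lambda_1| * 86400`, about 15%/day at
defaults; it vanishes with the noise and scales as `1/beta`.

## Down-scaled reference network

Full-scale spiking runs (12 500 neurons, hundreds of seconds biological
time) are not practical for a test suite, so the simulation tests use a
tenfold smaller network, N_E = 1000, N_I = 250.  Naive scaling of the
static wiring (in-degrees 0.1 of the source populations) leaves
inhibition ten times weaker, the zero-EE firing rate (15 Hz) already
exceeds the 8 Hz target, and no homeostatic equilibrium exists.  The
scaled preset therefore raises the static inhibitory in-degree to 124
contacts (keeping `g = 8` and all single-neuron parameters), which
restores the full-scale operating point: equilibrium EE in-degree 100
(connectivity 0.1), inhibitory rate 8 Hz, input moments mu = 15.7 mV,
sigma = 4.0 mV (full scale: 13.8, 5.5).  The plasticity clock is
accelerated (tau_Ca = 1 s, beta = 0.4, Delta_T_s = 10 ms) so that growth
completes in 100 s of model time; these are the parameters the
conditioning experiments use anyway.

A note on the readout neuron: a readout wired from a balanced random
sample (the same fraction of excitatory and inhibitory neurons, weights
`+w` and `-g w`) has a nearly stimulus-invariant *mean* input, because
the inhibitory population self-consistently tracks total excitatory
activity.  Its discrimination between an encoded engram and a random
ensemble is carried by the input *variance*, which grows with the
stimulated members' firing rates: at full scale the readout's Siegert
rate is 11.7 Hz at rest, 12.6 Hz during random-ensemble stimulation and
13.3 Hz during stimulation of a 0.19-connectivity engram.  In the scaled
network the sample contains only ~9 engram members and the variance
signal vanishes, so the discrimination property is verified with the
full-scale population model, while the spiking tests check the readout
wiring quantitatively (its firing rate against the Siegert prediction of
its sampled input moments) and the silent-without-inputs limit.

Two further caveats follow.  First, the fast plasticity clock also accelerates
fluctuation-driven forgetting (the scaled slow-manifold lifetime is
~36 s), so scaled engrams saturate near C = 0.2 under periodic
stimulation.  Second, recurrent amplification scales with `j_EE * N`,
which is ~8x weaker in the scaled network; evoked-activity probes
(pattern completion, readout) therefore use stronger probe stimuli
(1.3x external rate) than the full-scale protocols (1.05-1.1x) to obtain
a detectable effect.  Passing scaled tests demonstrate the mechanisms —
homeostatic convergence, engram formation and ordering, associative
cross-wiring, completion, readout discrimination — not the full-scale
effect sizes, which the mean-field model reproduces instead.

## Numerical choices

- Quadratures: 48/80-node Gauss–Legendre on the erfcx form of the Siegert
  integrand; adaptive scipy quadrature (abs. tol. 1e-10) for the CV
  double integral; asymptotic branches beyond |(V - mu)/sigma| ~ 25.
- The compiled ODE integrator mirrors the reference numpy implementation
  of the flow; tests require agreement to ~1e-9 relative over a short
  horizon and ~1e-6 against the scipy Siegert across a (mu, sigma) grid.
- Connectivity means are clamped at zero during integration; deletion
  terms guard against zero degrees.  Excitatory rates above 100 Hz set a
  `runaway` flag (the non-linear burst regime) without stopping the
  integration.
- Exponential decay fits initialize the offset from the final 10% of the
  series and the time constant from a log-linear regression of the
  residual, then refine by Levenberg–Marquardt.
- Time-averaged overlaps discard the first 500 ms of a stimulation
  window (onset transient); the window convention is configurable.
- Conditioning episode order during encoding alternates (US+C1), C2,
  (US+C1), ... starting with the paired stimulus; the schedule is pure
  data and can be replaced.

## Known limitations

- Dense integer connectivity storage: memory grows with N^2; fine up to a
  few thousand neurons, not intended for the full 12 500-neuron network
  (use the mean-field model at full scale).
- The analytic Jacobian assembly assumes beta_a = beta_d (the default
  setup); unequal growth parameters introduce a kink in the pairing-rate
  maximum that the rank-one form does not capture.
- The mean-field model treats all neurons of a population as
  exchangeable; pairwise-correlation structure within engrams is outside
  its scope.
- The self-pairing redraw after the cap conditions only approximately on
  "no self-connection" in adversarial states where one neuron owns almost
  all free elements.
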