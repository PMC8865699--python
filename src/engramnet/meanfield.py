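"""Population-level theory: Siegert transfer function, ISI irregularity,
diffusion input moments, noise-corrected element rates and the coupled
rate/calcium/connectivity ODE system.

The spiking network is reduced to populations ``E_1 .. E_nE`` (plastic) and
``I`` (static).  Recurrent input to a neuron of population ``Y`` is treated
as Gaussian white noise with moments

    mu_Y    = tau_m * ( J * sum_Z C_YZ N_Z r_Z(t-D) - g J K_I r_I(t-D)
                        + J nu_ext )
    sigma_Y^2 = tau_m * ( J^2 * sum_Z C_YZ N_Z r_Z + g^2 J^2 K_I r_I
                        + J^2 nu_ext )

and the stationary rate is the Siegert first-passage formula.  Population
rates relax toward it with a fast time constant ``tau_rate`` (Wilson-Cowan
heuristic), calcium follows the rate with ``tau_Ca``, and the mean EE
connectivity ``C_YZ`` evolves under the homeostatic drift with
noise-corrected element creation/deletion rates: the calcium trace of a
spiking neuron fluctuates (shot noise of the spike train), so creation and
deletion of synaptic elements continue even at the set-point, with rates
given by the rectified-Gaussian mean ``R_sigma(mu)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import integrate, optimize
from scipy.special import erfcx, erfi

from .network import LIFParams

__all__ = [
    "PopulationModel",
    "InputMoments",
    "MeanFieldState",
    "MeanFieldTrajectory",
    "siegert_rate",
    "siegert_derivatives",
    "cv_isi",
    "input_moments",
    "sigma_element",
    "element_rate_mean",
    "connectivity_flow",
    "integrate_model",
    "equilibrium_indegree",
    "equilibrium_state",
    "OperatingPoint",
    "operating_point",
]

_GL_X, _GL_W = np.polynomial.legendre.leggauss(80)


# ----------------------------------------------------------------------
# single-neuron transfer functions
# ----------------------------------------------------------------------

def _erfcx_integral(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """``int_lo^hi erfcx(-u) du`` for array bounds, stable for |u| <= ~25.

    For u <= 0 the integrand is the slowly varying scaled complementary
    error function; for u > 0 it is split as ``2 e^{u^2} - erfcx(u)`` whose
    first part integrates to ``sqrt(pi) * erfi(u)`` in closed form.
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    a_neg, b_neg = np.minimum(lo, 0.0), np.minimum(hi, 0.0)
    a_pos, b_pos = np.maximum(lo, 0.0), np.maximum(hi, 0.0)
    # negative-side quadrature of erfcx(-u)
    mid = 0.5 * (a_neg + b_neg)[..., None]
    half = 0.5 * (b_neg - a_neg)[..., None]
    u = mid + half * _GL_X
    res = (half * _GL_W * erfcx(-u)).sum(axis=-1)
    # positive side: closed form + quadrature of -erfcx(u)
    res = res + np.sqrt(np.pi) * (erfi(b_pos) - erfi(a_pos))
    mid = 0.5 * (a_pos + b_pos)[..., None]
    half = 0.5 * (b_pos - a_pos)[..., None]
    u = mid + half * _GL_X
    res = res - (half * _GL_W * erfcx(u)).sum(axis=-1)
    return res


def siegert_rate(mu, sigma, params: LIFParams):
    """Stationary LIF firing rate (spikes/s) for Gaussian-white input.

    Evaluates ``r = [t_ref + tau_m sqrt(pi) * I]^-1`` with
    ``I = int_{(V_r-mu)/sigma}^{(V_th-mu)/sigma} e^{u^2} erfc(-u) du``,
    using the scaled error function and a closed-form erfi split for
    numerical stability; strongly subthreshold arguments fall back to the
    leading asymptotic term (rate ~ 0 for ``(V_th-mu)/sigma > 25``).
    """
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    tau_s = params.tau_m * 1e-3
    tref_s = params.t_ref * 1e-3
    yr = (params.V_r - mu) / sigma
    yth = (params.V_th - mu) / sigma
    scalar = yth.ndim == 0
    yr, yth = np.atleast_1d(yr), np.atleast_1d(yth)
    out = np.zeros(yth.shape)
    deep = yth > 25.0
    if np.any(deep):  # asymptotic: I ~ e^{yth^2}/yth, rate ~ yth e^{-yth^2}
        y = yth[deep]
        with np.errstate(under="ignore"):
            out[deep] = y * np.exp(-y * y) / (tau_s * np.sqrt(np.pi))
    ok = ~deep
    if np.any(ok):
        I = _erfcx_integral(yr[ok], yth[ok])
        out[ok] = 1.0 / (tref_s + tau_s * np.sqrt(np.pi) * I)
    return float(out[0]) if scalar else out


def siegert_derivatives(mu: float, sigma: float, params: LIFParams,
                        h: float = 1e-4) -> Tuple[float, float]:
    """Richardson-extrapolated central differences d(rate)/d(mu, sigma)."""
    def cd(f, x, step):
        return (f(x + step) - f(x - step)) / (2 * step)

    def rich(f, x):
        d1 = cd(f, x, h)
        d2 = cd(f, x, h / 2)
        return (4 * d2 - d1) / 3

    dmu = rich(lambda m: siegert_rate(m, sigma, params), mu)
    dsig = rich(lambda s: siegert_rate(mu, s, params), sigma)
    return dmu, dsig


def cv_isi(mu: float, sigma: float, params: LIFParams) -> float:
    """Interspike-interval irregularity statistic of the LIF neuron.

    Evaluates the first-passage double integral

        CV(mu, sigma) = 2 pi (nu0 tau_m)^2
            * int_{y_r}^{y_th} e^{x^2} int_{-inf}^{x} e^{y^2}(1+erf y)^2 dy dx

    which the noise theory uses directly as its irregularity correction
    (eta).  In the standard first-passage normalization this expression is
    the *squared* coefficient of variation of the ISI distribution, so the
    conventional CV equals ``sqrt(cv_isi(...))``; see the methods note.
    """
    nu0 = siegert_rate(mu, sigma, params)
    if nu0 <= 0:
        raise ValueError("operating point has zero rate; CV undefined")
    tau_s = params.tau_m * 1e-3
    yr = (params.V_r - mu) / sigma
    yth = (params.V_th - mu) / sigma

    def inner(x):
        val, _ = integrate.quad(
            lambda y: np.exp(-(y - x) * (y + x)) * erfcx(-y) ** 2,
            -np.inf, x, epsabs=1e-12, limit=200)
        return val

    outer, err = integrate.quad(inner, yr, yth, epsabs=1e-10, limit=200)
    if not np.isfinite(outer):
        raise ArithmeticError(f"CV quadrature failed (outer={outer}, err={err})")
    return 2 * np.pi * (nu0 * tau_s) ** 2 * outer


# ----------------------------------------------------------------------
# populations
# ----------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Plastic excitatory populations plus one static inhibitory pool.

    ``sizes_e`` lists the plastic population sizes (e.g. [1000, 9000] for a
    10% engram in 10000 excitatory neurons); connectivity to and from the
    inhibitory population is static with in-degree fraction ``epsilon``.
    ``eta`` is the spike-train irregularity correction entering the element
    noise (0 switches to the deterministic sharp-rectifier model).
    """

    sizes_e: np.ndarray
    N_I: int
    lif: LIFParams = field(default_factory=LIFParams)
    nu_target_hz: float = 8.0
    beta_a: float = 2.0
    beta_d: float = 2.0
    tau_ca_s: float = 10.0
    eta: float = 0.7
    epsilon: float = 0.1
    tau_rate_ms: Optional[float] = None  # default tau_m / 2
    K_I: Optional[float] = None          # inhibitory in-degree (contacts)
    K_IE: Optional[float] = None         # excitatory in-degree of I neurons

    def __post_init__(self) -> None:
        self.sizes_e = np.asarray(self.sizes_e, dtype=float)
        if self.tau_rate_ms is None:
            self.tau_rate_ms = self.lif.tau_m / 2.0
        if self.K_I is None:
            self.K_I = self.epsilon * self.N_I
        if self.K_IE is None:
            self.K_IE = self.epsilon * self.N_E

    @property
    def n_e(self) -> int:
        return self.sizes_e.size

    @property
    def N_E(self) -> float:
        return float(self.sizes_e.sum())


@dataclass
class InputMoments:
    """Mean (mV) and standard deviation (mV) of the aggregated input."""

    mu: np.ndarray      # per population, E populations then I
    sigma: np.ndarray


def input_moments(model: PopulationModel, C: np.ndarray,
                  rates: np.ndarray,
                  ext_mult: Optional[np.ndarray] = None) -> InputMoments:
    """Diffusion moments of the input to every population.

    ``rates`` holds the (delayed) population rates ``(r_E1..r_EnE, r_I)``;
    ``ext_mult`` the external-rate multipliers of the E populations.
    """
    rates = np.asarray(rates, float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    lif = model.lif
    tau = lif.tau_m * 1e-3
    J, g = lif.J, lif.g
    K_I = model.K_I
    K_IE = model.K_IE
    re, rI = rates[:-1], rates[-1]
    mult = np.ones(model.n_e) if ext_mult is None else np.asarray(ext_mult, float)

    rec = C @ (model.sizes_e * re)
    mu_e = tau * (J * rec - g * J * K_I * rI + J * lif.nu_ext * mult)
    var_e = tau * (J ** 2 * rec + g ** 2 * J ** 2 * K_I * rI
                   + J ** 2 * lif.nu_ext * mult)
    r_e_mean = float(model.sizes_e @ re) / model.N_E
    mu_i = tau * (J * K_IE * r_e_mean - g * J * K_I * rI + J * lif.nu_ext)
    var_i = tau * (J ** 2 * K_IE * r_e_mean + g ** 2 * J ** 2 * K_I * rI
                   + J ** 2 * lif.nu_ext)
    mu = np.append(mu_e, mu_i)
    sigma = np.sqrt(np.append(var_e, var_i))
    return InputMoments(mu, sigma)


# ----------------------------------------------------------------------
# noise-corrected element rates and connectivity drift
# ----------------------------------------------------------------------

def sigma_element(eta: float, nu: float, tau_ca_s: float, beta: float) -> float:
    """Std of the element-rate noise, ``eta * sqrt(nu / (2 tau_Ca)) / beta``.

    Campbell's theorem gives the calcium-trace variance
    ``CV^2 * nu / (2 tau_Ca)``; scaled by the growth parameter it becomes
    the noise level of the element creation/deletion drive.
    """
    return eta * np.sqrt(nu / (2.0 * tau_ca_s)) / beta


def element_rate_mean(mu_drive, sigma_x):
    """Mean creation and deletion rates of synaptic elements.

    For a Gaussian-fluctuating homeostatic drive with mean ``mu`` and std
    ``sigma_x`` the rectified means are ``R_sigma(mu)`` (creation) and
    ``R_sigma(-mu)`` (deletion) with

        R_sigma(m) = (m + m erf(m/(sqrt2 sigma)) + sqrt(2/pi) sigma
                      e^{-m^2/(2 sigma^2)}) / 2,

    which satisfies ``R(m) - R(-m) = m`` and tends to ``max(m, 0)`` as the
    noise vanishes.  Returns ``(creation, deletion)``.
    """
    mu_drive = np.asarray(mu_drive, float)
    return _rect_mean(mu_drive, sigma_x), _rect_mean(-mu_drive, sigma_x)


def _rect_mean(m, sigma):
    m = np.asarray(m, float)
    if np.ndim(sigma) == 0 and sigma == 0:
        return np.maximum(m, 0.0)
    from scipy.special import erf
    with np.errstate(under="ignore"):
        return 0.5 * (m + m * erf(m / (np.sqrt(2.0) * sigma))
                      + np.sqrt(2.0 / np.pi) * sigma
                      * np.exp(-m * m / (2.0 * sigma ** 2)))


def connectivity_flow(model: PopulationModel, phi: np.ndarray,
                      C: np.ndarray) -> np.ndarray:
    """Time derivative of the mean EE connectivity matrix ``C_YZ``.

    Drift = pairing of corrected free-element rates minus random deletion:

        dC_YZ/dt = rho'd+_Y rho'a+_Z / rho
                   - C_YZ (rho d-_Y / K^in_Y + rho a-_Z / K^out_Z)

    with ``rho = max(total corrected free-axonal rate, total corrected
    free-dendritic rate)``.  The corrections add elements freed when the
    partner of a bonded element is deleted.  With ``eta > 0`` all rates are
    the rectified-Gaussian means; with ``eta = 0`` they are sharp
    rectifiers and every constant-in-degree configuration is stationary.
    """
    nu = model.nu_target_hz
    drive = nu - np.asarray(phi, float)
    sig_a = sigma_element(model.eta, nu, model.tau_ca_s, model.beta_a)
    sig_d = sigma_element(model.eta, nu, model.tau_ca_s, model.beta_d)
    a_plus, a_minus = element_rate_mean(drive / model.beta_a, sig_a)
    d_plus, d_minus = element_rate_mean(drive / model.beta_d, sig_d)

    sizes = model.sizes_e
    K_in = C @ sizes
    K_out = C.T @ sizes
    inv_in = np.where(K_in > 0, 1.0 / np.where(K_in > 0, K_in, 1.0), 0.0)
    inv_out = np.where(K_out > 0, 1.0 / np.where(K_out > 0, K_out, 1.0), 0.0)

    # elements freed by deletion of their bonded counterpart
    d_plus_c = d_plus + C @ (sizes * a_minus * inv_out)
    a_plus_c = a_plus + C.T @ (sizes * d_minus * inv_in)

    rho = max(float(sizes @ a_plus_c), float(sizes @ d_plus_c))
    if rho > 0:
        creation = np.outer(d_plus_c, a_plus_c) / rho
    else:
        creation = np.zeros_like(C)
    deletion = C * (d_minus * inv_in)[:, None] + C * (a_minus * inv_out)[None, :]
    return creation - deletion


# ----------------------------------------------------------------------
# self-consistent equilibria
# ----------------------------------------------------------------------

def _rI_selfconsistent(lif: LIFParams, r_e: float, N_E: float, N_I: float,
                       epsilon: float, K_I=None, K_IE=None) -> float:
    tau = lif.tau_m * 1e-3
    J, g = lif.J, lif.g
    K_IE = epsilon * N_E if K_IE is None else K_IE
    K_I = epsilon * N_I if K_I is None else K_I

    def res(rI):
        mu = tau * (J * K_IE * r_e - g * J * K_I * rI + J * lif.nu_ext)
        s2 = tau * (J ** 2 * K_IE * r_e + g ** 2 * J ** 2 * K_I * rI
                    + J ** 2 * lif.nu_ext)
        return siegert_rate(mu, np.sqrt(s2), lif) - rI

    return optimize.brentq(res, 0.0, 1.0 / (lif.t_ref * 1e-3), xtol=1e-10)


def equilibrium_indegree(lif: LIFParams, nu: float, N_E: float = 10000,
                         N_I: float = 2500, epsilon: float = 0.1,
                         K_I=None, K_IE=None) -> float:
    """EE in-degree K at which the excitatory rate self-consistently
    equals the target ``nu`` (inhibitory rates solved at fixed static
    wiring).  Raises if no root exists in ``[0, N_E]``.
    """
    tau = lif.tau_m * 1e-3
    J, g = lif.J, lif.g
    K_I = epsilon * N_I if K_I is None else K_I
    rI = _rI_selfconsistent(lif, nu, N_E, N_I, epsilon, K_I, K_IE)

    def res(K):
        mu = tau * (J * K * nu - g * J * K_I * rI + J * lif.nu_ext)
        s2 = tau * (J ** 2 * K * nu + g ** 2 * J ** 2 * K_I * rI
                    + J ** 2 * lif.nu_ext)
        return siegert_rate(mu, np.sqrt(s2), lif) - nu

    try:
        return optimize.brentq(res, 0.0, N_E, xtol=1e-8)
    except ValueError as exc:
        raise ValueError(f"no self-consistent in-degree for nu={nu}") from exc


@dataclass
class OperatingPoint:
    """Self-consistent grown-network working point and local couplings."""

    nu: float
    K: float                  # EE in-degree (contacts)
    c: float                  # K / N_E
    r_I: float
    mu_e: float
    sigma_e: float
    mu_i: float
    sigma_i: float
    j_ee: float
    j_ei: float
    j_ie: float
    j_ii: float


def operating_point(lif: LIFParams, nu: float = 8.0, N_E: float = 10000,
                    N_I: float = 2500, epsilon: float = 0.1,
                    K_I=None, K_IE=None) -> OperatingPoint:
    """Solve the grown equilibrium and the effective synaptic couplings.

    ``j_YZ = J_Z tau_m df/dmu_Y + J_Z^2 tau_m / (2 sigma_Y) df/dsigma_Y``
    is the dimensionless rate gain of one synapse from population Z onto a
    neuron of population Y (derivatives of the Siegert function, evaluated
    numerically).
    """
    tau = lif.tau_m * 1e-3
    J, g = lif.J, lif.g
    K = equilibrium_indegree(lif, nu, N_E, N_I, epsilon, K_I, K_IE)
    rI = _rI_selfconsistent(lif, nu, N_E, N_I, epsilon, K_I, K_IE)
    K_I = epsilon * N_I if K_I is None else K_I
    K_IE = epsilon * N_E if K_IE is None else K_IE
    mu_e = tau * (J * K * nu - g * J * K_I * rI + J * lif.nu_ext)
    s_e = np.sqrt(tau * (J ** 2 * K * nu + g ** 2 * J ** 2 * K_I * rI
                         + J ** 2 * lif.nu_ext))
    mu_i = tau * (J * K_IE * nu - g * J * K_I * rI + J * lif.nu_ext)
    s_i = np.sqrt(tau * (J ** 2 * K_IE * nu + g ** 2 * J ** 2 * K_I * rI
                         + J ** 2 * lif.nu_ext))
    dme, dse = siegert_derivatives(mu_e, s_e, lif)
    dmi, dsi = siegert_derivatives(mu_i, s_i, lif)
    j_ee = J * tau * dme + J ** 2 * tau / (2 * s_e) * dse
    j_ei = -g * J * tau * dme + g ** 2 * J ** 2 * tau / (2 * s_e) * dse
    j_ie = J * tau * dmi + J ** 2 * tau / (2 * s_i) * dsi
    j_ii = -g * J * tau * dmi + g ** 2 * J ** 2 * tau / (2 * s_i) * dsi
    return OperatingPoint(nu, K, K / N_E, rI, mu_e, float(s_e), mu_i,
                          float(s_i), j_ee, j_ei, j_ie, j_ii)


# ----------------------------------------------------------------------
# ODE integration
# ----------------------------------------------------------------------

@dataclass
class MeanFieldState:
    """State vector of the population model."""

    phi: np.ndarray   # (n_E,) calcium traces
    C: np.ndarray     # (n_E, n_E) mean EE connectivity
    r: np.ndarray     # (n_E + 1,) rates, inhibitory last

    def copy(self) -> "MeanFieldState":
        return MeanFieldState(self.phi.copy(), self.C.copy(), self.r.copy())


def equilibrium_state(model: PopulationModel,
                      K_star: Optional[float] = None) -> MeanFieldState:
    """Homogeneous grown equilibrium (most entropic point of the manifold)."""
    if K_star is None:
        K_star = equilibrium_indegree(model.lif, model.nu_target_hz,
                                      model.N_E, model.N_I, model.epsilon,
                                      model.K_I, model.K_IE)
    c = K_star / model.N_E
    rI = _rI_selfconsistent(model.lif, model.nu_target_hz, model.N_E,
                            model.N_I, model.epsilon, model.K_I, model.K_IE)
    n = model.n_e
    return MeanFieldState(np.full(n, model.nu_target_hz),
                          np.full((n, n), c),
                          np.append(np.full(n, model.nu_target_hz), rI))


@dataclass
class MeanFieldTrajectory:
    """Sampled trajectories of the population model."""

    time_s: np.ndarray
    phi: np.ndarray        # (T, n_E)
    C: np.ndarray          # (T, n_E, n_E)
    r: np.ndarray          # (T, n_E + 1)
    runaway: bool = False  # rate excursion beyond 100 Hz detected

    def final(self) -> MeanFieldState:
        return MeanFieldState(self.phi[-1].copy(), self.C[-1].copy(),
                              self.r[-1].copy())


def integrate_model(model: PopulationModel,
                    episodes: Sequence[Tuple[float, np.ndarray]],
                    state: Optional[MeanFieldState] = None,
                    dt_ms: Optional[float] = None,
                    record_every_s: float = 1.0) -> MeanFieldTrajectory:
    """Integrate the coupled rate/calcium/connectivity ODEs.

    ``episodes`` is a list of ``(duration_s, external multipliers for the
    E populations)``.  The synaptic delay is realized as a one-step rate
    buffer at ``dt = D`` (default), with calcium and connectivity advanced
    by the same explicit Euler step (they are orders of magnitude slower).
    Rates are hard-limited below ``1/t_ref`` by the transfer function
    itself; an excursion of any excitatory rate beyond 100 Hz sets the
    ``runaway`` flag (non-linear instability regime).
    """
    from ._mfkernel import _GLX, _GLW, _mf_integrate

    lif = model.lif
    if dt_ms is None:
        dt_ms = lif.D
    n_del = max(1, int(round(lif.D / dt_ms)))
    dt = dt_ms * 1e-3
    if state is None:
        state = equilibrium_state(model)
    phi = state.phi.copy()
    C = state.C.copy()
    r = state.r.copy()

    ep_steps = np.array([int(round(d / dt)) for d, _ in episodes],
                        dtype=np.int64)
    ep_mult = np.array([np.broadcast_to(np.asarray(m, float), (model.n_e,))
                        for _, m in episodes])
    rec_stride = max(1, int(round(record_every_s / dt)))
    n_rec = int(ep_steps.sum()) // rec_stride + 2
    T = np.empty(n_rec)
    PHI = np.empty((n_rec, model.n_e))
    CC = np.empty((n_rec, model.n_e, model.n_e))
    R = np.empty((n_rec, model.n_e + 1))

    nrec, runaway = _mf_integrate(
        model.sizes_e, float(model.K_I), float(model.K_IE),
        lif.tau_m * 1e-3, lif.t_ref * 1e-3, lif.V_th, lif.V_r,
        lif.J, lif.g, lif.nu_ext,
        model.nu_target_hz, model.beta_a, model.beta_d,
        sigma_element(model.eta, model.nu_target_hz, model.tau_ca_s,
                      model.beta_a),
        sigma_element(model.eta, model.nu_target_hz, model.tau_ca_s,
                      model.beta_d),
        model.tau_ca_s, model.tau_rate_ms * 1e-3,
        dt, n_del, ep_steps, ep_mult, rec_stride,
        phi, C, r, T, PHI, CC, R, _GLX, _GLW)
    return MeanFieldTrajectory(T[:nrec], PHI[:nrec], CC[:nrec], R[:nrec],
                               bool(runaway))
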