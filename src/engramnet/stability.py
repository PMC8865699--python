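"""Analytic structure of the homeostatic rewiring model.

The deterministic population model has a continuum of stationary states
(connectivity configurations with fixed in- and out-degrees): a line
attractor in the two-population case, a hyperplane of dimension
``(n_E - 1)^2`` in general.  Spiking noise deforms the line into a slow
manifold with a single attracting fixed point (the most entropic,
homogeneous configuration); the relaxation along the manifold is governed
by the slow eigenvalue

    lambda_1 = -(R_a(0) + R_d(0)) / (c N_E),

whose reciprocal is the memory (engram) lifetime.  This module assembles
the 9-dimensional Jacobian of the two-population system, the reduced
one-population Jacobian used to locate oscillatory homeostatic responses,
the critical engram connectivity where rate stability is lost, and the
synapse turnover ratio implied by the equilibrium rewiring rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .network import LIFParams
from .meanfield import (OperatingPoint, PopulationModel, connectivity_flow,
                        element_rate_mean, equilibrium_indegree,
                        input_moments, operating_point, sigma_element,
                        siegert_rate, _rI_selfconsistent)

__all__ = [
    "line_attractor_point",
    "admissible_segment",
    "JacobianModel",
    "build_jacobian",
    "numerical_jacobian",
    "full_rhs",
    "connectivity_block",
    "slow_mode_eigenvalue",
    "slow_mode_timescale",
    "reduced_jacobian",
    "oscillation_boundary",
    "optimal_target_rate",
    "critical_connectivity",
    "rate_block_determinant",
    "turnover_ratio",
    "slow_manifold_dimension",
]


# ----------------------------------------------------------------------
# line attractor
# ----------------------------------------------------------------------

def admissible_segment(N_E1: float, N_E2: float,
                       K_star: float) -> Tuple[float, float]:
    """Range of ``x = C_E1E1`` with all connectivity components >= 0."""
    lo = max(0.0, K_star * (N_E1 - N_E2) / N_E1 ** 2)
    hi = K_star / N_E1
    return lo, hi


def line_attractor_point(x: float, model: PopulationModel,
                         K_star: Optional[float] = None,
                         r_I: Optional[float] = None) -> np.ndarray:
    """Stationary state vector on the line attractor, parameterized by
    the within-engram connectivity ``x = C_E1E1``.

    Returns ``(phi_E1, phi_E2, C_E1E1, C_E1E2, C_E2E1, C_E2E2, r_E1,
    r_E2, r_I)``.  Every point satisfies the constant in-degree condition
    ``K* = C_Y,E1 N_E1 + C_Y,E2 N_E2`` for both populations.
    """
    if model.n_e != 2:
        raise ValueError("line attractor is defined for two E populations")
    N1, N2 = model.sizes_e
    nu = model.nu_target_hz
    if K_star is None:
        K_star = equilibrium_indegree(model.lif, nu, model.N_E, model.N_I,
                                      model.epsilon)
    lo, hi = admissible_segment(N1, N2, K_star)
    if not (lo - 1e-12 <= x <= hi + 1e-12):
        raise ValueError(f"x={x} outside admissible segment [{lo}, {hi}]")
    if r_I is None:
        r_I = _rI_selfconsistent(model.lif, nu, model.N_E, model.N_I,
                                 model.epsilon)
    c12 = (K_star - x * N1) / N2
    c22 = (K_star / N2 - (N1 / N2) * (K_star / N2)) + x * (N1 / N2) ** 2
    return np.array([nu, nu, x, c12, c12, c22, nu, nu, r_I])


# ----------------------------------------------------------------------
# Jacobian assembly
# ----------------------------------------------------------------------

def full_rhs(model: PopulationModel, y: np.ndarray,
             ext_mult: Optional[np.ndarray] = None) -> np.ndarray:
    """Right-hand side of the population ODEs for a flat state vector
    ``(phi_1..phi_n, C_11..C_nn row-major, r_1..r_n, r_I)`` (delay
    ignored, as appropriate for fixed-point analysis)."""
    n = model.n_e
    phi = y[:n]
    C = y[n:n + n * n].reshape(n, n)
    r = y[n + n * n:]
    mom = input_moments(model, C, np.maximum(r, 0.0), ext_mult)
    f = siegert_rate(mom.mu, mom.sigma, model.lif)
    dphi = (r[:n] - phi) / model.tau_ca_s
    dC = connectivity_flow(model, phi, C)
    dr = (f - r) / (model.tau_rate_ms * 1e-3)
    return np.concatenate([dphi, dC.ravel(), dr])


def numerical_jacobian(model: PopulationModel, y: np.ndarray,
                       h: float = 1e-7) -> np.ndarray:
    """Central finite-difference Jacobian of :func:`full_rhs` at ``y``."""
    m = y.size
    J = np.empty((m, m))
    for k in range(m):
        dy = np.zeros(m)
        step = h * max(1.0, abs(y[k]))
        dy[k] = step
        J[:, k] = (full_rhs(model, y + dy) - full_rhs(model, y - dy)) / (2 * step)
    return J


def connectivity_block(model: PopulationModel, c: float) -> np.ndarray:
    """Analytic connectivity sub-Jacobian at the homogeneous fixed point.

    Rank-one matrix ``c0 * u w^T`` with ``u = (-N2^2, N1 N2, N1 N2,
    -N1^2)``, ``w = (1, -1, -1, 1)`` and prefactor
    ``c0 = eta sqrt(nu/(pi tau_Ca)) (1/beta_a + 1/beta_d) / (2 c N_E^3)``;
    its eigenvalues are 0 (threefold) and ``lambda_1 = -c0 N_E^2``.
    """
    if model.n_e != 2:
        raise ValueError("analytic connectivity block needs two populations")
    N1, N2 = model.sizes_e
    N_E = model.N_E
    nu = model.nu_target_hz
    c0 = (model.eta * np.sqrt(nu / (np.pi * model.tau_ca_s))
          * (1.0 / model.beta_a + 1.0 / model.beta_d) / (2.0 * c * N_E ** 3))
    u = np.array([-N2 ** 2, N1 * N2, N1 * N2, -N1 ** 2])
    w = np.array([1.0, -1.0, -1.0, 1.0])
    return c0 * np.outer(u, w)


def slow_mode_eigenvalue(tau_ca_s: float = 10.0, nu: float = 8.0,
                         eta: float = 0.7, N_E: float = 10000,
                         c: float = 0.1, beta_a: float = 2.0,
                         beta_d: float = 2.0) -> float:
    """Nonzero eigenvalue ``lambda_1 = -(R_a(0)+R_d(0))/(c N_E)`` (1/s)."""
    Ra0 = element_rate_mean(0.0, sigma_element(eta, nu, tau_ca_s, beta_a))[0]
    Rd0 = element_rate_mean(0.0, sigma_element(eta, nu, tau_ca_s, beta_d))[0]
    return -float(Ra0 + Rd0) / (c * N_E)


def slow_mode_timescale(tau_ca_s: float = 10.0, nu: float = 8.0,
                        eta: float = 0.7, N_E: float = 10000,
                        c: float = 0.1, beta_a: float = 2.0,
                        beta_d: float = 2.0) -> float:
    """Memory lifetime ``tau_diffusion = 1/|lambda_1|`` in seconds.

    Equals ``sqrt(4 pi tau_Ca / (eta^2 nu)) * N_E c / (1/beta_a +
    1/beta_d)``; about 5.7e3 s at default parameters.
    """
    lam = slow_mode_eigenvalue(tau_ca_s, nu, eta, N_E, c, beta_a, beta_d)
    return 1.0 / abs(lam)


def lambda1_eigenvector(N_E1: float, N_E2: float) -> np.ndarray:
    """Connectivity-space eigenvector of the slow mode (tangent of L)."""
    q = N_E1 / N_E2
    return np.array([1.0, -q, -q, q * q])


@dataclass
class JacobianModel:
    """Assembled Jacobian of the two-population system at the global
    fixed point, with its building blocks."""

    J: np.ndarray              # full 9x9
    Jc: np.ndarray             # 4x4 connectivity block
    Jr: np.ndarray             # 3x3 rate block
    op: OperatingPoint         # couplings j_EE .. j_II at the fixed point
    lambda1: float             # slow-mode eigenvalue (1/s)

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.J)


def build_jacobian(model: PopulationModel,
                   op: Optional[OperatingPoint] = None) -> JacobianModel:
    """Assemble the 9x9 Jacobian at the homogeneous grown fixed point.

    Block structure: calcium rows couple to rates with ``1/tau_Ca``;
    connectivity rows couple to calcium with ``(n_W - delta_YW -
    delta_ZW)/(beta N_E)`` and to themselves through the rank-one
    connectivity block; rate rows carry the effective synaptic couplings
    (numeric derivatives of the Siegert function).
    """
    if model.n_e != 2:
        raise ValueError("build_jacobian expects two E populations")
    if abs(model.beta_a - model.beta_d) > 1e-12:
        raise ValueError("analytic assembly requires beta_a == beta_d")
    if op is None:
        op = operating_point(model.lif, model.nu_target_hz, model.N_E,
                             model.N_I, model.epsilon)
    N1, N2 = model.sizes_e
    N_E = model.N_E
    nu = model.nu_target_hz
    c = op.c
    beta = model.beta_d
    tau_rate = model.tau_rate_ms * 1e-3
    eps = model.epsilon

    J = np.zeros((9, 9))
    # calcium block: dphi_Y/dt = (r_Y - phi_Y)/tau_Ca
    J[0, 0] = J[1, 1] = -1.0 / model.tau_ca_s
    J[0, 6] = J[1, 7] = 1.0 / model.tau_ca_s
    # connectivity rows (order C11, C12, C21, C22): calcium couplings
    n_frac = model.sizes_e / N_E
    labels = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for row, (Y, Z) in enumerate(labels):
        for W in (0, 1):
            J[2 + row, W] = (n_frac[W] - (Y == W) - (Z == W)) / (beta * N_E)
    J[2:6, 2:6] = connectivity_block(model, c)
    # rate rows: d r/dt = (f(mu, sigma) - r)/tau_rate
    jEE, jEI, jIE, jII = op.j_ee, op.j_ei, op.j_ie, op.j_ii
    Jr = np.array([
        [-1 + jEE * c * N1, jEE * c * N2, jEI * eps * model.N_I],
        [jEE * c * N1, -1 + jEE * c * N2, jEI * eps * model.N_I],
        [jIE * eps * N1, jIE * eps * N2, -1 + jII * eps * model.N_I],
    ]) / tau_rate
    J[6:9, 6:9] = Jr
    # rate sensitivity to connectivity: d f_Y / d C_YZ = j_EE N_Z r_Z
    J[6, 2] = jEE * N1 * nu / tau_rate
    J[6, 3] = jEE * N2 * nu / tau_rate
    J[7, 4] = jEE * N1 * nu / tau_rate
    J[7, 5] = jEE * N2 * nu / tau_rate
    lam1 = slow_mode_eigenvalue(model.tau_ca_s, nu, model.eta, N_E, c,
                                model.beta_a, model.beta_d)
    return JacobianModel(J, J[2:6, 2:6].copy(), Jr, op, lam1)


# ----------------------------------------------------------------------
# reduced one-population system and oscillation boundary
# ----------------------------------------------------------------------

def reduced_jacobian(tau_ca_s: float, beta_d: float, op: OperatingPoint,
                     model_lif: LIFParams, N_E: float = 10000,
                     N_I: float = 2500, epsilon: float = 0.1,
                     tau_rate_ms: Optional[float] = None) -> np.ndarray:
    """4x4 Jacobian of (phi, C, r_E, r_I) for one plastic population.

    The homeostatic loop is phi -> C (deterministic growth derivative
    ``-1/(N_E beta_d)``) -> r (synaptic gain ``j_EE N_E nu``) -> phi.
    """
    if tau_rate_ms is None:
        tau_rate_ms = model_lif.tau_m / 2.0
    tau_rate = tau_rate_ms * 1e-3
    nu, c = op.nu, op.c
    return np.array([
        [-1.0 / tau_ca_s, 0.0, 1.0 / tau_ca_s, 0.0],
        [-1.0 / (N_E * beta_d), 0.0, 0.0, 0.0],
        [0.0, op.j_ee * N_E * nu / tau_rate,
         (-1.0 + op.j_ee * c * N_E) / tau_rate,
         op.j_ei * epsilon * N_I / tau_rate],
        [0.0, 0.0, op.j_ie * epsilon * N_E / tau_rate,
         (-1.0 + op.j_ii * epsilon * N_I) / tau_rate],
    ])


def _least_stable_imag(tau_ca_s: float, beta_d: float, op: OperatingPoint,
                       lif: LIFParams, N_E: float, N_I: float,
                       epsilon: float) -> Tuple[float, float]:
    lam = np.linalg.eigvals(reduced_jacobian(tau_ca_s, beta_d, op, lif,
                                             N_E, N_I, epsilon))
    lam = lam[np.argsort(-lam.real)]
    return abs(lam[0].imag), lam[0].real


def oscillation_boundary(beta_grid: Sequence[float],
                         lif: Optional[LIFParams] = None,
                         nu: float = 8.0, N_E: float = 10000,
                         N_I: float = 2500, epsilon: float = 0.1,
                         tau_lo: float = 1e-3, tau_hi: float = 500.0,
                         tol: float = 1e-3):
    """Oscillation onset of the homeostatic response.

    For each dendritic growth parameter ``beta_d``, bisect in ``tau_Ca``
    for the smallest calcium time constant at which the least-stable
    eigenvalue pair of the reduced Jacobian acquires a nonzero imaginary
    part.  Returns ``(boundary tau_Ca values, slope of the through-origin
    fit tau_Ca = slope * beta_d, max Re[lambda] seen)``.
    """
    if lif is None:
        lif = LIFParams()
    op = operating_point(lif, nu, N_E, N_I, epsilon)
    bounds = []
    max_re = -np.inf
    for bd in beta_grid:
        lo, hi = tau_lo, tau_hi
        im_lo, re = _least_stable_imag(lo, bd, op, lif, N_E, N_I, epsilon)
        max_re = max(max_re, re)
        osc_lo = im_lo > 1e-12
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            im, re = _least_stable_imag(mid, bd, op, lif, N_E, N_I, epsilon)
            max_re = max(max_re, re)
            if (im > 1e-12) == osc_lo:
                lo = mid
            else:
                hi = mid
        bounds.append(0.5 * (lo + hi))
    beta_grid = np.asarray(beta_grid, float)
    bounds = np.asarray(bounds)
    slope = float((bounds * beta_grid).sum() / (beta_grid ** 2).sum())
    return bounds, slope, max_re


# ----------------------------------------------------------------------
# memory longevity, critical connectivity, turnover
# ----------------------------------------------------------------------

def optimal_target_rate(nu_grid: Sequence[float],
                        lif: Optional[LIFParams] = None,
                        tau_ca_s: float = 10.0, eta: float = 0.7,
                        N_E: float = 10000, N_I: float = 2500,
                        beta_a: float = 2.0, beta_d: float = 2.0):
    """Target rate maximizing the memory lifetime.

    The equilibrium connectivity ``c(nu) = K(nu)/N_E`` is recomputed
    self-consistently for every candidate target rate; infeasible rates
    (no self-consistent in-degree) are skipped.  Returns ``(best rate,
    lifetimes on the grid)``.
    """
    if lif is None:
        lif = LIFParams()
    taus = np.full(len(nu_grid), np.nan)
    for k, nu in enumerate(nu_grid):
        try:
            K = equilibrium_indegree(lif, float(nu), N_E, N_I)
        except ValueError:
            continue
        if K <= 0:
            continue
        taus[k] = slow_mode_timescale(tau_ca_s, float(nu), eta, N_E,
                                      K / N_E, beta_a, beta_d)
    if np.all(np.isnan(taus)):
        raise ValueError("no feasible target rate on the grid")
    best = int(np.nanargmax(taus))
    return float(np.asarray(nu_grid, float)[best]), taus


def rate_block_determinant(x: float, model: PopulationModel,
                           op: OperatingPoint,
                           K_star: Optional[float] = None) -> float:
    """Determinant of the reduced 2x2 rate Jacobian along the line L(x).

    Loss of rate stability along the line attractor occurs where this
    determinant changes sign.
    """
    y = line_attractor_point(x, model, K_star=K_star, r_I=op.r_I)
    N1, N2 = model.sizes_e
    C11, C12, C21, C22 = y[2:6]
    j = op.j_ee
    M = np.array([[-1 + j * C11 * N1, j * C12 * N2],
                  [j * C21 * N1, -1 + j * C22 * N2]])
    return float(np.linalg.det(M))


def critical_connectivity(model: PopulationModel,
                          op: Optional[OperatingPoint] = None) -> float:
    """Critical within-engram connectivity ``eps (1 + N_E2/(N_E1 j_E))``.

    ``j_E = eps N_E j_EE`` is the dimensionless recurrent excitability.
    Beyond this connectivity the fixed-in-degree network loses rate
    stability (population burst regime).  Returns ``inf`` if ``j_E <= 0``
    (no instability possible).
    """
    if op is None:
        op = operating_point(model.lif, model.nu_target_hz, model.N_E,
                             model.N_I, model.epsilon)
    N1, N2 = model.sizes_e
    eps = model.epsilon
    j_E = eps * model.N_E * op.j_ee
    if j_E <= 0:
        return np.inf
    return eps * (1.0 + N2 / (N1 * j_E))


def turnover_ratio(tau_ca_s: float = 10.0, nu: float = 8.0,
                   eta: float = 0.7, N_E: float = 10000, c: float = 0.1,
                   beta_a: float = 2.0, beta_d: float = 2.0) -> float:
    """Daily synapse turnover ratio at the homeostatic set-point.

    TOR = (created + deleted synapses per day) / (2 * synapse count).
    At equilibrium the network creates and deletes
    ``(R_a(0) + R_d(0)) N_E`` synapses per second (fluctuation-driven
    rewiring), so the definitional ratio reduces to ``|lambda_1| * 86400``.
    """
    Ra0 = element_rate_mean(0.0, sigma_element(eta, nu, tau_ca_s, beta_a))[0]
    Rd0 = element_rate_mean(0.0, sigma_element(eta, nu, tau_ca_s, beta_d))[0]
    per_neuron_rate = float(Ra0 + Rd0)      # synapses created /s /neuron
    n_spines = c * N_E                       # synapses per neuron
    created_per_day = per_neuron_rate * 86400.0
    return 2 * created_per_day / (2 * n_spines)


def slow_manifold_dimension(sizes_e: Sequence[float]) -> int:
    """Dimension of the stationary connectivity manifold.

    The stationary states are the configurations preserving all population
    in- and out-degrees; with ``n_E`` plastic populations the constraint
    matrix has rank ``2 n_E - 1`` and the manifold dimension is
    ``(n_E - 1)^2``.  Computed numerically from the nullity of the degree
    constraint matrix.
    """
    sizes = np.asarray(sizes_e, float)
    n = sizes.size
    rows = []
    for Y in range(n):          # in-degree of population Y
        M = np.zeros((n, n))
        M[Y, :] = sizes
        rows.append(M.ravel())
    for Z in range(n):          # out-degree of population Z
        M = np.zeros((n, n))
        M[:, Z] = sizes
        rows.append(M.ravel())
    A = np.array(rows)
    rank = np.linalg.matrix_rank(A, tol=1e-9 * np.abs(A).max())
    return n * n - rank
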