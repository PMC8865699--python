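"""Compiled fast path for the population-model ODE integrator.

Numerics mirror :mod:`engramnet.meanfield` (which holds the reference
scipy-based implementations); tests cross-check the two.  The Siegert
integrand is evaluated through the scaled complementary error function;
strongly subthreshold operating points (upper limit above ~5) switch to the
leading asymptotic term, where the rate is dynamically zero (< 1e-9 /s)
but remains finite and monotone up to arguments of +-40.
"""

import math

import numpy as np
from numba import njit

_GLX, _GLW = np.polynomial.legendre.leggauss(48)
_SQRT_PI = math.sqrt(math.pi)


@njit(cache=True)
def _erfcx_pos(x):
    """erfcx(x) for x >= 0."""
    if x < 25.0:
        return math.exp(x * x) * math.erfc(x)
    ix2 = 1.0 / (x * x)
    return (1.0 - 0.5 * ix2 * (1.0 - 1.5 * ix2)) / (x * _SQRT_PI)


@njit(cache=True)
def _siegert_nb(mu, sigma, tau_s, tref_s, V_th, V_r, glx, glw):
    """Stationary LIF rate; see meanfield.siegert_rate."""
    yr = (V_r - mu) / sigma
    yth = (V_th - mu) / sigma
    if yth > 5.0:
        # deep subthreshold: I ~ e^{yth^2}/(2 yth) * 2, rate ~ 0
        if yth > 25.0:
            return yth * math.exp(-yth * yth) / (tau_s * _SQRT_PI)
        I = math.exp(yth * yth) / yth
        return 1.0 / (tref_s + tau_s * _SQRT_PI * I)
    I = 0.0
    # negative part: integrand erfcx(-u), u in [min(yr,0), min(yth,0)]
    a = yr if yr < 0.0 else 0.0
    b = yth if yth < 0.0 else 0.0
    if b > a:
        mid = 0.5 * (a + b)
        half = 0.5 * (b - a)
        s = 0.0
        for k in range(glx.shape[0]):
            s += glw[k] * _erfcx_pos(-(mid + half * glx[k]))
        I += half * s
    # positive part: integrand 2 e^{u^2} - erfcx(u), u in [max(yr,0), yth]
    a = yr if yr > 0.0 else 0.0
    b = yth
    if b > a:
        mid = 0.5 * (a + b)
        half = 0.5 * (b - a)
        s = 0.0
        for k in range(glx.shape[0]):
            u = mid + half * glx[k]
            s += glw[k] * (2.0 * math.exp(u * u) - _erfcx_pos(u))
        I += half * s
    return 1.0 / (tref_s + tau_s * _SQRT_PI * I)


@njit(cache=True)
def _rect(m, sigma):
    """Rectified-Gaussian mean R_sigma(m)."""
    if sigma == 0.0:
        return m if m > 0.0 else 0.0
    z = m / (1.4142135623730951 * sigma)
    return 0.5 * (m + m * math.erf(z)
                  + 0.7978845608028654 * sigma * math.exp(-z * z))


@njit(cache=True)
def _mf_integrate(sizes, K_I, K_IE, tau_s, tref_s, V_th, V_r, J, g, nu_ext,
                  nu, beta_a, beta_d, sig_a, sig_d, tau_ca, tau_rate,
                  dt, n_del, ep_steps, ep_mult, rec_stride,
                  phi, C, r, T, PHI, CC, R, glx, glw):
    """Integrate the population ODEs; returns (n_recorded, runaway)."""
    n = sizes.shape[0]
    N_E = 0.0
    for y in range(n):
        N_E += sizes[y]
    rbuf = np.empty((n_del, n + 1))
    for k in range(n_del):
        for y in range(n + 1):
            rbuf[k, y] = r[y]
    bpos = 0
    f = np.empty(n + 1)
    dC = np.empty((n, n))
    ap = np.empty(n)
    am = np.empty(n)
    dp = np.empty(n)
    dm = np.empty(n)
    apc = np.empty(n)
    dpc = np.empty(n)
    K_in = np.empty(n)
    K_out = np.empty(n)
    runaway = False
    nrec = 0
    # record initial state
    T[nrec] = 0.0
    for y in range(n):
        PHI[nrec, y] = phi[y]
        for z in range(n):
            CC[nrec, y, z] = C[y, z]
    for y in range(n + 1):
        R[nrec, y] = r[y]
    nrec += 1
    step = 0
    t = 0.0
    for e in range(ep_steps.shape[0]):
        for _ in range(ep_steps[e]):
            # --- input moments and transfer, with delayed rates
            rI_d = rbuf[bpos, n]
            for y in range(n):
                rec = 0.0
                for z in range(n):
                    rec += C[y, z] * sizes[z] * rbuf[bpos, z]
                ext = nu_ext * ep_mult[e, y]
                mu = tau_s * (J * rec - g * J * K_I * rI_d + J * ext)
                var = tau_s * (J * J * rec + g * g * J * J * K_I * rI_d
                               + J * J * ext)
                f[y] = _siegert_nb(mu, math.sqrt(var), tau_s, tref_s,
                                   V_th, V_r, glx, glw)
            re_mean = 0.0
            for y in range(n):
                re_mean += sizes[y] * rbuf[bpos, y]
            re_mean /= N_E
            mu = tau_s * (J * K_IE * re_mean - g * J * K_I * rI_d + J * nu_ext)
            var = tau_s * (J * J * K_IE * re_mean + g * g * J * J * K_I * rI_d
                           + J * J * nu_ext)
            f[n] = _siegert_nb(mu, math.sqrt(var), tau_s, tref_s,
                               V_th, V_r, glx, glw)
            # --- element rates with calcium-noise correction
            for y in range(n):
                drv = nu - phi[y]
                ap[y] = _rect(drv / beta_a, sig_a)
                am[y] = _rect(-drv / beta_a, sig_a)
                dp[y] = _rect(drv / beta_d, sig_d)
                dm[y] = _rect(-drv / beta_d, sig_d)
                ki = 0.0
                ko = 0.0
                for z in range(n):
                    ki += C[y, z] * sizes[z]
                    ko += C[z, y] * sizes[z]
                K_in[y] = ki
                K_out[y] = ko
            for y in range(n):
                s1 = dp[y]
                s2 = ap[y]
                for z in range(n):
                    if K_out[z] > 0.0:
                        s1 += C[y, z] * sizes[z] * am[z] / K_out[z]
                    if K_in[z] > 0.0:
                        s2 += C[z, y] * sizes[z] * dm[z] / K_in[z]
                dpc[y] = s1
                apc[y] = s2
            rho_a = 0.0
            rho_d = 0.0
            for y in range(n):
                rho_a += sizes[y] * apc[y]
                rho_d += sizes[y] * dpc[y]
            rho = rho_a if rho_a > rho_d else rho_d
            for y in range(n):
                for z in range(n):
                    cre = dpc[y] * apc[z] / rho if rho > 0.0 else 0.0
                    dele = 0.0
                    if K_in[y] > 0.0:
                        dele += C[y, z] * dm[y] / K_in[y]
                    if K_out[z] > 0.0:
                        dele += C[y, z] * am[z] / K_out[z]
                    dC[y, z] = cre - dele
            # --- Euler updates, delay buffer rotation
            for y in range(n + 1):
                rbuf[bpos, y] = r[y]
            bpos += 1
            if bpos == n_del:
                bpos = 0
            for y in range(n + 1):
                r[y] = r[y] + dt * (f[y] - r[y]) / tau_rate
            for y in range(n):
                phi[y] = phi[y] + dt * (r[y] - phi[y]) / tau_ca
                if r[y] > 100.0:
                    runaway = True
                for z in range(n):
                    cyz = C[y, z] + dt * dC[y, z]
                    C[y, z] = cyz if cyz > 0.0 else 0.0
            step += 1
            t += dt
            if step % rec_stride == 0 and nrec < T.shape[0]:
                T[nrec] = t
                for y in range(n):
                    PHI[nrec, y] = phi[y]
                    for z in range(n):
                        CC[nrec, y, z] = C[y, z]
                for y in range(n + 1):
                    R[nrec, y] = r[y]
                nrec += 1
    return nrec, runaway
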