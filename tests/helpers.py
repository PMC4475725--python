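"""Independent oracles used by the test suite.

These implementations deliberately avoid the package's code paths: the
two-site CPMG oracle is the Carver-Richards echo-train treatment carried to
its exact finite-n closed form using only scalar 2x2 algebra (closed-form
matrix exponential, closed-form eigenvalues of the two-echo unit propagator,
exact projection of the initial magnetization), the multi-state CPMG oracle
propagates with scipy's expm directly, and the CEST oracle integrates the
Bloch-McConnell ODEs with an adaptive Runge-Kutta solver.
"""

from __future__ import annotations

import cmath

import numpy as np
import scipy.linalg
from scipy.integrate import solve_ivp


def carver_richards_exact(nu_cpmg, t_cpmg, p_e, k_ex, delta_omega,
                          r2g, r2e) -> np.ndarray:
    """Exact two-site CPMG R_2,eff for ideal 180 pulses, all echo counts.

    ``delta_omega`` in rad/s.  Scalar closed-form algebra throughout.
    """
    k_ge = p_e * k_ex
    k_eg = (1.0 - p_e) * k_ex
    a00 = -k_ge - r2g + 0j
    a01 = k_eg + 0j
    a10 = k_ge + 0j
    a11 = -k_eg - r2e + 1j * delta_omega

    def expm2(t):
        mu = (a00 + a11) / 2
        b, c, d = a00 - mu, a01, a10
        q = cmath.sqrt(b * b + c * d)
        ch = cmath.cosh(q * t)
        sh = cmath.sinh(q * t) / q if abs(q) > 1e-300 else t
        f = cmath.exp(mu * t)
        return (f * (ch + sh * b), f * (sh * c), f * (sh * d), f * (ch - sh * b))

    def mul(x, y):
        return (x[0] * y[0] + x[1] * y[2], x[0] * y[1] + x[1] * y[3],
                x[2] * y[0] + x[3] * y[2], x[2] * y[1] + x[3] * y[3])

    def conj2(x):
        return tuple(z.conjugate() for z in x)

    out = []
    for v in np.atleast_1d(np.asarray(nu_cpmg, dtype=float)):
        n = int(round(v * t_cpmg))
        tau = 1.0 / (4.0 * v)
        p = expm2(tau)
        # two echoes (tau-180-tau)(tau-180-tau) form one linear unit
        unit = mul(mul(p, conj2(p)), mul(conj2(p), p))
        tr = unit[0] + unit[3]
        det = unit[0] * unit[3] - unit[1] * unit[2]
        disc = cmath.sqrt(tr * tr - 4 * det)
        m0 = (1.0 - p_e, p_e)
        if abs(disc) < 1e-13 * max(1.0, abs(tr)):
            m = m0
            for _ in range(n):
                m = (unit[0] * m[0] + unit[1] * m[1],
                     unit[2] * m[0] + unit[3] * m[1])
            signal = abs(m[0] + m[1])
        else:
            l1, l2 = (tr + disc) / 2, (tr - disc) / 2
            if abs(unit[1]) > 1e-300:
                v1 = (unit[1], l1 - unit[0])
                v2 = (unit[1], l2 - unit[0])
            else:
                v1 = (l1 - unit[3], unit[2])
                v2 = (l2 - unit[3], unit[2])
            den = v1[0] * v2[1] - v1[1] * v2[0]
            c1 = (m0[0] * v2[1] - m0[1] * v2[0]) / den
            c2 = (v1[0] * m0[1] - v1[1] * m0[0]) / den
            signal = abs(c1 * l1**n * (v1[0] + v1[1])
                         + c2 * l2**n * (v2[0] + v2[1]))
        out.append(-np.log(signal) / t_cpmg)
    return np.array(out)


def brute_force_cpmg(rate_matrix, populations, shifts_ppm, r2, nu_cpmg,
                     t_cpmg, nucleus_freq) -> np.ndarray:
    """N-state CPMG by direct expm propagation (independent code path)."""
    shifts = np.asarray(shifts_ppm, dtype=float)
    omega = 2 * np.pi * nucleus_freq * (shifts - shifts[0])
    a = (np.asarray(rate_matrix, dtype=complex)
         + np.diag(1j * omega - np.asarray(r2, dtype=complex)))
    pops = np.asarray(populations, dtype=complex)
    out = []
    for v in np.atleast_1d(np.asarray(nu_cpmg, dtype=float)):
        n = int(round(v * t_cpmg))
        tau = 1.0 / (4.0 * v)
        p = scipy.linalg.expm(a * tau)
        m = pops.copy()
        for _ in range(2 * n):
            m = p @ np.conj(p @ m)
        out.append(float(-np.log(np.abs(m.sum()) / np.abs(pops.sum())) / t_cpmg))
    return np.array(out)


def lumpable_asymmetric_dimer_3state(k_fwd, k_dm, dw_ppm, r2, nu_cpmg,
                                     t_cpmg, nucleus_freq,
                                     pool_split=0.9) -> np.ndarray:
    """Three-state (M, D2, D1) oracle for the reduced asymmetric-dimer model.

    The silent subunit environment D2 shares the monomer's shift and R2 and
    exchanges into the shifted environment D1 at the same per-capita rate as
    M, which makes {M, D2} exactly lumpable onto the two-state reduction
    with forward rate ``k_fwd`` = k_MD [M] and reverse ``k_dm``.
    """
    p_d = k_fwd / (k_fwd + k_dm)
    s = pool_split
    k = np.zeros((3, 3))  # states: 0 = M, 1 = D2 (silent), 2 = D1
    k[2, 0] = k_fwd
    k[2, 1] = k_fwd
    k[0, 2] = k_dm * s
    k[1, 2] = k_dm * (1 - s)
    mu = 50.0  # silent within-pool exchange; any value preserves lumpability
    k[1, 0] = mu * (1 - s)
    k[0, 1] = mu * s
    k -= np.diag(k.sum(axis=0))
    pops = [s * (1 - p_d), (1 - s) * (1 - p_d), p_d]
    return brute_force_cpmg(k, pops, [0.0, 0.0, dw_ppm], [r2, r2, r2],
                            nu_cpmg, t_cpmg, nucleus_freq)


def cest_ode(dw_ppm, k_ex, p_e, offsets_ppm, b1_field, nucleus_freq,
             r1, r2, t_cest) -> np.ndarray:
    """Two-state CEST by direct ODE integration of the Bloch-McConnell system."""
    k_ge = p_e * k_ex
    k_eg = (1.0 - p_e) * k_ex
    w1 = 2 * np.pi * b1_field
    out = []
    for off in np.atleast_1d(np.asarray(offsets_ppm, dtype=float)):
        og = 2 * np.pi * nucleus_freq * (0.0 - off)
        oe = 2 * np.pi * nucleus_freq * (dw_ppm - off)

        def f(_t, m):
            gx, gy, gz, ex_, ey, ez = m
            return [
                -r2 * gx + og * gy - k_ge * gx + k_eg * ex_,
                -og * gx - r2 * gy + w1 * gz - k_ge * gy + k_eg * ey,
                -w1 * gy - r1 * gz - k_ge * gz + k_eg * ez,
                -r2 * ex_ + oe * ey + k_ge * gx - k_eg * ex_,
                -oe * ex_ - r2 * ey + w1 * ez + k_ge * gy - k_eg * ey,
                -w1 * ey - r1 * ez + k_ge * gz - k_eg * ez,
            ]

        sol = solve_ivp(f, [0.0, t_cest], [0, 0, 1 - p_e, 0, 0, p_e],
                        rtol=1e-10, atol=1e-12)
        out.append(sol.y[2, -1] / (1 - p_e))
    return np.array(out)
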