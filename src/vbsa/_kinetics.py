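"""Compiled mass-action kinetics kernels.

The right-hand side and Jacobian of the kinetic equations are evaluated once
per solver step for up to ~10^5 trajectories in a sensitivity run, so both
are JIT-compiled. Signatures follow ``scipy.integrate.odeint`` order
``(y, t, *args)``.

Exponent matrices are dense ``(N, M)`` float arrays of small nonnegative
integers; ``q**0`` contributes nothing and is skipped.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def mass_action_rhs(q, t, kf, kr, Vr, Vp, S):
    """dq/dt = S @ rho with rho_m = kf_m prod q^Vr[:,m] - kr_m prod q^Vp[:,m]."""
    N, M = Vr.shape
    dq = np.zeros(N)
    for m in range(M):
        pf = kf[m]
        pr = kr[m]
        for n in range(N):
            v = Vr[n, m]
            if v != 0.0:
                pf *= q[n] ** v
            v = Vp[n, m]
            if v != 0.0:
                pr *= q[n] ** v
        rho = pf - pr
        for n in range(N):
            s = S[n, m]
            if s != 0.0:
                dq[n] += s * rho
    return dq


@numba.njit(cache=True)
def mass_action_jac(q, t, kf, kr, Vr, Vp, S):
    """Analytic Jacobian d(dq/dt)/dq; keeps the stiff solver off finite
    differences (23 extra RHS calls per Jacobian on a MAPK-size model)."""
    N, M = Vr.shape
    J = np.zeros((N, N))
    for m in range(M):
        for k in range(N):
            df = 0.0
            dr = 0.0
            vk = Vr[k, m]
            if vk != 0.0:
                p = kf[m] * vk
                for n in range(N):
                    e = Vr[n, m]
                    if n == k:
                        e -= 1.0
                    if e != 0.0:
                        p *= q[n] ** e
                df = p
            vk = Vp[k, m]
            if vk != 0.0:
                p = kr[m] * vk
                for n in range(N):
                    e = Vp[n, m]
                    if n == k:
                        e -= 1.0
                    if e != 0.0:
                        p *= q[n] ** e
                dr = p
            d = df - dr
            if d != 0.0:
                for n in range(N):
                    s = S[n, m]
                    if s != 0.0:
                        J[n, k] += s * d
    return J
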