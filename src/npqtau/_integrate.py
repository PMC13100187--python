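"""Compiled right-hand side and adaptive Runge–Kutta integration.

The quenching kinetics are a 12-dimensional mass-action system that
must be solved ~10⁵ times during stepwise fitting and bootstrapping, so
the right-hand side and a Dormand–Prince RK45 stepper are JIT-compiled
with numba.  ``scipy.integrate.solve_ivp`` remains available as an
alternate backend through :func:`npqtau.kinetics.simulate` and is used
as an independent cross-check in the test suite.

State vector layout (concentrations in mmol/mol Chl):
``[V, A, Z, PV, PA, PZ, PL, QV, QA, QZ, QL, alpha_qI]``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the packed parameter vector
(I_KVA, I_KAZ, I_KZA, I_KAV,
 I_PVF, I_PVB, I_PAF, I_PAB, I_PZF, I_PZB,
 I_QVF, I_QVB, I_QAF, I_QAB, I_QZF, I_QZB, I_QLF, I_QLB,
 I_PTOT, I_KQI_HL, I_KQI_LASER, I_VDE_ACT, I_ZEP_ACT) = range(23)

NPAR = 23
NSTATE = 12

(SV, SA, SZ, SPV, SPA, SPZ, SPL, SQV, SQA, SQZ, SQL, SALPHA) = range(12)


def pack_params(p) -> np.ndarray:
    """Pack a KineticParameters instance into the RHS parameter vector."""
    return np.array(
        [p.k_va, p.k_az, p.k_za, p.k_av,
         p.k_pvf, p.k_pvb, p.k_paf, p.k_pab, p.k_pzf, p.k_pzb,
         p.k_qvf, p.k_qvb, p.k_qaf, p.k_qab, p.k_qzf, p.k_qzb,
         p.k_qlf, p.k_qlb,
         p.P_tot, p.k_qI_HL, p.k_qI_laser, p.VDE_act, p.ZEP_act],
        dtype=np.float64,
    )


@njit(cache=True)
def rhs(y, par, u, laser, out):
    """Mass-action derivatives; light gate u ∈ {0,1}, laser ∈ {0,1}."""
    V, A, Z = y[SV], y[SA], y[SZ]
    PV, PA_, PZ = y[SPV], y[SPA], y[SPZ]
    PL = y[SPL]
    QV, QA_, QZ, QL = y[SQV], y[SQA], y[SQZ], y[SQL]
    alpha = y[SALPHA]

    vde = u * par[I_VDE_ACT]
    zep = par[I_ZEP_ACT]
    # xanthophyll cycle on the free pools
    f_va = par[I_KVA] * vde * V
    f_az = par[I_KAZ] * vde * A
    f_za = par[I_KZA] * zep * Z
    f_av = par[I_KAV] * zep * A
    # antenna binding, free sites shared by V/A/Z
    p_free = par[I_PTOT] - PV - PA_ - PZ
    if p_free < 0.0:
        p_free = 0.0
    b_v = par[I_PVF] * V * p_free - par[I_PVB] * PV
    b_a = par[I_PAF] * A * p_free - par[I_PAB] * PA_
    b_z = par[I_PZF] * Z * p_free - par[I_PZB] * PZ
    # quencher activation (PsbS-gated forward)
    q_v = par[I_QVF] * u * PV - par[I_QVB] * QV
    q_a = par[I_QAF] * u * PA_ - par[I_QAB] * QA_
    q_z = par[I_QZF] * u * PZ - par[I_QZB] * QZ
    q_l = par[I_QLF] * u * PL - par[I_QLB] * QL

    out[SV] = -f_va + f_av - b_v
    out[SA] = f_va - f_az + f_za - f_av - b_a
    out[SZ] = f_az - f_za - b_z
    out[SPV] = b_v - q_v
    out[SPA] = b_a - q_a
    out[SPZ] = b_z - q_z
    out[SPL] = -q_l
    out[SQV] = q_v
    out[SQA] = q_a
    out[SQZ] = q_z
    out[SQL] = q_l
    out[SALPHA] = (par[I_KQI_HL] * u + par[I_KQI_LASER] * laser) * (1.0 - alpha)


# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0, 1.0, 1.0])
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (19372.0 / 6561.0, -25360.0 / 2187.0,
                          64448.0 / 6561.0, -212.0 / 729.0)
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0,
                                46732.0 / 5247.0, 49.0 / 176.0,
                                -5103.0 / 18656.0)
_B1, _B3, _B4, _B5, _B6 = (35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
                           -2187.0 / 6784.0, 11.0 / 84.0)
# 4th-order embedded weights
_E1, _E3, _E4, _E5, _E6, _E7 = (5179.0 / 57600.0, 7571.0 / 16695.0,
                                393.0 / 640.0, -92097.0 / 339200.0,
                                187.0 / 2100.0, 1.0 / 40.0)


@njit(cache=True)
def _step(y, h, par, u, laser, k1, ynew, err):
    """One RK45 step; fills ynew and the per-component error estimate."""
    n = y.shape[0]
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    k7 = np.empty(n)
    tmp = np.empty(n)

    for i in range(n):
        tmp[i] = y[i] + h * _A21 * k1[i]
    rhs(tmp, par, u, laser, k2)
    for i in range(n):
        tmp[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
    rhs(tmp, par, u, laser, k3)
    for i in range(n):
        tmp[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
    rhs(tmp, par, u, laser, k4)
    for i in range(n):
        tmp[i] = y[i] + h * (_A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i]
                             + _A54 * k4[i])
    rhs(tmp, par, u, laser, k5)
    for i in range(n):
        tmp[i] = y[i] + h * (_A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i]
                             + _A64 * k4[i] + _A65 * k5[i])
    rhs(tmp, par, u, laser, k6)
    for i in range(n):
        ynew[i] = y[i] + h * (_B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i]
                              + _B5 * k5[i] + _B6 * k6[i])
    rhs(ynew, par, u, laser, k7)
    for i in range(n):
        y4 = y[i] + h * (_E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i]
                         + _E5 * k5[i] + _E6 * k6[i] + _E7 * k7[i])
        err[i] = ynew[i] - y4
    return k7  # FSAL: derivative at ynew


@njit(cache=True)
def integrate_phase(y0, t0, t1, par, u, laser, t_eval, y_out, rtol, atol):
    """Integrate one constant-light phase from t0 to t1.

    Output states are recorded at the (sorted) times in ``t_eval`` that
    fall inside [t0, t1]; steps are shortened to land on them exactly.
    Returns the state at t1.
    """
    n = y0.shape[0]
    y = y0.copy()
    k1 = np.empty(n)
    ynew = np.empty(n)
    err = np.empty(n)
    rhs(y, par, u, laser, k1)

    # next output index
    j = 0
    while j < t_eval.shape[0] and t_eval[j] < t0 - 1e-12:
        j += 1

    t = t0
    h = (t1 - t0) * 1e-3
    if h <= 0.0:
        h = 1e-6
    max_h = t1 - t0
    n_attempts = 0
    while t < t1 - 1e-12:
        n_attempts += 1
        if n_attempts > 500_000:
            raise ValueError("step budget exhausted (pathologically stiff "
                             "parameter values)")
        # record outputs that coincide with the current time
        while j < t_eval.shape[0] and t_eval[j] <= t + 1e-9 and t_eval[j] <= t1 + 1e-9:
            for i in range(n):
                y_out[j, i] = y[i]
            j += 1
        target = t1
        if j < t_eval.shape[0] and t_eval[j] < target:
            target = t_eval[j]
        if h > target - t:
            h = target - t
        if h > max_h:
            h = max_h
        # attempt step
        k7 = _step(y, h, par, u, laser, k1, ynew, err)
        enorm = 0.0
        for i in range(n):
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            e = err[i] / sc
            enorm += e * e
        enorm = np.sqrt(enorm / n)
        if enorm <= 1.0:
            t = t + h
            for i in range(n):
                y[i] = ynew[i]
                k1[i] = k7[i]
            fac = 5.0
            if enorm > 0.0:
                fac = 0.9 * enorm ** (-0.2)
                if fac > 5.0:
                    fac = 5.0
            h = h * fac
        else:
            fac = 0.9 * enorm ** (-0.2)
            if fac < 0.2:
                fac = 0.2
            h = h * fac
            if h < 1e-12:
                raise ValueError("step size underflow in RK45 integration")
    while j < t_eval.shape[0] and t_eval[j] <= t1 + 1e-9:
        for i in range(n):
            y_out[j, i] = y[i]
        j += 1
    return y


def integrate_sequence(y0, par, edges, u_phases, laser, t_eval,
                       rtol=1e-8, atol=1e-11):
    """Integrate across all phases of a light sequence.

    Parameters
    ----------
    y0 : initial state vector (12,)
    par : packed parameter vector (see :func:`pack_params`)
    edges : phase boundary times, length n_phases + 1, starting at 0
    u_phases : light indicator per phase (0/1)
    laser : 0/1 detection-laser indicator
    t_eval : sorted output times within [0, edges[-1]]

    The integration restarts at every phase boundary so the binary light
    gate is handled event-exactly.  Returns the states at ``t_eval``.
    """
    t_eval = np.ascontiguousarray(t_eval, dtype=np.float64)
    par = np.ascontiguousarray(par, dtype=np.float64)
    y = np.ascontiguousarray(y0, dtype=np.float64)
    y_out = np.empty((t_eval.shape[0], y.shape[0]))
    for k in range(len(u_phases)):
        y = integrate_phase(
            y, float(edges[k]), float(edges[k + 1]), par,
            float(u_phases[k]), float(laser), t_eval, y_out, rtol, atol,
        )
    return y_out
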