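"""Numba time-stepping kernels for the 1D conduction solver.

Both kernels advance the vertex-centred finite-volume discretization

    rhoC_i w_i dx dT_i/dt = [kh_i (T_{i+1}-T_i) - kh_{i-1} (T_i-T_{i-1})]/dx + q_surf delta_{i0}

with half cells (w = 1/2) at both boundaries and harmonic-mean interface
conductivities kh.  The surface source q_surf is h (T_fluid - T_0) for a
convective phase, the prescribed net flux for a flame phase, and zero for
an adiabatic phase; the deepest node is always adiabatic.

The update coefficients are pre-scaled by dt:

    cL[i] = dt kh_{i-1} / (rhoC_i w_i dx^2)   (0 at the surface node)
    cR[i] = dt kh_i / (rhoC_i w_i dx^2)       (0 at the bottom node)
    cS    = 2 dt / (rhoC_0 dx)                (surface source coefficient)

Boundary-condition codes: 0 = adiabatic, 1 = convective (p1 = h,
p2 = fluid temperature), 2 = fixed flux (p1 = net flux into the skin).
"""

import numba
import numpy as np

BC_ADIABATIC = 0
BC_CONVECTIVE = 1
BC_FIXED_FLUX = 2


@numba.njit(cache=True, fastmath=True)
def run_phase_explicit(T, T_work, cL, cR, cS, bc_kind, p1, p2,
                       step_start, step_stop, record_every, rec_nodes, out):
    """Advance forward-Euler steps [step_start, step_stop) of one phase.

    Records the listed nodes into ``out`` at every global step divisible
    by ``record_every`` (the state *at* that step, before its update).
    Returns the index of the first non-finite step, or -1 on success.
    """
    n = T.shape[0]
    h_eff = 0.0
    q_const = 0.0
    if bc_kind == BC_CONVECTIVE:
        h_eff = p1
        q_const = p1 * p2
    elif bc_kind == BC_FIXED_FLUX:
        q_const = p1
    for step in range(step_start, step_stop):
        if step % record_every == 0:
            row = step // record_every
            for j in range(rec_nodes.shape[0]):
                out[row, j] = T[rec_nodes[j]]
        q_surf = q_const - h_eff * T[0]
        T_work[0] = T[0] + cR[0] * (T[1] - T[0]) + cS * q_surf
        for i in range(1, n - 1):
            T_work[i] = T[i] + cR[i] * (T[i + 1] - T[i]) + cL[i] * (T[i - 1] - T[i])
        T_work[n - 1] = T[n - 1] + cL[n - 1] * (T[n - 2] - T[n - 1])
        for i in range(n):
            T[i] = T_work[i]
        if not np.isfinite(T[0]):
            return step
    return -1


@numba.njit(cache=True, fastmath=True)
def run_phase_implicit(T, rhs, lo, di, up, cprime, dprime, cL, cR, cS, theta,
                       bc_kind, p1, p2, step_start, step_stop,
                       record_every, rec_nodes, out):
    """Advance theta-scheme steps of one phase with a Thomas solve per step.

    theta = 0.5 gives Crank-Nicolson, theta = 1 backward Euler.  The
    tridiagonal left-hand side (lo, di, up) is constant within a phase.
    Returns the index of the first non-finite step, or -1 on success.
    """
    n = T.shape[0]
    h_eff = 0.0
    q_const = 0.0
    if bc_kind == BC_CONVECTIVE:
        h_eff = p1
        q_const = p1 * p2
    elif bc_kind == BC_FIXED_FLUX:
        q_const = p1

    # LHS rows for this phase
    for i in range(n):
        lo[i] = -theta * cL[i]
        up[i] = -theta * cR[i]
        di[i] = 1.0 + theta * (cL[i] + cR[i])
    di[0] += theta * cS * h_eff

    # Thomas forward-elimination multipliers are step-independent
    cprime[0] = up[0] / di[0]
    for i in range(1, n):
        denom = di[i] - lo[i] * cprime[i - 1]
        cprime[i] = up[i] / denom
        di[i] = denom  # store the reduced diagonal

    one_m = 1.0 - theta
    for step in range(step_start, step_stop):
        if step % record_every == 0:
            row = step // record_every
            for j in range(rec_nodes.shape[0]):
                out[row, j] = T[rec_nodes[j]]
        rhs[0] = T[0] + one_m * (cR[0] * (T[1] - T[0]) + cS * (q_const - h_eff * T[0])) \
            + theta * cS * q_const
        for i in range(1, n - 1):
            rhs[i] = T[i] + one_m * (cR[i] * (T[i + 1] - T[i]) + cL[i] * (T[i - 1] - T[i]))
        rhs[n - 1] = T[n - 1] + one_m * cL[n - 1] * (T[n - 2] - T[n - 1])

        dprime[0] = rhs[0] / di[0]
        for i in range(1, n):
            dprime[i] = (rhs[i] - lo[i] * dprime[i - 1]) / di[i]
        T[n - 1] = dprime[n - 1]
        for i in range(n - 2, -1, -1):
            T[i] = dprime[i] - cprime[i] * T[i + 1]
        if not np.isfinite(T[0]):
            return step
    return -1
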