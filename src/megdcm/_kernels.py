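"""Batched numerical kernels for the conductance neural-mass model.

All kernels operate on a batch of B independent parameter sets at once
(used both for plain simulation and for the finite-difference sensitivity
sweeps of the variational fitter). The internal state layout is
channel-major: ``X[b, 0:16] = V``, ``X[b, 16:32] = g_ampa``,
``X[b, 32:48] = g_gaba``, ``X[b, 48:64] = g_nmda``, with population index
``p = 4 * region + pop`` and populations ordered (ss, sp, ii, dp).

Couplings are passed as sparse entry lists (rows, cols, weights) per
receptor channel; weights carry the batch dimension.
"""

import numpy as np
from numba import njit

_FM = {"contract", "arcp", "nsz", "reassoc"}

NPOP = 16
NSTATE = 64


@njit(cache=True, fastmath=_FM)
def _deriv(X, dX, rowsA, colsA, wA, rowsG, colsG, wG, rowsN, colsN, wN,
           kapA, kapG, kapN, cmask, uvals,
           vl, ve, vi, vthr, slope, amg, gl, cm,
           sig, drvA, drvG, drvN):
    B = X.shape[0]
    for b in range(B):
        for p in range(NPOP):
            sig[p] = 1.0 / (1.0 + np.exp(-(X[b, p] - vthr) / slope))
            drvA[p] = 0.0
            drvG[p] = 0.0
            drvN[p] = 0.0
        for e in range(rowsA.shape[0]):
            drvA[rowsA[e]] += wA[b, e] * sig[colsA[e]]
        for e in range(rowsG.shape[0]):
            drvG[rowsG[e]] += wG[b, e] * sig[colsG[e]]
        for e in range(rowsN.shape[0]):
            drvN[rowsN[e]] += wN[b, e] * sig[colsN[e]]
        for p in range(NPOP):
            V = X[b, p]
            mg = 1.0 / (1.0 + 0.2 * np.exp(-amg * V))
            dX[b, p] = (gl * (vl - V) + X[b, 16 + p] * (ve - V)
                        + X[b, 32 + p] * (vi - V)
                        + X[b, 48 + p] * mg * (ve - V)
                        + cmask[p] * uvals[b]) / cm
            dX[b, 16 + p] = kapA[b, p] * (drvA[p] - X[b, 16 + p])
            dX[b, 32 + p] = kapG[b, p] * (drvG[p] - X[b, 32 + p])
            dX[b, 48 + p] = kapN[b, p] * (drvN[p] - X[b, 48 + p])


@njit(cache=True, fastmath=_FM)
def rk4_run(X0, rowsA, colsA, wA, rowsG, colsG, wG, rowsN, colsN, wN,
            kapA, kapG, kapN, cmask, onset, width, amp,
            t0, dt, nsteps,
            vl, ve, vi, vthr, slope, amg, gl, cm,
            jw, obsg, V0, store_traj):
    """Fixed-step RK4 integration with on-the-fly observation.

    Returns ``(y, traj, Xf)`` where ``y[b, r, it]`` is the observed
    (baseline subtracted, J-weighted, gain-scaled) signal per region,
    ``traj`` is the full state trajectory ``(B, nsteps + 1, 64)`` when
    ``store_traj`` (else empty), and ``Xf`` is the final state.
    """
    B = X0.shape[0]
    nr = NPOP // 4
    X = X0.copy()
    dX1 = np.empty((B, NSTATE))
    dX2 = np.empty((B, NSTATE))
    dX3 = np.empty((B, NSTATE))
    dX4 = np.empty((B, NSTATE))
    Xs = np.empty((B, NSTATE))
    sig = np.empty(NPOP)
    drvA = np.empty(NPOP)
    drvG = np.empty(NPOP)
    drvN = np.empty(NPOP)
    u = np.empty(B)
    y = np.empty((B, nr, nsteps + 1))
    alive = np.ones(B, dtype=np.bool_)
    if store_traj:
        traj = np.empty((B, nsteps + 1, NSTATE))
    else:
        traj = np.empty((0, 0, 0))

    for it in range(nsteps + 1):
        for b in range(B):
            if alive[b]:
                for r in range(nr):
                    acc = 0.0
                    for p in range(4):
                        acc += jw[p] * (X[b, 4 * r + p] - V0[b, 4 * r + p])
                    y[b, r, it] = obsg[b, r] * acc
            else:
                # diverged element: emit a huge sentinel, freeze its state
                for r in range(nr):
                    y[b, r, it] = 1e30
        if store_traj:
            traj[:, it, :] = X
        if it == nsteps:
            break
        t = t0 + it * dt
        # stage 1
        for b in range(B):
            z = (t - onset[b]) / width[b]
            u[b] = amp[b] * np.exp(-0.5 * z * z)
        _deriv(X, dX1, rowsA, colsA, wA, rowsG, colsG, wG, rowsN, colsN, wN,
               kapA, kapG, kapN, cmask, u, vl, ve, vi, vthr, slope, amg, gl, cm,
               sig, drvA, drvG, drvN)
        # stage 2 & 3 at t + dt/2
        th = t + 0.5 * dt
        for b in range(B):
            z = (th - onset[b]) / width[b]
            u[b] = amp[b] * np.exp(-0.5 * z * z)
        for b in range(B):
            for q in range(NSTATE):
                Xs[b, q] = X[b, q] + 0.5 * dt * dX1[b, q]
        _deriv(Xs, dX2, rowsA, colsA, wA, rowsG, colsG, wG, rowsN, colsN, wN,
               kapA, kapG, kapN, cmask, u, vl, ve, vi, vthr, slope, amg, gl, cm,
               sig, drvA, drvG, drvN)
        for b in range(B):
            for q in range(NSTATE):
                Xs[b, q] = X[b, q] + 0.5 * dt * dX2[b, q]
        _deriv(Xs, dX3, rowsA, colsA, wA, rowsG, colsG, wG, rowsN, colsN, wN,
               kapA, kapG, kapN, cmask, u, vl, ve, vi, vthr, slope, amg, gl, cm,
               sig, drvA, drvG, drvN)
        # stage 4 at t + dt
        tf = t + dt
        for b in range(B):
            z = (tf - onset[b]) / width[b]
            u[b] = amp[b] * np.exp(-0.5 * z * z)
        for b in range(B):
            for q in range(NSTATE):
                Xs[b, q] = X[b, q] + dt * dX3[b, q]
        _deriv(Xs, dX4, rowsA, colsA, wA, rowsG, colsG, wG, rowsN, colsN, wN,
               kapA, kapG, kapN, cmask, u, vl, ve, vi, vthr, slope, amg, gl, cm,
               sig, drvA, drvG, drvN)
        for b in range(B):
            if not alive[b]:
                continue
            for q in range(NSTATE):
                X[b, q] = X[b, q] + (dt / 6.0) * (dX1[b, q] + 2.0 * dX2[b, q]
                                                  + 2.0 * dX3[b, q] + dX4[b, q])
            for p in range(NPOP):
                v = X[b, p]
                if not np.isfinite(v) or np.abs(v) > 1e5:
                    alive[b] = False
                    break
    return y, traj, X


@njit(cache=True, fastmath=_FM)
def _balance(V, rowsA, colsA, wA, rowsG, colsG, wG, rowsN, colsN, wN,
             vl, ve, vi, vthr, slope, amg, gl,
             sig, drvA, drvG, drvN, F):
    """Membrane balance residual with conductances at their equilibria."""
    for p in range(NPOP):
        sig[p] = 1.0 / (1.0 + np.exp(-(V[p] - vthr) / slope))
        drvA[p] = 0.0
        drvG[p] = 0.0
        drvN[p] = 0.0
    for e in range(rowsA.shape[0]):
        drvA[rowsA[e]] += wA[e] * sig[colsA[e]]
    for e in range(rowsG.shape[0]):
        drvG[rowsG[e]] += wG[e] * sig[colsG[e]]
    for e in range(rowsN.shape[0]):
        drvN[rowsN[e]] += wN[e] * sig[colsN[e]]
    for p in range(NPOP):
        mg = 1.0 / (1.0 + 0.2 * np.exp(-amg * V[p]))
        F[p] = (gl * (vl - V[p]) + drvA[p] * (ve - V[p])
                + drvG[p] * (vi - V[p]) + drvN[p] * mg * (ve - V[p]))


@njit(cache=True, fastmath=_FM)
def fixed_point(wA_b, wG_b, wN_b, rowsA, colsA, rowsG, colsG, rowsN, colsN,
                vl, ve, vi, vthr, slope, amg, gl,
                Vinit, tol, maxiter):
    """Damped Newton solve of the 16-dim membrane balance per batch element.

    Returns the full 64-dim equilibrium state and the final residual
    infinity-norm per batch element.
    """
    B = wA_b.shape[0]
    Xeq = np.empty((B, NSTATE))
    resid = np.empty(B)
    sig = np.empty(NPOP)
    drvA = np.empty(NPOP)
    drvG = np.empty(NPOP)
    drvN = np.empty(NPOP)
    F = np.empty(NPOP)
    F2 = np.empty(NPOP)
    J = np.empty((NPOP, NPOP))
    for b in range(B):
        V = Vinit[b].copy()
        _balance(V, rowsA, colsA, wA_b[b], rowsG, colsG, wG_b[b],
                 rowsN, colsN, wN_b[b], vl, ve, vi, vthr, slope, amg, gl,
                 sig, drvA, drvG, drvN, F)
        rn = np.max(np.abs(F))
        it = 0
        while rn > tol and it < maxiter:
            # forward-difference Jacobian
            for q in range(NPOP):
                h = 1e-6 * (1.0 + np.abs(V[q]))
                Vq = V[q]
                V[q] = Vq + h
                _balance(V, rowsA, colsA, wA_b[b], rowsG, colsG, wG_b[b],
                         rowsN, colsN, wN_b[b], vl, ve, vi, vthr, slope, amg,
                         gl, sig, drvA, drvG, drvN, F2)
                V[q] = Vq
                for p in range(NPOP):
                    J[p, q] = (F2[p] - F[p]) / h
            ridge = 1e-9 * (1.0 + np.abs(J).max())
            for q in range(NPOP):
                J[q, q] += ridge
            step = np.linalg.solve(J, F)
            lam = 1.0
            improved = False
            for _ in range(12):
                Vn = V - lam * step
                _balance(Vn, rowsA, colsA, wA_b[b], rowsG, colsG, wG_b[b],
                         rowsN, colsN, wN_b[b], vl, ve, vi, vthr, slope, amg,
                         gl, sig, drvA, drvG, drvN, F2)
                rn2 = np.max(np.abs(F2))
                if rn2 < rn:
                    V = Vn
                    for p in range(NPOP):
                        F[p] = F2[p]
                    rn = rn2
                    improved = True
                    break
                lam *= 0.5
            if not improved:
                break
            it += 1
        # conductance equilibria at the solved potentials
        _balance(V, rowsA, colsA, wA_b[b], rowsG, colsG, wG_b[b],
                 rowsN, colsN, wN_b[b], vl, ve, vi, vthr, slope, amg, gl,
                 sig, drvA, drvG, drvN, F)
        for p in range(NPOP):
            Xeq[b, p] = V[p]
            Xeq[b, 16 + p] = drvA[p]
            Xeq[b, 32 + p] = drvG[p]
            Xeq[b, 48 + p] = drvN[p]
        resid[b] = rn
    return Xeq, resid
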