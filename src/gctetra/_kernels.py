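"""Numba kernels for the DC-FSSH propagation loop.

The kernel integrates nuclei with velocity-Verlet on the active adiabatic
surface of a linear-vibronic-coupling Hamiltonian, propagates the electronic
amplitudes of the excited states with fixed-step RK4 at the quantum substep
(linearly interpolated energies and couplings), accumulates fewest-switches
hop probabilities over the substeps of each classical step, applies
energy-based decoherence damping once per classical step, and terminates
when the active-ground gap falls below the threshold.

Nonadiabatic coupling magnitudes use the gap-curvature (Baeck-An) estimate
from the three most recent classical steps; the sign gauge is fixed by
taking the upper triangle nonnegative.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# termination reason codes
REASON_MAX_TIME = 0
REASON_GAP = 1


@njit(cache=True)
def tdba_sigma(gap_now: float, gap_prev: float, gap_prev2: float, dt: float) -> float:
    """Baeck-An coupling magnitude 0.5*sqrt(gap''/gap); 0 on the clamped branch."""
    if gap_now <= 0.0:
        return 0.0
    curv = (gap_now - 2.0 * gap_prev + gap_prev2) / (dt * dt)
    ratio = curv / gap_now
    if ratio <= 0.0:
        return 0.0
    return 0.5 * np.sqrt(ratio)


@njit(cache=True)
def _amp_deriv(c, e_exc, sig, hbar):
    """dc/dt = -i/hbar * E c - sigma c with antisymmetric sigma (upper tri >= 0)."""
    n = c.shape[0]
    out = np.zeros(n, dtype=np.complex128)
    for j in range(n):
        acc = -1j / hbar * e_exc[j] * c[j]
        for k in range(n):
            if k != j:
                s = sig[j, k] if j < k else -sig[k, j]
                acc -= s * c[k]
        out[j] = acc
    return out


@njit(cache=True)
def propagate_kernel(
    eps,            # (C,) config offsets, eV
    kap,            # (C, M) slopes
    om2,            # (M,) omega^2
    V,              # (C, C) diabatic couplings
    x0,             # (M,)
    p0,             # (M,)
    active0,        # int, adiabatic excited index (1..C-1)
    dt,             # classical step, fs
    nq,             # substeps per classical step
    hbar,           # eV fs
    alpha_ev,       # decoherence parameter, eV
    gap_term,       # termination gap, eV
    max_steps,      # int
    invert_frustrated,  # bool
    uniforms,       # (max_steps,) hop decision draws
):
    C = eps.shape[0]
    M = x0.shape[0]
    Ne = C - 1
    x = x0.copy()
    p = p0.copy()
    act = active0

    # outputs
    E_out = np.zeros((max_steps + 1, C))
    act_out = np.zeros(max_steps + 1, dtype=np.int64)
    x_out = np.zeros((max_steps + 1, M))
    ucomp_out = np.zeros((max_steps + 1, C, Ne))   # |U_dm|^2 for excited m
    pop_out = np.zeros((max_steps + 1, Ne))
    etot_out = np.zeros(max_steps + 1)
    hop_log = np.zeros((max_steps, 6))             # step, from, to, accepted, e_before, e_after
    n_hops = 0

    # initial electronic structure
    H = np.zeros((C, C))
    for a_ in range(C):
        for b_ in range(C):
            H[a_, b_] = V[a_, b_]
        H[a_, a_] = eps[a_]
        for k in range(M):
            H[a_, a_] += kap[a_, k] * x[k]
    w, U = np.linalg.eigh(H)
    harm = 0.0
    for k in range(M):
        harm += 0.5 * om2[k] * x[k] * x[k]
    E = w + harm

    c = np.zeros(Ne, dtype=np.complex128)
    c[act - 1] = 1.0 + 0.0j

    E_prev = E.copy()
    E_prev2 = E.copy()
    sig_prev = np.zeros((Ne, Ne))

    ke = 0.0
    for k in range(M):
        ke += 0.5 * p[k] * p[k]

    E_out[0] = E
    act_out[0] = act
    x_out[0] = x
    for d in range(C):
        for m in range(Ne):
            ucomp_out[0, d, m] = U[d, m + 1] * U[d, m + 1]
    for j in range(Ne):
        pop_out[0, j] = (c[j] * np.conj(c[j])).real
    etot_out[0] = ke + E[act]

    reason = REASON_MAX_TIME
    nstep = 0
    for step in range(1, max_steps + 1):
        # terminate on a small excited-ground gap, or when the active surface
        # has dived through the (uncoupled) crossing within one classical step
        # and is now dominated by the closed-shell ground configuration
        if E[act] - E[0] < gap_term or U[0, act] * U[0, act] > 0.5:
            reason = REASON_GAP
            break

        # velocity-Verlet on the active adiabatic surface
        g = np.zeros(M)
        for k in range(M):
            g[k] = om2[k] * x[k]
        for d in range(C):
            ud2 = U[d, act] * U[d, act]
            for k in range(M):
                g[k] += ud2 * kap[d, k]
        for k in range(M):
            p[k] -= 0.5 * dt * g[k]
            x[k] += dt * p[k]
        for a_ in range(C):
            for b_ in range(C):
                H[a_, b_] = V[a_, b_]
            H[a_, a_] = eps[a_]
            for k in range(M):
                H[a_, a_] += kap[a_, k] * x[k]
        U_prev = U
        w, U = np.linalg.eigh(H)
        harm = 0.0
        for k in range(M):
            harm += 0.5 * om2[k] * x[k] * x[k]
        # state-identity tracking through trivial (unresolved) crossings:
        # assign each previous excited state to the new eigenvector with the
        # largest overlap (diabatic basis is fixed, so the overlap is a dot
        # product).  Amplitudes, the active index and the gap histories
        # follow the assignment; for well-separated states this is the
        # identity and the dynamics is untouched.
        Ov = np.zeros((Ne, Ne))
        for mm in range(Ne):
            for jj in range(Ne):
                acc = 0.0
                for d in range(C):
                    acc += U[d, jj + 1] * U_prev[d, mm + 1]
                Ov[jj, mm] = abs(acc)
        perm = np.full(Ne, -1, dtype=np.int64)
        used_new = np.zeros(Ne, dtype=np.bool_)
        used_old = np.zeros(Ne, dtype=np.bool_)
        for _ in range(Ne):
            best = -1.0
            bj = 0
            bm = 0
            for jj in range(Ne):
                if used_new[jj]:
                    continue
                for mm in range(Ne):
                    if used_old[mm]:
                        continue
                    if Ov[jj, mm] > best:
                        best = Ov[jj, mm]
                        bj = jj
                        bm = mm
            perm[bm] = bj
            used_new[bj] = True
            used_old[bm] = True
        identity = True
        for mm in range(Ne):
            if perm[mm] != mm:
                identity = False
        if not identity:
            c_new = np.zeros(Ne, dtype=np.complex128)
            ep1 = np.zeros(Ne)
            ep2 = np.zeros(Ne)
            for mm in range(Ne):
                c_new[perm[mm]] = c[mm]
                ep1[perm[mm]] = E_prev[mm + 1]
                ep2[perm[mm]] = E_prev2[mm + 1]
            c = c_new
            for mm in range(Ne):
                E_prev[mm + 1] = ep1[mm]
                E_prev2[mm + 1] = ep2[mm]
            if perm[act - 1] + 1 != act:
                # index reassignment, not a hop: flag code 2 in the log
                hop_log[n_hops, 0] = step
                hop_log[n_hops, 1] = act
                hop_log[n_hops, 2] = perm[act - 1] + 1
                hop_log[n_hops, 3] = 2.0
                hop_log[n_hops, 4] = 0.0
                hop_log[n_hops, 5] = 0.0
                n_hops += 1
                act = perm[act - 1] + 1

        E_new = w + harm
        # terminate before recording a post-crossing frame
        if E_new[act] - E_new[0] < gap_term or U[0, act] * U[0, act] > 0.5:
            reason = REASON_GAP
            break
        g2 = np.zeros(M)
        for k in range(M):
            g2[k] = om2[k] * x[k]
        for d in range(C):
            ud2 = U[d, act] * U[d, act]
            for k in range(M):
                g2[k] += ud2 * kap[d, k]
        for k in range(M):
            p[k] -= 0.5 * dt * g2[k]

        # Baeck-An couplings among excited states at the new step.  When the
        # excited-block diabatic coupling vanishes identically the true
        # nonadiabatic coupling is zero by symmetry and the gap-curvature
        # estimate is suppressed (exact zero-coupling limit).
        has_coupling = False
        for a_ in range(1, C):
            for b_ in range(a_ + 1, C):
                if V[a_, b_] != 0.0:
                    has_coupling = True
        sig_new = np.zeros((Ne, Ne))
        if step >= 2 and has_coupling:
            for i in range(Ne):
                for j in range(i + 1, Ne):
                    gn = E_new[j + 1] - E_new[i + 1]
                    gp = E_prev[j + 1] - E_prev[i + 1]
                    gp2 = E_prev2[j + 1] - E_prev2[i + 1]
                    sig_new[i, j] = tdba_sigma(abs(gn), abs(gp), abs(gp2), dt)

        # quantum substeps with linear interpolation, accumulating hop prob
        a_idx = act - 1
        bprob = np.zeros(Ne)
        dtq = dt / nq
        e_exc0 = np.zeros(Ne)
        e_exc1 = np.zeros(Ne)
        for j in range(Ne):
            e_exc0[j] = E_prev[j + 1] - E_prev[1]
            e_exc1[j] = E_new[j + 1] - E_new[1]
        for q in range(nq):
            f0 = q / nq
            f1 = (q + 0.5) / nq
            f2 = (q + 1.0) / nq
            eA = e_exc0 * (1.0 - f0) + e_exc1 * f0
            eB = e_exc0 * (1.0 - f1) + e_exc1 * f1
            eC = e_exc0 * (1.0 - f2) + e_exc1 * f2
            sA = sig_prev * (1.0 - f0) + sig_new * f0
            sB = sig_prev * (1.0 - f1) + sig_new * f1
            sC = sig_prev * (1.0 - f2) + sig_new * f2
            k1 = _amp_deriv(c, eA, sA, hbar)
            k2 = _amp_deriv(c + 0.5 * dtq * k1, eB, sB, hbar)
            k3 = _amp_deriv(c + 0.5 * dtq * k2, eB, sB, hbar)
            k4 = _amp_deriv(c + dtq * k3, eC, sC, hbar)
            c = c + dtq / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            ca2 = (c[a_idx] * np.conj(c[a_idx])).real
            if ca2 > 1e-30:
                for j in range(Ne):
                    if j != a_idx:
                        # flux of |c_a|^2 into j: the j-contribution to
                        # -d|c_a|^2/dt is +2*sigma_aj*Re(c_a^* c_j)
                        s = sC[a_idx, j] if a_idx < j else -sC[j, a_idx]
                        val = 2.0 * dtq * s * (np.conj(c[a_idx]) * c[j]).real / ca2
                        if val > 0.0:
                            bprob[j] += val

        # hop decision (one draw per classical step)
        r = uniforms[step - 1]
        cum = 0.0
        target = -1
        for j in range(Ne):
            if j == a_idx:
                continue
            cum += bprob[j]
            if r < cum:
                target = j
                break
        if target >= 0:
            new_state = target + 1
            dE = E_new[new_state] - E_new[act]
            # direction: mass-weighted gradient difference (harmonic part cancels)
            dvec = np.zeros(M)
            for d in range(C):
                du = U[d, new_state] * U[d, new_state] - U[d, act] * U[d, act]
                for k in range(M):
                    dvec[k] += du * kap[d, k]
            dnorm = 0.0
            for k in range(M):
                dnorm += dvec[k] * dvec[k]
            dnorm = np.sqrt(dnorm)
            ke_before = 0.0
            for k in range(M):
                ke_before += 0.5 * p[k] * p[k]
            accepted = False
            if dnorm > 1e-14:
                for k in range(M):
                    dvec[k] /= dnorm
                pd = 0.0
                for k in range(M):
                    pd += p[k] * dvec[k]
                disc = pd * pd - 2.0 * dE
                if disc >= 0.0:
                    sgn = 1.0 if pd >= 0.0 else -1.0
                    gamma = sgn * np.sqrt(disc) - pd
                    for k in range(M):
                        p[k] += gamma * dvec[k]
                    accepted = True
                elif invert_frustrated:
                    pd2 = 0.0
                    for k in range(M):
                        pd2 += p[k] * dvec[k]
                    for k in range(M):
                        p[k] -= 2.0 * pd2 * dvec[k]
            ke_after = 0.0
            for k in range(M):
                ke_after += 0.5 * p[k] * p[k]
            hop_log[n_hops, 0] = step
            hop_log[n_hops, 1] = act
            hop_log[n_hops, 2] = new_state
            hop_log[n_hops, 3] = 1.0 if accepted else 0.0
            hop_log[n_hops, 4] = ke_before + E_new[act]
            hop_log[n_hops, 5] = ke_after + E_new[new_state if accepted else act]
            n_hops += 1
            if accepted:
                act = new_state

        # a hop may have landed on a state already inside the termination
        # window (or on the far side of the ground crossing): stop here
        # rather than record a post-crossing frame
        if E_new[act] - E_new[0] < gap_term or U[0, act] * U[0, act] > 0.5:
            reason = REASON_GAP
            break

        # decoherence damping + exact renormalization
        ekin = 0.0
        for k in range(M):
            ekin += 0.5 * p[k] * p[k]
        a_idx = act - 1
        if ekin > 1e-12:
            rest = 0.0
            for j in range(Ne):
                if j == a_idx:
                    continue
                dEj = abs(E_new[j + 1] - E_new[act])
                if dEj > 1e-12:
                    tau_d = hbar / dEj * (1.0 + alpha_ev / ekin)
                    c[j] *= np.exp(-dt / tau_d)
                rest += (c[j] * np.conj(c[j])).real
            ca2 = (c[a_idx] * np.conj(c[a_idx])).real
            if ca2 > 1e-30 and rest < 1.0:
                c[a_idx] *= np.sqrt((1.0 - rest) / ca2)

        # bookkeeping
        E_prev2 = E_prev
        E_prev = E_new
        sig_prev = sig_new
        E = E_new
        E_out[step] = E
        act_out[step] = act
        x_out[step] = x
        for d in range(C):
            for m in range(Ne):
                ucomp_out[step, d, m] = U[d, m + 1] * U[d, m + 1]
        for j in range(Ne):
            pop_out[step, j] = (c[j] * np.conj(c[j])).real
        etot_out[step] = ekin + E[act]
        nstep = step

    n = nstep + 1
    return (
        n,
        reason,
        E_out[:n],
        act_out[:n],
        x_out[:n],
        ucomp_out[:n],
        pop_out[:n],
        etot_out[:n],
        hop_log[:n_hops],
    )
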