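"""Compiled numerical core for the scaffold-cycle motif.

Works on the conservation-reduced coordinates x = (Sp, SK, SpP, KT, PT);
the free species follow from the four conserved moiety totals
(S_total, K_total, P_total, T_total).  Steady states are found by damped
Newton iteration with an L-stable Rosenbrock(2,3) stiff integration
fallback; transient peaks for the pulse protocol are tracked during
integration with cubic-Hermite refinement inside steps whose output
derivative changes sign.

All rate constants are passed zero-indexed: k[0] = k1 ... k[9] = k10.
Units are uM and seconds throughout.
"""

import numpy as np
from numba import njit

# reduced-coordinate indices
# x = [Sp, SK, SpP, KT, PT]; totals = [S_total, K_total, P_total, T_total]

NEWTON_TOL_FACTOR = 1e-12      # Newton polish target: ||rhs||_inf < factor*max(totals)
STEADY_TOL_FACTOR = 1e-10      # steady declared when ||rhs||_inf < factor*max(totals)
DEFAULT_HORIZON = 1.0e6        # s, cap on a single relaxation integration
MAX_STEPS = 50_000


@njit(cache=True, fastmath=False)
def free_species(x, totals):
    """Return (S, K, P, T) implied by reduced coordinates and totals."""
    S = totals[0] - x[0] - x[1] - x[2]
    K = totals[1] - x[1] - x[3]
    P = totals[2] - x[2] - x[4]
    T = totals[3] - x[3] - x[4]
    return S, K, P, T


@njit(cache=True, fastmath=False)
def rhs5(k, totals, x, out):
    """Mass-action time derivatives of the reduced coordinates."""
    Sp = x[0]
    SK = x[1]
    SpP = x[2]
    KT = x[3]
    PT = x[4]
    S, K, P, T = free_species(x, totals)
    out[0] = k[2] * SK - k[3] * Sp * P + k[4] * SpP
    out[1] = k[0] * S * K - (k[1] + k[2]) * SK
    out[2] = k[3] * Sp * P - (k[4] + k[5]) * SpP
    out[3] = k[6] * K * T - k[7] * KT
    out[4] = k[8] * P * T - k[9] * PT


@njit(cache=True, fastmath=False)
def jac5(k, totals, x, J):
    """Analytic Jacobian of rhs5 w.r.t. the reduced coordinates."""
    Sp = x[0]
    S, K, P, T = free_species(x, totals)
    # f0 = k3*SK - k4*Sp*P + k5*SpP
    J[0, 0] = -k[3] * P
    J[0, 1] = k[2]
    J[0, 2] = k[4] + k[3] * Sp
    J[0, 3] = 0.0
    J[0, 4] = k[3] * Sp
    # f1 = k1*S*K - (k2+k3)*SK
    J[1, 0] = -k[0] * K
    J[1, 1] = -k[0] * (K + S) - (k[1] + k[2])
    J[1, 2] = -k[0] * K
    J[1, 3] = -k[0] * S
    J[1, 4] = 0.0
    # f2 = k4*Sp*P - (k5+k6)*SpP
    J[2, 0] = k[3] * P
    J[2, 1] = 0.0
    J[2, 2] = -k[3] * Sp - (k[4] + k[5])
    J[2, 3] = 0.0
    J[2, 4] = -k[3] * Sp
    # f3 = k7*K*T - k8*KT
    J[3, 0] = 0.0
    J[3, 1] = -k[6] * T
    J[3, 2] = 0.0
    J[3, 3] = -k[6] * (T + K) - k[7]
    J[3, 4] = -k[6] * K
    # f4 = k9*P*T - k10*PT
    J[4, 0] = 0.0
    J[4, 1] = 0.0
    J[4, 2] = -k[8] * T
    J[4, 3] = -k[8] * P
    J[4, 4] = -k[8] * (T + P) - k[9]


@njit(cache=True, fastmath=False)
def solve5(A, b):
    """In-place 5x5 Gaussian elimination with partial pivoting; returns x.

    A and b are overwritten.  Singular (pivot underflow) signalled by NaNs.
    """
    n = 5
    for col in range(n):
        piv = col
        amax = abs(A[col, col])
        for r in range(col + 1, n):
            a = abs(A[r, col])
            if a > amax:
                amax = a
                piv = r
        if amax < 1e-300:
            for i in range(n):
                b[i] = np.nan
            return b
        if piv != col:
            for c in range(col, n):
                tmp = A[col, c]
                A[col, c] = A[piv, c]
                A[piv, c] = tmp
            tmp = b[col]
            b[col] = b[piv]
            b[piv] = tmp
        inv = 1.0 / A[col, col]
        for r in range(col + 1, n):
            f = A[r, col] * inv
            if f != 0.0:
                for c in range(col, n):
                    A[r, c] -= f * A[col, c]
                b[r] -= f * b[col]
    for i in range(n - 1, -1, -1):
        s = b[i]
        for c in range(i + 1, n):
            s -= A[i, c] * b[c]
        b[i] = s / A[i, i]
    return b


@njit(cache=True, fastmath=False)
def _max_alpha_physical(x, dx, totals):
    """Largest step fraction in direction dx keeping all 9 species >= -eps."""
    eps = 1e-14 * (totals[0] + totals[1] + totals[2] + totals[3] + 1.0)
    alpha = 1.0
    # reduced coords themselves must stay >= 0
    for i in range(5):
        if dx[i] < 0.0 and x[i] + dx[i] < -eps:
            a = (eps + x[i]) / (-dx[i])
            if a < alpha:
                alpha = a
    # free species: S, K, P, T linear in x
    S = totals[0] - x[0] - x[1] - x[2]
    dS = -dx[0] - dx[1] - dx[2]
    K = totals[1] - x[1] - x[3]
    dK = -dx[1] - dx[3]
    P = totals[2] - x[2] - x[4]
    dP = -dx[2] - dx[4]
    T = totals[3] - x[3] - x[4]
    dT = -dx[3] - dx[4]
    if dS < 0.0 and S + dS < -eps:
        a = (eps + S) / (-dS)
        if a < alpha:
            alpha = a
    if dK < 0.0 and K + dK < -eps:
        a = (eps + K) / (-dK)
        if a < alpha:
            alpha = a
    if dP < 0.0 and P + dP < -eps:
        a = (eps + P) / (-dP)
        if a < alpha:
            alpha = a
    if dT < 0.0 and T + dT < -eps:
        a = (eps + T) / (-dT)
        if a < alpha:
            alpha = a
    return alpha


@njit(cache=True, fastmath=False)
def newton_steady(k, totals, x0, tol, max_iter=60):
    """Damped Newton on the reduced system.  Returns (x, ok).

    Steps are damped to stay inside the physical simplex (all nine species
    non-negative) and halved until the residual norm decreases.
    """
    x = x0.copy()
    f = np.empty(5)
    J = np.empty((5, 5))
    step = np.empty(5)
    rhs5(k, totals, x, f)
    fnorm = 0.0
    for i in range(5):
        a = abs(f[i])
        if a > fnorm:
            fnorm = a
    for _ in range(max_iter):
        if fnorm < tol:
            return x, True
        jac5(k, totals, x, J)
        for i in range(5):
            step[i] = -f[i]
        solve5(J, step)
        if np.isnan(step[0]):
            return x, False
        alpha = _max_alpha_physical(x, step, totals)
        if alpha < 1.0:
            alpha *= 0.95
        improved = False
        xn = np.empty(5)
        for _ls in range(30):
            for i in range(5):
                xn[i] = x[i] + alpha * step[i]
            rhs5(k, totals, xn, f)
            fn = 0.0
            for i in range(5):
                a = abs(f[i])
                if a > fn:
                    fn = a
            if fn < fnorm or fn < tol:
                x = xn.copy()
                fnorm = fn
                improved = True
                break
            alpha *= 0.5
        if not improved:
            rhs5(k, totals, x, f)  # restore residual at x
            return x, fnorm < tol
    return x, fnorm < tol


@njit(cache=True, fastmath=False)
def _clip_physical(x, totals):
    """Project tiny negatives (solver floor) back onto the physical set."""
    for i in range(5):
        if x[i] < 0.0:
            x[i] = 0.0
    s_bound = totals[0]
    if x[0] + x[1] + x[2] > s_bound and s_bound >= 0.0:
        f = s_bound / (x[0] + x[1] + x[2] + 1e-300)
        x[0] *= f
        x[1] *= f
        x[2] *= f
    if x[1] + x[3] > totals[1]:
        f = totals[1] / (x[1] + x[3] + 1e-300)
        x[1] *= f
        x[3] *= f
    if x[2] + x[4] > totals[2]:
        f = totals[2] / (x[2] + x[4] + 1e-300)
        x[2] *= f
        x[4] *= f
    if x[3] + x[4] > totals[3]:
        f = totals[3] / (x[3] + x[4] + 1e-300)
        x[3] *= f
        x[4] *= f


@njit(cache=True, fastmath=False)
def rosenbrock_relax(k, totals, x0, track_ref, horizon, rtol, atol,
                     steady_tol):
    """Integrate the reduced system until steady (or horizon/step budget).

    Shampine's Rosenbrock(2,3) pair (the ode23s scheme) with analytic
    Jacobian; L-stable, so steps grow geometrically once transients decay.
    Tracks the maximum deviation |Sp(t) - track_ref| along the way, refining
    inside any step where the Sp-derivative changes sign via cubic Hermite
    sampling.

    Returns (x, peak_dev, t_end, status) with status 0 = steady reached,
    1 = horizon reached, 2 = step-budget/failure.
    """
    d = 1.0 / (2.0 + np.sqrt(2.0))
    e32 = 6.0 + np.sqrt(2.0)

    x = x0.copy()
    _clip_physical(x, totals)
    f0 = np.empty(5)
    f1 = np.empty(5)
    f2 = np.empty(5)
    k1v = np.empty(5)
    k2v = np.empty(5)
    k3v = np.empty(5)
    W = np.empty((5, 5))
    J = np.empty((5, 5))
    xmid = np.empty(5)
    xnew = np.empty(5)
    err = np.empty(5)

    rhs5(k, totals, x, f0)
    fmax = 0.0
    for i in range(5):
        a = abs(f0[i])
        if a > fmax:
            fmax = a
    peak = abs(x[0] - track_ref)
    if fmax < steady_tol:
        return x, peak, 0.0, 0

    # initial step: small relative to fastest local rate
    xmax = atol
    for i in range(5):
        a = abs(x[i])
        if a > xmax:
            xmax = a
    h = 1e-6 * xmax / (fmax + 1e-300)
    if h <= 0.0 or not np.isfinite(h):
        h = 1e-6
    t = 0.0
    nsteps = 0
    while nsteps < MAX_STEPS:
        nsteps += 1
        if t + h > horizon:
            h = horizon - t
            if h <= 0.0:
                return x, peak, t, 1
        jac5(k, totals, x, J)
        # W = I - h*d*J
        hd = h * d
        for r in range(5):
            for c in range(5):
                W[r, c] = -hd * J[r, c]
            W[r, r] += 1.0
        for i in range(5):
            k1v[i] = f0[i]
        Wc = W.copy()
        solve5(Wc, k1v)
        if np.isnan(k1v[0]):
            h *= 0.5
            continue
        for i in range(5):
            xmid[i] = x[i] + 0.5 * h * k1v[i]
        rhs5(k, totals, xmid, f1)
        for i in range(5):
            k2v[i] = f1[i] - k1v[i]
        Wc = W.copy()
        solve5(Wc, k2v)
        for i in range(5):
            k2v[i] += k1v[i]
            xnew[i] = x[i] + h * k2v[i]
        rhs5(k, totals, xnew, f2)
        for i in range(5):
            k3v[i] = f2[i] - e32 * (k2v[i] - f1[i]) - 2.0 * (k1v[i] - f0[i])
        Wc = W.copy()
        solve5(Wc, k3v)
        # error estimate
        enorm = 0.0
        bad = False
        for i in range(5):
            err[i] = (h / 6.0) * (k1v[i] - 2.0 * k2v[i] + k3v[i])
            sc = atol + rtol * max(abs(x[i]), abs(xnew[i]))
            e = abs(err[i]) / sc
            if not np.isfinite(e):
                bad = True
                break
            if e > enorm:
                enorm = e
        if bad or not np.isfinite(xnew[0]):
            h *= 0.25
            if h < 1e-300:
                return x, peak, t, 2
            continue
        if enorm <= 1.0:
            # accepted: peak tracking with Hermite refinement on sign change
            dev = abs(xnew[0] - track_ref)
            if dev > peak:
                peak = dev
            if f0[0] * f2[0] < 0.0:
                # cubic Hermite for Sp over [t, t+h]
                p0 = x[0]
                p1 = xnew[0]
                m0 = f0[0] * h
                m1 = f2[0] * h
                for j in range(1, 10):
                    s = j / 10.0
                    h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
                    h10 = s * (1.0 - s) ** 2
                    h01 = s * s * (3.0 - 2.0 * s)
                    h11 = s * s * (s - 1.0)
                    sp = h00 * p0 + h10 * m0 + h01 * p1 + h11 * m1
                    dv = abs(sp - track_ref)
                    if dv > peak:
                        peak = dv
            t += h
            for i in range(5):
                x[i] = xnew[i]
            _clip_physical(x, totals)
            rhs5(k, totals, x, f0)
            fmax = 0.0
            for i in range(5):
                a = abs(f0[i])
                if a > fmax:
                    fmax = a
            if fmax < steady_tol:
                return x, peak, t, 0
            if t >= horizon:
                return x, peak, t, 1
            fac = 0.9 * enorm ** (-1.0 / 3.0) if enorm > 0.0 else 5.0
            if fac > 5.0:
                fac = 5.0
            h *= fac
        else:
            fac = 0.9 * enorm ** (-1.0 / 3.0)
            if fac < 0.1:
                fac = 0.1
            h *= fac
    return x, peak, t, 2


@njit(cache=True, fastmath=False)
def steady5(k, totals, x0, horizon=DEFAULT_HORIZON):
    """Steady state: damped Newton first, stiff relaxation as fallback.

    Returns (x, ok).  The Newton solution is only accepted when physical;
    the fallback integrates the dynamics (thereby selecting the dynamically
    reached branch) and polishes with Newton afterwards.
    """
    maxtot = max(max(totals[0], totals[1]), max(totals[2], totals[3]))
    tol = NEWTON_TOL_FACTOR * (maxtot + 1e-30)
    x, ok = newton_steady(k, totals, x0, tol)
    if ok:
        physical = True
        S, K, P, T = free_species(x, totals)
        if S < -tol or K < -tol or P < -tol or T < -tol:
            physical = False
        for i in range(5):
            if x[i] < -tol:
                physical = False
        if physical:
            _clip_physical(x, totals)
            return x, True
    steady_tol = STEADY_TOL_FACTOR * (maxtot + 1e-30)
    x2, _pk, _t, status = rosenbrock_relax(
        k, totals, x0, 0.0, horizon, 1e-6, 1e-12 + 1e-9 * maxtot, steady_tol
    )
    x3, ok3 = newton_steady(k, totals, x2, tol)
    if ok3:
        _clip_physical(x3, totals)
        return x3, True
    if status == 0:
        _clip_physical(x2, totals)
        return x2, True
    return x2, False


@njit(cache=True, fastmath=False)
def relax_track(k, totals, x0, track_ref, horizon=DEFAULT_HORIZON):
    """Relax to steady state while tracking peak |Sp - track_ref|.

    Returns (x_ss, peak_dev, ok).  Used for the pulse-protocol transients,
    where the trajectory (not just the endpoint) matters.
    """
    maxtot = max(max(totals[0], totals[1]), max(totals[2], totals[3]))
    steady_tol = STEADY_TOL_FACTOR * (maxtot + 1e-30)
    x, peak, _t, status = rosenbrock_relax(
        k, totals, x0, track_ref, horizon, 1e-6, 1e-12 + 1e-9 * maxtot,
        steady_tol
    )
    tol = NEWTON_TOL_FACTOR * (maxtot + 1e-30)
    xp, okp = newton_steady(k, totals, x, tol)
    if okp:
        _clip_physical(xp, totals)
        dev = abs(xp[0] - track_ref)
        if dev > peak:
            peak = dev
        return xp, peak, True
    return x, peak, status == 0


@njit(cache=True, fastmath=False)
def apply_kinase_change(x, totals, new_K_total, policy=0):
    """Return (x', totals') after an instantaneous kinase-level signal event.

    Raising the level adds free kinase.  Lowering removes kinase according
    to ``policy``: 0 = free-first (remove from the free pool, any shortfall
    pro rata from SK and KT), 1 = proportional (pro rata across free,
    substrate-bound and scaffold-bound pools).  Substrate and scaffold from
    dissolved complexes return to their free pools (the reduced coordinates
    make that bookkeeping implicit); either way the new total is exact and
    nothing goes negative.
    """
    xn = x.copy()
    tn = totals.copy()
    old = totals[1]
    tn[1] = new_K_total
    if new_K_total >= old:
        return xn, tn  # free K is implicit: K = K_total - SK - KT grows
    if old <= 0.0:
        return xn, tn
    if policy == 1:
        f = new_K_total / old
        # scale kinase-containing complexes; free K scales implicitly since
        # K' = f*K_total - f*SK - f*KT = f*K
        xn[1] *= f  # SK
        xn[3] *= f  # KT
        return xn, tn
    # free-first: K = old - SK - KT absorbs up to its size, remainder pro
    # rata from the complexes
    deficit = old - new_K_total
    K_free = old - x[1] - x[3]
    if K_free < deficit:
        short = deficit - K_free
        bound = x[1] + x[3]
        if bound > 0.0:
            f = 1.0 - short / bound
            if f < 0.0:
                f = 0.0
            xn[1] = x[1] * f
            xn[3] = x[3] * f
    return xn, tn


@njit(cache=True, fastmath=False)
def staircase_eval(k, S_total, P_total, T_total, levels,
                   horizon=DEFAULT_HORIZON):
    """Drive the staircase protocol; return plateau outputs and diagnostics.

    levels: the full visiting order of K_total including the initial
    baseline, e.g. [base, L1, L2, L3, L2, L1, base] (7 entries).

    Returns (plateau_Sp, mean_fracs, ok) where mean_fracs is the 6-vector
    of staircase-averaged enzyme fractions
    (SK/K_tot, KT/K_tot, K/K_tot, SpP/P_tot, PT/P_tot, P/P_tot).
    """
    n = levels.shape[0]
    plateaus = np.zeros(n)
    fr = np.zeros(6)
    totals = np.empty(4)
    totals[0] = S_total
    totals[1] = levels[0]
    totals[2] = P_total
    totals[3] = T_total
    x = np.zeros(5)
    ok_all = True
    nfr = 0
    for j in range(n):
        if j > 0:
            x, totals = apply_kinase_change(x, totals, levels[j], 1)
        x, ok = steady5(k, totals, x, horizon)
        if not ok:
            ok_all = False
        plateaus[j] = x[0]
        Kt = totals[1]
        if Kt > 0.0:
            S, K, P, T = free_species(x, totals)
            fr[0] += x[1] / Kt
            fr[1] += x[3] / Kt
            fr[2] += K / Kt
            if P_total > 0.0:
                fr[3] += x[2] / P_total
                fr[4] += x[4] / P_total
                fr[5] += P / P_total
            nfr += 1
    if nfr > 0:
        for i in range(6):
            fr[i] /= nfr
    return plateaus, fr, ok_all


@njit(cache=True, fastmath=False)
def pulse_eval(k, S_total, P_total, T_total, baseline_K, magnitudes,
               horizon=DEFAULT_HORIZON, policy=0):
    """Drive the square-pulse protocol; return per-pulse response records.

    ``magnitudes`` are absolute kinase increments (uM) over the baseline
    (the protocol layer converts relative magnitudes upstream).  For each
    magnitude M: from the relaxed baseline, step K_total up by M, relax
    (recording the peak output deviation), then step back down under the
    given removal ``policy`` (0 free-first, 1 proportional) and relax
    again.  Records rows [dOmax_up, dOss_up, dOmax_dn, dOss_dn, O0, O1]
    where O0 is the pre-pulse and O1 the on-pulse steady-state output.

    Returns (records, ok).
    """
    m = magnitudes.shape[0]
    rec = np.zeros((m, 6))
    totals = np.empty(4)
    totals[0] = S_total
    totals[1] = baseline_K
    totals[2] = P_total
    totals[3] = T_total
    x = np.zeros(5)
    x, ok = steady5(k, totals, x, horizon)
    ok_all = ok
    for i in range(m):
        O0 = x[0]
        # up-step
        xu, tu = apply_kinase_change(x, totals, baseline_K + magnitudes[i],
                                     policy)
        xu, peak_up, ok_u = relax_track(k, tu, xu, O0, horizon)
        if not ok_u:
            ok_all = False
        O1 = xu[0]
        # down-step back to baseline
        xd, td = apply_kinase_change(xu, tu, baseline_K, policy)
        xd, peak_dn, ok_d = relax_track(k, td, xd, O1, horizon)
        if not ok_d:
            ok_all = False
        O_end = xd[0]
        rec[i, 0] = peak_up
        rec[i, 1] = abs(O1 - O0)
        rec[i, 2] = peak_dn
        rec[i, 3] = abs(O_end - O1)
        rec[i, 4] = O0
        rec[i, 5] = O1
        x = xd
        totals = td
    return rec, ok_all
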