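"""Numba kernels for the pseudo-likelihood MCMC sweeps.

All randomness is pre-drawn outside the kernels from a single
``numpy.random.Generator`` and passed in as arrays, so a fixed seed
yields a bit-identical chain.  The kernels mutate state arrays in
place and return acceptance counters.

The dominant cost is the truncated log-normalizer of every node
conditional,

    D_tj = log sum_{k=0}^{B} exp( k*a_tj - log k! - F(k)*eta_tj ),

with a_tj = log(lambda_tj) and eta_tj = sum_{l != j} beta_jl F(x_tl).
The summand is unimodal in k, so the streaming log-sum-exp below exits
once terms fall 45 nats below the running maximum (a relative error
< 1e-18, far inside float64 noise).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: fresh-draw weight semantics in the Dirichlet-process reassignment
MODE_PREDICTIVE = 0  # collapsed prior-predictive (negative-binomial) mass
MODE_DENSITY = 1  # gamma density evaluated at the current value
MODE_EXACT = 2  # full node-conditional weights + quadrature predictive

# powers of two for the fast exp below (exact in binary)
_POW2 = 2.0 ** np.arange(-80, 2).astype(np.float64)
_LOG2E = 1.4426950408889634
_LN2_HI = 0.6931471803691238
_LN2_LO = 1.9082149292705877e-10


@njit(inline="always", fastmath=True)
def _exp_neg(x):
    """exp(x) for x in [-inf, ~1], ~1e-14 relative error.

    The default math library exponential dominates the sampler's run
    time (no vector math library is assumed); this range-reduced
    Taylor polynomial with a power-of-two table is several times
    cheaper.  Arguments below -45 return 0, which is far below the
    relative resolution of the log-sum-exp accumulations it serves.
    """
    if x < -45.0:
        return 0.0
    kf = np.rint(x * _LOG2E)
    r = (x - kf * _LN2_HI) - kf * _LN2_LO
    p = 1.0 + r * (
        1.0
        + r
        * (
            0.5
            + r
            * (
                1.0 / 6
                + r
                * (
                    1.0 / 24
                    + r
                    * (
                        1.0 / 120
                        + r
                        * (
                            1.0 / 720
                            + r
                            * (
                                1.0 / 5040
                                + r
                                * (
                                    1.0 / 40320
                                    + r * (1.0 / 362880 + r * (1.0 / 3628800))
                                )
                            )
                        )
                    )
                )
            )
        )
    )
    return p * _POW2[np.int64(kf) + 80]


@njit(cache=True, fastmath=True)
def logtrunc_denom(a, eta, Fk, lgk):
    """Streaming log-sum-exp of the truncated conditional normalizer."""
    B1 = Fk.shape[0]
    m = -1.0e308
    s = 0.0
    prev = 1.0e308
    for k in range(B1):
        t = k * a - lgk[k] - Fk[k] * eta
        if t > m:
            s = s * _exp_neg(m - t) + 1.0
            m = t
        else:
            s += _exp_neg(t - m)
            if t < m - 40.0 and t < prev:
                break
        prev = t
    return m + math.log(s)


@njit(cache=True)
def denom_matrix(A, Eta, Fk, lgk, out):
    n, P = A.shape
    for t in range(n):
        for j in range(P):
            out[t, j] = logtrunc_denom(A[t, j], Eta[t, j], Fk, lgk)


@njit(cache=True)
def reassign_logweights(x_tj, t, lam_col, M, base_a, base_b, mode, out):
    """Log weights of the collapsed DP reassignment for observation (t, j).

    ``out[k]`` for k != t is the Poisson log-likelihood of x_tj under the
    k-th replicate's current rate; ``out[t]`` is the fresh-draw weight
    scaled by the concentration M.
    """
    n = lam_col.shape[0]
    lgx = math.lgamma(x_tj + 1.0)
    for k in range(n):
        if k != t:
            out[k] = x_tj * math.log(lam_col[k]) - lam_col[k] - lgx
    if mode == MODE_PREDICTIVE:
        # integral of Pois(x | lam) against the Gamma(a, b) base measure
        out[t] = (
            math.log(M)
            + math.lgamma(base_a + x_tj)
            - math.lgamma(base_a)
            - lgx
            + base_a * math.log(base_b / (base_b + 1.0))
            - x_tj * math.log(base_b + 1.0)
        )
    else:
        # literal form: gamma(a + x, b + 1) density at the current value
        lam0 = lam_col[t]
        aa = base_a + x_tj
        bb = base_b + 1.0
        out[t] = (
            math.log(M)
            + aa * math.log(bb)
            - math.lgamma(aa)
            + (aa - 1.0) * math.log(lam0)
            - bb * lam0
        )


@njit(cache=True)
def lambda_sweep(
    X,
    lam,
    A,
    Eta,
    M,
    base_a,
    base_b,
    K1,
    mode,
    Fk,
    lgk,
    Aux,
    U_idx,
    Gcand,
    U_mh,
    acc_out,
):
    """One sweep of Dirichlet-process updates over all (t, j).

    In MODE_EXACT the sweep is the auxiliary-variable collapsed Gibbs
    move for non-conjugate DP mixtures (Neal 2000, Algorithm 8):
    existing rates are weighted by the full truncated node conditional
    of x_tj (the edge terms included, normalizers memoized over the
    column's distinct rates), and the fresh-draw branch is represented
    by ``m_aux`` auxiliary rates drawn from the Gamma base measure
    (pre-drawn in ``Aux``, shape n x P x m_aux), each carrying weight
    M/m_aux times its conditional likelihood; when the current rate is
    a singleton it occupies the first auxiliary slot.  No
    Metropolis-Hastings correction is needed, so the move is exact.

    The simpler modes keep the plain-Poisson weights with a shrunk
    Gamma(a + x, b + 1) Metropolis-Hastings fresh draw.  ``acc_out``
    receives (fresh-branch selections, attempts).
    """
    n, P = X.shape
    m_aux = Aux.shape[2]
    w = np.empty(n)
    wf = np.empty(m_aux)
    vf = np.empty(m_aux)
    uniq = np.empty(n)
    ud = np.empty(n)
    accepts = 0
    attempts = 0
    for j in range(P):
        for t in range(n):
            x = float(X[t, j])
            lgx = math.lgamma(x + 1.0)
            if mode == MODE_EXACT:
                eta = Eta[t, j]
                n_u = 0
                singleton = True
                for k in range(n):
                    if k == t:
                        continue
                    lamk = lam[k, j]
                    if lamk == lam[t, j]:
                        singleton = False
                    d = 0.0
                    found = False
                    for u in range(n_u):
                        if uniq[u] == lamk:
                            d = ud[u]
                            found = True
                            break
                    if not found:
                        d = logtrunc_denom(A[k, j], eta, Fk, lgk)
                        uniq[n_u] = lamk
                        ud[n_u] = d
                        n_u += 1
                    w[k] = x * A[k, j] - d
                # auxiliary fresh values; -log x! - F(x) eta are common
                # to every branch and dropped throughout
                logM = math.log(M[j] / m_aux)
                for i in range(m_aux):
                    if i == 0 and singleton:
                        vf[0] = lam[t, j]
                    else:
                        vf[i] = Aux[t, j, i]
                    av = math.log(vf[i])
                    wf[i] = logM + x * av - logtrunc_denom(av, eta, Fk, lgk)
                mx = wf[0]
                for i in range(1, m_aux):
                    if wf[i] > mx:
                        mx = wf[i]
                for k in range(n):
                    if k != t and w[k] > mx:
                        mx = w[k]
                total = 0.0
                for k in range(n):
                    if k != t:
                        w[k] = _exp_neg(w[k] - mx)
                        total += w[k]
                for i in range(m_aux):
                    wf[i] = _exp_neg(wf[i] - mx)
                    total += wf[i]
                attempts += 1
                if total > 0.0 and math.isfinite(total):
                    u01 = U_idx[t, j] * total
                    csum = 0.0
                    picked = False
                    for k in range(n):
                        if k == t:
                            continue
                        csum += w[k]
                        if u01 <= csum:
                            lam[t, j] = lam[k, j]
                            A[t, j] = A[k, j]
                            picked = True
                            break
                    if not picked:
                        for i in range(m_aux):
                            csum += wf[i]
                            if u01 <= csum:
                                lam[t, j] = vf[i]
                                A[t, j] = math.log(vf[i])
                                accepts += 1
                                break
                continue
            else:
                # plain Poisson approximation to the conditional
                for k in range(n):
                    if k != t:
                        w[k] = x * A[k, j] - lam[k, j] - lgx
                if mode == MODE_PREDICTIVE:
                    w[t] = (
                        math.log(M[j])
                        + math.lgamma(base_a + x)
                        - math.lgamma(base_a)
                        - lgx
                        + base_a * math.log(base_b / (base_b + 1.0))
                        - x * math.log(base_b + 1.0)
                    )
                else:
                    aa = base_a + x
                    bb = base_b + 1.0
                    w[t] = (
                        math.log(M[j])
                        + aa * math.log(bb)
                        - math.lgamma(aa)
                        + (aa - 1.0) * A[t, j]
                        - bb * lam[t, j]
                    )
            mx = w[0]
            for k in range(1, n):
                if w[k] > mx:
                    mx = w[k]
            total = 0.0
            for k in range(n):
                w[k] = _exp_neg(w[k] - mx)
                total += w[k]
            pick = t  # fresh branch if weights degenerate
            if total > 0.0 and math.isfinite(total):
                u = U_idx[t, j] * total
                csum = 0.0
                for k in range(n):
                    csum += w[k]
                    if u <= csum:
                        pick = k
                        break
            if pick != t:
                lam[t, j] = lam[pick, j]
                A[t, j] = math.log(lam[pick, j])
                continue
            # fresh draw with MH correction
            attempts += 1
            lam0 = lam[t, j]
            lamc = Gcand[t, j]
            lamp = lam0 + K1 * (lamc - lam0)
            if lamp <= 0.0:
                continue
            lamcr = (lam0 - (1.0 - K1) * lamp) / K1
            if lamcr <= 0.0:
                continue
            a0 = A[t, j]
            ap = math.log(lamp)
            eta = Eta[t, j]
            d0 = logtrunc_denom(a0, eta, Fk, lgk)
            dp = logtrunc_denom(ap, eta, Fk, lgk)
            # Gamma(base_a, base_b) prior + node conditional likelihood
            dtarget = (
                (base_a - 1.0) * (ap - a0)
                - base_b * (lamp - lam0)
                + x * (ap - a0)
                - (dp - d0)
            )
            aa = base_a + x
            bb = base_b + 1.0
            dq = (aa - 1.0) * (math.log(lamcr) - math.log(lamc)) - bb * (lamcr - lamc)
            if math.log(U_mh[t, j]) < dtarget + dq:
                lam[t, j] = lamp
                A[t, j] = ap
                accepts += 1
    acc_out[0] = accepts
    acc_out[1] = attempts


@njit(cache=True)
def cluster_remix(
    X,
    lam,
    A,
    Eta,
    base_a,
    base_b,
    Fk,
    lgk,
    Z,
    U_mh,
    acc_out,
):
    """Resample each cluster's shared rate given all its members.

    Reassignment alone only introduces rate values through
    single-observation proposals, so a shared cluster value can never
    settle at the multi-member conditional posterior; this move
    proposes, for every distinct value in a column, a log-scale
    random-walk candidate with step size matched to the aggregated
    conjugate posterior (sd ~ 1/sqrt(a + sum of member counts)) and
    accepts under the Gamma(a, b) base density times all member
    conditionals (with the log-normal proposal's Jacobian).
    ``Z``/``U_mh`` are (P, n) pre-drawn normals/uniforms; acc_out
    receives (accepts, attempts).
    """
    n, P = X.shape
    uniq = np.empty(n)
    accepts = 0
    attempts = 0
    for j in range(P):
        n_u = 0
        for t in range(n):
            v = lam[t, j]
            seen = False
            for u in range(n_u):
                if uniq[u] == v:
                    seen = True
                    break
            if not seen:
                uniq[n_u] = v
                n_u += 1
        for u in range(n_u):
            v = uniq[u]
            sx = 0.0
            m = 0
            for t in range(n):
                if lam[t, j] == v:
                    sx += X[t, j]
                    m += 1
            attempts += 1
            sigma = 2.4 / math.sqrt(base_a + sx)
            lamp = v * math.exp(sigma * Z[j, u])
            a0 = math.log(v)
            ap = math.log(lamp)
            dlog = ap - a0
            # base density + Jacobian of the log-normal walk
            logr = base_a * dlog - base_b * (lamp - v)
            for t in range(n):
                if lam[t, j] == v:
                    eta = Eta[t, j]
                    logr += X[t, j] * dlog - (
                        logtrunc_denom(ap, eta, Fk, lgk)
                        - logtrunc_denom(a0, eta, Fk, lgk)
                    )
            if math.log(U_mh[j, u]) < logr:
                for t in range(n):
                    if lam[t, j] == v:
                        lam[t, j] = lamp
                        A[t, j] = ap
                accepts += 1
    acc_out[0] = accepts
    acc_out[1] = attempts


@njit(cache=True)
def _submatrix_drop(Mfull, l, out):
    P = Mfull.shape[0]
    r = 0
    for i in range(P):
        if i == l:
            continue
        c = 0
        for jj in range(P):
            if jj == l:
                continue
            out[r, c] = Mfull[i, jj]
            c += 1
        r += 1


@njit(cache=True)
def beta_sweep(
    Beta,
    s,
    gamma,
    nu3,
    K2,
    p_indep,
    FX,
    A,
    Eta,
    D,
    Fk,
    lgk,
    Z,
    U_kind,
    U_mh,
    acc_out,
):
    """One sweep of edge-coefficient row updates.

    Row l of the working precision surrogate Omega (= Beta with a fixed
    diagonal) is updated by a Metropolis-Hastings move built from the
    surrogate-Gibbs covariance C = ((s_ll + gamma) Omega_{-l,-l}^{-1}
    + I/nu3)^{-1}: with probability ``p_indep`` an independence draw
    from MVN(-C s_{l,-l}, C) with its exact Gaussian density
    correction, otherwise a symmetric preconditioned random-walk step
    cur + K2 * chol(C) z (no correction).  Both kernels leave the
    pseudo-posterior (pseudo-likelihood x N(0, nu3) edge priors)
    invariant; the mean and covariance involve only Omega_{-l,-l},
    which the row-l move does not touch, so forward and reverse share
    them.  Because the chain can visit Beta values for which
    Omega_{-l,-l} is indefinite, the surrogate precision is
    eigenvalue-floored at the prior precision 1/nu3 before use.
    ``D`` caches the conditional log-normalizers and is kept in sync
    with accepted moves.
    """
    n, P = FX.shape
    Pm = P - 1
    sub = np.empty((Pm, Pm))
    EtaNew = np.empty((n, P))
    DNew = np.empty((n, P))
    cur = np.empty(Pm)
    srow = np.empty(Pm)
    for l in range(P):
        _submatrix_drop(Beta, l, sub)
        w0, V0 = np.linalg.eigh(sub)
        for i in range(Pm):
            if abs(w0[i]) < 1e-8:
                w0[i] = 1e-8
        invOm = np.dot(V0 * (1.0 / w0), V0.T)
        Cinv = (s[l, l] + gamma) * invOm
        for i in range(Pm):
            Cinv[i, i] += 1.0 / nu3
        Cinv = 0.5 * (Cinv + Cinv.T)
        w, V = np.linalg.eigh(Cinv)
        for i in range(Pm):
            if w[i] < 1.0 / nu3:
                w[i] = 1.0 / nu3
        Cinv = np.dot(V * w, V.T)
        C = np.dot(V * (1.0 / w), V.T)
        L = V * (1.0 / np.sqrt(w))  # L L^T = C
        c = 0
        for jj in range(P):
            if jj == l:
                continue
            srow[c] = s[l, jj]
            cur[c] = Beta[l, jj]
            c += 1
        mean = -np.dot(C, srow)
        indep = U_kind[l] < p_indep
        if indep:
            new = mean + np.dot(L, Z[l])
        else:
            new = cur + K2 * np.dot(L, Z[l])
        # eta and log-normalizer under the proposed row
        dnum = 0.0
        for t in range(n):
            shift_l = 0.0
            c = 0
            for jj in range(P):
                if jj == l:
                    EtaNew[t, jj] = 0.0  # placeholder, filled after loop
                    continue
                dlt = new[c] - cur[c]
                EtaNew[t, jj] = Eta[t, jj] + dlt * FX[t, l]
                shift_l += dlt * FX[t, jj]
                c += 1
            EtaNew[t, l] = Eta[t, l] + shift_l
        for t in range(n):
            for jj in range(P):
                DNew[t, jj] = logtrunc_denom(A[t, jj], EtaNew[t, jj], Fk, lgk)
                dnum += -FX[t, jj] * (EtaNew[t, jj] - Eta[t, jj]) - (
                    DNew[t, jj] - D[t, jj]
                )
        dprior = 0.0
        for i in range(Pm):
            dprior += (cur[i] ** 2 - new[i] ** 2) / (2.0 * nu3)
        # proposal correction: zero for the symmetric walk; for the
        # independence draw, log N(cur; mean, C) - log N(new; mean, C)
        qc = 0.0
        if indep:
            for i in range(Pm):
                for jj in range(Pm):
                    qc += 0.5 * Cinv[i, jj] * (
                        (new[i] - mean[i]) * (new[jj] - mean[jj])
                        - (cur[i] - mean[i]) * (cur[jj] - mean[jj])
                    )
        logr = dnum + dprior + qc
        if math.log(U_mh[l]) < logr:
            c = 0
            for jj in range(P):
                if jj == l:
                    continue
                Beta[l, jj] = new[c]
                Beta[jj, l] = new[c]
                c += 1
            for t in range(n):
                for jj in range(P):
                    Eta[t, jj] = EtaNew[t, jj]
                    D[t, jj] = DNew[t, jj]
            acc_out[l] = 1
        else:
            acc_out[l] = 0
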