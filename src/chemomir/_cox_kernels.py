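"""Compiled Newton-Raphson kernels for the Efron partial likelihood.

The permutation significance machinery re-runs univariate Cox screening
inside every leave-one-out fold of every permutation replicate — on the
order of a million single-feature fits per analysis — so the inner Newton
loops are JIT-compiled.  Samples arrive sorted by time ascending with events
preceding censored samples at tied times; ``risk_start[g]`` is the first
at-risk row of the g-th distinct event time and ``d[g]`` its tied-event
count, so the events of group g occupy rows ``risk_start[g] ..
risk_start[g]+d[g]-1``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ETA_CLIP = 80.0


@njit(cache=True)
def screen_newton(Zt, risk_start, d, sum_x_events, beta0, grad_tol, max_iter,
                  beta_max, step_max):
    """Independent univariate Newton fits; ``Zt`` is (features, samples).

    Returns ``(beta, hess, converged)``; ``hess`` is the second derivative of
    the partial log-likelihood at the returned beta (negative information).
    """
    p, n = Zt.shape
    G = risk_start.shape[0]
    beta = np.empty(p)
    hess_out = np.empty(p)
    converged = np.zeros(p, np.uint8)
    th = np.empty(n)
    xth = np.empty(n)
    x2th = np.empty(n)
    for j in range(p):
        b = beta0[j]
        if b > beta_max:
            b = beta_max
        elif b < -beta_max:
            b = -beta_max
        conv = False
        hess = 0.0
        for _ in range(max_iter):
            for i in range(n):
                x = Zt[j, i]
                u = b * x
                if u > _ETA_CLIP:
                    u = _ETA_CLIP
                elif u < -_ETA_CLIP:
                    u = -_ETA_CLIP
                e = np.exp(u)
                th[i] = e
                xth[i] = x * e
                x2th[i] = x * x * e
            grad = sum_x_events[j]
            hess = 0.0
            i = n - 1
            s0 = 0.0
            s1 = 0.0
            s2 = 0.0
            for g in range(G - 1, -1, -1):
                rs = risk_start[g]
                dg = d[g]
                while i >= rs:
                    s0 += th[i]
                    s1 += xth[i]
                    s2 += x2th[i]
                    i -= 1
                e0 = 0.0
                e1 = 0.0
                e2 = 0.0
                for r in range(rs, rs + dg):
                    e0 += th[r]
                    e1 += xth[r]
                    e2 += x2th[r]
                for l in range(dg):
                    f = l / dg
                    phi = s0 - f * e0
                    m1 = (s1 - f * e1) / phi
                    m2 = (s2 - f * e2) / phi
                    grad -= m1
                    hess -= m2 - m1 * m1
            if abs(grad) < grad_tol:
                conv = True
                break
            if hess >= -1e-300 or abs(b) > beta_max:
                break
            step = grad / (-hess)
            if step > step_max:
                step = step_max
            elif step < -step_max:
                step = -step_max
            b += step
        beta[j] = b
        hess_out[j] = hess
        converged[j] = 1 if conv else 0
    return beta, hess_out, converged


@njit(cache=True)
def multiv_newton(Zs, risk_start, d, sum_z_events, grad_tol, max_iter,
                  beta_max, step_max):
    """Joint Newton fit for a small number of covariates (samples, q).

    Returns ``(beta, H, status)`` with ``H`` the Hessian at beta; status
    0 = converged, 1 = not converged, 2 = diverged/singular.
    """
    n, q = Zs.shape
    G = risk_start.shape[0]
    beta = np.zeros(q)
    th = np.empty(n)
    grad = np.empty(q)
    H = np.zeros((q, q))
    s1 = np.empty(q)
    e1 = np.empty(q)
    m = np.empty(q)
    S2 = np.empty((q, q))
    E2 = np.empty((q, q))
    status = 1
    for _ in range(max_iter):
        for i in range(n):
            u = 0.0
            for a in range(q):
                u += Zs[i, a] * beta[a]
            if u > _ETA_CLIP:
                u = _ETA_CLIP
            elif u < -_ETA_CLIP:
                u = -_ETA_CLIP
            th[i] = np.exp(u)
        for a in range(q):
            grad[a] = sum_z_events[a]
            for b in range(q):
                H[a, b] = 0.0
        i = n - 1
        s0 = 0.0
        for a in range(q):
            s1[a] = 0.0
            for b in range(q):
                S2[a, b] = 0.0
        for g in range(G - 1, -1, -1):
            rs = risk_start[g]
            dg = d[g]
            while i >= rs:
                t = th[i]
                s0 += t
                for a in range(q):
                    za = Zs[i, a]
                    s1[a] += za * t
                    for b in range(a, q):
                        S2[a, b] += za * Zs[i, b] * t
                i -= 1
            e0 = 0.0
            for a in range(q):
                e1[a] = 0.0
                for b in range(q):
                    E2[a, b] = 0.0
            for r in range(rs, rs + dg):
                t = th[r]
                e0 += t
                for a in range(q):
                    za = Zs[r, a]
                    e1[a] += za * t
                    for b in range(a, q):
                        E2[a, b] += za * Zs[r, b] * t
            for l in range(dg):
                f = l / dg
                phi = s0 - f * e0
                for a in range(q):
                    m[a] = (s1[a] - f * e1[a]) / phi
                    grad[a] -= m[a]
                for a in range(q):
                    for b in range(a, q):
                        H[a, b] -= (S2[a, b] - f * E2[a, b]) / phi - m[a] * m[b]
        for a in range(q):
            for b in range(a):
                H[a, b] = H[b, a]
        gmax = 0.0
        for a in range(q):
            if abs(grad[a]) > gmax:
                gmax = abs(grad[a])
        if gmax < grad_tol:
            status = 0
            break
        det_ok = True
        step = np.linalg.solve(-H, grad)
        for a in range(q):
            if not np.isfinite(step[a]):
                det_ok = False
        if not det_ok:
            status = 2
            break
        nrm = 0.0
        for a in range(q):
            nrm += step[a] * step[a]
        nrm = np.sqrt(nrm)
        if nrm > step_max:
            for a in range(q):
                step[a] *= step_max / nrm
        bmax = 0.0
        for a in range(q):
            beta[a] += step[a]
            if abs(beta[a]) > bmax:
                bmax = abs(beta[a])
        if bmax > beta_max:
            status = 2
            break
    return beta, H, status
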