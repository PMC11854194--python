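"""Compiled hot-loop kernels for the balanced-design Gibbs sweep.

These duplicate, with explicit loops, exactly the arithmetic of the
reference numpy path in :mod:`fidlme.sampler` / :mod:`fidlme.model`;
a unit test pins the two paths together.  Only balanced designs (equal
n_i) with a full-column-rank augmented design go through here — anything
else falls back to the numpy path, which also handles rank deficiency.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def ls_sweep(x3, z3, y3, u, y, tol_factor):
    """Least-squares quantities of y on X_u for the current u.

    Returns (gls, S, rss, ok) with S the lower Cholesky factor of
    (X_u'X_u)^{-1}; ok=False when the Cholesky pivots indicate an
    ill-conditioned Gram matrix (caller must redo the sweep on the
    rank-revealing numpy path).  Raises LinAlgError when X_u'X_u is not
    numerically positive definite.
    """
    m, ni, p = x3.shape
    q = z3.shape[2]
    n = m * ni
    k = p + q
    xu = np.empty((n, k))
    r = 0
    for i in range(m):
        for j in range(ni):
            for a in range(p):
                xu[r, a] = x3[i, j, a]
            for b in range(q):
                xu[r, p + b] = z3[i, j, b] * u[i, b]
            r += 1
    gram = xu.T @ xu
    for i in range(k):
        for j in range(i):
            v = 0.5 * (gram[i, j] + gram[j, i])
            gram[i, j] = v
            gram[j, i] = v
    chol = np.linalg.cholesky(gram)
    dmin = chol[0, 0]
    dmax = chol[0, 0]
    for i in range(1, k):
        if chol[i, i] < dmin:
            dmin = chol[i, i]
        if chol[i, i] > dmax:
            dmax = chol[i, i]
    ok = dmin > tol_factor * dmax
    gls = np.zeros(k)
    smat = np.zeros((k, k))
    rss = 0.0
    if ok:
        # forward substitution: chol @ linv = I
        linv = np.zeros((k, k))
        for col in range(k):
            linv[col, col] = 1.0 / chol[col, col]
            for row in range(col + 1, k):
                s = 0.0
                for t in range(col, row):
                    s += chol[row, t] * linv[t, col]
                linv[row, col] = -s / chol[row, row]
        ainv = linv.T @ linv
        for i in range(k):
            for j in range(i):
                v = 0.5 * (ainv[i, j] + ainv[j, i])
                ainv[i, j] = v
                ainv[j, i] = v
        smat = np.linalg.cholesky(ainv)
        b = xu.T @ y
        gls = ainv @ b
        for r2 in range(n):
            s = y[r2]
            for c in range(k):
                s -= xu[r2, c] * gls[c]
            rss += s * s
    return gls, smat, rss, ok


@njit(cache=False)
def u_sweep(x3, z3, y3, beta, delta, sigma2, noise):
    """One refresh of the latent standardized effects U given eta.

    Per subject: V = sigma^2 I + z diag(delta^2) z', mean = diag(|delta|)
    z'V^{-1}(y - x beta), var = I - diag(|delta|) z'V^{-1}z diag(|delta|);
    draw mean + F noise_i with F an eigen square root of var (negative
    eigenvalues clipped at zero).
    """
    m, ni, p = x3.shape
    q = z3.shape[2]
    adelta = np.abs(delta)
    unew = np.empty((m, q))
    for i in range(m):
        resid = np.empty(ni)
        for j in range(ni):
            s = y3[i, j]
            for a in range(p):
                s -= x3[i, j, a] * beta[a]
            resid[j] = s
        vi = np.empty((ni, ni))
        for j1 in range(ni):
            for j2 in range(ni):
                s = 0.0
                for b in range(q):
                    s += z3[i, j1, b] * delta[b] * delta[b] * z3[i, j2, b]
                vi[j1, j2] = s
            vi[j1, j1] += sigma2
        rhs = np.empty((ni, 1 + q))
        for j1 in range(ni):
            rhs[j1, 0] = resid[j1]
            for b in range(q):
                rhs[j1, 1 + b] = z3[i, j1, b]
        sol = np.linalg.solve(vi, rhs)
        mean = np.empty(q)
        for b in range(q):
            s = 0.0
            for j1 in range(ni):
                s += z3[i, j1, b] * sol[j1, 0]
            mean[b] = adelta[b] * s
        var = np.empty((q, q))
        for b1 in range(q):
            for b2 in range(q):
                s = 0.0
                for j1 in range(ni):
                    s += z3[i, j1, b1] * sol[j1, 1 + b2]
                var[b1, b2] = -adelta[b1] * s * adelta[b2]
            var[b1, b1] += 1.0
        for b1 in range(q):
            for b2 in range(b1):
                v = 0.5 * (var[b1, b2] + var[b2, b1])
                var[b1, b2] = v
                var[b2, b1] = v
        if q == 1:
            vv0 = var[0, 0]
            if vv0 < 0.0:
                vv0 = 0.0
            unew[i, 0] = mean[0] + np.sqrt(vv0) * noise[i, 0]
        else:
            w, vecs = np.linalg.eigh(var)
            for b in range(q):
                if w[b] < 0.0:
                    w[b] = 0.0
            for b1 in range(q):
                s = mean[b1]
                for b2 in range(q):
                    s += vecs[b1, b2] * np.sqrt(w[b2]) * noise[i, b2]
                unew[i, b1] = s
    return unew
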