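"""Coordinate-descent graphical lasso kernel.

Block coordinate descent over the working covariance matrix W: each column's
update is the solution of an L1-penalized quadratic program (a lasso with Gram
matrix W11), itself solved by cyclic coordinate descent.  The diagonal is not
penalized, so W_ii = S_ii throughout (the same convention used by
scikit-learn's covariance module, against which this kernel is tested).

Compiled with numba because the surrounding resampling procedures (permutation
network comparison, case-dropping bootstrap) re-estimate networks tens of
thousands of times on small (p ~ 10) problems, where per-call overhead of a
generic solver dominates.
"""

import numpy as np
from numba import njit

__all__ = ["glasso_kernel", "new_workspace"]


@njit(cache=True)
def glasso_kernel(S, lam, W, B, tol, max_iter, inner_tol, inner_max_iter):
    """One graphical-lasso solve; W and B are warm-startable workspaces.

    Parameters
    ----------
    S : (p, p) covariance/correlation matrix.
    lam : L1 penalty on off-diagonal precision entries.
    W : (p, p) working covariance, modified in place.  Pass ``S.copy()`` for a
        cold start or the previous solution for a warm start along a path.
    B : (p, p-1) per-column lasso coefficients, modified in place.
    tol : outer convergence threshold on the max absolute change of W.
    inner_tol : per-lasso coordinate-descent threshold.

    Returns
    -------
    K : (p, p) estimated precision matrix (symmetrized).
    converged : bool
    """
    p = S.shape[0]
    idx = np.empty(p - 1, np.int64)
    converged = False
    for i in range(p):
        W[i, i] = S[i, i]
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            k = 0
            for i in range(p):
                if i != j:
                    idx[k] = i
                    k += 1
            beta = B[j]
            for _ in range(inner_max_iter):
                inner_delta = 0.0
                for a in range(p - 1):
                    ia = idx[a]
                    r = S[ia, j]
                    for b in range(p - 1):
                        if b != a:
                            r -= W[ia, idx[b]] * beta[b]
                    old = beta[a]
                    if r > lam:
                        new = (r - lam) / W[ia, ia]
                    elif r < -lam:
                        new = (r + lam) / W[ia, ia]
                    else:
                        new = 0.0
                    if new != old:
                        beta[a] = new
                        d = abs(new - old)
                        if d > inner_delta:
                            inner_delta = d
                if inner_delta < inner_tol:
                    break
            for a in range(p - 1):
                ia = idx[a]
                w = 0.0
                for b in range(p - 1):
                    w += W[ia, idx[b]] * beta[b]
                d = abs(w - W[ia, j])
                if d > max_delta:
                    max_delta = d
                W[ia, j] = w
                W[j, ia] = w
        if max_delta < tol:
            converged = True
            break
    K = np.zeros((p, p))
    for j in range(p):
        k = 0
        for i in range(p):
            if i != j:
                idx[k] = i
                k += 1
        beta = B[j]
        wb = 0.0
        for a in range(p - 1):
            wb += W[idx[a], j] * beta[a]
        k22 = 1.0 / (W[j, j] - wb)
        K[j, j] = k22
        for a in range(p - 1):
            K[idx[a], j] = -beta[a] * k22
    # symmetrize; the two per-column solutions agree at convergence, so exact
    # zeros are kept only when both directions are zero
    for i in range(p):
        for j in range(i + 1, p):
            if K[i, j] == 0.0 and K[j, i] == 0.0:
                continue
            v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    return K, converged


def new_workspace(S):
    """Cold-start workspace (W, B) for :func:`glasso_kernel`."""
    p = S.shape[0]
    return S.copy(), np.zeros((p, p - 1))
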