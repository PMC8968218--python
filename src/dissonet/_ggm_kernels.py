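"""Compiled kernels for GGM estimation.

Two hot loops live here because model selection re-fits thousands of
candidate structures (and the bootstrap re-runs the whole selection per
replicate):

* ``glasso_pattern`` — graphical-lasso block coordinate descent, used only
  to propose sparsity patterns along a penalty path;
* ``ggm_refit`` — maximum-likelihood fit of a concentration matrix under
  zero constraints (the classic modified-regression/IPF scheme): at the
  fixed point the implied covariance reproduces S exactly on edges and the
  diagonal, and the concentration matrix is exactly zero off-structure.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def glasso_pattern(S, alpha, max_sweeps=100, tol=1e-4, inner_iters=100, inner_tol=1e-6):
    """Return the symmetrized nonzero pattern of the glasso solution."""
    p = S.shape[0]
    W = S.copy()
    for i in range(p):
        W[i, i] += alpha
    B = np.zeros((p, p))  # B[k, j]: coefficient of variable k in column j's lasso
    off_scale = 0.0
    for i in range(p):
        for k in range(p):
            if i != k and abs(S[i, k]) > off_scale:
                off_scale = abs(S[i, k])
    if off_scale == 0.0:
        return np.zeros((p, p), dtype=np.bool_)
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            # lasso subproblem: min .5 b' W11 b - s12' b + alpha |b|_1
            for _ in range(inner_iters):
                inner_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * B[l, j]
                    if r > alpha:
                        b = (r - alpha) / W[k, k]
                    elif r < -alpha:
                        b = (r + alpha) / W[k, k]
                    else:
                        b = 0.0
                    d = abs(b - B[k, j])
                    if d > inner_delta:
                        inner_delta = d
                    B[k, j] = b
                if inner_delta < inner_tol:
                    break
            for i in range(p):
                if i == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l != j:
                        w += W[i, l] * B[l, j]
                d = abs(w - W[i, j])
                if d > delta:
                    delta = d
                W[i, j] = w
                W[j, i] = w
        if delta < tol * off_scale:
            break
    pattern = np.zeros((p, p), dtype=np.bool_)
    for i in range(p):
        for j in range(p):
            if i != j and (B[i, j] != 0.0 or B[j, i] != 0.0):
                pattern[i, j] = True
                pattern[j, i] = True
    return pattern


@njit(cache=True)
def ggm_refit(S, adj, tol=1e-8, max_sweeps=500):
    """Constrained MLE of the concentration matrix.

    Returns (K, W, n_sweeps, converged) where W is the implied covariance
    (K^-1 at convergence).  ``adj`` must be symmetric with a False diagonal.
    """
    p = S.shape[0]
    W = S.copy()
    beta = np.zeros(p)
    converged = False
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        delta = 0.0
        for j in range(p):
            nb_count = 0
            for i in range(p):
                if adj[i, j]:
                    nb_count += 1
            if nb_count == 0:
                for i in range(p):
                    if i != j:
                        d = abs(W[i, j])
                        if d > delta:
                            delta = d
                        W[i, j] = 0.0
                        W[j, i] = 0.0
                continue
            nb = np.empty(nb_count, dtype=np.int64)
            c = 0
            for i in range(p):
                if adj[i, j]:
                    nb[c] = i
                    c += 1
            A = np.empty((nb_count, nb_count))
            rhs = np.empty(nb_count)
            for a in range(nb_count):
                rhs[a] = S[nb[a], j]
                for b in range(nb_count):
                    A[a, b] = W[nb[a], nb[b]]
            sol = np.linalg.solve(A, rhs)
            for i in range(p):
                beta[i] = 0.0
            for a in range(nb_count):
                beta[nb[a]] = sol[a]
            for i in range(p):
                if i == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l != j and beta[l] != 0.0:
                        w += W[i, l] * beta[l]
                d = abs(w - W[i, j])
                if d > delta:
                    delta = d
                W[i, j] = w
                W[j, i] = w
        if delta < tol:
            converged = True
            break
    # assemble K column by column from the final W
    K = np.zeros((p, p))
    for j in range(p):
        nb_count = 0
        for i in range(p):
            if adj[i, j]:
                nb_count += 1
        if nb_count == 0:
            K[j, j] = 1.0 / S[j, j]
            continue
        nb = np.empty(nb_count, dtype=np.int64)
        c = 0
        for i in range(p):
            if adj[i, j]:
                nb[c] = i
                c += 1
        A = np.empty((nb_count, nb_count))
        rhs = np.empty(nb_count)
        for a in range(nb_count):
            rhs[a] = S[nb[a], j]
            for b in range(nb_count):
                A[a, b] = W[nb[a], nb[b]]
        sol = np.linalg.solve(A, rhs)
        dot = 0.0
        for a in range(nb_count):
            dot += sol[a] * rhs[a]
        k22 = 1.0 / (S[j, j] - dot)
        K[j, j] = k22
        for a in range(nb_count):
            K[nb[a], j] = -sol[a] * k22
    # symmetrize (zeros off-structure are preserved exactly)
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    return K, W, sweeps, converged
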