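"""Numerical hot loops, JIT-compiled when numba is available.

The pure-python fallbacks implement identical arithmetic; numba only makes
them fast.  Sequential full-correction (Gauss-Seidel) sweeps over the
segments of each fiber re-impose the rest lengths after the unconstrained
Langevin move.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def bend_implicit(X, nv, beta):
    """In-place implicit bending relaxation per fiber.

    Solves (I + beta * D2^T D2) x_new = x for each coordinate, where D2 is
    the second-difference operator with free ends — the backward-Euler step
    of the linearized worm-like-chain bending force.  The pentadiagonal SPD
    system is solved by banded LDL^T in O(n) per fiber.
    """
    F, V = X.shape[0], X.shape[1]
    d0 = np.empty(V)
    d1 = np.empty(V)
    d2 = np.empty(V)
    dia = np.empty(V)
    l1 = np.empty(V)
    l2 = np.empty(V)
    z = np.empty(V)
    for i in range(F):
        n = nv[i]
        if n < 3:
            continue
        for j in range(n):
            d0[j] = 1.0
            d1[j] = 0.0
            d2[j] = 0.0
        for r in range(n - 2):
            d0[r] += beta
            d0[r + 1] += 4.0 * beta
            d0[r + 2] += beta
            d1[r] += -2.0 * beta
            d1[r + 1] += -2.0 * beta
            d2[r] += beta
        # banded LDL^T, bandwidth 2
        for j in range(n):
            dj = d0[j]
            if j >= 1:
                dj -= l1[j - 1] * l1[j - 1] * dia[j - 1]
            if j >= 2:
                dj -= l2[j - 2] * l2[j - 2] * dia[j - 2]
            dia[j] = dj
            if j + 1 < n:
                t = d1[j]
                if j >= 1:
                    t -= l2[j - 1] * l1[j - 1] * dia[j - 1]
                l1[j] = t / dj
            if j + 2 < n:
                l2[j] = d2[j] / dj
        for comp in range(2):
            # forward substitution L z = b
            for j in range(n):
                t = X[i, j, comp]
                if j >= 1:
                    t -= l1[j - 1] * z[j - 1]
                if j >= 2:
                    t -= l2[j - 2] * z[j - 2]
                z[j] = t
            # diagonal and backward substitution L^T x = D^{-1} z
            for j in range(n - 1, -1, -1):
                t = z[j] / dia[j]
                if j + 1 < n:
                    t -= l1[j] * X[i, j + 1, comp]
                if j + 2 < n:
                    t -= l2[j] * X[i, j + 2, comp]
                X[i, j, comp] = t


@njit(cache=False)
def project_segments(X, T, nv, tol, max_sweeps):
    """In-place segment-length projection.

    Symmetric over-relaxed Gauss-Seidel sweeps: each segment correction is
    split evenly between its two endpoints, so the projection introduces no
    systematic bias along the chain.

    Returns ``(sweeps_used, worst_residual_before_last_sweep)``; the caller
    treats ``worst >= tol`` after ``max_sweeps`` as non-convergence.
    """
    F = X.shape[0]
    omega = 1.4  # over-relaxation, halves the sweep count on long chains
    worst = 0.0
    for sweep in range(max_sweeps):
        worst = 0.0
        for i in range(F):
            m = nv[i] - 1
            # symmetric sweep: forward then backward along the chain
            for k in range(2 * m):
                j = k if k < m else 2 * m - 1 - k
                dx = X[i, j + 1, 0] - X[i, j, 0]
                dy = X[i, j + 1, 1] - X[i, j, 1]
                dist = math.sqrt(dx * dx + dy * dy)
                err = dist - T[i, j]
                if k < m:
                    a = abs(err)
                    if a > worst:
                        worst = a
                if dist > 0.0:
                    c = 0.5 * omega * err / dist
                    cx = c * dx
                    cy = c * dy
                    X[i, j, 0] += cx
                    X[i, j, 1] += cy
                    X[i, j + 1, 0] -= cx
                    X[i, j + 1, 1] -= cy
        if worst < tol:
            return sweep + 1, worst
    return max_sweeps, worst
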