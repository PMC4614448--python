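"""Inner loops, JIT-compiled when numba is available.

Pure-Python definitions below are the reference behaviour; numba only
accelerates them.  Everything here operates on plain numpy arrays so
that the compiled and interpreted paths are bit-identical.
"""

from __future__ import annotations

import numpy as np

RING, CHAIN = 0, 1


def _hvg_edges_impl(x):
    # Single pass with a monotone stack: index i is popped once nothing
    # to its right can see past the new point j.  An intermediate value
    # EQUAL to the smaller endpoint blocks visibility (strict criterion),
    # so an equal stack top is linked and then retired.
    n = x.shape[0]
    edges = np.empty((2 * n - 3, 2), dtype=np.int64)
    stack = np.empty(n, dtype=np.int64)
    top = -1
    m = 0
    for j in range(n):
        while top >= 0 and x[stack[top]] < x[j]:
            edges[m, 0] = stack[top]
            edges[m, 1] = j
            m += 1
            top -= 1
        if top >= 0:
            edges[m, 0] = stack[top]
            edges[m, 1] = j
            m += 1
            if x[stack[top]] == x[j]:
                top -= 1
        top += 1
        stack[top] = j
    return edges[:m]


def _cml_run_impl(x0, eps, n_record, transient, topology):
    # Diffusive lattice of fully chaotic logistic maps f(x) = 4x(1-x):
    # x_{t+1}[a] = (1-eps) f(x_t[a]) + (eps/2) (f(left) + f(right)).
    # Ring: periodic neighbours; chain: mirrored ends (ghost of site 0
    # is site 1, ghost of site M-1 is site M-2).
    M = x0.shape[0]
    out = np.empty((n_record, M))
    x = x0.copy()
    fx = np.empty(M)
    for t in range(transient + n_record):
        for a in range(M):
            fx[a] = 4.0 * x[a] * (1.0 - x[a])
        for a in range(M):
            if topology == RING:
                left = fx[a - 1] if a > 0 else fx[M - 1]
                right = fx[a + 1] if a < M - 1 else fx[0]
            else:
                left = fx[a - 1] if a > 0 else fx[1]
                right = fx[a + 1] if a < M - 1 else fx[M - 2]
            x[a] = (1.0 - eps) * fx[a] + 0.5 * eps * (left + right)
        if t >= transient:
            for a in range(M):
                out[t - transient, a] = x[a]
    return out


def _gcm_run_impl(x0, eps, n_record, transient):
    # Mean-field (globally coupled) variant:
    # x_{t+1}[a] = (1-eps) f(x_t[a]) + (eps/M) sum_b f(x_t[b]).
    M = x0.shape[0]
    out = np.empty((n_record, M))
    x = x0.copy()
    fx = np.empty(M)
    for t in range(transient + n_record):
        s = 0.0
        for a in range(M):
            fx[a] = 4.0 * x[a] * (1.0 - x[a])
            s += fx[a]
        mean_fx = s / M
        for a in range(M):
            x[a] = (1.0 - eps) * fx[a] + eps * mean_fx
        if t >= transient:
            for a in range(M):
                out[t - transient, a] = x[a]
    return out


try:  # optional acceleration; the interpreted path is authoritative
    from numba import njit

    hvg_edges = njit(_hvg_edges_impl)
    cml_run = njit(_cml_run_impl)
    gcm_run = njit(_gcm_run_impl)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    hvg_edges = _hvg_edges_impl
    cml_run = _cml_run_impl
    gcm_run = _gcm_run_impl
    HAVE_NUMBA = False
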