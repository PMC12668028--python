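"""Numba kernels for single-spin-flip Metropolis sampling of the
K-pairwise model.  The proposal flips one uniformly chosen spin; the move
is accepted with probability min(1, exp(-dH/T)).  Local fields
phi_i = sum_j J_ij sigma_j are cached so an attempt costs O(1) and an
accepted flip O(N)."""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the scalar accumulator passed to the kernels
SUM_E, SUM_E2, SUM_M, SUM_M2, N_SAMP, N_PAIR, N_ACC, FINAL_E = range(8)


@njit(cache=True)
def energy_kernel(h, J, V, sigma):  # pragma: no cover
    n = sigma.size
    e = 0.0
    k = 0
    for i in range(n):
        e -= h[i] * sigma[i]
        if sigma[i] > 0:
            k += 1
        for j in range(i + 1, n):
            e -= J[i, j] * sigma[i] * sigma[j]
    e -= V[k]
    return e


@njit(cache=True)
def metropolis_kernel(h, J, V, T, sigma, n_attempts, burn_in, stride,
                      pair_stride, seed, sum_s, sum_pair, hist_k,
                      scal):  # pragma: no cover
    np.random.seed(seed)
    n = sigma.size
    phi = np.zeros(n)
    k = 0
    for i in range(n):
        if sigma[i] > 0:
            k += 1
        for j in range(n):
            phi[i] += J[i, j] * sigma[j]
    e = energy_kernel(h, J, V, sigma)
    total = burn_in + n_attempts
    for a in range(1, total + 1):
        i = np.random.randint(0, n)
        si = sigma[i]
        de = 2.0 * h[i] * si + 2.0 * si * phi[i] + V[k] - V[k - si]
        if de <= 0.0 or np.random.random() < np.exp(-de / T):
            sigma[i] = -si
            for j in range(n):
                phi[j] -= 2.0 * J[j, i] * si
            k -= si
            e += de
            scal[N_ACC] += 1.0
        if a > burn_in:
            s = a - burn_in
            if s % stride == 0:
                for j in range(n):
                    sum_s[j] += sigma[j]
                hist_k[k] += 1.0
                m = 2.0 * k - n
                scal[SUM_E] += e
                scal[SUM_E2] += e * e
                scal[SUM_M] += m
                scal[SUM_M2] += m * m
                scal[N_SAMP] += 1.0
            if s % pair_stride == 0:
                for i2 in range(n):
                    for j2 in range(i2 + 1, n):
                        sum_pair[i2, j2] += sigma[i2] * sigma[j2]
                scal[N_PAIR] += 1.0
    scal[FINAL_E] = e


@njit(cache=True)
def raster_kernel(h, J, V, T, sigma, n_rows, thin, burn_in, seed,
                  out):  # pragma: no cover
    np.random.seed(seed)
    n = sigma.size
    phi = np.zeros(n)
    k = 0
    for i in range(n):
        if sigma[i] > 0:
            k += 1
        for j in range(n):
            phi[i] += J[i, j] * sigma[j]
    row = 0
    a = 0
    while row < n_rows:
        a += 1
        i = np.random.randint(0, n)
        si = sigma[i]
        de = 2.0 * h[i] * si + 2.0 * si * phi[i] + V[k] - V[k - si]
        if de <= 0.0 or np.random.random() < np.exp(-de / T):
            sigma[i] = -si
            for j in range(n):
                phi[j] -= 2.0 * J[j, i] * si
            k -= si
        if a > burn_in and (a - burn_in) % thin == 0:
            for j in range(n):
                out[j, row] = sigma[j]
            row += 1
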