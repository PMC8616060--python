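"""Numba kernels for the Bernoulli-emission HMM.

All routines work on one or more observation segments concatenated into a
single (T, M) uint8 array; ``starts``/``ends`` delimit independent segments
(assembly gaps break the Markov chain, so each segment restarts from the
initial distribution).  Scaled (normalised) forward/backward recursions are
used: per-step renormalisation keeps everything in linear space without
underflow for arbitrarily long sequences.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _emission_probs(X, P):
    """Per-bin emission likelihoods b[t, k] = prod_m P[k,m]^x (1-P[k,m])^(1-x)."""
    T, M = X.shape
    K = P.shape[0]
    B = np.empty((T, K))
    for t in range(T):
        for k in range(K):
            p = 1.0
            for m in range(M):
                if X[t, m]:
                    p *= P[k, m]
                else:
                    p *= 1.0 - P[k, m]
            B[t, k] = p
    return B


@njit(cache=True)
def forward_loglik(X, starts, ends, pi, A, P):
    """Total log-likelihood of all segments under the model (scaled forward)."""
    K = pi.shape[0]
    B = _emission_probs(X, P)
    loglik = 0.0
    alpha = np.empty(K)
    alpha_new = np.empty(K)
    for s in range(starts.shape[0]):
        t0, t1 = starts[s], ends[s]
        c = 0.0
        for k in range(K):
            alpha[k] = pi[k] * B[t0, k]
            c += alpha[k]
        loglik += np.log(c)
        for k in range(K):
            alpha[k] /= c
        for t in range(t0 + 1, t1):
            c = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[i] * A[i, j]
                alpha_new[j] = acc * B[t, j]
                c += alpha_new[j]
            loglik += np.log(c)
            for k in range(K):
                alpha[k] = alpha_new[k] / c
    return loglik


@njit(cache=True)
def baum_welch_estep(X, starts, ends, pi, A, P):
    """One E-step over all segments.

    Returns (loglik, gamma0, trans_num, emit_num, gamma_sum):
      gamma0[k]       — sum of segment-initial posteriors
      trans_num[i,j]  — expected i->j transition counts
      emit_num[k,m]   — expected 1-emissions per (state, track)
      gamma_sum[k]    — expected occupancy per state
    """
    T, M = X.shape
    K = pi.shape[0]
    B = _emission_probs(X, P)
    gamma0 = np.zeros(K)
    trans_num = np.zeros((K, K))
    emit_num = np.zeros((K, M))
    gamma_sum = np.zeros(K)
    loglik = 0.0

    for s in range(starts.shape[0]):
        t0, t1 = starts[s], ends[s]
        L = t1 - t0
        alpha = np.empty((L, K))
        scale = np.empty(L)
        # scaled forward
        c = 0.0
        for k in range(K):
            alpha[0, k] = pi[k] * B[t0, k]
            c += alpha[0, k]
        scale[0] = c
        for k in range(K):
            alpha[0, k] /= c
        for t in range(1, L):
            c = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[t - 1, i] * A[i, j]
                alpha[t, j] = acc * B[t0 + t, j]
                c += alpha[t, j]
            scale[t] = c
            for k in range(K):
                alpha[t, k] /= c
        for t in range(L):
            loglik += np.log(scale[t])
        # scaled backward with on-the-fly accumulation
        beta = np.ones(K)
        beta_new = np.empty(K)
        for k in range(K):
            g = alpha[L - 1, k]
            gamma_sum[k] += g
            for m in range(M):
                if X[t0 + L - 1, m]:
                    emit_num[k, m] += g
        for t in range(L - 2, -1, -1):
            c = scale[t + 1]
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += A[i, j] * B[t0 + t + 1, j] * beta[j]
                beta_new[i] = acc / c
            # xi contributions at step t -> t+1
            for i in range(K):
                for j in range(K):
                    trans_num[i, j] += (
                        alpha[t, i] * A[i, j] * B[t0 + t + 1, j] * beta[j] / c
                    )
            gnorm = 0.0
            for k in range(K):
                beta[k] = beta_new[k]
                gnorm += alpha[t, k] * beta[k]
            for k in range(K):
                g = alpha[t, k] * beta[k] / gnorm
                gamma_sum[k] += g
                if t == 0:
                    gamma0[k] += g
                for m in range(M):
                    if X[t0 + t, m]:
                        emit_num[k, m] += g
        if L == 1:
            for k in range(K):
                gamma0[k] += alpha[0, k]
    return loglik, gamma0, trans_num, emit_num, gamma_sum


@njit(cache=True)
def viterbi_path(X, starts, ends, pi, A, P):
    """Most probable state path per segment; ties go to the lowest state index."""
    T = X.shape[0]
    K = pi.shape[0]
    logB = np.log(_emission_probs(X, P))
    logpi = np.log(pi)
    logA = np.log(A)
    path = np.empty(T, dtype=np.int32)
    for s in range(starts.shape[0]):
        t0, t1 = starts[s], ends[s]
        L = t1 - t0
        delta = np.empty((L, K))
        psi = np.zeros((L, K), dtype=np.int32)
        for k in range(K):
            delta[0, k] = logpi[k] + logB[t0, k]
        for t in range(1, L):
            for j in range(K):
                best = delta[t - 1, 0] + logA[0, j]
                arg = 0
                for i in range(1, K):
                    v = delta[t - 1, i] + logA[i, j]
                    if v > best:  # strict: first (lowest) index wins ties
                        best = v
                        arg = i
                delta[t, j] = best + logB[t0 + t, j]
                psi[t, j] = arg
        best = delta[L - 1, 0]
        arg = 0
        for k in range(1, K):
            if delta[L - 1, k] > best:
                best = delta[L - 1, k]
                arg = k
        path[t0 + L - 1] = arg
        for t in range(L - 2, -1, -1):
            arg = psi[t + 1, arg]
            path[t0 + t] = arg
    return path


@njit(cache=True)
def sample_path(starts, ends, pi, A, uniforms):
    """Sample a state path segment-by-segment from the chain (inverse CDF)."""
    T = uniforms.shape[0]
    K = pi.shape[0]
    path = np.empty(T, dtype=np.int32)
    for s in range(starts.shape[0]):
        t0, t1 = starts[s], ends[s]
        u = uniforms[t0]
        acc = 0.0
        k = K - 1
        for j in range(K):
            acc += pi[j]
            if u < acc:
                k = j
                break
        path[t0] = k
        for t in range(t0 + 1, t1):
            u = uniforms[t]
            acc = 0.0
            nxt = K - 1
            for j in range(K):
                acc += A[k, j]
                if u < acc:
                    nxt = j
                    break
            k = nxt
            path[t] = k
    return path
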