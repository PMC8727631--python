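"""Inner recursions of the two-state HMM.

The forward-backward and Viterbi recursions are inherently sequential in
the bin index, so chromosome-scale tracks need compiled loops. When numba
is importable the kernels below are jitted; otherwise equivalent pure-Python
versions run (same arithmetic, same operation order), which is fine for the
short sequences used in oracle tests.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-300


def _forward_backward_py(pi, A, e, obs):
    T = obs.size
    b = np.where(obs[:, None] == 1, e[None, :], 1.0 - e[None, :])
    alpha = np.empty((T, 2))
    scale = np.empty(T)
    alpha[0] = pi * b[0]
    scale[0] = alpha[0].sum() + _EPS
    alpha[0] /= scale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * b[t]
        scale[t] = alpha[t].sum() + _EPS
        alpha[t] /= scale[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((2, 2))
    for t in range(T - 1):
        xi_sum += (alpha[t][:, None] * A) * (b[t + 1] * beta[t + 1])[None, :] / scale[t + 1]
    loglik = float(np.log(scale).sum())
    return gamma, xi_sum, loglik


def _viterbi_py(log_pi, log_A, log_b):
    T = log_b.shape[0]
    delta = log_pi + log_b[0]
    back = np.zeros((T, 2), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + log_A
        back[t] = np.argmax(cand, axis=0)  # lower index wins ties
        delta = cand[back[t], np.arange(2)] + log_b[t]
    path = np.empty(T, dtype=np.int8)
    path[-1] = np.argmax(delta)
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=False)
    def _forward_backward_nb(pi, A, e, obs):  # noqa: C901
        T = obs.size
        b = np.empty((T, 2))
        for t in range(T):
            if obs[t] == 1:
                b[t, 0] = e[0]
                b[t, 1] = e[1]
            else:
                b[t, 0] = 1.0 - e[0]
                b[t, 1] = 1.0 - e[1]
        alpha = np.empty((T, 2))
        scale = np.empty(T)
        a0 = pi[0] * b[0, 0]
        a1 = pi[1] * b[0, 1]
        scale[0] = a0 + a1 + _EPS
        alpha[0, 0] = a0 / scale[0]
        alpha[0, 1] = a1 / scale[0]
        for t in range(1, T):
            a0 = (alpha[t - 1, 0] * A[0, 0] + alpha[t - 1, 1] * A[1, 0]) * b[t, 0]
            a1 = (alpha[t - 1, 0] * A[0, 1] + alpha[t - 1, 1] * A[1, 1]) * b[t, 1]
            scale[t] = a0 + a1 + _EPS
            alpha[t, 0] = a0 / scale[t]
            alpha[t, 1] = a1 / scale[t]
        beta = np.empty((T, 2))
        beta[T - 1, 0] = 1.0
        beta[T - 1, 1] = 1.0
        for t in range(T - 2, -1, -1):
            x0 = b[t + 1, 0] * beta[t + 1, 0]
            x1 = b[t + 1, 1] * beta[t + 1, 1]
            beta[t, 0] = (A[0, 0] * x0 + A[0, 1] * x1) / scale[t + 1]
            beta[t, 1] = (A[1, 0] * x0 + A[1, 1] * x1) / scale[t + 1]
        gamma = np.empty((T, 2))
        for t in range(T):
            g0 = alpha[t, 0] * beta[t, 0]
            g1 = alpha[t, 1] * beta[t, 1]
            s = g0 + g1
            gamma[t, 0] = g0 / s
            gamma[t, 1] = g1 / s
        xi_sum = np.zeros((2, 2))
        for t in range(T - 1):
            x0 = b[t + 1, 0] * beta[t + 1, 0]
            x1 = b[t + 1, 1] * beta[t + 1, 1]
            s = scale[t + 1]
            xi_sum[0, 0] += alpha[t, 0] * A[0, 0] * x0 / s
            xi_sum[0, 1] += alpha[t, 0] * A[0, 1] * x1 / s
            xi_sum[1, 0] += alpha[t, 1] * A[1, 0] * x0 / s
            xi_sum[1, 1] += alpha[t, 1] * A[1, 1] * x1 / s
        loglik = 0.0
        for t in range(T):
            loglik += np.log(scale[t])
        return gamma, xi_sum, loglik

    @njit(cache=False)
    def _viterbi_nb(log_pi, log_A, log_b):
        T = log_b.shape[0]
        d0 = log_pi[0] + log_b[0, 0]
        d1 = log_pi[1] + log_b[0, 1]
        back = np.zeros((T, 2), dtype=np.int8)
        for t in range(1, T):
            # to state 0
            c00 = d0 + log_A[0, 0]
            c10 = d1 + log_A[1, 0]
            if c00 >= c10:
                back[t, 0] = 0
                n0 = c00 + log_b[t, 0]
            else:
                back[t, 0] = 1
                n0 = c10 + log_b[t, 0]
            # to state 1
            c01 = d0 + log_A[0, 1]
            c11 = d1 + log_A[1, 1]
            if c01 >= c11:
                back[t, 1] = 0
                n1 = c01 + log_b[t, 1]
            else:
                back[t, 1] = 1
                n1 = c11 + log_b[t, 1]
            d0, d1 = n0, n1
        path = np.empty(T, dtype=np.int8)
        path[T - 1] = 0 if d0 >= d1 else 1
        for t in range(T - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        return path

    forward_backward = _forward_backward_nb
    viterbi_kernel = _viterbi_nb
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    forward_backward = _forward_backward_py
    viterbi_kernel = _viterbi_py
    HAVE_NUMBA = False
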