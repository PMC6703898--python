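"""Compiled inner loops for likelihood evaluation, replay and simulation.

These mirror the single-step operations in :mod:`metacontrol.model` exactly;
the test suite asserts agreement between both paths. All condition handling
(omega per cell, eta = 1 in stable blocks) is resolved by the caller into
per-trial parameter arrays, so the kernels are variant-agnostic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def loglik_packed(
    s1, a_loc, key1, planet, reward, miss1, miss2, key0, q_init,
    alpha, lam, eta, etacf, omega, beta, pi, rho,
):
    q1 = np.full((2, 2), q_init)
    q2 = np.full(2, q_init)
    T = np.full((2, 2, 2), 0.5)
    prev_a = -1
    prev_k = -1
    total = 0.0
    n = s1.shape[0]
    for t in range(n):
        if miss1[t]:
            continue
        s = s1[t]
        om = omega[t]
        z0 = 0.0
        z1 = 0.0
        for a in range(2):
            qmb = T[s, a, 0] * q2[0] + T[s, a, 1] * q2[1]
            qnet = (1.0 - om) * q1[s, a] + om * qmb
            ka = key0[t] if a == 0 else 1 - key0[t]
            z = beta[t] * qnet
            if prev_a == 2 * s + a:
                z += pi[t]
            if prev_k == ka:
                z += rho[t]
            if a == 0:
                z0 = z
            else:
                z1 = z
        m = z0 if z0 > z1 else z1
        lse = m + np.log(np.exp(z0 - m) + np.exp(z1 - m))
        a = a_loc[t]
        total += (z0 if a == 0 else z1) - lse

        p = planet[t]
        T[s, a, p] += eta[t] * (1.0 - T[s, a, p])
        T[s, a, 1 - p] *= 1.0 - eta[t]
        T[s, 1 - a, 1 - p] += etacf[t] * (1.0 - T[s, 1 - a, 1 - p])
        T[s, 1 - a, p] *= 1.0 - etacf[t]
        if not miss2[t]:
            r = reward[t]
            d1 = q2[p] - q1[s, a]
            d2 = r - q2[p]
            q1[s, a] += alpha[t] * (d1 + lam[t] * d2)
            q2[p] += alpha[t] * d2
        prev_a = 2 * s + a
        prev_k = key0[t] if a == 0 else 1 - key0[t]
    return total


@njit(cache=True)
def replay_packed(
    s1, a_loc, key1, planet, reward, miss1, miss2, key0, q_init,
    alpha, lam, eta, etacf, omega, beta, pi, rho,
):
    """Like :func:`loglik_packed` but returns per-trial traces:
    (logp_choice, q2_visited), NaN where undefined."""
    n = s1.shape[0]
    logp = np.full(n, np.nan)
    q2v = np.full(n, np.nan)
    q1 = np.full((2, 2), q_init)
    q2 = np.full(2, q_init)
    T = np.full((2, 2, 2), 0.5)
    prev_a = -1
    prev_k = -1
    for t in range(n):
        if miss1[t]:
            continue
        s = s1[t]
        om = omega[t]
        z0 = 0.0
        z1 = 0.0
        for a in range(2):
            qmb = T[s, a, 0] * q2[0] + T[s, a, 1] * q2[1]
            qnet = (1.0 - om) * q1[s, a] + om * qmb
            ka = key0[t] if a == 0 else 1 - key0[t]
            z = beta[t] * qnet
            if prev_a == 2 * s + a:
                z += pi[t]
            if prev_k == ka:
                z += rho[t]
            if a == 0:
                z0 = z
            else:
                z1 = z
        m = z0 if z0 > z1 else z1
        lse = m + np.log(np.exp(z0 - m) + np.exp(z1 - m))
        a = a_loc[t]
        logp[t] = (z0 if a == 0 else z1) - lse

        p = planet[t]
        q2v[t] = q2[p]
        T[s, a, p] += eta[t] * (1.0 - T[s, a, p])
        T[s, a, 1 - p] *= 1.0 - eta[t]
        T[s, 1 - a, 1 - p] += etacf[t] * (1.0 - T[s, 1 - a, 1 - p])
        T[s, 1 - a, p] *= 1.0 - etacf[t]
        if not miss2[t]:
            r = reward[t]
            d1 = q2[p] - q1[s, a]
            d2 = r - q2[p]
            q1[s, a] += alpha[t] * (d1 + lam[t] * d2)
            q2[p] += alpha[t] * d2
        prev_a = 2 * s + a
        prev_k = key0[t] if a == 0 else 1 - key0[t]
    return logp, q2v


@njit(cache=True)
def simulate_packed(
    s1, key0, mapping, walks, miss1_draw, miss2_draw, u, q_init,
    alpha, lam, eta, etacf, omega, beta, pi, rho,
):
    """Generate one agent's choices on a sequence.

    ``u`` are pre-drawn uniforms for the softmax choice, ``miss*_draw``
    pre-drawn miss flags, ``mapping`` the per-trial action->planet map,
    ``walks`` the per-planet rewards. Returns (a_loc, planet, reward,
    q2_visited, p_first) with -1 / NaN for missing entries; ``p_first`` is
    the probability assigned to local action 0 on each trial.
    """
    n = s1.shape[0]
    a_out = np.full(n, -1, np.int64)
    p_out = np.full(n, -1, np.int64)
    r_out = np.full(n, -1, np.int64)
    q2v = np.full(n, np.nan)
    pfirst = np.full(n, np.nan)
    q1 = np.full((2, 2), q_init)
    q2 = np.full(2, q_init)
    T = np.full((2, 2, 2), 0.5)
    prev_a = -1
    prev_k = -1
    for t in range(n):
        if miss1_draw[t]:
            continue
        s = s1[t]
        om = omega[t]
        z0 = 0.0
        z1 = 0.0
        for a in range(2):
            qmb = T[s, a, 0] * q2[0] + T[s, a, 1] * q2[1]
            qnet = (1.0 - om) * q1[s, a] + om * qmb
            ka = key0[t] if a == 0 else 1 - key0[t]
            z = beta[t] * qnet
            if prev_a == 2 * s + a:
                z += pi[t]
            if prev_k == ka:
                z += rho[t]
            if a == 0:
                z0 = z
            else:
                z1 = z
        m = z0 if z0 > z1 else z1
        p0 = np.exp(z0 - m) / (np.exp(z0 - m) + np.exp(z1 - m))
        pfirst[t] = p0
        a = 0 if u[t] < p0 else 1
        a_out[t] = a

        p = mapping[t, s, a]
        p_out[t] = p
        q2v[t] = q2[p]
        T[s, a, p] += eta[t] * (1.0 - T[s, a, p])
        T[s, a, 1 - p] *= 1.0 - eta[t]
        T[s, 1 - a, 1 - p] += etacf[t] * (1.0 - T[s, 1 - a, 1 - p])
        T[s, 1 - a, p] *= 1.0 - etacf[t]
        if not miss2_draw[t]:
            r = walks[p, t]
            r_out[t] = r
            d1 = q2[p] - q1[s, a]
            d2 = r - q2[p]
            q1[s, a] += alpha[t] * (d1 + lam[t] * d2)
            q2[p] += alpha[t] * d2
        prev_a = 2 * s + a
        prev_k = key0[t] if a == 0 else 1 - key0[t]
    return a_out, p_out, r_out, q2v, pfirst
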