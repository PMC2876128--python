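"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive — direct enumeration and scalar
formulas — and shares no code with the package's dynamic-programming
implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import norm


def bf_patterns(m: int) -> set[tuple[int, ...]]:
    """All contiguous runs of length >= m containing offset 0 in a 2m-1 window."""
    half = m - 1
    window = list(range(-half, half + 1))
    out = set()
    for i in range(len(window)):
        for j in range(i, len(window)):
            run = tuple(window[i : j + 1])
            if len(run) >= m and 0 in run:
                out.add(run)
    return out


def bf_local_evidence(values, t, state, mu, sd, m) -> float:
    """Max over run patterns of the mean Gaussian loglik of available offsets."""
    T = len(values)
    best = -math.inf
    for pat in bf_patterns(m):
        offs = [o for o in pat if 0 <= t + o < T]
        ll = [norm.logpdf(values[t + o], loc=mu[state], scale=sd[state]) for o in offs]
        best = max(best, sum(ll) / len(ll))
    return best


def bf_theta(d_mb, rho, floor=1e-10):
    th = 0.5 * (1.0 - math.exp(-2.0 * rho * d_mb))
    return min(max(th, floor), np.nextafter(0.5, 0))


def bf_labeling_score(labels, values, d_mb, mu, sd, m, rho, K) -> float:
    """psi(y, x): local evidence plus Haldane transition terms."""
    score = 0.0
    for t, y in enumerate(labels):
        score += bf_local_evidence(values, t, y, mu, sd, m)
        if t > 0:
            th = bf_theta(d_mb[t - 1], rho)
            if labels[t - 1] == y:
                score += math.log(1.0 - th)
            else:
                score += math.log(th) - math.log(K - 1)
    return score


def bf_tables(values, d_mb, states, mu, sd, m, rho):
    """Per-locus evidence and per-step transition tables by direct evaluation."""
    T, K = len(values), len(states)
    ev = np.array(
        [[bf_local_evidence(values, t, s, mu, sd, m) for s in states] for t in range(T)]
    )
    trans = np.empty((T - 1, K, K))
    for t in range(T - 1):
        th = bf_theta(d_mb[t], rho)
        for i in range(K):
            for j in range(K):
                trans[t, i, j] = (
                    math.log(1.0 - th) if i == j else math.log(th) - math.log(K - 1)
                )
    return ev, trans


def bf_enumerate(values, d_mb, states, mu, sd, m, rho):
    """Exhaustive enumeration over all K^T labelings.

    Returns (best_labels, best_score, log_Z, marginals) where marginals
    is the (T, K) posterior over states from the normalized scores.
    """
    T, K = len(values), len(states)
    ev, trans = bf_tables(values, d_mb, states, mu, sd, m, rho)
    paths = np.array(list(itertools.product(range(K), repeat=T)))
    scores = ev[np.arange(T)[None, :], paths].sum(axis=1)
    for t in range(1, T):
        scores = scores + trans[t - 1, paths[:, t - 1], paths[:, t]]
    best = int(np.argmax(scores))
    mx = float(scores.max())
    log_Z = mx + math.log(np.exp(scores - mx).sum())
    w = np.exp(scores - log_Z)
    marg = np.zeros((T, K))
    for t in range(T):
        for k in range(K):
            marg[t, k] = w[paths[:, t] == k].sum()
    marg /= marg.sum(axis=1, keepdims=True)
    best_labels = np.array([states[k] for k in paths[best]])
    return best_labels, float(scores[best]), log_Z, marg
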