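"""Exact inference for the CRP copy-number model.

The joint score of a labeling y for an observed log2-ratio series x is

    psi(y, x) = sum_t [ f_TP(y_{t-1}, y_t; d_t) + f_LE(window_t, y_t) ]

with the transition potential omitted at the first locus.  f_TP is the
distance-dependent Haldane change penalty; f_LE is the local evidence:
the maximum over candidate run patterns of the mean Gaussian
log-likelihood of the pattern's observations under the locus's state.
Because the evidence is a per-locus function of the observations only,
the score factorises as a chain and Viterbi / forward-backward are
exact in O(T K^2) after an O(T K P) evidence pass (P = number of
patterns).  All computation is in log space; series of 10^6 markers
decode without underflow.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

from .model import (
    CrpModel,
    DecodeResult,
    EmissionParams,
    ProbeSeries,
    Segment,
    StateSpace,
    TransitionParams,
)

__all__ = [
    "transition_theta",
    "transition_potential",
    "transition_matrix",
    "emission_loglik",
    "local_evidence",
    "local_evidence_matrix",
    "viterbi_decode",
    "path_normalized_probability",
    "posterior_marginals",
    "fit_emission_params",
    "segments_from_path",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    """Shifted log-sum-exp; hot path of the DP recursions."""
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


# ---------------------------------------------------------------------------
# transitions

def transition_theta(d_mb: float, params: TransitionParams) -> float:
    """Change probability between adjacent markers at distance d (Mb).

    Haldane's map function theta = 0.5 * (1 - exp(-2 rho d)) converts a
    genetic distance into a recombination-like change fraction; here it
    is the probability that the copy-number state differs between two
    consecutive markers.  The result is clamped to
    [theta_floor, 0.5) so that log(theta) stays finite at d = 0 and the
    stay probability stays positive.
    """
    d = np.asarray(d_mb, dtype=float)
    if np.any(d < 0):
        raise ValueError("marker distances must be non-negative")
    theta = 0.5 * (1.0 - np.exp(-2.0 * params.morgans_per_mb * d))
    hi = np.nextafter(params.max_theta, 0.0)
    theta = np.clip(theta, params.theta_floor, hi)
    return float(theta) if np.ndim(d_mb) == 0 else theta


def transition_potential(
    y_prev: int,
    y_curr: int,
    d_mb: float,
    params: TransitionParams,
    states: StateSpace,
) -> float:
    """Log transition potential between two copy-number states.

    log(1 - theta) for staying; log(theta / (K - 1)) for a change, the
    change mass being split uniformly over the K - 1 alternative
    states.  Rows of exp(potential) therefore sum to one.
    """
    states.index(y_prev)
    states.index(y_curr)
    theta = transition_theta(d_mb, params)
    if y_prev == y_curr:
        return math.log1p(-theta)
    return math.log(theta) - math.log(states.K - 1)


def transition_matrix(d_mb: np.ndarray, params: TransitionParams, K: int) -> np.ndarray:
    """(len(d), K, K) array of log transition potentials."""
    theta = np.atleast_1d(transition_theta(np.asarray(d_mb, dtype=float), params))
    off = np.log(theta) - math.log(K - 1)
    out = np.repeat(off[:, None, None], K, axis=1).repeat(K, axis=2)
    stay = np.log1p(-theta)
    idx = np.arange(K)
    out[:, idx, idx] = stay[:, None]
    return out


# ---------------------------------------------------------------------------
# emissions and local evidence

def emission_loglik(x, state: int, emission: EmissionParams):
    """Gaussian log density of a log2-ratio under one copy-number state."""
    if state not in emission.mean:
        raise ValueError(f"unknown copy-number state {state!r}")
    return norm.logpdf(x, loc=emission.mean[state], scale=emission.sd[state])


def _loglik_table(values: np.ndarray, model: CrpModel) -> np.ndarray:
    """(T, K) Gaussian log-likelihoods for every marker x state."""
    mu, sd = model.emission.arrays(model.states)
    z = (values[:, None] - mu[None, :]) / sd[None, :]
    return -0.5 * z * z - np.log(sd)[None, :] - _LOG_SQRT_2PI


def local_evidence_matrix(values: np.ndarray, model: CrpModel) -> np.ndarray:
    """(T, K) local evidence: per state, max over patterns of the mean
    log-likelihood of the pattern's observations.

    Patterns are contiguous runs of offsets around each locus, so each
    pattern term is a windowed mean computed from one cumulative sum of
    the (T, K) log-likelihood table.  Near chromosome ends a pattern is
    intersected with the offsets that exist; the center offset always
    exists, so no pattern ever becomes empty.
    """
    values = np.asarray(values, dtype=float)
    T = len(values)
    ll = _loglik_table(values, model)
    csum = np.vstack([np.zeros((1, model.states.K)), np.cumsum(ll, axis=0)])
    t = np.arange(T)
    best = np.full_like(ll, -np.inf)
    for a, b in model.patterns.runs():
        lo = np.clip(t + a, 0, T - 1)
        hi = np.clip(t + b, 0, T - 1)
        n = (hi - lo + 1).astype(float)
        term = (csum[hi + 1] - csum[lo]) / n[:, None]
        np.maximum(best, term, out=best)
    return best


def local_evidence(window, state: int, model: CrpModel, center: int | None = None) -> float:
    """Local evidence for one locus from its observation window.

    ``window`` holds up to 2m-1 consecutive observations; ``center``
    is the index of the locus's own observation within it (defaults to
    the middle for a full window).  Each pattern's term is the mean
    Gaussian log-likelihood of the pattern's available observations
    under ``state`` — a geometric-mean rescaling of the product
    likelihood, which puts runs of different length on a common
    per-observation scale.  The evidence is the maximum term.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("observation window must not be empty")
    if center is None:
        if window.size != 2 * model.patterns.m - 1:
            raise ValueError(
                "center index required for a truncated window "
                f"(got {window.size} observations for m={model.patterns.m})"
            )
        center = window.size // 2
    if not 0 <= center < window.size:
        raise ValueError("center index outside the window")
    ll = emission_loglik(window, state, model.emission)
    best = -np.inf
    for a, b in model.patterns.runs():
        lo = max(center + a, 0)
        hi = min(center + b, window.size - 1)
        best = max(best, float(np.mean(ll[lo : hi + 1])))
    return best


# ---------------------------------------------------------------------------
# dynamic programming

def _prepare(series: ProbeSeries, model: CrpModel) -> tuple[np.ndarray, np.ndarray]:
    series.require_finite()
    ev = local_evidence_matrix(series.value, model)
    trans = transition_matrix(series.distances_mb(), model.transition, model.states.K)
    return ev, trans


def _viterbi(ev: np.ndarray, trans: np.ndarray, states: StateSpace) -> tuple[np.ndarray, float]:
    """Max-sum DP; returns (state-index path, best final log score).

    Ties are broken toward the state whose copy number is closest to
    normal, deterministically, via a fixed preference permutation.
    """
    T, K = ev.shape
    pref = states.preference_order()
    delta = ev[0].copy()
    back = np.empty((T, K), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + trans[t - 1]          # (prev, curr)
        best_prev = pref[np.argmax(cand[pref, :], axis=0)]
        back[t] = best_prev
        delta = cand[best_prev, np.arange(K)] + ev[t]
    last = int(pref[np.argmax(delta[pref])])
    path = np.empty(T, dtype=np.intp)
    path[-1] = last
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(delta[last])


def _forward_logZ(ev: np.ndarray, trans: np.ndarray) -> float:
    alpha = ev[0].copy()
    for t in range(1, ev.shape[0]):
        alpha = _logsumexp(alpha[:, None] + trans[t - 1], axis=0) + ev[t]
    return float(_logsumexp(alpha, axis=0))


def _forward_backward(ev: np.ndarray, trans: np.ndarray) -> tuple[np.ndarray, float]:
    T, K = ev.shape
    alpha = np.empty((T, K))
    alpha[0] = ev[0]
    for t in range(1, T):
        alpha[t] = _logsumexp(alpha[t - 1][:, None] + trans[t - 1], axis=0) + ev[t]
    beta = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        beta[t] = _logsumexp(trans[t] + (ev[t + 1] + beta[t + 1])[None, :], axis=1)
    log_Z = float(_logsumexp(alpha[-1], axis=0))
    post = np.exp(alpha + beta - log_Z)
    post /= post.sum(axis=1, keepdims=True)
    return post, log_Z


def viterbi_decode(series: ProbeSeries, model: CrpModel) -> DecodeResult:
    """Exact maximum a posteriori copy-number path for one chromosome.

    Returns the best path, its normalized probability
    max_y delta_T(y) / Z(x), per-locus posterior marginals from
    forward-backward over the same potentials, and the path's maximal
    constant-state segments.
    """
    ev, trans = _prepare(series, model)
    idx_path, delta_final = _viterbi(ev, trans, model.states)
    posteriors, log_Z = _forward_backward(ev, trans)
    path = np.array([model.states.labels[i] for i in idx_path])
    segments = segments_from_path(path, series, posteriors, model)
    return DecodeResult(
        path=path,
        delta_final=delta_final,
        log_Z=log_Z,
        path_probability=float(np.exp(delta_final - log_Z)),
        posteriors=posteriors,
        segments=tuple(segments),
    )


def path_normalized_probability(series: ProbeSeries, model: CrpModel) -> float:
    """Probability of the best labeling, exp(max_y delta_T(y) - log Z)."""
    ev, trans = _prepare(series, model)
    _, delta_final = _viterbi(ev, trans, model.states)
    return float(np.exp(delta_final - _forward_logZ(ev, trans)))


def posterior_marginals(series: ProbeSeries, model: CrpModel) -> np.ndarray:
    """(T, K) per-locus copy-number posteriors via forward-backward."""
    ev, trans = _prepare(series, model)
    post, _ = _forward_backward(ev, trans)
    return post


# ---------------------------------------------------------------------------
# parameter estimation and segmentation

def fit_emission_params(
    values,
    labels,
    states: StateSpace,
    fallback: EmissionParams,
) -> EmissionParams:
    """Fit per-state Gaussian emission parameters from labelled markers.

    For each state present in ``labels`` the mean is the sample mean
    and the sd the n-1 sample standard deviation, as one would fit from
    known monosomy/trisomy regions.  States absent from the labels keep
    the fallback parameters.  Non-monotone fitted means warn (they may
    simply reflect noise) rather than error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    mean = {s: fallback.mean[s] for s in fallback.mean}
    sd = {s: fallback.sd[s] for s in fallback.sd}
    for s in states.labels:
        sel = values[labels == s]
        if sel.size == 0:
            continue
        if sel.size == 1:
            raise ValueError(
                f"state {s} has a single labelled observation; "
                "its standard deviation is undefined"
            )
        mean[s] = float(np.mean(sel))
        sd[s] = float(np.std(sel, ddof=1))
    return EmissionParams(mean=mean, sd=sd)


def segments_from_path(
    path,
    series: ProbeSeries,
    posteriors: np.ndarray,
    model: CrpModel,
) -> list[Segment]:
    """Collapse a per-marker path into maximal constant-state segments.

    Segment bp coordinates are 0-based half-open: [start marker's
    position, last marker's position + 1).  Segments shorter than the
    model's minimum run length m are flagged, not removed.
    """
    path = np.asarray(path)
    if len(path) != series.T:
        raise ValueError("path length must equal the number of markers")
    change = np.flatnonzero(path[1:] != path[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [series.T]])
    state_index = {s: i for i, s in enumerate(model.states.labels)}
    segments = []
    for a, b in zip(starts, ends):
        state = int(path[a])
        k = state_index[state]
        segments.append(
            Segment(
                chromosome=series.chromosome,
                start_index=int(a),
                end_index=int(b),
                start_bp=int(series.pos_bp[a]),
                end_bp=int(series.pos_bp[b - 1]) + 1,
                state=state,
                n_markers=int(b - a),
                mean_probability=float(np.mean(posteriors[a:b, k])),
                short=bool(b - a < model.patterns.m),
            )
        )
    return segments
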