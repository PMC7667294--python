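"""Linear-chain conditional random field primitives (numpy).

Works on raw emission score sequences: given per-position class scores
``emissions`` (T x C), start scores (C,) and a transition matrix (C x C,
``trans[i, j]`` = score of moving from class i to class j), provides the
log-partition, negative log-likelihood with exact gradients
(forward-backward), and Viterbi decoding.  Shared by the biLSTM-CRF and the
naive-Bayes + transition-smoothing baseline.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp


def sequence_score(
    emissions: np.ndarray, tags: np.ndarray, start: np.ndarray, trans: np.ndarray
) -> float:
    score = start[tags[0]] + emissions[0, tags[0]]
    for t in range(1, len(tags)):
        score += trans[tags[t - 1], tags[t]] + emissions[t, tags[t]]
    return float(score)


def forward_log_partition(
    emissions: np.ndarray, start: np.ndarray, trans: np.ndarray
) -> tuple[float, np.ndarray]:
    """Returns (logZ, alpha) where alpha[t, j] = log-sum of paths ending in j."""
    T, C = emissions.shape
    alpha = np.empty((T, C))
    alpha[0] = start + emissions[0]
    for t in range(1, T):
        alpha[t] = emissions[t] + logsumexp(alpha[t - 1][:, None] + trans, axis=0)
    return float(logsumexp(alpha[-1])), alpha


def backward_log(emissions: np.ndarray, trans: np.ndarray) -> np.ndarray:
    T, C = emissions.shape
    beta = np.zeros((T, C))
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(trans + (emissions[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


def nll_and_gradients(
    emissions: np.ndarray,
    tags: np.ndarray,
    start: np.ndarray,
    trans: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Negative log-likelihood of the tag sequence and exact gradients.

    Returns (nll, d_emissions, d_start, d_trans); gradients are marginal
    expectations minus observed indicator counts.
    """
    T, C = emissions.shape
    logz, alpha = forward_log_partition(emissions, start, trans)
    beta = backward_log(emissions, trans)

    nll = logz - sequence_score(emissions, tags, start, trans)

    # unary marginals
    gamma = np.exp(alpha + beta - logz)
    d_emissions = gamma.copy()
    d_emissions[np.arange(T), tags] -= 1.0

    d_start = gamma[0].copy()
    d_start[tags[0]] -= 1.0

    d_trans = np.zeros_like(trans)
    for t in range(1, T):
        pair = (
            alpha[t - 1][:, None]
            + trans
            + (emissions[t] + beta[t])[None, :]
        )
        d_trans += np.exp(pair - logz)
        d_trans[tags[t - 1], tags[t]] -= 1.0
    return float(nll), d_emissions, d_start, d_trans


def viterbi_decode(
    emissions: np.ndarray, start: np.ndarray, trans: np.ndarray
) -> np.ndarray:
    """Most probable tag sequence; ties resolve to the lowest class index."""
    T, C = emissions.shape
    delta = start + emissions[0]
    backptr = np.zeros((T, C), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + trans
        backptr[t] = np.argmax(cand, axis=0)
        delta = emissions[t] + cand[backptr[t], np.arange(C)]
    tags = np.empty(T, dtype=np.intp)
    tags[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        tags[t - 1] = backptr[t, tags[t]]
    return tags
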