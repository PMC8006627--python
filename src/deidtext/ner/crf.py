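"""Linear-chain CRF: forward algorithm, negative log-likelihood and Viterbi.

Scores live in an emission matrix (one row of tag scores per token) and a
transition matrix of shape ``(n_tags + 2, n_tags + 2)`` whose last two
indices are the virtual START and STOP states.  A path score is::

    trans[START, t_0] + sum_i emis[i, t_i]
                      + sum_i trans[t_{i-1}, t_i] + trans[t_{T-1}, STOP]

The partition function is computed in log space (stable for any score
magnitude).  The NumPy functions here are the inference/oracle surface; the
training loss re-implements the same recursion on autograd tensors in
:mod:`deidtext.ner.model`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "start_stop_indices",
    "crf_log_partition",
    "crf_gold_score",
    "crf_nll",
    "viterbi_decode",
]


def start_stop_indices(n_tags: int) -> tuple[int, int]:
    """(START, STOP) row/column indices for a tag inventory of size n_tags."""
    return n_tags, n_tags + 1


def _check(emissions: np.ndarray, transitions: np.ndarray):
    emissions = np.asarray(emissions, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be (T >= 1, n_tags)")
    n_tags = emissions.shape[1]
    if transitions.shape != (n_tags + 2, n_tags + 2):
        raise ValueError(
            f"transitions must be ({n_tags + 2}, {n_tags + 2}), "
            f"got {transitions.shape}"
        )
    return emissions, transitions, n_tags


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    return np.squeeze(
        m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True)), axis=axis
    )


def crf_log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log sum over all tag paths of exp(path score), by the forward
    algorithm in log space."""
    emissions, transitions, n_tags = _check(emissions, transitions)
    start, stop = start_stop_indices(n_tags)
    alpha = transitions[start, :n_tags] + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = _logsumexp(
            alpha[:, None] + transitions[:n_tags, :n_tags], axis=0
        ) + emissions[t]
    return float(_logsumexp(alpha + transitions[:n_tags, stop], axis=0))


def crf_gold_score(
    emissions: np.ndarray, transitions: np.ndarray, tags: np.ndarray
) -> float:
    """Score of one tag path, including START/STOP transitions."""
    emissions, transitions, n_tags = _check(emissions, transitions)
    tags = np.asarray(tags, dtype=np.intp)
    if tags.shape[0] != emissions.shape[0]:
        raise ValueError("one tag per token required")
    if tags.min() < 0 or tags.max() >= n_tags:
        raise ValueError(f"tag index out of range [0, {n_tags})")
    start, stop = start_stop_indices(n_tags)
    score = transitions[start, tags[0]] + emissions[0, tags[0]]
    for t in range(1, len(tags)):
        score += transitions[tags[t - 1], tags[t]] + emissions[t, tags[t]]
    return float(score + transitions[tags[-1], stop])


def crf_nll(
    emissions: np.ndarray, transitions: np.ndarray, tags: np.ndarray
) -> float:
    """Negative log-likelihood of the gold path: log Z minus its score.

    Non-negative up to floating error; zero iff the gold path carries all
    probability mass.
    """
    return crf_log_partition(emissions, transitions) - crf_gold_score(
        emissions, transitions, tags
    )


def viterbi_decode(
    emissions: np.ndarray, transitions: np.ndarray
) -> tuple[list[int], float]:
    """Best-scoring tag path and its score (max-product decoding).

    Ties are broken toward the lowest tag index at every backtracking step
    (``argmax`` returns the first maximum), which makes decoding fully
    deterministic.
    """
    emissions, transitions, n_tags = _check(emissions, transitions)
    start, stop = start_stop_indices(n_tags)
    T = emissions.shape[0]
    delta = transitions[start, :n_tags] + emissions[0]
    backptr = np.zeros((T, n_tags), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + transitions[:n_tags, :n_tags]
        backptr[t] = np.argmax(scores, axis=0)
        delta = np.max(scores, axis=0) + emissions[t]
    final = delta + transitions[:n_tags, stop]
    last = int(np.argmax(final))
    path = [last]
    for t in range(T - 1, 0, -1):
        last = int(backptr[t, last])
        path.append(last)
    path.reverse()
    return path, float(final[path[-1]])
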