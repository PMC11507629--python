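"""Linear-chain conditional random field over secondary-structure labels.

A label path y = (y_1 .. y_L) for emissions e (an L x K matrix of
unnormalized per-residue state scores) is scored as

    s(y) = start[y_1] + sum_t e[t, y_t] + sum_t T[y_{t-1}, y_t] + stop[y_L]

where T is the learned K x K transition-score matrix.  The path
probability is P(y) = exp(s(y)) / Z with Z the sum of exp-scores over
all K^L paths.  Training minimizes the negative log-likelihood
log Z - s(y*); decoding returns the argmax path by Viterbi dynamic
programming with deterministic lowest-index tie-breaking.

All recursions run in log space (logsumexp with max subtraction): the
literal exponential form of Z overflows for chains beyond ~100 steps.
``brute_force_oracle`` enumerates all paths explicitly and exists for
testing only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .autodiff import Tensor

__all__ = [
    "CrfParameters", "score_path", "log_partition", "forward_backward",
    "nll_loss", "nll_gradients", "viterbi_decode", "brute_force_oracle",
    "crf_nll_batch", "export_transitions_csv",
]


@dataclass
class CrfParameters:
    """Transition scores plus boundary (start/stop) score vectors.

    ``start``/``stop`` realize the chain-boundary features of standard
    linear-chain practice; initialize them to zero (and keep them frozen)
    for a boundary-free chain.
    """

    transitions: np.ndarray  # (K, K): score of state a followed by state b
    start: np.ndarray        # (K,)
    stop: np.ndarray         # (K,)

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        self.start = np.asarray(self.start, dtype=np.float64)
        self.stop = np.asarray(self.stop, dtype=np.float64)
        K = self.transitions.shape[0]
        if self.transitions.shape != (K, K):
            raise ValueError("transitions must be square")
        if self.start.shape != (K,) or self.stop.shape != (K,):
            raise ValueError("start/stop must be length-K vectors")
        for arr in (self.transitions, self.start, self.stop):
            if not np.all(np.isfinite(arr)):
                raise ValueError("CRF parameters must be finite")

    @property
    def num_states(self) -> int:
        return self.transitions.shape[0]

    @classmethod
    def zeros(cls, K: int) -> "CrfParameters":
        return cls(np.zeros((K, K)), np.zeros(K), np.zeros(K))


def _check_emissions(emissions: np.ndarray, params: CrfParameters) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=np.float64)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be a (L >= 1, K) matrix")
    if emissions.shape[1] != params.num_states:
        raise ValueError(
            f"emissions have {emissions.shape[1]} states, parameters "
            f"{params.num_states}"
        )
    return emissions


def score_path(
    emissions: np.ndarray, y: Sequence[int], params: CrfParameters
) -> float:
    """Unnormalized score of one label path."""
    emissions = _check_emissions(emissions, params)
    y = np.asarray(y, dtype=np.intp)
    L, K = emissions.shape
    if y.shape != (L,):
        raise ValueError(f"path length {y.shape} does not match emissions ({L},)")
    if L == 0:
        raise ValueError("empty label sequence")
    if y.min() < 0 or y.max() >= K:
        raise ValueError("label index outside alphabet")
    s = params.start[y[0]] + emissions[np.arange(L), y].sum() + params.stop[y[-1]]
    if L > 1:
        s += params.transitions[y[:-1], y[1:]].sum()
    return float(s)


def log_partition(emissions: np.ndarray, params: CrfParameters) -> float:
    """log Z: log-sum-exp of path scores over all K^L paths, in O(L K^2)."""
    emissions = _check_emissions(emissions, params)
    alpha = params.start + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = logsumexp(alpha[:, None] + params.transitions, axis=0) + emissions[t]
    return float(logsumexp(alpha + params.stop))


def forward_backward(
    emissions: np.ndarray, params: CrfParameters
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Log-partition plus exact posterior marginals.

    Returns ``(logZ, unary, pairwise)`` where ``unary[t, k]`` is
    P(y_t = k) and ``pairwise[t, a, b]`` is P(y_t = a, y_{t+1} = b)
    (shape (L-1, K, K); empty for L = 1).
    """
    emissions = _check_emissions(emissions, params)
    L, K = emissions.shape
    alpha = np.empty((L, K))
    alpha[0] = params.start + emissions[0]
    for t in range(1, L):
        alpha[t] = (
            logsumexp(alpha[t - 1][:, None] + params.transitions, axis=0)
            + emissions[t]
        )
    log_z = float(logsumexp(alpha[-1] + params.stop))

    beta = np.empty((L, K))
    beta[-1] = params.stop
    for t in range(L - 2, -1, -1):
        beta[t] = logsumexp(
            params.transitions + (emissions[t + 1] + beta[t + 1])[None, :], axis=1
        )

    unary = np.exp(alpha + beta - log_z)
    pairwise = np.empty((L - 1, K, K))
    for t in range(L - 1):
        pairwise[t] = np.exp(
            alpha[t][:, None]
            + params.transitions
            + (emissions[t + 1] + beta[t + 1])[None, :]
            - log_z
        )
    return log_z, unary, pairwise


def nll_loss(
    emissions: np.ndarray, y_true: Sequence[int], params: CrfParameters
) -> float:
    """Negative log-likelihood of the true path: log Z - s(y_true); >= 0."""
    return log_partition(emissions, params) - score_path(emissions, y_true, params)


def nll_gradients(
    emissions: np.ndarray, y_true: Sequence[int], params: CrfParameters
) -> Tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NLL and its exact gradients.

    The gradient w.r.t. emissions is (posterior marginals - one-hot truth);
    w.r.t. transitions, (expected - observed) transition counts; likewise
    for the boundary vectors.  Returns
    ``(loss, d_emissions, d_transitions, d_start, d_stop)``.
    """
    emissions = _check_emissions(emissions, params)
    y = np.asarray(y_true, dtype=np.intp)
    L, K = emissions.shape
    log_z, unary, pairwise = forward_backward(emissions, params)
    loss = log_z - score_path(emissions, y, params)

    d_em = unary.copy()
    d_em[np.arange(L), y] -= 1.0

    d_trans = pairwise.sum(axis=0) if L > 1 else np.zeros((K, K))
    if L > 1:
        np.add.at(d_trans, (y[:-1], y[1:]), -1.0)

    d_start = unary[0].copy()
    d_start[y[0]] -= 1.0
    d_stop = unary[-1].copy()
    d_stop[y[-1]] -= 1.0
    return float(loss), d_em, d_trans, d_start, d_stop


def viterbi_decode(
    emissions: np.ndarray, params: CrfParameters
) -> Tuple[List[int], float]:
    """Maximum-scoring label path and its score.

    Ties at every max are broken toward the lowest state index (argmax
    returns the first maximizer), so decoding is deterministic.
    """
    emissions = _check_emissions(emissions, params)
    L, K = emissions.shape
    delta = params.start + emissions[0]
    back = np.empty((L, K), dtype=np.intp)
    for t in range(1, L):
        cand = delta[:, None] + params.transitions  # (prev, next)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + emissions[t]
    final = delta + params.stop
    last = int(np.argmax(final))
    best = float(final[last])
    path = [last]
    for t in range(L - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, best


def brute_force_oracle(
    emissions: np.ndarray, params: CrfParameters, max_paths: int = 10**6
) -> Tuple[np.ndarray, List[int], float]:
    """Exhaustive enumeration over all K^L paths (test oracle only).

    Returns ``(scores, best_path, log_partition)`` with ``scores`` in
    lexicographic path order and the best path chosen with the same
    lowest-index tie-breaking as :func:`viterbi_decode`.
    """
    emissions = _check_emissions(emissions, params)
    L, K = emissions.shape
    if K**L > max_paths:
        raise ValueError(f"instance too large to enumerate: {K}^{L} paths")
    # all K^L paths in lexicographic order, one row each
    paths = np.stack(
        np.meshgrid(*[np.arange(K)] * L, indexing="ij"), axis=-1
    ).reshape(-1, L)
    scores = (
        params.start[paths[:, 0]]
        + emissions[np.arange(L)[None, :], paths].sum(axis=1)
        + params.stop[paths[:, -1]]
    )
    if L > 1:
        scores += params.transitions[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    best = int(np.argmax(scores))  # first max: lexicographically lowest path
    return scores, list(paths[best]), float(logsumexp(scores))


# -- batched training loss --------------------------------------------------


def crf_nll_batch(
    emissions: Tensor,
    transitions: Tensor,
    start: Tensor,
    stop: Tensor,
    labels: np.ndarray,
    lengths: np.ndarray,
) -> Tensor:
    """Mean per-sequence NLL over a right-padded batch, as a tape node.

    ``emissions`` is (B, L_max, K); ``labels`` (B, L_max) integer states
    (entries beyond each length are ignored); ``lengths`` (B,).  The
    backward pass uses the exact forward-backward marginals rather than
    differentiating through the recursion.
    """
    labels = np.asarray(labels, dtype=np.intp)
    lengths = np.asarray(lengths, dtype=np.intp)
    B = emissions.data.shape[0]
    params = CrfParameters(transitions.data, start.data, stop.data)

    total = 0.0
    g_em = np.zeros_like(emissions.data)
    g_tr = np.zeros_like(transitions.data)
    g_st = np.zeros_like(start.data)
    g_sp = np.zeros_like(stop.data)
    for b in range(B):
        Lb = int(lengths[b])
        loss, d_em, d_tr, d_st, d_sp = nll_gradients(
            emissions.data[b, :Lb], labels[b, :Lb], params
        )
        total += loss
        g_em[b, :Lb] += d_em
        g_tr += d_tr
        g_st += d_st
        g_sp += d_sp

    value = total / B

    def vjp(g):
        scale = float(g) / B
        return (scale * g_em, scale * g_tr, scale * g_st, scale * g_sp)

    return Tensor(
        value, _parents=(emissions, transitions, start, stop), _vjp=vjp
    )


def export_transitions_csv(path: str, params: CrfParameters, states: str) -> None:
    """Write the transition matrix as labeled CSV for inspection."""
    import pandas as pd

    df = pd.DataFrame(params.transitions, index=list(states), columns=list(states))
    df.to_csv(path, index_label="from\\to")
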