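"""Three-state Markov model of a pair of excitatory neurons.

Every unordered pair of excitatory neurons is, at any snapshot, either
unconnected (U), singly connected (S) or doubly/reciprocally connected
(D).  Treating each pair as an independent three-state Markov chain with
per-interval transition probabilities p_US, p_SU, p_SD, p_DS (direct
U<->D jumps are assumed negligible), the stationary distribution has the
closed form

    u = 1 / (1 + alpha (1 + beta)),   s = alpha u,   d = alpha beta u,

with alpha = p_US / p_SU and beta = p_SD / p_DS.  The overall connection
probability is p = s/2 + d, and the predicted overrepresentation of
doubly connected pairs relative to a density-matched random graph
(d_random = p^2) is

    A = d / d_random = (beta + alpha beta (1 + beta))
                       / (alpha/4 + alpha beta (1 + beta)),

which is an algebraic identity with d / (s/2 + d)^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransitionEstimate",
    "pair_states",
    "estimate_transitions",
    "transition_matrix",
    "stationary_distribution",
    "random_graph_pair_distribution",
    "overrepresentation_A",
    "simulate_pair_chains",
]


@dataclass
class TransitionEstimate:
    """Per-interval transition probabilities estimated from snapshots."""

    p_us: float
    p_su: float
    p_sd: float
    p_ds: float
    counts: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=np.int64))
    n_ignored_ud: int = 0
    undefined: tuple = ()

    @property
    def alpha(self) -> float:
        return self.p_us / self.p_su if self.p_su > 0 else np.nan

    @property
    def beta(self) -> float:
        return self.p_sd / self.p_ds if self.p_ds > 0 else np.nan


def pair_states(adj: np.ndarray) -> np.ndarray:
    """State (0=U, 1=S, 2=D) of every unordered pair, upper-triangle order."""
    a = np.asarray(adj, dtype=bool)
    iu, ju = np.triu_indices(a.shape[0], k=1)
    return a[iu, ju].astype(np.int8) + a[ju, iu].astype(np.int8)


def estimate_transitions(snapshots, window_s: tuple[float, float]) -> TransitionEstimate:
    """Maximum-likelihood transition probabilities from a snapshot series.

    For states X, Y the estimate is ``p_XY = (#X->Y transitions) /
    (#intervals starting in X)``, counted over consecutive snapshots in
    the window.  Direct U<->D jumps violate the model's no-double-event
    assumption: they are excluded from both numerator and denominator,
    tallied separately, and trigger a warning above 1% of transitions.
    States never visited leave their outgoing probabilities undefined
    (NaN, flagged in ``undefined``).
    """
    idx = snapshots.window(*window_s)
    if len(idx) < 2:
        raise ValueError("need at least two snapshots in the window")
    counts = np.zeros((3, 3), dtype=np.int64)
    prev = pair_states(snapshots.adjacency(idx[0]))
    for k in idx[1:]:
        cur = pair_states(snapshots.adjacency(k))
        counts += np.bincount((prev * 3 + cur).astype(np.int64), minlength=9).reshape(3, 3)
        prev = cur
    return _estimate_from_counts(counts)


def _estimate_from_counts(counts: np.ndarray) -> TransitionEstimate:
    n_ud = int(counts[0, 2] + counts[2, 0])
    total = int(counts.sum())
    if total and n_ud / total > 0.01:
        warnings.warn(
            f"direct U<->D jumps are {n_ud / total:.1%} of transitions; "
            "the three-state model assumes they are negligible"
        )
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return np.nan
        return num / den

    p_us = ratio(counts[0, 1], counts[0, 0] + counts[0, 1], "p_us")
    p_su = ratio(counts[1, 0], counts[1].sum(), "p_su")
    p_sd = ratio(counts[1, 2], counts[1].sum(), "p_sd")
    p_ds = ratio(counts[2, 1], counts[2, 1] + counts[2, 2], "p_ds")
    return TransitionEstimate(p_us, p_su, p_sd, p_ds, counts, n_ud, tuple(undefined))


def estimate_from_states(states: np.ndarray) -> TransitionEstimate:
    """Transition estimate from a raw (n_times, n_pairs) state array.

    Same counting conventions as :func:`estimate_transitions`.
    """
    s = np.asarray(states, dtype=np.int64)
    if s.shape[0] < 2:
        raise ValueError("need at least two time points")
    flat = (s[:-1] * 3 + s[1:]).ravel()
    counts = np.bincount(flat, minlength=9).reshape(3, 3)
    return _estimate_from_counts(counts)


def transition_matrix(p_us: float, p_su: float, p_sd: float, p_ds: float) -> np.ndarray:
    """Row-stochastic {U, S, D} transition matrix (U<->D entries zero)."""
    probs = np.array([p_us, p_su, p_sd, p_ds])
    if (probs < 0).any() or (probs > 1).any() or p_su + p_sd > 1:
        raise ValueError("transition probabilities must form a stochastic matrix")
    return np.array(
        [
            [1.0 - p_us, p_us, 0.0],
            [p_su, 1.0 - p_su - p_sd, p_sd],
            [0.0, p_ds, 1.0 - p_ds],
        ]
    )


def stationary_distribution(alpha: float, beta: float) -> tuple[float, float, float]:
    """Closed-form stationary (u, s, d); the left unit eigenvector of T."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    u = 1.0 / (1.0 + alpha * (1.0 + beta))
    return u, alpha * u, alpha * beta * u


def random_graph_pair_distribution(p: float) -> tuple[float, float, float]:
    """Pair-state distribution of an Erdos-Renyi graph at density p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("connection probability must lie in [0, 1]")
    return (1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2


def overrepresentation_A(alpha: float, beta: float) -> float:
    """Predicted bidirectional overrepresentation d / p^2 of the pair model."""
    if alpha <= 0:
        raise ValueError("overrepresentation requires alpha > 0")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    core = alpha * beta * (1.0 + beta)
    return (beta + core) / (alpha / 4.0 + core)


def simulate_pair_chains(
    p_us: float,
    p_su: float,
    p_sd: float,
    p_ds: float,
    n_pairs: int,
    n_steps: int,
    seed=None,
) -> np.ndarray:
    """Simulate independent pair chains; returns states (n_steps+1, n_pairs).

    Used as the consistency oracle: transition estimates recovered from
    the simulated states converge to the inputs, and the long-run state
    occupancy converges to the closed-form stationary distribution.
    """
    T = transition_matrix(p_us, p_su, p_sd, p_ds)
    cum = T.cumsum(axis=1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.zeros((n_steps + 1, n_pairs), dtype=np.int8)
    for t in range(n_steps):
        u = rng.uniform(size=n_pairs)
        row = cum[states[t]]
        states[t + 1] = (u[:, None] > row).sum(axis=1)
    return states
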