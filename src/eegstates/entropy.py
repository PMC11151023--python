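"""Entropy production of brain-state switching.

A subject's state sequence is collapsed to its visit sequence (consecutive
identical labels merge; continuity breaks are never bridged) and reduced to
a table of off-diagonal transition counts ``N_ij``.  With the +1 increment
``N''_ij = N_ij + 1`` (avoiding singularities) and joint probabilities
``P_ij = N''_ij / Σ N''`` over ordered off-diagonal pairs, entropy
production is the KL divergence between forward and time-reversed joint
transition laws::

    H = Σ_{i≠j} P_ij · log2(P_ij / P_ji)    [bits]

The estimator is biased upward at finite trajectory length, so each subject
gets a surrogate-based correction: 1000 Markov chains of the same length
are simulated from the subject's own (incremented, row-normalized)
transition table and the same number again from its symmetrized table; the
mean symmetric-table entropy — the finite-length noise floor — is
subtracted from every asymmetric-table value.  The mean and variance of the
corrected distribution are the subject's entropy-production estimate and
its variance.  Because observed and surrogate tables pass through the
identical counting-and-increment estimator, the floor subtraction also
cancels the effect of the increment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .phase_dynamics import StateSequence, _runs

try:  # optional fast path for surrogate chain walks
    from numba import njit

    @njit(cache=False)
    def _walk_chains(cum, state0, u, counts):  # pragma: no cover - jitted
        n_steps, n_chains = u.shape
        for j in range(n_chains):
            s = state0[j]
            for i in range(n_steps):
                uu = u[i, j]
                row = cum[s]
                t = 0
                while row[t] < uu:
                    t += 1
                counts[j, s, t] += 1
                s = t

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "TransitionTable",
    "EntropyEstimate",
    "count_transitions",
    "table_from_counts",
    "entropy_production",
    "log_ratio_matrix",
    "pair_contribution_matrix",
    "simulate_surrogates",
    "noise_floor",
    "subject_entropy",
    "EntropyProduction",
]


@dataclass(frozen=True)
class TransitionTable:
    """Off-diagonal transition counts and the derived joint probabilities."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if np.any(c < 0) or np.any(c != np.round(c)):
            raise ValueError("counts must be non-negative integers")
        if np.any(np.diag(c) != 0):
            raise ValueError("diagonal must be zero (self-transitions removed)")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    @property
    def incremented(self) -> np.ndarray:
        """``N''_ij = N_ij + 1`` on off-diagonal cells (diagonal stays unused)."""
        inc = self.counts + 1
        np.fill_diagonal(inc, 0)
        return inc

    @property
    def joint_probs(self) -> np.ndarray:
        """``P_ij`` over ordered off-diagonal pairs; sums to 1, all positive."""
        inc = self.incremented.astype(float)
        return inc / inc.sum()

    @property
    def conditional(self) -> np.ndarray:
        """Row-stochastic chain ``Q_ij`` derived from the incremented table."""
        inc = self.incremented.astype(float)
        return inc / inc.sum(axis=1, keepdims=True)

    def symmetrized(self) -> np.ndarray:
        """Detailed-balance reference: ``(N'' + N''ᵀ) / 2``."""
        inc = self.incremented.astype(float)
        return (inc + inc.T) / 2.0


def count_transitions(seq: StateSequence) -> TransitionTable:
    """Count visit-to-visit transitions, never across continuity breaks."""
    visit_labels, _ = _runs(seq)  # raises on empty input
    K = seq.K
    counts = np.zeros((K, K), dtype=np.int64)
    # visits are maximal runs; a transition exists between consecutive runs
    # of the same segment
    change = np.diff(seq.labels) != 0
    seg_change = np.diff(seq.segment_id) != 0
    idx = np.flatnonzero(change & ~seg_change)
    np.add.at(counts, (seq.labels[idx] - 1, seq.labels[idx + 1] - 1), 1)
    return TransitionTable(counts=counts)


def table_from_counts(counts: np.ndarray) -> TransitionTable:
    return TransitionTable(counts=np.asarray(counts))


def entropy_production(table: TransitionTable) -> float:
    """Eq. ``H = Σ P_ij log2(P_ij / P_ji)`` over ordered off-diagonal pairs."""
    P = table.joint_probs
    off = ~np.eye(table.K, dtype=bool)
    return float(np.sum(P[off] * np.log2(P[off] / P.T[off])))


def log_ratio_matrix(table: TransitionTable) -> np.ndarray:
    """Signed log-ratio of forward vs reverse transition probability.

    ``L_ij = log2(P_ij / P_ji)``; antisymmetric, zero diagonal.  This is the
    per-pair directionality preference the irreversibility matrices display.
    """
    P = table.joint_probs
    off = ~np.eye(table.K, dtype=bool)
    L = np.zeros_like(P)
    L[off] = np.log2(P[off] / P.T[off])
    return L


def pair_contribution_matrix(table: TransitionTable) -> np.ndarray:
    """Symmetric per-pair contribution to total entropy production.

    ``C_ij = P_ij log2(P_ij/P_ji) + P_ji log2(P_ji/P_ij)``; each unordered
    pair's additive share of H (non-negative, sums to H over i<j).
    """
    P = table.joint_probs
    off = ~np.eye(table.K, dtype=bool)
    term = np.zeros_like(P)
    term[off] = P[off] * np.log2(P[off] / P.T[off])
    return term + term.T


def _simulate_chain_tables(
    Q: np.ndarray,
    length: int,
    n_chains: int,
    init_probs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Transition-count tables of ``n_chains`` Markov walks of ``length`` steps.

    Vectorized across chains; returns (n_chains, K, K) raw counts.
    """
    K = Q.shape[0]
    cum = np.cumsum(Q, axis=1)
    cum[:, -1] = 1.0 + 1e-12  # guard against round-off in the last column
    state0 = rng.choice(K, size=n_chains, p=init_probs)
    u = rng.random((length, n_chains))
    counts = np.zeros((n_chains, K, K), dtype=np.int64)
    if _HAVE_NUMBA:
        _walk_chains(cum, state0, u, counts)
        return counts
    states = np.empty((length + 1, n_chains), dtype=np.int64)
    states[0] = state0
    for step in range(length):
        states[step + 1] = (cum[states[step]] < u[step][:, None]).sum(axis=1)
    # one bincount over (chain, from, to) codes instead of a per-step add
    chain_idx = np.broadcast_to(np.arange(n_chains), (length, n_chains))
    codes = (chain_idx * K + states[:-1]) * K + states[1:]
    flat = np.bincount(codes.ravel(), minlength=n_chains * K * K)
    return flat.reshape(n_chains, K, K)


def _visit_init_probs(table: TransitionTable) -> np.ndarray:
    """Empirical visit frequencies (uniform fallback for an empty table)."""
    visits = table.counts.sum(axis=1).astype(float)
    if visits.sum() == 0:
        return np.full(table.K, 1.0 / table.K)
    return visits / visits.sum()


def simulate_surrogates(
    table: TransitionTable,
    length: int,
    n_surrogates: int = 1000,
    seed: int = 0,
) -> list[TransitionTable]:
    """Surrogate tables from the subject's own (incremented) chain.

    Each surrogate is a realization of the row-conditional chain derived
    from ``N''`` with exactly ``length`` transitions, started from the
    empirical visit frequencies, and counted by the same estimator as the
    observed data.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    counts = _simulate_chain_tables(
        table.conditional, length, n_surrogates, _visit_init_probs(table), rng
    )
    return [TransitionTable(counts=c) for c in counts]


def noise_floor(
    table: TransitionTable,
    length: int,
    n_surrogates: int = 1000,
    seed: int = 0,
) -> float:
    """Mean surrogate entropy of the symmetrized (detailed-balance) table.

    A perfectly symmetric chain produces zero entropy in the infinite-length
    limit; at finite length the estimator is inflated, and this mean is
    exactly that inflation.
    """
    S = table.symmetrized()
    Q = S / S.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    counts = _simulate_chain_tables(Q, length, n_surrogates, _visit_init_probs(table), rng)
    values = [entropy_production(TransitionTable(counts=c)) for c in counts]
    return float(np.mean(values))


@dataclass(frozen=True)
class EntropyEstimate:
    """Per-subject corrected entropy production.

    ``corrected_H = surrogate_H − noise_floor_mean`` elementwise; individual
    corrected values may be negative (clipping would bias the mean upward).
    """

    H_raw: float
    surrogate_H: np.ndarray
    noise_floor_mean: float
    H_mean: float
    H_var: float
    n_transitions: int

    @property
    def corrected_H(self) -> np.ndarray:
        return self.surrogate_H - self.noise_floor_mean


class EntropyProduction(BaseEstimator):
    """Estimator for a subject's noise-floor-corrected entropy production.

    Parameters
    ----------
    n_surrogates : int, default=1000
        Markov surrogates per subject (same count for the asymmetric and
        the symmetrized table).
    random_state : int, default=0

    Attributes (after :meth:`fit`)
    ------------------------------
    table_ : TransitionTable
    H_raw_ : float
        Uncorrected entropy of the observed table, bits.
    surrogate_H_ : ndarray
        Entropies of the asymmetric-table surrogates.
    noise_floor_ : float
    H_mean_, H_var_ : float
        Mean and variance of the corrected distribution.
    """

    def __init__(self, n_surrogates: int = 1000, random_state: int = 0):
        self.n_surrogates = n_surrogates
        self.random_state = random_state

    def fit(self, seq: StateSequence, y=None):
        table = count_transitions(seq)
        length = table.n_transitions
        if length < 2:
            raise ValueError("need at least 2 observed transitions")
        rng_seed = int(self.random_state)
        surr = simulate_surrogates(table, length, self.n_surrogates, seed=rng_seed)
        h = np.array([entropy_production(t) for t in surr])
        floor = noise_floor(table, length, self.n_surrogates, seed=rng_seed + 1)
        corrected = h - floor
        self.table_ = table
        self.H_raw_ = entropy_production(table)
        self.surrogate_H_ = h
        self.noise_floor_ = floor
        self.H_mean_ = float(corrected.mean())
        self.H_var_ = float(corrected.var(ddof=1))
        return self

    def estimate(self) -> EntropyEstimate:
        return EntropyEstimate(
            H_raw=self.H_raw_,
            surrogate_H=self.surrogate_H_,
            noise_floor_mean=self.noise_floor_,
            H_mean=self.H_mean_,
            H_var=self.H_var_,
            n_transitions=self.table_.n_transitions,
        )


def subject_entropy(
    seq: StateSequence, n_surrogates: int = 1000, seed: int = 0
) -> EntropyEstimate:
    """Functional wrapper over :class:`EntropyProduction`."""
    est = EntropyProduction(n_surrogates=n_surrogates, random_state=seed).fit(seq)
    return est.estimate()
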