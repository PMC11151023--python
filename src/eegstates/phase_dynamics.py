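"""Leading-eigenvector dynamics: phases, eigenvectors, patching, clustering.

The instantaneous phase-coherence matrix at time ``t`` is
``M[x, y] = cos(φ_x(t) − φ_y(t))``; its leading eigenvector summarizes the
momentary topography of relative phases.  Because the matrix equals
``c cᵀ + s sᵀ`` with ``c = cos φ(t)`` and ``s = sin φ(t)``, it has rank 2
and the leading eigenvector is computed from a 2×2 problem, vectorized over
all timepoints.

Brain states are obtained by pooling the eigenvectors of all subjects and
clustering them with a polarity-invariant k-means
(:class:`PolarityInvariantKMeans`): the distance between a vector ``v`` and
a centroid ``c`` is ``1 − |v·c|``, and the centroid update is the dominant
eigenvector of the assigned vectors' scatter matrix, so a topography and
its sign flip belong to the same state — the same convention used for EEG
microstate segmentation.

Bad channels are "patched" in two steps before the final clustering: a
plain k-means over the good-channel eigenvectors stratifies the timepoints
into dynamical clusters, and each missing phase value is filled by sampling
a donor phase from other subjects of the same group, at the same electrode,
within the same cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

from .preprocess import contiguous_segments
from .recording import EEGRecording
from scipy.signal import hilbert

__all__ = [
    "PhaseArray",
    "EigenvectorSequence",
    "BrainStateModel",
    "StateSequence",
    "hilbert_phase",
    "phase_coherence_matrix",
    "leading_eigenvector",
    "leading_eigenvectors_from_phases",
    "cluster_for_patching",
    "patch_bad_channels",
    "PolarityInvariantKMeans",
    "fit_brain_states",
    "assign_states",
    "state_duration_stats",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# containers


@dataclass
class PhaseArray:
    """Instantaneous phases on retained, edge-trimmed timepoints.

    ``phases`` is channels × timepoints, wrapped to (−π, π]; ``segment_id``
    marks recording continuity (phases with different ids come from
    different contiguous stretches and must never be bridged).
    """

    phases: np.ndarray
    fs: float
    segment_id: np.ndarray
    subject_id: str = ""
    bad_channels: set[int] = field(default_factory=set)
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.segment_id = np.asarray(self.segment_id, dtype=int)
        if self.phases.ndim != 2:
            raise ValueError("phases must be channels x timepoints")
        if self.segment_id.shape != (self.phases.shape[1],):
            raise ValueError("segment_id length mismatch")


@dataclass
class EigenvectorSequence:
    """Per-timepoint unit leading eigenvectors (timepoints × channels)."""

    vectors: np.ndarray
    segment_id: np.ndarray
    fs: float = 100.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.segment_id = np.asarray(self.segment_id, dtype=int)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be timepoints x channels")
        if self.segment_id.shape != (self.vectors.shape[0],):
            raise ValueError("segment_id length mismatch")


@dataclass
class BrainStateModel:
    """K polarity-invariant centroid topographies, ranked by dominance.

    Row 0 of ``centroids`` is the most dominant state (state 1); dominance
    is the share of pooled timepoints assigned to each state, in percent.
    """

    centroids: np.ndarray
    dominance_pct: np.ndarray
    K: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.dominance_pct = np.asarray(self.dominance_pct, dtype=float)
        if self.centroids.shape[0] != self.K:
            raise ValueError("centroids must have K rows")
        if abs(self.dominance_pct.sum() - 100.0) > 0.01:
            raise ValueError("dominance percentages must sum to 100")
        if np.any(np.diff(self.dominance_pct) > 1e-9):
            raise ValueError("states must be ordered by descending dominance")


@dataclass
class StateSequence:
    """Dominance-ranked state labels (1..K) on retained timepoints."""

    labels: np.ndarray
    segment_id: np.ndarray
    K: int
    fs: float = 100.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.segment_id = np.asarray(self.segment_id, dtype=int)
        if self.labels.shape != self.segment_id.shape:
            raise ValueError("labels/segment_id length mismatch")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.K):
            raise ValueError("labels must lie in 1..K")


# --------------------------------------------------------------------------
# phases and eigenvectors


def hilbert_phase(rec: EEGRecording, edge_seconds: float = 1.0) -> PhaseArray:
    """Analytic-signal phase on each contiguous retained stretch.

    The first and last ``edge_seconds`` of every stretch are dropped
    (filter and Hilbert edge transients); the output carries only the
    surviving timepoints, with a segment id per stretch.
    """
    segs = contiguous_segments(rec.epoch_mask)
    if not segs:
        raise ValueError("recording has no retained samples")
    edge = int(round(edge_seconds * rec.fs))
    phase_parts, seg_ids, label_parts = [], [], []
    true_labels = rec.meta.get("true_labels")
    for sid, (start, stop) in enumerate(segs):
        if stop - start <= 2 * edge:
            continue
        analytic = hilbert(rec.data[:, start:stop], axis=1)
        ph = np.angle(analytic)[:, edge : stop - start - edge]
        phase_parts.append(ph)
        seg_ids.append(np.full(ph.shape[1], sid, dtype=int))
        if true_labels is not None:
            label_parts.append(
                np.asarray(true_labels)[start + edge : stop - edge]
            )
    if not phase_parts:
        raise ValueError("all retained segments shorter than the edge margin")
    return PhaseArray(
        phases=np.concatenate(phase_parts, axis=1),
        fs=rec.fs,
        segment_id=np.concatenate(seg_ids),
        subject_id=getattr(rec.meta.get("subject"), "subject_id", ""),
        bad_channels=set(rec.bad_channels),
        true_labels=np.concatenate(label_parts) if label_parts else None,
    )


def phase_coherence_matrix(phases_t: np.ndarray) -> np.ndarray:
    """Instantaneous phase-coherence matrix ``M[x, y] = cos(φ_x − φ_y)``."""
    phi = np.asarray(phases_t, dtype=float)
    if phi.ndim != 1:
        raise ValueError("phases_t must be a 1-D phase vector")
    if not np.all(np.isfinite(phi)):
        raise ValueError("phases must be finite")
    return np.cos(phi[:, None] - phi[None, :])


def _canonical_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip each vector so the mean of its elements is <= 0."""
    vectors = np.atleast_2d(vectors)
    flip = vectors.mean(axis=1) > 0
    out = vectors.copy()
    out[flip] *= -1.0
    return out


def leading_eigenvector(M: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the algebraically largest eigenvalue of ``M``.

    Sign is canonicalized (element mean <= 0), which is irrelevant to the
    polarity-invariant clustering but makes serialization reproducible.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("M must be symmetric")
    vals, vecs = np.linalg.eigh(M)
    v = vecs[:, -1]
    return _canonical_sign(v)[0]


def leading_eigenvectors_from_phases(phase: PhaseArray) -> EigenvectorSequence:
    """Leading eigenvectors of all per-timepoint coherence matrices at once.

    Exploits the rank-2 structure ``M_t = c_t c_tᵀ + s_t s_tᵀ``: in the
    (c, s) basis the operator is the 2×2 Gram matrix, whose top eigenpair
    is available in closed form.
    """
    C = np.cos(phase.phases)  # n x T
    S = np.sin(phase.phases)
    a = np.einsum("ct,ct->t", C, C)
    b = np.einsum("ct,ct->t", C, S)
    d = np.einsum("ct,ct->t", S, S)
    disc = np.sqrt((a - d) ** 2 + 4 * b**2)
    lam = (a + d + disc) / 2.0
    # eigenvector of [[a, b], [b, d]] for eigenvalue lam; pick the better-
    # conditioned of the two equivalent forms componentwise
    use_first = np.abs(lam - a) <= np.abs(lam - d)
    y0 = np.where(use_first, b, lam - d)
    y1 = np.where(use_first, lam - a, b)
    norm = np.hypot(y0, y1)
    degenerate = norm < 1e-12  # all phases equal: b = 0, a = lam
    y0 = np.where(degenerate, 1.0, y0 / np.where(degenerate, 1.0, norm))
    y1 = np.where(degenerate, 0.0, y1 / np.where(degenerate, 1.0, norm))
    V = (C * y0[None, :] + S * y1[None, :]).T  # T x n
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    return EigenvectorSequence(
        vectors=_canonical_sign(V),
        segment_id=phase.segment_id.copy(),
        fs=phase.fs,
        subject_id=phase.subject_id,
    )


# --------------------------------------------------------------------------
# patching


def cluster_for_patching(
    good_eigs: np.ndarray, k: int, seed: int = 0, n_init: int = 5
) -> tuple[np.ndarray, KMeans]:
    """Step-1 stratification: plain k-means over good-channel eigenvectors.

    Standard (not polarity-invariant) k-means, pooled over the group;
    deterministic given ``seed``.
    """
    X = check_array(np.asarray(good_eigs, dtype=float))
    if X.shape[0] < k:
        raise ValueError("fewer vectors than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km


def patch_bad_channels(
    group_phases: list[PhaseArray],
    patch_labels: list[np.ndarray],
    seed: int = 0,
) -> list[PhaseArray]:
    """Fill bad-channel phases from same-group donors, stratified by cluster.

    A missing value of electrode ``x`` at a timepoint in cluster ``ℓ`` is
    replaced by a phase sampled from other subjects of the group, at the
    same electrode, among their timepoints assigned to ``ℓ``.  Fallbacks
    (logged): the subject's own same-cluster values at ``x`` if no other
    subject has ``x`` good; the nearest good electrode's same-cluster
    ensemble if ``x`` is bad everywhere.  Good-channel values are never
    altered.
    """
    if len(group_phases) != len(patch_labels):
        raise ValueError("one label array per subject required")
    rng = np.random.default_rng(seed)
    n_ch = group_phases[0].phases.shape[0]
    patched: list[PhaseArray] = []
    for s, pa in enumerate(group_phases):
        out = pa.phases.copy()
        labels_s = np.asarray(patch_labels[s])
        if labels_s.shape != (pa.phases.shape[1],):
            raise ValueError("patch labels misaligned with phases")
        for x in sorted(pa.bad_channels):
            for lab in np.unique(labels_s):
                t_idx = np.flatnonzero(labels_s == lab)
                pool = [
                    gp.phases[x, np.asarray(patch_labels[o]) == lab]
                    for o, gp in enumerate(group_phases)
                    if o != s and x not in gp.bad_channels
                ]
                pool = (
                    np.concatenate([p for p in pool if p.size]) if pool else np.array([])
                )
                if pool.size == 0:
                    logger.warning(
                        "no donor for subject %s electrode %d cluster %d; "
                        "falling back to nearest good electrode",
                        pa.subject_id,
                        x,
                        lab,
                    )
                    own_good = [c for c in range(n_ch) if c not in pa.bad_channels]
                    if not own_good:
                        raise ValueError("subject has no good channels to patch from")
                    nearest = min(own_good, key=lambda c: abs(c - x))
                    pool = pa.phases[nearest, t_idx]
                out[x, t_idx] = rng.choice(pool, size=t_idx.size, replace=True)
        patched.append(
            PhaseArray(
                phases=out,
                fs=pa.fs,
                segment_id=pa.segment_id.copy(),
                subject_id=pa.subject_id,
                bad_channels=set(),
                true_labels=None if pa.true_labels is None else pa.true_labels.copy(),
            )
        )
    return patched


# --------------------------------------------------------------------------
# polarity-invariant k-means


class PolarityInvariantKMeans(ClusterMixin, BaseEstimator):
    """K-means under the polarity-invariant metric ``d(v, c) = 1 − |v·c|``.

    Designed for unit-norm leading eigenvectors, where a pattern and its
    negation describe the same phase topography.  The centroid of a cluster
    is the dominant eigenvector of the scatter matrix of its members (the
    polarity-invariant mean direction).  Initialization is k-means++-style
    under the same metric; the best of ``n_init`` restarts by total
    within-cluster distance is kept.

    Parameters
    ----------
    n_clusters : int, default=12
        Number of brain states.
    n_init : int, default=20
        Independent restarts.
    max_iter : int, default=500
        Iteration cap per restart; convergence is reached when the
        assignment no longer changes.
    random_state : int or RandomState, optional

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
        Unit-norm centroids, sign-canonicalized.
    labels_ : ndarray of shape (n_samples,)
        0-based cluster index of the training vectors.
    inertia_ : float
        Total within-cluster ``1 − |v·c|``.
    n_iter_ : int
        Iterations used by the best restart.
    """

    def __init__(
        self,
        n_clusters: int = 12,
        n_init: int = 20,
        max_iter: int = 500,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _normalize_rows(X: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        if np.any(norms < 1e-12):
            raise ValueError("input vectors must be non-zero")
        return X / norms

    def _init_centroids(self, X: np.ndarray, rng: np.random.RandomState) -> np.ndarray:
        n = X.shape[0]
        centers = np.empty((self.n_clusters, X.shape[1]))
        centers[0] = X[rng.randint(n)]
        d = 1.0 - np.abs(X @ centers[0])
        for k in range(1, self.n_clusters):
            probs = np.clip(d, 0.0, None)
            total = probs.sum()
            if total <= 0:
                centers[k] = X[rng.randint(n)]
            else:
                centers[k] = X[rng.choice(n, p=probs / total)]
            d = np.minimum(d, 1.0 - np.abs(X @ centers[k]))
        return centers

    @staticmethod
    def _update_centroid(members: np.ndarray) -> np.ndarray:
        scatter = members.T @ members
        vals, vecs = np.linalg.eigh(scatter)
        v = vecs[:, -1]
        return v / np.linalg.norm(v)

    def _single_run(
        self, X: np.ndarray, rng: np.random.RandomState
    ) -> tuple[np.ndarray, np.ndarray, float, int]:
        centers = self._init_centroids(X, rng)
        labels = np.full(X.shape[0], -1, dtype=int)
        for it in range(1, self.max_iter + 1):
            sim = np.abs(X @ centers.T)
            new_labels = np.argmax(sim, axis=1)
            # re-seed empty clusters from the worst-fitted vector
            for k in range(self.n_clusters):
                if not np.any(new_labels == k):
                    worst = int(np.argmin(sim[np.arange(len(new_labels)), new_labels]))
                    centers[k] = X[worst]
                    new_labels[worst] = k
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for k in range(self.n_clusters):
                centers[k] = self._update_centroid(X[labels == k])
        else:
            logger.warning("polarity-invariant k-means did not converge; best iterate kept")
            it = self.max_iter
        sim = np.abs(X @ centers.T)
        labels = np.argmax(sim, axis=1)
        inertia = float(np.sum(1.0 - sim[np.arange(len(labels)), labels]))
        return centers, labels, inertia, it

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        X = check_array(np.asarray(X, dtype=float))
        if X.shape[0] < self.n_clusters:
            raise ValueError("fewer vectors than clusters")
        X = self._normalize_rows(X)
        rng = check_random_state(self.random_state)
        best = None
        for _ in range(self.n_init):
            centers, labels, inertia, it = self._single_run(X, rng)
            if best is None or inertia < best[2]:
                best = (centers, labels, inertia, it)
        centers, labels, inertia, it = best
        self.cluster_centers_ = _canonical_sign(centers)
        self.labels_ = labels
        self.inertia_ = inertia
        self.n_iter_ = it
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = check_array(np.asarray(X, dtype=float))
        X = self._normalize_rows(X)
        return np.argmax(np.abs(X @ self.cluster_centers_.T), axis=1)

    def transform(self, X):
        """Polarity-invariant distances ``1 − |v·c|`` to every centroid."""
        check_is_fitted(self, "cluster_centers_")
        X = check_array(np.asarray(X, dtype=float))
        X = self._normalize_rows(X)
        return 1.0 - np.abs(X @ self.cluster_centers_.T)


# --------------------------------------------------------------------------
# brain-state model, assignment, dwell statistics


def fit_brain_states(
    eigs: list[EigenvectorSequence] | np.ndarray,
    K: int = 12,
    seed: int = 0,
    n_restarts: int = 20,
) -> tuple[BrainStateModel, PolarityInvariantKMeans]:
    """Pool eigenvectors over subjects and fit the dominance-ranked model."""
    if isinstance(eigs, np.ndarray):
        X = eigs
    else:
        X = np.concatenate([e.vectors for e in eigs], axis=0)
    km = PolarityInvariantKMeans(
        n_clusters=K, n_init=n_restarts, random_state=seed
    ).fit(X)
    counts = np.bincount(km.labels_, minlength=K).astype(float)
    dominance = 100.0 * counts / counts.sum()
    order = np.argsort(-dominance, kind="stable")
    model = BrainStateModel(
        centroids=km.cluster_centers_[order],
        dominance_pct=dominance[order],
        K=K,
        seed=seed,
    )
    return model, km


def assign_states(eigs: EigenvectorSequence, model: BrainStateModel) -> StateSequence:
    """Label each eigenvector with its nearest state (1 = most dominant).

    Distance is ``1 − |v·c|``; exact ties break toward the lower (more
    dominant) rank index.
    """
    if eigs.vectors.shape[1] != model.centroids.shape[1]:
        raise ValueError("dimension mismatch between vectors and model")
    sim = np.abs(eigs.vectors @ model.centroids.T)
    labels = np.argmax(sim, axis=1) + 1  # argmax takes the first maximum: low rank
    return StateSequence(
        labels=labels,
        segment_id=eigs.segment_id.copy(),
        K=model.K,
        fs=eigs.fs,
        subject_id=eigs.subject_id,
    )


def _runs(seq: StateSequence) -> tuple[np.ndarray, np.ndarray]:
    """(label, length) of maximal runs, never spanning segment boundaries."""
    if seq.labels.size == 0:
        raise ValueError("empty state sequence")
    change = (np.diff(seq.labels) != 0) | (np.diff(seq.segment_id) != 0)
    starts = np.r_[0, np.flatnonzero(change) + 1]
    ends = np.r_[np.flatnonzero(change) + 1, seq.labels.size]
    return seq.labels[starts], (ends - starts)


def state_duration_stats(seq: StateSequence) -> dict:
    """Dwell-time and dominance summary.

    Dwell = run length × sampling interval, reported in ms; runs never
    bridge continuity breaks.  Dominance is each state's share of retained
    samples, in percent.
    """
    labels, lengths = _runs(seq)
    ms = lengths * 1000.0 / seq.fs
    counts = np.bincount(seq.labels, minlength=seq.K + 1)[1:].astype(float)
    return {
        "mean_dwell_ms": float(ms.mean()),
        "sd_dwell_ms": float(ms.std(ddof=1)) if ms.size > 1 else 0.0,
        "range_dwell_ms": (float(ms.min()), float(ms.max())),
        "n_visits": int(lengths.size),
        "dominance_pct": 100.0 * counts / counts.sum(),
    }
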