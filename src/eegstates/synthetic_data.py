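"""Synthetic EEG with planted brain-state dynamics.

Every downstream stage of the pipeline is validated against recordings
generated here, because the ground truth is known exactly:

* **Topographies** — each brain state is a unit vector over channels whose
  positive and negative supports form two spatially contiguous electrode
  subsets (the phase-opposition geometry the leading-eigenvector analysis
  extracts from real alpha-band EEG).  Magnitudes are equal (±1/√n): the
  leading eigenvector of a cosine phase-difference matrix recovers the
  *sign pattern* of relative phases, so an equal-magnitude topography is
  exactly the pattern the method can recover.
* **Switching process** — a first-order Markov chain over states with zero
  diagonal and a tunable violation of detailed balance, whose analytic
  entropy production (bits per transition) is available in closed form.
* **Signal model** — each channel carries an alpha-band (default 10 Hz)
  cosine whose phase is offset by π on the negative subset of the active
  state, plus white Gaussian noise; "bad" channels carry pure noise.

The generator is fully deterministic given its seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import Delaunay

from .io import write_cohort_csv, write_edf, write_sidecar
from .recording import EEGRecording, SubjectSpec, default_channel_labels

__all__ = [
    "StateTopography",
    "MarkovGroundTruth",
    "default_adjacency",
    "make_state_topographies",
    "make_ground_truth",
    "ground_truth_with_entropy",
    "joint_entropy_production",
    "stationary_distribution",
    "sample_state_path",
    "sample_path_for_duration",
    "synthesize_recording",
    "make_cohort",
    "simulate_cohort_to_dir",
]


# --------------------------------------------------------------------------
# topographies


@dataclass(frozen=True)
class StateTopography:
    """A brain-state topography: unit weights with two opposed contiguous subsets."""

    weights: np.ndarray
    subset_A: tuple[int, ...]
    subset_B: tuple[int, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(np.linalg.norm(w) - 1.0) > 1e-9:
            raise ValueError("weights must be unit norm")
        if set(self.subset_A) & set(self.subset_B):
            raise ValueError("subsets must be disjoint")
        if np.any(w[list(self.subset_A)] <= 0) or np.any(w[list(self.subset_B)] >= 0):
            raise ValueError("subset_A must be positive, subset_B negative")


def default_adjacency(n_channels: int) -> nx.Graph:
    """Channel neighbourhood graph.

    A ring for small montages; for larger ones (e.g. a 128-channel geodesic
    net) a triangulated spherical-cap layout: channels are spread over a cap
    with a Fibonacci lattice, projected to the plane and Delaunay-triangulated.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    if n_channels <= 16:
        g = nx.cycle_graph(n_channels)
        return g
    golden = (1 + 5**0.5) / 2
    idx = np.arange(n_channels)
    theta_max = math.radians(70.0)
    # equal-area spacing in cos(theta) over the cap
    cos_t = 1 - (1 - math.cos(theta_max)) * (idx + 0.5) / n_channels
    theta = np.arccos(cos_t)
    phi = 2 * np.pi * idx / golden
    x = np.sin(theta) * np.cos(phi)
    y = np.sin(theta) * np.sin(phi)
    tri = Delaunay(np.c_[x, y])
    g = nx.Graph()
    g.add_nodes_from(range(n_channels))
    for simplex in tri.simplices:
        a, b, c = (int(v) for v in simplex)
        g.add_edges_from([(a, b), (b, c), (a, c)])
    return g


def _grow_partition(
    graph: nx.Graph, seed_a: int, seed_b: int, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Bipartition all nodes into two connected cells by simultaneous BFS."""
    assign = {seed_a: 0, seed_b: 1}
    frontier = [seed_a, seed_b]
    while frontier:
        nxt: list[int] = []
        order = rng.permutation(len(frontier))
        for k in order:
            node = frontier[k]
            for nb in graph.neighbors(node):
                if nb not in assign:
                    assign[nb] = assign[node]
                    nxt.append(nb)
        frontier = nxt
    cell_a = [v for v, c in assign.items() if c == 0]
    cell_b = [v for v, c in assign.items() if c == 1]
    return sorted(cell_a), sorted(cell_b)


def make_state_topographies(
    n_channels: int,
    K: int,
    adjacency: nx.Graph | None = None,
    seed: int = 0,
    max_cosine: float = 0.8,
    max_attempts: int = 500,
) -> list[StateTopography]:
    """Draw ``K`` pairwise-distinct two-subset topographies.

    Distinctness means pairwise absolute cosine similarity below
    ``max_cosine``.  Raises ``RuntimeError`` if the request cannot be
    satisfied within ``max_attempts`` candidate partitions (over-constrained
    combination of ``K``, montage size and adjacency).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if n_channels < 4:
        raise ValueError("n_channels must be >= 4")
    graph = default_adjacency(n_channels) if adjacency is None else adjacency
    if graph.number_of_nodes() != n_channels or not nx.is_connected(graph):
        raise ValueError("adjacency must be a connected graph on all channels")
    rng = np.random.default_rng(seed)
    unit = 1.0 / math.sqrt(n_channels)

    topos: list[StateTopography] = []
    signs: list[np.ndarray] = []
    attempts = 0
    while len(topos) < K:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not find {K} distinct topographies in {max_attempts} attempts"
            )
        a, b = rng.choice(n_channels, size=2, replace=False)
        cell_a, cell_b = _grow_partition(graph, int(a), int(b), rng)
        s = np.full(n_channels, -1.0)
        s[cell_a] = 1.0
        if all(abs(float(s @ t)) / n_channels < max_cosine for t in signs):
            w = s * unit
            topos.append(
                StateTopography(weights=w, subset_A=tuple(cell_a), subset_B=tuple(cell_b))
            )
            signs.append(s)
    return topos


# --------------------------------------------------------------------------
# Markov ground truth


@dataclass(frozen=True)
class MarkovGroundTruth:
    """Zero-diagonal row-stochastic chain with known entropy production."""

    K: int
    P_cond: np.ndarray
    pi: np.ndarray
    H_true: float

    def __post_init__(self) -> None:
        P = np.asarray(self.P_cond, dtype=float)
        if P.shape != (self.K, self.K):
            raise ValueError("P_cond must be K x K")
        if np.any(np.abs(np.diag(P)) > 0):
            raise ValueError("P_cond must have zero diagonal")
        if np.any(np.abs(P.sum(axis=1) - 1) > 1e-9):
            raise ValueError("P_cond rows must sum to 1")
        pi = np.asarray(self.pi, dtype=float)
        if np.any(np.abs(pi @ P - pi) > 1e-8):
            raise ValueError("pi must be stationary for P_cond")
        if self.H_true < -1e-12:
            raise ValueError("H_true must be non-negative")


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    P = np.asarray(P, dtype=float)
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def joint_entropy_production(P_cond: np.ndarray, pi: np.ndarray | None = None) -> float:
    """Entropy production rate of the visit chain, in bits per transition.

    KL divergence between the stationary joint law of (state, next state)
    and its time reverse: sum_ij pi_i P_ij log2(pi_i P_ij / (pi_j P_ji)).
    """
    P = np.asarray(P_cond, dtype=float)
    if pi is None:
        pi = stationary_distribution(P)
    J = pi[:, None] * P
    mask = (J > 0) & (J.T > 0)
    if np.any((J > 0) & ~(J.T > 0)):
        return float("inf")
    return float(np.sum(J[mask] * np.log2(J[mask] / J.T[mask])))


def make_ground_truth(K: int, asymmetry: float, seed: int = 0) -> MarkovGroundTruth:
    """Random zero-diagonal chain with a tunable breach of detailed balance.

    ``asymmetry = 0`` yields a reversible chain (random-walk on symmetric
    edge weights, hence detailed balance and zero entropy production).
    Increasing ``asymmetry`` multiplies the weights by ``exp(±3·asymmetry)``
    along/against a cyclic direction, driving a probability current; for a
    fixed seed the analytic entropy production is non-decreasing in it.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if not 0 <= asymmetry <= 1:
        raise ValueError("asymmetry must be in [0, 1]")
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.5, 1.5, size=(K, K))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)

    d = (np.arange(K)[None, :] - np.arange(K)[:, None]) % K
    f = np.where((d >= 1) & (d < K / 2), 1.0, np.where(d > K / 2, -1.0, 0.0))
    A = W * np.exp(3.0 * asymmetry * f)
    P = A / A.sum(axis=1, keepdims=True)
    pi = stationary_distribution(P)
    H = joint_entropy_production(P, pi)
    if asymmetry == 0:
        H = 0.0  # reversible by construction; clear numerical dust
    return MarkovGroundTruth(K=K, P_cond=P, pi=pi, H_true=H)


def ground_truth_with_entropy(
    K: int, H_target: float, seed: int = 0, tol: float = 1e-10
) -> MarkovGroundTruth:
    """Chain whose analytic entropy production equals ``H_target`` bits.

    Root-finds the asymmetry parameter of :func:`make_ground_truth`; the
    target must be reachable with asymmetry in [0, 1] for the given seed.
    """
    if H_target < 0:
        raise ValueError("H_target must be non-negative")
    if H_target == 0:
        return make_ground_truth(K, 0.0, seed)

    def h_of(a: float) -> float:
        return make_ground_truth(K, a, seed).H_true - H_target

    hi = h_of(1.0)
    if hi < 0:
        raise ValueError(f"H_target={H_target} unreachable (max {hi + H_target:.4f})")
    a_star = brentq(h_of, 0.0, 1.0, xtol=tol)
    return make_ground_truth(K, float(a_star), seed)


# --------------------------------------------------------------------------
# state paths and recordings


def _truncated_geometric_pmf(mean: float, lo: int, hi: int) -> np.ndarray:
    """pmf over run lengths {lo..hi} with ratio q^(k-lo) matching ``mean``."""
    if not lo <= mean <= hi:
        raise ValueError("requested dwell mean outside the truncation range")
    k = np.arange(lo, hi + 1, dtype=float)

    def pmf(logq: float) -> np.ndarray:
        e = (k - lo) * logq
        w = np.exp(e - e.max())  # stable for either sign of logq
        return w / w.sum()

    def m(logq: float) -> float:
        return float(k @ pmf(logq)) - mean

    if abs(m(0.0)) < 1e-12:
        logq = 0.0
    else:
        logq = brentq(m, -20.0, 20.0, xtol=1e-13)
    return pmf(logq)


def sample_state_path(
    gt: MarkovGroundTruth,
    n_transitions: int,
    dwell_mean: float = 125.0,
    dwell_range: tuple[float, float] = (50.0, 500.0),
    fs: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample label sequence realizing ``gt`` with truncated-geometric dwells.

    ``dwell_mean`` and ``dwell_range`` are in milliseconds; each visit's
    duration in samples is drawn independently, so the run-length-collapsed
    sequence is exactly a realization of ``gt.P_cond``.
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if n_transitions < 0:
        raise ValueError("n_transitions must be >= 0")
    rng = np.random.default_rng(seed)
    visits = _sample_visits(gt, n_transitions + 1, rng)
    lo = max(1, int(round(dwell_range[0] * fs / 1000.0)))
    hi = int(round(dwell_range[1] * fs / 1000.0))
    pmf = _truncated_geometric_pmf(dwell_mean * fs / 1000.0, lo, hi)
    dwells = rng.choice(np.arange(lo, hi + 1), size=visits.size, p=pmf)
    return np.repeat(visits, dwells)


def _sample_visits(
    gt: MarkovGroundTruth, n_visits: int, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(gt.P_cond, axis=1)
    visits = np.empty(n_visits, dtype=int)
    visits[0] = rng.choice(gt.K, p=gt.pi)
    u = rng.random(n_visits - 1)
    for i in range(1, n_visits):
        visits[i] = int(np.searchsorted(cum[visits[i - 1]], u[i - 1], side="right"))
    return visits


def sample_path_for_duration(
    gt: MarkovGroundTruth,
    duration: float,
    fs: float,
    dwell_mean: float = 125.0,
    dwell_range: tuple[float, float] = (50.0, 500.0),
    seed: int = 0,
) -> np.ndarray:
    """Label sequence of exactly ``duration * fs`` samples (last visit trimmed)."""
    n_samples = int(round(duration * fs))
    mean_dwell_samples = dwell_mean * fs / 1000.0
    n_tr = int(n_samples / mean_dwell_samples * 1.5) + 10
    path = sample_state_path(gt, n_tr, dwell_mean, dwell_range, fs, seed)
    while path.size < n_samples:  # pragma: no cover - generous margin above
        n_tr *= 2
        path = sample_state_path(gt, n_tr, dwell_mean, dwell_range, fs, seed)
    return path[:n_samples]


def synthesize_recording(
    topos: list[StateTopography],
    path: np.ndarray,
    carrier_freq: float = 10.0,
    fs: float = 1000.0,
    noise_sd: float = 0.5,
    spec: SubjectSpec | None = None,
    amplitude_uv: float = 20.0,
) -> EEGRecording:
    """Render a label path into a multichannel recording.

    Channel ``c`` at time ``t`` carries the carrier scaled by the magnitude
    of the active state's weight at ``c``, phase-offset by π where the
    weight is negative (equivalently: ``w_c · cos(2π f t)``), plus white
    noise of standard deviation ``noise_sd`` (in weight units).  Bad
    channels are overwritten with pure noise.  The true per-sample labels
    ride along in ``meta["true_labels"]``.
    """
    path = np.asarray(path, dtype=int)
    n_channels = topos[0].weights.size
    if spec is None:
        spec = SubjectSpec(
            subject_id="S000", CA=12.5, BA=12.5, duration=path.size / fs, fs=fs
        )
    expected = int(round(spec.duration * spec.fs))
    if path.size != expected:
        raise ValueError(f"path length {path.size} != duration*fs = {expected}")
    if not 2 * carrier_freq < fs:
        raise ValueError("fs must exceed twice the carrier frequency")

    W = np.stack([t.weights for t in topos])  # K x n
    t = np.arange(path.size) / fs
    carrier = np.cos(2 * np.pi * carrier_freq * t)
    data = W[path].T * carrier[None, :]  # n x T

    rng = np.random.default_rng(spec.seed)
    bad = sorted(
        int(c) for c in rng.choice(n_channels, size=spec.n_bad_channels, replace=False)
    )
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
        if bad:
            data[bad] = rng.normal(0.0, noise_sd, size=(len(bad), path.size))
    elif bad:
        data[bad] = 0.0

    return EEGRecording(
        data=amplitude_uv * data,
        fs=fs,
        channel_labels=default_channel_labels(n_channels),
        bad_channels=set(bad),
        meta={
            "subject": spec,
            "true_labels": path.copy(),
            "carrier_freq": carrier_freq,
            "noise_sd": noise_sd,
        },
    )


# --------------------------------------------------------------------------
# cohorts


def make_cohort(
    bin_specs: list[tuple[str, tuple[float, float], tuple[float, float], int]],
    seed: int = 0,
    duration: float = 300.0,
    fs: float = 1000.0,
    max_bad_channels: int = 12,
) -> tuple[list[SubjectSpec], pd.DataFrame]:
    """Draw subject specs for age/maturity bins.

    Each bin is ``(name, (CA_lo, CA_hi), (dBA_lo, dBA_hi), n)`` with CA in
    years and dBA = BA - CA.  CA and dBA are uniform within the bin.  Two
    bins may not overlap in both CA and BA-CA (that would make maturity
    groups ambiguous).
    """
    for i in range(len(bin_specs)):
        for j in range(i + 1, len(bin_specs)):
            _, ca_i, d_i, _ = bin_specs[i]
            _, ca_j, d_j, _ = bin_specs[j]
            ca_overlap = ca_i[0] < ca_j[1] and ca_j[0] < ca_i[1]
            d_overlap = d_i[0] < d_j[1] and d_j[0] < d_i[1]
            if ca_overlap and d_overlap:
                raise ValueError(f"bins {i} and {j} overlap in CA and BA-CA")

    from .pipeline import assign_maturity_group  # local to avoid an import cycle

    rng = np.random.default_rng(seed)
    specs: list[SubjectSpec] = []
    rows = []
    idx = 0
    for name, (ca_lo, ca_hi), (d_lo, d_hi), n in bin_specs:
        for _ in range(n):
            ca = float(rng.uniform(ca_lo, ca_hi))
            dba = float(rng.uniform(d_lo, d_hi))
            spec = SubjectSpec(
                subject_id=f"S{idx:03d}",
                CA=ca,
                BA=ca + dba,
                n_bad_channels=int(rng.integers(0, max_bad_channels + 1)),
                seed=int(rng.integers(0, 2**31 - 1)),
                duration=duration,
                fs=fs,
            )
            specs.append(spec)
            rows.append(
                {
                    "subject_id": spec.subject_id,
                    "CA": spec.CA,
                    "BA": spec.BA,
                    "group": assign_maturity_group(spec.CA, spec.BA),
                    "bin": name,
                    "n_bad_channels": spec.n_bad_channels,
                    "seed": spec.seed,
                }
            )
            idx += 1
    return specs, pd.DataFrame(rows)


def simulate_cohort_to_dir(
    bin_specs: list[tuple[str, tuple[float, float], tuple[float, float], int]],
    out_dir: str | Path,
    seed: int = 0,
    n_channels: int = 128,
    K: int = 12,
    asymmetry_by_bin: dict[str, float] | None = None,
    duration: float = 300.0,
    fs: float = 1000.0,
    noise_sd: float = 0.5,
    dwell_mean: float = 125.0,
    dwell_range: tuple[float, float] = (50.0, 500.0),
    max_bad_channels: int = 12,
) -> pd.DataFrame:
    """Write a full synthetic cohort (EDF + sidecar JSON per subject + CSV).

    All subjects share one set of planted topographies; the Markov chain may
    differ per bin (``asymmetry_by_bin``) so group differences in entropy
    production can be planted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # keep small montages viable: bad channels never exceed a quarter of them
    max_bad_channels = min(max_bad_channels, n_channels // 4)
    topos = make_state_topographies(n_channels, K, seed=seed)
    specs, table = make_cohort(
        bin_specs, seed=seed, duration=duration, fs=fs, max_bad_channels=max_bad_channels
    )
    gts = {}
    for name, *_ in bin_specs:
        a = (asymmetry_by_bin or {}).get(name, 0.3)
        gts[name] = make_ground_truth(K, a, seed=seed + 1)

    edf_paths, sidecar_paths, h_true = [], [], []
    for spec, (_, row) in zip(specs, table.iterrows()):
        gt = gts[row["bin"]]
        path = sample_path_for_duration(
            gt, duration, fs, dwell_mean, dwell_range, seed=spec.seed
        )
        rec = synthesize_recording(
            topos, path, fs=fs, noise_sd=noise_sd, spec=spec
        )
        edf = write_edf(rec, out_dir / f"{spec.subject_id}.edf")
        sidecar = write_sidecar(
            out_dir / f"{spec.subject_id}.json",
            spec,
            np.stack([t.weights for t in topos]),
            gt.P_cond,
            gt.pi,
            gt.H_true,
            path,
            sorted(rec.bad_channels),
        )
        edf_paths.append(str(edf))
        sidecar_paths.append(str(sidecar))
        h_true.append(gt.H_true)

    table = table.assign(edf_path=edf_paths, sidecar_path=sidecar_paths, H_true=h_true)
    write_cohort_csv(table, out_dir / "cohort.csv")
    return table
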