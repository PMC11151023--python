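"""LEiDA core: phases, eigenvectors, patching, polarity-invariant clustering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.optimize import linear_sum_assignment
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from eegstates.phase_dynamics import (
    BrainStateModel,
    EigenvectorSequence,
    PhaseArray,
    PolarityInvariantKMeans,
    StateSequence,
    assign_states,
    cluster_for_patching,
    fit_brain_states,
    hilbert_phase,
    leading_eigenvector,
    leading_eigenvectors_from_phases,
    patch_bad_channels,
    phase_coherence_matrix,
    state_duration_stats,
)
from eegstates.preprocess import preprocess_recording

from conftest import make_recording


def power_iteration(M, n_iter=5000):
    """Brute-force dominant-eigenvector oracle (with shift for positivity)."""
    M = M + (np.abs(M).sum() + 1.0) * np.eye(M.shape[0])
    v = np.ones(M.shape[0]) / np.sqrt(M.shape[0])
    for _ in range(n_iter):
        w = M @ v
        v = w / np.linalg.norm(w)
    return v


class TestPhaseCoherence:
    def test_equal_phases_give_all_ones(self):
        assert np.allclose(phase_coherence_matrix(np.zeros(5)), 1.0)

    def test_antiphase_pair(self):
        M = phase_coherence_matrix(np.array([0.0, np.pi]))
        assert np.allclose(M, [[1.0, -1.0], [-1.0, 1.0]], atol=1e-12)

    def test_three_phase_example(self):
        M = phase_coherence_matrix(np.array([0.0, np.pi / 3, np.pi / 2]))
        assert M[0, 1] == pytest.approx(0.5)
        assert M[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert M[1, 2] == pytest.approx(np.sqrt(3) / 2)

    @given(
        arrays(
            float,
            st.integers(2, 8),
            elements=st.floats(-np.pi, np.pi),
        )
    )
    def test_symmetry_and_unit_diagonal(self, phi):
        M = phase_coherence_matrix(phi)
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)
        assert np.all((M >= -1 - 1e-12) & (M <= 1 + 1e-12))


class TestLeadingEigenvector:
    def test_all_ones_matrix(self):
        v = leading_eigenvector(np.ones((4, 4)))
        assert np.allclose(np.abs(v), 0.5)

    def test_antiphase_matrix(self):
        v = leading_eigenvector(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        assert np.allclose(np.abs(v), 1 / np.sqrt(2))
        assert np.sign(v[0]) != np.sign(v[1])

    def test_matches_power_iteration_oracle(self, rng):
        for _ in range(200):
            A = rng.normal(size=(6, 6))
            M = (A + A.T) / 2
            v = leading_eigenvector(M)
            w = power_iteration(M)
            assert min(np.linalg.norm(v - w), np.linalg.norm(v + w)) < 1e-8

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            leading_eigenvector(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_rank2_fast_path_agrees_with_dense_solver(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(6, 40))
        pa = PhaseArray(phases=phases, fs=100.0, segment_id=np.zeros(40, dtype=int))
        fast = leading_eigenvectors_from_phases(pa).vectors
        for t in range(40):
            dense = leading_eigenvector(phase_coherence_matrix(phases[:, t]))
            assert min(
                np.linalg.norm(fast[t] - dense), np.linalg.norm(fast[t] + dense)
            ) < 1e-6


class TestHilbertPhase:
    def test_tone_phase_velocity(self):
        from eegstates.recording import EEGRecording

        t = np.arange(1000) / 100.0
        rec = EEGRecording(data=np.cos(2 * np.pi * 10 * t)[None, :], fs=100.0)
        pa = hilbert_phase(rec, edge_seconds=1.0)
        dphi = np.angle(np.exp(1j * np.diff(pa.phases[0])))
        assert np.allclose(dphi, 2 * np.pi * 10 / 100.0, atol=0.01)

    def test_antiphase_and_quadrature_differences(self):
        from eegstates.recording import EEGRecording

        t = np.arange(2000) / 100.0
        theta = 2 * np.pi * 10 * t
        rec = EEGRecording(
            data=np.stack([np.cos(theta), -np.cos(theta), np.sin(theta)]), fs=100.0
        )
        pa = hilbert_phase(rec, edge_seconds=1.0)
        d01 = np.abs(np.angle(np.exp(1j * (pa.phases[0] - pa.phases[1]))))
        d02 = np.abs(np.angle(np.exp(1j * (pa.phases[0] - pa.phases[2]))))
        assert np.allclose(d01, np.pi, atol=0.05)
        assert np.allclose(d02, np.pi / 2, atol=0.05)

    def test_segments_split_and_edges_trimmed(self):
        from eegstates.recording import EEGRecording

        mask = np.ones(3000, dtype=bool)
        mask[1000:1500] = False
        t = np.arange(3000) / 100.0
        rec = EEGRecording(
            data=np.cos(2 * np.pi * 10 * t)[None, :], fs=100.0, epoch_mask=mask
        )
        pa = hilbert_phase(rec, edge_seconds=1.0)
        # 1000-sample segment keeps 800, 1500-sample keeps 1300
        assert pa.phases.shape[1] == 800 + 1300
        assert set(np.unique(pa.segment_id)) == {0, 1}

    def test_empty_recording_rejected(self):
        from eegstates.recording import EEGRecording

        rec = EEGRecording(
            data=np.zeros((1, 100)), fs=100.0, epoch_mask=np.zeros(100, dtype=bool)
        )
        with pytest.raises(ValueError):
            hilbert_phase(rec)


class TestPatchingKMeans:
    def test_separable_clusters_recovered_exactly(self, rng):
        a = np.r_[np.ones(5), np.zeros(5)] / np.sqrt(5)
        b = np.r_[np.zeros(5), np.ones(5)] / np.sqrt(5)
        X = np.concatenate(
            [a + rng.normal(0, 0.01, (30, 10)), b + rng.normal(0, 0.01, (30, 10))]
        )
        labels, _ = cluster_for_patching(X, k=2, seed=0)
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_k1_gives_single_label(self, rng):
        labels, _ = cluster_for_patching(rng.normal(size=(20, 4)), k=1, seed=0)
        assert np.all(labels == labels[0])

    def test_fewer_vectors_than_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_for_patching(rng.normal(size=(3, 4)), k=5, seed=0)

    def test_planted_state_stratification_high_ari(self, rng):
        # eigenvector-level: 4 planted sign topographies + noise
        n = 16
        topos = np.sign(rng.normal(size=(4, n))) / np.sqrt(n)
        hidden = rng.integers(0, 4, size=400)
        X = topos[hidden] + rng.normal(0, 0.05, size=(400, n))
        labels, _ = cluster_for_patching(X, k=4, seed=1)
        assert adjusted_rand_score(hidden, labels) > 0.9


class TestPatching:
    def _phase_group(self, rng, n_subjects=5, n_ch=8, T=200, bad=()):
        # two alternating dynamical clusters with distinct per-channel phases
        cluster = np.tile([0, 1], T // 2)
        base = rng.uniform(-np.pi, np.pi, size=(2, n_ch))
        group, labels = [], []
        for s in range(n_subjects):
            phases = base[cluster].T + rng.normal(0, 0.05, size=(n_ch, T))
            group.append(
                PhaseArray(
                    phases=phases,
                    fs=100.0,
                    segment_id=np.zeros(T, dtype=int),
                    subject_id=f"S{s}",
                    bad_channels=set(bad) if s == 0 else set(),
                )
            )
            labels.append(cluster.copy())
        return group, labels, base

    def test_no_bad_channels_is_identity(self, rng):
        group, labels, _ = self._phase_group(rng)
        out = patch_bad_channels(group, labels, seed=0)
        for before, after in zip(group, out):
            assert np.array_equal(before.phases, after.phases)

    def test_single_valued_donor_pool(self):
        # donors all carry pi/4 in the relevant cluster
        T = 50
        donors = [
            PhaseArray(
                phases=np.full((2, T), np.pi / 4),
                fs=100.0,
                segment_id=np.zeros(T, dtype=int),
                subject_id=f"D{i}",
            )
            for i in range(2)
        ]
        target = PhaseArray(
            phases=np.zeros((2, T)),
            fs=100.0,
            segment_id=np.zeros(T, dtype=int),
            subject_id="T",
            bad_channels={1},
        )
        labels = [np.zeros(T, dtype=int)] * 3
        out = patch_bad_channels([target] + donors, labels, seed=0)
        assert np.allclose(out[0].phases[1], np.pi / 4)
        assert np.allclose(out[0].phases[0], 0.0)  # good channel untouched

    def test_patched_phases_match_donor_cluster_ensemble(self, rng):
        group, labels, base = self._phase_group(rng, bad=(2, 5))
        out = patch_bad_channels(group, labels, seed=3)
        for ch in (2, 5):
            for cl in (0, 1):
                idx = labels[0] == cl
                patched = out[0].phases[ch, idx]
                # all patched values near the donor ensemble's cluster phase
                d = np.angle(np.exp(1j * (patched - base[cl, ch])))
                assert np.abs(d).max() < 0.3

    def test_good_channels_never_altered(self, rng):
        group, labels, _ = self._phase_group(rng, bad=(1,))
        out = patch_bad_channels(group, labels, seed=1)
        good = [c for c in range(8) if c != 1]
        assert np.array_equal(out[0].phases[good], group[0].phases[good])


class TestPolarityInvariantKMeans:
    def test_sign_flips_do_not_split_clusters(self):
        v = np.array([1.0, 0.0, 0.0, 0.0])
        w = np.array([0.0, 1.0, 0.0, 0.0])
        X = np.stack([v, -v, w, -w])
        km = PolarityInvariantKMeans(n_clusters=2, n_init=5, random_state=0).fit(X)
        assert km.labels_[0] == km.labels_[1]
        assert km.labels_[2] == km.labels_[3]
        assert km.labels_[0] != km.labels_[2]

    def test_duplicating_with_flipped_signs_gives_same_model(self, rng):
        # separable planted clusters: both fits reach the same optimum
        topos = np.sign(rng.normal(size=(3, 12))) / np.sqrt(12)
        hidden = rng.integers(0, 3, size=90)
        X = topos[hidden] + rng.normal(0, 0.05, size=(90, 12))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        km1 = PolarityInvariantKMeans(n_clusters=3, n_init=10, random_state=1).fit(X)
        km2 = PolarityInvariantKMeans(n_clusters=3, n_init=10, random_state=1).fit(
            np.concatenate([X, -X])
        )
        sim = np.abs(km1.cluster_centers_ @ km2.cluster_centers_.T)
        r, c = linear_sum_assignment(-sim)
        assert np.all(sim[r, c] > 1 - 1e-6)
        # sign-flipped copies land in the same cluster as their originals
        assert np.array_equal(km2.labels_[:90], km2.labels_[90:])

    def test_negating_input_subset_leaves_assignments_unchanged(self, rng):
        X = rng.normal(size=(80, 10))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        km = PolarityInvariantKMeans(n_clusters=4, n_init=10, random_state=2).fit(X)
        flip = rng.random(80) < 0.5
        Y = X.copy()
        Y[flip] *= -1
        assert np.array_equal(km.predict(Y), km.predict(X))

    def test_recovers_planted_topographies(self, rng):
        n = 24
        topos = np.sign(rng.normal(size=(4, n))) / np.sqrt(n)
        hidden = rng.integers(0, 4, size=600)
        signs = np.where(rng.random(600) < 0.5, 1.0, -1.0)
        X = signs[:, None] * topos[hidden] + rng.normal(0, 0.08, size=(600, n))
        km = PolarityInvariantKMeans(n_clusters=4, n_init=10, random_state=3).fit(X)
        sim = np.abs(km.cluster_centers_ @ topos.T)
        r, c = linear_sum_assignment(-sim)
        assert np.all(sim[r, c] > 0.9)

    def test_sklearn_estimator_contract(self, rng):
        X = rng.normal(size=(30, 5))
        km = PolarityInvariantKMeans(n_clusters=3, n_init=2, random_state=0)
        cloned = clone(km)
        assert cloned.get_params() == km.get_params()
        km.fit(X)
        assert km.cluster_centers_.shape == (3, 5)
        assert np.allclose(np.linalg.norm(km.cluster_centers_, axis=1), 1.0)
        assert np.array_equal(km.predict(X), km.labels_)
        assert km.transform(X).shape == (30, 3)
        assert km.inertia_ >= 0

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 6))
        a = PolarityInvariantKMeans(n_clusters=3, n_init=5, random_state=7).fit(X)
        b = PolarityInvariantKMeans(n_clusters=3, n_init=5, random_state=7).fit(X)
        assert np.array_equal(a.labels_, b.labels_)
        assert np.allclose(a.cluster_centers_, b.cluster_centers_)


class TestAssignStates:
    def _model(self, rng, K=3, n=6):
        C = rng.normal(size=(K, n))
        C /= np.linalg.norm(C, axis=1, keepdims=True)
        dom = np.array([50.0, 30.0, 20.0])
        return BrainStateModel(centroids=C, dominance_pct=dom, K=K)

    def test_centroid_and_its_negation_get_same_label(self, rng):
        model = self._model(rng)
        for k in range(3):
            for sign in (1.0, -1.0):
                eig = EigenvectorSequence(
                    vectors=sign * model.centroids[k : k + 1],
                    segment_id=np.zeros(1, dtype=int),
                )
                assert assign_states(eig, model).labels[0] == k + 1

    def test_matches_brute_force_distance_scan(self, rng):
        model = self._model(rng)
        V = rng.normal(size=(40, 6))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        eig = EigenvectorSequence(vectors=V, segment_id=np.zeros(40, dtype=int))
        labels = assign_states(eig, model).labels
        for t in range(40):
            d = [1 - abs(V[t] @ c) for c in model.centroids]
            assert labels[t] == int(np.argmin(d)) + 1


class TestDurationStats:
    def test_single_run(self):
        seq = StateSequence(
            labels=np.ones(50, dtype=int), segment_id=np.zeros(50, dtype=int), K=2
        )
        stats = state_duration_stats(seq)
        assert stats["mean_dwell_ms"] == 500.0
        assert stats["n_visits"] == 1

    def test_alternating_labels(self):
        labels = np.tile([1, 2], 50)
        seq = StateSequence(
            labels=labels, segment_id=np.zeros(100, dtype=int), K=2
        )
        stats = state_duration_stats(seq)
        assert stats["mean_dwell_ms"] == 10.0
        assert np.allclose(stats["dominance_pct"], [50.0, 50.0])

    def test_mean_duration_convention(self, rng):
        # 1000 samples with average run 9.8 samples -> mean duration 98 ms
        runs = []
        while sum(runs) < 1000:
            runs.append(int(rng.integers(5, 15)))
        labels = np.concatenate(
            [np.full(r, 1 + i % 3) for i, r in enumerate(runs)]
        )
        seq = StateSequence(
            labels=labels, segment_id=np.zeros(labels.size, dtype=int), K=3
        )
        stats = state_duration_stats(seq)
        assert stats["mean_dwell_ms"] == pytest.approx(
            np.mean(runs) * 10.0, rel=1e-12
        )

    def test_runs_do_not_span_segment_boundaries(self):
        labels = np.array([1, 1, 1, 1])
        seg = np.array([0, 0, 1, 1])
        seq = StateSequence(labels=labels, segment_id=seg, K=1)
        assert state_duration_stats(seq)["n_visits"] == 2


class TestEndToEndRecovery:
    @pytest.mark.parametrize("K", [3, 4])
    def test_planted_topographies_and_labels_recovered(self, K):
        # dwells at/above the band-pass filter's temporal resolution so the
        # planted switching is identifiable from the filtered signal
        rec, topos, _ = make_recording(
            n_channels=32, K=K, duration=40.0, fs=500.0, noise_sd=0.3, seed=K
        )
        pa = hilbert_phase(preprocess_recording(rec))
        eig = leading_eigenvectors_from_phases(pa)
        model, _ = fit_brain_states(eig.vectors, K=K, seed=0, n_restarts=8)
        W = np.stack([t.weights for t in topos])
        sim = np.abs(model.centroids @ W.T)
        r, c = linear_sum_assignment(-sim)
        assert np.all(sim[r, c] > 0.9)
        seq = assign_states(eig, model)
        true = pa.true_labels
        conf = np.zeros((K, K))
        np.add.at(conf, (seq.labels - 1, true), 1.0)
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() / true.size > 0.85
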