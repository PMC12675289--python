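"""Population analyses: PCA, PC distance, HMM segmentation, decoding."""

import numpy as np
import pytest

from pupstate import population as pop
from pupstate import vocab
from pupstate.datatypes import TraceMatrix

from conftest import make_log


def make_traces(dff, rate=20.0):
    dff = np.atleast_2d(np.asarray(dff, float))
    t = np.arange(dff.shape[1]) / rate
    return TraceMatrix(t, dff)


def make_state_model(path, K):
    """StateModel with a fixed path (alignment/detection don't touch the HMM)."""
    path = np.asarray(path, int)
    return pop.StateModel(
        K=K,
        means=np.zeros((K, 1)),
        covars=np.ones((K, 1)),
        transmat=np.full((K, K), 1.0 / K),
        startprob=np.full(K, 1.0 / K),
        state_path=path,
        loglik_trace=np.array([0.0]),
        hmm=None,
    )


class TestFitPCA:
    def test_perfectly_correlated_pair_is_one_dimensional(self, rng):
        shared = rng.normal(size=500)
        tm = make_traces(np.vstack([shared, 2.0 * shared + 1.0]))
        pc = pop.fit_pca(tm)
        assert pc.explained[0] == pytest.approx(1.0)
        assert pc.usable

    def test_eigenvalues_sum_to_covariance_trace(self, rng):
        tm = make_traces(rng.normal(size=(12, 400)))
        pc = pop.fit_pca(tm)
        assert pc.eigenvalues.sum() == pytest.approx(np.trace(pc.covariance))
        assert pc.explained.sum() == pytest.approx(1.0)

    def test_white_noise_session_not_usable(self, rng):
        tm = make_traces(rng.normal(size=(20, 2000)))
        pc = pop.fit_pca(tm)
        assert pc.explained[:2].sum() < 0.3
        assert not pc.usable

    def test_full_projection_preserves_distances(self, rng):
        tm = make_traces(rng.normal(size=(6, 300)))
        pc = pop.fit_pca(tm)
        Z = pc.standardize(tm.dff.T)
        P = pc.project(tm.dff.T)
        # orthonormal basis: pairwise distances survive the rotation
        for _ in range(10):
            i, j = rng.integers(0, 300, size=2)
            assert np.linalg.norm(Z[i] - Z[j]) == pytest.approx(
                np.linalg.norm(P[i] - P[j]), abs=1e-8
            )

    def test_zero_variance_neuron_dropped_with_warning(self, rng):
        tm = make_traces(np.vstack([np.ones(100), rng.normal(size=(3, 100))]))
        with pytest.warns(UserWarning, match="zero-variance"):
            pc = pop.fit_pca(tm)
        assert len(pc.neuron_ids) == 3

    def test_n_components_for_target(self):
        pc = pop.PCModel(
            mu=np.zeros(3),
            sigma=np.ones(3),
            covariance=np.eye(3),
            eigenvectors=np.eye(3),
            eigenvalues=np.array([6.0, 3.0, 1.0]),
            explained=np.array([0.6, 0.3, 0.1]),
        )
        assert pc.n_components_for(0.6) == 1
        assert pc.n_components_for(0.9) == 2
        assert pc.n_components_for(0.95) == 3

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            pop.fit_pca(make_traces(np.zeros((1, 100))))


class TestPCDistance:
    def test_identity_gives_zero(self, rng):
        A = rng.normal(size=(100, 4))
        assert pop.pc_distance(A, A) == 0.0

    def test_planted_offset_has_closed_form(self):
        A = np.zeros((50, 3))
        B = np.zeros((50, 3))
        B[:, 1] = 0.5
        assert pop.pc_distance(A, B) == pytest.approx(np.sqrt(50 * 0.25))
        assert pop.pc_distance(A, B, method="summed") == pytest.approx(50 * 0.5)

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(200):
            A, B, C = rng.normal(size=(3, 20, 3))
            dab = pop.pc_distance(A, B)
            dba = pop.pc_distance(B, A)
            assert dab == pytest.approx(dba)
            assert dab <= pop.pc_distance(A, C) + pop.pc_distance(C, B) + 1e-12

    def test_projection_through_model_reduces_dimensions(self, rng):
        tm = make_traces(rng.normal(size=(6, 300)))
        pc = pop.fit_pca(tm)
        A = rng.normal(size=(10, 6))
        B = rng.normal(size=(10, 6))
        d2 = pop.pc_distance(A, B, pc_model=pc, k=2)
        manual = np.linalg.norm(pc.project(A, 2) - pc.project(B, 2))
        assert d2 == pytest.approx(manual)

    def test_shape_mismatch_and_bad_method_rejected(self):
        with pytest.raises(ValueError):
            pop.pc_distance(np.zeros((5, 2)), np.zeros((4, 2)))
        with pytest.raises(ValueError, match="method"):
            pop.pc_distance(np.zeros((5, 2)), np.zeros((5, 2)), method="city")


class TestExtractEpisode:
    def test_block_shape_and_content(self):
        dff = np.arange(200, dtype=float).reshape(2, 100)
        tm = make_traces(dff, rate=10.0)
        ep = pop.extract_episode(tm, onset_s=2.0, duration_s=3.0)
        assert ep.shape == (30, 2)
        assert np.allclose(ep[:, 0], dff[0, 20:50])

    def test_episode_past_end_rejected(self):
        tm = make_traces(np.zeros((2, 100)), rate=10.0)
        with pytest.raises(ValueError):
            pop.extract_episode(tm, onset_s=9.0, duration_s=3.0)


class TestFitHmm:
    def test_recovers_planted_two_regime_structure(self, rng):
        X = np.vstack(
            [rng.normal(0.0, 1.0, size=(400, 2)), rng.normal(8.0, 1.0, size=(400, 2))]
        )
        sm = pop.fit_hmm(X, K=2, seed=0)
        first = np.bincount(sm.state_path[:400], minlength=2).argmax()
        second = 1 - first
        acc = (
            np.mean(sm.state_path[:400] == first)
            + np.mean(sm.state_path[400:] == second)
        ) / 2
        assert acc >= 0.99

    def test_single_state_path_is_constant(self, rng):
        sm = pop.fit_hmm(rng.normal(size=(100, 2)), K=1, seed=0)
        assert (sm.state_path == 0).all()

    def test_loglik_trace_nondecreasing(self, rng):
        X = np.vstack(
            [rng.normal(0.0, 1.0, size=(200, 2)), rng.normal(4.0, 1.0, size=(200, 2))]
        )
        sm = pop.fit_hmm(X, K=3, seed=1)
        assert (np.diff(sm.loglik_trace) >= -1e-6).all()

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            pop.fit_hmm(rng.normal(size=(100, 2)), K=0)
        with pytest.raises(ValueError):
            pop.fit_hmm(rng.normal(size=(5, 2)), K=4)


class TestSelectNumStates:
    def test_knee_found_at_planted_state_count(self, rng):
        X = np.vstack(
            [rng.normal(0.0, 1.0, size=(400, 2)), rng.normal(8.0, 1.0, size=(400, 2))]
        )
        k_star, curve = pop.select_num_states(X, K_range=range(1, 6), seed=0)
        assert k_star == 2
        assert list(curve["K"]) == [1, 2, 3, 4, 5]
        # richer models never lose likelihood on the training data (up to EM noise)
        ll = curve["loglik_per_frame"].to_numpy()
        assert ll[1] > ll[0]

    def test_short_candidate_range_rejected(self, rng):
        with pytest.raises(ValueError):
            pop.select_num_states(rng.normal(size=(100, 2)), K_range=[2, 3])


class TestAlignment:
    def test_hand_aligned_state_and_conditional_prob(self):
        path = [0, 0, 1, 1, 1, 0, 0, 0, 0, 0]
        log = make_log([(vocab.PUP_SNIFFING, 2.0, 5.0)], duration=10.0)
        out = pop.align_states_to_behaviour(make_state_model(path, 2), log, frame_rate=1.0)
        assert out[vocab.PUP_SNIFFING]["aligned_state"] == 1
        assert out[vocab.PUP_SNIFFING]["conditional_prob"] == pytest.approx(1.0)

    def test_tie_breaks_to_lower_state_index(self):
        path = [0, 1, 0, 1]
        log = make_log([(vocab.PUP_SNIFFING, 0.0, 4.0)], duration=4.0)
        out = pop.align_states_to_behaviour(make_state_model(path, 2), log, frame_rate=1.0)
        assert out[vocab.PUP_SNIFFING]["aligned_state"] == 0

    def test_absent_behaviour_maps_to_none(self):
        log = make_log([(vocab.PUP_SNIFFING, 0.0, 2.0)], duration=4.0)
        out = pop.align_states_to_behaviour(
            make_state_model([0, 0, 1, 1], 2), log, frame_rate=1.0,
            behaviours=[vocab.AGGRESSIVE_CONTACT],
        )
        assert out[vocab.AGGRESSIVE_CONTACT]["aligned_state"] is None


class TestDetectionRate:
    def test_hand_case_half_detected(self):
        path = np.zeros(20, int)
        path[[0, 1]] = 1  # first episode 50% covered
        path[13] = 1  # second episode 25% covered
        log = make_log(
            [
                (vocab.AGGRESSIVE_CONTACT, 0.0, 4.0),
                (vocab.AGGRESSIVE_CONTACT, 10.0, 14.0),
            ],
            duration=20.0,
        )
        rate = pop.hmm_detection_rate(
            make_state_model(path, 2), log, frame_rate=1.0, aligned_state=1
        )
        assert rate == pytest.approx(0.5)

    def test_invariant_to_state_relabelling(self):
        path = np.zeros(20, int)
        path[[0, 1, 13]] = 1
        log = make_log([(vocab.AGGRESSIVE_CONTACT, 0.0, 4.0)], duration=20.0)
        a = pop.hmm_detection_rate(
            make_state_model(path, 2), log, frame_rate=1.0, aligned_state=1
        )
        b = pop.hmm_detection_rate(
            make_state_model(1 - path, 2), log, frame_rate=1.0, aligned_state=0
        )
        assert a == b

    def test_no_episodes_returns_none_with_warning(self):
        log = make_log([(vocab.PUP_SNIFFING, 0.0, 2.0)], duration=4.0)
        with pytest.warns(UserWarning, match="undefined"):
            rate = pop.hmm_detection_rate(
                make_state_model([0, 0, 0, 0], 1), log, frame_rate=1.0
            )
        assert rate is None


class TestEpisodesAndSplits:
    def test_build_episodes_filters_short_bouts_and_clips(self):
        log = make_log(
            [
                (vocab.PUP_SNIFFING, 0.0, 1.5),  # too short
                (vocab.PUP_SNIFFING, 5.0, 10.0),
                (vocab.PUP_GROOMING, 12.0, 30.0),  # clipped at n_frames
            ],
            duration=30.0,
        )
        eps = pop.build_episodes(
            log, [vocab.PUP_SNIFFING, vocab.PUP_GROOMING], frame_rate=1.0, n_frames=20
        )
        assert [(e.label, e.start, e.stop) for e in eps] == [
            (vocab.PUP_SNIFFING, 5, 10),
            (vocab.PUP_GROOMING, 12, 20),
        ]

    def test_episode_split_is_disjoint_and_stratified(self):
        eps = [pop.Episode("a", i, i + 1) for i in range(8)]
        eps += [pop.Episode("b", 10 + i, 11 + i) for i in range(8)]
        train, test = pop.episode_split(eps, seed=0, test_size=0.25)
        assert set(train).isdisjoint(test)
        assert len(train) + len(test) == 16
        test_labels = [eps[i].label for i in test]
        assert test_labels.count("a") == 2 and test_labels.count("b") == 2


class TestSmote:
    def test_balances_class_counts(self, rng):
        X = np.vstack([rng.normal(size=(20, 3)), rng.normal(5.0, size=(5, 3))])
        y = np.array(["a"] * 20 + ["b"] * 5)
        Xo, yo = pop.smote_oversample(X, y, rng)
        _, counts = np.unique(yo, return_counts=True)
        assert (counts == 20).all()

    def test_synthetic_points_interpolate_within_class_range(self, rng):
        X = np.vstack([np.zeros((10, 1)), rng.uniform(4.0, 6.0, size=(4, 1))])
        y = np.array(["a"] * 10 + ["b"] * 4)
        Xo, yo = pop.smote_oversample(X, y, rng)
        synth_b = Xo[len(y):]
        assert (synth_b >= 4.0).all() and (synth_b <= 6.0).all()

    def test_singleton_class_skipped_with_warning(self, rng):
        X = np.vstack([np.zeros((5, 2)), np.ones((1, 2))])
        y = np.array(["a"] * 5 + ["b"])
        with pytest.warns(UserWarning, match="SMOTE skipped"):
            Xo, yo = pop.smote_oversample(X, y, rng)
        assert (yo == "b").sum() == 1


class TestDecoding:
    def _separable(self):
        # 8 episodes per class, 10 frames each, classes at distinct locations
        n_frames = 160
        features = np.zeros((n_frames, 2))
        episodes = []
        for i in range(8):
            s = i * 10
            features[s:s + 10] = [0.0, 0.0]
            episodes.append(pop.Episode("sniff", s, s + 10))
        for i in range(8):
            s = 80 + i * 10
            features[s:s + 10] = [5.0, 5.0]
            episodes.append(pop.Episode("groom", s, s + 10))
        return features, episodes

    def test_separable_classes_decoded_perfectly(self):
        features, episodes = self._separable()
        res = pop.decode_behaviour(features, episodes, n_iter=5, seed=0)
        assert res.mean_accuracy == pytest.approx(1.0)
        assert np.allclose(np.diag(res.confusion_pct), 100.0)

    def test_confusion_rows_sum_to_hundred(self):
        features, episodes = self._separable()
        res = pop.decode_behaviour(features, episodes, n_iter=3, seed=1)
        assert np.allclose(res.confusion_pct.sum(axis=1), 100.0)

    def test_deterministic_for_fixed_seed(self):
        features, episodes = self._separable()
        a = pop.decode_behaviour(features, episodes, n_iter=3, seed=7)
        b = pop.decode_behaviour(features, episodes, n_iter=3, seed=7)
        assert np.array_equal(a.accuracies, b.accuracies)
        assert np.array_equal(a.confusion_counts, b.confusion_counts)

    def test_rare_class_dropped_then_too_few_classes_errors(self):
        features = np.zeros((30, 2))
        episodes = [
            pop.Episode("sniff", 0, 10),
            pop.Episode("sniff", 10, 20),
            pop.Episode("groom", 20, 30),
        ]
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(ValueError, match="classes"):
                pop.decode_behaviour(features, episodes, n_iter=2, seed=0)
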