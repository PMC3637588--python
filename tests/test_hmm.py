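"""Dual Gaussian-mixture HMM: initialization, EM, likelihoods, selection."""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import nirsdecode as nd
from nirsdecode.features import Observation
from nirsdecode.hmm import (
    EMConfig,
    GaussianMixtureHMM,
    Topology,
    hmm_from_dict,
    hmm_to_dict,
    init_hmm,
    kappa_score,
    log_likelihood,
    select_model_pair,
    train_hmm,
)
from conftest import sample_lr_hmm_sequences


def brute_force_log_likelihood(hmm: GaussianMixtureHMM,
                               obs: np.ndarray) -> float:
    """Enumerate every state path: sum of pi * prod A * prod mixture pdf."""
    T = obs.shape[0]
    S, M = hmm.weights.shape
    total = 0.0
    for path in itertools.product(range(S), repeat=T):
        p = hmm.startprob[path[0]]
        for a, b in zip(path[:-1], path[1:]):
            p *= hmm.transmat[a, b]
        if p == 0.0:
            continue
        for t, s in enumerate(path):
            emit = sum(hmm.weights[s, m]
                       * multivariate_normal.pdf(obs[t], hmm.means[s, m],
                                                 hmm.covars[s, m])
                       for m in range(M))
            p *= emit
        total += p
    return np.log(total)


def random_hmm(n_states, n_mix, d, rng) -> GaussianMixtureHMM:
    transmat = np.zeros((n_states, n_states))
    for s in range(n_states - 1):
        draw = rng.uniform(0.2, 1.0, 2)
        transmat[s, s], transmat[s, s + 1] = draw / draw.sum()
    transmat[-1, -1] = 1.0
    weights = rng.uniform(0.5, 1.0, (n_states, n_mix))
    weights /= weights.sum(axis=1, keepdims=True)
    means = rng.normal(0, 2, (n_states, n_mix, d))
    covars = np.empty((n_states, n_mix, d, d))
    for s in range(n_states):
        for m in range(n_mix):
            a = rng.normal(0, 1, (d, d))
            covars[s, m] = a @ a.T + 0.5 * np.eye(d)
    return GaussianMixtureHMM(topology=Topology(n_states, n_mix),
                              startprob=np.eye(n_states)[0],
                              transmat=transmat, weights=weights,
                              means=means, covars=covars)


class TestLogLikelihood:
    def test_single_state_single_mixture_closed_form(self):
        rng = np.random.default_rng(0)
        hmm = random_hmm(1, 1, 2, rng)
        obs = rng.normal(0, 1, (20, 2))
        expected = multivariate_normal.logpdf(obs, hmm.means[0, 0],
                                              hmm.covars[0, 0]).sum()
        assert log_likelihood(hmm, obs) == pytest.approx(expected, abs=1e-10)

    def test_matches_brute_force_enumeration(self):
        """Randomized battery over N_s <= 3, T <= 5, N_m <= 2."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            S = int(rng.integers(1, 4))
            M = int(rng.integers(1, 3))
            T = int(rng.integers(1, 6))
            d = int(rng.integers(1, 3))
            hmm = random_hmm(S, M, d, rng)
            obs = rng.normal(0, 1.5, (T, d))
            assert log_likelihood(hmm, obs) == pytest.approx(
                brute_force_log_likelihood(hmm, obs), abs=1e-10)

    def test_agrees_with_hmmlearn(self):
        """Independent library cross-check for single-Gaussian emissions."""
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(3)
        ours = random_hmm(3, 1, 2, rng)
        ref = hmmlearn_hmm.GaussianHMM(n_components=3, covariance_type="full",
                                       init_params="")
        ref.startprob_ = ours.startprob
        ref.transmat_ = ours.transmat
        ref.means_ = ours.means[:, 0]
        ref.covars_ = ours.covars[:, 0]
        obs = rng.normal(0, 1, (40, 2))
        assert log_likelihood(ours, obs) == pytest.approx(ref.score(obs),
                                                          abs=1e-8)

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(0)
        hmm = random_hmm(2, 1, 3, rng)
        with pytest.raises(ValueError, match="dimension"):
            log_likelihood(hmm, rng.normal(size=(10, 2)))


class TestInit:
    def test_single_state_single_mixture_pooled_moments(self):
        rng = np.random.default_rng(1)
        X = rng.normal(2.0, 1.5, (6, 30, 2))
        hmm = init_hmm(X, Topology(1, 1), seed=0)
        flat = X.reshape(-1, 2)
        np.testing.assert_allclose(hmm.means[0, 0], flat.mean(axis=0),
                                   atol=1e-9)
        np.testing.assert_allclose(hmm.covars[0, 0],
                                   np.cov(flat, rowvar=False), atol=1e-6)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (8, 20, 2))
        a = init_hmm(X, Topology(3, 2), seed=5)
        b = init_hmm(X, Topology(3, 2), seed=5)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.transmat, b.transmat)

    def test_left_to_right_structure_all_seeds(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (6, 25, 2))
        for seed in range(100):
            hmm = init_hmm(X, Topology(4, 1), seed=seed)
            hmm.validate()     # includes sparsity, simplex, SPD checks

    def test_too_few_rows_rejected(self):
        X = np.zeros((1, 3, 2))
        with pytest.raises(ValueError):
            init_hmm(X, Topology(5, 2), seed=0)

    def test_temporal_ordering_of_states(self):
        """Early-mean clusters initialize left states on ramped sequences."""
        rng = np.random.default_rng(4)
        first = rng.normal(-3.0, 0.3, (10, 15, 1))
        second = rng.normal(3.0, 0.3, (10, 15, 1))
        X = np.concatenate([first, second], axis=1)
        hmm = init_hmm(X, Topology(2, 1), seed=0)
        assert hmm.means[0, 0, 0] < hmm.means[1, 0, 0]


class TestTrainHMM:
    def test_monotone_log_likelihood(self):
        X = sample_lr_hmm_sequences(40, 20, seed=0)
        initial = init_hmm(X, Topology(2, 1), seed=1)
        trained = train_hmm(X, initial)
        ll = np.asarray(trained.log_likelihoods)
        assert ll.size >= 2
        assert np.all(np.diff(ll) >= -1e-8)

    def test_degenerate_single_gaussian_one_step_fixed_point(self):
        rng = np.random.default_rng(5)
        X = rng.normal(1.0, 2.0, (10, 25, 2))
        initial = init_hmm(X, Topology(1, 1), seed=0)
        trained = train_hmm(X, initial, EMConfig(max_iter=5))
        flat = X.reshape(-1, 2)
        np.testing.assert_allclose(trained.means[0, 0], flat.mean(axis=0),
                                   atol=1e-8)
        np.testing.assert_allclose(trained.covars[0, 0],
                                   np.cov(flat, rowvar=False, bias=True),
                                   atol=1e-6)
        assert len(trained.log_likelihoods) <= 3

    def test_parameter_recovery_two_state(self):
        """200 sequences from a known left-to-right model: means within 10%,
        transition probabilities within 0.1 after training."""
        true_means = np.array([[-1.0, 0.0], [2.0, 1.0]])
        X = sample_lr_hmm_sequences(200, 25, seed=7, means=true_means,
                                    self_prob=0.9, noise_sd=0.5)
        initial = init_hmm(X, Topology(2, 1), seed=2)
        trained = train_hmm(X, initial)
        order = np.argsort(trained.means[:, 0, 0])
        means = trained.means[order, 0]
        np.testing.assert_allclose(means, true_means,
                                   atol=0.1 * np.abs(true_means).max())
        assert abs(trained.transmat[order[0], order[0]] - 0.9) < 0.1

    def test_initializer_not_mutated(self):
        X = sample_lr_hmm_sequences(20, 15, seed=1)
        initial = init_hmm(X, Topology(2, 1), seed=3)
        means_before = initial.means.copy()
        train_hmm(X, initial)
        np.testing.assert_array_equal(initial.means, means_before)


class TestKappaAndSelection:
    def test_all_correct_gives_one(self):
        assert kappa_score([2.0, -1.0], ["active", "rest"]) == 1.0

    def test_all_wrong_gives_zero(self):
        assert kappa_score([-2.0, 1.0], ["active", "rest"]) == 0.0

    def test_hand_worked_example(self):
        # D = (+2, -1, +1), labels (active, active, rest): only trial 1
        # is correctly signed, kappa = 2 / (2+1+1)
        assert kappa_score([2.0, -1.0, 1.0],
                           ["active", "active", "rest"]) == pytest.approx(0.5)

    def test_zero_distance_trial_carries_zero_weight(self):
        # a D=0 trial is signed as rest (strict rule) but contributes |D|=0
        # to both sums, so kappa is driven by the remaining trials only
        assert kappa_score([0.0, 1.0], ["active", "active"]) == pytest.approx(
            1.0)
        assert kappa_score([0.0, -1.0], ["active", "active"]) == 0.0

    def test_all_zero_distances_warn(self):
        with pytest.warns(UserWarning, match="kappa"):
            assert kappa_score([0.0, 0.0], ["rest", "rest"]) == 0.0

    def test_selection_maximizes_kappa(self):
        rng = np.random.default_rng(6)
        good_a = random_hmm(1, 1, 1, rng)
        good_a.means[:] = 5.0
        good_r = random_hmm(1, 1, 1, rng)
        good_r.means[:] = -5.0
        bad = random_hmm(1, 1, 1, rng)
        bad.means[:] = 0.0
        obs = ([Observation(rng.normal(5, 1, (10, 1)), "active", i)
                for i in range(4)]
               + [Observation(rng.normal(-5, 1, (10, 1)), "rest", i + 4)
                  for i in range(4)])
        cands_a, cands_r = [bad, good_a], [bad, good_r]
        clf = select_model_pair(cands_a, cands_r, obs)
        labels = [o.label for o in obs]
        all_kappas = [
            kappa_score([log_likelihood(a, o.data) - log_likelihood(r, o.data)
                         for o in obs], labels)
            for a in cands_a for r in cands_r if a is not r]
        assert clf.kappa == pytest.approx(max(all_kappas))
        assert clf.kappa > 0.99


class TestClassify:
    def test_likelihood_comparison(self):
        rng = np.random.default_rng(7)
        hmm_a = random_hmm(1, 1, 1, rng)
        hmm_a.means[:] = 3.0
        hmm_r = random_hmm(1, 1, 1, rng)
        hmm_r.means[:] = -3.0
        hmm_a.covars[:] = hmm_r.covars[:] = np.eye(1)
        clf = nd.DualClassifier(hmm_a, hmm_r, kappa=1.0,
                                topology=Topology(1, 1))
        assert nd.classify(clf, np.full((5, 1), 3.0)) == "active"
        assert nd.classify(clf, np.full((5, 1), -3.0)) == "rest"
        # exact tie resolves to rest (strict inequality)
        assert nd.classify(clf, np.zeros((5, 1))) == "rest"

    def test_sampled_observations_classified_correctly(self):
        rng = np.random.default_rng(8)
        hmm_a = random_hmm(1, 1, 2, rng)
        hmm_a.means[:] = [2.0, 2.0]
        hmm_a.covars[:] = np.eye(2)
        hmm_r = random_hmm(1, 1, 2, rng)
        hmm_r.means[:] = [-2.0, -2.0]
        hmm_r.covars[:] = np.eye(2)
        clf = nd.DualClassifier(hmm_a, hmm_r, kappa=1.0,
                                topology=Topology(1, 1))
        hits = sum(
            nd.classify(clf, rng.normal(2.0, 1.0, (10, 2))) == "active"
            for _ in range(1000))
        assert hits >= 950


class TestSerialization:
    def test_round_trip_bit_faithful(self):
        rng = np.random.default_rng(9)
        X = sample_lr_hmm_sequences(20, 15, seed=2)
        trained = train_hmm(X, init_hmm(X, Topology(2, 1), seed=0))
        import json
        payload = json.loads(json.dumps(hmm_to_dict(trained)))
        restored = hmm_from_dict(payload)
        np.testing.assert_array_equal(restored.means, trained.means)
        np.testing.assert_array_equal(restored.covars, trained.covars)
        np.testing.assert_array_equal(restored.transmat, trained.transmat)
        assert restored.log_likelihoods == trained.log_likelihoods


class TestClassifierPersistence:
    def test_save_load_round_trip(self, tmp_path):
        from nirsdecode.hmm import load_classifier, save_classifier
        X = sample_lr_hmm_sequences(16, 15, seed=3)
        obs = ([Observation(x, "active", i) for i, x in enumerate(X[:8])]
               + [Observation(-x, "rest", i + 8) for i, x in enumerate(X[8:])])
        clf = nd.train_dual_classifier(obs, Topology(2, 1), n_restarts=2,
                                       seed=4)
        save_classifier(clf, tmp_path / "clf.json")
        back = load_classifier(tmp_path / "clf.json")
        assert back.kappa == clf.kappa
        np.testing.assert_array_equal(back.hmm_active.means,
                                      clf.hmm_active.means)
        np.testing.assert_array_equal(back.hmm_rest.covars,
                                      clf.hmm_rest.covars)
        for o in obs[:4]:
            assert nd.classify(back, o) == nd.classify(clf, o)
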