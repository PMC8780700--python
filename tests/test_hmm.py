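import itertools
import json
import warnings

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from scipy.stats import chi2, multivariate_normal

from conftest import make_segment
from headgest import hmm
from headgest.hmm import (
    GaussianHmm,
    PsiNull,
    baum_welch,
    classify_segment,
    extract_features,
    fit_psi_null,
    init_emissions_kmeans,
    log_likelihood,
    mahalanobis_score,
    sample_hmm,
    train_hmm_classifier,
)


def brute_force_log_likelihood(model: GaussianHmm, obs: np.ndarray) -> float:
    """Oracle: exhaustive sum over all state paths."""
    K, T = model.n_states, len(obs)
    terms = []
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(model.startprob[path[0]]) if model.startprob[path[0]] > 0 else -np.inf
        for a, b in zip(path, path[1:]):
            lp += np.log(model.transmat[a, b]) if model.transmat[a, b] > 0 else -np.inf
        for t, s in enumerate(path):
            lp += multivariate_normal.logpdf(obs[t], model.means[s], model.covars[s])
        terms.append(lp)
    return float(logsumexp(terms))


def random_hmm(rng, n_states, dim=2):
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    pi = rng.dirichlet(np.ones(n_states))
    means = rng.normal(0, 5, (n_states, dim))
    covars = np.array([np.eye(dim) * rng.uniform(0.5, 3.0) for _ in range(n_states)])
    return GaussianHmm(pi, A, means, covars)


def _segment_from_obs(x, y, vx, vy):
    n = len(x)
    return make_segment(np.arange(n) / 30.0, x, y, vx, vy)


class TestFeatures:
    def test_stationary_at_reference_gives_zero_position_features(self):
        seg = _segment_from_obs(np.full(10, 3.0), np.full(10, -2.0), np.ones(10), np.ones(10))
        feats = extract_features(seg, "P", reference_xy=(3.0, -2.0))
        assert np.allclose(feats, 0.0)

    def test_pv_concatenates_p_and_v(self, rng):
        x, y = rng.normal(size=(2, 10))
        vx, vy = rng.normal(size=(2, 10))
        seg = _segment_from_obs(x, y, vx, vy)
        ref = (0.5, -0.5)
        pv = extract_features(seg, "PV", ref)
        assert pv.shape == (10, 4)
        assert np.allclose(pv[:, :2], extract_features(seg, "P", ref))
        assert np.allclose(pv[:, 2:], extract_features(seg, "V", ref))

    def test_velocity_features_translation_invariant(self, rng):
        x, y, vx, vy = rng.normal(size=(4, 10))
        seg = _segment_from_obs(x, y, vx, vy)
        shifted = _segment_from_obs(x + 100, y - 40, vx, vy)
        assert np.allclose(
            extract_features(seg, "V"), extract_features(shifted, "V")
        )

    def test_unknown_kind_raises(self, rng):
        seg = _segment_from_obs(*rng.normal(size=(4, 10)))
        with pytest.raises(ValueError):
            extract_features(seg, "XY")


class TestForwardAlgorithm:
    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(10):
            K = int(rng.integers(1, 4))
            model = random_hmm(rng, K)
            obs = rng.normal(0, 4, (int(rng.integers(1, 7)), 2))
            assert log_likelihood(model, obs) == pytest.approx(
                brute_force_log_likelihood(model, obs), abs=1e-9
            )

    def test_single_state_reduces_to_sum_of_log_densities(self, rng):
        model = GaussianHmm(
            np.array([1.0]), np.array([[1.0]]),
            np.array([[1.0, -1.0]]), np.array([np.eye(2) * 2.0]),
        )
        obs = rng.normal(0, 2, (8, 2))
        expected = multivariate_normal.logpdf(obs, model.means[0], model.covars[0]).sum()
        assert log_likelihood(model, obs) == pytest.approx(expected, abs=1e-10)

    def test_finite_for_any_finite_input(self, rng, toy_left_right_hmm):
        obs = rng.normal(0, 500, (40, 2))
        assert np.isfinite(log_likelihood(toy_left_right_hmm, obs))

    def test_dimension_mismatch_raises(self, rng, toy_left_right_hmm):
        with pytest.raises(ValueError):
            log_likelihood(toy_left_right_hmm, rng.normal(size=(5, 3)))

    def test_matches_hmmlearn(self, rng, toy_left_right_hmm):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        m = toy_left_right_hmm
        ref = hmmlearn.GaussianHMM(n_components=4, covariance_type="full", init_params="")
        ref.startprob_ = m.startprob
        ref.transmat_ = m.transmat
        ref.means_ = m.means
        ref.covars_ = m.covars
        obs = sample_hmm(m, 25, rng)
        assert log_likelihood(m, obs) == pytest.approx(ref.score(obs), abs=1e-8)


class TestKmeansInit:
    def test_recovers_separated_clouds(self, rng):
        centers = np.array([[0, 0], [30, 0], [30, 30], [0, 30.0]])
        seqs = [
            np.vstack([rng.normal(c, 1.0, (8, 2)) for c in centers]) for _ in range(10)
        ]
        init = init_emissions_kmeans(seqs, seed=0)
        cost = np.linalg.norm(init.means[:, None] - centers[None], axis=2)
        r, c = linear_sum_assignment(cost)
        assert cost[r, c].max() < 1.0

    def test_states_ordered_by_occurrence_time(self, rng):
        centers = np.array([[0, 0], [30, 0], [30, 30], [0, 30.0]])
        seqs = [
            np.vstack([rng.normal(c, 1.0, (8, 2)) for c in centers]) for _ in range(10)
        ]
        init = init_emissions_kmeans(seqs, seed=0)
        # earliest-phase cloud becomes state 0, and so on
        for k, c in enumerate(centers):
            assert np.linalg.norm(init.means[k] - c) < 1.0

    def test_identical_observations_raise(self):
        seqs = [np.ones((20, 2))]
        with pytest.raises(ValueError):
            init_emissions_kmeans(seqs, seed=0)

    def test_left_right_topology_structure(self, rng):
        seqs = [rng.normal(0, 10, (30, 2)) for _ in range(5)]
        init = init_emissions_kmeans(seqs, seed=1, topology="left_right")
        A = init.transmat
        assert np.allclose(np.tril(A, -1), 0.0)
        assert np.allclose(np.triu(A, 2), 0.0)
        assert A[-1, -1] == pytest.approx(1.0)


class TestBaumWelch:
    def test_single_state_closed_form(self, rng):
        obs = [rng.normal(2.0, 1.5, (20, 2)) for _ in range(5)]
        init = GaussianHmm(
            np.array([1.0]), np.array([[1.0]]),
            np.array([[0.0, 0.0]]), np.array([np.eye(2)]),
        )
        model, _ = baum_welch(obs, init, max_iter=5)
        pooled = np.vstack(obs)
        assert np.allclose(model.transmat, [[1.0]])
        assert np.allclose(model.startprob, [1.0])
        assert np.allclose(model.means[0], pooled.mean(axis=0), atol=1e-8)
        assert np.allclose(model.covars[0], np.cov(pooled.T, bias=True), atol=1e-6)

    def test_log_likelihood_non_decreasing(self, rng, toy_left_right_hmm):
        seqs = [sample_hmm(toy_left_right_hmm, 30, rng) for _ in range(30)]
        init = init_emissions_kmeans(seqs, seed=2)
        _, history = baum_welch(seqs, init)
        assert np.all(np.diff(history) >= -1e-6)

    def test_parameter_recovery_single_seed(self, rng, toy_left_right_hmm):
        true = toy_left_right_hmm
        seqs = [sample_hmm(true, 30, rng) for _ in range(200)]
        init = init_emissions_kmeans(seqs, seed=0)
        model, _ = baum_welch(seqs, init)
        cost = np.linalg.norm(model.means[:, None] - true.means[None], axis=2)
        r, c = linear_sum_assignment(cost)
        perm = np.empty(4, int)
        perm[c] = r
        assert np.abs(model.transmat[perm][:, perm] - true.transmat).max() < 0.1
        assert np.linalg.norm(model.means[perm] - true.means, axis=1).max() < 0.5

    def test_frozen_emissions_only_updates_transitions(self, rng, toy_left_right_hmm):
        seqs = [sample_hmm(toy_left_right_hmm, 30, rng) for _ in range(20)]
        init = init_emissions_kmeans(seqs, seed=3)
        model, history = baum_welch(seqs, init, update_emissions=False)
        assert np.allclose(model.means, init.means)
        assert np.allclose(model.covars, init.covars)
        assert not np.allclose(model.transmat, init.transmat)
        assert np.all(np.diff(history) >= -1e-6)

    def test_structural_zeros_preserved(self, rng, toy_left_right_hmm):
        seqs = [sample_hmm(toy_left_right_hmm, 30, rng) for _ in range(20)]
        init = init_emissions_kmeans(seqs, seed=4, topology="left_right")
        model, _ = baum_welch(seqs, init)
        assert np.allclose(np.tril(model.transmat, -1), 0.0)


class TestPsiAndMahalanobis:
    def test_null_mean_is_arithmetic_mean(self):
        psis = [(-10, 20), (-12, 22), (-14, 24)]
        null = fit_psi_null(psis)
        assert np.allclose(null.mu, (-12, 22))

    def test_identical_psis_trigger_ridge_with_warning(self):
        with pytest.warns(UserWarning, match="singular"):
            null = fit_psi_null([(-10, 20)] * 5)
        np.linalg.cholesky(null.sigma)

    def test_too_few_segments_raise(self):
        with pytest.raises(ValueError):
            fit_psi_null([(-10, 20), (-11, 21)])

    def test_distance_zero_at_mean(self):
        null = PsiNull(mu=np.array([-10.0, 20.0]), sigma=np.eye(2))
        assert mahalanobis_score((-10, 20), null) == 0.0

    def test_identity_covariance_reduces_to_euclidean(self):
        null = PsiNull(mu=np.zeros(2), sigma=np.eye(2))
        assert mahalanobis_score((3, 4), null) == pytest.approx(5.0)

    def test_invariant_under_affine_rescaling(self, rng):
        for _ in range(20):
            mu = rng.normal(0, 5, 2)
            L = rng.normal(0, 1, (2, 2)) + np.eye(2) * 2
            sigma = L @ L.T
            psi = rng.normal(0, 5, 2)
            d0 = mahalanobis_score(psi, PsiNull(mu=mu, sigma=sigma))
            M = rng.normal(0, 1, (2, 2)) + np.eye(2) * 3  # invertible affine map
            b = rng.normal(0, 10, 2)
            d1 = mahalanobis_score(
                M @ psi + b, PsiNull(mu=M @ mu + b, sigma=M @ sigma @ M.T)
            )
            assert d1 == pytest.approx(d0, rel=1e-9)


class TestClassification:
    def _trained(self, rng):
        segs = []
        for _ in range(12):
            x = np.linspace(0, 120, 25) + rng.normal(0, 2, 25)
            vx = np.gradient(x) * 30
            segs.append(_segment_from_obs(x, np.zeros(25), vx, np.zeros(25)))
        clf, _ = train_hmm_classifier(segs, feature_kind="PV", seed=0)
        return clf, segs

    def test_psi_at_null_mean_is_valid_at_any_confidence(self, rng):
        clf, segs = self._trained(rng)
        psi = clf.psi(segs[0])
        null = PsiNull(mu=psi, sigma=clf.null.sigma, confidence=1e-9)
        score, decision = classify_segment(segs[0], clf.model, null)
        assert score == 0.0 and decision

    def test_boundary_distance_decided_valid(self, rng):
        clf, segs = self._trained(rng)
        # d^2 exactly at the chi-square quantile is accepted (<=)
        q = chi2.ppf(0.95, df=2)
        assert q == pytest.approx(5.991464547, abs=1e-6)
        score, decision = classify_segment(segs[0], clf.model, clf.null)
        assert decision  # training segment well inside the null

    def test_short_segment_rejected(self, rng):
        clf, _ = self._trained(rng)
        short = _segment_from_obs(np.zeros(3), np.zeros(3), np.ones(3), np.zeros(3))
        with pytest.warns(UserWarning, match="below scoreable minimum"):
            score, decision = classify_segment(short, clf.model, clf.null)
        assert score == -np.inf and not decision

    def test_confidence_zero_limit_rejects_everything(self, rng):
        clf, segs = self._trained(rng)
        for seg in segs[:3]:
            score, decision = classify_segment(
                seg, clf.model, clf.null, confidence=1e-12
            )
            if score < 0:  # any nonzero distance
                assert not decision

    def test_serialization_round_trips_bit_identically(self, rng, tmp_path):
        clf, _ = self._trained(rng)
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        clf.to_json(p1)
        clf2 = hmm.HmmClassifier.from_json(p1)
        clf2.to_json(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(clf.model.transmat, clf2.model.transmat)
        assert np.array_equal(clf.null.sigma, clf2.null.sigma)
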