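"""Clustering of posture modes and AR-HMM inference.

The forward-backward and Viterbi recursions are checked against exhaustive
enumeration over all state sequences on small instances; clustering is
checked against planted blob labels.
"""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from gapcross import ARHMM, cluster_postures, occupancy_over_time, robustness_scan
from gapcross.errors import FitError
from gapcross.states import _design, modal_state_partition, state_probability_profile

from conftest import best_state_accuracy


def enum_posterior(model: ARHMM, x: np.ndarray):
    """Brute-force loglik, gamma and MAP path by enumerating sequences."""
    y, phi = _design(np.atleast_2d(x), model.ar_order)
    logb = model._log_emissions(y, phi)
    n, k = logb.shape
    logpi = np.log(model.startprob_)
    log_a = np.log(model.transmat_)
    seq_lps = []
    for seq in itertools.product(range(k), repeat=n):
        lp = logpi[seq[0]] + logb[0, seq[0]]
        for t in range(1, n):
            lp += log_a[seq[t - 1], seq[t]] + logb[t, seq[t]]
        seq_lps.append((lp, seq))
    total = -np.inf
    for lp, _ in seq_lps:
        total = np.logaddexp(total, lp)
    gamma = np.zeros((n, k))
    for lp, seq in seq_lps:
        w = np.exp(lp - total)
        for t, s in enumerate(seq):
            gamma[t, s] += w
    best = max(seq_lps, key=lambda p: p[0])
    return total, gamma, np.array(best[1])


def random_model(rng, k, d, p):
    m = ARHMM(n_states=k, ar_order=p)
    m.coefs_ = rng.normal(0, 0.5, (k, d, d * p))
    m.intercepts_ = rng.normal(0, 1, (k, d))
    raw = rng.normal(0, 1, (k, d, d))
    m.covars_ = np.stack([c @ c.T + 0.5 * np.eye(d) for c in raw])
    a = rng.random((k, k)) + 0.1
    m.transmat_ = a / a.sum(1, keepdims=True)
    s = rng.random(k) + 0.1
    m.startprob_ = s / s.sum()
    return m


def planted_model():
    gen = ARHMM(n_states=3, ar_order=1)
    thetas = [0.5, -0.4, 0.05]
    gen.coefs_ = np.stack([
        0.95 * np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        for t in thetas
    ])
    gen.intercepts_ = np.array([[0.5, 0.0], [-0.5, 0.5], [0.0, -0.6]])
    gen.covars_ = np.stack([0.05 * np.eye(2)] * 3)
    gen.transmat_ = np.array(
        [[0.94, 0.04, 0.02], [0.03, 0.95, 0.02], [0.02, 0.03, 0.95]]
    )
    gen.startprob_ = np.ones(3) / 3
    return gen


class TestClustering:
    def test_identical_frames_single_cluster(self):
        x = np.ones((100, 3))
        c = cluster_postures(x, knn_k=15, seed=0)
        assert c.n_clusters_ == 1

    def test_two_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x = np.vstack([
            rng.normal((0, 0), 1.0, (200, 2)),
            rng.normal((40, 0), 1.0, (200, 2)),  # 20 sigma apart
        ])
        labels_true = np.repeat([0, 1], 200)
        c = cluster_postures(x, knn_k=15, resolution=0.1, seed=0)
        assert c.n_clusters_ == 2
        assert adjusted_rand_score(labels_true, c.labels_) == 1.0

    def test_frame_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x = np.vstack([
            rng.normal((0, 0), 1.0, (150, 2)),
            rng.normal((30, 0), 1.0, (150, 2)),
        ])
        perm = rng.permutation(len(x))
        c1 = cluster_postures(x, seed=0)
        c2 = cluster_postures(x[perm], seed=0)
        assert adjusted_rand_score(c1.labels_[perm], c2.labels_) == 1.0

    def test_small_clusters_merged(self):
        rng = np.random.default_rng(2)
        x = np.vstack([
            rng.normal((0, 0), 1.0, (500, 2)),
            rng.normal((40, 0), 1.0, (500, 2)),
            rng.normal((20, 30), 0.3, (8, 2)),  # < 2% of frames
        ])
        c = cluster_postures(x, seed=0, min_occupancy_frac=0.02)
        assert c.n_clusters_ == 2

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            cluster_postures(np.zeros((10, 2)), knn_k=15)


class TestOccupancy:
    def test_single_cluster_occupancy_one(self):
        occ = occupancy_over_time(np.zeros(50, int), np.arange(50) * 2.0)
        assert np.allclose(occ.occupancy, 1.0)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        occ = occupancy_over_time(
            rng.integers(0, 4, 500), rng.uniform(-100, 100, 500), bin_ms=10.0
        )
        assert np.abs(occ.occupancy.sum(axis=0) - 1.0).max() < 1e-9

    def test_modal_cluster_dominates_each_phase(self, small_cohort,
                                                cohort_embeddings):
        _, embs = cohort_embeddings
        pooled = np.vstack([e.scores for e in embs])
        times = np.concatenate([e.relative_time_ms for e in embs])
        phases = np.concatenate(
            [t.phase_per_frame for t in small_cohort.truths]
        ).astype(str)
        c = cluster_postures(pooled, seed=0)
        for phase in ("preparation", "propulsion", "flight", "landing"):
            m = phases == phase
            _, counts = np.unique(c.labels_[m], return_counts=True)
            assert counts.max() / counts.sum() > 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            occupancy_over_time(np.zeros(5, int), np.zeros(6))


class TestARHMMOracles:
    def test_forward_backward_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            k = int(rng.integers(2, 4))
            d = int(rng.integers(1, 3))
            p = int(rng.integers(1, 3))
            t = int(rng.integers(p + 2, 8))
            model = random_model(rng, k, d, p)
            x = rng.normal(0, 1, (t, d))
            post = model.posterior(x)
            ll, gamma, path = enum_posterior(model, x)
            assert abs(post.log_likelihood - ll) < 1e-10
            assert np.abs(post.gamma - gamma).max() < 1e-10
            assert np.array_equal(model.predict(x), path)

    def test_single_state_collapses_to_ols(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (200, 2)).cumsum(axis=0) * 0.1 + rng.normal(0, 1, (200, 2))
        m = ARHMM(n_states=1, ar_order=1, n_restarts=1).fit([x])
        y, phi = _design(x, 1)
        w_ols, *_ = np.linalg.lstsq(phi, y, rcond=None)
        fitted = np.concatenate([m.coefs_[0], m.intercepts_[0][:, None]], axis=1)
        assert np.abs(fitted - w_ols.T).max() < 1e-6
        post = m.posterior(x)
        assert np.allclose(post.gamma, 1.0)
        resid = y - phi @ w_ols
        assert np.abs(
            m.covars_[0] - resid.T @ resid / len(resid)
        ).max() < 1e-4

    def test_deterministic_transitions_constant_viterbi(self):
        rng = np.random.default_rng(2)
        m = random_model(rng, 3, 1, 1)
        m.transmat_ = np.eye(3) * (1 - 1e-12) + 1e-12 / 3
        x = rng.normal(0, 1, (10, 1))
        path = m.predict(x)
        assert np.all(path == path[0])

    def test_loglik_monotone_across_iterations(self):
        gen = planted_model()
        x, _ = gen.sample(400, seed=3)
        # pure maximum-likelihood EM (no sticky prior, which would make
        # the tracked data likelihood a penalized objective)
        fit = ARHMM(n_states=3, ar_order=1, n_restarts=1, random_state=0,
                    sticky_kappa=0.0).fit([x])
        h = np.array(fit.history_)
        assert np.all(np.diff(h) >= -1e-8 * np.maximum(1.0, np.abs(h[1:])))

    def test_viterbi_rejects_short_sequence(self):
        m = planted_model()
        with pytest.raises(ValueError):
            m.predict(np.zeros((1, 2)))


class TestARHMMRecovery:
    def test_planted_three_state_recovery(self):
        gen = planted_model()
        x, z = gen.sample(1500, seed=1)
        fit = ARHMM(n_states=3, ar_order=1, n_restarts=3, random_state=0).fit([x])
        acc = best_state_accuracy(fit.predict(x), z[1:], 3)
        assert acc >= 0.90

    def test_transition_matrix_recovered_in_total_variation(self):
        gen = planted_model()
        x, z = gen.sample(5000, seed=2)
        fit = ARHMM(n_states=3, ar_order=1, n_restarts=3, random_state=0).fit([x])
        path = fit.predict(x)
        perm = max(
            itertools.permutations(range(3)),
            key=lambda p: np.mean(np.asarray(p)[path] == z[1:]),
        )
        inv = np.argsort(perm)
        tv = 0.5 * np.abs(fit.transmat_[np.ix_(inv, inv)] - gen.transmat_).sum(axis=1)
        assert tv.max() < 0.1

    def test_all_restart_failures_raise(self):
        x = np.zeros((50, 2))  # degenerate: zero-variance data
        with pytest.raises((FitError, ValueError)):
            ARHMM(n_states=2, ar_order=1, n_restarts=2, ridge=0.0).fit([x])


class TestStateProfiles:
    def test_single_trial_single_state_profile_ones(self):
        gen = planted_model()
        x, _ = gen.sample(100, seed=0)
        m = ARHMM(n_states=1, ar_order=1, n_restarts=1).fit([x])
        post = m.posterior(x, relative_time_ms=np.arange(100) * 2.0)
        centers, prof = state_probability_profile([post], bin_ms=4.0)
        assert np.allclose(prof, 1.0)

    def test_profile_columns_stochastic(self, cohort_embeddings):
        _, embs = cohort_embeddings
        m = ARHMM(n_states=4, ar_order=1, n_restarts=1, max_iter=30,
                  random_state=0).fit([e.scores for e in embs[:8]])
        posts = [m.posterior(e.scores, e.relative_time_ms) for e in embs[:8]]
        _, prof = state_probability_profile(posts)
        assert np.abs(prof.sum(axis=0) - 1.0).max() < 1e-9

    def test_modal_state_switches_between_propulsion_and_flight(
        self, cohort_embeddings
    ):
        """A propulsive state engages before takeoff and gives way to a
        different state during flight (checked over several fit seeds)."""
        _, embs = cohort_embeddings
        sub = embs[:12]
        switches = 0
        for seed in range(3):
            m = ARHMM(n_states=6, ar_order=1, n_restarts=3, max_iter=100,
                      random_state=seed).fit([e.scores for e in sub])
            posts = [m.posterior(e.scores, e.relative_time_ms) for e in sub]
            centers, prof = state_probability_profile(posts)
            prop = (centers >= -50) & (centers < -10)
            fly = (centers >= 20) & (centers < 70)
            switches += int(np.argmax(prof[:, prop].sum(1))) != int(
                np.argmax(prof[:, fly].sum(1))
            )
        assert switches >= 2


class TestRobustnessScan:
    def test_same_setting_twice_perfect_agreement(self, cohort_embeddings):
        _, embs = cohort_embeddings
        scan = robustness_scan(
            embs[:6], k_grid=(3, 3), p_grid=(1,), seeds=(0,),
            n_restarts=1, max_iter=20,
        )
        assert scan["ari_matrix"][0, 1] == pytest.approx(1.0)

    def test_planted_data_scan_agreement(self):
        gen = planted_model()
        seqs = []
        times = []
        for s in range(4):
            x, _ = gen.sample(400, seed=s)
            seqs.append(x)
            times.append(np.arange(400) * 2.0 - 100.0)
        from gapcross.posture import PostureEmbedding

        embs = [
            PostureEmbedding(scores=x, relative_time_ms=t, trial_id=str(i))
            for i, (x, t) in enumerate(zip(seqs, times))
        ]
        scan = robustness_scan(
            embs, k_grid=(3, 4, 5), p_grid=(1,), seeds=(0,),
            n_restarts=2, max_iter=50,
        )
        assert scan["mean_pairwise_ari"] >= 0.7

    def test_empty_grid_rejected(self, cohort_embeddings):
        _, embs = cohort_embeddings
        with pytest.raises(ValueError):
            robustness_scan(embs, k_grid=(), p_grid=(1,), seeds=(0,))
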