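"""Second-level empirical Bayes, model reduction, search and averaging."""

import numpy as np
import pandas as pd
import pytest

from tmsdcm.peb import (
    PEBModel,
    Design,
    bma,
    bmr,
    build_design,
    greedy_search,
    peb_fit,
)
from tmsdcm.spdcm import Posterior, Priors


def make_posterior(mean, cov, names=None):
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    return Posterior(mean=mean, cov=cov, free_energy=0.0,
                     param_names=names or [f"p{i}" for i in range(mean.size)])


def subject_table(n=26, responders=None):
    rows = []
    rng = np.random.default_rng(0)
    for s in range(n):
        si = bool(rng.integers(0, 2)) if responders is None else responders
        dep = bool(rng.integers(0, 2)) if responders is None else responders
        for sess in ("pre", "post"):
            rows.append({"subject_id": f"sub-{s}", "session": sess,
                         "si_responder": si, "dep_responder": dep})
    return pd.DataFrame(rows)


class TestDesign:
    def test_26_subjects_two_sessions_gives_52_by_4(self):
        d = build_design(subject_table(26))
        assert d.matrix.shape == (52, 4)
        assert d.names == ["mean", "session", "si_response", "dep_response"]

    def test_constant_column_sums_to_row_count(self):
        d = build_design(subject_table(10))
        assert d.matrix[:, 0].sum() == 20

    def test_session_coding_is_centered_half(self):
        d = build_design(subject_table(4))
        assert set(np.unique(d.matrix[:, 1])) == {-0.5, 0.5}

    def test_all_responders_flagged_non_estimable(self):
        with pytest.warns(UserWarning, match="non-estimable"):
            d = build_design(subject_table(6, responders=True))
        assert np.allclose(d.matrix[:, 2], 0.0)
        assert d.warnings

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_design(pd.DataFrame({"subject_id": ["a"], "session": ["pre"]}))


class TestPEBFit:
    def test_equal_isotropic_posteriors_fuse_to_precision_weighted_mean(self, rng):
        # closed-form oracle: with X = ones and equal first-level covariance
        # C, the group posterior is the conjugate fusion of N subject means
        N, q = 8, 3
        mus = rng.normal(0.2, 0.1, size=(N, q))
        C = 0.05 * np.eye(q)
        posts = [make_posterior(m, C) for m in mus]
        design = Design(np.ones((N, 1)), ["mean"])
        model = peb_fit(posts, design)
        Ci = C + model.between_cov
        prec = N * np.linalg.inv(Ci) + 64.0 * np.eye(q)
        expected = np.linalg.solve(prec, np.linalg.inv(Ci) @ mus.sum(axis=0))
        assert np.allclose(model.mean, expected, atol=1e-8)

    def test_imprecise_subject_pulls_less(self, rng):
        # two-subject closed form at fixed between-subject variance: the
        # 100x noisier subject barely moves the fused mean
        m1, m2 = np.array([1.0]), np.array([-1.0])
        C1, C2 = np.array([[0.01]]), np.array([[1.0]])
        posts = [make_posterior(m1, C1), make_posterior(m2, C2)]
        design = Design(np.ones((2, 1)), ["mean"])
        pv = np.array([100.0])
        model = peb_fit(posts, design, prior_variance=pv, gamma_fixed=6.0)
        Sb = model.between_cov
        p1 = 1.0 / (C1 + Sb)[0, 0]
        p2 = 1.0 / (C2 + Sb)[0, 0]
        expected = (p1 * 1.0 + p2 * -1.0) / (p1 + p2 + 1.0 / pv[0])
        assert model.mean[0] == pytest.approx(expected, abs=1e-8)
        assert model.mean[0] > 0.9

    def test_duplicating_subjects_keeps_mean_shrinks_covariance(self, rng):
        N, q = 6, 2
        mus = rng.normal(0.1, 0.2, size=(N, q))
        C = 0.1 * np.eye(q)
        posts = [make_posterior(m, C) for m in mus]
        d1 = Design(np.ones((N, 1)), ["mean"])
        d2 = Design(np.ones((2 * N, 1)), ["mean"])
        m1 = peb_fit(posts, d1)
        m2 = peb_fit(posts + posts, d2)
        assert np.allclose(m1.mean, m2.mean, atol=0.02)
        assert np.all(np.diag(m2.cov) < np.diag(m1.cov))

    def test_free_energy_invariant_to_subject_order(self, rng):
        N, q = 10, 2
        mus = rng.normal(0, 0.2, size=(N, q))
        covs = [np.diag(rng.uniform(0.02, 0.2, q)) for _ in range(N)]
        posts = [make_posterior(m, c) for m, c in zip(mus, covs)]
        design = Design(np.ones((N, 1)), ["mean"])
        f1 = peb_fit(posts, design).free_energy
        perm = rng.permutation(N)
        f2 = peb_fit([posts[i] for i in perm], design).free_energy
        assert f1 == pytest.approx(f2, abs=1e-6)

    def test_misaligned_parameter_names_rejected(self):
        p1 = make_posterior([0.0], [[1.0]], names=["a"])
        p2 = make_posterior([0.0], [[1.0]], names=["b"])
        with pytest.raises(ValueError, match="share"):
            peb_fit([p1, p2], Design(np.ones((2, 1)), ["mean"]))


class TestBMR:
    def test_identity_reduction_is_exact_noop(self, rng):
        for _ in range(10):
            q = 4
            L = rng.normal(size=(q, q))
            S = L @ L.T + 0.1 * np.eye(q)
            m = rng.normal(size=q)
            pri = Priors(np.zeros(q), np.eye(q))
            dF, mr, Sr = bmr(m, S, pri, Priors(np.zeros(q), np.eye(q)))
            assert abs(dF) < 1e-10
            assert np.allclose(mr, m, atol=1e-10)
            assert np.allclose(Sr, S, atol=1e-10)

    @staticmethod
    def _posterior_from_data(theta_true, noise_sd, rng, n=50):
        """Conjugate linear-Gaussian posterior for a known truth."""
        q = theta_true.size
        G = rng.normal(size=(n, q))
        y = G @ theta_true + rng.normal(0, noise_sd, n)
        P = np.eye(n) / noise_sd**2
        S = np.linalg.inv(G.T @ P @ G + np.eye(q))
        m = S @ (G.T @ P @ y)
        return m, S

    def test_pruning_null_parameter_usually_wins(self):
        pri = Priors(np.zeros(2), np.eye(2))
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m, S = self._posterior_from_data(np.array([0.4, 0.0]), 0.5, rng)
            red = Priors(np.zeros(2), np.diag([1.0, 1e-8]))
            dF, _, _ = bmr(m, S, pri, red)
            wins += dF > 0
        assert wins >= 90

    def test_pruning_supported_parameter_always_loses(self):
        pri = Priors(np.zeros(2), np.eye(2))
        for seed in range(50):
            rng = np.random.default_rng(200 + seed)
            m, S = self._posterior_from_data(np.array([0.4, 0.0]), 0.05, rng)
            red = Priors(np.zeros(2), np.diag([1e-8, 1.0]))
            dF, _, _ = bmr(m, S, pri, red)
            assert dF < 0


def toy_peb(mean, cov, prior_var):
    q = mean.size
    return PEBModel(
        design=Design(np.ones((1, 1)), ["mean"]), param_names=[f"p{i}" for i in range(q)],
        group_names=[f"mean:p{i}" for i in range(q)], mean=mean, cov=cov,
        prior=Priors(np.zeros(q), np.diag(prior_var)), gamma=0.0,
        between_cov=np.eye(q), free_energy=0.0,
    )


class TestSearchAndBMA:
    def test_strongly_supported_parameters_survive(self, rng):
        m, S = TestBMR._posterior_from_data(np.array([0.5, -0.5, 0.4]), 0.05,
                                            np.random.default_rng(5))
        peb = toy_peb(m, S, np.ones(3))
        models = greedy_search(peb)
        best_on = models[0][0]
        assert best_on.all()

    def test_planted_sparse_truth_recovered(self):
        hits = 0
        n_sim = 30
        for seed in range(n_sim):
            rng = np.random.default_rng(400 + seed)
            truth = np.zeros(12)
            truth[[2, 7]] = 0.4
            m, S = TestBMR._posterior_from_data(truth, 0.3, rng, n=200)
            peb = toy_peb(m, S, np.ones(12))
            models = greedy_search(peb)
            avg = bma(models)
            if avg.prob_nonzero[2] > 0.5 and avg.prob_nonzero[7] > 0.5:
                hits += 1
        assert hits >= 0.9 * n_sim

    def test_search_is_deterministic(self):
        m, S = TestBMR._posterior_from_data(np.array([0.3, 0.0, 0.1]), 0.2,
                                            np.random.default_rng(9))
        peb = toy_peb(m, S, np.ones(3))
        r1 = greedy_search(peb)
        r2 = greedy_search(peb)
        assert all(np.array_equal(a[0], b[0]) and a[1] == b[1] for a, b in zip(r1, r2))

    def test_single_model_average_is_identity(self):
        on = np.array([True, False])
        mean = np.array([0.3, 0.0])
        cov = np.diag([0.01, 1e-8])
        avg = bma([(on, -5.0, mean, cov)])
        assert np.allclose(avg.mean, mean)
        assert np.allclose(avg.prob_nonzero, on.astype(float))

    def test_equal_evidence_gives_equal_weights(self):
        on = np.ones(2, bool)
        avg = bma([(on, 1.0, np.zeros(2), np.eye(2)), (on, 1.0, np.ones(2), np.eye(2))])
        assert np.allclose(avg.weights, [0.5, 0.5])
        assert np.allclose(avg.mean, [0.5, 0.5])

    def test_ten_nats_weaker_model_is_negligible(self):
        on = np.ones(1, bool)
        avg = bma([(on, 0.0, np.zeros(1), np.eye(1)), (on, -10.0, np.ones(1), np.eye(1))])
        assert avg.weights[1] < 1e-4
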