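import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.special import multigammaln

from braindyn.hmm import (
    HMMModel,
    VariationalGaussianHMM,
    _gaussian_loglik,
    fit_hmm,
    forward_backward,
    select_n_states,
    viterbi,
)
from braindyn.simulate import SimulationConfig

from conftest import build_cohort, truth_state_means


def enumerate_posteriors(logb, log_a, log_pi):
    """Brute-force hidden-path posterior by summing over all K^T paths."""
    T, K = logb.shape
    total = 0.0
    gamma = np.zeros((T, K))
    xi = np.zeros((K, K))
    for path in itertools.product(range(K), repeat=T):
        lp = log_pi[path[0]] + logb[0, path[0]]
        for t in range(1, T):
            lp += log_a[path[t - 1], path[t]] + logb[t, path[t]]
        p = np.exp(lp)
        total += p
        for t in range(T):
            gamma[t, path[t]] += p
        for t in range(1, T):
            xi[path[t - 1], path[t]] += p
    return gamma / total, xi / total, np.log(total)


class TestForwardBackward:
    @pytest.mark.parametrize("trial", range(8))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        K = int(rng.integers(1, 4))
        T = int(rng.integers(2, 7))
        logb = rng.normal(size=(T, K))
        # sub-normalized parameters, as produced by expected-log posteriors
        log_a = np.log(rng.dirichlet(np.ones(K), size=K)) - rng.uniform(0, 0.3)
        log_pi = np.log(rng.dirichlet(np.ones(K))) - rng.uniform(0, 0.3)
        gamma, xi, log_norm = forward_backward(logb, log_a, log_pi)
        g0, x0, l0 = enumerate_posteriors(logb, log_a, log_pi)
        np.testing.assert_allclose(gamma, g0, atol=1e-10)
        np.testing.assert_allclose(xi, x0, atol=1e-10)
        assert log_norm == pytest.approx(l0, abs=1e-10)

    def test_single_state_degenerates_to_density_sum(self):
        logb = np.array([[-1.0], [-2.0], [-0.5]])
        gamma, xi, log_norm = forward_backward(logb, np.zeros((1, 1)), np.zeros(1))
        np.testing.assert_array_equal(gamma, 1.0)
        assert xi[0, 0] == pytest.approx(2.0)
        assert log_norm == pytest.approx(logb.sum())

    def test_symmetric_inputs_give_uniform_gamma(self):
        K, T = 3, 5
        logb = np.tile(np.linspace(-1, 1, T)[:, None], (1, K))
        log_a = np.full((K, K), np.log(1 / K))
        log_pi = np.full(K, np.log(1 / K))
        gamma, _, _ = forward_backward(logb, log_a, log_pi)
        np.testing.assert_allclose(gamma, 1 / K, atol=1e-12)

    def test_rejects_non_finite_densities(self):
        with pytest.raises(ValueError, match="finite"):
            forward_backward(
                np.array([[np.nan, 0.0]]), np.zeros((2, 2)), np.zeros(2)
            )

    def test_gamma_rows_and_counts_mass(self):
        rng = np.random.default_rng(9)
        logb = rng.normal(size=(20, 4))
        log_a = np.log(rng.dirichlet(np.ones(4), size=4))
        log_pi = np.log(rng.dirichlet(np.ones(4)))
        gamma, xi, _ = forward_backward(logb, log_a, log_pi)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
        assert xi.sum() == pytest.approx(19.0, abs=1e-8)


class TestViterbi:
    def test_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(0)
        K, T, R = 2, 4, 3
        model = HMMModel(
            K=K,
            means=rng.normal(size=(K, R)),
            covariances=np.stack([np.eye(R)] * K),
            transition=rng.dirichlet(np.ones(K), size=K),
            initial=rng.dirichlet(np.ones(K)),
        )
        X = rng.normal(size=(T, R))
        logb = _gaussian_loglik(X, model.means, model.covariances)
        best, best_lp = None, -np.inf
        for p in itertools.product(range(K), repeat=T):
            lp = np.log(model.initial[p[0]]) + logb[0, p[0]]
            for t in range(1, T):
                lp += np.log(model.transition[p[t - 1], p[t]]) + logb[t, p[t]]
            if lp > best_lp:
                best_lp, best = lp, p
        assert tuple(viterbi(model, X)) == best

    def test_identity_transition_gives_constant_path(self):
        K, R = 3, 2
        model = HMMModel(
            K=K,
            means=np.array([[0.0, 0], [5, 5], [-5, -5]]),
            covariances=np.stack([np.eye(R)] * K),
            transition=np.eye(K),
            initial=np.array([0.2, 0.5, 0.3]),
        )
        X = np.vstack([[5, 5]] * 3 + [[-5, -5]] * 3)
        path = viterbi(model, X)
        assert len(set(path)) == 1

    def test_noiseless_emissions_recover_generating_path(self):
        rng = np.random.default_rng(1)
        K, R = 3, 4
        means = rng.normal(size=(K, R)) * 3
        model = HMMModel(
            K=K,
            means=means,
            covariances=np.stack([np.eye(R)] * K),
            transition=np.full((K, K), 1 / K),
            initial=np.full(K, 1 / K),
        )
        true_path = rng.integers(0, K, size=30)
        path = viterbi(model, means[true_path])
        np.testing.assert_array_equal(path, true_path)


class TestVBFit:
    def test_free_energy_monotone_on_fixture(self, small_cohort):
        _, _, dataset, _ = small_cohort
        est = VariationalGaussianHMM(n_states=3, n_restarts=2, random_state=0)
        est.fit(dataset)
        trace = np.array(est.free_energy_trace_)
        assert np.all(np.diff(trace) <= 1e-6)

    def test_k1_free_energy_matches_closed_form_evidence(self, small_cohort):
        """With one state the variational posterior is exact, so -F must
        equal the Normal-Inverse-Wishart log marginal likelihood."""
        _, _, dataset, _ = small_cohort
        X = dataset.data[:150]
        est = VariationalGaussianHMM(
            n_states=1, n_restarts=1, random_state=0, cov_reg=0.0
        ).fit(X, [150])
        N, R = X.shape
        kappa0, nu0 = 1.0, R + 2.0
        m0 = X.mean(axis=0)
        Psi0 = np.cov(X, rowvar=False, ddof=1)
        xbar = X.mean(axis=0)
        S = (X - xbar).T @ (X - xbar)
        d0 = (xbar - m0)[:, None]
        kN, nuN = kappa0 + N, nu0 + N
        PsiN = Psi0 + S + (kappa0 * N / kN) * (d0 @ d0.T)

        def logdet(M):
            return np.linalg.slogdet(M)[1]

        log_ml = (
            -(N * R / 2) * np.log(np.pi)
            + multigammaln(nuN / 2, R)
            - multigammaln(nu0 / 2, R)
            + (nu0 / 2) * logdet(Psi0)
            - (nuN / 2) * logdet(PsiN)
            + (R / 2) * np.log(kappa0 / kN)
        )
        assert est.free_energy_ == pytest.approx(-log_ml, abs=1e-5)

    def test_duplicating_data_doubles_evidence_terms(self, small_cohort):
        """Holding the fitted posterior fixed, the data-dependent free-energy
        term (the summed segment evidence contributions) is additive, so an
        exact duplicate of the dataset doubles it while the parameter KL
        penalty stays put: F(X, X) = F(X) - L(X) with L = KL - F."""
        from braindyn.hmm import _kl_total

        _, _, dataset, _ = small_cohort
        X = dataset.data[:80]
        est = VariationalGaussianHMM(n_states=2, n_restarts=1, random_state=0)
        est.fit(X, [80])
        f_single = est.free_energy(X, [80])
        kl = _kl_total(est.posterior_, est.priors_, est.cov_reg)
        evidence_term = kl - f_single
        f_double = est.free_energy(np.vstack([X, X]), [80, 80])
        assert f_double == pytest.approx(f_single - evidence_term, rel=1e-10)

    def test_fit_is_deterministic_given_seed(self, small_cohort):
        _, _, dataset, _ = small_cohort
        a = VariationalGaussianHMM(n_states=3, n_restarts=2, random_state=5).fit(dataset)
        b = VariationalGaussianHMM(n_states=3, n_restarts=2, random_state=5).fit(dataset)
        np.testing.assert_array_equal(a.means_, b.means_)
        np.testing.assert_array_equal(a.transmat_, b.transmat_)
        assert a.free_energy_trace_ == b.free_energy_trace_

    def test_label_permutation_equivariance(self, small_cohort):
        """Permuting the initial responsibilities permutes the fitted model."""
        _, _, dataset, _ = small_cohort
        X = dataset.data
        est = VariationalGaussianHMM(n_states=3, max_iter=20)
        priors = est._make_priors(X)
        resp = est.init_responsibilities(X, seed=0)
        perm = np.array([2, 0, 1])
        state_a, _, _ = est._fit_single(X, dataset.boundaries, resp, priors)
        state_b, _, _ = est._fit_single(X, dataset.boundaries, resp[:, perm], priors)
        np.testing.assert_allclose(
            state_a.posterior.m, state_b.posterior.m[np.argsort(perm)][..., :], atol=1e-8
        )
        assert state_a.free_energy_trace[-1] == pytest.approx(
            state_b.free_energy_trace[-1], abs=1e-6
        )

    def test_recovers_planted_states(self, small_cohort):
        manifest, _, dataset, truth = small_cohort
        model, est = fit_hmm(dataset, 3, n_restarts=3, random_state=1)
        tm = truth_state_means(dataset, truth, manifest, 3)
        C = np.corrcoef(np.vstack([model.means, tm]))[:3, 3:]
        ri, ci = linear_sum_assignment(-C)
        assert C[ri, ci].min() > 0.95

    def test_decoded_path_matches_partition_when_separated(self):
        """With well-separated emission clusters the decoded labels
        reproduce the generating partition almost exactly."""
        cfg = SimulationConfig(
            k_true=2, n_regions=5, n_timepoints=150, n_patients=3, n_controls=3,
            state_mean_scale=4.0, control_stickiness=0.9, patient_stickiness=0.9,
            suppression_factor=1.0, suppressed_states=(),
            covariate_target_state=1, seed=42,
        )
        manifest, _, dataset, truth = build_cohort(cfg)
        model, est = fit_hmm(dataset, 2, n_restarts=2, random_state=0)
        tm = truth_state_means(dataset, truth, manifest, 2)
        C = np.corrcoef(np.vstack([model.means, tm]))[:2, 2:]
        ri, ci = linear_sum_assignment(-C)
        perm = np.empty(2, dtype=int)
        perm[ri] = ci
        decoded = perm[est.predict(dataset)]
        z = np.concatenate([truth.paths[sid] for sid in manifest.subject_ids])
        assert (decoded == z).mean() > 0.95

    def test_gamma_rows_sum_to_one(self, small_cohort):
        _, _, dataset, _ = small_cohort
        est = VariationalGaussianHMM(n_states=3, n_restarts=1, random_state=0)
        est.fit(dataset)
        gamma = est.predict_proba(dataset)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
        counts = est.vb_state_.trans_counts
        lengths = [e - s for s, e in dataset.boundaries]
        np.testing.assert_allclose(
            counts.sum(axis=(1, 2)), np.array(lengths) - 1, atol=1e-8
        )

    def test_transition_error_shrinks_with_scan_length(self):
        """Median matched transition-matrix error is non-increasing in T."""
        errors = []
        for T in (100, 200, 400):
            errs = []
            for seed in range(3):
                cfg = SimulationConfig(
                    k_true=3, n_regions=6, n_timepoints=T,
                    n_patients=5, n_controls=5,
                    control_stickiness=0.9, patient_stickiness=0.9,
                    suppression_factor=1.0, suppressed_states=(),
                    covariate_target_state=1, seed=100 + seed,
                )
                manifest, _, dataset, truth = build_cohort(cfg)
                model, _ = fit_hmm(dataset, 3, n_restarts=2, random_state=seed)
                tm = truth_state_means(dataset, truth, manifest, 3)
                C = np.corrcoef(np.vstack([model.means, tm]))[:3, 3:]
                ri, ci = linear_sum_assignment(-C)
                perm = np.empty(3, dtype=int)
                perm[ci] = ri
                A = model.transition[np.ix_(perm, perm)]
                errs.append(
                    np.abs(A - truth.model_per_group["control"].transition).max()
                )
            errors.append(np.median(errs))
        assert errors[2] <= errors[0] + 1e-9


class TestSelectK:
    def test_singleton_grid(self, small_cohort):
        _, _, dataset, _ = small_cohort
        report = select_n_states(dataset, [7], n_restarts=1, random_state=0)
        assert report.selected_k == 7

    def test_report_fields(self, small_cohort):
        _, _, dataset, _ = small_cohort
        report = select_n_states(
            dataset, [2, 3, 4], n_restarts=1, random_state=0
        )
        assert report.selected_k in (2, 3, 4)
        assert len(report.free_energy) == 3
        assert all(np.isfinite(report.free_energy))
        assert "selected" in report.rule_trace
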