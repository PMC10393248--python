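"""SupCP factorization: recovery, EM ascent, marginal likelihood oracle."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from tensoreeg.simulate import TensorSimSpec, simulate_supcp_tensor
from tensoreeg.supcp import (
    SupCPModel,
    cp_reconstruct,
    extract_factor_report,
    factor_congruence,
    fit_supcp,
    marginal_log_likelihood,
)


def make_sim(n=40, dims=(8, 6, 4), rank=3, score_sd=1.0, noise_sd=0.0, seed=3,
             b_scale=2.0):
    rng = np.random.default_rng(seed + 100)
    return TensorSimSpec(
        n_participants=n, mode_dims=dims, rank=rank,
        coeff_matrix=b_scale * rng.standard_normal((1, rank)),
        score_sd=score_sd, noise_sd=noise_sd, seed=seed,
    )


def dense_marginal_oracle(model: SupCPModel, x_i, y_i) -> float:
    """Materialize the full mean vector and covariance matrix explicitly."""
    factors = model.factor_matrices
    cols = []
    for r in range(model.rank):
        w = factors[0][:, r]
        for v in factors[1:]:
            w = np.kron(w, v[:, r])
        cols.append(w)
    w_mat = np.stack(cols, axis=1)
    mu = w_mat @ (np.atleast_1d(y_i) @ model.coeff_matrix)
    cov = w_mat @ np.diag(model.score_var) @ w_mat.T + model.noise_var * np.eye(w_mat.shape[0])
    return float(multivariate_normal(mean=mu, cov=cov).logpdf(np.asarray(x_i).ravel()))


class TestFit:
    def test_noiseless_rank3_recovery(self):
        """Loadings and the low-rank part are recovered from clean data."""
        tensor, sup, truth = simulate_supcp_tensor(make_sim())
        model = fit_supcp(tensor, sup, R=3, tol=1e-8, max_iter=400, seed=0, n_starts=3)
        rec = model.low_rank()
        rel = np.linalg.norm(rec - tensor.array) / np.linalg.norm(tensor.array)
        assert rel < 1e-3
        for k in range(3):
            cong, _ = factor_congruence(truth.factor_matrices[k], model.factor_matrices[k])
            assert cong > 0.99

    @pytest.mark.parametrize("seed", range(10))
    def test_em_loglik_nondecreasing(self, seed):
        """EM ascent across random small specs."""
        rng = np.random.default_rng(seed)
        spec = make_sim(
            n=int(rng.integers(10, 25)),
            dims=(int(rng.integers(3, 6)), int(rng.integers(3, 6)), int(rng.integers(3, 6))),
            rank=int(rng.integers(1, 3)),
            noise_sd=float(rng.uniform(0.1, 0.8)),
            seed=seed,
        )
        tensor, sup, _ = simulate_supcp_tensor(spec)
        model = fit_supcp(tensor, sup, R=spec.rank, tol=1e-8, max_iter=120, seed=seed)
        diffs = np.diff(model.loglik_trace)
        floor = -1e-8 * np.maximum(np.abs(model.loglik_trace[:-1]), 1.0)
        assert np.all(diffs >= floor)

    def test_noise_variance_recovered(self):
        """Moderate-SNR fit estimates sigma^2 within 20%."""
        spec = make_sim(n=100, noise_sd=0.5, seed=7)
        tensor, sup, _ = simulate_supcp_tensor(spec)
        model = fit_supcp(tensor, sup, R=3, tol=1e-7, max_iter=300, seed=0)
        assert abs(model.noise_var - 0.25) / 0.25 < 0.2

    def test_two_seeds_agree_on_well_separated_factors(self):
        """Identifiability: refits recover the same factor set."""
        spec = make_sim(n=50, rank=2, noise_sd=0.0, seed=9)
        tensor, sup, _ = simulate_supcp_tensor(spec)
        m1 = fit_supcp(tensor, sup, R=2, tol=1e-9, max_iter=400, seed=1, n_starts=3)
        m2 = fit_supcp(tensor, sup, R=2, tol=1e-9, max_iter=400, seed=2, n_starts=3)
        for k in range(3):
            cong, _ = factor_congruence(m1.factor_matrices[k], m2.factor_matrices[k])
            assert cong > 0.99

    def test_intercept_only_coefficients_are_score_means(self):
        """With a lone intercept column, B reduces to per-factor score means."""
        spec = make_sim(n=60, noise_sd=0.3, seed=4)
        tensor, _, _ = simulate_supcp_tensor(spec)
        model = fit_supcp(tensor, None, R=3, tol=1e-7, max_iter=200, seed=0)
        np.testing.assert_allclose(
            model.coeff_matrix[0], model.scores.mean(axis=0), rtol=1e-4, atol=1e-6
        )

    def test_infeasible_rank_errors(self):
        tensor, sup, _ = simulate_supcp_tensor(make_sim(n=10, dims=(3, 3, 3), rank=2))
        with pytest.raises(ValueError, match="infeasible"):
            fit_supcp(tensor, sup, R=28)


class TestMarginalLikelihood:
    @pytest.mark.parametrize("dims,rank", [((2, 2, 2), 1), ((3, 2, 2), 2), ((3, 3, 3), 2)])
    def test_equals_dense_gaussian_oracle(self, dims, rank):
        spec = make_sim(n=12, dims=dims, rank=rank, score_sd=0.7, noise_sd=0.3, seed=5)
        tensor, sup, _ = simulate_supcp_tensor(spec)
        model = fit_supcp(tensor, sup, R=rank, tol=1e-7, max_iter=150, seed=0)
        for i in range(3):
            ours = marginal_log_likelihood(model, tensor.array[i], sup.Y[i])
            oracle = dense_marginal_oracle(model, tensor.array[i], sup.Y[i])
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_factor_permutation_invariance(self):
        spec = make_sim(n=15, dims=(3, 3, 3), rank=2, noise_sd=0.4, seed=6)
        tensor, sup, _ = simulate_supcp_tensor(spec)
        model = fit_supcp(tensor, sup, R=2, tol=1e-7, max_iter=100, seed=0)
        permuted = model.permuted(np.array([1, 0]))
        a = marginal_log_likelihood(model, tensor.array[0], sup.Y[0])
        b = marginal_log_likelihood(permuted, tensor.array[0], sup.Y[0])
        assert a == pytest.approx(b, abs=1e-10)

    def test_exponent_is_finite_positive_likelihood(self):
        spec = make_sim(n=10, dims=(2, 2, 2), rank=1, noise_sd=0.5, seed=8)
        tensor, sup, _ = simulate_supcp_tensor(spec)
        model = fit_supcp(tensor, sup, R=1, tol=1e-7, max_iter=100, seed=0)
        lik = np.exp(marginal_log_likelihood(model, tensor.array[0], sup.Y[0]))
        assert np.isfinite(lik) and lik > 0

    def test_dimension_mismatch_errors(self):
        spec = make_sim(n=10, dims=(2, 2, 2), rank=1)
        tensor, sup, _ = simulate_supcp_tensor(spec)
        model = fit_supcp(tensor, sup, R=1, max_iter=30, seed=0)
        with pytest.raises(ValueError, match="shape"):
            marginal_log_likelihood(model, np.zeros((3, 2, 2)), sup.Y[0])


class TestFactorReport:
    def _model_with_scores(self, scores):
        r = scores.shape[1]
        return SupCPModel(
            rank=r,
            factor_matrices=[np.eye(4)[:, :r] for _ in range(3)],
            coeff_matrix=np.zeros((1, r)),
            score_var=np.ones(r),
            noise_var=1.0,
            scores=scores,
            loglik_trace=np.empty(0),
        )

    def test_perfect_age_factor_ranks_first(self):
        rng = np.random.default_rng(0)
        ages = np.array([1, 3, 5, 7] * 5, dtype=float)
        scores = np.column_stack([rng.standard_normal(20), ages, rng.standard_normal(20)])
        report = extract_factor_report(self._model_with_scores(scores), ages)
        assert report.factor_index[0] == 1
        assert report.r[0] == pytest.approx(1.0)

    def test_retention_threshold(self):
        rng = np.random.default_rng(1)
        ages = np.linspace(0, 1, 40)
        weak = rng.standard_normal(40) * 5 + 0.01 * ages
        scores = np.column_stack([ages, weak])
        report = extract_factor_report(self._model_with_scores(scores), ages)
        assert bool(report.retained[0]) is True
        assert np.all(np.abs(report.r[~report.retained]) <= 0.2)

    def test_constant_factor_flagged_zero(self):
        ages = np.linspace(0, 1, 10)
        scores = np.column_stack([np.ones(10), ages])
        report = extract_factor_report(self._model_with_scores(scores), ages)
        assert report.flags and "constant" in report.flags[0]
        assert 0.0 in np.round(report.r, 12)


def test_cp_reconstruct_matches_outer_products():
    rng = np.random.default_rng(2)
    u = rng.standard_normal((5, 2))
    factors = [rng.standard_normal((3, 2)), rng.standard_normal((4, 2))]
    direct = np.zeros((5, 3, 4))
    for r in range(2):
        direct += u[:, r, None, None] * np.multiply.outer(factors[0][:, r], factors[1][:, r])
    np.testing.assert_allclose(cp_reconstruct(u, factors), direct, atol=1e-12)
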