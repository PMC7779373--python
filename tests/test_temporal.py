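"""HRF kernel contract, time-course updates, and the netmat hierarchy."""

import numpy as np
import pytest

from pfmlab import temporal as tm
from pfmlab.datasets import ConfigurationError
from helpers import gamma_posterior_is, wishart_posterior_mean_is


def make_run(m, t, tr=2.0, seed=0):
    rng = np.random.default_rng(seed)
    kern = tm.build_hrf_kernel(t, tr)
    return tm.RunTemporalPosterior(
        B_eig_mean=rng.standard_normal((m, t)) * 0.1,
        B_cov=np.broadcast_to(0.01 * np.eye(m), (t, m, m)).copy(),
        xi_mean=rng.standard_normal((m, t)) * 0.05,
        xi_cov=0.01 * np.eye(m),
        omega_shape=np.full(m, 2.0),
        omega_rate=np.full(m, 2.0),
        kernel=kern,
    ), rng


class TestHRFKernel:
    @pytest.mark.parametrize("t,tr", [(1, 2.0), (10, 0.72), (64, 2.0), (200, 3.0)])
    def test_unit_diagonal_symmetric_toeplitz(self, t, tr):
        kern = tm.build_hrf_kernel(t, tr)
        k = kern.K
        assert k.shape == (t, t)
        assert np.allclose(np.diag(k), 1.0, atol=1e-12)
        assert np.allclose(k, k.T)
        # Toeplitz: constant along diagonals
        for off in range(1, min(t, 5)):
            assert np.allclose(np.diag(k, off), k[0, off])

    def test_t1_is_identity(self):
        assert tm.build_hrf_kernel(1, 2.0).K == pytest.approx(np.ones((1, 1)))

    def test_lag_autocorrelation_matches_fft_oracle(self):
        """Kernel entries equal the HRF autocorrelation computed by an
        independent FFT-based route."""
        tr = 2.0
        tgrid = np.arange(0.0, 256.0, tr)
        h = tm.canonical_hrf(tgrid)
        n = 4 * len(h)
        spec = np.abs(np.fft.rfft(h, n)) ** 2
        acf = np.fft.irfft(spec, n)[: len(h)]
        acf /= acf[0]
        kern = tm.build_hrf_kernel(16, tr)
        # jitter shifts lag-0 by 1e-8 before renormalisation
        assert np.allclose(kern.K[0, 1:8], acf[1:8], atol=1e-7)
        assert abs(kern.K[0, 1] - acf[1]) < 1e-7

    @pytest.mark.parametrize("t,tr", [(500, 0.5), (1200, 0.72), (2000, 3.0)])
    def test_positive_definite_for_long_runs(self, t, tr):
        kern = tm.build_hrf_kernel(t, tr)
        assert np.linalg.eigvalsh(kern.K).min() > 0

    def test_invalid_dimensions(self):
        with pytest.raises(ConfigurationError):
            tm.build_hrf_kernel(0, 2.0)
        with pytest.raises(ConfigurationError):
            tm.build_hrf_kernel(10, -1.0)


class TestTimecourseUpdate:
    def test_zero_data_weight_returns_prior_means(self):
        m, t = 3, 20
        run, rng = make_run(m, t)
        proj = rng.standard_normal((m, t))
        tm.update_timecourses(proj, np.eye(m), np.eye(m), run, E_psi=0.0)
        assert np.allclose(run.E_B, 0.0)
        assert np.allclose(run.xi_mean, 0.0)

    def test_reduces_to_ridge_for_identity_kernel(self):
        """With K = I and E[alpha] = I the B update is elementwise ridge."""
        m, t = 2, 15
        run, rng = make_run(m, t)
        run.kernel = tm.HRFKernel(K=np.eye(t), tr=2.0)
        run.xi_mean[:] = 0.0
        proj = rng.standard_normal((m, t))
        w = np.eye(m) * 3.0
        tm.update_timecourses(proj, w, np.eye(m), run, E_psi=2.0)
        ridge = 2.0 * proj / (1.0 + 2.0 * 3.0)
        assert np.allclose(run.E_B, ridge, atol=1e-10)

    def test_matches_dense_joint_gaussian_solve(self):
        """M=2, T=3: posterior mean and netmat statistic against a dense
        6-unknown Gaussian linear solve."""
        m, t = 2, 3
        run, rng = make_run(m, t)
        e_alpha = np.array([[2.0, 0.5], [0.5, 1.5]])
        w = np.array([[3.0, 0.8], [0.8, 2.0]])
        proj = rng.standard_normal((m, t))
        xi = run.xi_mean.copy()
        psi = 1.7
        tm.update_timecourses(proj, w, e_alpha, run, psi)

        kinv = np.linalg.inv(run.kernel.K)
        big = np.zeros((m * t, m * t))
        for i in range(m):
            for j in range(m):
                blk = slice(i * t, (i + 1) * t), slice(j * t, (j + 1) * t)
                big[blk] = e_alpha[i, j] * kinv + psi * w[i, j] * np.eye(t)
        rhs = (psi * (proj - w @ xi)).ravel()
        sol = np.linalg.solve(big, rhs).reshape(m, t)
        assert np.allclose(run.E_B, sol, atol=1e-8)

        cov = np.linalg.inv(big)
        stat = sol @ kinv @ sol.T
        for i in range(m):
            for j in range(m):
                blk = cov[i * t:(i + 1) * t, j * t:(j + 1) * t]
                stat[i, j] += np.sum(kinv * blk.T)
        assert np.allclose(run.B_kernel_stat(), stat, atol=1e-8)


class TestRunNetmat:
    def test_no_data_returns_prior(self):
        e_beta = np.array([[2.0, 0.3], [0.3, 1.0]])
        post = tm.update_run_netmat(np.zeros((2, 2)), 0, e_beta, a_alpha=3.0)
        assert post.dof == pytest.approx(3.0)
        assert np.allclose(post.rate, e_beta)

    def test_dof_is_prior_plus_timepoints(self):
        post = tm.update_run_netmat(np.eye(2), 57, np.eye(2), a_alpha=3.0)
        assert post.dof == pytest.approx(60.0)

    def test_posterior_mean_matches_sampling_oracle(self, rng):
        """2x2 conjugate pair: E[alpha] against importance sampling."""
        a_alpha = 4.0
        beta = np.array([[4.0, 1.0], [1.0, 3.0]])
        b = rng.standard_normal((2, 10))
        bbt = b @ b.T
        post = tm.update_run_netmat(bbt, 10, beta, a_alpha)

        def loglik(xs):
            s, logdet = np.linalg.slogdet(xs)
            return 0.5 * 10 * logdet - 0.5 * np.einsum("nij,ji->n", xs, bbt)

        oracle, se = wishart_posterior_mean_is(rng, a_alpha, beta, loglik,
                                               n=150_000)
        assert np.all(np.abs(post.mean - oracle) < 3 * se + 1e-9)


class TestGroupNetmat:
    def make_hyp(self, m=2):
        return tm.TemporalHyperpriors.default(m)

    def test_empty_family_rejected(self):
        with pytest.raises(ConfigurationError):
            tm.update_group_netmat({}, self.make_hyp(), {"all": []})

    def test_identical_runs_double_the_data_term(self):
        hyp = self.make_hyp()
        a = tm.WishartPosterior(dof=10.0, rate=5.0 * np.eye(2))
        one = tm.update_group_netmat({0: a}, hyp, {"all": [0]})
        two = tm.update_group_netmat({0: a, 1: a}, hyp, {"all": [0, 1]})
        assert np.allclose(two.for_family("all").rate - hyp.B_beta,
                           2.0 * (one.for_family("all").rate - hyp.B_beta))
        assert two.for_family("all").dof == pytest.approx(
            hyp.a_beta + 2 * hyp.a_alpha)

    def test_posterior_mean_matches_sampling_oracle(self, rng):
        hyp = tm.TemporalHyperpriors(a_alpha=5.0, a_beta=4.0,
                                     B_beta=np.array([[3.0, 0.5], [0.5, 2.0]]))
        alphas = {i: tm.WishartPosterior(20.0, 20.0 * np.linalg.inv(
            np.array([[1.0, 0.3], [0.3, 1.0]]) * (i + 1))) for i in range(2)}
        post = tm.update_group_netmat(alphas, hyp, {"all": [0, 1]}
                                      ).for_family("all")
        s = sum(a.mean for a in alphas.values())

        def loglik(xs):
            _, logdet = np.linalg.slogdet(xs)
            return 0.5 * 2 * hyp.a_alpha * logdet - 0.5 * np.einsum(
                "nij,ji->n", xs, s)

        oracle, se = wishart_posterior_mean_is(rng, hyp.a_beta, hyp.B_beta,
                                               loglik, n=150_000)
        assert np.all(np.abs(post.mean - oracle) < 3 * se + 1e-9)


class TestTimecourseNoise:
    def test_no_timepoints_returns_prior(self):
        run, _ = make_run(2, 5)
        run.xi_mean = np.zeros((2, 0))
        run.xi_cov = np.zeros((2, 2))
        run.B_eig_mean = np.zeros((2, 0))
        tm.update_timecourse_noise(run, tm.TemporalHyperpriors.default(2))
        assert np.allclose(run.omega_shape, 1.0)
        assert np.allclose(run.omega_rate, 1.0)

    def test_shape_and_sampling_oracle(self, rng):
        m, t = 1, 12
        run, _ = make_run(m, t, seed=3)
        hyp = tm.TemporalHyperpriors.default(m)
        hyp.a_omega, hyp.b_omega = 2.0, 1.5
        run.xi_cov = np.zeros((1, 1))
        tm.update_timecourse_noise(run, hyp)
        assert run.omega_shape[0] == pytest.approx(2.0 + t / 2)
        xi_sq = float(np.sum(run.xi_mean ** 2))

        def loglik(x):
            return 0.5 * t * np.log(x) - 0.5 * x * xi_sq

        est = run.omega_shape[0] / run.omega_rate[0]
        oracle, se = gamma_posterior_is(rng, 2.0, 1.5, loglik, lambda x: x)
        assert abs(est - oracle) < 3 * se


class TestFABT:
    def test_pure_clean_and_balanced_power(self):
        run, _ = make_run(2, 8)
        run.B_cov[:] = 0.0
        run.xi_cov[:] = 0.0
        run.xi_mean[:] = 0.0
        assert np.allclose(tm.compute_fabt(run), 1.0)
        run.xi_mean = run.B_eig_mean.copy()  # orthogonal transform preserves power
        assert np.allclose(tm.compute_fabt(run), 0.5)

    def test_zero_power_is_missing(self):
        run, _ = make_run(1, 4)
        run.B_eig_mean[:] = 0.0
        run.B_cov[:] = 0.0
        run.xi_mean[:] = 0.0
        run.xi_cov[:] = 0.0
        assert np.isnan(tm.compute_fabt(run)[0])

    def test_matches_direct_second_moment_computation(self):
        run, _ = make_run(3, 10, seed=5)
        pow_b = (run.B_eig_mean ** 2).sum(axis=1) + np.einsum("tmm->m", run.B_cov)
        pow_xi = (run.xi_mean ** 2).sum(axis=1) + 10 * np.diag(run.xi_cov)
        assert np.allclose(tm.compute_fabt(run), pow_b / (pow_b + pow_xi))


def test_whitening_flattens_autocorrelation(rng):
    """B K^{-1/2} has lag-1 autocorrelation pulled toward zero relative to
    the HRF-induced autocorrelation of B itself."""
    t = 300
    kern = tm.build_hrf_kernel(t, 2.0)
    lam, u = kern.eig()
    b = rng.standard_normal((4, t)) @ ((u * np.sqrt(lam)) @ u.T)
    bw = b @ kern.whitening_matrix()

    def lag1(x):
        return np.mean([np.corrcoef(r[:-1], r[1:])[0, 1] for r in x])

    assert lag1(b) > 0.5           # HRF smoothing induces strong lag-1
    assert abs(lag1(bw)) < lag1(b) * 0.3
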