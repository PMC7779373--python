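"""Spatial model updates against quadrature / sampling / grid-search oracles."""

import numpy as np
import pytest

from pfmlab import spatial as sp
from helpers import (
    gamma_posterior_is,
    mixture_responsibility_quadrature,
    spike_slab_responsibilities_quadrature,
)


def point_group_moments(mu, sigma, pi, zeta=1.0):
    """GroupMoments with point-mass hyperparameters (scalar case, V=M=1)."""
    arr = lambda x: np.full((1, 1), float(x))
    with np.errstate(divide="ignore"):
        log_pi, log_1mpi = np.log(pi), np.log1p(-pi)
    return sp.GroupMoments(
        E_mu=arr(mu), E_mu2=arr(mu ** 2),
        E_sigma_inv2=arr(sigma ** -2), E_log_sigma_inv2=arr(np.log(sigma ** -2)),
        E_log_pi=arr(log_pi), E_log_1mpi=arr(log_1mpi),
        E_zeta_inv2=np.full(1, zeta ** -2),
        E_log_zeta_inv2=np.full(1, np.log(zeta ** -2)),
    )


class TestSubjectMapUpdate:
    def test_no_data_limit_returns_prior(self):
        gm = point_group_moments(mu=1.2, sigma=0.8, pi=0.3)
        post = sp.update_subject_maps(np.zeros((1, 1)), np.zeros((1, 1)), gm,
                                      eta=np.array([0.5]))
        assert post.signal_mean[0, 0] == pytest.approx(1.2)
        assert post.signal_var[0, 0] == pytest.approx(0.64)
        assert post.responsibility[0, 0] == pytest.approx(0.3)

    def test_certain_membership_gives_unit_responsibility(self):
        gm = point_group_moments(mu=0.0, sigma=1.0, pi=1.0 - 1e-300)
        post = sp.update_subject_maps(np.full((1, 1), 4.0), np.ones((1, 1)), gm,
                                      eta=np.array([0.1]))
        assert post.responsibility[0, 0] == pytest.approx(1.0)

    def test_responsibility_matches_quadrature(self):
        """Scalar case mu=1, sigma=1, noise std 0.1, pi=0.5, pseudo-obs (4, 1)."""
        gm = point_group_moments(mu=1.0, sigma=1.0, pi=0.5)
        post = sp.update_subject_maps(np.full((1, 1), 4.0), np.ones((1, 1)), gm,
                                      eta=np.array([0.1]))
        oracle = mixture_responsibility_quadrature(
            prior_w1=0.5, mu=1.0, sigma=1.0, noise_std=0.1,
            like_prec=4.0, like_mean=1.0,
        )
        assert post.responsibility[0, 0] == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("like_prec,like_mean,pi", [
        (0.5, -2.0, 0.1), (10.0, 0.05, 0.9), (3.0, 1.5, 0.5),
    ])
    def test_quadrature_across_regimes(self, like_prec, like_mean, pi):
        gm = point_group_moments(mu=0.7, sigma=1.3, pi=pi, zeta=2.0)
        eta = np.array([0.25])
        post = sp.update_subject_maps(np.full((1, 1), like_prec),
                                      np.full((1, 1), like_mean), gm, eta)
        oracle = mixture_responsibility_quadrature(
            prior_w1=pi, mu=0.7, sigma=1.3, noise_std=eta[0] * 2.0,
            like_prec=like_prec, like_mean=like_mean,
        )
        assert post.responsibility[0, 0] == pytest.approx(oracle, abs=1e-8)

    def test_noise_branch_disabled_collapses_to_ridge(self, rng):
        """With pi == 1 the subject maps are the conjugate (ridge) combination
        of group prior and pseudo-observation."""
        v, m = 30, 2
        group = sp.GroupSpatialPosterior.from_prior(v, m, sp.SpatialHyperpriors())
        group.pi_a = np.full((v, m), 1e9)
        group.pi_b = np.full((v, m), 1e-9)
        lp = rng.random((v, m)) * 5
        lm = rng.standard_normal((v, m))
        post = sp.update_subject_maps(lp, lm, group, eta=np.full(m, 0.1))
        assert np.allclose(post.responsibility, 1.0)
        prec = group.E_sigma_inv2
        ridge = (prec * group.E_mu + lp * lm) / (prec + lp)
        assert np.allclose(post.signal_mean, ridge, atol=1e-10)


class TestGroupMeanUpdate:
    def make_group(self, v=1, m=1):
        return sp.GroupSpatialPosterior.from_prior(v, m, sp.SpatialHyperpriors())

    def test_zero_evidence_returns_prior(self):
        hyp = sp.SpatialHyperpriors()
        group = self.make_group()
        zeros = np.zeros((1, 1))
        stats = sp.PooledSubjectStats(zeros, zeros, zeros, 0)
        sp.update_group_means(stats, group, hyp)
        assert np.allclose(group.rho_resp[0, 0], hyp.lambda_mu)
        assert group.slab_mean[0, 0, 0] == pytest.approx(hyp.tau_mu1)
        assert group.slab_var[0, 0, 1] == pytest.approx(hyp.gamma_mu2 ** 2)

    def test_collapsed_mixture_is_single_conjugate_update(self):
        hyp = sp.SpatialHyperpriors(lambda_mu=(0.0, 1.0, 0.0))
        group = self.make_group()
        stats = sp.PooledSubjectStats(np.full((1, 1), 2.0), np.full((1, 1), 3.0),
                                      np.full((1, 1), 5.0), 2)
        sp.update_group_means(stats, group, hyp)
        assert group.rho_resp[0, 0, 1] == pytest.approx(1.0)
        prior_prec = 1.0 / hyp.gamma_mu1 ** 2
        l_mu = group.E_sigma_inv2[0, 0] * 2.0
        b_mu = group.E_sigma_inv2[0, 0] * 3.0
        expect = (prior_prec * hyp.tau_mu1 + b_mu) / (prior_prec + l_mu)
        assert group.slab_mean[0, 0, 0] == pytest.approx(expect)

    def test_responsibilities_match_quadrature(self):
        """Two-subject scalar case with exact component evidences."""
        hyp = sp.SpatialHyperpriors()
        group = self.make_group()
        group.sigma_shape[:] = 3.0
        group.sigma_rate[:] = 1.5  # E[sigma^-2] = 2
        n_eff = np.full((1, 1), 1.7)
        mean_sum = np.full((1, 1), 2.1)
        stats = sp.PooledSubjectStats(n_eff, mean_sum, np.full((1, 1), 4.0), 2)
        sp.update_group_means(stats, group, hyp)
        oracle = spike_slab_responsibilities_quadrature(
            lambdas=hyp.lambda_mu,
            taus=[hyp.tau_mu1, hyp.tau_mu2],
            gammas=[hyp.gamma_mu1, hyp.gamma_mu2],
            l_mu=2.0 * 1.7, b_mu=2.0 * 2.1,
        )
        assert np.allclose(group.rho_resp[0, 0], oracle, atol=1e-8)
        assert np.all(group.rho_resp >= 0)
        assert group.rho_resp[0, 0].sum() == pytest.approx(1.0)


class TestGroupStdUpdate:
    def test_zero_count_returns_prior(self):
        hyp = sp.SpatialHyperpriors(a_sigma=2.0, b_sigma=3.0)
        group = sp.GroupSpatialPosterior.from_prior(1, 1, hyp)
        zeros = np.zeros((1, 1))
        sp.update_group_stds(sp.PooledSubjectStats(zeros, zeros, zeros, 0),
                             group, hyp)
        assert group.sigma_shape[0, 0] == pytest.approx(2.0)
        assert group.sigma_rate[0, 0] == pytest.approx(3.0)

    def test_shape_is_prior_plus_half_count(self):
        hyp = sp.SpatialHyperpriors()
        group = sp.GroupSpatialPosterior.from_prior(1, 1, hyp)
        stats = sp.PooledSubjectStats(np.full((1, 1), 2.6), np.zeros((1, 1)),
                                      np.full((1, 1), 1.0), 3)
        sp.update_group_stds(stats, group, hyp)
        assert group.sigma_shape[0, 0] == pytest.approx(hyp.a_sigma + 1.3)

    def test_posterior_mean_matches_importance_sampling(self, rng):
        """3 subjects with certain membership and point mu: the exact
        conditional posterior over sigma^-2 is recovered by IS from the
        prior."""
        hyp = sp.SpatialHyperpriors(a_sigma=2.0, b_sigma=1.0)
        group = sp.GroupSpatialPosterior.from_prior(1, 1, hyp)
        mu = 0.5
        group.rho_resp[0, 0] = [0.0, 1.0, 0.0]
        group.slab_mean[0, 0, 0] = mu
        group.slab_var[0, 0, :] = 0.0
        obs = np.array([1.3, -0.2, 0.9])
        n_eff = np.full((1, 1), 3.0)
        mean_sum = np.full((1, 1), obs.sum())
        sq_sum = np.full((1, 1), np.sum(obs ** 2))
        sp.update_group_stds(sp.PooledSubjectStats(n_eff, mean_sum, sq_sum, 3),
                             group, hyp)
        # analytic posterior mean of sigma^2 = rate / (shape - 1)
        est = group.sigma_rate[0, 0] / (group.sigma_shape[0, 0] - 1.0)

        def loglik(x):  # x = sigma^-2
            return 0.5 * 3 * np.log(x) - 0.5 * x * np.sum((obs - mu) ** 2)

        oracle, se = gamma_posterior_is(rng, 2.0, 1.0, loglik, lambda x: 1.0 / x)
        assert abs(est - oracle) < 3 * se


class TestMembershipUpdate:
    def test_prior_and_counting_and_mean(self):
        hyp = sp.SpatialHyperpriors(a_pi=1.0, b_pi=19.0)
        group = sp.GroupSpatialPosterior.from_prior(1, 3, hyp)
        sp.update_memberships(np.zeros((1, 3)), 0, group, hyp)
        assert np.allclose(group.pi_a, 1.0) and np.allclose(group.pi_b, 19.0)
        sp.update_memberships(np.array([[2.0, 0.5, 0.0]]), 3, group, hyp)
        assert np.allclose(group.pi_a[0], [3.0, 1.5, 1.0])
        assert np.allclose(group.pi_b[0], [20.0, 21.5, 22.0])
        # all-0.5 responsibilities with S=4: mean (a+2)/(a+b+4)
        sp.update_memberships(np.full((1, 3), 2.0), 4, group, hyp)
        assert np.allclose(group.E_pi, 3.0 / 24.0)


class TestNoiseScales:
    def make_subject(self, v, m, resp, noise_mean, noise_var, eta):
        return sp.SubjectSpatialPosterior(
            signal_mean=np.zeros((v, m)), signal_var=np.ones((v, m)),
            noise_mean=np.full((v, m), noise_mean),
            noise_var=np.full((v, m), noise_var),
            responsibility=np.full((v, m), resp), eta=np.full(m, eta),
        )

    def test_zero_noise_responsibility_returns_priors(self):
        hyp = sp.SpatialHyperpriors(a_zeta=2.0, b_zeta=5.0)
        group = sp.GroupSpatialPosterior.from_prior(4, 2, hyp)
        subj = self.make_subject(4, 2, resp=1.0, noise_mean=1.0,
                                 noise_var=0.5, eta=0.3)
        sp.update_noise_scales([subj], group, hyp)
        assert np.allclose(group.zeta_shape, 2.0)
        assert np.allclose(group.zeta_rate, 5.0)
        assert np.all(subj.eta <= sp.ETA_FLOOR + 1e-12)  # prior MAP is 0

    def test_zeta_shape_counts_noise_mass(self):
        hyp = sp.SpatialHyperpriors()
        group = sp.GroupSpatialPosterior.from_prior(3, 2, hyp)
        subj = self.make_subject(3, 2, resp=0.25, noise_mean=0.1,
                                 noise_var=0.01, eta=0.2)
        sp.update_noise_scales([subj], group, hyp)
        # each voxel collects (1 - resp) over 2 modes
        assert np.allclose(group.zeta_shape, hyp.a_zeta + 0.5 * (0.75 * 2))

    def test_eta_map_matches_grid_search(self):
        """Closed-form eta maximiser vs a dense grid of the objective."""
        n, s, gamma = 37.0, 2.4, 0.1

        def objective(eta):
            return (-n * np.log(eta) - s / (2 * eta ** 2)
                    - eta ** 2 / (2 * gamma ** 2))

        grid = np.linspace(1e-4, 2.0, 2_000_001)
        best = grid[np.argmax(objective(grid))]
        assert abs(sp.eta_map(n, s, gamma) - best) < 1e-6


def test_group_map_summary_linearity():
    hyp = sp.SpatialHyperpriors()
    group = sp.GroupSpatialPosterior.from_prior(1, 1, hyp)
    group.pi_a[:] = 3.0
    group.pi_b[:] = 1.0   # E[pi] = 0.75
    group.rho_resp[0, 0] = [0.5, 0.5, 0.0]
    group.slab_mean[0, 0, 0] = 2.0
    assert sp.group_map_summary(group)[0, 0] == pytest.approx(0.75 * 1.0)
    group.pi_a[:] = 1e12  # E[pi] -> 1, all mass on slab 1
    group.rho_resp[0, 0] = [0.0, 1.0, 0.0]
    assert sp.group_map_summary(group)[0, 0] == pytest.approx(2.0, rel=1e-6)
    group.pi_a[:] = 1e-12  # E[pi] -> 0
    assert sp.group_map_summary(group)[0, 0] == pytest.approx(0.0, abs=1e-10)
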