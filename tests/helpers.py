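"""Independent oracles used by the unit tests: quadrature, importance
sampling over conjugate pairs, and brute-force enumeration.

These deliberately avoid the package's own update formulas: posteriors are
reconstructed by numerically integrating or sampling the explicit prior x
likelihood products.
"""

import numpy as np
from scipy import integrate


def weighted_mean_se(values, log_weights):
    """Self-normalised importance-sampling mean and its standard error."""
    lw = np.asarray(log_weights, float)
    w = np.exp(lw - lw.max())
    w /= w.sum()
    mean = float(np.sum(w * values))
    var = float(np.sum(w ** 2 * (values - mean) ** 2))
    return mean, np.sqrt(var)


def mixture_responsibility_quadrature(
    prior_w1, mu, sigma, noise_std, like_prec, like_mean, lim=40.0
):
    """P(q=1 | pseudo-data) for the two-branch subject-map factor.

    Integrates prior-branch density times the Gaussian pseudo-likelihood
    exp(-like_prec (P - like_mean)^2 / 2) over P for both branches.
    """
    def lik(p):
        return np.exp(-0.5 * like_prec * (p - like_mean) ** 2)

    def branch1(p):
        return (prior_w1 * np.exp(-0.5 * ((p - mu) / sigma) ** 2)
                / (sigma * np.sqrt(2 * np.pi)) * lik(p))

    def branch0(p):
        return ((1 - prior_w1) * np.exp(-0.5 * (p / noise_std) ** 2)
                / (noise_std * np.sqrt(2 * np.pi)) * lik(p))

    z1, _ = integrate.quad(branch1, -lim, lim, limit=200)
    z0, _ = integrate.quad(branch0, -lim, lim, limit=200)
    return z1 / (z0 + z1)


def spike_slab_responsibilities_quadrature(
    lambdas, taus, gammas, l_mu, b_mu, lim=60.0
):
    """Component posteriors of the 3-component group-mean mixture.

    The likelihood in mu is exp(-l_mu mu^2 / 2 + b_mu mu); component 0 is a
    point mass at zero, components 1 and 2 are Gaussian slabs.
    """
    def lik(mu):
        return np.exp(-0.5 * l_mu * mu ** 2 + b_mu * mu)

    masses = [lambdas[0] * lik(0.0)]
    for tau, gam, lam in zip(taus, gammas, lambdas[1:]):
        def f(mu, tau=tau, gam=gam):
            return (np.exp(-0.5 * ((mu - tau) / gam) ** 2)
                    / (gam * np.sqrt(2 * np.pi)) * lik(mu))

        z, _ = integrate.quad(f, -lim, lim, limit=200)
        masses.append(lam * z)
    masses = np.asarray(masses)
    return masses / masses.sum()


def gamma_posterior_is(rng, a, b, loglik, transform, n=200_000):
    """IS posterior expectation of ``transform(x)`` for x ~ Gamma(a, b) prior."""
    x = rng.gamma(a, 1.0 / b, size=n)
    return weighted_mean_se(transform(x), loglik(x))


def wishart_posterior_mean_is(rng, dof, rate, loglik, n=100_000):
    """IS posterior mean of a matrix X with Wishart(dof, rate) prior.

    ``loglik`` maps a stack (n, M, M) to per-sample log-likelihoods.
    Returns (mean matrix, elementwise standard errors).
    """
    from scipy.stats import wishart

    scale = np.linalg.inv(rate)
    xs = wishart.rvs(df=dof, scale=scale, size=n, random_state=rng)
    lw = loglik(xs)
    w = np.exp(lw - lw.max())
    w /= w.sum()
    mean = np.einsum("n,nij->ij", w, xs)
    var = np.einsum("n,nij->ij", w ** 2, (xs - mean) ** 2)
    return mean, np.sqrt(var)
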