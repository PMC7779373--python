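"""Exponential-family expectations and KL divergences shared by the VB updates.

All Wishart quantities use the *rate* parameterisation,

    W(X | n, R)  with  density ∝ |X|^((n-M-1)/2) exp(-tr(R X) / 2),

so that E[X] = n R^{-1}.  This makes the netmat hierarchy (run precision
alpha with a group-level Wishart hyperprior beta) exactly conjugate.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, digamma, gammaln, multigammaln

LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Gamma (shape/rate) over a precision x
# ---------------------------------------------------------------------------

def gamma_mean(shape, rate):
    return np.asarray(shape) / np.asarray(rate)


def gamma_E_log(shape, rate):
    """E[log x] under Gamma(shape, rate)."""
    return digamma(shape) - np.log(rate)


def gamma_kl(shape_q, rate_q, shape_p, rate_p):
    """KL( Gamma(shape_q, rate_q) || Gamma(shape_p, rate_p) ), elementwise."""
    shape_q, rate_q = np.asarray(shape_q, float), np.asarray(rate_q, float)
    return (
        (shape_q - shape_p) * digamma(shape_q)
        - gammaln(shape_q)
        + gammaln(shape_p)
        + shape_p * (np.log(rate_q) - np.log(rate_p))
        + shape_q * (rate_p - rate_q) / rate_q
    )


# ---------------------------------------------------------------------------
# Beta
# ---------------------------------------------------------------------------

def beta_kl(a_q, b_q, a_p, b_p):
    a_q, b_q = np.asarray(a_q, float), np.asarray(b_q, float)
    dg_sum = digamma(a_q + b_q)
    return (
        betaln(a_p, b_p)
        - betaln(a_q, b_q)
        + (a_q - a_p) * (digamma(a_q) - dg_sum)
        + (b_q - b_p) * (digamma(b_q) - dg_sum)
    )


# ---------------------------------------------------------------------------
# Wishart (rate parameterisation)
# ---------------------------------------------------------------------------

def wishart_mean(dof, rate):
    return dof * np.linalg.inv(rate)


def wishart_E_logdet(dof, rate):
    """E[log |X|] under W(dof, rate)."""
    m = rate.shape[0]
    i = np.arange(1, m + 1)
    sign, logdet = np.linalg.slogdet(rate)
    if sign <= 0:
        raise np.linalg.LinAlgError("Wishart rate matrix is not positive definite")
    return float(np.sum(digamma((dof + 1 - i) / 2.0)) + m * np.log(2.0) - logdet)


def wishart_E_logq(dof, rate):
    """E_q[log q(X)] for q = W(dof, rate)."""
    m = rate.shape[0]
    _, logdet = np.linalg.slogdet(rate)
    log_norm = 0.5 * dof * logdet - 0.5 * dof * m * np.log(2.0) - multigammaln(dof / 2.0, m)
    e_logdet_x = wishart_E_logdet(dof, rate)
    # tr(R E[X]) = dof * M
    return log_norm + 0.5 * (dof - m - 1) * e_logdet_x - 0.5 * dof * m


def wishart_E_logp(dof_q, rate_q, dof_p, E_rate_p, E_logdet_rate_p):
    """E_q[log p(X)] for p = W(dof_p, rate) with the rate possibly uncertain.

    ``E_rate_p`` and ``E_logdet_rate_p`` are the posterior expectations of the
    prior rate matrix and of its log-determinant (they coincide with the plain
    values when the prior rate is a fixed constant).
    """
    m = rate_q.shape[0]
    e_x = wishart_mean(dof_q, rate_q)
    e_logdet_x = wishart_E_logdet(dof_q, rate_q)
    return (
        0.5 * dof_p * E_logdet_rate_p
        + 0.5 * (dof_p - m - 1) * e_logdet_x
        - 0.5 * float(np.sum(E_rate_p * e_x))
        - 0.5 * dof_p * m * np.log(2.0)
        - multigammaln(dof_p / 2.0, m)
    )


# ---------------------------------------------------------------------------
# Gaussians
# ---------------------------------------------------------------------------

def gaussian_entropy(cov):
    """Entropy of a multivariate Gaussian with covariance ``cov``."""
    m = cov.shape[0]
    _, logdet = np.linalg.slogdet(cov)
    return 0.5 * (m * (1.0 + LOG_2PI) + logdet)


def gaussian_kl_diag_prior(mean_q, cov_q, mean_p, var_p):
    """KL(N(mean_q, cov_q) || prod_i N(mean_p_i, var_p_i))."""
    mean_q = np.asarray(mean_q, float)
    var_p = np.broadcast_to(np.asarray(var_p, float), mean_q.shape)
    mean_p = np.broadcast_to(np.asarray(mean_p, float), mean_q.shape)
    m = mean_q.size
    _, logdet_q = np.linalg.slogdet(cov_q)
    quad = np.sum((np.diag(cov_q) + (mean_q - mean_p) ** 2) / var_p)
    return 0.5 * (np.sum(np.log(var_p)) - logdet_q - m + quad)


def solve_psd(a, b):
    """Solve a x = b for symmetric positive-definite ``a`` via Cholesky."""
    from scipy.linalg import cho_factor, cho_solve

    return cho_solve(cho_factor(a, lower=True), b)


def cov2corr(c):
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def precision_to_partial_corr(prec):
    """Partial correlations implied by a precision matrix (unit diagonal)."""
    d = np.sqrt(np.diag(prec))
    p = -prec / np.outer(d, d)
    np.fill_diagonal(p, 1.0)
    return p


def cov_to_partial_corr(cov, ridge=0.0):
    c = np.asarray(cov, float)
    if ridge > 0:
        c = c + ridge * np.mean(np.diag(c)) * np.eye(c.shape[0])
    return precision_to_partial_corr(np.linalg.inv(c))
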