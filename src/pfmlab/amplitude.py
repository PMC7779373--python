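"""Amplitude model: run-level mode amplitudes with group hyperpriors.

Each run carries an M-vector h of mode amplitudes with a joint Gaussian
prior N(mu_h, Sigma_h); the group mean mu_h and covariance Sigma_h capture
consistent cross-subject amplitude structure (e.g. correlated sensorimotor
amplitudes).  Sign indeterminacy of the factorisation is resolved by a
post-hoc positivity constraint: negative posterior amplitude means are
negated together with the corresponding time-course rows, leaving the
reconstruction P H A unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import NumericalError
from .temporal import WishartPosterior


@dataclass
class AmplitudeHyperpriors:
    tau_mu_h: float
    gamma_mu_h: float
    a_h: float
    B_h: np.ndarray

    @classmethod
    def default(cls, n_modes: int) -> "AmplitudeHyperpriors":
        m = n_modes
        return cls(tau_mu_h=1.0, gamma_mu_h=1.0, a_h=m + 1.0, B_h=np.eye(m) * (m + 1.0))

    def validate(self, n_modes: int) -> None:
        if self.gamma_mu_h <= 0:
            raise ValueError("gamma_mu_h must be positive")
        if self.a_h <= n_modes - 1:
            raise ValueError("a_h must exceed M - 1")
        if np.linalg.eigvalsh(self.B_h).min() <= 0:
            raise ValueError("B_h must be positive definite")


@dataclass
class RunAmplitudePosterior:
    """Gaussian posterior over one run's amplitude vector (full covariance)."""

    mean: np.ndarray   # (M,)
    cov: np.ndarray    # (M, M)

    def second_moment(self) -> np.ndarray:
        return self.cov + np.outer(self.mean, self.mean)


@dataclass
class AmplitudePosterior:
    """Run posteriors plus the group-level amplitude hierarchy."""

    runs: dict                      # (subject, run) -> RunAmplitudePosterior
    mu_mean: np.ndarray             # (M,)
    mu_cov: np.ndarray              # (M, M)
    sigma_inv: WishartPosterior     # posterior over Sigma_h^{-1}

    @classmethod
    def from_prior(cls, run_keys, hyp: AmplitudeHyperpriors, n_modes: int):
        m = n_modes
        runs = {
            key: RunAmplitudePosterior(mean=np.ones(m), cov=0.1 * np.eye(m))
            for key in run_keys
        }
        return cls(
            runs=runs,
            mu_mean=np.full(m, hyp.tau_mu_h),
            mu_cov=np.eye(m) * hyp.gamma_mu_h ** 2,
            sigma_inv=WishartPosterior(dof=hyp.a_h, rate=hyp.B_h.copy()),
        )


def update_amplitudes(
    proj_diag: np.ndarray,
    E_PtP: np.ndarray,
    E_AAt: np.ndarray,
    E_psi: float,
    amp: AmplitudePosterior,
    key,
    dof_factor: float = 1.0,
) -> None:
    """Conjugate Gaussian update of one run's q(h).

    The likelihood is linear in h with design built from second moments of P
    and A: the data precision is psi * (E[P^T P] o E[A A^T]) (Hadamard) and
    the linear term is psi * diag(E[P]^T D E[A]^T) (``proj_diag``).  The
    prior is N(E[mu_h], ...) with precision E[Sigma_h^{-1}].
    """
    if not np.all(np.isfinite(proj_diag)):
        raise NumericalError("non-finite projection in amplitude update")
    e_prec = amp.sigma_inv.mean
    c_psi = dof_factor * E_psi
    post_prec = e_prec + c_psi * (E_PtP * E_AAt)
    b = e_prec @ amp.mu_mean + c_psi * proj_diag
    try:
        cov = np.linalg.inv(post_prec)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular posterior precision in amplitude update") from exc
    run = amp.runs[key]
    run.cov = 0.5 * (cov + cov.T)
    run.mean = cov @ b


def update_amplitude_hypers(amp: AmplitudePosterior, hyp: AmplitudeHyperpriors) -> None:
    """Conjugate updates of q(mu_h) and q(Sigma_h^{-1}) from the run posteriors."""
    keys = list(amp.runs)
    m = amp.mu_mean.shape[0]
    if not keys:
        amp.mu_mean = np.full(m, hyp.tau_mu_h)
        amp.mu_cov = np.eye(m) * hyp.gamma_mu_h ** 2
        amp.sigma_inv = WishartPosterior(dof=hyp.a_h, rate=hyp.B_h.copy())
        return
    n = len(keys)
    e_prec = amp.sigma_inv.mean

    prior_prec = np.eye(m) / hyp.gamma_mu_h ** 2
    post_prec = prior_prec + n * e_prec
    b = prior_prec @ np.full(m, hyp.tau_mu_h) + e_prec @ sum(
        amp.runs[k].mean for k in keys
    )
    amp.mu_cov = np.linalg.inv(post_prec)
    amp.mu_cov = 0.5 * (amp.mu_cov + amp.mu_cov.T)
    amp.mu_mean = amp.mu_cov @ b

    scatter = np.zeros((m, m))
    for k in keys:
        run = amp.runs[k]
        d = run.mean - amp.mu_mean
        scatter += run.cov + np.outer(d, d) + amp.mu_cov
    amp.sigma_inv = WishartPosterior(dof=hyp.a_h + n, rate=hyp.B_h + scatter)


def enforce_positivity(amp: AmplitudePosterior, temporal_runs: dict) -> int:
    """Post-hoc positivity constraint on the amplitudes.

    For every run mode with a negative posterior amplitude mean, negate the
    amplitude and the corresponding time-course row (both the clean and the
    noise part).  The reconstruction P H A is unchanged to machine precision;
    applying the operation twice equals applying it once.  Returns the number
    of sign flips performed.
    """
    n_flips = 0
    for key, run_amp in amp.runs.items():
        neg = run_amp.mean < 0
        if not np.any(neg):
            continue
        s = np.where(neg, -1.0, 1.0)
        run_amp.mean = s * run_amp.mean
        run_amp.cov = run_amp.cov * np.outer(s, s)
        tc = temporal_runs[key]
        tc.B_eig_mean = s[:, None] * tc.B_eig_mean
        tc.B_cov = tc.B_cov * np.outer(s, s)[None, :, :]
        tc.xi_mean = s[:, None] * tc.xi_mean
        tc.xi_cov = tc.xi_cov * np.outer(s, s)
        tc._refresh_EB()
        n_flips += int(neg.sum())
    return n_flips
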