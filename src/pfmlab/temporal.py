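"""Temporal model: HRF kernel, clean/noisy time courses, and netmat hierarchy.

Mode time courses decompose as A = B + xi.  B carries the haemodynamically
plausible signal: a white "neuronal" process convolved with the canonical
double-gamma HRF induces temporal autocorrelation described by a Toeplitz
kernel K_B (scaled to unit diagonal), and B follows a matrix-normal prior
MN(0, alpha^-1, K_B) whose row precision alpha is the run-level functional
coupling netmat.  alpha is tied across the cohort through a group-level
Wishart hyperprior beta.  xi is unstructured Gaussian noise with per-mode
precision omega, excluded from the netmat sufficient statistics but included
when projecting data onto maps.

Wishart distributions use the rate parameterisation throughout (see _math),
which makes the alpha -> beta hierarchy exactly conjugate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ConfigurationError, NumericalError
from ._math import gamma_E_log, gamma_mean, wishart_E_logdet, wishart_mean

KERNEL_JITTER = 1e-8


# ---------------------------------------------------------------------------
# Canonical HRF and its autocorrelation kernel
# ---------------------------------------------------------------------------

def canonical_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Double-gamma haemodynamic response sampled at times ``t`` (seconds)."""
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, float)
    peak = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - ratio * under
    norm = np.sqrt(np.sum(h ** 2))
    return h / norm if norm > 0 else h


def hrf_autocorrelation(n_lags: int, tr: float, **hrf_kwargs) -> np.ndarray:
    """Normalised autocorrelation of the sampled canonical HRF at integer lags.

    This is the autocorrelation a white neuronal process acquires after
    convolution with the HRF, evaluated at lags 0 .. n_lags-1 in units of TR.
    """
    # sample the HRF long enough for the tail to vanish
    support = max(64.0, 4 * n_lags * tr)
    t = np.arange(0.0, support, tr)
    h = canonical_hrf(t, **hrf_kwargs)
    full = np.correlate(h, h, mode="full")[len(h) - 1:]
    acf = np.zeros(n_lags)
    k = min(n_lags, len(full))
    acf[:k] = full[:k] / full[0]
    return acf


@dataclass
class HRFKernel:
    """T x T temporal autocorrelation matrix of HRF-filtered white noise.

    Symmetric positive-definite Toeplitz with unit diagonal.  A small
    diagonal jitter is applied before re-normalisation so the smallest
    eigenvalue stays strictly positive even for long runs.
    """

    K: np.ndarray
    tr: float
    hrf_params: dict = field(default_factory=dict)
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def T(self) -> int:
        return self.K.shape[0]

    def eig(self):
        """Cached eigendecomposition (eigenvalues ascending, orthonormal U)."""
        if self._eig is None:
            lam, u = np.linalg.eigh(self.K)
            if lam.min() <= 0:
                raise NumericalError("HRF kernel is not positive definite")
            self._eig = (lam, u)
        return self._eig

    def whitening_matrix(self) -> np.ndarray:
        """K^(-1/2); right-multiplying B by it flattens HRF autocorrelation."""
        lam, u = self.eig()
        return (u / np.sqrt(lam)) @ u.T


def build_hrf_kernel(n_timepoints: int, tr: float, **hrf_kwargs) -> HRFKernel:
    """Construct K_B for a run of ``n_timepoints`` samples at repetition ``tr``."""
    if n_timepoints < 1:
        raise ConfigurationError("HRF kernel needs at least one time point")
    if tr <= 0:
        raise ConfigurationError("TR must be positive")
    acf = hrf_autocorrelation(n_timepoints, tr, **hrf_kwargs)
    from scipy.linalg import toeplitz

    k = toeplitz(acf)
    k[np.diag_indices_from(k)] += KERNEL_JITTER
    k /= k[0, 0]  # re-normalise to exact unit diagonal
    return HRFKernel(K=k, tr=tr, hrf_params=dict(hrf_kwargs))


# ---------------------------------------------------------------------------
# Hyperpriors and posteriors
# ---------------------------------------------------------------------------

@dataclass
class TemporalHyperpriors:
    a_alpha: float
    a_beta: float
    B_beta: np.ndarray
    a_omega: float = 1.0
    b_omega: float = 1.0

    @classmethod
    def default(cls, n_modes: int) -> "TemporalHyperpriors":
        m = n_modes
        return cls(a_alpha=m + 1.0, a_beta=m + 1.0, B_beta=np.eye(m) * (m + 1.0))

    def validate(self, n_modes: int) -> None:
        if self.a_alpha <= n_modes - 1 or self.a_beta <= n_modes - 1:
            raise ConfigurationError("Wishart dofs must exceed M - 1")
        if self.a_omega <= 0 or self.b_omega <= 0:
            raise ConfigurationError("omega hyperprior constants must be positive")
        if self.B_beta.shape != (n_modes, n_modes):
            raise ConfigurationError("B_beta must be M x M")
        if np.linalg.eigvalsh(self.B_beta).min() <= 0:
            raise ConfigurationError("B_beta must be positive definite")


@dataclass
class RunTemporalPosterior:
    """Posterior over one run's time courses and temporal noise.

    The clean time courses are stored in the eigenbasis of K_B: writing
    K_B = U diag(lam) U^T, the columns of B U are a posteriori independent
    M-vectors, each with its own covariance (``B_cov[k]``).  ``E_B`` caches
    the posterior mean back in the time basis.
    """

    B_eig_mean: np.ndarray      # (M, T) mean of B U
    B_cov: np.ndarray           # (T, M, M) covariance per eigencolumn
    xi_mean: np.ndarray         # (M, T)
    xi_cov: np.ndarray          # (M, M), shared across time points
    omega_shape: np.ndarray     # (M,)
    omega_rate: np.ndarray      # (M,)
    kernel: HRFKernel
    E_B: np.ndarray = None      # (M, T), derived

    def __post_init__(self):
        if self.E_B is None:
            self._refresh_EB()

    def _refresh_EB(self):
        _, u = self.kernel.eig()
        self.E_B = self.B_eig_mean @ u.T

    @property
    def E_A(self) -> np.ndarray:
        return self.E_B + self.xi_mean

    def E_AAt(self) -> np.ndarray:
        """E[A A^T] including all posterior covariance terms."""
        eb, ex = self.E_B, self.xi_mean
        t = eb.shape[1]
        out = eb @ eb.T + self.B_cov.sum(axis=0)
        out += eb @ ex.T + ex @ eb.T
        out += ex @ ex.T + t * self.xi_cov
        return out

    def B_kernel_stat(self) -> np.ndarray:
        """E[B K_B^{-1} B^T], the netmat sufficient statistic."""
        lam, _ = self.kernel.eig()
        w = self.B_eig_mean / lam[None, :]
        return w @ self.B_eig_mean.T + np.tensordot(1.0 / lam, self.B_cov, axes=(0, 0))

    def xi_sq_sum(self) -> np.ndarray:
        """sum_t E[xi_mt^2] per mode."""
        t = self.xi_mean.shape[1]
        return (self.xi_mean ** 2).sum(axis=1) + t * np.diag(self.xi_cov)

    @property
    def E_omega(self) -> np.ndarray:
        return gamma_mean(self.omega_shape, self.omega_rate)

    @property
    def E_log_omega(self) -> np.ndarray:
        return gamma_E_log(self.omega_shape, self.omega_rate)


@dataclass
class WishartPosterior:
    """Wishart posterior (rate parameterisation) over a precision matrix."""

    dof: float
    rate: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return wishart_mean(self.dof, self.rate)

    @property
    def E_logdet(self) -> float:
        return wishart_E_logdet(self.dof, self.rate)


@dataclass
class GroupTemporalPosterior:
    """Wishart posteriors over the group netmat(s), one per run family."""

    families: dict  # family label -> WishartPosterior

    def for_family(self, label) -> WishartPosterior:
        return self.families[label]


# ---------------------------------------------------------------------------
# Updates
# ---------------------------------------------------------------------------

def update_timecourses(
    proj: np.ndarray,
    map_precision: np.ndarray,
    E_alpha: np.ndarray,
    run: RunTemporalPosterior,
    E_psi: float,
    dof_factor: float = 1.0,
) -> None:
    """Joint update of q(B) then q(xi) for one run.

    ``proj`` is E[H] E[P]^T D (M x T), the amplitude-weighted projection of
    the data onto the maps; ``map_precision`` is E[h h^T] * E[P^T P]
    (elementwise), the M x M data precision shared by every time point.  The
    matrix-normal prior couples time points through K_B; diagonalising K_B
    makes the posterior separable over eigencolumns, each requiring one M x M
    solve.  q(xi) then updates as independent Gaussian columns with prior
    precision diag(E[omega]).
    """
    if not (np.all(np.isfinite(proj)) and np.all(np.isfinite(map_precision))):
        raise NumericalError("non-finite projection statistics in time-course update")
    lam, u = run.kernel.eig()
    c_psi = dof_factor * E_psi
    data_prec = c_psi * map_precision

    rhs = c_psi * proj - data_prec @ run.xi_mean   # linear coefficient for B
    rhs_eig = rhs @ u
    prec = E_alpha[None, :, :] / lam[:, None, None] + data_prec[None, :, :]
    try:
        cov = np.linalg.inv(prec)                  # batched over eigencolumns
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError("non-invertible precision in B update") from exc
    run.B_cov = 0.5 * (cov + np.swapaxes(cov, 1, 2))
    run.B_eig_mean = np.einsum("tij,jt->it", run.B_cov, rhs_eig)
    run._refresh_EB()

    prec_xi = np.diag(run.E_omega) + data_prec
    try:
        run.xi_cov = np.linalg.inv(prec_xi)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError("non-invertible precision in xi update") from exc
    run.xi_cov = 0.5 * (run.xi_cov + run.xi_cov.T)
    run.xi_mean = run.xi_cov @ (c_psi * proj - data_prec @ run.E_B)


def update_run_netmat(
    B_stat: np.ndarray,
    n_timepoints: int,
    E_beta: np.ndarray,
    a_alpha: float,
) -> WishartPosterior:
    """Conjugate Wishart update of the run (or pooled subject) precision alpha.

    ``B_stat`` is E[B K_B^{-1} B^T], summed over runs when pooling (in which
    case ``n_timepoints`` is the pooled total).  The temporally specific
    noise xi is deliberately excluded from this statistic.
    """
    b = np.asarray(B_stat, float)
    if not np.allclose(b, b.T, atol=1e-8):
        raise NumericalError("netmat sufficient statistic is not symmetric")
    return WishartPosterior(dof=a_alpha + n_timepoints, rate=E_beta + b)


def update_group_netmat(
    alpha_posteriors: dict,
    hyp: TemporalHyperpriors,
    families: dict,
) -> GroupTemporalPosterior:
    """Conjugate Wishart update of the group netmat(s) beta.

    ``alpha_posteriors`` maps an alpha key (run or subject) to its Wishart
    posterior; ``families`` maps each family label to the list of alpha keys
    it governs.  Per family: dof = a_beta + (number of member alphas) *
    a_alpha; rate = B_beta + sum of the members' posterior means.
    """
    out = {}
    for label, members in families.items():
        if not members:
            raise ConfigurationError(f"netmat family {label!r} has no runs assigned")
        rate = hyp.B_beta.copy()
        for key in members:
            rate = rate + alpha_posteriors[key].mean
        dof = hyp.a_beta + len(members) * hyp.a_alpha
        out[label] = WishartPosterior(dof=dof, rate=rate)
    return GroupTemporalPosterior(families=out)


def update_timecourse_noise(run: RunTemporalPosterior, hyp: TemporalHyperpriors) -> None:
    """Conjugate gamma update of q(omega) from the xi second moments."""
    t = run.xi_mean.shape[1]
    run.omega_shape = np.full(run.xi_mean.shape[0], hyp.a_omega + 0.5 * t)
    run.omega_rate = hyp.b_omega + 0.5 * run.xi_sq_sum()


def compute_fabt(run: RunTemporalPosterior) -> np.ndarray:
    """Fractional amplitude of BOLD time courses, per mode.

    Power of the clean (HRF-consistent) time course relative to the total
    time-course power, using full posterior second moments.  Modes with zero
    total power return NaN.
    """
    t = run.B_eig_mean.shape[1]
    pow_b = (run.B_eig_mean ** 2).sum(axis=1) + np.einsum("tmm->m", run.B_cov)
    pow_xi = run.xi_sq_sum()
    total = pow_b + pow_xi
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, pow_b / np.where(total > 0, total, 1.0), np.nan)
    return out
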