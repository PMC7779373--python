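"""Global white-noise likelihood and its precision posterior.

The residual epsilon is zero-mean white Gaussian noise with one precision
psi per run, shared by all voxels and time points (voxelwise homoscedastic;
heteroscedasticity is handled by preprocessing).  The gamma posterior over
psi is conjugate given the mean-field expected reconstruction error, which
includes every posterior variance term of the maps, amplitudes and time
courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import NumericalError, PFMError
from ._math import gamma_E_log, gamma_mean


@dataclass
class RunNoisePosterior:
    shape: float
    rate: float

    @property
    def mean(self) -> float:
        return float(gamma_mean(self.shape, self.rate))

    @property
    def E_log(self) -> float:
        return float(gamma_E_log(self.shape, self.rate))


@dataclass
class NoisePosterior:
    runs: dict        # (subject, run) -> RunNoisePosterior
    a_psi: float
    b_psi: float

    @classmethod
    def from_prior(cls, run_keys, a_psi: float, b_psi: float):
        return cls(
            runs={key: RunNoisePosterior(a_psi, b_psi) for key in run_keys},
            a_psi=a_psi,
            b_psi=b_psi,
        )


def expected_reconstruction_error(
    D: np.ndarray,
    E_P: np.ndarray,
    E_PtP: np.ndarray,
    E_h: np.ndarray,
    E_hht: np.ndarray,
    E_A: np.ndarray,
    E_AAt: np.ndarray,
    PtD: np.ndarray | None = None,
) -> float:
    """E || D - P H A ||_F^2 under the factorised posterior.

    Expanding the square and using independence of the factors gives
    ||D||^2 - 2 tr(D^T E[P] E[H] E[A]) + tr(E[P^T P] (E[h h^T] o E[A A^T]))
    where o is the elementwise product; the second-moment matrices carry all
    the posterior variance contributions.
    """
    v, t = D.shape
    if E_P.shape[0] != v or E_A.shape[1] != t or E_P.shape[1] != E_A.shape[0]:
        raise PFMError("dimension mismatch in reconstruction error")
    if PtD is None:
        PtD = E_P.T @ D
    cross = float(np.einsum("mt,mt,m->", PtD, E_A, E_h))
    quad = float(np.sum(E_PtP * (E_hht * E_AAt)))
    err = float(np.sum(D * D)) - 2.0 * cross + quad
    return max(err, 0.0)


def update_global_noise(
    recon_error: float,
    n_voxels: int,
    n_timepoints: int,
    a_psi: float,
    b_psi: float,
    dof_factor: float = 1.0,
) -> RunNoisePosterior:
    """Conjugate gamma update of q(psi): shape = a + c V T / 2, rate = b + c err / 2."""
    if recon_error < 0:
        raise NumericalError("negative expected reconstruction error")
    return RunNoisePosterior(
        shape=a_psi + 0.5 * dof_factor * n_voxels * n_timepoints,
        rate=b_psi + 0.5 * dof_factor * recon_error,
    )
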