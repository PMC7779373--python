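"""Data containers, preprocessing and the spatial degrees-of-freedom weight.

The model assumes zero-mean, homoscedastic (over voxels) residual noise.
:func:`preprocess_run` enforces the two moment conditions that make this a
reasonable assumption: every voxel time series is demeaned, and the *grand*
variance (the mean over voxels of the temporal variances) is scaled to one.
Relative voxel variances are kept by default, so genuinely noisy voxels still
look noisy; full per-voxel variance normalisation is available as an option.

Spatial smoothness of fMRI noise means the effective number of independent
voxels is smaller than V.  Rather than modelling the spatial covariance, all
data-derived terms in the variational updates can be tempered by a scalar
``dof_factor`` in (0, 1]; see :func:`apply_dof_correction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np


class PFMError(Exception):
    """Base class for errors raised by pfmlab."""


class ConfigurationError(PFMError):
    """Invalid model or simulation configuration."""


class DegenerateDataError(PFMError):
    """Input data carries no usable signal (e.g. all-constant)."""


class NumericalError(PFMError):
    """A variational update produced a non-finite or non-PSD quantity."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class MultiRunDataset:
    """Voxels-by-time data matrices indexed by (subject, run).

    Parameters
    ----------
    data
        Mapping ``(subject, run) -> ndarray (V, T)``.  All runs must share the
        voxel count; time points may differ between runs.
    mask
        Boolean inclusion indicator over the original spatial grid.  The
        number of ``True`` entries equals V.  A dataset built directly from
        matrices uses an all-true mask of length V.
    tr
        Repetition time in seconds.
    """

    data: dict
    mask: np.ndarray
    tr: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tr <= 0:
            raise ConfigurationError(f"TR must be positive, got {self.tr}")
        if not self.data:
            raise ConfigurationError("dataset contains no runs")
        v = None
        for key, mat in self.data.items():
            mat = np.asarray(mat, dtype=float)
            self.data[key] = mat
            if mat.ndim != 2:
                raise ConfigurationError(f"run {key} is not a matrix")
            if mat.shape[1] < 2:
                raise ConfigurationError(f"run {key} has fewer than 2 time points")
            if v is None:
                v = mat.shape[0]
            elif mat.shape[0] != v:
                raise ConfigurationError("all runs must share the voxel count V")
        if int(self.mask.sum()) != v:
            raise ConfigurationError(
                f"mask selects {int(self.mask.sum())} voxels but data has V={v}"
            )

    # -- shape accessors ----------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def subjects(self) -> list:
        return sorted({s for s, _ in self.data})

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def runs(self, subject) -> list:
        return sorted(r for s, r in self.data if s == subject)

    def run_keys(self) -> list:
        return sorted(self.data.keys())

    def n_timepoints(self, subject, run) -> int:
        return self.data[(subject, run)].shape[1]

    @property
    def min_timepoints(self) -> int:
        return min(mat.shape[1] for mat in self.data.values())

    # -- preprocessing ------------------------------------------------------
    def preprocessed(self, per_voxel_variance: bool = False) -> "MultiRunDataset":
        new = {
            key: preprocess_run(mat, per_voxel_variance=per_voxel_variance)
            for key, mat in self.data.items()
        }
        meta = dict(self.meta)
        meta["preprocessed"] = True
        meta["normalisation"] = (
            "per-voxel demean, per-voxel variance + grand variance 1"
            if per_voxel_variance
            else "per-voxel demean, grand variance 1"
        )
        return MultiRunDataset(new, self.mask.copy(), self.tr, meta)


def preprocess_run(raw: np.ndarray, per_voxel_variance: bool = False) -> np.ndarray:
    """Demean each voxel and scale the run to unit grand variance.

    The transformation is affine per voxel.  The grand variance is the mean
    over voxels of the per-voxel temporal variance; after preprocessing it
    equals 1 exactly.  With ``per_voxel_variance=True`` every non-constant
    voxel is additionally scaled to equal temporal variance.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 2 or raw.shape[1] < 2:
        raise ConfigurationError("preprocess_run expects a V x T matrix with V, T >= 2")
    out = raw - raw.mean(axis=1, keepdims=True)
    var = out.var(axis=1)
    if per_voxel_variance:
        nz = var > 0
        if not np.any(nz):
            raise DegenerateDataError("input has zero variance in every voxel")
        out[nz] /= np.sqrt(var[nz])[:, None]
        var = out.var(axis=1)
    grand = var.mean()
    if grand <= 0:
        raise DegenerateDataError("input has zero variance in every voxel")
    return out / np.sqrt(grand)


def apply_dof_correction(c: float, likelihood_stats):
    """Scale data-derived likelihood statistics by the dof factor ``c``.

    Accepts an array or a mapping of arrays and returns the same structure
    with every entry multiplied by ``c``.  Prior contributions must not be
    passed through this function.  ``c = 1`` is the identity.
    """
    if not (0.0 < c <= 1.0):
        raise ConfigurationError(f"dof factor must lie in (0, 1], got {c}")
    if isinstance(likelihood_stats, Mapping):
        return {k: apply_dof_correction(c, v) for k, v in likelihood_stats.items()}
    return c * np.asarray(likelihood_stats, dtype=float)


# ---------------------------------------------------------------------------
# Model configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Configuration of a probabilistic functional mode decomposition.

    ``beta_families`` optionally maps run index -> family label to give each
    experimental condition its own group-level netmat hyperprior; by default
    all runs share a single group netmat.  ``pool_runs`` shares one temporal
    precision matrix ``alpha`` across all runs of a subject.
    """

    M: int
    dof_factor: float = 1.0
    pool_runs: bool = False
    beta_families: dict | None = None
    tol: float = 1e-6
    tol_sweeps: int = 3
    max_sweeps: int = 200
    prune_map_threshold: float = 1e-3
    prune_amp_threshold: float = 1e-3
    prune_after: int = 20
    seed: int = 0
    per_voxel_variance: bool = False
    spatial: "object" = None     # SpatialHyperpriors, resolved lazily
    temporal: "object" = None    # TemporalHyperpriors, depends on M
    amplitude: "object" = None   # AmplitudeHyperpriors, depends on M
    a_psi: float = 1e-3
    b_psi: float = 1e-3

    def __post_init__(self):
        if self.M < 1:
            raise ConfigurationError(f"mode count M must be >= 1, got {self.M}")
        if not (0.0 < self.dof_factor <= 1.0):
            raise ConfigurationError(
                f"dof factor must lie in (0, 1], got {self.dof_factor}"
            )
        if self.a_psi <= 0 or self.b_psi <= 0:
            raise ConfigurationError("noise hyperprior constants must be positive")
        from .spatial import SpatialHyperpriors
        from .temporal import TemporalHyperpriors
        from .amplitude import AmplitudeHyperpriors

        if self.spatial is None:
            self.spatial = SpatialHyperpriors()
        if self.temporal is None:
            self.temporal = TemporalHyperpriors.default(self.M)
        if self.amplitude is None:
            self.amplitude = AmplitudeHyperpriors.default(self.M)

    def validate_for(self, dataset: MultiRunDataset) -> None:
        bound = min(dataset.n_voxels, dataset.min_timepoints)
        if self.M >= bound:
            raise ConfigurationError(
                f"M={self.M} must be smaller than min(V, min T)={bound}"
            )


def subject_spatial_parameter_count(n_subjects: int, n_voxels: int, n_modes: int) -> int:
    """Number of scalars in the subject-level spatial posterior.

    Each (subject, voxel, mode) triple stores exactly five scalars: the
    signal-branch mean and variance, the noise-branch mean and variance, and
    the membership responsibility.  The count is structural: it is derived
    from the posterior layout, not from an allocated array.
    """
    from .spatial import SubjectSpatialPosterior

    n_fields = len(SubjectSpatialPosterior.PER_VOXEL_FIELDS)
    return int(n_subjects) * int(n_voxels) * int(n_modes) * n_fields
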