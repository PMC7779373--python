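"""Regression baselines: single regression, dual regression, group ICA.

Single regression maps the data onto fixed time courses in one least-squares
step; its error is exactly the projected noise (P-hat = P + eps A^-1 in the
square full-rank case).  Dual regression first regresses the run on group
maps to get time courses, then regresses the run on those time courses to
get subject maps.  Because both stages share the same noise, the two
projections cancel in the square full-rank case and the maps are recovered
exactly, whatever the additive noise.  The thresholded variant zeroes
non-positive map weights after stage 2 and re-regresses to obtain cleaner
time courses for netmat estimation, reducing the spatial contamination of
the temporal correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import ConfigurationError, MultiRunDataset
from ._math import cov_to_partial_corr


@dataclass
class DRResult:
    """Stage-wise dual-regression output for one run."""

    timecourses: np.ndarray           # (M, T) stage-1
    subject_maps: np.ndarray          # (V, M) stage-2
    final_timecourses: np.ndarray     # (M, T) stage-3 for thresholded variant,
                                      # otherwise identical to stage-1
    variant: str
    dropped_modes: np.ndarray | None = None


def single_regression(timecourses: np.ndarray, run: np.ndarray) -> np.ndarray:
    """OLS spatial maps given fixed time courses: P-hat = D A^T (A A^T)^-1."""
    a = np.asarray(timecourses, float)
    sol, *_ = np.linalg.lstsq(a.T, np.asarray(run, float).T, rcond=None)
    return sol.T


def dual_regression(group_maps: np.ndarray, run: np.ndarray) -> DRResult:
    """Standard two-stage dual regression (no shrinkage, no normalisation)."""
    g = np.asarray(group_maps, float)
    d = np.asarray(run, float)
    if np.linalg.matrix_rank(g) < g.shape[1]:
        raise ConfigurationError("group maps are rank deficient")
    tc, *_ = np.linalg.lstsq(g, d, rcond=None)              # stage 1
    maps, *_ = np.linalg.lstsq(tc.T, d.T, rcond=None)       # stage 2
    return DRResult(
        timecourses=tc, subject_maps=maps.T, final_timecourses=tc,
        variant="standard",
    )


def threshold_maps(maps: np.ndarray, rule: str = "positive",
                   percentile: float = 75.0) -> np.ndarray:
    """Zero map weights below the threshold rule (default: keep positives)."""
    m = np.asarray(maps, float).copy()
    if rule == "positive":
        m[m <= 0] = 0.0
    elif rule == "percentile":
        thr = np.percentile(m, percentile, axis=0)
        m[m < thr[None, :]] = 0.0
    else:
        raise ConfigurationError(f"unknown threshold rule {rule!r}")
    return m


def thresholded_dual_regression(group_maps: np.ndarray, run: np.ndarray,
                                rule: str = "positive",
                                percentile: float = 75.0) -> DRResult:
    """Dual regression with post-stage-2 map thresholding and re-regression."""
    base = dual_regression(group_maps, run)
    thr = threshold_maps(base.subject_maps, rule=rule, percentile=percentile)
    nonzero = np.any(thr != 0, axis=0)
    dropped = np.flatnonzero(~nonzero)
    if dropped.size:
        warnings.warn(
            f"{dropped.size} mode(s) thresholded to zero; dropped from stage 3",
            RuntimeWarning, stacklevel=2,
        )
    final = base.timecourses.copy()
    if np.any(nonzero):
        tc, *_ = np.linalg.lstsq(thr[:, nonzero], np.asarray(run, float), rcond=None)
        final[nonzero] = tc
    return DRResult(
        timecourses=base.timecourses, subject_maps=thr, final_timecourses=final,
        variant="thresholded", dropped_modes=dropped,
    )


def group_ica(dataset: MultiRunDataset, n_modes: int, seed: int = 0) -> np.ndarray:
    """Spatial group ICA: temporal concatenation, PCA reduction, FastICA.

    Returns V x M variance-normalised group maps.  This is deliberately thin
    plumbing around scikit-learn's FastICA; it exists to seed dual
    regression, not as a contribution in itself.
    """
    from sklearn.decomposition import FastICA
    from sklearn.utils.extmath import randomized_svd

    d_cat = np.concatenate([dataset.data[k] for k in dataset.run_keys()], axis=1)
    rank_bound = min(d_cat.shape) - 1
    if n_modes > rank_bound:
        raise ConfigurationError(f"M={n_modes} exceeds the data rank bound {rank_bound}")
    u, sv, _ = randomized_svd(d_cat, n_components=n_modes,
                              random_state=int(seed) % (2 ** 31))
    reduced = u * sv  # (V, M): spatial representation of the top subspace
    ica = FastICA(
        n_components=n_modes, random_state=int(seed) % (2 ** 31),
        whiten="unit-variance", max_iter=1000, tol=1e-6,
    )
    maps = ica.fit_transform(reduced)  # voxels are samples -> spatial ICA
    maps = maps / maps.std(axis=0, keepdims=True)
    # sign convention: positive skew
    flip = np.sum(maps ** 3, axis=0) < 0
    maps[:, flip] *= -1.0
    return maps


def netmat_partial_corr(timecourses: np.ndarray, ridge: float = 0.01) -> np.ndarray:
    """Partial correlations between mode time courses.

    Inverts the (optionally ridge-regularised) empirical covariance and
    normalises to unit diagonal with the conventional off-diagonal sign flip.
    ``ridge`` scales the identity added to the covariance relative to its
    mean diagonal.
    """
    a = np.asarray(timecourses, float)
    m, t = a.shape
    if ridge <= 0 and t <= m:
        raise ConfigurationError("need T > M for an unregularised partial correlation")
    cov = np.cov(a)
    if m == 1:
        return np.ones((1, 1))
    return cov_to_partial_corr(cov, ridge=ridge)
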