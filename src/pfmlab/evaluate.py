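"""Recovery and bias metrics for comparing decompositions against ground truth.

Four metrics summarise how well a method recovers the simulated truth:

* spatial accuracy — mean Pearson correlation between estimated and true
  subject maps, after matching modes and aligning signs;
* netmat accuracy — correlation between the vectorised off-diagonal partial
  correlations of the estimated and true run netmats;
* amplitude accuracy — per-mode cross-subject correlation of *relative*
  amplitudes (each method's amplitudes are divided by their cross-subject
  mean per mode, removing scale conventions);
* spatial->temporal bias — correlation, across mode pairs and runs, between
  the netmat error (estimated minus true temporal correlation) and the
  subject's true spatial map correlation.  Zero means the temporal estimates
  are not contaminated by spatial overlap; dual regression characteristically
  shows positive values.

Mode matching is computed once from group-level maps (Hungarian assignment
on absolute spatial correlation) and applied to all subject-level
quantities.  All four metrics are invariant to mode permutations and sign
flips of the estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .datasets import PFMError
from .engine import match_modes, _column_corr
from .simulate import GroundTruth
from ._math import cov_to_partial_corr


def _offdiag(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return np.asarray(mat)[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x, y = np.asarray(x, float).ravel(), np.asarray(y, float).ravel()
    xs, ys = x.std(), y.std()
    if xs == 0 or ys == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class MethodEstimates:
    """One method's estimates in a common layout.

    ``subject_maps``: subject -> (V, M); ``netmats``: (s, r) -> (M, M)
    partial correlations; ``amplitudes``: (s, r) -> (M,); ``group_maps``:
    (V, M) used for matching.
    """

    name: str
    group_maps: np.ndarray
    subject_maps: dict
    netmats: dict
    amplitudes: dict


@dataclass
class EvalReport:
    """Per-method metrics, per dataset and pooled."""

    per_dataset: list = field(default_factory=list)   # list of {method: {metric: v}}

    def pooled(self) -> dict:
        if not self.per_dataset:
            return {}
        methods = self.per_dataset[0].keys()
        out = {}
        for meth in methods:
            out[meth] = {
                k: float(np.mean([d[meth][k] for d in self.per_dataset]))
                for k in self.per_dataset[0][meth]
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"per_dataset": self.per_dataset, "pooled": self.pooled()},
                      fh, indent=2)

    def to_table(self) -> "object":
        import pandas as pd

        rows = []
        for i, d in enumerate(self.per_dataset):
            for meth, metrics in d.items():
                rows.append({"dataset": i, "method": meth, **metrics})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The four metrics
# ---------------------------------------------------------------------------

def spatial_accuracy(est: MethodEstimates, truth: GroundTruth,
                     perm=None, signs=None) -> float:
    """Mean matched correlation between estimated and true subject maps."""
    if perm is None:
        perm, signs = match_modes(est.group_maps, truth.group_maps)
    vals = []
    for s, true_maps in truth.subject_maps.items():
        e = est.subject_maps[s]
        if e.shape[0] != true_maps.shape[0]:
            raise PFMError("subject map dimensions do not match the truth")
        aligned = e[:, perm] * signs[None, :]
        c = _column_corr(aligned, true_maps)
        vals.extend(np.diag(c))
    return float(np.mean(vals))


def netmat_accuracy(est: MethodEstimates, truth: GroundTruth,
                    perm=None, signs=None) -> float:
    """Correlation of vectorised off-diagonal partials, averaged over runs."""
    if perm is None:
        perm, signs = match_modes(est.group_maps, truth.group_maps)
    vals = []
    for key, true_c in truth.netmats.items():
        true_p = cov_to_partial_corr(true_c)
        e = est.netmats[key]
        aligned = (e[np.ix_(perm, perm)]) * np.outer(signs, signs)
        vals.append(_pearson(_offdiag(aligned), _offdiag(true_p)))
    return float(np.mean(vals))


def amplitude_accuracy(est: MethodEstimates, truth: GroundTruth,
                       perm=None, signs=None) -> float:
    """Cross-subject correlation of relative amplitudes, averaged over modes.

    Because every method (and the internal data normalisation) fixes the
    overall scale of each run by its own convention, only *relative*
    amplitudes are comparable: each run's amplitude vector is divided by its
    mean over modes (on both the estimate and the truth), runs are averaged
    within subject, each mode is divided by its cross-subject mean, and the
    result is correlated with the truth across subjects, per mode.
    """
    if perm is None:
        perm, signs = match_modes(est.group_maps, truth.group_maps)
    subjects = sorted(truth.subject_maps)
    if len(subjects) < 3:
        raise PFMError("amplitude accuracy needs at least 3 subjects")

    def per_subject(amp_dict, order=None):
        rows = []
        for s in subjects:
            runs = [np.asarray(amp_dict[k], float) for k in sorted(amp_dict)
                    if k[0] == s]
            runs = [a / np.maximum(a.mean(), 1e-12) for a in runs]
            a = np.mean(runs, axis=0)
            rows.append(a[order] if order is not None else a)
        return np.asarray(rows)  # (S, M)

    est_a = per_subject(est.amplitudes, order=perm)
    true_a = per_subject(truth.amplitudes)
    est_a = est_a / np.maximum(est_a.mean(axis=0, keepdims=True), 1e-12)
    true_a = true_a / np.maximum(true_a.mean(axis=0, keepdims=True), 1e-12)
    vals = [_pearson(est_a[:, j], true_a[:, j]) for j in range(true_a.shape[1])]
    return float(np.mean(vals))


def spatial_temporal_bias(est: MethodEstimates, truth: GroundTruth,
                          perm=None, signs=None, statistic: str = "pearson") -> float:
    """Correlation between netmat errors and true spatial correlations.

    Pools mode pairs over all runs.  ``statistic='slope'`` returns the
    regression slope of the error on the spatial correlation instead.
    """
    if perm is None:
        perm, signs = match_modes(est.group_maps, truth.group_maps)
    errors, spatial = [], []
    for key, true_c in truth.netmats.items():
        true_p = cov_to_partial_corr(true_c)
        e = est.netmats[key]
        aligned = (e[np.ix_(perm, perm)]) * np.outer(signs, signs)
        errors.append(_offdiag(aligned) - _offdiag(true_p))
        spatial.append(_offdiag(truth.spatial_corr[key[0]]))
    err = np.concatenate(errors)
    spa = np.concatenate(spatial)
    if statistic == "slope":
        if spa.std() == 0:
            return 0.0
        return float(np.polyfit(spa, err, 1)[0])
    return _pearson(err, spa)


def evaluate_method(est: MethodEstimates, truth: GroundTruth) -> dict:
    """All four metrics for one method on one dataset."""
    perm, signs = match_modes(est.group_maps, truth.group_maps)
    return {
        "spatial_accuracy": spatial_accuracy(est, truth, perm, signs),
        "netmat_accuracy": netmat_accuracy(est, truth, perm, signs),
        "amplitude_accuracy": amplitude_accuracy(est, truth, perm, signs),
        "spatial_temporal_bias": spatial_temporal_bias(est, truth, perm, signs),
    }


# ---------------------------------------------------------------------------
# Method wrappers producing MethodEstimates
# ---------------------------------------------------------------------------

def estimates_from_pfm(result) -> MethodEstimates:
    """Package a fitted PFM decomposition for evaluation."""
    from ._math import precision_to_partial_corr

    netmats = {}
    amplitudes = {}
    for key in result.temporal_runs:
        netmats[key] = precision_to_partial_corr(result.run_netmat(*key))
        amplitudes[key] = result.run_amplitudes(*key)
    return MethodEstimates(
        name="PROFUMO",
        group_maps=result.group_maps(),
        subject_maps={s: result.subject_maps(s) for s in result.subjects},
        netmats=netmats,
        amplitudes=amplitudes,
    )


def estimates_from_dr(dataset, group_maps, variant: str = "standard",
                      name: str | None = None, ridge: float = 0.01) -> MethodEstimates:
    """Run dual regression on every run and package the results.

    Subject maps are averaged over each subject's runs; netmats are partial
    correlations of the (stage-3 for the thresholded variant) time courses;
    amplitudes are the stage-1 time-course standard deviations.
    """
    from . import baselines as bl

    per_run = {}
    for key in dataset.run_keys():
        run = dataset.data[key]
        if variant == "thresholded":
            per_run[key] = bl.thresholded_dual_regression(group_maps, run)
        else:
            per_run[key] = bl.dual_regression(group_maps, run)
    subject_maps = {}
    for s in dataset.subjects:
        maps = [per_run[(s, r)].subject_maps for r in dataset.runs(s)]
        subject_maps[s] = np.mean(maps, axis=0)
    netmats = {
        key: bl.netmat_partial_corr(res.final_timecourses, ridge=ridge)
        for key, res in per_run.items()
    }
    amplitudes = {
        key: res.timecourses.std(axis=1) for key, res in per_run.items()
    }
    return MethodEstimates(
        name=name or f"DR-{variant}",
        group_maps=np.asarray(group_maps, float),
        subject_maps=subject_maps,
        netmats=netmats,
        amplitudes=amplitudes,
    )


def compare_methods(dataset, truth: GroundTruth, n_modes: int, seed: int = 0,
                    config=None, methods=("PROFUMO", "ICA-DR", "ICA-DRt",
                                          "GTg-DR", "GTg-DRt")) -> dict:
    """Fit the model and the dual-regression baselines on one dataset.

    Returns {method name: {metric: value}}.  ICA-seeded and ground-truth-
    seeded (GTg) dual regression come in standard and thresholded (t)
    variants, mirroring the usual comparison suite.
    """
    from . import baselines as bl
    from .datasets import ModelConfig
    from .engine import fit

    pre = dataset.preprocessed() if not dataset.meta.get("preprocessed") else dataset
    out = {}
    if any(m.startswith("ICA") for m in methods):
        ica_maps = bl.group_ica(pre, n_modes, seed=seed)
    for meth in methods:
        if meth == "PROFUMO":
            cfg = config or ModelConfig(M=n_modes, seed=seed)
            est = estimates_from_pfm(fit(pre, cfg))
        elif meth == "ICA-DR":
            est = estimates_from_dr(pre, ica_maps, "standard", name=meth)
        elif meth == "ICA-DRt":
            est = estimates_from_dr(pre, ica_maps, "thresholded", name=meth)
        elif meth == "GTg-DR":
            est = estimates_from_dr(pre, truth.group_maps, "standard", name=meth)
        elif meth == "GTg-DRt":
            est = estimates_from_dr(pre, truth.group_maps, "thresholded", name=meth)
        else:
            raise PFMError(f"unknown method {meth!r}")
        out[meth] = evaluate_method(est, truth)
    return out
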