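"""Synthetic multi-subject fMRI generator with ground truth.

The generator reproduces the statistical structure that makes multi-subject
mode estimation hard: spatially overlapping, temporally correlated modes;
subject-specific misalignment (smooth displacement of functional regions,
plus mixed displaced copies approximating non-homotopic splits);
cross-subject amplitude variability with correlation between modes; a weakly
nonlinear haemodynamic response that varies over subjects and (through a
smooth mixing field) over space; spatially and temporally smooth residuals;
and optional rank-1 structured artefacts per subject.

Maps live on a 1-D voxel lattice: the model is voxelwise exchangeable, so
geometry enters only through smoothness and misalignment, and a 1-D lattice
keeps desk-scale cost low.  A thin wrapper embeds the lattice in a NIfTI
volume for I/O testing (see :mod:`pfmlab.io`).

The default dimensions are 15 modes, 40 subjects with two runs each, 10,000
voxels and 500 time points at TR 2.0 s; replication studies pool 10
datasets (see :func:`batch_generate`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .datasets import ConfigurationError, MultiRunDataset
from .temporal import canonical_hrf
from ._math import cov2corr


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_modes: int = 15
    n_subjects: int = 40
    n_runs: int = 2
    n_voxels: int = 10_000
    n_timepoints: int = 500
    tr: float = 2.0
    # spatial structure
    spatial_overlap: float = 0.5      # 0 = well separated blobs, 1 = heavy overlap
    misalignment: float | None = None  # displacement-field std in voxels;
                                       # None -> half the blob width (residual
                                       # misalignment comparable to functional
                                       # region size)
    split_weight: float = 0.15        # weight of the second displaced copy
    map_jitter: float = 0.2           # sd of smooth subject-specific weight jitter
    additive_map_noise: bool = False  # additive (model-style) instead of
                                      # multiplicative weight jitter
    # temporal structure
    temporal_corr_strength: float = 0.4
    netmat_dof_factor: float = 10.0   # run netmats ~ Wishart(dof_factor * M, group)
    # haemodynamics
    hrf_variability: float = 0.5      # subject delay jitter, seconds
    hrf_nonlinearity: float = 0.1     # saturation strength kappa
    # amplitudes
    amp_spread: float = 0.3           # lognormal sigma across subjects
    amp_correlation: float = 0.5      # cross-mode correlation of subject amplitudes
    # residuals
    snr: float = 1.0                  # signal variance / residual variance
    residual_smooth_space: float = 2.0
    residual_smooth_time: float = 1.0
    # structured noise
    artefacts: str = "off"            # off | spatial | global
    artefact_strength: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_modes", "n_subjects", "n_runs", "n_voxels", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_modes > self.n_voxels:
            raise ConfigurationError("more modes than voxels is infeasible")
        if self.snr <= 0:
            raise ConfigurationError("SNR must be positive")
        if self.misalignment is None:
            self.misalignment = 0.5 * self.blob_sigma()
        if self.misalignment < 0:
            raise ConfigurationError("misalignment must be non-negative")
        if self.artefacts not in ("off", "spatial", "global"):
            raise ConfigurationError(f"unknown artefact mode {self.artefacts!r}")

    def blob_sigma(self) -> float:
        """Gaussian width of the primary mode blobs, in voxels."""
        return (self.n_voxels / self.n_modes) * (0.12 + 0.24 * self.spatial_overlap)


def desk_preset(**overrides) -> SimConfig:
    """Desk-scale preset: 10 modes, 12 subjects x 2 runs, 2000 voxels, 300 TRs."""
    base = dict(n_modes=10, n_subjects=12, n_runs=2, n_voxels=2000, n_timepoints=300)
    base.update(overrides)
    return SimConfig(**base)


def model_matched_preset(**overrides) -> SimConfig:
    """Conditions under which the generative process matches the model exactly:
    no misalignment, a single linear canonical HRF, white residuals."""
    base = dict(
        n_modes=5, n_subjects=6, n_runs=1, n_voxels=500, n_timepoints=200,
        misalignment=0.0, split_weight=0.0, hrf_variability=0.0,
        hrf_nonlinearity=0.0, residual_smooth_space=0.0,
        residual_smooth_time=0.0, snr=1.0, artefacts="off",
        additive_map_noise=True,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class GroundTruth:
    """Everything the generator knows, for evaluation."""

    config: SimConfig
    group_maps: np.ndarray            # (V, M)
    subject_maps: dict                # s -> (V, M)
    neural: dict                      # (s, r) -> (M, T) white neuronal processes
    bold: dict                        # (s, r) -> (M, T) post-HRF time courses
    amplitudes: dict                  # (s, r) -> (M,)
    netmats: dict                     # (s, r) -> (M, M) neural correlation matrices
    spatial_corr: dict                # s -> (M, M) subject map correlations
    group_netmat: np.ndarray          # (M, M)
    realised_snr: float = np.nan


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _smooth_field(rng, n, smooth, std=1.0):
    x = rng.standard_normal(n)
    if smooth > 0:
        x = gaussian_filter1d(x, smooth, mode="wrap")
    s = x.std()
    return x / s * std if s > 0 else x


def _group_maps(rng, cfg: SimConfig) -> np.ndarray:
    v, m = cfg.n_voxels, cfg.n_modes
    x = np.arange(v, dtype=float)
    spacing = v / m
    # blob support ~ 4 sigma: 10-25% of the lattice per mode, rising with overlap
    sigma = cfg.blob_sigma()
    maps = np.zeros((v, m))
    centers = (np.arange(m) + 0.5) * spacing
    for j in range(m):
        c = centers[j] + rng.uniform(-0.2, 0.2) * spacing
        maps[:, j] = np.exp(-0.5 * ((x - c) / sigma) ** 2)
        # secondary blob inside another mode's territory: genuinely shared
        # voxels, giving the spatial correlations between modes that make
        # group-seeded regression hard
        if cfg.spatial_overlap > 0 and m > 1:
            other = (j + 1 + rng.integers(m - 1)) % m
            c2 = centers[other] + rng.uniform(-0.3, 0.3) * sigma
            w2 = cfg.spatial_overlap * rng.uniform(0.4, 0.8)
            maps[:, j] += w2 * np.exp(-0.5 * ((x - c2) / (0.7 * sigma)) ** 2)
        maps[:, j] /= maps[:, j].max()
    return maps


def _displace(field_map: np.ndarray, displacement: np.ndarray) -> np.ndarray:
    v = field_map.shape[0]
    x = np.arange(v, dtype=float)
    return np.interp(np.clip(x + displacement, 0, v - 1), x, field_map)


def _subject_maps(rng, cfg: SimConfig, group: np.ndarray) -> np.ndarray:
    v, m = group.shape
    out = np.empty_like(group)
    if cfg.misalignment > 0:
        d1 = _smooth_field(rng, v, 0.05 * v, cfg.misalignment)
        d2 = _smooth_field(rng, v, 0.05 * v, cfg.misalignment)
    else:
        d1 = d2 = np.zeros(v)
    w = cfg.split_weight if cfg.misalignment > 0 else 0.0
    for j in range(m):
        warped = (1 - w) * _displace(group[:, j], d1) + w * _displace(group[:, j], d2)
        if cfg.map_jitter > 0:
            if cfg.additive_map_noise:
                # the model's own subject variability: voxelwise-independent
                # additive deviations, full strength on the mode's support
                # plus a small spurious-weight floor elsewhere
                support = (np.abs(group[:, j]) > 0.1 * np.abs(group[:, j]).max())
                eps = rng.standard_normal(v)
                scale = np.where(support, cfg.map_jitter, 0.25 * cfg.map_jitter)
                warped = warped + scale * eps
            else:
                warped = warped * np.exp(_smooth_field(rng, v, 0.02 * v,
                                                       cfg.map_jitter))
        out[:, j] = warped
    return out


def _group_netmat(rng, cfg: SimConfig) -> np.ndarray:
    """Random group-level correlation matrix with controllable strength."""
    m = cfg.n_modes
    if cfg.temporal_corr_strength <= 0:
        return np.eye(m)
    n_factors = max(2, m // 3)
    load = rng.standard_normal((m, n_factors)) * cfg.temporal_corr_strength
    cov = np.eye(m) + load @ load.T
    return cov2corr(cov)


def _run_netmat(rng, cfg: SimConfig, group_netmat: np.ndarray) -> np.ndarray:
    m = group_netmat.shape[0]
    dof = max(cfg.netmat_dof_factor * m, m + 1)
    sample = np.zeros((m, m))
    chol = np.linalg.cholesky(group_netmat / dof)
    draws = chol @ rng.standard_normal((m, int(round(dof))))
    sample = draws @ draws.T
    return cov2corr(sample)


def hrf_pad(tr: float) -> int:
    """Burn-in samples needed for steady-state HRF convolution."""
    return int(np.ceil(32.0 / tr))


def _hrf_convolve(neural_ext: np.ndarray, tr: float, peak_delay: float,
                  nonlinearity: float, n_out: int) -> np.ndarray:
    """Convolve padded neural processes and keep the steady-state tail.

    ``neural_ext`` carries ``hrf_pad(tr)`` extra leading samples so the
    returned segment has the full stationary autocorrelation of the kernel
    (no start-up transient).
    """
    t_hrf = np.arange(0.0, 32.0, tr)
    h = canonical_hrf(t_hrf, peak_delay=peak_delay)
    pad = neural_ext.shape[1] - n_out
    out = np.empty((neural_ext.shape[0], n_out))
    for j in range(neural_ext.shape[0]):
        out[j] = np.convolve(neural_ext[j], h)[pad: pad + n_out]
    if nonlinearity > 0:
        out = out + nonlinearity * (np.tanh(out) - out)
    out = out - out.mean(axis=1, keepdims=True)
    std = out.std(axis=1)
    std[std == 0] = 1.0
    return out / std[:, None]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate(config: SimConfig) -> tuple[MultiRunDataset, GroundTruth]:
    """Simulate one multi-subject dataset with full ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    v, m, t = cfg.n_voxels, cfg.n_modes, cfg.n_timepoints

    group = _group_maps(rng, cfg)
    group_netmat = _group_netmat(rng, cfg)

    # cross-subject amplitude structure: two functional "systems" whose
    # amplitudes correlate positively within and negatively across (a global
    # common factor would be removed by any per-run normalisation, so the
    # recoverable structure is the categorical one)
    rho = cfg.amp_correlation
    loading = np.where(np.arange(m) < (m + 1) // 2, 1.0, -1.0)
    amp_cov = cfg.amp_spread ** 2 * (
        (1 - rho) * np.eye(m) + rho * np.outer(loading, loading)
    )
    amp_chol = np.linalg.cholesky(amp_cov + 1e-12 * np.eye(m))

    subject_maps, neural, bold, amplitudes, netmats, spatial_corr = (
        {}, {}, {}, {}, {}, {}
    )
    data = {}
    sig_var_acc, noise_var_acc = 0.0, 0.0

    for s in range(cfg.n_subjects):
        p_s = _subject_maps(rng, cfg, group)
        subject_maps[s] = p_s
        spatial_corr[s] = np.corrcoef(p_s.T)
        z_s = amp_chol @ rng.standard_normal(m)
        peak_delay = float(np.clip(6.0 + rng.normal(0, cfg.hrf_variability), 3.0, 10.0))

        if cfg.artefacts != "off":
            if cfg.artefacts == "spatial":
                center = rng.uniform(0, v)
                width = 0.02 * v
                profile = np.exp(-0.5 * ((np.arange(v) - center) / width) ** 2)
            else:
                profile = _smooth_field(rng, v, 0.05 * v)
            profile = profile / max(np.linalg.norm(profile), 1e-12)
        else:
            profile = None

        for r in range(cfg.n_runs):
            c_r = _run_netmat(rng, cfg, group_netmat)
            netmats[(s, r)] = c_r
            pad = hrf_pad(cfg.tr)
            x_ext = np.linalg.cholesky(c_r) @ rng.standard_normal((m, t + pad))
            neural[(s, r)] = x_ext[:, pad:]
            if cfg.hrf_variability > 0:
                a1 = _hrf_convolve(x_ext, cfg.tr,
                                   peak_delay - 0.25 * cfg.hrf_variability,
                                   cfg.hrf_nonlinearity, t)
                a2 = _hrf_convolve(x_ext, cfg.tr,
                                   peak_delay + 0.25 * cfg.hrf_variability,
                                   cfg.hrf_nonlinearity, t)
            else:
                a1 = _hrf_convolve(x_ext, cfg.tr, peak_delay,
                                   cfg.hrf_nonlinearity, t)
                a2 = a1
            bold[(s, r)] = a1
            h_sr = np.exp(z_s + rng.normal(0, cfg.amp_spread / 3.0, size=m))
            amplitudes[(s, r)] = h_sr

            if a2 is a1:
                signal = (p_s * h_sr[None, :]) @ a1
            else:
                # smooth spatial mixing of two HRF variants (space-varying HRF)
                wmix = 0.5 * (1.0 + np.tanh(_smooth_field(rng, v, 0.05 * v)))
                signal = ((p_s * (1 - wmix)[:, None]) * h_sr[None, :]) @ a1 \
                    + ((p_s * wmix[:, None]) * h_sr[None, :]) @ a2

            sig_var = float(signal.var())
            if np.isfinite(cfg.snr) and sig_var > 0:
                eps = rng.standard_normal((v, t))
                if cfg.residual_smooth_space > 0:
                    eps = gaussian_filter1d(eps, cfg.residual_smooth_space, axis=0,
                                            mode="wrap")
                if cfg.residual_smooth_time > 0:
                    eps = gaussian_filter1d(eps, cfg.residual_smooth_time, axis=1,
                                            mode="wrap")
                eps *= np.sqrt(sig_var / (cfg.snr * eps.var()))
            else:
                eps = np.zeros((v, t))

            d = signal + eps
            if profile is not None:
                art_tc = _smooth_field(rng, t, 2.0)
                d = d + (cfg.artefact_strength * np.sqrt(max(sig_var, 1e-12))
                         * np.outer(profile * np.sqrt(v), art_tc))
            data[(s, r)] = d
            sig_var_acc += sig_var
            noise_var_acc += float(eps.var())

    realised = sig_var_acc / noise_var_acc if noise_var_acc > 0 else np.inf
    dataset = MultiRunDataset(
        data, np.ones(v, dtype=bool), cfg.tr,
        meta={"simulated": True, "seed": cfg.seed, "realised_snr": realised},
    )
    truth = GroundTruth(
        config=cfg, group_maps=group, subject_maps=subject_maps, neural=neural,
        bold=bold, amplitudes=amplitudes, netmats=netmats,
        spatial_corr=spatial_corr, group_netmat=group_netmat,
        realised_snr=realised,
    )
    return dataset, truth


def batch_generate(config: SimConfig, n_datasets: int = 10) -> list:
    """Independent replicate datasets with seeds seed+0 .. seed+n-1."""
    return [generate(replace(config, seed=config.seed + i)) for i in range(n_datasets)]
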