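"""Mean-field variational inference for probabilistic functional modes.

Coordinate-ascent sweeps cycle through the factors in a fixed order (subject
maps, group spatial hyperparameters, amplitudes, time courses, netmats,
temporal noise, global noise, amplitude hyperparameters).  Every update is
an exact conditional maximisation of the evidence lower bound, so the free
energy is non-decreasing across sweeps; the single exception is the
post-hoc amplitude positivity flip, whose effect on the bound is limited to
the amplitude prior term and is negligible in practice after the first few
sweeps.

Initialisation uses a randomized SVD of the (per-subject dimension-reduced)
temporally concatenated data followed by a varimax rotation, with subject
maps seeded by ridge regression against the group maps.  Everything is
driven by a single seed, and a fit is a deterministic function of
(dataset, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from . import spatial as sp
from . import temporal as tm
from . import amplitude as am
from . import noise as ns
from .datasets import ConfigurationError, ModelConfig, MultiRunDataset, NumericalError
from ._math import (
    LOG_2PI,
    beta_kl,
    gamma_kl,
    gaussian_entropy,
    gaussian_kl_diag_prior,
    wishart_E_logp,
    wishart_E_logq,
)

logger = logging.getLogger(__name__)

RIDGE_FRACTION = 0.01


@dataclass
class PFMResult:
    """All variational posteriors plus the per-sweep free-energy trace."""

    config: ModelConfig
    group_spatial: sp.GroupSpatialPosterior
    subjects: dict                    # subject -> SubjectSpatialPosterior
    temporal_runs: dict               # (subject, run) -> RunTemporalPosterior
    alpha: dict                       # alpha key -> WishartPosterior
    group_temporal: tm.GroupTemporalPosterior
    amplitude: am.AmplitudePosterior
    noise: ns.NoisePosterior
    free_energy: list = field(default_factory=list)
    pruned: np.ndarray | None = None
    seed: int = 0
    converged: bool = False
    n_sweeps: int = 0
    dataset: MultiRunDataset | None = field(default=None, repr=False, compare=False)

    # -- convenience accessors ---------------------------------------------
    def group_maps(self) -> np.ndarray:
        return sp.group_map_summary(self.group_spatial)

    def subject_maps(self, subject) -> np.ndarray:
        return self.subjects[subject].E_P

    def alpha_key(self, subject, run):
        return subject if self.config.pool_runs else (subject, run)

    def run_netmat(self, subject, run) -> np.ndarray:
        """Posterior mean run precision matrix E[alpha]."""
        return self.alpha[self.alpha_key(subject, run)].mean

    def run_amplitudes(self, subject, run) -> np.ndarray:
        return self.amplitude.runs[(subject, run)].mean

    def fabt(self, subject, run) -> np.ndarray:
        return tm.compute_fabt(self.temporal_runs[(subject, run)])

    def active_modes(self) -> np.ndarray:
        if self.pruned is None:
            return np.arange(self.config.M)
        return np.flatnonzero(~self.pruned)


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def _varimax(maps: np.ndarray, gamma: float = 1.0, max_iter: int = 100,
             tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation of the columns of ``maps`` (V x M)."""
    v, m = maps.shape
    if m == 1:
        return maps.copy()
    rot = np.eye(m)
    d = 0.0
    for _ in range(max_iter):
        lam = maps @ rot
        u, s, vt = np.linalg.svd(
            maps.T @ (lam ** 3 - (gamma / v) * lam @ np.diag(np.sum(lam ** 2, axis=0)))
        )
        rot = u @ vt
        d_old, d = d, np.sum(s)
        if d_old != 0 and d / d_old < 1 + tol:
            break
    return maps @ rot


def _ridge_timecourses(maps: np.ndarray, data: np.ndarray) -> np.ndarray:
    g = maps.T @ maps
    lam = RIDGE_FRACTION * np.trace(g) / g.shape[0]
    return np.linalg.solve(g + lam * np.eye(g.shape[0]), maps.T @ data)


def _ridge_maps(timecourses: np.ndarray, data: np.ndarray) -> np.ndarray:
    g = timecourses @ timecourses.T
    lam = RIDGE_FRACTION * np.trace(g) / g.shape[0]
    return data @ timecourses.T @ np.linalg.inv(g + lam * np.eye(g.shape[0]))


def initialize(dataset: MultiRunDataset, config: ModelConfig) -> PFMResult:
    """Deterministic initial state from randomized SVD + varimax + ridge."""
    config.validate_for(dataset)
    config.temporal.validate(config.M)
    config.amplitude.validate(config.M)
    m = config.M
    v = dataset.n_voxels
    seed = int(config.seed) % (2 ** 31)
    from sklearn.utils.extmath import randomized_svd

    # per-subject dimension reduction, then group-level SVD
    blocks = []
    for s in dataset.subjects:
        d_s = np.concatenate([dataset.data[(s, r)] for r in dataset.runs(s)], axis=1)
        k = min(m, min(d_s.shape) - 1)
        u, sv, _ = randomized_svd(d_s, n_components=k, random_state=seed)
        blocks.append(u * sv)
    u, sv, _ = randomized_svd(np.concatenate(blocks, axis=1), n_components=m,
                              random_state=seed)
    g_maps = _varimax(u * sv)

    # sign convention: positive skew; scale: unit robust peak ~ main slab
    for j in range(m):
        col = g_maps[:, j]
        if np.sum(col ** 3) < 0:
            col *= -1.0
        peak = np.percentile(np.abs(col), 99)
        if peak > 0:
            col /= peak
        g_maps[:, j] = col

    hyp = config.spatial
    group = sp.GroupSpatialPosterior.from_prior(v, m, hyp)
    robust = 1.4826 * np.median(np.abs(g_maps), axis=0) + 1e-12
    big = np.abs(g_maps) > 2.5 * robust[None, :]
    r0 = np.where(big, 0.05, 0.95)
    group.rho_resp[..., 0] = r0
    group.rho_resp[..., 1] = (1.0 - r0) * 0.9
    group.rho_resp[..., 2] = (1.0 - r0) * 0.1
    group.slab_mean[..., 0] = g_maps
    group.slab_mean[..., 1] = g_maps
    group.slab_var[...] = 0.04

    subjects = {}
    temporal_runs = {}
    kernels: dict[int, tm.HRFKernel] = {}
    run_keys = dataset.run_keys()
    amp = am.AmplitudePosterior.from_prior(run_keys, config.amplitude, m)
    noise = ns.NoisePosterior.from_prior(run_keys, config.a_psi, config.b_psi)

    for s in dataset.subjects:
        d_s = np.concatenate([dataset.data[(s, r)] for r in dataset.runs(s)], axis=1)
        tc_s = _ridge_timecourses(g_maps, d_s)
        p_s = _ridge_maps(tc_s, d_s)
        subjects[s] = sp.SubjectSpatialPosterior(
            signal_mean=p_s,
            signal_var=np.full((v, m), 0.01),
            noise_mean=np.zeros((v, m)),
            noise_var=np.full((v, m), 1e-4),
            responsibility=np.where(big, 0.95, 0.05),
            eta=np.full(m, hyp.gamma_eta),
        )
        for r in dataset.runs(s):
            d = dataset.data[(s, r)]
            t = d.shape[1]
            if t not in kernels:
                kernels[t] = tm.build_hrf_kernel(t, dataset.tr)
            kern = kernels[t]
            tc = _ridge_timecourses(g_maps, d)
            scale = np.maximum(tc.std(axis=1), 1e-6)
            b = tc / scale[:, None]
            _, u_k = kern.eig()
            temporal_runs[(s, r)] = tm.RunTemporalPosterior(
                B_eig_mean=b @ u_k,
                B_cov=np.broadcast_to(0.01 * np.eye(m), (t, m, m)).copy(),
                xi_mean=np.zeros((m, t)),
                xi_cov=0.01 * np.eye(m),
                omega_shape=np.full(m, config.temporal.a_omega),
                omega_rate=np.full(m, config.temporal.b_omega),
                kernel=kern,
            )
            amp.runs[(s, r)].mean = scale.copy()
            resid = d - (g_maps * scale[None, :]) @ b
            resid_var = max(float(resid.var()), 1e-6)
            noise.runs[(s, r)] = ns.RunNoisePosterior(
                shape=config.a_psi + 0.5 * v * t,
                rate=config.b_psi + 0.5 * v * t * resid_var,
            )

    a_alpha = config.temporal.a_alpha
    alpha = {}
    for s in dataset.subjects:
        if config.pool_runs:
            alpha[s] = tm.WishartPosterior(dof=a_alpha, rate=a_alpha * np.eye(m))
        else:
            for r in dataset.runs(s):
                alpha[(s, r)] = tm.WishartPosterior(dof=a_alpha, rate=a_alpha * np.eye(m))

    families = _alpha_families(dataset, config)
    group_temporal = tm.GroupTemporalPosterior(
        families={
            label: tm.WishartPosterior(dof=config.temporal.a_beta,
                                       rate=config.temporal.B_beta.copy())
            for label in families
        }
    )

    return PFMResult(
        config=config,
        group_spatial=group,
        subjects=subjects,
        temporal_runs=temporal_runs,
        alpha=alpha,
        group_temporal=group_temporal,
        amplitude=amp,
        noise=noise,
        seed=config.seed,
        dataset=dataset,
    )


def _alpha_families(dataset: MultiRunDataset, config: ModelConfig) -> dict:
    """family label -> list of alpha keys governed by that group netmat."""
    if config.beta_families is None:
        if config.pool_runs:
            return {"all": list(dataset.subjects)}
        return {"all": dataset.run_keys()}
    if config.pool_runs:
        raise ConfigurationError(
            "condition-specific beta families are incompatible with run pooling"
        )
    families: dict = {}
    for s, r in dataset.run_keys():
        label = config.beta_families.get(r, "all")
        families.setdefault(label, []).append((s, r))
    return families


def _family_of(families: dict, key):
    for label, members in families.items():
        if key in members:
            return label
    raise ConfigurationError(f"alpha key {key!r} belongs to no netmat family")


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _run_moments(state: PFMResult, key):
    run = state.temporal_runs[key]
    ramp = state.amplitude.runs[key]
    e_h = ramp.mean
    e_hht = ramp.second_moment()
    return run, e_h, e_hht


def _update_subject_maps_sweep(state: PFMResult) -> None:
    c = state.config.dof_factor
    group_m = sp.GroupMoments.from_posterior(state.group_spatial)
    for s in state.dataset.subjects:
        subj = state.subjects[s]
        v, m = subj.signal_mean.shape
        proj = np.zeros((v, m))
        w = np.zeros((m, m))
        for r in state.dataset.runs(s):
            key = (s, r)
            run, e_h, e_hht = _run_moments(state, key)
            e_psi = state.noise.runs[key].mean
            d = state.dataset.data[key]
            proj += c * e_psi * (d @ run.E_A.T) * e_h[None, :]
            w += c * e_psi * (e_hht * run.E_AAt())
        ep = subj.E_P
        for j in range(m):
            lp = np.full(v, w[j, j])
            lin = proj[:, j] - ep @ w[:, j] + ep[:, j] * w[j, j]
            with np.errstate(invalid="ignore", divide="ignore"):
                lmean = np.where(lp > 0, lin / np.where(lp > 0, lp, 1.0), 0.0)
            sp.update_subject_maps(lp, lmean, group_m, subj.eta, out=subj, mode=j)
            rj = subj.responsibility[:, j]
            ep[:, j] = rj * subj.signal_mean[:, j] + (1 - rj) * subj.noise_mean[:, j]


def _update_group_spatial_sweep(state: PFMResult) -> None:
    subs = [state.subjects[s] for s in state.dataset.subjects]
    stats = sp.PooledSubjectStats.pool(subs)
    group = state.group_spatial
    hyp = state.config.spatial
    sp.update_group_means(stats, group, hyp)
    sp.update_group_stds(stats, group, hyp)
    sp.update_memberships(stats.n_eff, stats.n_subjects, group, hyp)
    sp.update_noise_scales(subs, group, hyp)


def _update_amplitudes_sweep(state: PFMResult) -> None:
    c = state.config.dof_factor
    for key in state.dataset.run_keys():
        run, _, _ = _run_moments(state, key)
        subj = state.subjects[key[0]]
        d = state.dataset.data[key]
        ptd = subj.E_P.T @ d
        proj_diag = np.einsum("mt,mt->m", ptd, run.E_A)
        am.update_amplitudes(
            proj_diag, subj.E_PtP(), run.E_AAt(),
            state.noise.runs[key].mean, state.amplitude, key, dof_factor=c,
        )


def _update_timecourses_sweep(state: PFMResult) -> None:
    c = state.config.dof_factor
    for key in state.dataset.run_keys():
        run, e_h, e_hht = _run_moments(state, key)
        subj = state.subjects[key[0]]
        d = state.dataset.data[key]
        proj = e_h[:, None] * (subj.E_P.T @ d)
        map_prec = e_hht * subj.E_PtP()
        e_alpha = state.alpha[state.alpha_key(*key)].mean
        tm.update_timecourses(proj, map_prec, e_alpha, run,
                              state.noise.runs[key].mean, dof_factor=c)


def _update_netmats_sweep(state: PFMResult, families: dict) -> None:
    hyp = state.config.temporal
    for akey in state.alpha:
        members = ([(akey, r) for r in state.dataset.runs(akey)]
                   if state.config.pool_runs else [akey])
        stat = sum(state.temporal_runs[k].B_kernel_stat() for k in members)
        t_total = sum(state.temporal_runs[k].xi_mean.shape[1] for k in members)
        label = _family_of(families, akey)
        e_beta = state.group_temporal.for_family(label).mean
        state.alpha[akey] = tm.update_run_netmat(stat, t_total, e_beta, hyp.a_alpha)
    state.group_temporal = tm.update_group_netmat(state.alpha, hyp, families)


def _update_noise_sweep(state: PFMResult) -> None:
    c = state.config.dof_factor
    for key in state.dataset.run_keys():
        run, e_h, e_hht = _run_moments(state, key)
        tm.update_timecourse_noise(run, state.config.temporal)
        subj = state.subjects[key[0]]
        d = state.dataset.data[key]
        err = ns.expected_reconstruction_error(
            d, subj.E_P, subj.E_PtP(), e_h, e_hht, run.E_A, run.E_AAt(),
        )
        state.noise.runs[key] = ns.update_global_noise(
            err, d.shape[0], d.shape[1], state.config.a_psi, state.config.b_psi,
            dof_factor=c,
        )


# ordered coordinate-ascent steps of one sweep; each is an exact conditional
# maximisation except "positivity" (a sign convention, not an ascent step)
SWEEP_STEPS = (
    ("subject_maps", lambda st, fam: _update_subject_maps_sweep(st)),
    ("group_spatial", lambda st, fam: _update_group_spatial_sweep(st)),
    ("amplitudes", lambda st, fam: _update_amplitudes_sweep(st)),
    ("positivity", lambda st, fam: am.enforce_positivity(st.amplitude,
                                                         st.temporal_runs)),
    ("timecourses", lambda st, fam: _update_timecourses_sweep(st)),
    ("netmats", _update_netmats_sweep),
    ("noise", lambda st, fam: _update_noise_sweep(st)),
    ("amplitude_hypers", lambda st, fam: am.update_amplitude_hypers(
        st.amplitude, st.config.amplitude)),
)


def sweep(state: PFMResult, families: dict) -> None:
    """One full coordinate-ascent pass over all factors."""
    for _name, step in SWEEP_STEPS:
        step(state, families)


# ---------------------------------------------------------------------------
# Free energy
# ---------------------------------------------------------------------------

def compute_free_energy(state: PFMResult) -> float:
    """Evidence lower bound: expected log joint minus posterior entropy terms.

    The eta point estimates contribute their (penalised-likelihood) prior
    density; the entropy of a point mass is a constant and is dropped.
    """
    cfg = state.config
    c = cfg.dof_factor
    hyp_s = cfg.spatial
    hyp_t = cfg.temporal
    hyp_a = cfg.amplitude
    group = state.group_spatial
    f = 0.0

    # ---- likelihood + time courses + amplitudes per run -------------------
    for key in state.dataset.run_keys():
        run, e_h, e_hht = _run_moments(state, key)
        subj = state.subjects[key[0]]
        d = state.dataset.data[key]
        v, t = d.shape
        m = e_h.shape[0]
        psi = state.noise.runs[key]
        err = ns.expected_reconstruction_error(
            d, subj.E_P, subj.E_PtP(), e_h, e_hht, run.E_A, run.E_AAt(),
        )
        f += c * (0.5 * v * t * (psi.E_log - LOG_2PI) - 0.5 * psi.mean * err)

        # q(B)
        apost = state.alpha[state.alpha_key(*key)]
        lam, _ = run.kernel.eig()
        bstat = run.B_kernel_stat()
        f += (
            0.5 * t * apost.E_logdet
            - 0.5 * m * np.sum(np.log(lam))
            - 0.5 * float(np.sum(apost.mean * bstat))
            - 0.5 * m * t * LOG_2PI
        )
        _, logdets = np.linalg.slogdet(run.B_cov)  # batched over eigencolumns
        f += 0.5 * (t * m * (1.0 + LOG_2PI) + float(np.sum(logdets)))

        # q(xi)
        f += (
            0.5 * t * float(np.sum(run.E_log_omega))
            - 0.5 * m * t * LOG_2PI
            - 0.5 * float(np.sum(run.E_omega * run.xi_sq_sum()))
        )
        f += 0.5 * t * (m * (1.0 + LOG_2PI) + np.linalg.slogdet(run.xi_cov)[1])

        # omega, psi KLs
        f -= float(np.sum(gamma_kl(run.omega_shape, run.omega_rate,
                                   hyp_t.a_omega, hyp_t.b_omega)))
        f -= float(gamma_kl(psi.shape, psi.rate, cfg.a_psi, cfg.b_psi))

        # q(h)
        ramp = state.amplitude.runs[key]
        omega_h = state.amplitude.sigma_inv.mean
        dmean = ramp.mean - state.amplitude.mu_mean
        quad = float(np.sum(omega_h * (ramp.cov + np.outer(dmean, dmean)
                                       + state.amplitude.mu_cov)))
        f += 0.5 * state.amplitude.sigma_inv.E_logdet - 0.5 * m * LOG_2PI - 0.5 * quad
        f += gaussian_entropy(ramp.cov)

    # ---- netmat hierarchy --------------------------------------------------
    families = _alpha_families(state.dataset, cfg)
    for akey, apost in state.alpha.items():
        beta = state.group_temporal.for_family(_family_of(families, akey))
        f += wishart_E_logp(apost.dof, apost.rate, hyp_t.a_alpha,
                            beta.mean, beta.E_logdet)
        f -= wishart_E_logq(apost.dof, apost.rate)
    for label, beta in state.group_temporal.families.items():
        _, logdet_bb = np.linalg.slogdet(hyp_t.B_beta)
        f += wishart_E_logp(beta.dof, beta.rate, hyp_t.a_beta, hyp_t.B_beta, logdet_bb)
        f -= wishart_E_logq(beta.dof, beta.rate)

    # ---- amplitude hierarchy ----------------------------------------------
    f -= gaussian_kl_diag_prior(state.amplitude.mu_mean, state.amplitude.mu_cov,
                                hyp_a.tau_mu_h, hyp_a.gamma_mu_h ** 2)
    _, logdet_bh = np.linalg.slogdet(hyp_a.B_h)
    si = state.amplitude.sigma_inv
    f += wishart_E_logp(si.dof, si.rate, hyp_a.a_h, hyp_a.B_h, logdet_bh)
    f -= wishart_E_logq(si.dof, si.rate)

    # ---- spatial model -----------------------------------------------------
    gm = sp.GroupMoments.from_posterior(group)
    for s in state.dataset.subjects:
        subj = state.subjects[s]
        r = subj.responsibility
        eta = np.maximum(subj.eta, sp.ETA_FLOOR)
        sq_sig = (subj.signal_mean ** 2 + subj.signal_var
                  - 2.0 * subj.signal_mean * gm.E_mu + gm.E_mu2)
        sq_noise = subj.noise_mean ** 2 + subj.noise_var
        elogp = r * (gm.E_log_pi + 0.5 * gm.E_log_sigma_inv2 - 0.5 * LOG_2PI
                     - 0.5 * gm.E_sigma_inv2 * sq_sig)
        elogp += (1.0 - r) * (
            gm.E_log_1mpi + 0.5 * gm.E_log_zeta_inv2[:, None]
            - np.log(eta)[None, :] - 0.5 * LOG_2PI
            - 0.5 * (gm.E_zeta_inv2[:, None] / eta[None, :] ** 2) * sq_noise
        )
        elogq = (xlogy(r, r) + xlogy(1.0 - r, 1.0 - r)
                 - 0.5 * r * (np.log(2.0 * np.pi * subj.signal_var) + 1.0)
                 - 0.5 * (1.0 - r) * (np.log(2.0 * np.pi * subj.noise_var) + 1.0))
        f += float(np.sum(elogp - elogq))
        # eta prior (point mass; delta entropy constant dropped)
        f += float(np.sum(-0.5 * np.log(2.0 * np.pi * hyp_s.gamma_eta ** 2)
                          - 0.5 * subj.eta ** 2 / hyp_s.gamma_eta ** 2))

    # group means mixture
    lam_mix = np.asarray(hyp_s.lambda_mu)
    with np.errstate(divide="ignore"):
        log_lam = np.log(lam_mix)
    taus = np.array([hyp_s.tau_mu1, hyp_s.tau_mu2])
    gam2 = np.array([hyp_s.gamma_mu1 ** 2, hyp_s.gamma_mu2 ** 2])
    rr = group.rho_resp
    # 0 * log(0) = 0 for empty mixture components
    elogp = np.where(rr[..., 0] > 0, rr[..., 0] * log_lam[0], 0.0)
    for i in range(2):
        mi, vi = group.slab_mean[..., i], group.slab_var[..., i]
        elogp = elogp + rr[..., i + 1] * (
            log_lam[i + 1] - 0.5 * np.log(2.0 * np.pi * gam2[i])
            - 0.5 * ((mi - taus[i]) ** 2 + vi) / gam2[i]
        )
    elogq = xlogy(rr, rr).sum(axis=-1)
    for i in range(2):
        elogq = elogq - 0.5 * rr[..., i + 1] * (
            np.log(2.0 * np.pi * group.slab_var[..., i]) + 1.0
        )
    f += float(np.sum(elogp - elogq))

    # sigma, pi, zeta
    f -= float(np.sum(gamma_kl(group.sigma_shape, group.sigma_rate,
                               hyp_s.a_sigma, hyp_s.b_sigma)))
    f -= float(np.sum(beta_kl(group.pi_a, group.pi_b, hyp_s.a_pi, hyp_s.b_pi)))
    f -= float(np.sum(gamma_kl(group.zeta_shape, group.zeta_rate,
                               hyp_s.a_zeta, hyp_s.b_zeta)))

    if not np.isfinite(f):
        raise NumericalError("free energy is not finite")
    return float(f)


# ---------------------------------------------------------------------------
# Fit driver
# ---------------------------------------------------------------------------

def fit(dataset: MultiRunDataset, config: ModelConfig) -> PFMResult:
    """Run coordinate-ascent VB to convergence and return the posteriors."""
    if not dataset.meta.get("preprocessed", False):
        dataset = dataset.preprocessed(per_voxel_variance=config.per_voxel_variance)
    state = initialize(dataset, config)
    families = _alpha_families(dataset, config)
    prev = None
    stable = 0
    for it in range(1, config.max_sweeps + 1):
        sweep(state, families)
        fe = compute_free_energy(state)
        state.free_energy.append(fe)
        logger.info("sweep %3d  free energy %.6f", it, fe)
        if prev is not None:
            rel = abs(fe - prev) / max(abs(fe), 1.0)
            stable = stable + 1 if rel < config.tol else 0
            if stable >= config.tol_sweeps:
                state.converged = True
                state.n_sweeps = it
                break
        prev = fe
    else:
        state.n_sweeps = config.max_sweeps
    prune_modes(state, config.prune_map_threshold, config.prune_amp_threshold)
    return state


def prune_modes(result: PFMResult, tau_map: float = 1e-3,
                tau_amp: float = 1e-3) -> PFMResult:
    """Flag modes eliminated by the Bayesian complexity penalties.

    A mode is flagged when its group map has shrunk to (numerical) zero or
    its mean posterior amplitude has collapsed.  Flagged modes are excluded
    from exported summaries but kept in the containers.
    """
    maps = result.group_maps()
    map_strength = np.max(np.abs(maps), axis=0)
    amps = np.array([r.mean for r in result.amplitude.runs.values()])
    amp_strength = amps.mean(axis=0)
    result.pruned = (map_strength < tau_map) | (amp_strength < tau_amp)
    return result


def match_modes(est_maps: np.ndarray, ref_maps: np.ndarray):
    """Optimal assignment of estimated to reference modes.

    Maximises the total absolute spatial correlation (Hungarian algorithm).
    Returns ``(perm, signs)`` such that ``est_maps[:, perm] * signs`` is
    aligned with ``ref_maps`` column by column.
    """
    from scipy.optimize import linear_sum_assignment

    est = np.asarray(est_maps, float)
    ref = np.asarray(ref_maps, float)
    if est.shape[0] != ref.shape[0]:
        raise ConfigurationError("map sets must share the voxel dimension")
    corr = _column_corr(est, ref)
    row, col = linear_sum_assignment(-np.abs(corr))
    order = np.argsort(col)
    row, col = row[order], col[order]
    perm = row
    signs = np.sign(corr[row, col])
    signs[signs == 0] = 1.0
    return perm, signs


def _column_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    an = np.sqrt((az ** 2).sum(axis=0))
    bn = np.sqrt((bz ** 2).sum(axis=0))
    an[an == 0] = 1.0
    bn[bn == 0] = 1.0
    return (az.T @ bz) / np.outer(an, bn)
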