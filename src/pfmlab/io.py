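"""HDF5 and NIfTI round-tripping for datasets, ground truth and results.

Dataset container schema (version 1): datasets ``data/s{idx}/r{idx}`` with
file attributes ``TR`` and ``mask``.  Results are stored in a single HDF5
file with a versioned schema mirroring the posterior containers.  All
datasets are written with ``track_times=False`` so identical content yields
identical bytes.
"""

from __future__ import annotations

import json
import re

import numpy as np

from .datasets import ConfigurationError, ModelConfig, MultiRunDataset, PFMError

SCHEMA_VERSION = 1
_DS_OPTS = dict(track_times=False)


# ---------------------------------------------------------------------------
# Dataset containers
# ---------------------------------------------------------------------------

def save_dataset_hdf5(dataset: MultiRunDataset, path, truth=None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["TR"] = dataset.tr
        fh.create_dataset("mask", data=dataset.mask.astype(np.uint8), **_DS_OPTS)
        grp = fh.create_group("data")
        for (s, r), mat in sorted(dataset.data.items()):
            grp.create_dataset(f"s{s}/r{r}", data=mat, **_DS_OPTS)
        if dataset.meta:
            fh.attrs["meta"] = json.dumps(
                {k: v for k, v in dataset.meta.items()
                 if isinstance(v, (str, int, float, bool))}
            )
        if truth is not None:
            _save_truth_group(fh.create_group("truth"), truth)


def load_dataset_hdf5(path) -> MultiRunDataset:
    import h5py

    data = {}
    with h5py.File(path, "r") as fh:
        tr = float(fh.attrs["TR"])
        mask = np.asarray(fh["mask"]).astype(bool)
        for s_name, s_grp in fh["data"].items():
            s = int(re.match(r"s(\d+)$", s_name).group(1))
            for r_name, ds in s_grp.items():
                r = int(re.match(r"r(\d+)$", r_name).group(1))
                data[(s, r)] = np.asarray(ds)
        meta = json.loads(fh.attrs["meta"]) if "meta" in fh.attrs else {}
    return MultiRunDataset(data, mask, tr, meta)


def _save_truth_group(grp, truth) -> None:
    grp.create_dataset("group_maps", data=truth.group_maps, **_DS_OPTS)
    grp.create_dataset("group_netmat", data=truth.group_netmat, **_DS_OPTS)
    grp.attrs["realised_snr"] = truth.realised_snr
    for s, maps in truth.subject_maps.items():
        grp.create_dataset(f"subject_maps/s{s}", data=maps, **_DS_OPTS)
        grp.create_dataset(f"spatial_corr/s{s}", data=truth.spatial_corr[s], **_DS_OPTS)
    for (s, r), arr in truth.neural.items():
        grp.create_dataset(f"neural/s{s}/r{r}", data=arr, **_DS_OPTS)
        grp.create_dataset(f"bold/s{s}/r{r}", data=truth.bold[(s, r)], **_DS_OPTS)
        grp.create_dataset(f"amplitudes/s{s}/r{r}", data=truth.amplitudes[(s, r)],
                           **_DS_OPTS)
        grp.create_dataset(f"netmats/s{s}/r{r}", data=truth.netmats[(s, r)], **_DS_OPTS)


def load_truth_hdf5(path):
    """Load a GroundTruth saved alongside a dataset container."""
    import h5py
    from .simulate import GroundTruth

    def keyed(grp, two_level):
        out = {}
        for s_name, sub in grp.items():
            s = int(s_name[1:])
            if two_level:
                for r_name, ds in sub.items():
                    out[(s, int(r_name[1:]))] = np.asarray(ds)
            else:
                out[s] = np.asarray(sub)
        return out

    with h5py.File(path, "r") as fh:
        if "truth" not in fh:
            raise PFMError(f"{path} contains no ground-truth group")
        g = fh["truth"]
        truth = GroundTruth(
            config=None,
            group_maps=np.asarray(g["group_maps"]),
            subject_maps=keyed(g["subject_maps"], False),
            neural=keyed(g["neural"], True),
            bold=keyed(g["bold"], True),
            amplitudes=keyed(g["amplitudes"], True),
            netmats=keyed(g["netmats"], True),
            spatial_corr=keyed(g["spatial_corr"], False),
            group_netmat=np.asarray(g["group_netmat"]),
            realised_snr=float(g.attrs["realised_snr"]),
        )
    return truth


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def load_dataset_nifti(run_paths: dict, mask_path, tr: float | None = None
                       ) -> MultiRunDataset:
    """Build a dataset from 4D NIfTI runs and a binary mask volume.

    ``run_paths`` maps (subject, run) to a NIfTI path.  Voxel ordering
    follows the mask scan order (C order over the volume grid).  The two
    readers (HDF5 and NIfTI) produce identical datasets for equivalent
    content.
    """
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj).astype(bool).ravel(order="C")
    data = {}
    tr_out = tr
    for key, path in run_paths.items():
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.ndim != 4:
            raise ConfigurationError(f"{path} is not a 4D image")
        flat = vol.reshape(-1, vol.shape[-1], order="C")
        data[key] = flat[mask]
        if tr_out is None:
            zooms = img.header.get_zooms()
            tr_out = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    if tr_out is None:
        raise ConfigurationError("TR not found in headers; pass tr= explicitly")
    return MultiRunDataset(data, mask, tr_out, meta={"source": "nifti"})


def maps_to_nifti(maps: np.ndarray, mask: np.ndarray, shape=None, affine=None):
    """Embed V x M maps into a 4D NIfTI image (modes along the 4th axis).

    Masked-out voxels are zero.  A 1-D lattice dataset is embedded as a
    (grid, 1, 1) volume by default.
    """
    import nibabel as nib

    mask = np.asarray(mask, dtype=bool)
    maps = np.atleast_2d(np.asarray(maps, float))
    if maps.shape[0] != int(mask.sum()):
        raise ConfigurationError("map voxel count does not match the mask")
    if shape is None:
        shape = (mask.size, 1, 1)
    full = np.zeros((mask.size, maps.shape[1]))
    full[mask] = maps
    vol = full.reshape(*shape, maps.shape[1], order="C")
    return nib.Nifti1Image(vol, affine if affine is not None else np.eye(4))


def dataset_to_nifti(dataset: MultiRunDataset, out_dir, shape=None, affine=None):
    """Write every run (and the mask) of a lattice dataset as NIfTI files."""
    import os

    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    mask = dataset.mask
    if shape is None:
        shape = (mask.size, 1, 1)
    mask_img = nib.Nifti1Image(
        mask.reshape(shape, order="C").astype(np.uint8),
        affine if affine is not None else np.eye(4),
    )
    mask_path = os.path.join(out_dir, "mask.nii")
    nib.save(mask_img, mask_path)
    paths = {}
    for (s, r), mat in sorted(dataset.data.items()):
        img = maps_to_nifti(mat, mask, shape=shape, affine=affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], dataset.tr))
        p = os.path.join(out_dir, f"sub-{s:03d}_run-{r:02d}.nii")
        nib.save(img, p)
        paths[(s, r)] = p
    return paths, mask_path


def export_maps(result, mask: np.ndarray, out_dir, shape=None, affine=None) -> dict:
    """Write group summary and parameter maps (and subject maps) as NIfTI.

    Exports E[pi mu] (the group summary), E[pi], E[mu], E[sigma^2]^(1/2),
    E[zeta^2]^(1/2) and per-subject posterior mean maps.  Pruned modes are
    excluded from the exported summaries.
    """
    import os

    import nibabel as nib

    mask = np.asarray(mask, dtype=bool)
    group = result.group_spatial
    if int(mask.sum()) != group.pi_a.shape[0]:
        raise ConfigurationError("mask voxel count does not match the result")
    os.makedirs(out_dir, exist_ok=True)
    active = result.active_modes()

    def sqrt_inv_mean(shape_arr, rate_arr):
        # E[x^2] = rate / (shape - 1) for the inverse-gamma over x^2
        denom = np.maximum(shape_arr - 1.0, 1e-6)
        return np.sqrt(rate_arr / denom)

    out = {
        "group_summary": result.group_maps()[:, active],
        "membership": group.E_pi[:, active],
        "signal_mean": group.E_mu[:, active],
        "signal_std": sqrt_inv_mean(group.sigma_shape, group.sigma_rate)[:, active],
        "noise_std": sqrt_inv_mean(group.zeta_shape, group.zeta_rate)[:, None],
    }
    for s in result.subjects:
        out[f"subject_{s:03d}"] = result.subject_maps(s)[:, active]
    paths = {}
    for name, maps in out.items():
        img = maps_to_nifti(maps, mask, shape=shape, affine=affine)
        p = os.path.join(out_dir, f"{name}.nii")
        nib.save(img, p)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------

def save_result_hdf5(result, path) -> None:
    import h5py

    from . import spatial as sp

    cfg = result.config
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["seed"] = result.seed
        fh.attrs["converged"] = result.converged
        fh.attrs["n_sweeps"] = result.n_sweeps
        fh.attrs["config"] = json.dumps(_config_dict(cfg))
        fh.create_dataset("free_energy", data=np.asarray(result.free_energy),
                          **_DS_OPTS)
        if result.pruned is not None:
            fh.create_dataset("pruned", data=result.pruned.astype(np.uint8), **_DS_OPTS)

        g = fh.create_group("group_spatial")
        gs = result.group_spatial
        for name in ("rho_resp", "slab_mean", "slab_var", "sigma_shape", "sigma_rate",
                     "pi_a", "pi_b", "zeta_shape", "zeta_rate"):
            g.create_dataset(name, data=getattr(gs, name), **_DS_OPTS)

        for s, subj in result.subjects.items():
            grp = fh.create_group(f"subjects/s{s}")
            for name in ("signal_mean", "signal_var", "noise_mean", "noise_var",
                         "responsibility", "eta"):
                grp.create_dataset(name, data=getattr(subj, name), **_DS_OPTS)

        for (s, r), run in result.temporal_runs.items():
            grp = fh.create_group(f"temporal/s{s}/r{r}")
            for name in ("B_eig_mean", "B_cov", "xi_mean", "xi_cov",
                         "omega_shape", "omega_rate"):
                grp.create_dataset(name, data=getattr(run, name), **_DS_OPTS)
            grp.attrs["TR"] = run.kernel.tr
            amp = result.amplitude.runs[(s, r)]
            grp.create_dataset("h_mean", data=amp.mean, **_DS_OPTS)
            grp.create_dataset("h_cov", data=amp.cov, **_DS_OPTS)
            psi = result.noise.runs[(s, r)]
            grp.attrs["psi_shape"] = psi.shape
            grp.attrs["psi_rate"] = psi.rate

        for key, post in result.alpha.items():
            name = f"s{key}" if not isinstance(key, tuple) else f"s{key[0]}/r{key[1]}"
            grp = fh.create_group(f"alpha/{name}")
            grp.attrs["dof"] = post.dof
            grp.create_dataset("rate", data=post.rate, **_DS_OPTS)

        for label, post in result.group_temporal.families.items():
            grp = fh.create_group(f"beta/{label}")
            grp.attrs["dof"] = post.dof
            grp.create_dataset("rate", data=post.rate, **_DS_OPTS)

        amp = result.amplitude
        grp = fh.create_group("amplitude_group")
        grp.create_dataset("mu_mean", data=amp.mu_mean, **_DS_OPTS)
        grp.create_dataset("mu_cov", data=amp.mu_cov, **_DS_OPTS)
        grp.attrs["sigma_inv_dof"] = amp.sigma_inv.dof
        grp.create_dataset("sigma_inv_rate", data=amp.sigma_inv.rate, **_DS_OPTS)


def load_result_hdf5(path):
    import h5py

    from . import amplitude as am
    from . import noise as ns
    from . import spatial as sp
    from . import temporal as tm
    from .engine import PFMResult

    with h5py.File(path, "r") as fh:
        cfg = ModelConfig(**json.loads(fh.attrs["config"]))
        g = fh["group_spatial"]
        group = sp.GroupSpatialPosterior(
            **{name: np.asarray(g[name]) for name in
               ("rho_resp", "slab_mean", "slab_var", "sigma_shape", "sigma_rate",
                "pi_a", "pi_b", "zeta_shape", "zeta_rate")}
        )
        subjects = {}
        for s_name, grp in fh["subjects"].items():
            subjects[int(s_name[1:])] = sp.SubjectSpatialPosterior(
                **{name: np.asarray(grp[name]) for name in
                   ("signal_mean", "signal_var", "noise_mean", "noise_var",
                    "responsibility", "eta")}
            )
        temporal_runs, amp_runs, noise_runs = {}, {}, {}
        kernels = {}
        for s_name, s_grp in fh["temporal"].items():
            s = int(s_name[1:])
            for r_name, grp in s_grp.items():
                r = int(r_name[1:])
                t = grp["xi_mean"].shape[1]
                tr = float(grp.attrs["TR"])
                if (t, tr) not in kernels:
                    kernels[(t, tr)] = tm.build_hrf_kernel(t, tr)
                temporal_runs[(s, r)] = tm.RunTemporalPosterior(
                    B_eig_mean=np.asarray(grp["B_eig_mean"]),
                    B_cov=np.asarray(grp["B_cov"]),
                    xi_mean=np.asarray(grp["xi_mean"]),
                    xi_cov=np.asarray(grp["xi_cov"]),
                    omega_shape=np.asarray(grp["omega_shape"]),
                    omega_rate=np.asarray(grp["omega_rate"]),
                    kernel=kernels[(t, tr)],
                )
                amp_runs[(s, r)] = am.RunAmplitudePosterior(
                    mean=np.asarray(grp["h_mean"]), cov=np.asarray(grp["h_cov"])
                )
                noise_runs[(s, r)] = ns.RunNoisePosterior(
                    shape=float(grp.attrs["psi_shape"]),
                    rate=float(grp.attrs["psi_rate"]),
                )
        alpha = {}
        for s_name, grp in fh["alpha"].items():
            s = int(s_name[1:])
            if "rate" in grp:
                alpha[s] = tm.WishartPosterior(float(grp.attrs["dof"]),
                                               np.asarray(grp["rate"]))
            else:
                for r_name, sub in grp.items():
                    alpha[(s, int(r_name[1:]))] = tm.WishartPosterior(
                        float(sub.attrs["dof"]), np.asarray(sub["rate"])
                    )
        families = {
            label: tm.WishartPosterior(float(grp.attrs["dof"]), np.asarray(grp["rate"]))
            for label, grp in fh["beta"].items()
        }
        ag = fh["amplitude_group"]
        amplitude = am.AmplitudePosterior(
            runs=amp_runs,
            mu_mean=np.asarray(ag["mu_mean"]),
            mu_cov=np.asarray(ag["mu_cov"]),
            sigma_inv=tm.WishartPosterior(float(ag.attrs["sigma_inv_dof"]),
                                          np.asarray(ag["sigma_inv_rate"])),
        )
        result = PFMResult(
            config=cfg,
            group_spatial=group,
            subjects=subjects,
            temporal_runs=temporal_runs,
            alpha=alpha,
            group_temporal=tm.GroupTemporalPosterior(families=families),
            amplitude=amplitude,
            noise=ns.NoisePosterior(noise_runs, cfg.a_psi, cfg.b_psi),
            free_energy=list(np.asarray(fh["free_energy"])),
            pruned=np.asarray(fh["pruned"]).astype(bool) if "pruned" in fh else None,
            seed=int(fh.attrs["seed"]),
            converged=bool(fh.attrs["converged"]),
            n_sweeps=int(fh.attrs["n_sweeps"]),
        )
    return result


def _config_dict(cfg: ModelConfig) -> dict:
    out = {}
    for name in ("M", "dof_factor", "pool_runs", "beta_families", "tol", "tol_sweeps",
                 "max_sweeps", "prune_map_threshold", "prune_amp_threshold",
                 "prune_after", "seed", "per_voxel_variance", "a_psi", "b_psi"):
        val = getattr(cfg, name)
        if isinstance(val, np.generic):
            val = val.item()
        out[name] = val
    return out


# ---------------------------------------------------------------------------
# Delimited-text exports
# ---------------------------------------------------------------------------

def export_netmats(result, out_dir, ridge: float = 0.0) -> dict:
    """Write per-run netmats as CSV in three variants.

    ``precision`` is the posterior mean run precision E[alpha]; ``corr`` the
    implied full correlations; ``pcorr`` the partial correlations.  Pruned
    modes are excluded.  Returns {variant: {(subject, run): path}}.
    """
    import os

    from ._math import cov2corr, precision_to_partial_corr

    os.makedirs(out_dir, exist_ok=True)
    active = result.active_modes()
    paths = {"precision": {}, "corr": {}, "pcorr": {}}
    for s, r in result.temporal_runs:
        prec = result.run_netmat(s, r)[np.ix_(active, active)]
        variants = {
            "precision": prec,
            "corr": cov2corr(np.linalg.inv(prec)),
            "pcorr": precision_to_partial_corr(prec),
        }
        for name, mat in variants.items():
            p = os.path.join(out_dir, f"sub-{s:03d}_run-{r:02d}_{name}.csv")
            np.savetxt(p, mat, delimiter=",")
            paths[name][(s, r)] = p
    return paths


def export_amplitudes(result, path) -> None:
    """Amplitude table as delimited text: one row per (subject, run)."""
    import pandas as pd

    active = result.active_modes()
    rows = []
    for (s, r), post in sorted(result.amplitude.runs.items()):
        row = {"subject": s, "run": r}
        row.update({f"mode_{m}": post.mean[m] for m in active})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
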