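"""End-to-end pipeline stages driven by a single YAML config.

Three stages mirror how the analysis runs on a real study: ``simulate``
writes a phantom cohort to disk (4D dynamics, masks, motion traces,
behavioral table, manifest with checksums), ``fit`` produces parametric
BP maps per session after motion screening and masked smoothing, and
``stats`` runs the voxelwise permutation analyses and the behavioral
ANOVAs, writing one JSON summary.  Every output records the config hash,
and all stages are deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from .images import (
    cohort_motion_report,
    extract_region_tac,
    fit_voxelwise,
    load_dynamic_image,
    load_parametric_image,
    masked_gaussian_smooth,
    save_dynamic_image,
    save_parametric_image,
    screen_motion,
)
from .kinetics import ActivationProfile, FrameSchedule
from .synth import (
    GROUPS,
    TASKS,
    TIMES,
    CohortDesign,
    PhantomSpec,
    simulate_behavior,
    simulate_phantom_scan,
)
from .voxelstats import group_time_anova, paired_t_map

logger = logging.getLogger("raclopy.workflow")

DEFAULT_CONFIG: dict = {
    "paths": {"dataset": "dataset", "output": "results"},
    "seed": 0,
    "cohort": {"n_training": 14, "n_control": 14, "pre_post_corr": 0.5},
    "phantom": {"size": "full", "noise_scale": None},
    "tasks": list(TASKS),
    "kinetics": {
        "onset_min": 55.0,
        "time_to_peak_min": 25.0 / 3.0,
        "shape_lambda": 3.0,
        "smooth_fwhm_mm": 10.0,
        "n_refine": 3,
        "weights": "uniform",          # or "duration"
    },
    "motion": {"threshold_mm": 2.5, "max_extra_fraction": 0.25},
    "stats": {
        "alpha_interaction": 0.05,
        "alpha_task": 0.01,
        "n_perm": 5000,
        "var_fwhm_mm": 10.0,
        "min_extent": 5,
    },
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge the default config with a YAML file and explicit overrides."""
    def merge(base: dict, extra: dict) -> dict:
        out = dict(base)
        for k, v in (extra or {}).items():
            out[k] = (merge(base.get(k, {}), v)
                      if isinstance(v, dict) else v)
        return out

    cfg = DEFAULT_CONFIG
    if path is not None:
        cfg = merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    return merge(cfg, overrides or {})


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _phantom_spec(config: dict) -> PhantomSpec:
    ph = config["phantom"]
    ns = ph.get("noise_scale")
    if ph.get("size") == "mini":
        return PhantomSpec.mini(noise_scale=ns)
    return PhantomSpec() if ns is None else PhantomSpec(noise_scale=ns)


def _profile(config: dict, schedule: FrameSchedule) -> ActivationProfile:
    kin = config["kinetics"]
    return ActivationProfile(
        onset=kin["onset_min"],
        time_to_peak=kin["time_to_peak_min"],
        shape_lambda=kin["shape_lambda"],
        window_end=schedule.total_duration,
    )


def _subjects(config: dict) -> pd.DataFrame:
    rows = []
    for group in GROUPS:
        n = config["cohort"][f"n_{group}"]
        for i in range(n):
            rows.append((f"{group[:2]}{i + 1:02d}", group))
    return pd.DataFrame(rows, columns=["subject", "group"])


def _session_seed(base: int, subj_idx: int, time: str, task: str) -> int:
    key = f"{base}:{subj_idx}:{time}:{task}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(config: dict, force: bool = False) -> Path:
    """Write the phantom cohort to the configured dataset directory."""
    root = Path(config["paths"]["dataset"])
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(
            f"dataset directory {root} is not empty (use --force)")
    (root / "sessions").mkdir(parents=True, exist_ok=True)
    (root / "motion").mkdir(exist_ok=True)
    spec = _phantom_spec(config)
    subjects = _subjects(config)
    tasks = config["tasks"]
    chash = config_hash(config)

    # masks and schedule are cohort-level
    import nibabel as nib
    for name, mask in [("striatum", spec.striatum_mask()),
                       ("reference", spec.reference_mask()),
                       ("effect", spec.effect_mask())]:
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), spec.affine()),
                 str(root / f"mask_{name}.nii"))
    (root / "schedule.json").write_text(json.dumps({
        "frame_start_min": spec.schedule.start.tolist(),
        "frame_duration_min": spec.schedule.duration.tolist(),
    }, indent=1))

    design = CohortDesign(
        n_training=config["cohort"]["n_training"],
        n_control=config["cohort"]["n_control"],
        pre_post_corr=config["cohort"]["pre_post_corr"],
    )
    behavior_df = simulate_behavior(design, seed=config["seed"])
    behavior_df.to_csv(root / "behavior.csv", index=False)
    subjects.to_csv(root / "design.csv", index=False)

    for idx, row in subjects.iterrows():
        for time in TIMES:
            for task in tasks:
                seed = _session_seed(config["seed"], idx, time, task)
                ses = simulate_phantom_scan(spec, row.group, time, task,
                                            seed=seed)
                stem = f"{row.subject}_{time}_{task}"
                save_dynamic_image(root / "sessions" / f"{stem}.nii",
                                   ses.data, ses.affine, ses.schedule)
                pd.DataFrame(ses.motion_trace.T,
                             columns=["tx", "ty", "tz", "rx", "ry", "rz"]
                             ).to_csv(root / "motion" / f"{stem}.csv",
                                      index=False)
                logger.info("simulated %s (seed %d)", stem, seed)

    files = sorted(p for p in root.rglob("*") if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "config_hash": chash,
        "files": {str(p.relative_to(root)): _sha256(p) for p in files},
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return root


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def run_fit(config: dict) -> Path:
    """Motion-screen, smooth, and voxelwise-fit every session on disk."""
    import nibabel as nib
    root = Path(config["paths"]["dataset"])
    out = Path(config["paths"]["output"]) / "maps"
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    striatum = np.asarray(
        nib.load(str(root / "mask_striatum.nii")).dataobj).astype(bool)
    reference = np.asarray(
        nib.load(str(root / "mask_reference.nii")).dataobj).astype(bool)
    kin = config["kinetics"]
    mot = config["motion"]
    reports = {}
    motion_reports = []
    for nii in sorted((root / "sessions").glob("*.nii")):
        stem = nii.stem
        try:
            data, affine, sched = load_dynamic_image(nii)
            profile = _profile(config, sched)
            trace = pd.read_csv(root / "motion" / f"{stem}.csv"
                                ).to_numpy().T
            screen = screen_motion(trace, sched, mot["threshold_mm"],
                                   mot["max_extra_fraction"])
            motion_reports.append(screen)
            if screen.excluded:
                reports[stem] = {"excluded_motion": True,
                                 "extra_subframes": screen.extra_subframes}
                logger.warning("%s excluded for motion (%d subframes)",
                               stem, screen.extra_subframes)
                continue
            ref_tac = extract_region_tac(data, reference, sched)
            if kin["smooth_fwhm_mm"] > 0:
                vs = float(np.abs(np.diag(affine)[:3]).mean())
                smoothed = masked_gaussian_smooth(
                    data, striatum, kin["smooth_fwhm_mm"], vs)
                data = np.where(striatum[..., None], smoothed, data)
            weights = (sched.duration if kin["weights"] == "duration"
                       else None)
            res = fit_voxelwise(data, ref_tac, striatum, affine=affine,
                                profile=profile, weights=weights,
                                n_refine=kin["n_refine"],
                                meta={"session": stem,
                                      "config_hash": chash})
            for label, img in [("BP0", res.bp0), ("BP1", res.bp1),
                               ("dBP", res.dbp), ("flag", res.flag)]:
                save_parametric_image(out / f"{stem}_{label}.nii", img)
            reports[stem] = {
                "excluded_motion": False,
                "extra_subframes": screen.extra_subframes,
                "flagged_fraction": res.flagged_fraction,
            }
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"session {stem}: {exc}") from exc
    summary = {
        "config_hash": chash,
        "motion": cohort_motion_report(motion_reports),
        "sessions": reports,
    }
    (out / "fit_report.json").write_text(json.dumps(summary, indent=1))
    return out


# ---------------------------------------------------------------------------
# stats
# ---------------------------------------------------------------------------

def _collect_maps(maps_dir: Path, subjects: pd.DataFrame, task: str,
                  label: str) -> dict[str, dict[str, np.ndarray]]:
    """subject -> time -> map data, for subjects with complete sessions."""
    out = {}
    for _, row in subjects.iterrows():
        per_time = {}
        for time in TIMES:
            p = maps_dir / f"{row.subject}_{time}_{task}_{label}.nii"
            if p.exists():
                per_time[time] = load_parametric_image(p).data
        out[row.subject] = per_time
    return out


def run_stats(config: dict) -> Path:
    """Permutation maps, cluster tables, and the behavioral report."""
    import nibabel as nib
    root = Path(config["paths"]["dataset"])
    out = Path(config["paths"]["output"])
    maps_dir = out / "maps"
    stats_dir = out / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    st = config["stats"]
    striatum_img = nib.load(str(root / "mask_striatum.nii"))
    striatum = np.asarray(striatum_img.dataobj).astype(bool)
    affine = striatum_img.affine
    voxel_size = tuple(np.abs(np.diag(affine)[:3]))
    subjects = pd.read_csv(root / "design.csv")
    summary: dict = {"config_hash": chash, "tasks": {}}

    for task in config["tasks"]:
        task_sum: dict = {}
        dbp = _collect_maps(maps_dir, subjects, task, "dBP")

        # task main effect at pre-training: BP1 vs BP0, both groups combined
        bp0 = _collect_maps(maps_dir, subjects, task, "BP0")
        bp1 = _collect_maps(maps_dir, subjects, task, "BP1")
        pre_subj = [s for s in bp0 if "pre" in bp0[s] and "pre" in bp1[s]]
        if len(pre_subj) >= 3:
            res_task = paired_t_map(
                np.stack([bp1[s]["pre"] for s in pre_subj]),
                np.stack([bp0[s]["pre"] for s in pre_subj]),
                striatum, alpha=st["alpha_task"], n_perm=st["n_perm"],
                min_extent=st["min_extent"], affine=affine,
                seed=config["seed"] + 1)
            task_sum["task_effect"] = _perm_summary(res_task)
            _save_stat_maps(stats_dir, f"{task}_taskeffect", res_task,
                            affine, chash)

        # group x time interaction on dBP change maps
        complete = [s for s in dbp
                    if "pre" in dbp[s] and "post" in dbp[s]]
        groups = subjects.set_index("subject").loc[complete, "group"]
        changes = np.stack([dbp[s]["post"] - dbp[s]["pre"]
                            for s in complete])
        labels = (groups == "training").to_numpy()
        if min(labels.sum(), (~labels).sum()) >= 2:
            res_int = group_time_anova(
                changes, labels, striatum,
                alpha=st["alpha_interaction"], n_perm=st["n_perm"],
                var_fwhm_mm=st["var_fwhm_mm"], voxel_size_mm=voxel_size,
                min_extent=st["min_extent"], affine=affine,
                seed=config["seed"] + 2)
            task_sum["interaction"] = _perm_summary(res_int)
            task_sum["n_complete"] = len(complete)
            _save_stat_maps(stats_dir, f"{task}_interaction", res_int,
                            affine, chash)
            _cluster_table(res_int).to_csv(
                stats_dir / f"{task}_interaction_clusters.csv", index=False)
        summary["tasks"][task] = task_sum

    # behavioral ANOVAs with 3xIQR pre-training outlier screening
    behavior_df = pd.read_csv(root / "behavior.csv")
    summary["behavior"] = {}
    for task, tdf in behavior_df.groupby("task"):
        pre = tdf[tdf.time == "pre"].set_index("subject")["score"]
        _, removed = beh.remove_extreme_outliers(pre.to_numpy())
        dropped = pre.index[removed].tolist()
        use = tdf[~tdf.subject.isin(dropped)]
        eff = beh.mixed_anova_2x2(use)
        inter = eff["interaction"]
        summary["behavior"][task] = {
            "outliers_removed": dropped,
            "interaction": {
                "F": inter.F, "df1": inter.df1, "df2": inter.df2,
                "p": inter.p, "eta_sq_partial": inter.eta_sq_partial,
                "cohens_d": inter.cohens_d,
            },
        }
    (stats_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, default=float))
    return stats_dir


# ---------------------------------------------------------------------------
# In-memory cohort studies (calibration / power experiments)
# ---------------------------------------------------------------------------

def simulate_study_change_maps(
    spec: PhantomSpec,
    n_training: int,
    n_control: int,
    effect: bool = True,
    seed: int = 0,
    smooth_fwhm_mm: float = 6.0,
    n_refine: int = 0,
    dt: float = 0.1,
):
    """Simulate one cohort and return per-subject ΔBP change maps.

    The in-memory fast path of the disk pipeline, used for repeated-cohort
    experiments (type-I calibration, power): voxel TACs are generated
    directly from the phantom's generative model (identical curves and
    noise law to :func:`raclopy.synth.simulate_phantom_scan`), smoothed
    within the striatal mask, fitted in batch, and reduced to per-subject
    (post − pre) ΔBP maps.  With ``effect=False`` the trained×post gamma
    increment is suppressed (null cohort).

    Returns ``(change_maps, labels, mask, effect_mask)`` where
    ``change_maps`` is (n_subjects, x, y, z), ``labels`` is True for the
    training group.
    """
    from .images import _fit_voxels_batch
    from .kinetics import KineticParams, mean_activation
    from .synth import simulate_reference_tac, simulate_target_tac

    rng = np.random.default_rng(seed)
    sched = spec.schedule
    prof = ActivationProfile(window_end=sched.total_duration)
    mask = spec.striatum_mask()
    blob = spec.effect_mask()
    blob_in_mask = blob[mask]
    n_vox = int(mask.sum())
    n_ref_vox = int(spec.reference_mask().sum())
    ref = simulate_reference_tac(spec.input_params, sched)

    p = spec.striatum_params
    curve_bg = simulate_target_tac(
        ref, KineticParams(p.r1, p.k2, p.k2a, spec.task_gamma), prof).values
    curve_eff = simulate_target_tac(
        ref, KineticParams(p.r1, p.k2, p.k2a,
                           spec.task_gamma + spec.effect_gamma_increment),
        prof).values
    hbar = mean_activation(prof)
    voxel_size = spec.voxel_size_mm

    # masked-smoothing kernel normalization is session-independent: cache it
    from scipy import ndimage
    sigma_vox = (smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                 / voxel_size)
    if smooth_fwhm_mm > 0:
        den = ndimage.gaussian_filter(mask.astype(float),
                                      sigma_vox, mode="constant")[mask]

    labels = np.array([True] * n_training + [False] * n_control)
    change_maps = np.empty((labels.size, *spec.shape))
    for s, is_trained in enumerate(labels):
        dbp = {}
        for time in TIMES:
            use_eff = effect and is_trained and time == "post"
            ct = np.tile(curve_bg, (n_vox, 1))
            if use_eff:
                ct[blob_in_mask] = curve_eff
            sd = spec.noise_scale * np.sqrt(
                np.maximum(ct, 0.0) / sched.duration)
            ct = ct + rng.normal(0.0, 1.0, ct.shape) * sd
            # reference TAC noise at region-mean level
            ref_sd = spec.noise_scale * np.sqrt(
                np.maximum(ref.values, 0.0) / sched.duration / n_ref_vox)
            ref_vals = ref.values + rng.normal(0.0, 1.0, ref.values.shape) \
                * ref_sd
            if smooth_fwhm_mm > 0:
                vols = np.zeros(spec.shape + (sched.n_frames,))
                vols[mask] = ct
                num = ndimage.gaussian_filter(
                    vols, (*[sigma_vox] * 3, 0.0), mode="constant")
                ct = num[mask] / den[:, None]
            beta = _fit_voxels_batch(ct, ref_vals, sched, prof,
                                     weights=None, n_refine=n_refine,
                                     dt=dt)
            with np.errstate(divide="ignore", invalid="ignore"):
                bp0 = beta[:, 1] / beta[:, 2] - 1.0
                bp1 = beta[:, 1] / (beta[:, 2] + beta[:, 3] * hbar) - 1.0
            dbp[time] = bp1 - bp0
        vol = np.full(spec.shape, np.nan)
        vol[mask] = dbp["post"] - dbp["pre"]
        change_maps[s] = vol
    return change_maps, labels, mask, blob


def _perm_summary(res) -> dict:
    return {
        "critical_value": res.critical_value,
        "alpha": res.alpha,
        "n_permutations": res.n_permutations,
        "exhaustive": res.exhaustive,
        "n_suprathreshold_voxels": res.n_suprathreshold,
        "clusters": [dataclasses.asdict(c) for c in res.clusters],
    }


def _save_stat_maps(stats_dir: Path, stem: str, res, affine, chash) -> None:
    from .images import ParametricImage
    save_parametric_image(
        stats_dir / f"{stem}_stat.nii",
        ParametricImage(res.stat_map, affine, "stat",
                        {"config_hash": chash,
                         "critical_value": res.critical_value}))
    if res.p_map is not None:
        save_parametric_image(
            stats_dir / f"{stem}_p.nii",
            ParametricImage(res.p_map, affine, "p_fwe",
                            {"config_hash": chash}))


def _cluster_table(res) -> pd.DataFrame:
    rows = [{
        "size": c.size,
        "peak_value": c.peak_value,
        "peak_i": c.peak_voxel[0], "peak_j": c.peak_voxel[1],
        "peak_k": c.peak_voxel[2],
        "peak_x_mm": c.peak_world[0], "peak_y_mm": c.peak_world[1],
        "peak_z_mm": c.peak_world[2],
    } for c in res.clusters]
    return pd.DataFrame(rows, columns=["size", "peak_value", "peak_i",
                                       "peak_j", "peak_k", "peak_x_mm",
                                       "peak_y_mm", "peak_z_mm"])
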