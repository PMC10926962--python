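"""End-to-end desk-scale demo runs on synthetic subjects.

``run_demo`` generates a cohort of synthetic "subjects" with group-dependent
true effects (responders vs non-responders), pushes each through every
analysis stage — LC phantom → contrast, oddball BOLD → ROI beta, DWI →
tensor scalars, streamlines → tract means — assembles the subject table,
runs the covariate linear models with FDR and VIF screening, and writes
TSV/NIfTI artifacts plus a manifest (inputs, seeds, versions, content
hashes).  All randomness flows from one master seed through per-subject,
per-stage derived seeds, so a rerun with the same seed reproduces every
output byte for byte.

``validate_outputs`` re-opens a demo directory and checks the manifest,
file hashes, TSV schemas, NIfTI headers and basic science invariants
(FA within [0, 1], finite contrasts, adjusted p >= raw p).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from lcmri import __version__, group_stats, lc_contrast, oddball_glm, synthio, tract_micro
from lcmri.volume import Volume, save_mask, save_volume

__all__ = ["RunConfig", "run_demo", "validate_outputs", "power_simulation"]

log = logging.getLogger("lcmri.workbench")

CONTRAST_METRICS = [
    f"contrast_{side}_{part}"
    for side in ("left", "right")
    for part in ("caudal", "medial", "rostral")
]
TRACT_METRICS = ["tract_FA", "tract_MD", "tract_AD", "tract_RD", "tract_wFVF"]


@dataclass
class RunConfig:
    """Knobs of the synthetic cohort and of every stage.

    Effects are expressed as responder-minus-non-responder differences on
    the true generating parameters.
    """

    n_subjects: int = 10
    seed: int = 0
    # LC phantom / contrast stage
    phantom_shape: tuple[int, int, int] = (48, 48, 12)
    base_contrast_ratio: float = 1.15
    contrast_effect: float = 0.05
    phantom_noise_sd: float = 5.0
    rater_jitter: int = 1
    reference_offset: int = 15
    # oddball stage
    base_beta: float = 1.0
    beta_effect: float = -0.5
    bold_noise_sd: float = 1.0
    bold_drift_amplitude: float = 1.0
    bold_motion_leak: float = 0.1
    # diffusion stage
    dwi_shape: tuple[int, int, int] = (32, 8, 4)
    dwi_voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    base_ad: float = 1.7e-3
    base_rd: float = 0.45e-3
    rd_effect: float = -0.05e-3
    dwi_sigma: float = 5.0
    dwi_s0: float = 1000.0
    base_fvf1: float = 0.5
    fvf_effect: float = 0.05
    n_streamlines: int = 20

    def __post_init__(self) -> None:
        if self.n_subjects < 8:
            # the covariate LM has 6 predictors plus an intercept
            raise ValueError("need at least 8 subjects for the covariate models")


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _subject_stages(cfg: RunConfig, subject: int, group_r: bool, ss) -> dict:
    """Run every per-subject stage; returns the subject's table row."""
    stage_ss = ss.spawn(4)
    row: dict = {}

    # --- LC phantom and contrast -------------------------------------
    ratio = cfg.base_contrast_ratio + (cfg.contrast_effect if group_r else 0.0)
    spec = synthio.PhantomSpec(
        shape=cfg.phantom_shape,
        contrast_ratio=ratio,
        noise_sd=cfg.phantom_noise_sd,
        seed=_derive_seed(stage_ss[0]),
    )
    vol, _, _ = synthio.generate_lc_phantom(spec)
    ref_spec = lc_contrast.ReferenceSpec(anterior_offset=cfg.reference_offset)
    for side, line in zip(("left", "right"), spec.lc_centerlines):
        side_mask = synthio.rasterize_tube(line, spec.shape, spec.voxel_size, spec.lc_radius)
        m1, m2, _ = synthio.perturb_rater_masks(
            side_mask, cfg.rater_jitter, seed=_derive_seed(stage_ss[0]) + 1
        )
        result = lc_contrast.extract_contrast(
            vol, m1, m2, side=side, factor=1, ref_spec=ref_spec
        )
        for part in ("caudal", "medial", "rostral"):
            row[f"contrast_{side}_{part}"] = result.contrast(part)
    row["_phantom"] = (vol, spec)

    # --- oddball BOLD -------------------------------------------------
    beta = cfg.base_beta + (cfg.beta_effect if group_r else 0.0)
    bold_spec = synthio.BoldSpec(
        beta=beta,
        noise_sd=cfg.bold_noise_sd,
        drift_amplitude=cfg.bold_drift_amplitude,
        motion_leak=cfg.bold_motion_leak,
        seed=_derive_seed(stage_ss[1]),
    )
    series, motion, _ = synthio.generate_bold(bold_spec)
    design = oddball_glm.build_design(
        bold_spec.paradigm, bold_spec.n_volumes, bold_spec.tr_s, motion=motion
    )
    row["lc_beta"] = oddball_glm.fit_glm(series, design).betas["target"]

    # --- diffusion ----------------------------------------------------
    rng = np.random.default_rng(_derive_seed(stage_ss[2]))
    rd = cfg.base_rd + (cfg.rd_effect if group_r else 0.0) + rng.normal(0, 0.01e-3)
    tensors = np.broadcast_to(
        np.diag([cfg.base_ad, rd, rd]), (*cfg.dwi_shape, 3, 3)
    ).copy()
    dwi_spec = synthio.DwiSpec(
        tensors=tensors,
        s0=cfg.dwi_s0,
        sigma=cfg.dwi_sigma,
        voxel_size=cfg.dwi_voxel_size,
        seed=_derive_seed(stage_ss[2]) + 1,
    )
    dwi, (bvals, bvecs) = synthio.generate_dwi(dwi_spec)
    fit = tract_micro.fit_dti(dwi, bvals, bvecs)
    scalars = tract_micro.dti_scalars(fit.evals)

    fvf1 = np.clip(
        cfg.base_fvf1 + (cfg.fvf_effect if group_r else 0.0) + rng.normal(0, 0.01),
        0.0,
        1.0,
    )
    wfvf_map = tract_micro.compute_wfvf(
        np.full(cfg.dwi_shape, 0.6),
        np.full(cfg.dwi_shape, fvf1),
        np.full(cfg.dwi_shape, 0.4),
        np.full(cfg.dwi_shape, min(1.0, fvf1 + 0.2)),
    )

    extent = np.asarray(cfg.dwi_shape) * np.asarray(cfg.dwi_voxel_size)
    path = np.array(
        [[2.0, extent[1] / 2, extent[2] / 2], [extent[0] - 2.0, extent[1] / 2, extent[2] / 2]]
    )
    streamlines, _ = synthio.generate_tract_fixture(
        path,
        cfg.dwi_shape,
        cfg.dwi_voxel_size,
        n_streamlines=cfg.n_streamlines,
        seed=_derive_seed(stage_ss[3]),
    )
    tractset = tract_micro.filter_streamlines(streamlines)
    if tractset.n_removed:
        log.warning(
            "subject %d: %d streamlines removed by length filter",
            subject,
            tractset.n_removed,
        )
    voxels = tract_micro.voxelize_streamlines(
        tractset.streamlines, cfg.dwi_shape, cfg.dwi_voxel_size
    )
    maps = {**scalars, "wFVF": wfvf_map}
    means = tract_micro.tract_mean_metrics(voxels, maps)
    for name in ("FA", "MD", "AD", "RD", "wFVF"):
        row[f"tract_{name}"] = means[name]["mean"]
        if means[name]["n_missing"]:
            log.warning(
                "subject %d: %d voxels missing for %s",
                subject,
                means[name]["n_missing"],
                name,
            )
    return row


def _covariates(rng: np.random.Generator, n: int, groups) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": groups,
            "duration_months": np.round(rng.uniform(6, 150, size=n), 1),
            "age": np.round(rng.uniform(18, 65, size=n), 1),
            "sex": [("F", "M")[i % 2] for i in range(n)],
            "asm_count": rng.integers(2, 5, size=n),
            "epilepsy_duration_y": np.round(rng.uniform(5, 40, size=n), 1),
            "benzodiazepine": rng.integers(0, 2, size=n),
        }
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_demo(config: RunConfig, out_dir) -> Path:
    """Run the full synthetic cohort and write artifacts plus a manifest."""
    t0 = time.monotonic()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    subject_ss = master.spawn(config.n_subjects + 1)
    groups = [
        "R_PR" if i >= config.n_subjects // 2 else "NR"
        for i in range(config.n_subjects)
    ]

    rows = []
    first_phantom = None
    for i in range(config.n_subjects):
        t_subj = time.monotonic()
        row = _subject_stages(config, i, groups[i] == "R_PR", subject_ss[i])
        phantom = row.pop("_phantom")
        if first_phantom is None:
            first_phantom = phantom
        row["subject_id"] = f"sub-{i:03d}"
        rows.append(row)
        log.info("subject %d done in %.2f s", i, time.monotonic() - t_subj)

    cov = _covariates(
        np.random.default_rng(_derive_seed(subject_ss[-1])), config.n_subjects, groups
    )
    metrics = pd.DataFrame(rows).set_index("subject_id").reset_index()
    table = pd.concat([metrics[["subject_id"]], cov, metrics.drop(columns="subject_id")], axis=1)
    table.to_csv(out / "subjects.tsv", sep="\t", index=False, float_format="%.10g")

    families = {
        "contrast": CONTRAST_METRICS,
        "activity": ["lc_beta"],
        **{m: [m] for m in TRACT_METRICS},
    }
    outcomes = CONTRAST_METRICS + ["lc_beta"] + TRACT_METRICS
    for predictor, fname in (("group", "lm_group.tsv"), ("duration_months", "lm_duration.tsv")):
        report = group_stats.lm_report(table, outcomes, predictor, fdr_families=families)
        report.to_csv(out / fname, sep="\t", index=False, float_format="%.10g")

    # example NIfTI artifacts for the first subject (uncompressed for
    # bit-reproducibility of the output directory)
    vol, spec = first_phantom
    save_volume(vol, out / "sub-000_phantom.nii")
    mask = np.zeros(spec.shape, dtype=bool)
    for line in spec.lc_centerlines:
        mask |= synthio.rasterize_tube(line, spec.shape, spec.voxel_size, spec.lc_radius)
    save_mask(mask, spec.voxel_size, out / "sub-000_lcmask.nii")

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "versions": {"lcmri": __version__, "numpy": np.__version__},
        "groups": groups,
        "files": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("demo complete in %.2f s", time.monotonic() - t0)
    return out


@dataclass
class ValidationReport:
    passed: bool
    issues: list[str] = field(default_factory=list)


def validate_outputs(out_dir) -> ValidationReport:
    """Check a demo directory: manifest, hashes, schemas, invariants."""
    import nibabel as nib

    out = Path(out_dir)
    issues: list[str] = []
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        return ValidationReport(False, ["manifest.json missing"])
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        return ValidationReport(False, [f"malformed manifest: {exc}"])
    for key in ("seed", "files", "versions"):
        if key not in manifest:
            issues.append(f"manifest missing key '{key}'")
    for name, digest in manifest.get("files", {}).items():
        p = out / name
        if not p.exists():
            issues.append(f"listed file missing: {name}")
        elif _sha256(p) != digest:
            issues.append(f"hash mismatch: {name}")

    subjects = out / "subjects.tsv"
    if subjects.exists():
        df = pd.read_csv(subjects, sep="\t")
        required = {"subject_id", "group", "age", "sex"}
        missing = required - set(df.columns)
        if missing:
            issues.append(f"subjects.tsv missing columns: {sorted(missing)}")
        if "tract_FA" in df.columns:
            fa = df["tract_FA"].dropna()
            if ((fa < 0) | (fa > 1)).any():
                issues.append("tract_FA outside [0, 1]")
        for col in df.columns:
            if col.startswith("contrast_") and not np.isfinite(df[col]).all():
                issues.append(f"non-finite values in {col}")
    else:
        issues.append("subjects.tsv missing")

    for fname in ("lm_group.tsv", "lm_duration.tsv"):
        p = out / fname
        if not p.exists():
            issues.append(f"{fname} missing")
            continue
        rep = pd.read_csv(p, sep="\t")
        if ((rep["p"] < 0) | (rep["p"] > 1)).any():
            issues.append(f"{fname}: p outside [0, 1]")
        if (rep["p_fdr"] < rep["p"] - 1e-12).any():
            issues.append(f"{fname}: adjusted p below raw p")

    for nii in out.glob("*.nii"):
        try:
            img = nib.load(str(nii))
            if any(z <= 0 for z in img.header.get_zooms()[:3]):
                issues.append(f"{nii.name}: non-positive voxel size")
        except Exception as exc:
            issues.append(f"{nii.name}: unreadable NIfTI ({exc})")

    return ValidationReport(passed=not issues, issues=issues)


def power_simulation(
    effect: float = 0.05,
    n_subjects: int = 40,
    n_replicates: int = 100,
    noise_sd: float = 5.0,
    seed: int = 0,
    alpha: float = 0.05,
    phantom_shape=(48, 48, 12),
) -> float:
    """Fraction of replicates in which the group LM detects a contrast effect.

    Each replicate draws a cohort with a group difference of ``effect`` in
    true contrast ratio, extracts the whole-LC contrast of the left side and
    tests the group coefficient in the covariate LM.
    """
    master = np.random.SeedSequence(seed)
    hits = 0
    for rep_ss in master.spawn(n_replicates):
        sub_ss = rep_ss.spawn(n_subjects + 1)
        groups = ["R_PR" if i >= n_subjects // 2 else "NR" for i in range(n_subjects)]
        vals = []
        for i in range(n_subjects):
            ratio = 1.15 + (effect if groups[i] == "R_PR" else 0.0)
            spec = synthio.PhantomSpec(
                shape=phantom_shape,
                contrast_ratio=ratio,
                noise_sd=noise_sd,
                seed=_derive_seed(sub_ss[i]),
            )
            vol, _, _ = synthio.generate_lc_phantom(spec)
            side_mask = synthio.rasterize_tube(
                spec.lc_centerlines[0], spec.shape, spec.voxel_size, spec.lc_radius
            )
            region = lc_contrast.subdivide_rostrocaudal(side_mask, side="left")
            res = lc_contrast.compute_contrast(
                vol, region, lc_contrast.ReferenceSpec(anterior_offset=15)
            )
            vals.append(res.contrast("whole"))
        table = _covariates(
            np.random.default_rng(_derive_seed(sub_ss[-1])), n_subjects, groups
        )
        table["contrast_whole"] = vals
        row = group_stats.fit_covariate_lm(table, "contrast_whole", "group")
        hits += row.p < alpha
    return hits / n_replicates
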