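"""End-to-end orchestration: simulate -> maps -> ROI table -> statistics.

Stages exchange data through files (NIfTI / CSV / JSON) rather than in-memory
handoff, so each stage can be re-run and inspected independently.  A manifest
records the seed, per-stage status and SHA-256 checksums of every artifact;
with a fixed seed a re-run reproduces the manifest checksums exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cest import compute_aptw_map, compute_b0_map
from .cohort import CohortConfig, generate_cohort
from .dki import DEFAULT_B_VALUES, fit_dki_map
from .io import load_bvals, load_nifti, load_offsets_json, save_bvals, save_nifti, save_offsets_json
from .nomogram import nomogram_from_model
from .offsets import default_offset_scheme
from .phantom import PhantomTruth, build_lesion_scene, simulate_cest_stack, simulate_dwi_stack, simulate_gre_phase_pair
from .roc import combine_predictors, delong_compare, roc_with_delong
from .roi import average_readers, icc_two_way, roi_mean
from .stats import compare_groups, contingency_test, multivariate_logit, spearman_assoc, univariate_logit

__all__ = ["RunConfig", "run_pipeline", "run_stats_stage"]

MARKERS = ("aptw", "mk", "md")
BINARY_COVARIATES = (
    "menopause", "histology_ca", "figo_advanced", "grade_high",
    "depth_deep", "scc_ag_high", "vascular",
)
CONTINUOUS_COVARIATES = ("age", "tumor_size_mm")


def _default_lesions(shape=(60, 60)):
    """Eight circular lesions alternating around the two outcome groups'
    marker means, laid out on a grid; enough subjects for an ICC."""
    rng = np.random.default_rng(7)
    lesions = []
    fracs = [(0.17, 0.17), (0.17, 0.5), (0.17, 0.83), (0.5, 0.17),
             (0.5, 0.83), (0.83, 0.17), (0.83, 0.5), (0.83, 0.83)]
    radius = max(3, int(round(min(shape) * 0.1)))
    centers = [(int(round(fy * (shape[0] - 1))), int(round(fx * (shape[1] - 1))))
               for fy, fx in fracs]
    for i, c in enumerate(centers):
        if i % 2 == 0:
            base = {"aptw_pct": 3.7, "md_e3": 0.989, "mk": 1.065}
        else:
            base = {"aptw_pct": 2.4, "md_e3": 1.193, "mk": 0.909}
        lesions.append({
            "name": f"lesion{i + 1}", "center": c, "radius": radius,
            "aptw_pct": base["aptw_pct"] + rng.normal(0, 0.4),
            "md_e3": max(base["md_e3"] + rng.normal(0, 0.1), 0.3),
            "mk": max(base["mk"] + rng.normal(0, 0.08), 0.2),
        })
    return lesions


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str = "aptdki_run"
    seed: int = 0
    scene_shape: tuple[int, int] = (60, 60)
    b0_amplitude_ppm: float = 0.3
    cest_noise_sd: float = 0.002      # fraction of S0
    dwi_noise_sigma: float = 2.0      # signal units at S0 = 1000
    te_delta_ms: float = 4.92
    b_values: tuple = DEFAULT_B_VALUES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    make_plots: bool = True

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        cohort = CohortConfig(**raw.pop("cohort")) if "cohort" in raw else CohortConfig()
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__},
                  cohort=cohort)
        cfg.scene_shape = tuple(cfg.scene_shape)
        cfg.b_values = tuple(cfg.b_values)
        return cfg

    def validate(self) -> None:
        self.cohort.validate()
        if self.seed is None or int(self.seed) < 0:
            raise ValueError("a non-negative seed is required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(cfg: RunConfig, out: Path, rng) -> dict:
    scheme = default_offset_scheme()
    truth, masks = build_lesion_scene(
        shape=cfg.scene_shape, lesions=_default_lesions(cfg.scene_shape),
        b0_amplitude_ppm=cfg.b0_amplitude_ppm)
    union = np.zeros(cfg.scene_shape, dtype=bool)
    for m in masks.values():
        union |= m
    # restrict CEST simulation to ROI voxels (plus margin) to keep runs short
    amide_amp = np.where(union, truth.aptw_pct / 100.0, 0.0)
    stack, true_aptw = simulate_cest_stack(
        amide_amp, truth.b0_ppm, scheme, noise_sd=cfg.cest_noise_sd, rng=rng)
    pair = simulate_gre_phase_pair(truth.b0_ppm, te_delta_ms=cfg.te_delta_ms)
    dwi = simulate_dwi_stack(truth, cfg.b_values, noise_sigma=cfg.dwi_noise_sigma, rng=rng)

    files = {}
    files["cest_stack"] = save_nifti(stack, out / "cest_stack.nii")
    files["offsets"] = save_offsets_json(scheme, out / "cest_offsets.json")
    files["phase_early"] = save_nifti(pair.phase_early, out / "gre_phase_early.nii")
    files["phase_late"] = save_nifti(pair.phase_late, out / "gre_phase_late.nii")
    files["dwi_stack"] = save_nifti(dwi, out / "dwi_stack.nii")
    files["bvals"] = save_bvals(cfg.b_values, out / "dwi.bval")
    files["truth_aptw"] = save_nifti(true_aptw, out / "truth_aptw_pct.nii")
    files["truth_b0"] = save_nifti(truth.b0_ppm, out / "truth_b0_ppm.nii")
    files["truth_md"] = save_nifti(truth.md_e3, out / "truth_md.nii")
    files["truth_mk"] = save_nifti(truth.mk, out / "truth_mk.nii")
    for name, m in masks.items():
        files[f"mask_{name}"] = save_nifti(m.astype(float), out / f"mask_{name}.nii")
    files["roi_union"] = save_nifti(union.astype(float), out / "mask_union.nii")

    cohort = generate_cohort(cfg.cohort, seed=rng)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    files["cohort"] = cohort_path
    return {name: str(p) for name, p in files.items()}


def _stage_maps(cfg: RunConfig, out: Path, sim_files: dict) -> dict:
    scheme = load_offsets_json(sim_files["offsets"])
    stack = load_nifti(sim_files["cest_stack"])
    union = load_nifti(sim_files["roi_union"]) > 0.5
    b0_map = compute_b0_map(
        load_nifti(sim_files["phase_early"]), load_nifti(sim_files["phase_late"]),
        te_delta_ms=cfg.te_delta_ms)
    aptw = compute_aptw_map(stack, scheme, b0_map=b0_map, mask=union)
    dwi = load_nifti(sim_files["dwi_stack"])
    bvals = load_bvals(sim_files["bvals"])
    md, mk, s0, qc = fit_dki_map(dwi, union, bvals)
    files = {
        "b0_map": save_nifti(b0_map.b0_ppm, out / "b0_map_ppm.nii"),
        "aptw_map": save_nifti(aptw, out / "aptw_map_pct.nii"),
        "md_map": save_nifti(md, out / "md_map.nii"),
        "mk_map": save_nifti(mk, out / "mk_map.nii"),
        "s0_map": save_nifti(s0, out / "s0_map.nii"),
        "qc_map": save_nifti(qc.astype(float), out / "dki_qc.nii"),
    }
    return {name: str(p) for name, p in files.items()}


def _reader2_mask(mask: np.ndarray, rng) -> np.ndarray:
    """Second reader's ROI: the first reader's contour shifted by one pixel."""
    dy, dx = rng.integers(-1, 2, size=2)
    return np.roll(np.roll(mask, int(dy), axis=0), int(dx), axis=1)


def _stage_roi(cfg: RunConfig, out: Path, sim_files: dict, map_files: dict, rng) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    maps = {
        "aptw": load_nifti(map_files["aptw_map"]),
        "mk": load_nifti(map_files["mk_map"]),
        "md": load_nifti(map_files["md_map"]),
    }
    lesion_names = sorted(
        name[len("mask_"):] for name in sim_files
        if name.startswith("mask_") and name != "mask_union" and "union" not in name)
    rows = []
    for lesion in lesion_names:
        m1 = load_nifti(sim_files[f"mask_{lesion}"]) > 0.5
        m2 = _reader2_mask(m1, rng)
        for param, pm in maps.items():
            for reader, m in (("R1", m1), ("R2", m2)):
                meas = roi_mean(pm, m, patient_id=lesion, reader_id=reader, parameter=param)
                rows.append(meas.__dict__)
    tidy = pd.DataFrame(rows)
    tidy_path = out / "roi_measurements.csv"
    tidy.to_csv(tidy_path, index=False)

    avg_rows, icc_rows = [], []
    for param in maps:
        sub = tidy[tidy.parameter == param].pivot(
            index="patient_id", columns="reader_id", values="value")
        for pid, row in sub.iterrows():
            avg_rows.append({"patient_id": pid, "parameter": param,
                             "value": average_readers([row["R1"], row["R2"]])})
        icc = icc_two_way(sub["R1"].to_numpy(), sub["R2"].to_numpy())
        icc_rows.append({"parameter": param, "icc": icc.icc,
                         "ci_lower": icc.ci_lower, "ci_upper": icc.ci_upper,
                         "band": icc.band})
    avg_path = out / "roi_reader_averaged.csv"
    pd.DataFrame(avg_rows).to_csv(avg_path, index=False)
    icc_path = out / "interobserver_icc.csv"
    pd.DataFrame(icc_rows).to_csv(icc_path, index=False)
    return {"roi_measurements": str(tidy_path),
            "roi_reader_averaged": str(avg_path),
            "interobserver_icc": str(icc_path)}


def run_stats_stage(records: pd.DataFrame, out: Path, make_plots: bool = True) -> dict:
    """Full inferential chain on a cohort table; writes the table analogs.

    Produces: group-comparison table (continuous + categorical), univariate
    and multivariate logistic table, ROC/DeLong table with Youden operating
    points, Spearman associations, nomogram spec JSON, ROC coordinates CSV
    and (optionally) a ROC figure.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    y = records["lnm"].to_numpy(int)

    # --- group comparisons -------------------------------------------------
    rows = []
    for col in MARKERS + CONTINUOUS_COVARIATES:
        cmp = compare_groups(records[col].to_numpy(float), y)
        rows.append({"variable": col, "kind": "continuous", "test": cmp.test,
                     "statistic": cmp.statistic, "p": cmp.p})
    for col in BINARY_COVARIATES:
        tab = pd.crosstab(records[col], records["lnm"]).reindex(
            index=[0, 1], columns=[0, 1], fill_value=0).to_numpy()
        res = contingency_test(tab)
        rows.append({"variable": col, "kind": "categorical", "test": res.test,
                     "statistic": res.statistic, "p": res.p})
    comp_path = out / "group_comparisons.csv"
    pd.DataFrame(rows).to_csv(comp_path, index=False)
    files["group_comparisons"] = str(comp_path)

    # --- logistic regression ----------------------------------------------
    candidates = list(MARKERS + CONTINUOUS_COVARIATES + BINARY_COVARIATES)
    uni_rows = []
    selected = []
    for col in candidates:
        fit = univariate_logit(records, col)
        row = fit.table.loc[col].to_dict()
        row["predictor"] = col
        row["separation"] = fit.separation
        uni_rows.append(row)
        if row["p"] < 0.05 and not fit.separation:
            selected.append(col)
    uni_path = out / "univariate_logit.csv"
    pd.DataFrame(uni_rows).set_index("predictor").to_csv(uni_path)
    files["univariate_logit"] = str(uni_path)

    multi = multivariate_logit(records, predictors=selected) if selected else None
    if multi is not None:
        multi_path = out / "multivariate_logit.csv"
        multi.table.to_csv(multi_path)
        files["multivariate_logit"] = str(multi_path)

    # --- ROC / DeLong / Youden --------------------------------------------
    roc_rows, roc_coords = [], []
    rocs = {}
    for col in MARKERS:
        roc = roc_with_delong(y, records[col].to_numpy(float))
        rocs[col] = (records[col].to_numpy(float), roc)
        roc_rows.append({
            "score": col, "auc": roc.auc, "ci_lower": roc.ci_lower,
            "ci_upper": roc.ci_upper, "cutoff": roc.youden_cutoff,
            "direction": roc.direction,
            "sensitivity_pct": 100 * roc.sensitivity,
            "specificity_pct": 100 * roc.specificity,
        })
        roc_coords.append(pd.DataFrame(
            {"score": col, "fpr": roc.fpr, "tpr": roc.tpr}))
    combo_score, combo_fit, combo_roc = combine_predictors(records, list(MARKERS))
    roc_rows.append({
        "score": "combination", "auc": combo_roc.auc,
        "ci_lower": combo_roc.ci_lower, "ci_upper": combo_roc.ci_upper,
        "cutoff": combo_roc.youden_cutoff, "direction": combo_roc.direction,
        "sensitivity_pct": 100 * combo_roc.sensitivity,
        "specificity_pct": 100 * combo_roc.specificity,
    })
    roc_coords.append(pd.DataFrame(
        {"score": "combination", "fpr": combo_roc.fpr, "tpr": combo_roc.tpr}))
    for col in MARKERS:
        _, _, diff, zstat, p = delong_compare(y, combo_score, records[col].to_numpy(float))
        roc_rows.append({"score": f"combination_vs_{col}", "auc": diff,
                         "z": zstat, "p": p})
    roc_path = out / "roc_summary.csv"
    pd.DataFrame(roc_rows).to_csv(roc_path, index=False)
    files["roc_summary"] = str(roc_path)
    coords_path = out / "roc_coordinates.csv"
    pd.concat(roc_coords, ignore_index=True).to_csv(coords_path, index=False)
    files["roc_coordinates"] = str(coords_path)

    # --- Spearman ----------------------------------------------------------
    sp_rows = []
    for col in MARKERS:
        rho, p = spearman_assoc(records, col)
        sp_rows.append({"parameter": col, "rho": rho, "p": p})
    sp_path = out / "spearman.csv"
    pd.DataFrame(sp_rows).to_csv(sp_path, index=False)
    files["spearman"] = str(sp_path)

    # --- nomogram ----------------------------------------------------------
    if multi is not None:
        ranges = {p: (float(records[p].min()), float(records[p].max()))
                  for p in multi.predictors}
        ranges = {p: r for p, r in ranges.items() if r[1] > r[0]}
        try:
            nomo = nomogram_from_model(multi, ranges)
            nomo_path = out / "nomogram.json"
            nomo_path.write_text(json.dumps(nomo.to_dict(), indent=1))
            files["nomogram"] = str(nomo_path)
        except ValueError:
            pass

    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for col in MARKERS:
            _, roc = rocs[col]
            ax.plot(roc.fpr, roc.tpr, label=f"{col} (AUC {roc.auc:.3f})")
        ax.plot(combo_roc.fpr, combo_roc.tpr, "k-",
                label=f"combination (AUC {combo_roc.auc:.3f})")
        ax.plot([0, 1], [0, 1], ":", color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        fig_path = out / "roc_curves.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        files["roc_figure"] = str(fig_path)
    return files


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order and write the run manifest.

    Returns the manifest dict; on stage failure the manifest records partial
    completion and the exception message, and ``status`` is ``"failed"``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "status": "running",
    }
    all_files: dict[str, str] = {}
    stages = [
        ("simulate", lambda: _stage_simulate(cfg, out / "inputs", rng)),
        ("maps", lambda: _stage_maps(cfg, out / "maps", all_files)),
        ("roi", lambda: _stage_roi(cfg, out / "roi", all_files, all_files, rng)),
        ("stats", lambda: run_stats_stage(
            pd.read_csv(all_files["cohort"]), out / "stats", cfg.make_plots)),
    ]
    for name, fn in stages:
        try:
            produced = fn()
        except Exception as exc:  # record partial completion
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            manifest["status"] = "failed"
            break
        all_files.update(produced)
        manifest["stages"][name] = {"status": "ok", "files": produced}
    else:
        manifest["status"] = "ok"
    manifest["checksums"] = {
        name: _sha256(Path(p)) for name, p in sorted(all_files.items())
        if Path(p).exists() and not p.endswith(".png")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
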