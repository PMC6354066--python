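"""End-to-end study orchestration.

``run_study`` executes the whole comparison from a single config: simulate a
cohort, render phantom images, parcellate them against a synthetic atlas set,
then run the volumetric (CNR, PVD/Bland-Altman), statistical (paired tests,
ANOVA, w-scores, change rates, mixed models) and classification stages, and
write every table plus a JSON manifest under the output directory.

Determinism: each stage draws its seed from a stable hash of (master seed,
stage name), so stages can be re-run in isolation and adding a stage never
reshuffles another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import assemble_features, cv_linear_svm, learning_curve
from .cohort import (CohortSpec, ModalityParams, SpecValidationError,
                     StructureDef, default_cohort_spec, make_cohort)
from .images import LabelMap
from .parcellation import (AtlasEntry, ParcellationConfig, extract_volumes,
                           parcellate, resample_image, split_hemispheres)
from .phantom import make_atlases, render_phantom
from .registration import AffineConfig, NonrigidConfig, register_affine
from .stats import (LME_FORMS, bh_fdr, change_rate, compare_lme, fit_lme,
                    fit_wscore, paired_test, relative_residuals, unpaired_test,
                    anova_bonferroni)
from .volumetrics import bland_altman, cnr, groupwise_background_roi, pvd

__all__ = ["StudyConfig", "StudyReport", "validate_config", "run_study",
           "stage_seed"]

log = logging.getLogger("murivol")

LME_STRUCTURES = ("hippocampus", "neocortex", "ventricles")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{int(master)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass(frozen=True)
class StudyConfig:
    cohort: CohortSpec = field(default_factory=default_cohort_spec)
    n_atlases: int = 3
    ncc_window: int = 5
    top_k: int | None = None
    affine_model: str = "ts"
    affine_levels: tuple[int, ...] = (4, 2)
    affine_maxiter: tuple[int, ...] = (2, 1)
    nonrigid_maxiter: int = 10      # 0: affine-only propagation
    reference_group: str = "UT"
    fdr_q: float = 0.05
    cv_folds: int = 3
    pca_fraction: float = 0.95
    learning_sizes: tuple[int, ...] = (6, 8, 10, 13, 17)
    learning_replicates: int = 20
    seed: int = 0
    outdir: str = "study_out"
    profile: str = "fast"

    def parcellation_config(self) -> ParcellationConfig:
        nr = (NonrigidConfig(maxiter=self.nonrigid_maxiter)
              if self.nonrigid_maxiter > 0 else None)
        return ParcellationConfig(
            affine=AffineConfig(levels=self.affine_levels,
                                maxiter=self.affine_maxiter,
                                model=self.affine_model),
            nonrigid=nr, ncc_window=self.ncc_window, top_k=self.top_k)


@dataclass
class StudyReport:
    outputs: dict
    runtimes: dict
    config: dict
    version: str = __version__

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"outputs": self.outputs, "runtimes_s": self.runtimes,
             "config": self.config, "version": self.version}, indent=1,
            default=str))


# ---------------------------------------------------------------------------
# config I/O


_FAST_OVERRIDES = dict(invivo_spacing=0.30, exvivo_spacing=0.15)


def _build_cohort(section: dict, profile: str) -> CohortSpec:
    spec = default_cohort_spec()
    known = {"group_sizes", "timepoints", "seed", "exvivo_factors",
             "gradient_drift_per_month", "invivo", "exvivo", "structures"}
    unknown = set(section) - known
    if unknown:
        raise SpecValidationError(f"unknown cohort keys: {sorted(unknown)}")
    kw = {}
    for key in ("group_sizes", "exvivo_factors", "gradient_drift_per_month", "seed"):
        if key in section:
            kw[key] = section[key]
    if "timepoints" in section:
        kw["timepoints"] = tuple(section["timepoints"])
    if "structures" in section:
        kw["structures"] = tuple(StructureDef(**s) for s in section["structures"])
    for mod in ("invivo", "exvivo"):
        if mod in section:
            base = getattr(spec, mod)
            m = dict(spacing_mm=base.spacing_mm, grid_shape=base.grid_shape,
                     intensity=base.intensity, noise_sd=base.noise_sd)
            m.update(section[mod])
            m["grid_shape"] = tuple(m["grid_shape"])
            kw[mod] = ModalityParams(**m)
    spec = spec.replace(**kw)
    if profile == "fast" and "invivo" not in section and "exvivo" not in section:
        spec = _apply_fast_profile(spec)
    return spec


def _apply_fast_profile(spec: CohortSpec) -> CohortSpec:
    """Coarsen both grids (same field of view) so CI runs in minutes."""
    fov = spec.invivo.spacing_mm * spec.invivo.grid_shape[0]
    iv = ModalityParams(_FAST_OVERRIDES["invivo_spacing"],
                        (int(round(fov / _FAST_OVERRIDES["invivo_spacing"])),) * 3,
                        spec.invivo.intensity, spec.invivo.noise_sd)
    ex = ModalityParams(_FAST_OVERRIDES["exvivo_spacing"],
                        (int(round(fov / _FAST_OVERRIDES["exvivo_spacing"])),) * 3,
                        spec.exvivo.intensity, spec.exvivo.noise_sd)
    return spec.replace(invivo=iv, exvivo=ex)


def validate_config(source, profile: str | None = None, strict: bool = True
                    ) -> StudyConfig:
    """Load and validate a study config from a YAML/JSON file, dict or None.

    Missing keys take defaults; unknown keys raise (strict) or warn (lax).
    """
    if source is None:
        raw = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise SpecValidationError("config root must be a mapping")
    fields = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - fields
    if unknown:
        msg = f"unknown config keys: {sorted(unknown)}"
        if strict:
            raise SpecValidationError(msg)
        log.warning(msg)
        for k in unknown:
            raw.pop(k)
    prof = profile or raw.get("profile", "fast")
    if prof not in ("fast", "full"):
        raise SpecValidationError(f"profile must be fast|full, got {prof!r}")
    cohort_section = raw.pop("cohort", {})
    if isinstance(cohort_section, CohortSpec):
        cohort = cohort_section if prof == "full" else _apply_fast_profile(cohort_section)
    else:
        cohort = _build_cohort(cohort_section, prof)
    tup_keys = ("affine_levels", "affine_maxiter", "learning_sizes")
    for k in tup_keys:
        if k in raw:
            raw[k] = tuple(raw[k])
    cfg = StudyConfig(cohort=cohort, profile=prof, **raw)
    if cfg.n_atlases < 1:
        raise SpecValidationError("n_atlases must be >= 1")
    if not 0 < cfg.fdr_q < 1:
        raise SpecValidationError("fdr_q must be in (0, 1)")
    return cfg


# ---------------------------------------------------------------------------
# stages


def _parcellate_cohort(cfg: StudyConfig, cohort, outdir: Path):
    """Render and parcellate every subject image.

    Returns the long volume table plus, per subject, the terminal in vivo and
    ex vivo images with their consensus label maps (for the CNR stage).
    """
    spec = cfg.cohort
    pconf = cfg.parcellation_config()
    # large ex vivo grids: optimize the non-rigid stage at half resolution
    pconf_ex = pconf
    if pconf.nonrigid is not None and max(spec.exvivo.grid_shape) > 50:
        pconf_ex = dataclasses.replace(
            pconf, nonrigid=dataclasses.replace(pconf.nonrigid, shrink=2))
    seed0 = stage_seed(cfg.seed, "render")
    atlas_seed = stage_seed(cfg.seed, "atlas")
    atlases = {m: [AtlasEntry(i, l, n) for i, l, n in
                   make_atlases(spec, cfg.n_atlases, seed=atlas_seed, modality=m)]
               for m in ("invivo", "exvivo", "exvivo_downsampled")}
    rows = []
    self_images = {}
    for si, traj in enumerate(cohort):
        for k, t in enumerate(traj.timepoints):
            scale = (1.0 + spec.gradient_drift_per_month * (t - traj.timepoints[0])
                     if spec.gradient_drift_per_month else 1.0)
            img, _ = render_phantom(traj.invivo_volumes[k], spec.structures,
                                    spec.invivo, seed=seed0 + 10 * si + k,
                                    linear_scale=scale)
            consensus = parcellate(img, atlases['invivo'], pconf)
            split = split_hemispheres(consensus)
            rows.extend(_volume_rows(split, traj, t, "invivo"))
            if k == len(traj.timepoints) - 1:
                self_images[traj.subject_id] = (img, consensus)
        ex_img, _ = render_phantom(traj.exvivo_volumes, spec.structures,
                                   spec.exvivo, seed=seed0 + 10 * si + 7)
        ex_cons = parcellate(ex_img, atlases['exvivo'], pconf_ex)
        rows.extend(_volume_rows(split_hemispheres(ex_cons), traj,
                                 traj.timepoints[-1], "exvivo"))
        exd_img = resample_image(ex_img, spec.invivo.spacing_mm, order=3)
        exd_cons = parcellate(exd_img, atlases['exvivo_downsampled'], pconf)
        rows.extend(_volume_rows(split_hemispheres(exd_cons), traj,
                                 traj.timepoints[-1], "exvivo_downsampled"))
        self_images[traj.subject_id] += (ex_img, ex_cons)
        log.info("parcellated subject %s", traj.subject_id)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "volumes.csv", index=False)
    return df, self_images


def _volume_rows(labels: LabelMap, traj, timepoint, modality):
    df = extract_volumes(labels)
    tbv = df.attrs["total_brain_volume_mm3"]
    out = []
    for _, r in df.iterrows():
        out.append({"subject": traj.subject_id, "group": traj.group,
                    "timepoint": timepoint, "modality": modality,
                    "structure": r["structure"], "tissue": r["tissue"],
                    "hemisphere": r["hemisphere"],
                    "volume_mm3": r["volume_mm3"], "tbv_mm3": tbv})
    return out


def _cnr_stage(cfg: StudyConfig, cohort, images, outdir: Path) -> pd.DataFrame:
    """Groupwise background-ROI propagation and per-subject CNR."""
    rows = []
    for modality, img_idx, lab_idx in (("invivo", 0, 1), ("exvivo", 2, 3)):
        subj_ids = [t.subject_id for t in cohort]
        imgs = [images[s][img_idx] for s in subj_ids]
        labs = [images[s][lab_idx] for s in subj_ids]
        ref = imgs[0]
        affines = [register_affine(ref, im, AffineConfig(
            levels=(4,), maxiter=(1,), model="t")) for im in imgs]
        roi = np.zeros(ref.shape, dtype=bool)
        oct_ = tuple(slice(0, max(2, n // 6)) for n in ref.shape)
        roi[oct_] = True
        rois, flags = groupwise_background_roi(
            affines, roi, ref, imgs, [l.data > 0 for l in labs])
        for traj, im, lab, r, fl in zip(cohort, imgs, labs, rois, flags):
            if fl or not r.any():
                log.warning("CNR skipped for %s (%s): flagged ROI",
                            traj.subject_id, modality)
                continue
            rec = cnr(im, lab, r)
            rows.append({"subject": traj.subject_id, "group": traj.group,
                         "modality": modality, "signal_gm": rec.signal_gm,
                         "signal_wm": rec.signal_wm, "noise": rec.noise,
                         "cnr": rec.cnr})
    df = pd.DataFrame(rows)
    # ex vivo > in vivo CNR, unpaired one-tailed per group, FDR across groups
    tests = []
    for group, sub in df.groupby("group"):
        a = sub.loc[sub.modality == "exvivo", "cnr"]
        b = sub.loc[sub.modality == "invivo", "cnr"]
        if len(a) >= 2 and len(b) >= 2:
            t = unpaired_test(a, b, alternative="greater")
            tests.append({"group": group, "t": t.statistic, "p": t.p})
    tdf = pd.DataFrame(tests)
    if len(tdf):
        tdf["p_adj"], tdf["reject"] = bh_fdr(tdf["p"], cfg.fdr_q)
    df.to_csv(outdir / "cnr.csv", index=False)
    tdf.to_csv(outdir / "cnr_tests.csv", index=False)
    return df


def _pvd_stage(cfg: StudyConfig, volumes: pd.DataFrame, outdir: Path):
    """PVD per subject/structure, Bland-Altman and group tests per structure."""
    tfinal = volumes["timepoint"].max()
    iv = volumes.query("modality == 'invivo' and timepoint == @tfinal")
    ex = volumes.query("modality == 'exvivo_downsampled'")
    merged = iv.merge(ex, on=["subject", "group", "structure", "tissue"],
                      suffixes=("_in", "_ex"))
    merged["pvd"] = [pvd(a, b) if a + b > 0 else np.nan for a, b in
                     zip(merged["volume_mm3_in"], merged["volume_mm3_ex"])]
    merged.to_csv(outdir / "pvd.csv", index=False)
    ba_rows, test_rows = [], []
    for (group, structure), sub in merged.groupby(["group", "structure"]):
        pairs = list(zip(sub["volume_mm3_in"], sub["volume_mm3_ex"]))
        if len(pairs) >= 2:
            s = bland_altman(pairs)
            ba_rows.append({"group": group, "structure": structure,
                            "bias_pct": s.bias, "sd_pct": s.sd,
                            "loa_lower": s.loa_lower, "loa_upper": s.loa_upper,
                            "n": s.n})
            t = paired_test(sub["volume_mm3_in"], sub["volume_mm3_ex"])
            test_rows.append({"group": group, "structure": structure,
                              "t": t.statistic, "p": t.p,
                              "degenerate": t.degenerate})
    ba = pd.DataFrame(ba_rows)
    tests = pd.DataFrame(test_rows)
    if len(tests):
        adj = []
        for group, sub in tests.groupby("group"):
            p_adj, rej = bh_fdr(sub["p"], cfg.fdr_q)
            adj.append(sub.assign(p_adj=p_adj, reject=rej))
        tests = pd.concat(adj, ignore_index=True)
    # ANOVA across groups on each structure's PVD + Bonferroni + FDR
    anova_rows = []
    for structure, sub in merged.groupby("structure"):
        gs = [g["pvd"].dropna().to_numpy() for _, g in sub.groupby("group")]
        if len(gs) >= 2 and all(len(g) >= 2 for g in gs):
            res = anova_bonferroni(gs)
            anova_rows.append({"structure": structure,
                               "F": res["anova"].statistic, "p": res["anova"].p})
    anova = pd.DataFrame(anova_rows)
    if len(anova):
        anova["p_adj"], anova["reject"] = bh_fdr(anova["p"], cfg.fdr_q)
    ba.to_csv(outdir / "bland_altman.csv", index=False)
    tests.to_csv(outdir / "pvd_paired_tests.csv", index=False)
    anova.to_csv(outdir / "pvd_anova.csv", index=False)
    return merged, ba


def _wscore_table(volumes: pd.DataFrame, modality: str, timepoint,
                  reference_group: str) -> pd.DataFrame:
    """Wide per-subject w-score table for one modality/timepoint."""
    sub = volumes.query("modality == @modality and timepoint == @timepoint")
    sub = sub[sub.group.isin([reference_group, "TT"])]
    out = {}
    groups = None
    for structure, s in sub.groupby("structure"):
        ref = s[s.group == reference_group]
        model = fit_wscore(ref["volume_mm3"], ref["tbv_mm3"], reference_group)
        w = model.wscore(s["volume_mm3"].to_numpy(), s["tbv_mm3"].to_numpy())
        ser = pd.Series(w, index=s["subject"])
        out[structure] = ser
        if groups is None:
            groups = pd.Series(s["group"].to_numpy(), index=s["subject"])
    table = pd.DataFrame(out)
    table["group"] = groups
    return table.sort_index()


def _rate_table(volumes: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Wide per-subject change-rate table from the longitudinal in vivo data."""
    iv = volumes.query("modality == 'invivo'")
    iv = iv[iv.group.isin([reference_group, "TT"])]
    out = {}
    groups = {}
    for (subject, structure), s in iv.groupby(["subject", "structure"]):
        s = s.sort_values("timepoint")
        fit = change_rate(s["timepoint"], s["volume_mm3"])
        out.setdefault(structure, {})[subject] = fit.slope
        groups[subject] = s["group"].iloc[0]
    table = pd.DataFrame(out)
    table["group"] = pd.Series(groups)
    return table.sort_index()


def _group_tests(table: pd.DataFrame, q: float) -> pd.DataFrame:
    rows = []
    for col in table.columns.drop("group"):
        a = table.loc[table.group == "TT", col]
        b = table.loc[table.group != "TT", col]
        t = unpaired_test(a, b)
        rows.append({"structure": col, "t": t.statistic, "p": t.p,
                     "degenerate": t.degenerate})
    df = pd.DataFrame(rows)
    df["p_adj"], df["reject"] = bh_fdr(df["p"], q)
    return df


def _lme_stage(cfg: StudyConfig, volumes: pd.DataFrame, outdir: Path):
    """Three-variant mixed-model comparison on the key structures."""
    iv = volumes.query("modality == 'invivo'").copy()
    # merge hemispheres back to whole structures for the trajectory models
    iv["base"] = iv["structure"].str.replace(r"_[LR]$", "", regex=True)
    comp_rows, resid_rows = [], []
    for base in LME_STRUCTURES:
        s = (iv[iv.base == base]
             .groupby(["subject", "group", "timepoint"], as_index=False)
             ["volume_mm3"].sum())
        df = s.rename(columns={"timepoint": "time", "volume_mm3": "volume"})
        fits = [fit_lme(df, form) for form in LME_FORMS]
        table = compare_lme(fits)
        table.insert(0, "structure", base)
        comp_rows.append(table)
        for fit in fits:
            rr = relative_residuals(fit, df)
            resid_rows.append(rr.assign(structure=base, form=fit.form))
    comp = pd.concat(comp_rows, ignore_index=True)
    resid = pd.concat(resid_rows, ignore_index=True)
    comp.to_csv(outdir / "lme_comparison.csv", index=False)
    resid.to_csv(outdir / "lme_relative_residuals.csv", index=False)
    return comp, resid


def _classification_stage(cfg: StudyConfig, volumes: pd.DataFrame, outdir: Path):
    """The five feature sets: in vivo single / longitudinal / combined,
    ex vivo original and down-sampled."""
    tfinal = volumes["timepoint"].max()
    ref = cfg.reference_group
    w_iv = _wscore_table(volumes, "invivo", tfinal, ref)
    w_ex = _wscore_table(volumes, "exvivo", tfinal, ref)
    w_exd = _wscore_table(volumes, "exvivo_downsampled", tfinal, ref)
    rates = _rate_table(volumes, ref)
    seed = stage_seed(cfg.seed, "classify")
    feature_sets = {
        "invivo_single": assemble_features(w_iv, None, "single"),
        "exvivo": assemble_features(w_ex, None, "single"),
        "invivo_longitudinal": assemble_features(None, rates, "longitudinal"),
        "invivo_combined": assemble_features(w_iv, rates, "combined"),
        "exvivo_downsampled": assemble_features(w_exd, None, "single"),
    }
    reports = {}
    curves = {}
    for name, fm in feature_sets.items():
        rep = cv_linear_svm(fm, cfg.cv_folds, seed, cfg.pca_fraction)
        sizes = [s for s in cfg.learning_sizes if 2 * cfg.cv_folds <= s <= fm.n]
        lc = learning_curve(fm, sizes or [fm.n], cfg.learning_replicates,
                            cfg.cv_folds, seed, cfg.pca_fraction)
        reports[name] = {"fold_aucs": rep.fold_aucs, "mean_auc": rep.mean_auc,
                         "fold_accuracies": rep.fold_accuracies}
        curves[name] = {"sizes": lc.sizes,
                        "train_mean": lc.train_mean.tolist(),
                        "train_sd": lc.train_sd.tolist(),
                        "test_mean": lc.test_mean.tolist(),
                        "test_sd": lc.test_sd.tolist()}
    (outdir / "classification.json").write_text(json.dumps(reports, indent=1))
    (outdir / "learning_curves.json").write_text(json.dumps(curves, indent=1))
    tests = {"invivo_single": _group_tests(w_iv, cfg.fdr_q).to_dict("records"),
             "exvivo": _group_tests(w_ex, cfg.fdr_q).to_dict("records"),
             "exvivo_downsampled": _group_tests(w_exd, cfg.fdr_q).to_dict("records"),
             "invivo_rates": _group_tests(rates, cfg.fdr_q).to_dict("records")}
    (outdir / "group_difference_tests.json").write_text(json.dumps(tests, indent=1))
    return reports, curves


def run_study(config: StudyConfig | None = None, outdir=None) -> StudyReport:
    """Run the full pipeline; returns a manifest of everything written."""
    cfg = config or validate_config(None)
    out = Path(outdir or cfg.outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise SpecValidationError(f"output directory not writable: {exc}") from exc
    runtimes = {}
    outputs = {}
    manifest_path = out / "manifest.json"

    def _stage(name, fn, *args):
        t0 = time.time()
        log.info("stage %s started", name)
        try:
            result = fn(*args)
        except Exception:
            StudyReport(outputs, runtimes, _config_echo(cfg)).save(manifest_path)
            log.error("stage %s failed; partial manifest persisted", name)
            raise
        runtimes[name] = round(time.time() - t0, 3)
        return result

    cohort = _stage("cohort", make_cohort, cfg.cohort,
                    stage_seed(cfg.seed, "cohort"))
    volumes, images = _stage("parcellation", _parcellate_cohort, cfg, cohort, out)
    outputs["volumes"] = str(out / "volumes.csv")
    _stage("cnr", _cnr_stage, cfg, cohort, images, out)
    outputs["cnr"] = str(out / "cnr.csv")
    outputs["cnr_tests"] = str(out / "cnr_tests.csv")
    _stage("pvd", _pvd_stage, cfg, volumes, out)
    outputs["pvd"] = str(out / "pvd.csv")
    outputs["bland_altman"] = str(out / "bland_altman.csv")
    outputs["pvd_paired_tests"] = str(out / "pvd_paired_tests.csv")
    outputs["pvd_anova"] = str(out / "pvd_anova.csv")
    _stage("lme", _lme_stage, cfg, volumes, out)
    outputs["lme_comparison"] = str(out / "lme_comparison.csv")
    outputs["lme_relative_residuals"] = str(out / "lme_relative_residuals.csv")
    _stage("classify", _classification_stage, cfg, volumes, out)
    outputs["classification"] = str(out / "classification.json")
    outputs["learning_curves"] = str(out / "learning_curves.json")
    outputs["group_difference_tests"] = str(out / "group_difference_tests.json")
    report = StudyReport(outputs, runtimes, _config_echo(cfg))
    report.save(manifest_path)
    outputs["manifest"] = str(manifest_path)
    missing = [p for p in outputs.values() if not Path(p).exists()]
    if missing:
        raise RuntimeError(f"declared outputs missing: {missing}")
    return report


def _config_echo(cfg: StudyConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [enc(o) for o in obj]
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj
    return enc(cfg)
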