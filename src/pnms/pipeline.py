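"""End-to-end driver: simulate -> preprocess -> pNMS -> stats -> interpret.

Chains the whole analysis on a phantom cohort (or user-supplied,
pre-aligned volumes) and writes a machine-readable run report plus tidy
CSV outputs. Every run is deterministic given its seed, and the
resolved configuration (with its hash) is written beside the outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, imageproc, interpret, stats
from .io import RunConfig, save_subject
from .synthetic import PhantomSpec, SubjectImages, make_cohort
from .volume import AIMap, Volume

__all__ = ["preprocess_subject", "extract_features", "run_pipeline"]

log = logging.getLogger("pnms")

MODALITIES = ("pet", "gm_density", "flair")


def preprocess_subject(subj: SubjectImages, config: RunConfig) -> dict[str, AIMap]:
    """Run the preprocessing chain on each modality of one subject.

    The stage order is taken from ``config.order`` (default: smooth,
    partial-volume correction for PET, standardize, asymmetry map).
    Partial-volume correction applies to PET only; voxels it marks
    invalid (insufficient gray matter) leave the brain mask for that
    modality.
    """
    out: dict[str, AIMap] = {}
    for modality in MODALITIES:
        vol: Volume = getattr(subj, modality)
        mask = subj.brain_mask.values.astype(bool)
        ai: AIMap | None = None
        for stage in config.order:
            if stage == "smooth":
                vol = imageproc.gaussian_smooth(vol, config.fwhm_mm)
            elif stage == "pvc":
                if modality == "pet" and config.pvc:
                    vol = imageproc.muller_gartner_pvc(
                        vol, subj.tissue_gm, subj.tissue_wm, subj.tissue_csf,
                        fwhm_mm=config.fwhm_mm, gm_floor=config.gm_floor,
                    )
                    valid = np.isfinite(vol.values)
                    mask = mask & valid
                    vol = vol.like(np.where(valid, vol.values, 0.0))
            elif stage == "zscore":
                if config.normalization == "zscore":
                    vol = imageproc.zscore_within_mask(vol, mask)
                elif config.normalization == "proportional":
                    vol = imageproc.proportional_scale(vol, mask)
                else:
                    raise ValueError(f"unknown normalization {config.normalization!r}")
            elif stage == "ai":
                ai = imageproc.asymmetry_index_map(
                    vol, eps=config.eps, mask=mask,
                    shift=config.ai_shift if config.ai_shift != "none" else None,
                )
            else:
                raise ValueError(f"unknown pipeline stage {stage!r}")
        if ai is None:
            raise ValueError("pipeline order must end with the 'ai' stage")
        out[modality] = ai
    return out


def extract_features(
    subj: SubjectImages, aimaps: dict[str, AIMap], config: RunConfig
) -> dict:
    """Per-subject scalar features for the cohort table.

    Mean AI of each modality within the ablation cavity; the pNMS built
    from the PET AI map at the configured threshold; ablative rates of
    the pNMS within the ipsilateral hippocampus and amygdala; Dice
    between pNMS and cavity; and the structural features (TIV,
    ipsilateral volumes, volumetric asymmetry indices, ipsi - contra
    convention).
    """
    row: dict = {"subject_id": subj.subject_id, "ez_side": subj.ez_side,
                 "outcome": subj.outcome, "sf": int(subj.outcome == "SF")}
    ablation = subj.ablation_mask.values.astype(bool)
    for modality, ai in aimaps.items():
        row[f"ai_{modality}"] = core.mean_ai_within_mask(ai, ablation)

    pnms = core.binarize_pnms(
        aimaps["pet"], threshold=config.pnms_threshold, hemisphere=subj.ez_side,
    )
    row["pnms_vox"] = pnms.n_voxels()
    row["dice_pnms_ablation"] = (
        core.dice(pnms.mask, ablation) if pnms.n_voxels() or ablation.any() else None
    )
    for structure in ("hippo", "amyg"):
        roi = subj.ipsilateral(structure)
        rate = core.ablative_rate(pnms, ablation, roi)
        row[f"ablative_rate_{structure}"] = None if rate is None else 100.0 * rate

    # structural volumetry: gray-matter-density-weighted volume within each
    # label, so atrophy registers continuously (both density loss and label
    # erosion reduce it); TIV is the full intracranial (brain-mask) volume
    voxvol = subj.pet.voxel_volume_mm3()
    row["tiv"] = float(subj.brain_mask.values.sum()) * voxvol
    gmd = subj.gm_density.values
    contra = "right" if subj.ez_side == "left" else "left"
    for structure in ("hippo", "amyg"):
        v_ipsi = float(gmd[subj.roi_mask(structure, subj.ez_side)].sum()) * voxvol
        v_contra = float(gmd[subj.roi_mask(structure, contra)].sum()) * voxvol
        row[f"{structure}_volume_ipsi"] = v_ipsi
        row[f"{structure}_vai"] = (
            (v_ipsi - v_contra) / ((v_ipsi + v_contra) * 0.5)
            if v_ipsi + v_contra > 0 else None
        )
    return row


# --------------------------------------------------------------------------
# report assembly helpers


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _rcs_section(x: np.ndarray, y: np.ndarray, cov: np.ndarray | None,
                 config: RunConfig, name: str) -> tuple[dict, pd.DataFrame]:
    spline = stats.rcs_logistic_curve(
        x, y, covariates=cov, knot_probs=config.knot_probs, predictor=name)
    lin = stats.rcs_logistic_curve(
        x, y, covariates=cov, knot_probs=config.knot_probs, predictor=name, linear=True)
    best = stats.select_rcs_by_bic([spline, lin])
    infl = stats.find_inflection(spline)
    section = {
        "predictor": name,
        "knots": spline.knots,
        "bic_spline": spline.bic,
        "bic_linear": lin.bic,
        "selected": "spline" if best.spline else "linear",
        "p_nonlinearity": spline.p_nonlinearity,
        "p_overall": spline.p_overall,
        "shape": infl.shape,
        "inflection_points": infl.points,
        "inflection_kinds": infl.kinds,
        "reference_threshold": infl.reference,
    }
    curve = pd.DataFrame({
        "x": spline.grid_x,
        "logodds": spline.grid_logodds,
        "or": spline.grid_or,
        "or_lo": spline.grid_or_ci[:, 0],
        "or_hi": spline.grid_or_ci[:, 1],
    })
    curve.insert(0, "predictor", name)
    return section, curve


def run_pipeline(
    config: RunConfig,
    subjects: list[SubjectImages] | None = None,
    cohort: pd.DataFrame | None = None,
) -> dict:
    """Execute the full analysis and write the run report.

    With no ``subjects`` a phantom cohort is simulated from the default
    :class:`PhantomSpec` at ``config.seed``. Returns the report dict
    (also written as ``report.json`` under ``config.out_dir`` together
    with the feature table, RCS curves, cross-validated predictions,
    Shapley table and the resolved config).
    """
    import warnings

    # small-cohort logistic fits legitimately brush against separation; the
    # resulting numerical overflow RuntimeWarnings are expected, not errors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return _run_pipeline_inner(config, subjects, cohort)


def _run_pipeline_inner(
    config: RunConfig,
    subjects: list[SubjectImages] | None,
    cohort: pd.DataFrame | None,
) -> dict:
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if subjects is None:
            subjects, cohort = make_cohort(
                PhantomSpec(), n=config.n_subjects, seed=config.seed)
        assert cohort is not None
        log.info("cohort of %d subjects ready (%.1fs)", len(subjects), time.time() - t0)

        stage = "preprocess"
        rows = []
        for subj in subjects:
            aimaps = preprocess_subject(subj, config)
            rows.append(extract_features(subj, aimaps, config))
            if config.write_volumes:
                save_subject(subj, out / "subjects")
        feats = pd.DataFrame(rows)
        table = cohort.merge(feats.drop(columns=["ez_side", "outcome", "sf"]),
                             on="subject_id")
        log.info("preprocessing done (%.1fs)", time.time() - t0)

        stage = "stats"
        y = table["sf"].to_numpy(dtype=float)
        covs = table[["seeg", "age_onset"]].copy()
        covs["ez_left"] = (table["ez_side"] == "left").astype(float)
        cov_arr = covs.to_numpy(dtype=float)

        group_comparisons = {}
        for modality in MODALITIES:
            col = f"ai_{modality}"
            a = table.loc[table.sf == 1, col].dropna().to_numpy()
            b = table.loc[table.sf == 0, col].dropna().to_numpy()
            group_comparisons[col] = {
                "t": stats.two_group_test(a, b, "t"),
                "mannwhitney": stats.two_group_test(a, b, "mannwhitney"),
                "mean_sf": float(np.mean(a)),
                "mean_nsf": float(np.mean(b)),
            }

        or_table = {}
        for col, scale in [("ai_pet", config.or_scale_ai),
                           ("ai_gm_density", config.or_scale_ai),
                           ("ai_flair", config.or_scale_ai),
                           ("age_onset", 1.0), ("true_coverage", 0.1)]:
            sub = table[[col, "sf"]].dropna()
            or_table[col] = stats.odds_ratio_report(
                sub[col].to_numpy(), sub["sf"].to_numpy(), scale=scale)

        rcs_sections = {}
        curves = []
        for modality in MODALITIES:
            col = f"ai_{modality}"
            sub = table[[col, "sf"]].dropna()
            sel = table[col].notna().to_numpy()
            section, curve = _rcs_section(
                sub[col].to_numpy(), sub["sf"].to_numpy(), cov_arr[sel], config, col)
            rcs_sections[col] = section
            curves.append(curve)

        stage = "ablative-rate"
        sub = table[["ablative_rate_hippo", "sf"]].dropna()
        n_missing = int(len(table) - len(sub))
        rate = sub["ablative_rate_hippo"].to_numpy()
        y_rate = sub["sf"].to_numpy(dtype=float)
        sel = table["ablative_rate_hippo"].notna().to_numpy()
        rate_section, rate_curve = _rcs_section(rate, y_rate, cov_arr[sel], config,
                                                "ablative_rate_hippo")
        curves.append(rate_curve)
        roc = stats.roc_youden(rate, y_rate)
        ablative = {
            "n_missing_rate": n_missing,
            "rcs": rate_section,
            "youden": {
                "threshold": roc.threshold,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "youden_j": roc.youden_j,
                "auc": roc.auc,
                "balanced_accuracy": roc.balanced_accuracy,
                "weighted_accuracy": roc.weighted_accuracy,
                "overall_accuracy": roc.overall_accuracy,
                "confusion": [roc.tp, roc.fp, roc.fn, roc.tn],
                "chi2": roc.chi2,
                "p": roc.p_value,
            },
        }
        ref = rate_section["reference_threshold"]
        if ref is not None:
            pred = rate >= ref
            t2 = np.array([[int(np.sum(pred & (y_rate == 1))), int(np.sum(~pred & (y_rate == 1)))],
                           [int(np.sum(pred & (y_rate == 0))), int(np.sum(~pred & (y_rate == 0)))]])
            if t2.sum(axis=1).min() > 0 and t2.sum(axis=0).min() > 0:
                chi2, p = stats.pearson_chi2(t2)
                ablative["rcs_threshold_test"] = {"threshold": ref, "chi2": chi2, "p": p}

        stage = "interpret"
        feat_cols = interpret.STRUCTURAL_FEATURES
        sub = table[feat_cols + ["ai_pet"]].dropna()
        X = sub[feat_cols]
        target = sub["ai_pet"].to_numpy()
        fit = interpret.fit_additive_model(X, target)
        shap = interpret.shapley_importance(X, target)
        cv = interpret.cross_validate(
            X, target, k=config.cv_k, iterations=config.cv_iterations,
            seed=config.seed)
        r, p = interpret.prediction_correlation(cv["actual"], cv["prediction"])
        grid = np.linspace(X["hippo_volume_ipsi"].min(), X["hippo_volume_ipsi"].max(), 50)
        pdep = interpret.partial_dependence(fit, X, "hippo_volume_ipsi", grid)
        interpretation = {
            "shapley_mean_signed": shap.mean_signed.to_dict(),
            "shapley_mean_abs": shap.mean_abs.to_dict(),
            "shapley_top_feature": shap.top_feature(),
            "shapley_baseline": shap.baseline,
            "cv_prediction_r": r,
            "cv_prediction_p": p,
            "n_used": int(len(sub)),
        }

        stage = "report"
        report = {
            "config_hash": config.hash(),
            "seed": config.seed,
            "pvc": "enabled" if config.pvc else "disabled",
            "cohort": {
                "n": int(len(table)),
                "n_sf": int(table["sf"].sum()),
                "sf_fraction": float(table["sf"].mean()),
            },
            "group_comparisons": group_comparisons,
            "odds_ratios": or_table,
            "rcs": rcs_sections,
            "ablative_rate": ablative,
            "interpretation": interpretation,
        }
        report = _jsonable(report)

        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        table.to_csv(out / "cohort_features.csv", index=False)
        pd.concat(curves, ignore_index=True).to_csv(out / "rcs_curves.csv", index=False)
        cv.to_csv(out / "cv_predictions.csv", index=False)
        shap.per_subject.to_csv(out / "shapley_values.csv", index=False)
        pdep.to_csv(out / "partial_dependence_hippo.csv", index=False)
        config.dump(out / "config.yaml")
        log.info("pipeline complete in %.1fs", time.time() - t0)
        return report
    except Exception as exc:
        log.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
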