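"""End-to-end orchestration: simulate -> extract -> delta -> model -> evaluate.

Each stage writes into its own content-addressed directory under the run
directory, keyed by a hash of exactly the configuration it depends on, so
rerunning with a changed rim width reuses the phantom cache but rebuilds
regions, features and models.  Every stage manifest embeds the stage hash,
package version and seed; identical config+seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import io as vio
from .deltas import NormalizationStats, apply_normalization, compute_delta, \
    fit_normalization
from .regions import extract_peritumoral_rim
from .response import cv_auc, evaluate_holdout, train_lda
from .shape import extract_shape_features
from .survival import RiskModel, compute_rrs, concordance_index, cox_fit, \
    fit_lasso_cox, km_logrank, stratify_by_cutoff
from .synthetic import CohortConfig, generate_cohort
from .texture import TextureConfig, extract_texture_features
from .utility import assess_calibration, build_nomogram, decision_curve, \
    horizon_outcomes

logger = logging.getLogger(__name__)

TEXTURE_FAMILIES = ("haralick_", "laws_", "gabor_")


@dataclass
class RunConfig:
    """One reproducible end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    rim_mm: float = 12.0
    fat_hu_max: float = -10.0
    texture: TextureConfig = field(default_factory=TextureConfig)
    train_fraction: float = 0.5
    n_folds: int = 100
    cv_criterion: str = "deviance"
    horizon_months: float = 36.0
    n_boot: int = 500
    calibration_groups: int = 10
    lda_iterations: int = 100
    lda_folds: int = 3
    seed: int = 0
    out_dir: str = "runs"

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["cohort"] = CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.get("cohort", {}).items()})
        tex = d.get("texture", {})
        for k in ("glcm_offsets", "gabor_wavelengths"):
            if k in tex:
                tex[k] = tuple(tuple(o) if isinstance(o, list) else o
                               for o in tex[k]) if k == "glcm_offsets" else tuple(tex[k])
        d["texture"] = TextureConfig(**tex)
        return cls(**d)

    @classmethod
    def demo(cls, out_dir: str = "runs", seed: int = 0) -> "RunConfig":
        """A 12-phantom configuration that completes end-to-end in minutes."""
        return cls(cohort=CohortConfig(n_patients=12, seed=seed, effect=1.5),
                   n_folds=10, n_boot=50, lda_iterations=100,
                   calibration_groups=3, seed=seed, out_dir=out_dir)


def _hash(*parts) -> str:
    blob = json.dumps(parts, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage_dir(run_dir, name, key) -> str:
    return os.path.join(run_dir, "stages", f"{name}_{key}")


def _complete(stage_dir) -> bool:
    return os.path.exists(os.path.join(stage_dir, "_manifest.json"))


def _finish(stage_dir, key, cfg: RunConfig, extra=None):
    manifest = {"stage_hash": key, "version": __version__, "seed": cfg.seed}
    if extra:
        manifest.update(extra)
    with open(os.path.join(stage_dir, "_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=float)


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def stage_simulate(cfg: RunConfig, run_dir) -> str:
    key = _hash("simulate", dataclasses.asdict(cfg.cohort))
    sdir = _stage_dir(run_dir, "simulate", key)
    if _complete(sdir):
        return sdir
    os.makedirs(sdir, exist_ok=True)
    cohort = generate_cohort(cfg.cohort)
    cohort.write(sdir)
    _finish(sdir, key, cfg)
    return sdir


def _extract_one(volume, mask, cfg: RunConfig) -> dict:
    pair = extract_peritumoral_rim(volume, mask, rim_mm=cfg.rim_mm,
                                   fat_hu_max=cfg.fat_hu_max)
    feats = extract_texture_features(volume, pair, cfg.texture)
    feats.update({f"shape_{k}": v
                  for k, v in extract_shape_features(mask).items()})
    feats["rim_excluded_voxels"] = pair.excluded_voxel_count
    return feats


def stage_extract(cfg: RunConfig, run_dir, sim_dir) -> str:
    key = _hash("extract", os.path.basename(sim_dir), cfg.rim_mm,
                cfg.fat_hu_max, cfg.texture.settings_hash())
    sdir = _stage_dir(run_dir, "extract", key)
    if _complete(sdir):
        return sdir
    os.makedirs(sdir, exist_ok=True)
    manifest = pd.read_csv(os.path.join(sim_dir, "manifest.csv"))
    for tp in ("pre", "post"):
        rows = []
        for _, rec in manifest.iterrows():
            vol = vio.read_volume(os.path.join(sim_dir, rec[f"{tp}_volume"]),
                                  timepoint=tp)
            mask = vio.read_mask(os.path.join(sim_dir, rec[f"{tp}_mask"]), vol)
            feats = _extract_one(vol, mask, cfg)
            feats["patient_id"] = rec["patient_id"]
            feats["timepoint"] = tp
            rows.append(feats)
        df = pd.DataFrame(rows)
        lead = ["patient_id", "timepoint"]
        df = df[lead + [c for c in df.columns if c not in lead]]
        vio.write_feature_table(df, os.path.join(sdir, f"features_{tp}.csv"))
    _finish(sdir, key, cfg)
    return sdir


def _split_ids(clinical: pd.DataFrame, train_fraction: float):
    """Deterministic head/tail split; training keeps at least 10 patients
    (the LASSO-Cox floor) whenever the cohort allows it."""
    ids = list(clinical["patient_id"])
    n = len(ids)
    n_train = int(round(n * train_fraction))
    n_train = max(n_train, min(10, n - 2))
    n_train = min(n_train, n - 2) if n > 4 else max(2, n_train)
    return ids[:n_train], ids[n_train:]


def stage_delta(cfg: RunConfig, run_dir, sim_dir, ext_dir) -> str:
    key = _hash("delta", os.path.basename(ext_dir), cfg.train_fraction)
    sdir = _stage_dir(run_dir, "delta", key)
    if _complete(sdir):
        return sdir
    os.makedirs(sdir, exist_ok=True)
    clinical = vio.read_clinical_table(os.path.join(sim_dir, "clinical.csv"))
    train_ids, _ = _split_ids(clinical, cfg.train_fraction)

    tables = {}
    for tp in ("pre", "post"):
        df = vio.read_feature_table(os.path.join(ext_dir, f"features_{tp}.csv"))
        tables[tp] = df.set_index("patient_id")
    feat_cols = [c for c in tables["pre"].columns
                 if c not in ("timepoint", "_settings_hash",
                              "rim_excluded_voxels")]
    pooled_train = pd.concat(
        [tables[tp].loc[train_ids, feat_cols] for tp in ("pre", "post")])
    stats = fit_normalization(pooled_train, provenance=key)
    stats.to_json(os.path.join(sdir, "normalization.json"))

    pre_n = apply_normalization(stats, tables["pre"][feat_cols],
                                keep_dropped=True)
    post_n = apply_normalization(stats, tables["post"][feat_cols],
                                 keep_dropped=True)
    deltas = compute_delta(pre_n, post_n)
    vol_change = (tables["post"]["shape_volume_ml"]
                  - tables["pre"]["shape_volume_ml"]).rename("volume_change_ml")
    out = pd.concat([deltas, vol_change], axis=1).reset_index()
    vio.write_feature_table(out, os.path.join(sdir, "deltas.csv"))
    _finish(sdir, key, cfg, {"n_train": len(train_ids)})
    return sdir


def stage_fit_survival(cfg: RunConfig, run_dir, sim_dir, delta_dir) -> str:
    key = _hash("fit_survival", os.path.basename(delta_dir), cfg.n_folds,
                cfg.cv_criterion, cfg.seed)
    sdir = _stage_dir(run_dir, "fit_survival", key)
    if _complete(sdir):
        return sdir
    os.makedirs(sdir, exist_ok=True)
    clinical = vio.read_clinical_table(os.path.join(sim_dir, "clinical.csv"))
    deltas = vio.read_feature_table(
        os.path.join(delta_dir, "deltas.csv")).set_index("patient_id")
    train_ids, val_ids = _split_ids(clinical, cfg.train_fraction)
    clin = clinical.set_index("patient_id")

    texture_cols = [c for c in deltas.columns
                    if c.startswith(TEXTURE_FAMILIES)]
    X_train = deltas.loc[train_ids, texture_cols]
    model = fit_lasso_cox(X_train, clin.loc[train_ids], n_folds=cfg.n_folds,
                          seed=cfg.seed, cv_criterion=cfg.cv_criterion)
    model.to_json(os.path.join(sdir, "risk_model.json"))

    report = {"n_texture_delta_features": len(texture_cols),
              "n_selected": len(model.features),
              "lambda": model.lambda_}
    rrs_all = compute_rrs(model, deltas[texture_cols])
    rrs_all.rename("rrs").reset_index().to_csv(
        os.path.join(sdir, "rrs.csv"), index=False, float_format="%.17g")
    for name, ids in (("train", train_ids), ("validation", val_ids)):
        if not ids:
            continue
        sub_clin = clin.loc[ids].reset_index()
        scores = rrs_all.loc[ids]
        entry = {}
        try:
            entry["c_index"] = concordance_index(scores.to_numpy(), sub_clin)
        except Exception as err:
            entry["c_index_error"] = str(err)
        groups = stratify_by_cutoff(scores.to_numpy(), model.rrs_cutoff)
        if len(np.unique(groups)) == 2:
            km = km_logrank(groups, sub_clin)
            entry.update(logrank_p=km.logrank_p,
                         logrank_statistic=km.logrank_statistic,
                         median_survival=km.median_survival)
        try:
            fit = cox_fit(pd.DataFrame({"rrs": scores.to_numpy()}), sub_clin)
            entry["rrs_hr"] = float(fit.summary["hr"].iloc[0])
            entry["rrs_p"] = float(fit.summary["p"].iloc[0])
        except Exception as err:
            entry["rrs_cox_error"] = str(err)
        report[name] = entry
    _write_json(report, os.path.join(sdir, "survival_report.json"))
    _finish(sdir, key, cfg)
    return sdir


def stage_utility(cfg: RunConfig, run_dir, sim_dir, fit_dir) -> str:
    key = _hash("utility", os.path.basename(fit_dir), cfg.horizon_months,
                cfg.n_boot, cfg.calibration_groups)
    sdir = _stage_dir(run_dir, "utility", key)
    if _complete(sdir):
        return sdir
    os.makedirs(sdir, exist_ok=True)
    clinical = vio.read_clinical_table(os.path.join(sim_dir, "clinical.csv"))
    rrs = pd.read_csv(os.path.join(fit_dir, "rrs.csv")).set_index("patient_id")
    train_ids, _ = _split_ids(clinical, cfg.train_fraction)
    clin = clinical.set_index("patient_id")
    train = clin.loc[train_ids].reset_index()
    if train["race"].dtype == object:
        train["race"] = (train["race"] != "white").astype(float)
    train_rrs = rrs.loc[train_ids, "rrs"]
    report = {}
    try:
        nomo = build_nomogram(train, train_rrs, horizon=cfg.horizon_months,
                              penalizer=0.1)
        nomo.points_table().to_csv(os.path.join(sdir, "nomogram_points.csv"),
                                   index=False, float_format="%.17g")
        data = train.copy()
        data["rrs"] = train_rrs.to_numpy()
        groups = min(cfg.calibration_groups, max(2, len(train) // 2))
        calib = assess_calibration(nomo, data, n_boot=cfg.n_boot,
                                   groups=groups, seed=cfg.seed)
        calib.curve.to_csv(os.path.join(sdir, "calibration.csv"), index=False,
                           float_format="%.17g")
        report["calibration"] = {
            "hl_statistic": calib.hl_statistic, "hl_p": calib.hl_p,
            "c_index_apparent": calib.c_index_apparent,
            "c_index_corrected": calib.c_index_corrected,
            "n_boot": len(calib.bootstrap_trace)}
        outcomes, evaluable = horizon_outcomes(train, cfg.horizon_months)
        pred = 1.0 - nomo.predict_survival(
            data.loc[evaluable].reset_index(drop=True))
        dca = decision_curve(pred, outcomes)
        dca.curve.to_csv(os.path.join(sdir, "dca.csv"), index=False,
                         float_format="%.17g")
        report["dca_prevalence"] = dca.prevalence
    except Exception as err:
        report["error"] = str(err)
        logger.warning("utility stage degraded: %s", err)
    _write_json(report, os.path.join(sdir, "utility_report.json"))
    _finish(sdir, key, cfg)
    return sdir


def stage_classify(cfg: RunConfig, run_dir, sim_dir, delta_dir, fit_dir) -> str:
    key = _hash("classify", os.path.basename(fit_dir), cfg.lda_iterations,
                cfg.lda_folds, cfg.seed)
    sdir = _stage_dir(run_dir, "classify", key)
    if _complete(sdir):
        return sdir
    os.makedirs(sdir, exist_ok=True)
    clinical = vio.read_clinical_table(os.path.join(sim_dir, "clinical.csv"))
    deltas = vio.read_feature_table(
        os.path.join(delta_dir, "deltas.csv")).set_index("patient_id")
    model = RiskModel.from_json(os.path.join(fit_dir, "risk_model.json"))
    train_ids, val_ids = _split_ids(clinical, cfg.train_fraction)
    clin = clinical.set_index("patient_id")
    report = {}
    if not model.features:
        report["skipped"] = "no features selected by LASSO"
    else:
        X = deltas[model.features]
        y = clin["response"]
        try:
            lda = train_lda(X.loc[train_ids], y.loc[train_ids])
            cv = cv_auc(X.loc[train_ids], y.loc[train_ids],
                        folds=cfg.lda_folds, iterations=cfg.lda_iterations,
                        seed=cfg.seed)
            pd.DataFrame({"iteration": range(len(cv["trace"])),
                          "auc": cv["trace"]}).to_csv(
                os.path.join(sdir, "cv_auc_trace.csv"), index=False,
                float_format="%.17g")
            report["train"] = {"mean_cv_auc": cv["mean_auc"], "ci": cv["ci"]}
            if val_ids:
                rep = evaluate_holdout(lda, X.loc[val_ids], y.loc[val_ids])
                report["validation"] = {
                    "auc": rep.auc, "auc_ci": rep.auc_ci,
                    "accuracy": rep.accuracy, "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "threshold": rep.threshold}
        except Exception as err:
            report["error"] = str(err)
            logger.warning("classify stage degraded: %s", err)
    _write_json(report, os.path.join(sdir, "classifier_report.json"))
    _finish(sdir, key, cfg)
    return sdir


STAGES = ("simulate", "extract", "delta", "fit-survival", "utility", "classify")


def run_pipeline(cfg: RunConfig, stages=STAGES) -> str:
    """Execute the requested stages in order; returns the run directory."""
    run_dir = os.path.join(cfg.out_dir, f"run_{_hash(dataclasses.asdict(cfg))}")
    os.makedirs(run_dir, exist_ok=True)
    cfg.to_json(os.path.join(run_dir, "run_config.json"))
    dirs = {}
    # core stages run up to the furthest one requested; utility/classify are
    # optional leaves off fit-survival
    core = ("simulate", "extract", "delta", "fit-survival")
    want_leaf = {"utility", "classify"} & set(stages)
    depth = max([core.index(s) for s in stages if s in core]
                + ([3] if want_leaf else [0]))
    try:
        dirs["simulate"] = stage_simulate(cfg, run_dir)
        if depth >= 1:
            dirs["extract"] = stage_extract(cfg, run_dir, dirs["simulate"])
        if depth >= 2:
            dirs["delta"] = stage_delta(cfg, run_dir, dirs["simulate"],
                                        dirs["extract"])
        if depth >= 3:
            dirs["fit-survival"] = stage_fit_survival(cfg, run_dir,
                                                      dirs["simulate"],
                                                      dirs["delta"])
        if "utility" in want_leaf:
            dirs["utility"] = stage_utility(cfg, run_dir, dirs["simulate"],
                                            dirs["fit-survival"])
        if "classify" in want_leaf:
            dirs["classify"] = stage_classify(cfg, run_dir, dirs["simulate"],
                                              dirs["delta"],
                                              dirs["fit-survival"])
    except StageError:
        raise
    except Exception as err:
        done = [s for s in STAGES if s in dirs]
        pending = [s for s in stages if s not in dirs]
        stage = pending[0] if pending else "unknown"
        raise StageError(stage, err) from err
    _write_json({s: os.path.basename(d) for s, d in dirs.items()},
                os.path.join(run_dir, "stage_index.json"))
    return run_dir
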