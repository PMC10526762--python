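"""End-to-end orchestration: simulate -> extract -> classify-rep -> survival.

Each stage writes its artifacts under ``config.out_dir`` together with a
machine-readable run log (seed, package version, config hash); stages are
idempotent and resume from the feature CSV. Running a stage whose inputs
are missing raises a stale-input error instead of silently recomputing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import balanced_cv_evaluate, metrics_to_frame, two_step_select
from .config import RunConfig, config_hash
from .copula import ClaytonCopula
from .io import load_manifest, load_study
from .survival import (
    cg_estimator,
    copula_feature_selection,
    permutation_test,
    prognostic_index,
    rep_group_crosstab,
    select_alpha,
    split_by_pi,
    standardize,
    vertical_distance,
)
from .synthetic import (
    CopulaSurvivalTruth,
    gen_copula_survival,
    gen_phantom_study,
    write_phantom,
)
from .texture import extract_all_features

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "StaleInputError"]

STAGES = ("simulate", "extract", "classify-rep", "survival")


class StaleInputError(RuntimeError):
    """An upstream artifact required by this stage is missing or partial."""


def _write_run_log(out: Path, cfg: RunConfig, stage: str) -> None:
    entry = {"stage": stage, "seed": cfg.seed, "version": __version__,
             "config_hash": config_hash(cfg)}
    log_path = out / "run_log.json"
    history = json.loads(log_path.read_text()) if log_path.exists() else []
    history.append(entry)
    log_path.write_text(json.dumps(history, indent=1))
    cfg.to_yaml(out / "config.yaml")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StaleInputError(f"missing {path.name}; run the '{producer}' stage first")
    return path


def run_pipeline(config: RunConfig, stage: str) -> dict:
    """Run one pipeline stage; returns a dict of artifact paths."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    if stage == "simulate":
        sim = config.simulate
        rng = np.random.default_rng(config.seed)
        rows = []
        for i in range(sim.n_subjects):
            is_rep = i < sim.n_rep
            # REP-like phantoms get an enlarged, rougher necrotic core
            nec = (9.0, 7.5, 6.0) if is_rep else (6.0, 5.0, 4.0)
            study = gen_phantom_study(
                semi_axes={"edema": (20.0, 17.0, 15.0), "enhancing": (13.0, 11.0, 9.0),
                           "necrosis": nec},
                region_hurst={"edema": 0.6, "enhancing": 0.4 if is_rep else 0.7,
                              "necrosis": 0.5},
                noise_sd=sim.noise_sd, texture_sd=sim.texture_sd,
                seed=int(rng.integers(2 ** 31)), size=sim.volume_size,
            )
            row = write_phantom(study, out / "phantoms", f"S{i:04d}")
            row["rep_label"] = int(is_rep)
            rows.append(row)
        manifest = pd.DataFrame(rows)
        truth = CopulaSurvivalTruth(beta=sim.beta, gamma=sim.gamma, alpha=sim.alpha,
                                    baseline_death=tuple(sim.baseline_death),
                                    baseline_censor=tuple(sim.baseline_censor),
                                    n=sim.n_subjects, seed=config.seed)
        surv = gen_copula_survival(truth)
        clin = surv.to_frame()
        clin["subject_id"] = manifest["subject_id"].to_numpy()
        clin["rep_label"] = manifest["rep_label"].to_numpy()
        clin_path = out / "clinical.csv"
        clin.to_csv(clin_path, index=False)
        manifest = manifest.merge(clin[["subject_id", "time_days", "event", "rep_label"]],
                                  on="subject_id", suffixes=("", "_y"))
        man_path = out / "manifest.csv"
        manifest.drop(columns=[c for c in manifest.columns if c.endswith("_y")]) \
                .to_csv(man_path, index=False)
        artifacts.update(manifest=str(man_path), clinical=str(clin_path))

    elif stage == "extract":
        man_path = _require(out / "manifest.csv", "simulate")
        manifest = load_manifest(man_path)
        rows = []
        for _, row in manifest.iterrows():
            study = load_study(row)
            rows.append(extract_all_features(study, config.features))
        features = pd.DataFrame(rows)
        features.insert(0, "subject_id", manifest["subject_id"].to_numpy())
        feat_path = out / "features.csv"
        features.to_csv(feat_path, index=False)
        artifacts["features"] = str(feat_path)

    elif stage == "classify-rep":
        feat_path = _require(out / "features.csv", "extract")
        man_path = _require(out / "manifest.csv", "simulate")
        features = pd.read_csv(feat_path).set_index("subject_id")
        manifest = pd.read_csv(man_path).set_index("subject_id")
        labels = manifest.loc[features.index, "rep_label"].to_numpy(int)
        usable = features.columns[features.notna().any()]
        selected = two_step_select(features[usable], labels, k_final=config.cv.k_final,
                                   n_iterations=config.cv.screen_iterations,
                                   seed=config.seed)
        dists = balanced_cv_evaluate(features, labels, features=selected,
                                     iterations=config.cv.iterations,
                                     folds=config.cv.folds, seed=config.seed,
                                     learner_params=config.cv.learner_params)
        met_path = out / "rep_metrics.csv"
        metrics_to_frame(dists).to_csv(met_path, index=False)
        sel_path = out / "rep_selected.json"
        sel_path.write_text(json.dumps({
            "features": selected.names,
            "p_values": {k: float(v) for k, v in selected.p_values.items()},
            "summary": {m: [d.mean, d.sd] for m, d in dists.items()},
        }, indent=1))
        artifacts.update(metrics=str(met_path), selected=str(sel_path))

    elif stage == "survival":
        feat_path = _require(out / "features.csv", "extract")
        clin_path = _require(out / "clinical.csv", "simulate")
        features = pd.read_csv(feat_path).set_index("subject_id")
        clin = pd.read_csv(clin_path).set_index("subject_id").loc[features.index]
        time = clin["time_days"].to_numpy(float)
        event = clin["event"].to_numpy(int)
        usable = features.columns[features.notna().any() & (features.std(ddof=0) > 0)]
        table = features[usable].fillna(features[usable].median())

        cop_cfg = config.copula
        from .classify import per_feature_f1

        f1 = per_feature_f1(table, event, n_iterations=cop_cfg.f1_iterations,
                            seed=config.seed)
        survivors = list(f1.index[f1 > cop_cfg.f1_threshold]) or list(usable[:5])
        alpha, cindex = select_alpha(time, event, table[survivors],
                                     alpha_grid=cop_cfg.alpha_grid,
                                     folds=cop_cfg.folds, seed=config.seed)
        copula = ClaytonCopula(alpha)
        fits = copula_feature_selection(table, time, event, copula,
                                        f1_threshold=cop_cfg.f1_threshold,
                                        p_threshold=cop_cfg.p_threshold,
                                        seed=config.seed, f1_scores=f1)
        fits_df = pd.DataFrame([{"feature": f.feature, "beta": f.beta, "se": f.se,
                                 "p_value": f.p_value} for f in fits])
        fits_path = out / "survival_fits.csv"
        fits_df.to_csv(fits_path, index=False)

        report: dict = {"alpha": alpha, "c_index": cindex.to_dict("records")}
        if fits:
            top = fits[: max(cop_cfg.top_k, 1)]
            coef = {f.feature: f.beta for f in top}
            z = standardize(table)
            pi = prognostic_index(coef, z)
            groups = split_by_pi(pi)
            curves = []
            for g in ("good", "bad"):
                m = groups == g
                c = cg_estimator(time[m], event[m], copula, group=g)
                curves.append(pd.DataFrame({"group": g, "time": c.times, "S": c.surv}))
            pd.concat(curves).to_csv(out / "survival_curves.csv", index=False)
            perm = permutation_test(time, event, groups, copula,
                                    n_perm=cop_cfg.n_perm, seed=config.seed)
            report.update(D=perm["D"], p_value=perm["p_value"],
                          groups={g: int((groups == g).sum()) for g in ("good", "bad")})
            if "rep_label" in clin.columns:
                ct = rep_group_crosstab(groups, clin["rep_label"].to_numpy(int))
                report["rep_crosstab"] = ct["counts"].to_dict()
                report["rep_in_bad_percent"] = ct["rep_in_bad_percent"]
        else:
            log.warning("survival stage: no significant features; report limited")
        rep_path = out / "survival_report.json"
        rep_path.write_text(json.dumps(report, indent=1, default=str))
        artifacts.update(fits=str(fits_path), report=str(rep_path))

    _write_run_log(out, config, stage)
    return artifacts
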