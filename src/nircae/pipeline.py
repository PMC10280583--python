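"""End-to-end benchmark: preprocessing x PLSR/PCR grid vs CAE latents + MLR.

For one dataset the experiment is:

1. seeded random split into calibration and prediction sets;
2. baselines — for each preprocessing operator (original, MSC, SNV, SG,
   MC; all fitted on calibration only) and each family (PLSR, PCR), pick
   the component count in 1..k_max by seeded 5-fold cross-validated RMSE
   on the calibration set, refit, and score both sets;
3. proposed method — train the convolutional autoencoder once on the raw
   calibration spectra (unsupervised, no chemometric preprocessing),
   encode both sets, and fit one MLR per target on the same latent matrix;
4. assemble an evaluation report: per target, one row per
   (preprocessing, family) pair plus one CAE+MLR row, with R2 and RMSE on
   calibration and prediction sets, and a reconstruction-RMSPE summary.

Every random decision draws from a named seed in the config, so reruns
are byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cae import CAEConfig, ConvolutionalAutoencoder
from .dataset import SpectraSet, random_split, write_spectra
from .metrics import evaluate_predictions, format_report, rmspe_summary
from .preprocess import LABELS, make_preprocessor
from .regression import FAMILIES, LatentMLR, select_components_cv

DEFAULT_PREPROCESSING = ("none", "msc", "snv", "savgol", "mean_center")


@dataclass
class ExperimentConfig:
    """Seeds, grids and toggles for one benchmark run."""

    n_calibration: int = 60
    preprocessing: tuple[str, ...] = DEFAULT_PREPROCESSING
    families: tuple[str, ...] = ("plsr", "pcr")
    k_max: int = 10
    folds: int = 5
    cae: CAEConfig = field(default_factory=CAEConfig)
    run_cae: bool = True
    targets: tuple[str, ...] | None = None  # None = all targets in the data
    split_seed: int = 0
    cv_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "cae" in d:
            d["cae"] = CAEConfig.from_dict(d["cae"])
        for key in ("preprocessing", "families", "targets"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ExperimentResult:
    report: pd.DataFrame
    rmspe: pd.DataFrame | None
    split: object
    cae_model: ConvolutionalAutoencoder | None
    latents_cal: np.ndarray | None
    latents_pred: np.ndarray | None
    log: list[dict]


def run_experiment(data: SpectraSet, config: ExperimentConfig | None = None
                   ) -> ExperimentResult:
    """Run the full benchmark on one dataset; see the module docstring."""
    config = config or ExperimentConfig()
    if data.targets is None:
        raise ValueError("dataset has no targets")
    targets = list(config.targets or data.target_names)
    log: list[dict] = []

    def _log(stage, **info):
        log.append({"stage": stage, **info})

    t0 = time.perf_counter()
    split = random_split(data, config.n_calibration, config.split_seed)
    cal = data.subset(split.calibration_ids)
    pred = data.subset(split.prediction_ids)
    _log("split", seed=config.split_seed, n_calibration=cal.n_samples,
         n_prediction=pred.n_samples)

    rows = []
    # baselines: preprocessing x family grid, CV component selection
    for prep_name in config.preprocessing:
        op = make_preprocessor(prep_name)
        Xc = op.fit_transform(cal.absorbance)  # fitted on calibration only
        Xp = op.transform(pred.absorbance)
        _log("preprocess", operator=prep_name, fit_on="calibration",
             split_seed=split.seed)
        for family in config.families:
            for target in targets:
                yc = cal.targets[target].to_numpy(dtype=float)
                yp = pred.targets[target].to_numpy(dtype=float)
                cv = select_components_cv(
                    Xc, yc, family, k_max=config.k_max,
                    folds=config.folds, seed=config.cv_seed)
                model = FAMILIES[family](n_components=cv.selected).fit(Xc, yc)
                scores = evaluate_predictions(
                    yc, model.predict(Xc), yp, model.predict(Xp))
                rows.append({
                    "target": target,
                    "method": family.upper(),
                    "preprocessing": LABELS[prep_name],
                    "n_components": cv.selected,
                    **scores,
                })
                _log("baseline_fit", family=family, preprocessing=prep_name,
                     target=target, n_components=cv.selected,
                     fit_on="calibration")

    # proposed method: one unsupervised CAE, reused across all targets
    cae_model = latents_cal = latents_pred = None
    rmspe_frame = None
    if config.run_cae:
        cae_model = ConvolutionalAutoencoder(**config.cae.to_dict())
        cae_model.fit(cal.absorbance)
        latents_cal = cae_model.transform(cal.absorbance)
        latents_pred = cae_model.transform(pred.absorbance)
        _log("cae_fit", seed=config.cae.seed, fit_on="calibration",
             epochs=len(cae_model.training_log_),
             stopped_early=cae_model.stopped_early_)
        rmspe_frame = pd.DataFrame({
            "calibration": rmspe_summary(
                cal.absorbance, cae_model.reconstruct(cal.absorbance)),
            "prediction": rmspe_summary(
                pred.absorbance, cae_model.reconstruct(pred.absorbance)),
        }).T[["min", "max", "mean", "std"]]
        for target in targets:
            yc = cal.targets[target].to_numpy(dtype=float)
            yp = pred.targets[target].to_numpy(dtype=float)
            mlr = LatentMLR().fit(latents_cal, yc)
            scores = evaluate_predictions(
                yc, mlr.predict(latents_cal), yp, mlr.predict(latents_pred))
            rows.append({
                "target": target,
                "method": "CAE+MLR",
                "preprocessing": "-",
                "n_components": config.cae.latent_dim,
                **scores,
            })
            _log("mlr_fit", target=target, fit_on="calibration")

    report = pd.DataFrame(rows).sort_values(
        ["target", "method", "preprocessing"], kind="stable"
    ).reset_index(drop=True)
    _log("done", elapsed_s=round(time.perf_counter() - t0, 3))
    return ExperimentResult(report=report, rmspe=rmspe_frame, split=split,
                            cae_model=cae_model, latents_cal=latents_cal,
                            latents_pred=latents_pred, log=log)


def render_tables(report: pd.DataFrame) -> dict[str, str]:
    """Per-target markdown tables with best-in-column flags.

    The highest prediction R2 and the lowest prediction RMSE in each
    target block are marked in bold; exact ties are all marked. An
    improvement summary (percent change of the proposed method's
    prediction R2 over each baseline family's best row) is appended under
    the key ``"improvement"``.
    """
    if report.empty:
        raise ValueError("empty report")
    rounded = format_report(report)
    tables: dict[str, str] = {}
    improvements = []
    for target, block in rounded.groupby("target", sort=False):
        block = block.copy()
        best_r2 = block["r2_pred"].max()
        best_rmse = block["rmse_pred"].min()
        block["R2_pred"] = [
            f"**{v}**" if v == best_r2 else str(v) for v in block["r2_pred"]]
        block["RMSE_pred"] = [
            f"**{v}**" if v == best_rmse else str(v)
            for v in block["rmse_pred"]]
        cols = ["method", "preprocessing", "n_components",
                "r2_cal", "rmse_cal", "R2_pred", "RMSE_pred"]
        tables[target] = block[cols].to_markdown(index=False)
        cae_rows = block[block["method"] == "CAE+MLR"]
        if not cae_rows.empty:
            cae_r2 = float(cae_rows["r2_pred"].iloc[0])
            for fam in block.loc[block["method"] != "CAE+MLR", "method"].unique():
                ref = float(block.loc[block["method"] == fam, "r2_pred"].max())
                if ref != 0:
                    improvements.append({
                        "target": target,
                        "reference": fam,
                        "r2_improvement_pct":
                            round((cae_r2 - ref) / abs(ref) * 100.0, 2),
                    })
    if improvements:
        tables["improvement"] = pd.DataFrame(improvements).to_markdown(
            index=False)
    return tables


def save_artifacts(result: ExperimentResult, data: SpectraSet,
                   out_dir) -> None:
    """Persist split, report, RMSPE summary, tables, latents, model, log."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    result.split.to_json(os.path.join(out_dir, "split.json"))
    format_report(result.report).to_csv(
        os.path.join(out_dir, "report.csv"), index=False)
    if result.rmspe is not None:
        result.rmspe.round(2).to_csv(os.path.join(out_dir, "rmspe_summary.csv"))
    tdir = os.path.join(out_dir, "tables")
    os.makedirs(tdir, exist_ok=True)
    for name, text in render_tables(result.report).items():
        with open(os.path.join(tdir, f"{name}.md"), "w") as fh:
            fh.write(text + "\n")
    if result.cae_model is not None:
        result.cae_model.save(os.path.join(out_dir, "model"))
        lat = pd.DataFrame(
            np.vstack([result.latents_cal, result.latents_pred]),
            index=result.split.calibration_ids + result.split.prediction_ids)
        lat.to_csv(os.path.join(out_dir, "latents.csv"))
    with open(os.path.join(out_dir, "log.jsonl"), "w") as fh:
        for entry in result.log:
            fh.write(json.dumps(entry) + "\n")
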