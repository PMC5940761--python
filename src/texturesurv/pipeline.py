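"""End-to-end pipeline: simulate -> extract -> cutpoints -> survive -> report.

Each stage writes plain CSV artifacts into the run directory so any stage can
be re-run or inspected in isolation; a single global seed fans out to
per-stage seeds by fixed offsets.  The report tables follow the layout of a
typical CT-texture survival study:

* ``table1.csv`` — baseline group comparisons (recurrence vs non-recurrence);
* ``features.csv`` — per-patient texture features, one column per
  feature x filter scale;
* ``cutoffs.csv`` — ROC AUC, optimal cutoff, direction, sensitivity /
  specificity (and LOOCV modal cutoff) per feature;
* ``table3.csv`` — Kaplan-Meier restricted mean survival, 95% CI and
  log-rank p per dichotomized variable (full-data and LOOCV assignments);
* ``table4.csv`` — per-filter forward-stepwise Cox models (HR, CI, p);
* ``km_curves.csv`` — step-function data for survival plots.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coxph import CoxResult, feature_column, per_filter_cox
from .cutpoint import CutoffResult, dichotomize, loocv_cutoff, youden_cutoff
from .lesion import LesionImage, write_lesion_png
from .survival import km_fit, logrank, mann_whitney, two_by_two_test
from .synthetic import SyntheticConfig, generate_cohort, records_to_frame
from .texture import ALLOWED_SIGMAS, FEATURE_NAMES, extract_features

#: Fixed per-stage seed offsets fanned out from the global seed.
_STAGE_SEED_OFFSETS = {"simulate": 101, "extract": 202, "cutpoints": 303, "survive": 404}


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    outdir: str = "run_output"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    sigmas: tuple[float, ...] = ALLOWED_SIGMAS
    filter_mode: str = "band-plus-dc"
    quantization: str = "raw-integer"
    n_bins: int = 32
    loocv: bool = True
    ties: str = "breslow"
    entry_p: float = 0.05
    screen: str = "logrank"
    write_images: bool = True

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, default=list) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        syn = payload.pop("synthetic", {})
        for key in ("sd_hu_range", "image_shape", "roi_pixel_range", "censoring_time_range"):
            if key in syn:
                syn[key] = tuple(syn[key])
        cfg = cls(**{k: (tuple(v) if k == "sigmas" else v) for k, v in payload.items()},
                  synthetic=SyntheticConfig(**syn))
        return cfg


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    clinical: pd.DataFrame
    features: pd.DataFrame
    cutoffs: pd.DataFrame
    cutoff_objects: dict[str, CutoffResult]
    table1: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    cox_results: dict[float, CoxResult]
    outdir: Path


def _stage_seed(config: RunConfig, stage: str) -> int:
    return (config.seed + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def simulate_stage(config: RunConfig, outdir: Path) -> tuple[list[LesionImage], pd.DataFrame]:
    syn = dataclasses.replace(config.synthetic, seed=_stage_seed(config, "simulate"))
    lesions, records = generate_cohort(syn)
    clinical = records_to_frame(records)
    clinical.to_csv(outdir / "cohort.csv", index=False)
    if config.write_images:
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        for rec, lesion in zip(records, lesions):
            write_lesion_png(lesion, img_dir / f"{rec.patient_id}.png",
                             img_dir / f"{rec.patient_id}_mask.png")
    return lesions, clinical


def extract_stage(config: RunConfig, lesions: list[LesionImage],
                  clinical: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    rows = []
    for pid, lesion in zip(clinical["patient_id"], lesions):
        fv = extract_features(lesion, sigmas=config.sigmas, mode=config.filter_mode,
                              quantization=config.quantization, n_bins=config.n_bins)
        row: dict[str, float | str] = {"patient_id": pid}
        for sigma, vec in fv.items():
            for name, value in vec.as_dict().items():
                row[feature_column(name, sigma)] = value
        rows.append(row)
    features = pd.DataFrame(rows)
    features.to_csv(outdir / "features.csv", index=False)
    return features


def cutpoint_stage(config: RunConfig, features: pd.DataFrame, clinical: pd.DataFrame,
                   outdir: Path) -> tuple[pd.DataFrame, dict[str, CutoffResult], dict]:
    labels = clinical["recurrence"].to_numpy(dtype=bool)
    rows, objects, loocv_objects = [], {}, {}
    for sigma in config.sigmas:
        for name in FEATURE_NAMES:
            col = feature_column(name, sigma)
            if col not in features.columns:
                continue
            vals = features[col].to_numpy(dtype=float)
            cut = youden_cutoff(vals, labels, feature_id=col)
            row = {
                "feature_id": col, "feature": name, "sigma": sigma,
                "auc": cut.auc, "cutoff": cut.cutoff, "direction": cut.direction,
                "sensitivity": cut.sensitivity, "specificity": cut.specificity,
                "degenerate": cut.degenerate,
            }
            if config.loocv:
                lo = loocv_cutoff(vals, labels, feature_id=col)
                loocv_objects[col] = lo
                row["modal_cutoff"] = lo.modal_cutoff
                row["modal_direction"] = lo.modal_direction
            rows.append(row)
            objects[col] = cut
    cutoffs = pd.DataFrame(rows)
    cutoffs.to_csv(outdir / "cutoffs.csv", index=False)
    return cutoffs, objects, loocv_objects


def _table1(clinical: pd.DataFrame) -> pd.DataFrame:
    recur = clinical["recurrence"].to_numpy(dtype=bool)
    rows = []

    def cat_row(label: str, flag: np.ndarray) -> None:
        table = np.array([
            [int((flag & recur).sum()), int((flag & ~recur).sum())],
            [int((~flag & recur).sum()), int((~flag & ~recur).sum())],
        ])
        try:
            p = two_by_two_test(table, method="fisher")
        except ValueError:
            p = float("nan")
        rows.append({"characteristic": label,
                     "recurrence_group": int((flag & recur).sum()),
                     "non_recurrence_group": int((flag & ~recur).sum()),
                     "p_value": p})

    cat_row("sex = male", (clinical["sex"] == "male").to_numpy())
    cat_row("tumor size >= 2.5 cm", (clinical["size_class"] == ">=2.5 cm").to_numpy())
    cat_row("lymph node metastasis", (clinical["nodal_status"] == "positive").to_numpy())
    cat_row("poor differentiation", (clinical["differentiation"] == "poor").to_numpy())
    cat_row("R1 resection", (clinical["resection"] == "R1").to_numpy())
    age = clinical["age"].to_numpy(dtype=float)
    _, p_age = mann_whitney(age[recur], age[~recur])
    rows.append({"characteristic": "age (years)",
                 "recurrence_group": float(np.round(age[recur].mean(), 2)),
                 "non_recurrence_group": float(np.round(age[~recur].mean(), 2)),
                 "p_value": p_age})
    return pd.DataFrame(rows)


def survive_stage(config: RunConfig, features: pd.DataFrame, clinical: pd.DataFrame,
                  cutoff_objects: dict[str, CutoffResult], loocv_objects: dict,
                  outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                         dict[float, CoxResult]]:
    times = clinical["dfs_months"].to_numpy(dtype=float)
    events = clinical["event"].to_numpy(dtype=bool)

    table1 = _table1(clinical)
    table1.to_csv(outdir / "table1.csv", index=False)

    # Table-3-style KM rows: nodal status plus every dichotomized feature.
    rows = []
    curves = []

    def km_rows(label_high: str, label_low: str, high: np.ndarray,
                loocv_high: np.ndarray | None, group_name: str) -> None:
        if high.all() or not high.any():
            return
        try:
            p = logrank(times, events, high).p_value
        except ValueError:
            p = float("nan")
        p_loocv = float("nan")
        if loocv_high is not None and loocv_high.any() and not loocv_high.all():
            try:
                p_loocv = logrank(times, events, loocv_high).p_value
            except ValueError:
                pass
        for label, sel in ((label_high, high), (label_low, ~high)):
            fit = km_fit(times[sel], events[sel])
            rows.append({
                "variable": group_name, "group": label, "n": int(sel.sum()),
                "mean_months": fit.mean_survival,
                "ci_low": fit.mean_ci[0], "ci_high": fit.mean_ci[1],
                "logrank_p": p, "loocv_logrank_p": p_loocv,
            })
            for t, s in zip(fit.timeline, fit.survival):
                curves.append({"variable": group_name, "group": label,
                               "time_months": float(t), "survival": float(s)})

    nodal = (clinical["nodal_status"] == "positive").to_numpy()
    km_rows("pN+", "pN-", nodal, None, "nodal status")
    for col, cut in cutoff_objects.items():
        vals = features[col].to_numpy(dtype=float)
        high = dichotomize(vals, cut.cutoff, cut.direction)
        op = "<=" if cut.direction == "le" else ">"
        inv = ">" if cut.direction == "le" else "<="
        lo = loocv_objects.get(col)
        loocv_high = lo.fold_assignments if lo is not None else None
        km_rows(f"{col} {op} {cut.cutoff:.6f}", f"{col} {inv} {cut.cutoff:.6f}",
                high, loocv_high, col)

    table3 = pd.DataFrame(rows)
    table3.to_csv(outdir / "table3.csv", index=False)
    pd.DataFrame(curves).to_csv(outdir / "km_curves.csv", index=False)

    cox_results = per_filter_cox(features, clinical, cutoff_objects,
                                 sigmas=config.sigmas, entry_p=config.entry_p,
                                 ties=config.ties, screen=config.screen)
    t4_rows = []
    for sigma, res in cox_results.items():
        if not res.selected_variables:
            t4_rows.append({"sigma": sigma, "variable": "(no variable entered)",
                            "hr": float("nan"), "ci_low": float("nan"),
                            "ci_high": float("nan"), "p_value": float("nan")})
        for name in res.selected_variables:
            t4_rows.append({"sigma": sigma, "variable": name, "hr": res.hr[name],
                            "ci_low": res.hr_ci[name][0], "ci_high": res.hr_ci[name][1],
                            "p_value": res.p_value[name]})
    table4 = pd.DataFrame(t4_rows)
    table4.to_csv(outdir / "table4.csv", index=False)
    return table1, table3, table4, cox_results


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write all artifacts under ``config.outdir``.

    Re-running with an identical config reproduces byte-identical CSVs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "run_config.json")
    log_lines = [f"texturesurv pipeline, seed = {config.seed}"]
    for pkg in ("numpy", "scipy", "pandas", "lifelines", "skimage"):
        mod = __import__(pkg)
        log_lines.append(f"{pkg} {getattr(mod, '__version__', '?')}")

    stage = "simulate"
    try:
        lesions, clinical = simulate_stage(config, outdir)
        log_lines.append(f"simulate: n = {len(lesions)}, "
                         f"events = {int(clinical['event'].sum())}")
        stage = "extract"
        features = extract_stage(config, lesions, clinical, outdir)
        log_lines.append(f"extract: {features.shape[1] - 1} feature columns")
        stage = "cutpoints"
        cutoffs, cut_objects, loocv_objects = cutpoint_stage(config, features,
                                                             clinical, outdir)
        log_lines.append(f"cutpoints: {len(cut_objects)} cutoffs")
        stage = "survive"
        table1, table3, table4, cox_results = survive_stage(
            config, features, clinical, cut_objects, loocv_objects, outdir)
        log_lines.append("survive: done")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        config=config, clinical=clinical, features=features, cutoffs=cutoffs,
        cutoff_objects=cut_objects, table1=table1, table3=table3, table4=table4,
        cox_results=cox_results, outdir=outdir,
    )


def render_reports(result: PipelineResult) -> str:
    """Render the run's tables as a single markdown report (also written to disk)."""
    lines = ["# Texture-survival pipeline report", ""]
    lines += ["## Baseline characteristics (recurrence vs non-recurrence)", "",
              result.table1.round(4).to_markdown(index=False), ""]
    lines += ["## Feature cutoffs (ROC / Youden)", "",
              result.cutoffs.round(6).to_markdown(index=False), ""]
    lines += ["## Kaplan-Meier disease-free survival", "",
              result.table3.round(4).to_markdown(index=False), ""]
    lines += ["## Per-filter stepwise Cox models", ""]
    t4 = result.table4.copy()
    for col in ("hr", "ci_low", "ci_high"):
        t4[col] = t4[col].round(2)
    t4["p_value"] = t4["p_value"].round(4)
    lines += [t4.to_markdown(index=False), ""]
    report = "\n".join(lines)
    (result.outdir / "report.md").write_text(report)
    return report
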