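"""End-to-end experiment orchestration.

``run_all`` wires the stages together: synthesize (or load) a cohort,
audit feature interdependencies, run the cumulative-feature experiment
plus one combined experiment per differential bin width (2, 4, 6, 8 Gy),
and compare every combined model set against the cumulative-only baseline
on shared outer splits. Outputs land in a fixed layout under the chosen
directory (features/, correlations/, models/, reports/) together with a
manifest recording the config, seeds and a checksum of every file, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import group_dependency_summary, plot_heatmap, spearman_matrix
from .dvh import BinSchedule, cdvh_feature_names
from .prediction import (ExperimentConfig, ExperimentResult, compare_models,
                         run_experiment, selection_frequency,
                         top_coefficient_frequency)
from .synthesis import CohortSpec, load_cohort, make_cohort, save_cohort

log = logging.getLogger("dvhlasso")

__all__ = ["DEFAULT_CONFIG", "load_config", "run_all", "validate_inputs",
           "RunManifest", "experiment_names"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "csv": None,  # path to an existing feature CSV; None -> synthesize
        "n_patients": 153,
        "target_prevalence": 0.268,
        "true_model": {"dV37-41Gy": 0.7, "dV41-45Gy": 0.7, "cV60Gy": 0.5},
    },
    "experiment": {
        "n_iterations": 6,
        "splits_per_iteration": 5,
        "test_fraction": 0.3,
        "inner_folds": 5,
        "n_lambda": 100,
        "lambda_min_ratio": 1e-3,
        "outer_scheme": "shuffle",
    },
    "bin_widths": [2, 4, 6, 8],
    "plots": False,
}


def load_config(path=None) -> dict:
    """Merge a YAML/JSON config file over the defaults (shallow per section)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def experiment_names(bin_widths) -> dict[str, str]:
    """Display name -> file slug for the baseline and each combined set."""
    names = {"cDVH": "cdvh"}
    for w in bin_widths:
        names[f"+dDVH (bin = {w:g} Gy)"] = f"ddvh_bin{w:g}"
    return names


@dataclass(frozen=True)
class RunManifest:
    """Record of one pipeline run: config, seed, versions, output checksums."""

    config: dict
    seed: int
    version: str
    outputs: dict[str, str]  # relative path -> sha256
    wall_times: dict[str, float]

    def write(self, path) -> None:
        payload = {"config": self.config, "seed": self.seed,
                   "version": self.version, "outputs": self.outputs,
                   "stage_seconds": {k: round(v, 3)
                                     for k, v in self.wall_times.items()}}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _model_json(result: ExperimentResult) -> dict:
    return {
        "name": result.name,
        "split_fingerprint": result.split_fingerprint,
        "auc_summary": result.auc_summary(),
        "models": [
            {"split_id": m.split_id, "lambda_star": m.lambda_star,
             "intercept": m.intercept, "coefficients": m.coefficients,
             "selected": list(m.selected), "train_auc": m.train_auc,
             "test_auc": m.test_auc}
            for m in result.models
        ],
    }


def run_all(config: dict | str | Path | None = None, outdir="results",
            seed: int | None = None) -> RunManifest:
    """Run the whole analysis; returns the manifest (also written to disk)."""
    cfg = config if isinstance(config, dict) else load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(outdir)
    for sub in ("features", "correlations", "models", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    times: dict[str, float] = {}
    widths = [float(w) for w in cfg["bin_widths"]]
    schedules = [BinSchedule(w) for w in widths]

    # --- stage: cohort ---------------------------------------------------
    t0 = time.perf_counter()
    if cfg["cohort"].get("csv"):
        table, labels = load_cohort(cfg["cohort"]["csv"])
        issues = validate_inputs(cfg["cohort"]["csv"])
        if issues:
            raise ValueError("cohort CSV failed validation: " + "; ".join(issues))
        truth = None
    else:
        spec = CohortSpec(
            n_patients=int(cfg["cohort"]["n_patients"]),
            target_prevalence=float(cfg["cohort"]["target_prevalence"]),
            true_model=dict(cfg["cohort"]["true_model"]),
            bin_widths=tuple(widths),
            seed=int(cfg["seed"]))
        cohort = make_cohort(spec)
        table, labels, truth = cohort.feature_table, cohort.labels, cohort.true_model
        save_cohort(cohort, out / "features" / "cohort.csv",
                    out / "features" / "true_model.json")
    times["cohort"] = time.perf_counter() - t0
    log.info("cohort ready: %d patients, prevalence %.3f (%.1fs)",
             len(table), float(np.mean(labels)), times["cohort"])

    # --- stage: correlations --------------------------------------------
    t0 = time.perf_counter()
    cdvh_cols = cdvh_feature_names()
    matrices = {"cdvh": spearman_matrix(table, cdvh_cols)}
    for w, sched in zip(widths, schedules):
        matrices[f"ddvh_bin{w:g}"] = spearman_matrix(table, sched.feature_names())
    for slug, cm in matrices.items():
        cm.to_frame().to_csv(out / "correlations" / f"{slug}.csv")
        if cfg.get("plots"):
            plot_heatmap(cm, out / "correlations" / f"{slug}.png", slug)
    volume_cols = [c for c in cdvh_cols if c != "MLD"]
    groups = {"cDVH": volume_cols}
    for w, sched in zip(widths, schedules):
        groups[f"dDVH bin {w:g} Gy"] = sched.feature_names()
    summary_rows = []
    for name, feats in groups.items():
        cm = spearman_matrix(table, feats)
        val = group_dependency_summary(cm, {name: feats})[name]
        summary_rows.append({"group": name, "mean_abs_rho": val})
    pd.DataFrame(summary_rows).to_csv(
        out / "correlations" / "group_summary.csv", index=False)
    times["correlations"] = time.perf_counter() - t0
    log.info("correlations written (%.1fs)", times["correlations"])

    # --- stage: experiments ---------------------------------------------
    t0 = time.perf_counter()
    exp_cfg = cfg["experiment"]
    names = experiment_names(widths)
    feature_sets = {"cDVH": tuple(cdvh_cols)}
    for w, sched in zip(widths, schedules):
        feature_sets[f"+dDVH (bin = {w:g} Gy)"] = tuple(
            cdvh_cols + sched.feature_names())
    results: dict[str, ExperimentResult] = {}
    for disp, cols in feature_sets.items():
        config_ = ExperimentConfig(
            name=disp, feature_columns=cols,
            n_iterations=int(exp_cfg["n_iterations"]),
            splits_per_iteration=int(exp_cfg["splits_per_iteration"]),
            test_fraction=float(exp_cfg["test_fraction"]),
            inner_folds=int(exp_cfg["inner_folds"]),
            n_lambda=int(exp_cfg["n_lambda"]),
            lambda_min_ratio=float(exp_cfg["lambda_min_ratio"]),
            base_seed=int(cfg["seed"]),
            outer_scheme=str(exp_cfg["outer_scheme"]))
        results[disp] = run_experiment(table, labels, config_)
        slug = names[disp]
        (out / "models" / f"{slug}.json").write_text(
            json.dumps(_model_json(results[disp]), indent=2, sort_keys=True))
        log.info("experiment %s: mean test AUC %.3f", disp,
                 results[disp].test_aucs.mean())
    times["experiments"] = time.perf_counter() - t0

    # --- stage: reports --------------------------------------------------
    t0 = time.perf_counter()
    pd.DataFrame([r.auc_summary() for r in results.values()]).to_csv(
        out / "reports" / "auc_summary.csv", index=False)
    for disp, result in results.items():
        slug = names[disp]
        freq = selection_frequency(result.models)
        df = freq.to_frame()
        df["n_models"] = freq.n_models
        df.to_csv(out / "reports" / f"selection_frequency_{slug}.csv", index=False)
        top = top_coefficient_frequency(result.models)
        pd.DataFrame({"feature": list(top), "count": list(top.values())}).to_csv(
            out / "reports" / f"top_coefficient_{slug}.csv", index=False)
    comp_rows = []
    for disp in list(results)[1:]:
        comp = compare_models(results[disp], results["cDVH"])
        comp_rows.append({"model_a": disp, "model_b": "cDVH",
                          "mean_auc_difference": comp.mean_difference,
                          "wilcoxon_W": comp.statistic,
                          "p_value": comp.p_value})
    pd.DataFrame(comp_rows).to_csv(out / "reports" / "comparisons.csv",
                                   index=False)
    times["reports"] = time.perf_counter() - t0

    outputs = {str(p.relative_to(out)): _sha256(p)
               for p in sorted(out.rglob("*"))
               if p.is_file() and p.name != "manifest.json"}
    manifest = RunManifest(cfg, int(cfg["seed"]), __version__, outputs, times)
    manifest.write(out / "manifest.json")
    return manifest


def validate_inputs(cohort_csv) -> list[str]:
    """Sanity-check a cohort feature CSV; returns an itemized issue list."""
    path = Path(cohort_csv)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    issues: list[str] = []
    if "label" not in df.columns:
        issues.append("missing 'label' column")
    else:
        bad = df.index[~df["label"].isin([0, 1])]
        issues += [f"row {i}: non-binary label {df.at[i, 'label']!r}" for i in bad]
    canonical = re.compile(r"^(cV\d+(\.\d+)?Gy|dV\d+(\.\d+)?-\d+(\.\d+)?Gy|MLD)$")
    for col in df.columns:
        if col == "label":
            continue
        if not canonical.match(col):
            issues.append(f"column {col!r}: not a canonical DVH feature name")
            continue
        ser = df[col]
        na = ser.index[ser.isna()]
        issues += [f"row {i}: missing value in {col}" for i in na]
        ser = ser.dropna()
        if col.startswith(("cV", "dV")):
            bad = ser.index[(ser < 0) | (ser > 100)]
            issues += [f"row {i}: {col}={ser[i]:g} outside [0, 100]" for i in bad]
        elif col == "MLD":
            bad = ser.index[ser < 0]
            issues += [f"row {i}: negative MLD {ser[i]:g}" for i in bad]
    return issues
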