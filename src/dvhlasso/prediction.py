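"""Nested double cross-validation for L1-penalized pneumonitis models.

Protocol per outer split: 70% of patients form the inner set, 30% the
held-out test set. Features are converted to Z-scores using inner-set
statistics only; a penalty strength lambda* is chosen by stratified
fivefold cross-validation inside the inner set (minimum mean held-out
binomial deviance, ties resolved toward the more regularized model);
the model is refitted on the whole inner set at lambda* and scored on the
untouched test set by AUC. Six iterations of five stratified shuffle
splits give 30 fitted models per feature set; selection frequencies,
top-coefficient frequencies and paired Wilcoxon comparisons across
feature sets are computed over those 30 models.

Splits are derived deterministically from a base seed and the labels
alone, so experiments on different feature sets share outer splits
exactly and can be compared pairwise.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .lasso import lasso_logistic_fit, lasso_logistic_path, lambda_max
from .stats import WilcoxonResult, auc, mean_ci, wilcoxon_signed_rank

__all__ = [
    "StandardizationParams",
    "ExperimentConfig",
    "CVModelResult",
    "ExperimentResult",
    "ModelComparison",
    "SelectionFrequencies",
    "derive_seed",
    "zscore",
    "select_lambda",
    "run_experiment",
    "selection_frequency",
    "top_coefficient_frequency",
    "compare_models",
]


def derive_seed(base_seed: int, *tags) -> int:
    """Deterministic sub-seed from a base seed and a tag tuple.

    SHA-256 of the decimal base seed joined with the tags, truncated to
    31 bits, so different pipeline stages get independent, reproducible
    randomness from one user-facing seed.
    """
    text = ":".join([str(int(base_seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class StandardizationParams:
    """Training-set feature means/SDs; constant features are dropped."""

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    dropped: tuple[str, ...] = ()

    def transform(self, rows: pd.DataFrame) -> np.ndarray:
        X = rows[list(self.feature_names)].to_numpy(dtype=float)
        return (X - self.means) / self.sds


def zscore(train_rows: pd.DataFrame, apply_rows: pd.DataFrame | None = None
           ) -> tuple[StandardizationParams, np.ndarray, np.ndarray | None]:
    """Z-score features on training statistics (population SD, ddof=0).

    Constant training columns carry no information and are dropped with a
    warning. ``apply_rows`` (e.g. a test partition) is transformed with the
    training parameters only.
    """
    if len(train_rows) < 2:
        raise ValueError("need at least 2 training rows to standardize")
    means = train_rows.mean(axis=0)
    sds = train_rows.std(axis=0, ddof=0)
    keep = sds > 0
    dropped = tuple(train_rows.columns[~keep])
    if dropped:
        warnings.warn(f"dropping constant feature(s): {dropped}", stacklevel=2)
    names = tuple(train_rows.columns[keep])
    params = StandardizationParams(names, means[keep].to_numpy(),
                                   sds[keep].to_numpy(), dropped)
    train_z = params.transform(train_rows)
    apply_z = params.transform(apply_rows) if apply_rows is not None else None
    return params, train_z, apply_z


def _deviance(eta: np.ndarray, y: np.ndarray) -> float:
    """Mean binomial deviance of linear predictor eta against labels y."""
    return float(2.0 * np.mean(np.logaddexp(0.0, eta) - y * eta))


def select_lambda(train_X: np.ndarray, train_y: np.ndarray,
                  grid: np.ndarray | None = None, folds: int = 5,
                  seed: int = 0, n_lambda: int = 100,
                  lambda_min_ratio: float = 1e-3
                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """Choose the penalty by stratified inner cross-validation.

    Returns (lambda*, per-lambda mean held-out deviance, grid). The grid
    defaults to ``n_lambda`` log-spaced values from lambda_max down to
    lambda_max * lambda_min_ratio. Ties in mean loss resolve to the larger
    lambda (the more regularized model).
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=float).ravel()
    if grid is None:
        lmax = lambda_max(train_X, train_y)
        grid = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1].copy()
    losses = np.zeros((folds, grid.size))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for k, (tr, va) in enumerate(skf.split(train_X, train_y)):
        y_tr = train_y[tr]
        if y_tr.min() == y_tr.max():
            raise ValueError(f"inner fold {k} lost a class after stratification")
        coefs, icepts = lasso_logistic_path(train_X[tr], y_tr, grid)
        etas = train_X[va] @ coefs.T + icepts
        for l in range(grid.size):
            losses[k, l] = _deviance(etas[:, l], train_y[va])
    mean_loss = losses.mean(axis=0)
    if not np.all(np.isfinite(mean_loss)):
        raise RuntimeError("non-finite cross-validation loss")
    # grid is descending, argmin returns the first (largest-lambda) minimum
    best = int(np.argmin(mean_loss))
    return float(grid[best]), mean_loss, grid


@dataclass(frozen=True)
class ExperimentConfig:
    """One feature set's cross-validation experiment.

    ``n_iterations`` blocks of ``splits_per_iteration`` stratified shuffle
    splits at ``test_fraction`` held out (default 6 x 5 = 30 models).
    ``outer_scheme`` may be "shuffle" (default) or "kfold", which instead
    partitions each iteration into five disjoint stratified folds.
    """

    name: str
    feature_columns: tuple[str, ...]
    n_iterations: int = 6
    splits_per_iteration: int = 5
    test_fraction: float = 0.3
    inner_folds: int = 5
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    base_seed: int = 0
    outer_scheme: str = "shuffle"

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction <= 0.5:
            raise ValueError("test fraction must lie in (0, 0.5]")
        if self.outer_scheme not in ("shuffle", "kfold"):
            raise ValueError("outer_scheme must be 'shuffle' or 'kfold'")

    @property
    def n_models(self) -> int:
        return self.n_iterations * self.splits_per_iteration


@dataclass(frozen=True)
class CVModelResult:
    """One outer split: chosen penalty, standardized coefficients, AUCs."""

    split_id: int
    lambda_star: float
    coefficients: dict[str, float]
    intercept: float
    selected: tuple[str, ...]
    train_auc: float
    test_auc: float
    test_indices: tuple[int, ...]


@dataclass(frozen=True)
class ExperimentResult:
    """All outer-split models for one feature set, with AUC summaries."""

    name: str
    config: ExperimentConfig
    models: tuple[CVModelResult, ...]
    split_fingerprint: str

    @property
    def test_aucs(self) -> np.ndarray:
        return np.array([m.test_auc for m in self.models])

    @property
    def train_aucs(self) -> np.ndarray:
        return np.array([m.train_auc for m in self.models])

    def auc_summary(self) -> dict[str, float]:
        tr, tr_lo, tr_hi = mean_ci(self.train_aucs)
        te, te_lo, te_hi = mean_ci(self.test_aucs)
        return {"model": self.name,
                "train_auc_mean": tr, "train_auc_lo": tr_lo, "train_auc_hi": tr_hi,
                "test_auc_mean": te, "test_auc_lo": te_lo, "test_auc_hi": te_hi}


def _outer_splits(labels: np.ndarray, config: ExperimentConfig
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    if config.outer_scheme == "shuffle":
        sss = StratifiedShuffleSplit(
            n_splits=config.n_models, test_size=config.test_fraction,
            random_state=derive_seed(config.base_seed, "outer"))
        return list(sss.split(np.zeros_like(labels), labels))
    splits = []
    for it in range(config.n_iterations):
        skf = StratifiedKFold(
            n_splits=config.splits_per_iteration, shuffle=True,
            random_state=derive_seed(config.base_seed, "outer", it))
        splits.extend(skf.split(np.zeros_like(labels), labels))
    return splits


def _fingerprint(splits) -> str:
    h = hashlib.sha256()
    for _, te in splits:
        h.update(np.sort(np.asarray(te)).astype(np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()


def run_experiment(table: pd.DataFrame, labels, config: ExperimentConfig
                   ) -> ExperimentResult:
    """Run the full double cross-validation for one feature set."""
    missing = [c for c in config.feature_columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature columns not in table: {missing}")
    y = np.asarray(labels, dtype=float).ravel()
    if len(table) != y.size:
        raise ValueError("labels length must match the feature table")
    sub = table[list(config.feature_columns)]
    splits = _outer_splits(y, config)
    models = []
    for s, (tr, te) in enumerate(splits):
        y_tr, y_te = y[tr], y[te]
        if y_tr.min() == y_tr.max() or y_te.min() == y_te.max():
            raise ValueError(f"outer split {s}: a partition lost a class")
        params, X_tr, X_te = zscore(sub.iloc[tr], sub.iloc[te])
        lam, _, _ = select_lambda(
            X_tr, y_tr, folds=config.inner_folds,
            seed=derive_seed(config.base_seed, "inner", s),
            n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio)
        fit = lasso_logistic_fit(X_tr, y_tr, lam,
                                 feature_names=params.feature_names)
        coef = {name: 0.0 for name in config.feature_columns}
        coef.update(dict(zip(params.feature_names, fit.coefficients)))
        models.append(CVModelResult(
            split_id=s, lambda_star=lam, coefficients=coef,
            intercept=fit.intercept, selected=fit.selected_names,
            train_auc=auc(fit.decision_function(X_tr), y_tr),
            test_auc=auc(fit.decision_function(X_te), y_te),
            test_indices=tuple(int(i) for i in np.sort(te))))
    return ExperimentResult(config.name, config, tuple(models),
                            _fingerprint(splits))


@dataclass(frozen=True)
class SelectionFrequencies:
    """Per-feature nonzero-coefficient counts plus selected-set size stats."""

    counts: dict[str, int]
    mean_size: float
    sd_size: float
    n_models: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": list(self.counts),
                             "count": list(self.counts.values())})


def selection_frequency(results) -> SelectionFrequencies:
    """How often each feature enters the model across the outer splits."""
    results = list(results)
    if not results:
        raise ValueError("no models given")
    counts = {name: 0 for name in results[0].coefficients}
    sizes = []
    for m in results:
        sizes.append(len(m.selected))
        for name in m.selected:
            counts[name] += 1
    sizes = np.array(sizes, dtype=float)
    sd = float(sizes.std(ddof=1)) if sizes.size > 1 else 0.0
    return SelectionFrequencies(counts, float(sizes.mean()), sd, len(results))


def top_coefficient_frequency(results) -> dict[str, int]:
    """Per model, the feature with the largest |standardized coefficient|.

    Models in which every coefficient was shrunk to zero are counted in a
    reserved "none" bucket, so the counts always sum to the model count.
    """
    results = list(results)
    if not results:
        raise ValueError("no models given")
    counts = {name: 0 for name in results[0].coefficients}
    counts["none"] = 0
    for m in results:
        if not m.selected:
            counts["none"] += 1
            continue
        top = max(m.coefficients, key=lambda k: abs(m.coefficients[k]))
        counts[top] += 1
    return counts


@dataclass(frozen=True)
class ModelComparison:
    """Paired comparison of two experiments on identical outer splits."""

    name_a: str
    name_b: str
    differences: np.ndarray  # test AUC of a minus b, per shared split
    statistic: float
    p_value: float

    @property
    def mean_difference(self) -> float:
        return float(self.differences.mean())


def compare_models(a: ExperimentResult, b: ExperimentResult) -> ModelComparison:
    """Paired Wilcoxon signed-rank test on the two experiments' test AUCs."""
    if a.split_fingerprint != b.split_fingerprint:
        raise ValueError("unpaired experiments: outer splits differ")
    diffs = a.test_aucs - b.test_aucs
    res: WilcoxonResult = wilcoxon_signed_rank(diffs)
    return ModelComparison(a.name, b.name, diffs, res.statistic, res.p_value)
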