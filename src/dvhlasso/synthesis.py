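"""Synthetic dose phantoms and synthetic patient cohorts.

Clinical DVH datasets for pneumonitis modelling are rarely shareable, so
this module provides two substitutes:

* **Phantoms** — tiny 3D dose grids with known analytic structure
  (uniform, two-level, spherical target) whose DVH features can be
  verified against direct voxel counting.

* **Cohorts** — per-patient cumulative dose-volume curves drawn from a
  three-parameter sigmoid family, rejection-sampled to honour the lung
  dose constraints used in thoracic radiotherapy planning
  (V5Gy < 65%, V20Gy < 35%, MLD < 20 Gy), with a binary pneumonitis
  label generated from a known logistic model on Z-scored DVH features.
  The label model's intercept is tuned by bisection so the expected
  prevalence matches a target (default 26.8%, a realistic grade >= 2
  pneumonitis rate under these constraints).

The curve family is a sigmoid plus a localized high-dose shoulder,

    cV(d) = A * (1+e^(-d50/s)) / (1+e^((d-d50)/s)) + B / (1+e^((d-dB)/sB))

for d > 0, pinned to 1 at d = 0: the whole organ receives >= 0 Gy, while
only a fraction ~A+B receives any appreciable dose. A controls the
low-dose plateau, d50 the falloff midpoint (Gy), s the falloff width
(Gy); the second term models the small lung volume inside the high-dose
shell around the target (fraction B concentrated near dose dB with
spread sB), the feature that makes mid-to-high-dose differential bins
informative beyond the coarse cumulative sample points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dvh import (
    BinSchedule,
    DoseGrid,
    DoseVolumeCurve,
    StructureMask,
    cdvh_feature_names,
    curve_feature_vector,
)

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "CurveFamily",
    "CohortSpec",
    "SyntheticCohort",
    "sample_curve",
    "make_cohort",
    "make_recovery_cohort",
    "save_cohort",
    "load_cohort",
]

PHANTOM_KINDS = ("uniform", "two-level", "spherical-target")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for an analytic dose phantom.

    kind ``uniform``: constant dose ``dose`` everywhere.
    kind ``two-level``: first half of the voxels at ``low``, rest at ``high``.
    kind ``spherical-target``: dose decays sigmoidally with distance from
    ``center`` (voxel units): peak_dose / (1 + exp((r - radius)/falloff)).
    """

    kind: str
    shape: tuple[int, int, int] = (20, 20, 20)
    dose: float = 10.0
    low: float = 6.0
    high: float = 30.0
    center: tuple[float, float, float] | None = None
    radius: float = 6.0
    peak_dose: float = 60.0
    falloff: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; "
                             f"expected one of {PHANTOM_KINDS}")
        for d in (self.dose, self.low, self.high, self.peak_dose):
            if d < 0:
                raise ValueError("phantom doses must be >= 0")


def make_phantom(spec: PhantomSpec, seed: int = 0
                 ) -> tuple[DoseGrid, StructureMask]:
    """Build the phantom's dose grid and a full-organ mask (deterministic)."""
    shape = tuple(spec.shape)
    if spec.kind == "uniform":
        values = np.full(shape, float(spec.dose))
    elif spec.kind == "two-level":
        flat = np.empty(int(np.prod(shape)))
        half = flat.size // 2
        flat[:half] = spec.low
        flat[half:] = spec.high
        values = flat.reshape(shape)
    else:  # spherical-target
        center = spec.center or tuple((s - 1) / 2 for s in shape)
        zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape),
                                 indexing="ij")
        r = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                    + (xx - center[2]) ** 2)
        values = spec.peak_dose / (1.0 + np.exp((r - spec.radius) / spec.falloff))
    return DoseGrid(values), StructureMask(np.ones(shape, dtype=bool))


@dataclass(frozen=True)
class CurveFamily:
    """Distribution of the curve parameters across a cohort.

    Defaults put the accepted samples around realistic thoracic-plan lung
    DVHs: low-dose plateau A ~ U(0.35, 0.55), midpoint d50 ~ N(24, 5) Gy,
    falloff width s ~ N(6, 1.5) Gy truncated above 1 Gy; shoulder volume
    B ~ U(0, 0.08) (up to ~8% of lung in the high-dose shell), shoulder
    dose dB ~ U(35, 55) Gy, shoulder spread sB ~ U(1, 3) Gy. Set
    ``b_high = 0`` for a pure single-sigmoid cohort.
    """

    a_low: float = 0.35
    a_high: float = 0.55
    d50_mean: float = 24.0
    d50_sd: float = 5.0
    s_mean: float = 6.0
    s_sd: float = 1.5
    s_min: float = 1.0
    b_low: float = 0.0
    b_high: float = 0.08
    db_low: float = 35.0
    db_high: float = 55.0
    sb_low: float = 1.0
    sb_high: float = 3.0

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        a = rng.uniform(self.a_low, self.a_high)
        d50 = rng.normal(self.d50_mean, self.d50_sd)
        s = rng.normal(self.s_mean, self.s_sd)
        while s <= self.s_min:
            s = rng.normal(self.s_mean, self.s_sd)
        b = rng.uniform(self.b_low, self.b_high)
        db = rng.uniform(self.db_low, self.db_high)
        sb = rng.uniform(self.sb_low, self.sb_high)
        return {"A": float(a), "d50": float(d50), "s": float(s),
                "B": float(b), "dB": float(db), "sB": float(sb)}


#: Planning constraints every synthetic patient must satisfy.
DOSE_CONSTRAINTS = {"cV5Gy": 65.0, "cV20Gy": 35.0, "MLD": 20.0}


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic cohort."""

    n_patients: int = 153
    target_prevalence: float = 0.268
    true_model: dict[str, float] = field(
        default_factory=lambda: {"dV37-41Gy": 0.7, "dV41-45Gy": 0.7,
                                 "cV60Gy": 0.5})
    family: CurveFamily = field(default_factory=CurveFamily)
    bin_widths: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    seed: int = 0
    max_tries: int = 1000
    dose_resolution: float = 0.1
    max_dose: float = 80.0
    n_noise_features: int = 0  # extra pure-noise columns for recovery tests

    def __post_init__(self) -> None:
        if self.n_patients < 20:
            raise ValueError("cohort needs at least 20 patients")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target prevalence must lie in (0, 1)")

    def schedules(self) -> list[BinSchedule]:
        return [BinSchedule(w) for w in self.bin_widths]

    def feature_names(self) -> list[str]:
        names = cdvh_feature_names()
        for sched in self.schedules():
            names += sched.feature_names()
        names += [f"noise{k+1}" for k in range(self.n_noise_features)]
        return names


def _family_curve(params: dict[str, float], resolution: float,
                  max_dose: float) -> DoseVolumeCurve:
    d = np.arange(0.0, max_dose + resolution / 2, resolution)
    a, d50, s = params["A"], params["d50"], params["s"]
    f = a * (1.0 + np.exp(-d50 / s)) / (1.0 + np.exp((d - d50) / s))
    f += params.get("B", 0.0) / (1.0 + np.exp((d - params.get("dB", 45.0))
                                              / params.get("sB", 2.0)))
    f[0] = 1.0
    f = np.minimum.accumulate(np.clip(f, 0.0, 1.0))
    f[f < 1e-12] = 0.0
    f[-1] = 0.0  # maximum dose reached: no volume beyond the grid
    return DoseVolumeCurve(d, f)


def _passes_constraints(curve: DoseVolumeCurve) -> bool:
    return (100.0 * curve.volume_at(5.0) < DOSE_CONSTRAINTS["cV5Gy"]
            and 100.0 * curve.volume_at(20.0) < DOSE_CONSTRAINTS["cV20Gy"]
            and curve.mean_dose() < DOSE_CONSTRAINTS["MLD"])


def sample_curve(spec: CohortSpec, rng: np.random.Generator
                 ) -> tuple[DoseVolumeCurve, dict[str, float]]:
    """Draw one constraint-satisfying cumulative curve (rejection sampling)."""
    for _ in range(spec.max_tries):
        params = spec.family.draw(rng)
        curve = _family_curve(params, spec.dose_resolution, spec.max_dose)
        if _passes_constraints(curve):
            return curve, params
    raise RuntimeError(
        f"constraints unsatisfiable: no accepted curve in {spec.max_tries} tries")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: features, labels and the generating ground truth."""

    feature_table: pd.DataFrame
    labels: np.ndarray
    true_model: dict[str, float]  # includes the tuned "intercept"
    curve_parameters: pd.DataFrame
    spec: CohortSpec

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.labels))


def _tune_intercept(eta_raw: np.ndarray, target: float,
                    tol: float = 1e-6) -> float:
    """Bisection on b0 so that mean sigmoid(b0 + eta_raw) hits the target."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = float(np.mean(1.0 / (1.0 + np.exp(-(mid + eta_raw)))))
        if abs(p - target) <= tol:
            return mid
        if p < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a fully reproducible synthetic cohort from its spec."""
    known = set(spec.feature_names())
    unknown = set(spec.true_model) - known
    if unknown:
        raise ValueError(f"true_model refers to unknown features: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    schedules = spec.schedules()
    rows, params_rows = [], []
    for _ in range(spec.n_patients):
        curve, params = sample_curve(spec, rng)
        rows.append(curve_feature_vector(curve, schedules))
        params_rows.append(params)
    table = pd.DataFrame(rows)
    for k in range(spec.n_noise_features):
        # standard-normal columns carrying no outcome signal, used by
        # feature-recovery stress tests
        table[f"noise{k+1}"] = rng.standard_normal(spec.n_patients)
    table = table[spec.feature_names()]

    # cohort-level Z-scores define the generative risk; this is part of the
    # data-generating process, not an analysis step
    beta = np.array([spec.true_model.get(c, 0.0) for c in table.columns])
    z = (table.to_numpy() - table.to_numpy().mean(0)) / table.to_numpy().std(0)
    eta_raw = z @ beta
    b0 = _tune_intercept(eta_raw, spec.target_prevalence)
    p = 1.0 / (1.0 + np.exp(-(b0 + eta_raw)))
    labels = (rng.random(spec.n_patients) < p).astype(int)

    true_model = {"intercept": b0, **spec.true_model}
    return SyntheticCohort(table, labels, true_model,
                           pd.DataFrame(params_rows), spec)


#: Typical cohort mean and spread of each cumulative feature (percent; Gy
#: for MLD), used by the recovery stress-test table below.
_CDVH_PROFILE = {
    "cV5Gy": (40.0, 9.0), "cV10Gy": (31.0, 8.0), "cV20Gy": (24.0, 7.5),
    "cV30Gy": (18.0, 6.0), "cV40Gy": (12.0, 5.0), "cV50Gy": (7.0, 3.0),
    "cV60Gy": (3.0, 1.5), "MLD": (11.0, 2.5),
}


def make_recovery_cohort(n_patients: int = 300,
                         target_prevalence: float = 0.268,
                         planted: tuple[str, ...] = ("dV37-41Gy", "dV41-45Gy",
                                                     "dV45-49Gy"),
                         effect: float = 1.5,
                         n_noise_features: int = 5,
                         bin_width: float = 4.0,
                         seed: int = 0) -> SyntheticCohort:
    """Feature-recovery stress-test cohort (synthetic by construction).

    Unlike :func:`make_cohort`, whose features all derive from one smooth
    curve, this table separates the signal paths so recovery is decidable:
    the cumulative block is a strongly collinear background driven by one
    latent severity factor and carries no outcome signal; the ``planted``
    differential bins vary independently of that factor and carry the
    whole signal (coefficient ``effect`` each on the Z scale); the
    remaining differential bins are weakly tied to the background; and
    ``n_noise_features`` pure-noise columns carry nothing at all. Useful
    for verifying that the pipeline ranks planted features above noise and
    that adding differential bins improves the AUC when the signal lives
    in them.
    """
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n_patients)  # latent severity factor
    table = pd.DataFrame(index=range(n_patients))
    for name, (mean, sd) in _CDVH_PROFILE.items():
        noise_sd = 0.15 * sd
        vals = mean + sd * f + noise_sd * rng.standard_normal(n_patients)
        table[name] = np.clip(vals, 0.0, None if name == "MLD" else 100.0)
    sched = BinSchedule(bin_width)
    unknown = set(planted) - set(sched.feature_names())
    if unknown:
        raise ValueError(f"planted bins not in the width-{bin_width:g} "
                         f"schedule: {sorted(unknown)}")
    for name in sched.feature_names():
        if name in planted:
            vals = np.abs(1.5 + 1.0 * rng.standard_normal(n_patients))
        else:
            vals = np.abs(1.5 + 0.5 * f + 0.8 * rng.standard_normal(n_patients))
        table[name] = np.clip(vals, 0.0, 100.0)
    for k in range(n_noise_features):
        table[f"noise{k+1}"] = rng.standard_normal(n_patients)

    arr = table[list(planted)].to_numpy()
    z = (arr - arr.mean(0)) / arr.std(0)
    eta_raw = z @ np.full(len(planted), float(effect))
    b0 = _tune_intercept(eta_raw, target_prevalence)
    p = 1.0 / (1.0 + np.exp(-(b0 + eta_raw)))
    labels = (rng.random(n_patients) < p).astype(int)
    true_model = {"intercept": b0, **{name: float(effect) for name in planted}}
    spec = CohortSpec(n_patients=n_patients, target_prevalence=target_prevalence,
                      true_model={name: float(effect) for name in planted},
                      bin_widths=(bin_width,), seed=seed,
                      n_noise_features=n_noise_features)
    return SyntheticCohort(table, labels, true_model, pd.DataFrame(), spec)


def save_cohort(cohort: SyntheticCohort, csv_path, truth_path=None) -> None:
    """Write features + label column as CSV, ground truth as sidecar JSON."""
    df = cohort.feature_table.copy()
    df["label"] = cohort.labels
    df.to_csv(csv_path, index=False)
    if truth_path is not None:
        payload = {"true_model": cohort.true_model,
                   "seed": cohort.spec.seed,
                   "n_patients": cohort.spec.n_patients,
                   "target_prevalence": cohort.spec.target_prevalence}
        Path(truth_path).write_text(json.dumps(payload, indent=2))


def load_cohort(csv_path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a cohort CSV back as (feature table, labels)."""
    df = pd.read_csv(csv_path)
    if "label" not in df.columns:
        raise ValueError("cohort CSV must contain a 'label' column")
    labels = df.pop("label").to_numpy()
    return df, labels
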