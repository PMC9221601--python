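"""Dose-volume curves and DVH feature extraction.

A dose-volume histogram (DVH) summarises a 3D dose distribution inside an
organ. The *cumulative* curve cV(d) is the fraction of the organ volume
receiving at least ``d`` Gy; a *differential* feature dV_a-bGy is the
fraction receiving a dose in the half-open bin [a, b), which equals
cV(a) - cV(b) exactly under the ">= d" voxel-inclusion convention used
throughout this package.

Canonical feature names follow clinical usage: ``cV5Gy``, ``cV10Gy`` ...
``cV60Gy`` (10-Gy steps above 10), ``MLD`` (mean lung dose, Gy) and
``dV{a}-{b}Gy`` for each differential bin. Volumes are stored in percent
(0-100); MLD in Gy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseGrid",
    "StructureMask",
    "DoseVolumeCurve",
    "BinSchedule",
    "CDVH_DOSES",
    "cdvh_feature_names",
    "compute_curve",
    "cdvh_features",
    "ddvh_features",
    "mld",
    "extract_feature_table",
    "curve_feature_vector",
    "save_dose_npz",
    "load_dose_npz",
]

#: Dose points (Gy) of the cumulative features: V5 plus V10..V60 in 10-Gy steps.
CDVH_DOSES: tuple[int, ...] = (5, 10, 20, 30, 40, 50, 60)


def cdvh_feature_names() -> list[str]:
    """Canonical cumulative-feature column names, MLD last."""
    return [f"cV{d}Gy" for d in CDVH_DOSES] + ["MLD"]


@dataclass(frozen=True)
class DoseGrid:
    """A voxelised absorbed-dose distribution.

    Parameters
    ----------
    values : ndarray
        3D array of absorbed dose in Gy; finite and non-negative.
    spacing : tuple of float
        Voxel edge lengths in mm along each axis (positive).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("dose grid must be a nonempty 3D array")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("dose values must be finite and >= 0")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class StructureMask:
    """Binary organ membership on the same voxel lattice as its DoseGrid."""

    membership: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=bool)
        if m.ndim != 3:
            raise ValueError("mask must be a 3D boolean array")
        if not m.any():
            raise ValueError("empty structure")
        object.__setattr__(self, "membership", m)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.membership.shape

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())


@dataclass(frozen=True)
class DoseVolumeCurve:
    """Cumulative dose -> fractional-volume function for one organ.

    ``dose_points`` is strictly increasing and starts at 0 Gy;
    ``fractional_volume`` holds values in [0, 1], is monotone nonincreasing,
    equals 1 at dose 0 and 0 beyond the maximum dose present.
    """

    dose_points: np.ndarray
    fractional_volume: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_points, dtype=float)
        f = np.asarray(self.fractional_volume, dtype=float)
        if d.ndim != 1 or d.shape != f.shape or d.size < 2:
            raise ValueError("curve needs matching 1D dose and volume arrays")
        if d[0] != 0.0 or np.any(np.diff(d) <= 0):
            raise ValueError("dose points must start at 0 and strictly increase")
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ValueError("fractional volumes must lie in [0, 1]")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("fractional volume must be nonincreasing")
        object.__setattr__(self, "dose_points", d)
        object.__setattr__(self, "fractional_volume", np.clip(f, 0.0, 1.0))

    def volume_at(self, dose: float | np.ndarray) -> np.ndarray | float:
        """Fractional volume receiving >= ``dose`` Gy (linear interpolation).

        Doses beyond the last curve point return 0.
        """
        return np.interp(dose, self.dose_points, self.fractional_volume,
                         left=1.0, right=0.0)

    def mean_dose(self) -> float:
        """Mean organ dose as the integral of the curve over dose (trapezoid)."""
        return float(np.trapezoid(self.fractional_volume, self.dose_points))


@dataclass(frozen=True)
class BinSchedule:
    """Differential-DVH bin layout: fixed-width bins walking up from 5 Gy.

    Lower edges are ``lower + k*width`` for k = 0, 1, ... while the lower
    edge stays below ``upper``; every bin keeps the full width, so the last
    bin's upper edge may exceed ``upper`` (width 6 ends at 59-65 Gy).
    """

    width: float
    lower: float = 5.0
    upper: float = 60.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        if self.lower >= self.upper:
            raise ValueError("lower bound must be below upper bound")

    def bins(self) -> list[tuple[float, float]]:
        edges = []
        a = self.lower
        while a < self.upper - 1e-9:
            edges.append((a, a + self.width))
            a += self.width
        return edges

    def feature_names(self) -> list[str]:
        return [f"dV{_fmt(a)}-{_fmt(b)}Gy" for a, b in self.bins()]


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def compute_curve(grid: DoseGrid, mask: StructureMask,
                  resolution: float = 0.1) -> DoseVolumeCurve:
    """Cumulative dose-volume curve of ``grid`` restricted to ``mask``.

    At each dose point d (0, resolution, 2*resolution, ... up to one step
    beyond the maximum masked dose) the fractional volume is the share of
    masked voxels with dose >= d.
    """
    if grid.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: dose grid {grid.shape} vs mask {mask.shape}")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    doses = np.sort(grid.values[mask.membership])
    n = doses.size
    d_max = doses[-1]
    n_points = int(np.ceil(d_max / resolution)) + 2
    dose_points = np.arange(n_points) * resolution
    # voxels with dose >= d  ==  n - (# strictly below d)
    below = np.searchsorted(doses, dose_points, side="left")
    frac = (n - below) / n
    return DoseVolumeCurve(dose_points, frac)


def mld(grid: DoseGrid, mask: StructureMask) -> float:
    """Mean dose over masked voxels (Gy)."""
    if grid.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: dose grid {grid.shape} vs mask {mask.shape}")
    return float(grid.values[mask.membership].mean())


def cdvh_features(curve: DoseVolumeCurve) -> dict[str, float]:
    """Cumulative features cV5Gy, cV10Gy..cV60Gy (percent) plus MLD (Gy)."""
    out = {f"cV{d}Gy": 100.0 * float(curve.volume_at(d)) for d in CDVH_DOSES}
    out["MLD"] = curve.mean_dose()
    return out


def ddvh_features(curve: DoseVolumeCurve,
                  schedule: BinSchedule) -> dict[str, float]:
    """Differential features dV{a}-{b}Gy = cV(a) - cV(b), in percent."""
    out = {}
    for (a, b), name in zip(schedule.bins(), schedule.feature_names()):
        out[name] = 100.0 * float(curve.volume_at(a) - curve.volume_at(b))
    return out


def curve_feature_vector(curve: DoseVolumeCurve,
                         schedules: Sequence[BinSchedule] = ()) -> dict[str, float]:
    """Full ordered feature map for one curve: cDVH, MLD, then each schedule."""
    vec = cdvh_features(curve)
    for sched in schedules:
        vec.update(ddvh_features(curve, sched))
    return vec


def extract_feature_table(
    cohort: Iterable[tuple[DoseGrid, StructureMask]],
    schedules: Sequence[BinSchedule] = (),
    resolution: float = 0.1,
) -> pd.DataFrame:
    """One DVH feature row per patient, with a deterministic column order.

    Columns: cV5Gy..cV60Gy, MLD, then each schedule's dV bins in ascending
    dose. MLD comes from the voxel mean, the volumes from the cumulative
    curve. Any per-patient failure aborts with the patient index.
    """
    rows = []
    for i, (grid, mask) in enumerate(cohort):
        try:
            curve = compute_curve(grid, mask, resolution)
            vec = curve_feature_vector(curve, schedules)
            vec["MLD"] = mld(grid, mask)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for patient {i}: {exc}") from exc
        rows.append(vec)
    if not rows:
        raise ValueError("empty cohort")
    cols = cdvh_feature_names()
    for sched in schedules:
        cols += sched.feature_names()
    return pd.DataFrame(rows, columns=cols)


def save_dose_npz(path, grid: DoseGrid, masks: dict[str, StructureMask]) -> None:
    """Write a dose grid plus named masks to a compressed array archive."""
    arrays = {"dose": grid.values, "spacing": np.asarray(grid.spacing)}
    for name, m in masks.items():
        arrays[f"mask_{name}"] = m.membership
    np.savez_compressed(path, **arrays)


def load_dose_npz(path) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """Read a dose grid plus named masks written by :func:`save_dose_npz`."""
    with np.load(path) as data:
        grid = DoseGrid(data["dose"], tuple(data["spacing"]))
        masks = {k[5:]: StructureMask(data[k])
                 for k in data.files if k.startswith("mask_")}
    return grid, masks
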