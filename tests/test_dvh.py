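"""Dose-volume curve and DVH feature extraction against counting oracles."""

import numpy as np
import numpy.testing as npt
import pytest

from dvhlasso.dvh import (BinSchedule, DoseGrid, StructureMask, cdvh_features,
                          cdvh_feature_names, compute_curve,
                          curve_feature_vector, ddvh_features,
                          extract_feature_table, load_dose_npz, mld,
                          save_dose_npz)
from dvhlasso.synthesis import PhantomSpec, make_phantom

from conftest import random_phantom


def brute_force_cv(doses: np.ndarray, d: float) -> float:
    """Fraction of voxels receiving at least d Gy, in percent."""
    return 100.0 * np.mean(doses >= d)


def brute_force_dv(doses: np.ndarray, a: float, b: float) -> float:
    """Fraction of voxels with dose in [a, b), in percent."""
    return 100.0 * np.mean((doses >= a) & (doses < b))


class TestDoseVolumeCurve:
    def test_uniform_phantom_is_a_step_function(self):
        grid, mask = make_phantom(PhantomSpec("uniform", dose=10.0))
        curve = compute_curve(grid, mask)
        assert np.all(curve.fractional_volume[curve.dose_points <= 10.0] == 1.0)
        assert np.all(curve.fractional_volume[curve.dose_points > 10.0] == 0.0)

    def test_two_level_phantom_half_volume_at_mid_dose(self):
        grid, mask = make_phantom(PhantomSpec("two-level", low=6.0, high=30.0))
        curve = compute_curve(grid, mask)
        assert curve.volume_at(10.0) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_curve_matches_voxel_counting_oracle(self, seed):
        grid, mask = random_phantom(seed)
        curve = compute_curve(grid, mask)
        doses = grid.values[mask.membership]
        expect = [np.mean(doses >= d) for d in curve.dose_points]
        npt.assert_array_equal(curve.fractional_volume, expect)

    @pytest.mark.parametrize("seed", range(5))
    def test_curve_is_monotone_nonincreasing(self, seed):
        grid, mask = random_phantom(seed)
        curve = compute_curve(grid, mask)
        assert np.all(np.diff(curve.fractional_volume) <= 0)
        assert curve.fractional_volume[0] == 1.0
        assert curve.fractional_volume[-1] == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty structure"):
            StructureMask(np.zeros((3, 3, 3), dtype=bool))

    def test_shape_mismatch_rejected(self):
        grid = DoseGrid(np.ones((3, 3, 3)))
        mask = StructureMask(np.ones((3, 3, 4), dtype=bool))
        with pytest.raises(ValueError, match="mismatch"):
            compute_curve(grid, mask)


class TestCumulativeFeatures:
    def test_uniform_phantom_features(self):
        grid, mask = make_phantom(PhantomSpec("uniform", dose=10.0))
        feats = cdvh_features(compute_curve(grid, mask))
        assert feats["cV5Gy"] == 100.0
        assert feats["cV20Gy"] == 0.0
        assert feats["MLD"] == pytest.approx(10.0, rel=1e-2)

    def test_feature_name_set(self):
        grid, mask = make_phantom(PhantomSpec("uniform"))
        feats = cdvh_features(compute_curve(grid, mask))
        assert set(feats) == {"cV5Gy", "cV10Gy", "cV20Gy", "cV30Gy", "cV40Gy",
                              "cV50Gy", "cV60Gy", "MLD"}

    def test_inclusive_convention_counts_exact_dose(self):
        # voxels at exactly 30 Gy belong to cV30Gy
        grid, mask = make_phantom(PhantomSpec("two-level", low=6.0, high=30.0))
        feats = cdvh_features(compute_curve(grid, mask))
        assert feats["cV30Gy"] == pytest.approx(50.0, abs=1e-9)

    def test_stored_curve_point_reproduced_exactly(self):
        grid, mask = random_phantom(3)
        curve = compute_curve(grid, mask)
        k = 37
        assert curve.volume_at(curve.dose_points[k]) == curve.fractional_volume[k]


class TestMeanLungDose:
    def test_uniform_and_two_level_values(self):
        grid, mask = make_phantom(PhantomSpec("uniform", dose=10.0))
        assert mld(grid, mask) == 10.0
        grid, mask = make_phantom(PhantomSpec("two-level", low=6.0, high=30.0))
        assert mld(grid, mask) == 18.0

    @pytest.mark.parametrize("seed", range(5))
    def test_voxel_mean_equals_curve_integral(self, seed):
        # E[dose] equals the integral of the cumulative curve over dose
        grid, mask = random_phantom(seed)
        curve = compute_curve(grid, mask, resolution=0.1)
        assert curve.mean_dose() == pytest.approx(mld(grid, mask), rel=1e-2)


class TestBinSchedule:
    def test_width8_names_match_clinical_usage(self):
        names = BinSchedule(8).feature_names()
        assert "dV5-13Gy" in names and "dV45-53Gy" in names

    def test_width2_includes_lowest_bin(self):
        assert "dV5-7Gy" in BinSchedule(2).feature_names()

    def test_width4_enumerates_14_bins(self):
        bins = BinSchedule(4).bins()
        assert len(bins) == 14
        assert [a for a, _ in bins] == [5 + 4 * k for k in range(14)]

    def test_last_bin_keeps_full_width(self):
        assert BinSchedule(6).bins()[-1] == (59.0, 65.0)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            BinSchedule(0)
        with pytest.raises(ValueError):
            BinSchedule(2, lower=60, upper=5)


class TestDifferentialFeatures:
    def test_two_level_phantom_width4_low_bin(self):
        grid, mask = make_phantom(PhantomSpec("two-level", low=6.0, high=30.0))
        feats = ddvh_features(compute_curve(grid, mask), BinSchedule(4))
        assert feats["dV5-9Gy"] == pytest.approx(50.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("width", [2, 4, 6, 8])
    def test_bins_match_voxel_counting_oracle(self, seed, width):
        grid, mask = random_phantom(seed)
        curve = compute_curve(grid, mask)
        doses = grid.values[mask.membership]
        sched = BinSchedule(width)
        feats = ddvh_features(curve, sched)
        for (a, b), name in zip(sched.bins(), sched.feature_names()):
            npt.assert_allclose(feats[name], brute_force_dv(doses, a, b),
                                atol=1e-9)

    @pytest.mark.parametrize("width", [2, 4, 6, 8])
    def test_telescoping_conservation(self, width):
        grid, mask = random_phantom(9)
        curve = compute_curve(grid, mask)
        sched = BinSchedule(width)
        total = sum(ddvh_features(curve, sched).values())
        last_edge = sched.bins()[-1][1]
        expect = 100.0 * (curve.volume_at(5.0) - curve.volume_at(last_edge))
        assert total == pytest.approx(expect, abs=1e-9)


class TestFeatureTable:
    def test_three_phantoms_give_three_rows(self):
        cohort = [make_phantom(PhantomSpec("uniform", dose=d))
                  for d in (5.0, 10.0, 20.0)]
        table = extract_feature_table(cohort)
        assert table.shape == (3, 8)
        assert list(table.columns) == cdvh_feature_names()

    def test_width4_schedule_adds_14_columns(self):
        cohort = [make_phantom(PhantomSpec("uniform", dose=10.0))]
        table = extract_feature_table(cohort, [BinSchedule(4)])
        assert table.shape[1] == 8 + 14

    def test_failure_reports_patient_index(self):
        good = make_phantom(PhantomSpec("uniform", dose=10.0))
        bad = (DoseGrid(np.ones((2, 2, 2))),
               StructureMask(np.ones((2, 2, 3), dtype=bool)))
        with pytest.raises(RuntimeError, match="patient 1"):
            extract_feature_table([good, bad])

    def test_mld_column_uses_voxel_mean(self):
        grid, mask = random_phantom(5)
        table = extract_feature_table([(grid, mask)])
        assert table.at[0, "MLD"] == mld(grid, mask)


def test_dose_npz_roundtrip(tmp_path):
    grid, mask = random_phantom(2)
    path = tmp_path / "patient.npz"
    save_dose_npz(path, grid, {"lung": mask})
    grid2, masks = load_dose_npz(path)
    npt.assert_array_equal(grid2.values, grid.values)
    npt.assert_array_equal(masks["lung"].membership, mask.membership)
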