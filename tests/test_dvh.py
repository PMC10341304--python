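"""DVH construction and endpoint extraction against brute-force oracles."""

import numpy as np
import pytest

import hypofx as hx
from hypofx.dvh import (
    MetricSpec,
    compute_dvh,
    d_at_volume_percent,
    default_endpoint_catalogue,
    dvh_to_dataframe,
    extract_catalogue,
    integral_dose,
    max_dose,
    mean_dose,
    v_at_dose,
)

from conftest import make_geometry, make_mask, make_plan


def _grid(values, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    return hx.DoseGrid(values, make_geometry(values.shape, spacing))


def _uniform(shape, value, spacing=(1.0, 1.0, 1.0)):
    return _grid(np.full(shape, float(value)), spacing)


FULL = np.ones((2, 2, 2), dtype=bool)


class TestComputeDvh:
    def test_uniform_dose_step_curve(self):
        grid = _uniform((2, 2, 2), 10.0)
        curve = compute_dvh(grid, make_mask(FULL), bin_width=1.0)
        at = dict(zip(curve.dose_edges, curve.cum_volume_pct))
        assert at[0.0] == 100.0 and at[10.0] == 100.0 and at[11.0] == 0.0

    def test_two_voxel_half_coverage(self):
        values = np.zeros((2, 1, 1))
        values[0], values[1] = 5.0, 15.0
        occ = np.ones((2, 1, 1), dtype=bool)
        assert v_at_dose(_grid(values), make_mask(occ), 10.0, "%") == 50.0

    def test_random_grid_matches_per_voxel_counting(self):
        rng = np.random.default_rng(7)
        values = rng.random((5, 5, 5)) * 30
        occ = rng.random((5, 5, 5)) > 0.4
        curve = compute_dvh(_grid(values), make_mask(occ), bin_width=0.5)
        doses = values[occ]
        for edge, pct in zip(curve.dose_edges, curve.cum_volume_pct):
            assert pct == pytest.approx(100.0 * np.sum(doses >= edge) / doses.size)

    def test_monotone_nonincreasing_and_starts_at_total(self):
        rng = np.random.default_rng(8)
        values = rng.random((6, 6, 6)) * 25
        occ = rng.random((6, 6, 6)) > 0.5
        curve = compute_dvh(_grid(values), make_mask(occ))
        assert (np.diff(curve.cum_volume_cc) <= 0).all()
        assert curve.cum_volume_pct[0] == 100.0

    def test_empty_mask_rejected_with_structure_name(self):
        with pytest.raises(ValueError, match="liver"):
            compute_dvh(_uniform((2, 2, 2), 1.0), make_mask(np.zeros((2, 2, 2), bool), name="liver"))

    def test_dataframe_export_columns(self):
        curve = compute_dvh(_uniform((2, 2, 2), 3.0), make_mask(FULL))
        df = dvh_to_dataframe(curve)
        assert list(df.columns) == ["structure", "dose_gye", "volume_cc", "volume_pct"]


class TestVAtDose:
    def test_threshold_zero_full_volume(self):
        grid = _uniform((3, 3, 3), 4.0)
        m = make_mask(np.ones((3, 3, 3), bool))
        assert v_at_dose(grid, m, 0.0, "%") == 100.0
        assert v_at_dose(grid, m, 0.0, "cc") == pytest.approx(27 / 1000)

    def test_threshold_above_max_zero(self):
        assert v_at_dose(_uniform((2, 2, 2), 5.0), make_mask(FULL), 100.0, "%") == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        values = rng.random((4, 4, 4)) * 20
        occ = rng.random((4, 4, 4)) > 0.3
        grid, m = _grid(values, (2.0, 2.0, 2.0)), make_mask(occ, make_geometry((4, 4, 4), (2.0, 2.0, 2.0)))
        for thr in (0.0, 5.0, 12.5, 19.9):
            expected = np.sum(values[occ] >= thr)
            assert v_at_dose(grid, m, thr, "cc") == pytest.approx(expected * 8 / 1000)


class TestDAtVolumePercent:
    def test_uniform_dose_any_percent(self):
        grid = _uniform((2, 2, 2), 12.0)
        for p in (1, 50, 100):
            assert d_at_volume_percent(grid, make_mask(FULL), p) == 12.0

    def test_four_voxel_median_takes_second_hottest(self):
        values = np.array([0.0, 10.0, 20.0, 30.0]).reshape(4, 1, 1)
        m = make_mask(np.ones((4, 1, 1), bool))
        assert d_at_volume_percent(_grid(values), m, 50.0) == 20.0

    def test_p100_is_minimum(self):
        values = np.array([3.0, 10.0, 20.0, 30.0]).reshape(4, 1, 1)
        m = make_mask(np.ones((4, 1, 1), bool))
        assert d_at_volume_percent(_grid(values), m, 100.0) == 3.0

    def test_invalid_percent_rejected(self):
        with pytest.raises(ValueError, match="p must"):
            d_at_volume_percent(_uniform((2, 2, 2), 1.0), make_mask(FULL), 0.0)

    def test_consistency_with_v_at_dose(self):
        rng = np.random.default_rng(5)
        values = rng.random((5, 5, 5)) * 30
        grid = _grid(values)
        m = make_mask(rng.random((5, 5, 5)) > 0.4, make_geometry((5, 5, 5)))
        for p in (10, 33, 50, 90, 100):
            d = d_at_volume_percent(grid, m, p)
            assert v_at_dose(grid, m, d, "%") >= p


class TestMaxMeanIntegral:
    def test_uniform_grid(self):
        grid = _uniform((3, 3, 3), 7.5)
        m = make_mask(np.ones((3, 3, 3), bool))
        assert max_dose(grid, m) == 7.5
        assert mean_dose(grid, m) == 7.5

    def test_single_voxel_mask(self):
        values = np.arange(8.0).reshape(2, 2, 2)
        occ = np.zeros((2, 2, 2), bool)
        occ[1, 0, 1] = True
        m = make_mask(occ)
        assert max_dose(_grid(values), m) == mean_dose(_grid(values), m) == values[1, 0, 1]

    def test_mean_from_dvh_integration(self):
        rng = np.random.default_rng(11)
        values = rng.random((6, 6, 6)) * 20
        occ = rng.random((6, 6, 6)) > 0.5
        grid, m = _grid(values), make_mask(occ)
        bin_width = 0.05
        curve = compute_dvh(grid, m, bin_width)
        riemann = np.sum(curve.cum_volume_pct[1:] / 100.0) * bin_width
        assert riemann == pytest.approx(mean_dose(grid, m), abs=bin_width)

    def test_ten_joules_for_uniform_ten_gye_over_litre(self):
        # 1000 voxels of 1 cc at 10 GyE and unit density: 10 J/kg x 1 kg
        grid = _uniform((10, 10, 10), 10.0, spacing=(10.0, 10.0, 10.0))
        m = make_mask(np.ones((10, 10, 10), bool), make_geometry((10, 10, 10), (10.0, 10.0, 10.0)))
        assert integral_dose(grid, m) == pytest.approx(10.0, rel=1e-12)

    def test_zero_dose_zero_energy(self):
        grid = _uniform((3, 3, 3), 0.0)
        assert integral_dose(grid, make_mask(np.ones((3, 3, 3), bool))) == 0.0

    def test_energy_equals_mean_times_mass(self):
        rng = np.random.default_rng(13)
        values = rng.random((5, 5, 5)) * 30
        occ = rng.random((5, 5, 5)) > 0.3
        geom = make_geometry((5, 5, 5), (2.0, 3.0, 2.5))
        grid = hx.DoseGrid(values, geom)
        m = hx.StructureMask("m", occ, geom)
        mass_kg = m.volume_cc * 1.0 * 1e-3
        assert integral_dose(grid, m) == pytest.approx(mean_dose(grid, m) * mass_kg, rel=1e-9)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            integral_dose(_uniform((2, 2, 2), 1.0), make_mask(FULL), density_g_per_cc=0.0)


class TestExtractCatalogue:
    def _plan(self):
        rng = np.random.default_rng(17)
        shape = (8, 8, 8)
        values = rng.random(shape) * 28
        body = np.ones(shape, dtype=bool)
        ctv = np.zeros(shape, dtype=bool)
        ctv[2:5, 2:5, 2:5] = True
        left = np.zeros(shape, dtype=bool)
        left[5:7, 1:3, 1:3] = True
        right = np.zeros(shape, dtype=bool)
        right[5:7, 5:7, 5:7] = True
        return make_plan(
            values,
            {
                "body": body,
                "ctv": ctv,
                "kidney_ipsi": left,
                "kidney_contra": right,
                "kidneys_bilateral": left | right,
                "body_minus_ctv": body & ~ctv,
            },
        )

    def test_row_count_matches_configuration(self):
        plan = self._plan()
        cat = {
            "ctv": (MetricSpec("V_at_dose", 25.0, "%"),),
            "kidney_ipsi": (MetricSpec("mean"), MetricSpec("max")),
        }
        assert len(extract_catalogue(plan, cat)) == 3

    def test_bilateral_kidney_equals_union_oracle(self):
        plan = self._plan()
        results = extract_catalogue(
            plan, {"kidneys_bilateral": (MetricSpec("V_at_dose", 12.0, "%"),)}
        )
        union = plan.structures["kidneys_bilateral"]
        assert results[0].value == v_at_dose(plan.dose, union, 12.0, "%")
        # and the union is consistent with its parts in absolute volume
        cc_union = v_at_dose(plan.dose, union, 12.0, "cc")
        cc_parts = v_at_dose(plan.dose, plan.structures["kidney_ipsi"], 12.0, "cc") + v_at_dose(
            plan.dose, plan.structures["kidney_contra"], 12.0, "cc"
        )
        assert cc_union == pytest.approx(cc_parts)

    def test_body_minus_ctv_integral_below_body_integral(self):
        plan = self._plan()
        whole = integral_dose(plan.dose, plan.structures["body"])
        carved = integral_dose(plan.dose, plan.structures["body_minus_ctv"])
        assert carved < whole

    def test_explicit_catalogue_missing_structure_raises(self):
        with pytest.raises(KeyError, match="stomach"):
            extract_catalogue(self._plan(), {"stomach": (MetricSpec("mean"),)})

    def test_default_catalogue_covers_report_structures(self):
        cat = default_endpoint_catalogue()
        for name in ("bowel", "kidneys_bilateral", "bone", "body_minus_ctv"):
            assert name in cat

    def test_permutation_invariance(self):
        rng = np.random.default_rng(19)
        values = rng.random((4, 4, 4)) * 10
        occ = rng.random((4, 4, 4)) > 0.4
        grid, m = _grid(values), make_mask(occ)
        perm = rng.permutation(64).reshape(4, 4, 4)
        values_p = values.reshape(-1)[perm.reshape(-1)].reshape(4, 4, 4)
        occ_p = occ.reshape(-1)[perm.reshape(-1)].reshape(4, 4, 4)
        grid_p, m_p = _grid(values_p), make_mask(occ_p)
        assert mean_dose(grid, m) == pytest.approx(mean_dose(grid_p, m_p))
        assert max_dose(grid, m) == max_dose(grid_p, m_p)
        assert d_at_volume_percent(grid, m, 50) == d_at_volume_percent(grid_p, m_p, 50)
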