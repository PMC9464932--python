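import numpy as np
import pytest

from syctqa import VoxelGrid, compare_plans, compute_dvh, evaluate_metric, parse_metric
from syctqa.dvh_engine import DVHMetricSpec, dvh_band_gap, max_pointwise_dvh_gap
from syctqa.structure_raster import StructureMask

from oracles import dose_at_volume_oracle, dvh_curve_oracle, v_dose_oracle


def grid_and_mask(doses, voxel_volume_cc=2.0):
    doses = np.asarray(doses, dtype=float)
    g = VoxelGrid(doses.reshape(1, 1, -1), spacing=(10.0, 10.0, voxel_volume_cc * 10.0))
    m = StructureMask("s", np.ones(g.shape, bool), voxel_volume_cc)
    return g, m


class TestComputeDvh:
    def test_uniform_dose_is_a_step_at_the_dose(self):
        g, m = grid_and_mask(np.full(15, 10.0))
        curve = compute_dvh(g, m, bin_width=0.5)
        assert curve.cumulative_volume[0] == 100.0
        assert all(curve.cumulative_volume[curve.dose_edges <= 10.0] == 100.0)
        assert all(curve.cumulative_volume[curve.dose_edges > 10.0] == 0.0)
        assert curve.total_volume == pytest.approx(30.0)

    def test_two_level_dose_steps_at_both_levels(self):
        g, m = grid_and_mask([4.0] * 10 + [8.0] * 10)
        curve = compute_dvh(g, m, bin_width=0.1)
        v = lambda d: curve.cumulative_volume[np.searchsorted(curve.dose_edges, d)]
        assert v(0.0) == 100.0 and v(4.0) == 100.0
        assert v(4.1) == 50.0 and v(8.0) == 50.0
        assert v(8.1) == 0.0

    def test_curve_monotone_with_correct_endpoints_and_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        doses = rng.gamma(4.0, 2.0, 500)
        g, m = grid_and_mask(doses)
        curve = compute_dvh(g, m, bin_width=0.05)
        assert curve.cumulative_volume[0] == 100.0
        assert np.all(np.diff(curve.cumulative_volume) <= 0)
        assert curve.cumulative_volume[-1] == 0.0
        oracle = dvh_curve_oracle(doses, curve.dose_edges)
        # agreement within one bin: compare against the oracle at edges
        assert np.abs(curve.cumulative_volume - oracle).max() < 100.0 / doses.size + 1e-9

    def test_empty_mask_rejected(self):
        g, m = grid_and_mask(np.ones(5))
        m.mask[:] = False
        with pytest.raises(ValueError, match="empty mask"):
            compute_dvh(g, m)


class TestEvaluateMetric:
    """10 voxels of 2 cc with doses 1..10 Gy: the worked example structure."""

    def setup_method(self):
        self.g, self.m = grid_and_mask(np.arange(1.0, 11.0))

    @pytest.mark.parametrize(
        "metric,expected",
        [
            ("Dmax", 10.0),
            ("Dmean", 5.5),
            ("V5Gy", 60.0),  # 6 of 10 voxels at >= 5 Gy
            ("D2cc", 10.0),  # hottest 2 cc is exactly the hottest voxel
            ("VDpre@5Gy", 60.0),
        ],
    )
    def test_worked_examples(self, metric, expected):
        spec = parse_metric(metric)
        assert evaluate_metric(self.g, self.m, spec) == pytest.approx(expected, rel=1e-12)

    def test_d50_matches_quantile_by_sorting_oracle(self):
        spec = parse_metric("D50%")
        assert evaluate_metric(self.g, self.m, spec) == pytest.approx(
            dose_at_volume_oracle(self.g.values.ravel(), 0.50), rel=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_doses_match_sort_oracles(self, seed):
        rng = np.random.default_rng(seed)
        doses = rng.uniform(0, 40, 321)
        g, m = grid_and_mask(doses, voxel_volume_cc=0.7)
        for y in (2.0, 50.0, 95.0, 98.0):
            got = evaluate_metric(g, m, DVHMetricSpec("D_percent", y))
            assert got == pytest.approx(dose_at_volume_oracle(doses, y / 100.0), rel=1e-9)
        for cc in (0.5, 10.0, 100.0):
            got = evaluate_metric(g, m, DVHMetricSpec("D_volume", cc))
            assert got == pytest.approx(
                dose_at_volume_oracle(doses, cc / (321 * 0.7)), rel=1e-9
            )
        for x in (1.0, 12.0, 39.0):
            got = evaluate_metric(g, m, DVHMetricSpec("V_dose", x))
            assert got == pytest.approx(v_dose_oracle(doses, x), rel=1e-12)
        assert evaluate_metric(g, m, DVHMetricSpec("Dmean")) == pytest.approx(
            doses.mean(), rel=1e-9
        )

    def test_v_at_d_consistency(self):
        # V_{D_y%} >= y within one whole-voxel step
        rng = np.random.default_rng(8)
        doses = rng.uniform(0, 30, 200)
        g, m = grid_and_mask(doses)
        step = 100.0 / doses.size
        for y in (10.0, 50.0, 90.0):
            d_y = evaluate_metric(g, m, DVHMetricSpec("D_percent", y))
            v_at = evaluate_metric(g, m, DVHMetricSpec("V_dose", d_y))
            assert v_at >= y - step - 1e-9

    def test_volume_argument_beyond_structure_rejected(self):
        with pytest.raises(ValueError, match="exceeds structure volume"):
            evaluate_metric(self.g, self.m, DVHMetricSpec("D_volume", 21.0))

    @pytest.mark.parametrize("bad", ["Q5Gy", "D-3%", "V", "Dmaximum"])
    def test_unparseable_metric_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_metric(bad)

    def test_vdpre_without_prescription_rejected(self):
        with pytest.raises(ValueError, match="prescription"):
            parse_metric("VDpre")


class TestComparePlans:
    def test_identity_comparison_is_all_zeros(self):
        g, m = grid_and_mask(np.linspace(1, 20, 40))
        deltas, gaps = compare_plans(g, g, [m], {"s": ["Dmax", "Dmean", "V5Gy", "D50%"]})
        assert all(d.delta == 0.0 for d in deltas)
        assert gaps["s"] == 0.0

    def test_uniform_shift_moves_dmax_by_shift(self):
        g, m = grid_and_mask(np.linspace(1, 20, 40))
        shifted = g.with_values(g.values + 1.0)
        deltas, _ = compare_plans(g, shifted, [m], {"s": ["Dmax"]})
        assert deltas[0].delta == pytest.approx(1.0, rel=1e-12)
        assert deltas[0].unit == "Gy"

    def test_deltas_equal_compositional_recomputation(self):
        rng = np.random.default_rng(4)
        ref, m = grid_and_mask(rng.uniform(0, 30, 100))
        ev = ref.with_values(ref.values * (1 + 0.05 * rng.standard_normal(ref.shape)))
        table = {"s": ["Dmax", "Dmean", "D30%", "V10Gy"]}
        deltas, _ = compare_plans(ref, ev, [m], table)
        for d in deltas:
            expected = abs(
                evaluate_metric(ref, m, d.metric) - evaluate_metric(ev, m, d.metric)
            )
            assert d.delta == pytest.approx(expected, rel=1e-12)

    def test_structure_without_metric_entry_skipped_with_warning(self, caplog):
        g, m = grid_and_mask(np.ones(10))
        with caplog.at_level("WARNING"):
            deltas, gaps = compare_plans(g, g, [m], {})
        assert deltas == [] and gaps == {}
        assert "no metric table entry" in caplog.text


class TestDvhGaps:
    def test_band_gap_with_zero_window_equals_vertical_gap(self):
        rng = np.random.default_rng(6)
        ref, m = grid_and_mask(rng.uniform(5, 25, 80))
        ev = ref.with_values(ref.values + rng.uniform(-0.4, 0.4, ref.shape))
        vert = max_pointwise_dvh_gap(ref, ev, m, bin_width=0.02)
        band0 = dvh_band_gap(ref, ev, m, dose_window=0.0, bin_width=0.02)
        assert band0 == pytest.approx(vert, abs=1e-9)

    def test_small_dose_shift_is_absorbed_by_the_dose_window(self):
        # a steep DVH shifted by 0.5 Gy: huge vertical gap, zero band gap
        g, m = grid_and_mask(np.full(50, 20.0))
        shifted = g.with_values(g.values + 0.5)
        assert max_pointwise_dvh_gap(g, shifted, m) == 100.0
        assert dvh_band_gap(g, shifted, m, dose_window=1.0) == 0.0

    def test_volume_discrepancy_not_masked_by_window(self):
        # 30% of the structure loses dose entirely: no dose window hides that
        ref, m = grid_and_mask([20.0] * 100)
        ev = ref.with_values(np.array([20.0] * 70 + [5.0] * 30).reshape(ref.shape))
        assert dvh_band_gap(ref, ev, m, dose_window=1.0) == pytest.approx(30.0, abs=1e-9)
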