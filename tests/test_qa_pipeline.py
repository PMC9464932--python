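import numpy as np
import pytest

from syctqa import (
    EDAssignment,
    EDCalibration,
    QAConfig,
    ToleranceCriteria,
    TroubleshootThresholds,
    VoxelGrid,
    build_syct,
    case_config,
    classify_cohort,
    make_case,
    run_qa,
    troubleshoot,
)
from syctqa.structure_raster import StructureMask


@pytest.fixture(scope="module")
def concordant():
    return make_case("concordant", seed=0)


class TestRunQa:
    def test_plan_compared_against_itself_passes_with_zero_deltas(self, concordant):
        case = concordant
        report = run_qa(case.ct, case.masks, case.ref_dose, case.ref_dose, case_config(case))
        assert report.verdict == "PASS"
        assert all(d.delta == 0.0 for d in report.metric_deltas)
        assert all(g == 0.0 for g in report.dvh_gaps.values())
        for rates in report.gamma_pass_rates.values():
            assert all(r == 100.0 for r in rates.values())

    def test_missing_required_structure_rejected_before_analysis(self, concordant):
        case = concordant
        config = case_config(case)
        masks = [m for m in case.masks if m.name != "Target"]
        with pytest.raises(ValueError, match="Target"):
            run_qa(case.ct, masks, case.ref_dose, case.eval_dose, config)

    def test_verdict_is_auditable_from_clause_numbers(self, concordant):
        case = concordant
        report = run_qa(case.ct, case.masks, case.ref_dose, case.eval_dose, case_config(case))
        for c in report.clauses:
            if c.name.startswith("gamma"):
                assert c.passed == (c.value is not None and c.value > c.threshold)
            else:
                assert c.passed == (c.value < c.threshold)
        assert (report.verdict == "PASS") == all(c.passed for c in report.clauses)

    def test_report_body_is_reproducible_apart_from_timestamp(self, concordant):
        case = concordant
        config = case_config(case)
        r1 = run_qa(case.ct, case.masks, case.ref_dose, case.eval_dose, config)
        r2 = run_qa(case.ct, case.masks, case.ref_dose, case.eval_dose, config)
        d1, d2 = r1.to_dict(), r2.to_dict()
        d1["provenance"].pop("timestamp")
        d2["provenance"].pop("timestamp")
        assert d1 == d2

    def test_dose_grids_on_foreign_geometry_are_resampled(self, concordant):
        case = concordant
        # hand the doses over on a coarser grid: the pipeline resamples
        coarse = VoxelGrid(
            np.zeros((12, 24, 24)), (6.0, 6.0, 6.0),
            (case.ct.origin[0] + 1.5, case.ct.origin[1] + 1.5, case.ct.origin[2] + 1.5),
        )
        ref_c = case.ref_dose.resample_to(coarse)
        report = run_qa(case.ct, case.masks, ref_c, ref_c, case_config(case))
        assert report.verdict in ("PASS", "FAIL")  # completes with congruent internals
        assert all(d.delta == 0.0 for d in report.metric_deltas)


UNIT_CAL = EDCalibration(((-1000.0, 0.0), (0.0, 1.0)))


def _mask(shape, sl, name):
    arr = np.zeros(shape, dtype=bool)
    arr[sl] = True
    return StructureMask(name, arr, 0.008)


class TestTroubleshoot:
    shape = (4, 12, 12)

    def _ct(self, hu):
        return VoxelGrid(hu, (2, 2, 2))

    def _syct(self, ct, masks, assignments):
        return build_syct(ct, masks, assignments, UNIT_CAL)

    def test_consistent_homogeneous_phantom_yields_no_findings(self):
        hu = np.zeros(self.shape)
        body = _mask(self.shape, np.s_[:, 1:11, 1:11], "Body")
        assignments = [EDAssignment("Body", 1, None)]
        syct = self._syct(self._ct(hu), [body], assignments)
        out = troubleshoot(self._ct(hu), [body], syct.assignment_table, syct, UNIT_CAL)
        assert out == []

    def test_split_density_target_flagged_inhomogeneous_with_two_point_std(self):
        hu = np.zeros(self.shape)
        hu[:, :, :6] = -700.0  # ED 0.3 under the two-anchor calibration
        ct = self._ct(hu)
        target = _mask(self.shape, np.s_[:, :, :], "Target")
        assignments = [EDAssignment("Target", 1, None)]
        syct = self._syct(ct, [target], assignments)
        out = troubleshoot(ct, [target], syct.assignment_table, syct, UNIT_CAL)
        inh = [f for f in out if f.code == "INHOMOGENEOUS_STRUCTURE"]
        assert len(inh) == 1
        assert inh[0].data["std"] == pytest.approx(0.35, abs=1e-12)

    def test_skull_shadowed_by_higher_priority_whole_brain(self):
        hu = np.zeros(self.shape)
        ct = self._ct(hu)
        brain = _mask(self.shape, np.s_[:, 1:11, 1:11], "Brain")
        skull = _mask(self.shape, np.s_[:, 3:9, 3:9], "Skull")
        assignments = [EDAssignment("Skull", 1, 1.6), EDAssignment("Brain", 2, 1.0)]
        syct = build_syct(ct, [brain, skull], assignments, UNIT_CAL)
        out = troubleshoot(ct, [brain, skull], assignments, syct, UNIT_CAL)
        shadow = [f for f in out if f.code == "PRIORITY_SHADOWING"]
        assert [f.structure for f in shadow] == ["Skull"]
        assert shadow[0].data["shadowed_by"] == "Brain"
        assert shadow[0].data["covered_fraction"] == 1.0

    def test_assigned_ed_far_from_recomputed_value_flagged(self):
        hu = np.zeros(self.shape)
        ct = self._ct(hu)
        organ = _mask(self.shape, np.s_[:, 2:10, 2:10], "Organ")
        assignments = [EDAssignment("Organ", 1, 1.2)]  # anatomy says 1.0
        syct = build_syct(ct, [organ], assignments, UNIT_CAL)
        out = troubleshoot(ct, [organ], assignments, syct, UNIT_CAL)
        mism = [f for f in out if f.code == "ED_MISMATCH"]
        assert len(mism) == 1
        assert mism[0].data["recomputed"] == pytest.approx(1.0, abs=1e-12)

    def test_dense_voxels_outside_all_structures_flagged_as_hardware(self):
        hu = np.full(self.shape, -1000.0)
        hu[:, 1:9, 1:9] = 0.0
        hu[:, 10:12, 1:9] = 400.0  # plate, not contoured
        ct = self._ct(hu)
        body = _mask(self.shape, np.s_[:, 1:9, 1:9], "Body")
        assignments = [EDAssignment("Body", 1, None)]
        syct = self._syct(ct, [body], assignments)
        out = troubleshoot(ct, [body], syct.assignment_table, syct, UNIT_CAL)
        hw = [f for f in out if f.code == "UNASSIGNED_HARDWARE"]
        assert len(hw) == 1
        assert hw[0].data["dense_voxels_outside_structures"] == 4 * 2 * 8

    def test_inhomogeneity_check_scoped_to_configured_classes(self):
        hu = np.zeros(self.shape)
        hu[:, :, :6] = -700.0
        ct = self._ct(hu)
        body = _mask(self.shape, np.s_[:, :, :], "Body")
        assignments = [EDAssignment("Body", 1, None)]
        syct = self._syct(ct, [body], assignments)
        config = QAConfig(assignments=assignments, body="Body", targets=[])
        out = troubleshoot(
            ct, [body], syct.assignment_table, syct, UNIT_CAL,
            TroubleshootThresholds(), config,
        )
        assert all(f.code != "INHOMOGENEOUS_STRUCTURE" for f in out)


class TestClassifyCohort:
    @staticmethod
    def _fake_report(verdict, body_rate, codes=()):
        from syctqa.qa_pipeline import Clause, QAReport
        from syctqa.syct_builder import Finding

        return QAReport(
            verdict=verdict,
            clauses=[Clause("gamma", "Body", body_rate, 99.0, verdict == "PASS", "%")],
            gamma_pass_rates={"3%/3mm": {"Body": body_rate}},
            metric_deltas=[],
            dvh_gaps={},
            findings=[Finding(c, "", "") for c in codes],
            provenance={},
        )

    def test_counts_and_tallies(self):
        reports = [
            self._fake_report("PASS", 99.7),
            self._fake_report("PASS", 100.0),
            self._fake_report("PASS", 99.9, ["ED_MISMATCH"]),
            self._fake_report("FAIL", 98.0, ["ED_MISMATCH", "PRIORITY_SHADOWING"]),
        ]
        summary = classify_cohort(reports)
        assert summary["counts"] == {"PASS": 3, "FAIL": 1}
        assert summary["finding_tallies"] == {"ED_MISMATCH": 2, "PRIORITY_SHADOWING": 1}

    def test_median_by_standard_rule(self):
        reports = [self._fake_report("PASS", r) for r in (99.7, 98.0, 100.0)]
        assert classify_cohort(reports)["body_pass_rate"]["median"] == 99.7

    def test_randomized_batch_matches_direct_recount(self):
        rng = np.random.default_rng(17)
        codes = ["A", "B", "C"]
        reports = []
        expected_counts = {"PASS": 0, "FAIL": 0}
        expected_tallies = {}
        for _ in range(40):
            verdict = "PASS" if rng.random() > 0.3 else "FAIL"
            picked = [c for c in codes if rng.random() > 0.6]
            reports.append(self._fake_report(verdict, float(rng.uniform(90, 100)), picked))
            expected_counts[verdict] += 1
            for c in picked:
                expected_tallies[c] = expected_tallies.get(c, 0) + 1
        summary = classify_cohort(reports)
        assert summary["counts"] == expected_counts
        assert summary["finding_tallies"] == expected_tallies

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            classify_cohort([])


class TestConfigRoundTrip:
    def test_yaml_dict_round_trip_preserves_semantics(self, concordant):
        config = case_config(concordant)
        back = QAConfig.from_dict(config.to_dict())
        assert back.digest() == config.digest()

    def test_tolerances_reject_nonpositive_thresholds(self):
        with pytest.raises(ValueError):
            ToleranceCriteria(gamma_pass_min=0.0)
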