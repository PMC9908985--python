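import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldassign import synthetic
from foldassign.model_io import ResidueRecord, StructureModel
from foldassign.quality import (MetricError, Thresholds, assign_ss,
                                calibrate_thresholds, find_lurs, lur_verdict,
                                mean_plddt, order_metrics, packing_density,
                                qc_verdict, ses_area_volume)


def brute_force_lurs(series, min_len=5, cut=70.0):
    """Exhaustive run scanner: test every (start, stop) window."""
    runs = []
    n = len(series)
    for start in range(n):
        for stop in range(start, n):
            if all(series[k] < cut for k in range(start, stop + 1)):
                maximal = ((start == 0 or series[start - 1] >= cut)
                           and (stop == n - 1 or series[stop + 1] >= cut))
                if maximal and stop - start + 1 >= min_len:
                    runs.append((start, stop))
    return runs


def brute_force_packing(model, cutoff=5.0, hydrophobic=frozenset("AVLIMFWC")):
    counts = []
    residues = model.residues
    for i, ri in enumerate(residues):
        if ri.aa not in hydrophobic:
            continue
        n = 0
        for j, rj in enumerate(residues):
            if i == j:
                continue
            close = any(
                np.linalg.norm(a - b) <= cutoff
                for a in ri.atoms.values() for b in rj.atoms.values())
            if close:
                n += 1
        counts.append(n)
    return float(np.mean(counts))


class TestMeanPlddt:
    def test_constant_and_mixture(self, helix20):
        assert mean_plddt(synthetic.inject_plddt(helix20, 70.0)) == 70.0
        profile = [60.0, 80.0] * 10
        assert mean_plddt(synthetic.inject_plddt(helix20, profile)) == 70.0

    def test_random_profile_matches_brute_force(self, compact_bundle):
        rng = np.random.default_rng(5)
        profile = np.round(rng.uniform(0, 100, compact_bundle.n_residues), 2)
        m = synthetic.inject_plddt(compact_bundle, profile)
        assert mean_plddt(m) == pytest.approx(sum(profile) / len(profile))


class TestFindLurs:
    def test_single_run(self):
        series = [80.0] * 10 + [60.0] * 6 + [90.0] * 10
        assert find_lurs(series) == [(10, 15)]

    def test_short_run_excluded(self):
        series = [90.0] * 10 + [50.0] * 4 + [90.0] * 10
        assert find_lurs(series) == []

    def test_run_at_series_end(self):
        assert find_lurs([90.0] * 5 + [10.0] * 5) == [(5, 9)]

    def test_oracle_equivalence_on_random_profiles(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            series = rng.choice([50.0, 69.9, 70.0, 95.0], size=n,
                                p=[0.3, 0.2, 0.2, 0.3])
            assert find_lurs(series) == brute_force_lurs(series)


class TestLurVerdict:
    def _with_dip(self, model, dip_len, n=100):
        profile = [90.0] * n
        for i in range(10, 10 + dip_len):
            profile[i] = 60.0
        return synthetic.inject_plddt(model, profile)

    @pytest.fixture(scope="class")
    def chain100(self):
        return synthetic.make_chain([synthetic.HELIX_PHI_PSI] * 100)

    def test_strictly_over_30_percent_fails(self, chain100):
        assert lur_verdict(self._with_dip(chain100, 31)) == "fail"

    def test_exactly_30_percent_passes(self, chain100):
        assert lur_verdict(self._with_dip(chain100, 30)) == "pass"

    def test_two_disjoint_short_lurs_pass(self, chain100):
        profile = [90.0] * 100
        for i in list(range(5, 25)) + list(range(50, 70)):
            profile[i] = 60.0
        m = synthetic.inject_plddt(chain100, profile)
        assert lur_verdict(m) == "pass"  # no *single* LUR above 30%


class TestAssignSS:
    def test_ideal_helix_one_element(self, helix20):
        ann = assign_ss(helix20)
        assert ann.per_residue.count("H") >= 16
        assert [e[0] for e in ann.elements] == ["H"]

    def test_isolated_strand_is_coil(self):
        strand = synthetic.make_ideal_strand(12)
        assert set(assign_ss(strand).per_residue) == {"C"}

    def test_antiparallel_sheet_has_strand_ladder(self, sheet):
        ann = assign_ss(sheet)
        kinds = [e[0] for e in ann.elements]
        assert kinds.count("E") >= 2

    def test_deterministic(self, compact_bundle):
        assert assign_ss(compact_bundle).per_residue == \
            assign_ss(compact_bundle).per_residue

    def test_missing_backbone_atom_raises(self, helix20):
        residues = [ResidueRecord(r.seq_index, r.aa,
                                  {k: v for k, v in r.atoms.items()
                                   if k != "O"}, r.plddt)
                    for r in helix20.residues]
        broken = StructureModel("x", residues)
        with pytest.raises(MetricError, match="O"):
            assign_ss(broken)


class TestOrderMetrics:
    def test_counts(self, compact_bundle):
        ann = assign_ss(compact_bundle)
        unordered, n_sses = order_metrics(ann)
        # independent counting straight off the annotation string
        assert unordered == ann.per_residue.count("C") / len(ann.per_residue)
        assert n_sses == len(ann.elements) == 3

    def test_all_coil(self):
        from foldassign.quality import SSEAnnotation
        assert order_metrics(SSEAnnotation("C" * 30, [])) == (1.0, 0)


class TestPackingDensity:
    def test_isolated_residues_zero(self):
        res = [
            ResidueRecord(1, "L", {"CA": np.zeros(3)}, 90.0),
            ResidueRecord(2, "V", {"CA": np.array([50.0, 0, 0])}, 90.0),
        ]
        assert packing_density(StructureModel("x", res)) == 0.0

    def test_mutual_triangle(self):
        res = [ResidueRecord(i + 1, "L", {"CA": c}, 90.0)
               for i, c in enumerate([np.zeros(3), np.array([3.0, 0, 0]),
                                      np.array([0, 3.0, 0])])]
        assert packing_density(StructureModel("x", res)) == 2.0

    def test_no_hydrophobic_raises(self):
        res = [ResidueRecord(i + 1, "S", {"CA": np.array([i * 3.0, 0, 0])},
                             90.0) for i in range(5)]
        with pytest.raises(MetricError):
            packing_density(StructureModel("x", res))

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            m = synthetic.make_decoy(40, seed=200 + trial)
            assert packing_density(m) == pytest.approx(
                brute_force_packing(m), abs=1e-12)


class TestSesAreaVolume:
    def test_sphere_closed_form(self):
        # one pseudo-atom of radius 1.7 (C), probe 0: area/volume = 3/r
        m = StructureModel("s", [ResidueRecord(1, "A", {"CA": np.zeros(3)},
                                               90.0)])
        area, volume = ses_area_volume(m, probe_radius=0.0, voxel=0.25)
        r = 1.70
        assert area == pytest.approx(4 * math.pi * r ** 2, rel=0.05)
        assert volume == pytest.approx(4 / 3 * math.pi * r ** 3, rel=0.05)
        assert area / volume == pytest.approx(3 / r, rel=0.05)

    def test_grid_convergence(self, compact_bundle):
        a1, v1 = ses_area_volume(compact_bundle, voxel=0.4)
        a2, v2 = ses_area_volume(compact_bundle, voxel=0.2)
        assert abs(a2 / a1 - 1) < 0.03
        assert abs(v2 / v1 - 1) < 0.03

    def test_extended_less_compact_than_bundle(self, compact_bundle):
        helix = synthetic.make_ideal_helix(compact_bundle.n_residues)
        a_h, v_h = ses_area_volume(helix)
        a_b, v_b = ses_area_volume(compact_bundle)
        assert a_h / v_h > a_b / v_b

    def test_degenerate_rejected(self):
        res = [ResidueRecord(i + 1, "A", {"CA": np.zeros(3)}, 90.0)
               for i in range(3)]
        with pytest.raises(MetricError):
            ses_area_volume(StructureModel("x", res))


class TestCalibration:
    @staticmethod
    def _reports(packing_values, ses_values):
        from foldassign.quality import QCReport
        return [QCReport(f"d{i}", 90.0, 100, 0.0, 0.3, 3, p, s * 10, 10.0, s)
                for i, (p, s) in enumerate(zip(packing_values, ses_values))]

    def test_interpolated_percentile(self):
        reports = self._reports(range(1, 101), np.linspace(0.1, 1.0, 100))
        t = calibrate_thresholds(reports)
        # order-statistics oracle: rank (n-1)*q = 94.05 between 95 and 96
        assert t.max_packing_density == pytest.approx(95.05, abs=1e-9)

    def test_constant_distribution(self):
        reports = self._reports([7.0] * 30, [0.4] * 30)
        t = calibrate_thresholds(reports)
        assert t.max_packing_density == 7.0
        assert t.max_ses_per_volume == 0.4

    def test_shipped_defaults_without_calibration(self):
        t = Thresholds()
        assert t.max_packing_density == 9.75
        assert t.max_ses_per_volume == 0.494

    def test_too_few_references(self):
        with pytest.raises(ValueError):
            calibrate_thresholds(self._reports([1.0] * 5, [0.1] * 5))

    def test_percentile_one_admits_whole_reference(self, calibrated_thresholds):
        reports = [qc_verdict(m, calibrated_thresholds)
                   for m in synthetic.make_reference_battery(0)]
        t = calibrate_thresholds(reports, percentile=1.0)
        for r in reports:
            assert r.packing_density <= t.max_packing_density
            assert r.ses_per_volume <= t.max_ses_per_volume


class TestQcVerdict:
    def test_compact_bundle_passes(self, compact_bundle, calibrated_thresholds):
        report = qc_verdict(compact_bundle, calibrated_thresholds)
        assert report.verdict == "pass"
        assert report.failed_rules == []

    def test_under_40_residues_fails_size(self, calibrated_thresholds):
        small = synthetic.make_bundle(3, 9, 8.5, loop_len=6)
        assert small.n_residues == 39
        report = qc_verdict(small, calibrated_thresholds)
        assert "min_residues" in report.failed_rules

    def test_all_failures_recorded(self, compact_bundle, calibrated_thresholds):
        bad = synthetic.inject_plddt(compact_bundle, 65.0)
        report = qc_verdict(bad, calibrated_thresholds)
        assert "min_mean_plddt" in report.failed_rules
        assert "max_single_lur_fraction" in report.failed_rules

    def test_planted_battery_per_rule_counts(self, calibrated_thresholds):
        from foldassign.quality import SSEAnnotation, _elements_from_string
        battery = synthetic.make_qc_battery(calibrated_thresholds)
        for model, truth, ss in battery:
            ann = None
            if ss is not None:
                ann = SSEAnnotation(ss, _elements_from_string(ss))
            report = qc_verdict(model, calibrated_thresholds, ss=ann)
            assert report.failed_rules == truth.planted_qc_violations, \
                model.protein_id

    def test_monotone_in_thresholds(self, calibrated_thresholds):
        import dataclasses
        spread = synthetic.make_bundle(3, 18, 28.0)
        t = calibrated_thresholds
        assert qc_verdict(spread, t).verdict == "fail"
        looser = dataclasses.replace(t, max_ses_per_volume=10.0,
                                     max_packing_density=1000.0)
        assert qc_verdict(spread, looser).verdict == "pass"


@settings(max_examples=300, derandomize=True, deadline=None)
@given(st.lists(st.sampled_from([40.0, 69.0, 70.0, 71.0, 99.0]),
                min_size=1, max_size=40))
def test_lur_property_matches_oracle(series):
    """Property: the run scanner equals the exhaustive window scan."""
    assert find_lurs(series) == brute_force_lurs(series)
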