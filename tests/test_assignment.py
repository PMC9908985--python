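import numpy as np
import pytest

from foldassign import synthetic
from foldassign.assignment import (AcceptanceThresholds, ComparisonResult,
                                   DomainLibrary, LibraryEntry,
                                   PredictionRecord, accept_hit,
                                   align_structures, cascade_assign,
                                   kabsch_superpose, scan_library, tm_d0,
                                   tm_score_from_distances)
from foldassign.model_io import ResidueRecord, StructureModel


def quaternion_rmsd(A, B):
    """Independent superposition oracle (Horn's quaternion method)."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    M = B.T @ A
    K = np.empty((4, 4))
    K[0, 0] = M[0, 0] + M[1, 1] + M[2, 2]
    K[0, 1] = K[1, 0] = M[1, 2] - M[2, 1]
    K[0, 2] = K[2, 0] = M[2, 0] - M[0, 2]
    K[0, 3] = K[3, 0] = M[0, 1] - M[1, 0]
    K[1, 1] = M[0, 0] - M[1, 1] - M[2, 2]
    K[1, 2] = K[2, 1] = M[0, 1] + M[1, 0]
    K[1, 3] = K[3, 1] = M[0, 2] + M[2, 0]
    K[2, 2] = -M[0, 0] + M[1, 1] - M[2, 2]
    K[2, 3] = K[3, 2] = M[1, 2] + M[2, 1]
    K[3, 3] = -M[0, 0] - M[1, 1] + M[2, 2]
    lam = np.linalg.eigvalsh(K)[-1]
    sq = max(0.0, (np.sum(A ** 2) + np.sum(B ** 2) - 2 * lam) / len(A))
    return np.sqrt(sq)


def rigid_copy(model, seed=0):
    rng = np.random.default_rng(seed)
    M = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(M) < 0:
        M[:, 0] *= -1
    t = rng.uniform(-20, 20, 3)
    residues = [ResidueRecord(r.seq_index, r.aa,
                              {k: M @ v + t for k, v in r.atoms.items()},
                              r.plddt) for r in model.residues]
    return StructureModel(model.protein_id, residues)


class TestKabsch:
    def test_self_superposition_exact(self, decoy60):
        A = decoy60.ca_coords()
        B = rigid_copy(decoy60, seed=4).ca_coords()
        _, _, rmsd = kabsch_superpose(A, B)
        assert rmsd <= 1e-6

    def test_single_displaced_atom_closed_form(self):
        rng = np.random.default_rng(1)
        n = 64
        A = rng.normal(scale=10, size=(n, 3))
        B = A.copy()
        # tiny displacement: rmsd ~= d/sqrt(n); the optimal transform can
        # only absorb an O(1/n) share of it, so d/sqrt(n) upper-bounds it
        d = 1e-3
        B[0, 0] += d
        _, _, rmsd = kabsch_superpose(A, B)
        assert rmsd <= d / np.sqrt(n)
        assert rmsd == pytest.approx(d / np.sqrt(n), rel=0.02)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            A = rng.normal(scale=8, size=(30, 3))
            B = A + rng.normal(scale=1.5, size=(30, 3))
            _, _, rmsd = kabsch_superpose(A, B)
            assert rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-8)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(10, 3))
        B = -A  # mirror image: best fit must still be a proper rotation
        R, _, _ = kabsch_superpose(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(10)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTmScore:
    def test_d0_formula(self):
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8)
        assert tm_d0(16) == 0.5  # floored

    def test_identity_is_one(self, decoy60):
        r = align_structures(decoy60, decoy60)
        assert r.score == pytest.approx(1.0, abs=1e-9)
        assert r.query_overlap == 1.0

    def test_rigid_motion_invariance(self, decoy60):
        r = align_structures(decoy60, rigid_copy(decoy60, seed=12))
        assert r.score == pytest.approx(1.0, abs=1e-6)
        assert r.rmsd <= 1e-6

    def test_homolog_vs_unrelated_separation(self, decoy60):
        near = synthetic.perturb(decoy60, 0.5, seed=2)
        far = synthetic.make_decoy(60, seed=777)
        assert align_structures(decoy60, near).score > 0.8
        assert align_structures(decoy60, far).score < 0.3

    def test_noise_monotonicity(self, decoy60):
        scores = [align_structures(decoy60,
                                   synthetic.perturb(decoy60, s, seed=5)).score
                  for s in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert scores == sorted(scores, reverse=True)

    def test_shorter_chain_normalization_symmetric(self, decoy60):
        big = synthetic.make_decoy(90, seed=31)
        r_ab = align_structures(decoy60, big)
        r_ba = align_structures(big, decoy60)
        n_short = min(decoy60.n_residues, big.n_residues)
        tm_ab = tm_score_from_distances(r_ab.aligned_distances, n_short)
        tm_ba = tm_score_from_distances(r_ba.aligned_distances, n_short)
        assert tm_ab == pytest.approx(tm_ba, abs=0.05)

    def test_too_short_rejected(self):
        tiny = synthetic.make_ideal_helix(10)
        with pytest.raises(ValueError):
            align_structures(tiny, tiny)


class TestAcceptHit:
    @staticmethod
    def _res(score, overlap, score_type="bitscore"):
        return ComparisonResult("q", "t", score, score_type, 60,
                                overlap, overlap, 1.0)

    def test_class1_bitscore_cut(self):
        assert accept_hit(self._res(120, 0.7), 1)
        assert accept_hit(self._res(106, 0.6), 3)
        assert not accept_hit(self._res(105.9, 0.7), 1)

    def test_class2_needs_165(self):
        assert not accept_hit(self._res(120, 0.7), 2)
        assert accept_hit(self._res(165, 0.7), 2)

    def test_overlap_gate_applies_regardless_of_score(self):
        assert not accept_hit(self._res(200, 0.5), 1)
        assert not accept_hit(self._res(0.99, 0.59, "tmscore"), 1)

    def test_no_class_uses_strictest(self):
        assert not accept_hit(self._res(120, 0.7), None)
        assert accept_hit(self._res(170, 0.7), None)

    def test_class4_requires_configuration(self):
        with pytest.raises(ValueError):
            accept_hit(self._res(200, 0.7), 4)
        t = AcceptanceThresholds(bitscore_by_class={1: 106, 2: 165, 3: 106,
                                                    4: 165})
        assert accept_hit(self._res(200, 0.7), 4, t)

    def test_tm_and_ssap_cuts(self):
        assert accept_hit(self._res(0.55, 0.8, "tmscore"), 1)
        assert not accept_hit(self._res(0.45, 0.8, "tmscore"), 1)
        assert accept_hit(self._res(85, 0.8, "ssap"), 1)
        assert not accept_hit(self._res(75, 0.8, "ssap"), 1)


class TestScanLibrary:
    @pytest.fixture(scope="class")
    def library(self):
        bench = synthetic.make_assignment_benchmark(
            n_superfamilies=5, n_representatives=1, n_queries=0,
            n_decoys=0, seed=3)
        return [LibraryEntry(d, sf, m) for d, sf, m in bench["library"]]

    def test_self_hit_is_maximal(self, library):
        query = library[0].model
        best = scan_library(query, library)
        assert best is not None
        assert best[1].domain_id == library[0].domain_id
        assert best[0].score == pytest.approx(1.0, abs=1e-9)

    def test_perturbed_copy_found_among_unrelated(self, library):
        query = synthetic.perturb(library[2].model, 0.5, seed=9)
        best = scan_library(query, library)
        assert best is not None and best[1].domain_id == library[2].domain_id

    def test_impossible_thresholds_give_none(self, library):
        t = AcceptanceThresholds(tm_min=1.1)
        assert scan_library(library[0].model, library, thresholds=t) is None


class TestCascade:
    @pytest.fixture(scope="class")
    def bench(self):
        return synthetic.make_assignment_benchmark(
            n_superfamilies=4, n_representatives=2, n_queries=4,
            n_decoys=2, sigma=0.5, seed=5)

    @pytest.fixture(scope="class")
    def library(self, bench):
        return DomainLibrary([LibraryEntry(d, sf, m)
                              for d, sf, m in bench["library"]])

    def test_confident_prediction_assigns_at_stage_one(self, bench, library):
        qid, model, sf = bench["queries"][0]
        decision = cascade_assign(
            model, library, prediction=PredictionRecord(qid, sf, 0.9))
        assert decision.stage == "predicted_superfamily_scan"
        assert decision.assigned_superfamily == sf

    def test_low_probability_prediction_discarded_but_recovered(
            self, bench, library):
        qid, model, sf = bench["queries"][1]
        decision = cascade_assign(
            model, library, prediction=PredictionRecord(qid, sf, 0.2))
        assert decision.stage == "all_scan"
        assert decision.assigned_superfamily == sf

    def test_unrelated_query_unassigned(self, bench, library):
        _, model = bench["decoys"][0]
        decision = cascade_assign(model, library)
        assert decision.stage == "unassigned"
        assert decision.assigned_superfamily == ""

    def test_decision_consistent_with_accept_hit(self, bench, library):
        qid, model, sf = bench["queries"][2]
        decision = cascade_assign(
            model, library, prediction=PredictionRecord(qid, sf, 0.9))
        assert decision.best_hit is not None
        assert accept_hit(decision.best_hit, int(sf.split(".")[0]))

    def test_library_order_invariance(self, bench):
        qid, model, sf = bench["queries"][3]
        entries = [LibraryEntry(d, s, m) for d, s, m in bench["library"]]
        a = cascade_assign(model, DomainLibrary(entries),
                           prediction=PredictionRecord(qid, sf, 0.9))
        b = cascade_assign(model, DomainLibrary(entries[::-1]),
                           prediction=PredictionRecord(qid, sf, 0.9))
        assert a.assigned_superfamily == b.assigned_superfamily

    def test_missing_library_is_an_error(self, bench):
        _, model, _ = bench["queries"][0]
        with pytest.raises(ValueError):
            cascade_assign(model, DomainLibrary([]))
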