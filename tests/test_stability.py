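"""Per-residue stability statistic, focal ordering and cumulative curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import resiflex as rf
from resiflex.errors import ResidueLookupError, ResiflexError

from conftest import toy_topology, random_frame


# ---------------------------------------------------------------------------
# independent naive-loop oracles

def oracle_residue_dist(frame, reference, topology):
    """residue_dist by explicit per-atom loops."""
    out = {}
    for num, atom_ids in topology.residue_atom_ids().items():
        total = 0.0
        for aid in atom_ids:
            i = topology.atom_index_of(aid)
            total += float(np.sqrt(((frame[i] - reference[i]) ** 2).sum()))
        out[num] = total / len(atom_ids)
    return out


def oracle_profile(traj, reference):
    """stability mean/std by explicit per-frame loops (J-1 denominator)."""
    per_frame = [oracle_residue_dist(traj.coordinates[j],
                                     reference.coordinates, traj.topology)
                 for j in range(traj.n_frames)]
    mean, std = {}, {}
    for num in per_frame[0]:
        vals = [pf[num] for pf in per_frame]
        m = sum(vals) / len(vals)
        mean[num] = m
        if len(vals) >= 2:
            std[num] = (sum((v - m) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
    return mean, std


def oracle_focal_dist(traj, focal):
    """mean center-to-center distance by explicit double loops."""
    top = traj.topology
    out = {}
    for num, atom_ids in top.residue_atom_ids().items():
        total = 0.0
        for j in range(traj.n_frames):
            def center(n):
                ids = top.residue_atom_ids()[n]
                pts = [traj.coordinates[j, top.atom_index_of(a)] for a in ids]
                return np.mean(pts, axis=0)
            total += float(np.linalg.norm(center(num) - center(focal)))
        out[num] = total / traj.n_frames
    return out


# ---------------------------------------------------------------------------

class TestAtomDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 0, 0), (3, 4, 0), 5.0),
        ((1.5, -2.0, 7.0), (1.5, -2.0, 7.0), 0.0),
        ((1, 1, 1), (2, 3, 5), np.sqrt(21.0)),
    ])
    def test_values(self, a, b, expected):
        assert rf.atom_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert rf.atom_distance(b, a) == rf.atom_distance(a, b)


class TestResidueDistance:
    def test_zero_against_itself(self):
        top = toy_topology([3])
        f = random_frame(top, np.random.default_rng(0))
        assert rf.residue_distance(f, f, 700) == 0.0

    def test_hand_computed_two_atom_residue(self):
        top = toy_topology([2])
        ref = rf.StructureFrame(top, [[0, 0, 0], [5, 5, 5]])
        frame = rf.StructureFrame(top, [[1, 0, 0], [5, 5, 8]])
        # displacements 1 A and 3 A -> mean 2 A
        assert rf.residue_distance(frame, ref, 700) == pytest.approx(2.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(12)
        top = toy_topology([5, 3, 4])
        ref = random_frame(top, rng)
        frame = random_frame(top, rng)
        expect = oracle_residue_dist(frame.coordinates, ref.coordinates, top)
        for num, val in expect.items():
            assert rf.residue_distance(frame, ref, num) == pytest.approx(
                val, abs=1e-12)

    def test_missing_residue(self):
        top = toy_topology([2])
        f = random_frame(top, np.random.default_rng(0))
        with pytest.raises(ResidueLookupError):
            rf.residue_distance(f, f, 999)


class TestStabilityProfile:
    def test_static_trajectory_all_zero(self):
        top = toy_topology([2, 3])
        ref = random_frame(top, np.random.default_rng(1))
        traj = rf.Trajectory(top, np.repeat(ref.coordinates[None], 5, axis=0))
        prof = rf.stability_profile(traj, ref)
        assert np.all(prof.mean == 0.0) and np.all(prof.std == 0.0)

    def test_two_point_formula(self):
        # single-atom residue at distances 1 and 3 from reference
        top = toy_topology([1])
        ref = rf.StructureFrame(top, [[0.0, 0.0, 0.0]])
        traj = rf.Trajectory(top, [[[1.0, 0, 0]], [[3.0, 0, 0]]])
        prof = rf.stability_profile(traj, ref)
        assert prof.mean[0] == pytest.approx(2.0)
        assert prof.std[0] == pytest.approx(np.sqrt(2.0))

    def test_single_frame_std_undefined(self):
        top = toy_topology([2])
        ref = random_frame(top, np.random.default_rng(2))
        traj = rf.Trajectory(top, ref.coordinates[None] + 1.0)
        prof = rf.stability_profile(traj, ref)
        assert prof.std is None
        assert prof.mean[0] == pytest.approx(np.sqrt(3.0))
        with pytest.raises(ResiflexError, match="J = 1"):
            prof.statistic("std")

    def test_matches_loop_oracle_on_random_instance(self):
        rng = np.random.default_rng(13)
        top = toy_topology([4, 2, 5, 3])
        traj = rf.Trajectory(top, rng.uniform(-8, 8, (20, top.n_atoms, 3)))
        ref = random_frame(top, rng)
        prof = rf.stability_profile(traj, ref)
        omean, ostd = oracle_profile(traj, ref)
        for i, num in enumerate(prof.residue_numbers.tolist()):
            assert prof.mean[i] == pytest.approx(omean[num], abs=1e-10)
            assert prof.std[i] == pytest.approx(ostd[num], abs=1e-10)


class TestFocalOrdering:
    def test_focal_residue_rank_zero(self, small_traj):
        _, traj = small_traj
        focal = int(traj.topology.residue_numbers[5])
        ordering = rf.focal_ordering(traj, focal)
        assert ordering.dist_for(focal) == 0.0
        assert ordering.rank_of(focal) == 0
        assert sorted(ordering.rank_order.tolist()) == \
            sorted(traj.topology.residue_numbers.tolist())  # bijection

    def test_single_frame_two_single_atom_residues(self):
        top = toy_topology([1, 1])
        traj = rf.Trajectory(top, [[[0, 0, 0], [0, 0, 7]]])
        ordering = rf.focal_ordering(traj, 700)
        assert ordering.dist_for(701) == pytest.approx(7.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(14)
        top = toy_topology([3, 1, 4, 2, 5, 2, 3, 1, 2, 4])
        traj = rf.Trajectory(top, rng.uniform(-10, 10, (7, top.n_atoms, 3)))
        focal = 704
        ordering = rf.focal_ordering(traj, focal)
        expect = oracle_focal_dist(traj, focal)
        for num, val in expect.items():
            assert ordering.dist_for(num) == pytest.approx(val, abs=1e-12)

    def test_absent_focal_names_available_range(self, small_traj):
        _, traj = small_traj
        with pytest.raises(ResidueLookupError, match="available residues"):
            rf.focal_ordering(traj, 12345)


class TestTrim:
    def _profile(self, start, n):
        top = toy_topology([1] * n, start=start)
        traj = rf.Trajectory(top, np.zeros((2, n, 3)))
        return rf.stability_profile(traj, traj.frame(0))

    def test_default_window_and_gaps(self):
        prof = self._profile(697, 323)  # spans 697-1019
        trimmed = rf.trim_to_range(prof)
        assert trimmed.residue_numbers[0] == 716
        assert trimmed.residue_numbers[-1] == 976

    def test_full_span_identity_and_single(self):
        prof = self._profile(700, 10)
        full = rf.trim_to_range(prof, 700, 709)
        assert np.array_equal(full.residue_numbers, prof.residue_numbers)
        single = rf.trim_to_range(prof, 705, 705)
        assert single.residue_numbers.tolist() == [705]

    def test_empty_result_errors(self):
        prof = self._profile(700, 10)
        with pytest.raises(ResidueLookupError):
            rf.trim_to_range(prof, 900, 950)
        with pytest.raises(ValueError):
            rf.trim_to_range(prof, 800, 700)


def _profile_and_ordering(values, positions=None):
    """Single-atom residues at given 1-D positions; J=2 identical frames so
    stds are zero; per-residue means forced to ``values`` via reference."""
    n = len(values)
    top = toy_topology([1] * n)
    pos = np.zeros((n, 3))
    pos[:, 0] = positions if positions is not None else np.arange(n)
    ref = rf.StructureFrame(top, pos)
    shifted = pos + np.array([[0.0, 0.0, 1.0]]) * np.asarray(values)[:, None]
    traj = rf.Trajectory(top, np.stack([shifted, shifted]))
    prof = rf.stability_profile(traj, ref)
    ordering = rf.focal_ordering(traj, 700)
    return prof, ordering


class TestCumulativeCurve:
    def test_constant_profile_constant_curve(self):
        prof, ordering = _profile_and_ordering([3.0] * 6)
        curve = rf.cumulative_average(prof, ordering)
        np.testing.assert_allclose(curve.values, 3.0)

    def test_running_mean_of_2_4_6(self):
        prof, ordering = _profile_and_ordering([2.0, 4.0, 6.0])
        curve = rf.cumulative_average(prof, ordering)
        np.testing.assert_allclose(curve.values, [2.0, 3.0, 4.0])

    def test_head_is_focal_and_endpoint_is_global_mean(self, small_traj):
        ref, traj = small_traj
        focal = int(traj.topology.residue_numbers[3])
        prof, ordering, curves = rf.analyze_trajectory(
            traj, original=ref, focal_residue_number=focal, trim=None)
        for stat in ("mean", "std"):
            curve = curves[stat]
            assert curve.values[0] == pytest.approx(
                prof.value_for(focal, stat), abs=1e-12)
            assert curve.values[-1] == pytest.approx(
                prof.statistic(stat).mean(), abs=1e-10)

    def test_matches_prefix_sum_oracle(self):
        rng = np.random.default_rng(15)
        vals = rng.uniform(0.1, 2.0, 17)
        prof, ordering = _profile_and_ordering(vals.tolist())
        curve = rf.cumulative_average(prof, ordering)
        s = {n: v for n, v in zip(prof.residue_numbers.tolist(), prof.mean)}
        expect = []
        acc = 0.0
        for k, num in enumerate(ordering.rank_order.tolist()):
            acc += s[num]
            expect.append(acc / (k + 1))
        np.testing.assert_allclose(curve.values, expect, atol=1e-12)

    def test_residue_set_mismatch_lists_difference(self):
        prof, ordering = _profile_and_ordering([1.0, 2.0, 3.0, 4.0])
        trimmed = rf.trim_to_range(prof, 700, 702)
        with pytest.raises(ResiflexError, match="703"):
            rf.cumulative_average(trimmed, ordering)


class TestCompareMutants:
    def _curve(self, vals):
        return rf.CumulativeCurve("mean", np.asarray(vals, float),
                                  np.arange(700, 700 + len(vals)), 700)

    def test_identical_curves_reported_as_tie(self):
        c = self._curve([1.0, 2.0, 3.0])
        res = rf.compare_mutants({"a": c, "b": self._curve([1.0, 2.0, 3.0])},
                                 k_window=3)
        assert res.ties == [("a", "b")]

    def test_single_curve(self):
        res = rf.compare_mutants({"only": self._curve([1.0, 2.0])}, k_window=2)
        assert res.least_stable == "only" and res.ties == []

    def test_higher_curve_ranks_less_stable(self):
        res = rf.compare_mutants(
            {"hot": self._curve([2.0, 2.0, 2.0]),
             "cold": self._curve([1.0, 1.0, 1.0])}, k_window=2)
        assert res.labels == ["hot", "cold"]
        assert res.k_window == 2

    def test_empty_set_and_bad_window(self):
        with pytest.raises(ResiflexError):
            rf.compare_mutants({}, k_window=5)
        with pytest.raises(ResiflexError, match="exceeds"):
            rf.compare_mutants({"a": self._curve([1.0])}, k_window=5)


class TestScalingAndProperties:
    def test_stability_mean_linear_in_sigma(self):
        """Doubling the fluctuation amplitude doubles every profile entry."""
        base = rf.TrajectoryRecipe(n_residues=10, atoms_per_residue=4,
                                   n_frames=800, per_residue_sigma=0.25,
                                   seed=21)
        big = rf.TrajectoryRecipe(n_residues=10, atoms_per_residue=4,
                                  n_frames=800, per_residue_sigma=0.75,
                                  seed=21)  # paired seed: identical unit noise
        ref = rf.make_reference(base)
        prof_a = rf.stability_profile(rf.generate_trajectory(ref, base), ref)
        prof_b = rf.stability_profile(rf.generate_trajectory(ref, big), ref)
        np.testing.assert_allclose(prof_b.mean / prof_a.mean, 3.0, rtol=1e-10)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_pipeline_matches_naive_oracle(self, seed):
        """Production segment reductions equal the naive loops (<= 20 residues,
        <= 50 frames) to 1e-10."""
        rng = np.random.default_rng(seed)
        n_res = int(rng.integers(2, 21))
        sizes = rng.integers(1, 6, n_res).tolist()
        top = toy_topology(sizes)
        J = int(rng.integers(2, 51))
        traj = rf.Trajectory(top, rng.uniform(-10, 10, (J, top.n_atoms, 3)))
        ref = random_frame(top, rng)
        prof = rf.stability_profile(traj, ref)
        omean, ostd = oracle_profile(traj, ref)
        for i, num in enumerate(prof.residue_numbers.tolist()):
            assert abs(prof.mean[i] - omean[num]) < 1e-10
            assert abs(prof.std[i] - ostd[num]) < 1e-10
        focal = int(rng.choice(top.residue_numbers))
        ordering = rf.focal_ordering(traj, focal)
        ofocal = oracle_focal_dist(traj, focal)
        for num, val in ofocal.items():
            assert abs(ordering.dist_for(num) - val) < 1e-10
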