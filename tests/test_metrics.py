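import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalseg.metrics import (DiceReport, HecDefinition, binarize,
                              boundary_voxels, dice_report, hecs_for,
                              mean_dice, smoothed_dice, surface_dice)


def brute_force_surface_dice(a, b, spacing, tolerance):
    """O(n^2) all-pairs oracle over boundary voxel coordinates."""
    sa = np.argwhere(boundary_voxels(a)) * np.asarray(spacing)
    sb = np.argwhere(boundary_voxels(b)) * np.asarray(spacing)
    if len(sa) == 0 and len(sb) == 0:
        return 1.0
    if len(sa) == 0 or len(sb) == 0:
        return 0.0
    d = np.linalg.norm(sa[:, None, :] - sb[None, :, :], axis=-1)
    matched_a = int((d.min(axis=1) <= tolerance + 1e-9).sum())
    matched_b = int((d.min(axis=0) <= tolerance + 1e-9).sum())
    return (matched_a + matched_b) / (len(sa) + len(sb))


class TestSmoothedDice:
    def test_both_empty_is_one(self):
        z = np.zeros((3, 3, 3), dtype=bool)
        assert smoothed_dice(z, z) == 1.0

    def test_identical_masks(self):
        m = np.zeros((2, 5, 5), dtype=bool)
        m[0, 1:3, 1:6] = True  # 10 voxels: (2*10+1)/(10+10+1) = 1.0
        assert smoothed_dice(m, m) == 1.0

    def test_partial_overlap_oracle(self):
        # |a|=5, |b|=3, overlap 2 -> (2*2+1)/(5+3+1) = 5/9
        a = np.zeros((1, 1, 10), dtype=bool)
        b = np.zeros((1, 1, 10), dtype=bool)
        a[0, 0, :5] = True
        b[0, 0, 3:6] = True
        assert smoothed_dice(a, b) == pytest.approx(5 / 9)

    def test_symmetry_and_shape_check(self, rng):
        a = rng.uniform(size=(4, 4, 4)) > 0.5
        b = rng.uniform(size=(4, 4, 4)) > 0.5
        assert smoothed_dice(a, b) == smoothed_dice(b, a)
        with pytest.raises(ValueError, match="mismatch"):
            smoothed_dice(a, b[:2])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_set_arithmetic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(size=(3, 4, 4)) > 0.6
        b = rng.uniform(size=(3, 4, 4)) > 0.6
        expected = (2 * np.sum(a & b) + 1) / (np.sum(a) + np.sum(b) + 1)
        assert smoothed_dice(a, b) == pytest.approx(expected)

    def test_approaches_classical_dice_for_large_masks(self, rng):
        a = rng.uniform(size=(20, 20, 20)) > 0.3
        b = rng.uniform(size=(20, 20, 20)) > 0.3
        classical = 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))
        assert abs(smoothed_dice(a, b) - classical) < 1 / (np.sum(a) + np.sum(b))


class TestHecs:
    def test_kits21_compositions(self):
        by_name = {h.name: h.foreground_labels for h in hecs_for("kits21")}
        assert by_name == {"kidney": {1, 2, 3}, "mass": {2, 3},
                           "tumor": {2}, "cyst": {3}}

    def test_kits19_compositions(self):
        by_name = {h.name: h.foreground_labels for h in hecs_for("kits19")}
        assert by_name == {"kidney": {1, 2}, "tumor": {2}}

    def test_mass_ignores_kidney_errors(self):
        label = np.zeros((1, 4, 4), dtype=np.int16)
        label[0, 0, :] = 1   # kidney row
        label[0, 1, :] = 2   # tumor row
        label[0, 2, :] = 3   # cyst row
        pred = label.copy()
        pred[0, 0, :] = 0    # kidney entirely missed
        mass = next(h for h in hecs_for("kits21") if h.name == "mass")
        assert mean_dice([(label, pred)], mass) == 1.0

    def test_identity_scores_one_for_every_hec(self, rng):
        label = rng.integers(0, 4, size=(3, 5, 5)).astype(np.int16)
        for hec in hecs_for("kits21"):
            assert mean_dice([(label, label)], hec) == 1.0


class TestMeanDice:
    def test_single_perfect_case(self):
        lab = np.ones((1, 2, 2), dtype=np.int16)
        hec = HecDefinition("kidney", frozenset({1}))
        assert mean_dice([(lab, lab)], hec) == 1.0

    def test_arithmetic_mean_of_per_case_scores(self):
        hec = HecDefinition("tumor", frozenset({2}))
        lab1 = np.full((1, 1, 5), 2, dtype=np.int16)
        # case 2 engineered to score 5/9 (|a|=5, |b|=3, overlap 2)
        a = np.zeros((1, 1, 10), dtype=np.int16)
        b = np.zeros((1, 1, 10), dtype=np.int16)
        a[0, 0, :5] = 2
        b[0, 0, 3:6] = 2
        assert mean_dice([(lab1, lab1), (a, b)], hec) == pytest.approx(
            (1.0 + 5 / 9) / 2)

    def test_permutation_invariance(self, rng):
        hec = HecDefinition("kidney", frozenset({1}))
        cases = [(rng.integers(0, 2, size=(2, 3, 3)).astype(np.int16),
                  rng.integers(0, 2, size=(2, 3, 3)).astype(np.int16))
                 for _ in range(4)]
        assert mean_dice(cases, hec) == pytest.approx(
            mean_dice(list(reversed(cases)), hec))

    def test_empty_case_list_raises(self):
        with pytest.raises(ValueError):
            mean_dice([], HecDefinition("kidney", frozenset({1})))


class TestBoundary:
    def test_solid_cube_boundary_is_shell(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[1:5, 1:5, 1:5] = True
        shell = boundary_voxels(m)
        assert shell.sum() == 4 ** 3 - 2 ** 3
        assert not shell[2:4, 2:4, 2:4].any()

    def test_volume_edge_counts_as_background(self):
        m = np.ones((3, 3, 3), dtype=bool)
        assert boundary_voxels(m).sum() == 26  # all but the centre voxel


class TestSurfaceDice:
    def test_identical_masks_score_one(self):
        m = np.zeros((5, 8, 8), dtype=bool)
        m[1:4, 2:6, 2:6] = True
        assert surface_dice(m, m, tolerance=0.0) == 1.0

    def test_one_voxel_offset_within_tolerance(self):
        a = np.zeros((4, 8, 8), dtype=bool)
        b = np.zeros((4, 8, 8), dtype=bool)
        a[1:3, 2:5, 2:5] = True
        b[1:3, 3:6, 2:5] = True  # shifted one voxel along rows
        assert surface_dice(a, b, spacing=(1, 1, 1), tolerance=1.0) == 1.0

    def test_empty_conventions(self):
        z = np.zeros((3, 3, 3), dtype=bool)
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        assert surface_dice(z, z) == 1.0
        assert surface_dice(z, m) == 0.0
        assert surface_dice(m, z) == 0.0

    def test_negative_tolerance_rejected(self):
        z = np.zeros((2, 2, 2), dtype=bool)
        with pytest.raises(ValueError):
            surface_dice(z, z, tolerance=-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = np.zeros((8, 10, 10), dtype=bool)
        b = np.zeros((8, 10, 10), dtype=bool)
        # random blobs
        for m in (a, b):
            c = rng.integers(2, 7, size=3)
            r = rng.integers(2, 4)
            grids = np.ogrid[:8, :10, :10]
            m[sum((g - ci) ** 2 for g, ci in zip(grids, c)) <= r ** 2] = True
        spacing = tuple(rng.uniform(0.5, 3.0, size=3))
        for tol in (0.0, 1.0, 2.5, 5.0):
            assert surface_dice(a, b, spacing, tol) == pytest.approx(
                brute_force_surface_dice(a, b, spacing, tol))

    def test_anisotropic_spacing_matters(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[2, 2, 2] = True
        b[3, 2, 2] = True  # one step along axis 0
        assert surface_dice(a, b, spacing=(3.0, 1.0, 1.0), tolerance=1.0) == 0.0
        assert surface_dice(a, b, spacing=(3.0, 1.0, 1.0), tolerance=3.0) == 1.0

    def test_monotone_in_tolerance(self, rng):
        a = rng.uniform(size=(6, 8, 8)) > 0.7
        b = rng.uniform(size=(6, 8, 8)) > 0.7
        scores = [surface_dice(a, b, tolerance=t) for t in (0, 0.5, 1, 2, 4, 8)]
        assert all(s1 <= s2 + 1e-12 for s1, s2 in zip(scores, scores[1:]))


class TestDiceReport:
    def test_perfect_prediction_means_one(self, small_phantom):
        _, label = small_phantom
        report = dice_report({"case_0": (label, label)}, vocabulary="kits21")
        for hec, metrics_ in report.mean.items():
            assert metrics_["dice"] == 1.0
            assert metrics_["surface_dice"] == 1.0

    def test_kits19_report_has_two_hecs(self):
        lab = np.zeros((2, 4, 4), dtype=np.int16)
        lab[0, 0, 0] = 1
        report = dice_report({"c": (lab, lab)}, vocabulary="kits19")
        assert set(report.per_case["c"]) == {"kidney", "tumor"}

    def test_rows_include_mean(self):
        lab = np.zeros((2, 4, 4), dtype=np.int16)
        report = dice_report({"c1": (lab, lab), "c2": (lab, lab)},
                             vocabulary="kits19", compute_surface=False)
        rows = report.to_rows()
        assert sum(1 for r in rows if r["case"] == "MEAN") == 2
        assert sum(1 for r in rows if r["case"] != "MEAN") == 4
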