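import math
from collections import deque
from itertools import product

import numpy as np
import pytest
from scipy import stats

from cortseg.evaluation import (LesionComponent, MetricsReport, apply_min_size,
                                compare_methods, connected_components,
                                evaluate_case, lesion_detection,
                                min_lesion_volume_ul, size_stratified_detection,
                                spherical_volume_mm3, volume_correlation,
                                voxel_metrics)
from cortseg.volumes_io import LabelVolume

# ---------------------------------------------------------------- oracles

_OFFSETS = {
    6: [o for o in product((-1, 0, 1), repeat=3) if sum(map(abs, o)) == 1],
    18: [o for o in product((-1, 0, 1), repeat=3) if 1 <= sum(map(abs, o)) <= 2],
    26: [o for o in product((-1, 0, 1), repeat=3) if any(o)],
}


def flood_fill_components(mask, connectivity):
    """Brute-force BFS flood fill; returns a list of frozen voxel sets."""
    mask = np.asarray(mask) != 0
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in _OFFSETS[connectivity]:
                n = tuple(a + b for a, b in zip(v, off))
                if all(0 <= c < s for c, s in zip(n, mask.shape)) and mask[n] and not seen[n]:
                    seen[n] = True
                    queue.append(n)
        comps.append(frozenset(comp))
    return comps


def pairwise_overlap_detection(gt_sets, pred_sets):
    """O(n^2) oracle for lesion matching."""
    detected = [any(g & p for p in pred_sets) for g in gt_sets]
    false_pos = [not any(p & g for g in gt_sets) for p in pred_sets]
    ltpr = sum(detected) / len(gt_sets) if gt_sets else math.nan
    lfpr = sum(false_pos) / len(pred_sets) if pred_sets else math.nan
    return ltpr, lfpr


def _components_from_sets(sets, lesion_type="untyped"):
    return [LesionComponent(voxels=np.array(sorted(s)), size=len(s),
                            volume_ul=float(len(s)), lesion_type=lesion_type)
            for s in sets]


# ------------------------------------------------------- connected components

class TestConnectedComponents:
    def test_face_neighbours_one_component_any_connectivity(self):
        grid = np.zeros((4, 4, 4), np.uint8)
        grid[1, 1, 1] = grid[1, 1, 2] = 1
        for conn in (6, 18, 26):
            assert len(connected_components(grid, conn)) == 1

    def test_corner_neighbours_split_by_connectivity(self):
        grid = np.zeros((4, 4, 4), np.uint8)
        grid[1, 1, 1] = grid[2, 2, 2] = 1
        assert len(connected_components(grid, 26)) == 1
        assert len(connected_components(grid, 6)) == 2
        # edge-sharing pair: joined at 18, split at 6
        grid2 = np.zeros((4, 4, 4), np.uint8)
        grid2[1, 1, 1] = grid2[1, 2, 2] = 1
        assert len(connected_components(grid2, 18)) == 1
        assert len(connected_components(grid2, 6)) == 2

    def test_typed_extraction_keeps_touching_lesions_distinct(self):
        grid = np.zeros((4, 4, 4), np.uint8)
        grid[1, 1, 1] = 1
        grid[1, 1, 2] = 2  # face-adjacent WML and CL
        comps = connected_components(grid, 18, typed=True)
        assert sorted(c.lesion_type for c in comps) == ["CL", "WML"]

    def test_unknown_connectivity_rejected(self):
        with pytest.raises(ValueError, match="connectivity"):
            connected_components(np.zeros((3, 3, 3), np.uint8), 10)

    @pytest.mark.parametrize("conn", [6, 18, 26])
    def test_matches_flood_fill_oracle_on_random_masks(self, conn, rng):
        for _ in range(25):
            mask = (rng.random((20, 20, 20)) < 0.08).astype(np.uint8)
            comps = connected_components(mask, conn)
            oracle = flood_fill_components(mask, conn)
            assert len(comps) == len(oracle)
            assert {frozenset(map(tuple, c.voxels)) for c in comps} == set(oracle)

    def test_volume_uses_spacing_exactly(self):
        grid = np.zeros((4, 4, 4), np.uint8)
        grid[0, 0, :3] = 1
        comp, = connected_components(grid, 18, spacing=(1.0, 1.0, 1.2))
        assert comp.volume_ul == pytest.approx(3 * 1.2)


class TestApplyMinSize:
    def test_three_voxel_rule(self):
        grid = np.zeros((10, 10, 10), np.uint8)
        grid[1, 1, :2] = 1            # size 2: removed
        grid[4, 4, :3] = 1            # size 3: kept
        grid[7, 7, :7] = 1            # size 7: kept
        out = apply_min_size(grid, 3)
        assert len(connected_components(out, 18)) == 2
        assert not out[1, 1, :2].any()

    def test_min_one_is_identity_and_filter_idempotent(self, rng):
        mask = (rng.random((15, 15, 15)) < 0.1).astype(np.uint8)
        np.testing.assert_array_equal(apply_min_size(mask, 1), mask)
        once = apply_min_size(mask, 3)
        np.testing.assert_array_equal(apply_min_size(once, 3), once)

    def test_component_count_monotone_in_min_size(self, rng):
        mask = (rng.random((15, 15, 15)) < 0.15).astype(np.uint8)
        counts = [len(connected_components(apply_min_size(mask, m), 18))
                  for m in (1, 2, 3, 5, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_min_size(self):
        with pytest.raises(ValueError):
            apply_min_size(np.zeros((3, 3, 3), np.uint8), 0)

    def test_typed_grid_filtered_per_label(self):
        grid = np.zeros((8, 8, 8), np.uint8)
        grid[1, 1, :2] = 1  # small WML: removed
        grid[4, 4, :4] = 2  # CL of 4: kept
        out = apply_min_size(grid, 3)
        assert not (out == 1).any()
        assert (out == 2).sum() == 4


# ------------------------------------------------------------- voxel metrics

class TestVoxelMetrics:
    def test_identity_masks(self):
        g = np.zeros((5, 5, 5), np.uint8)
        g[2, 2, :3] = 1
        m = voxel_metrics(g, g)
        assert (m["dsc"], m["ppv"], m["avd"]) == (1.0, 1.0, 0.0)

    def test_hand_computed_half_overlap(self):
        p = np.zeros((3, 3, 3), np.uint8)
        g = np.zeros((3, 3, 3), np.uint8)
        p[0, 0, 0] = p[0, 0, 1] = 1
        g[0, 0, 1] = g[0, 0, 2] = 1
        m = voxel_metrics(p, g)
        assert m["dsc"] == pytest.approx(0.5)
        assert m["ppv"] == pytest.approx(0.5)
        assert m["avd"] == pytest.approx(0.0)

    def test_subset_avd(self):
        g = np.zeros((4, 4, 4), np.uint8)
        g.flat[:10] = 1
        p = np.zeros((4, 4, 4), np.uint8)
        p.flat[:8] = 1
        assert voxel_metrics(p, g)["avd"] == pytest.approx(0.2)

    def test_empty_gt_flagged_missing(self):
        p = np.zeros((3, 3, 3), np.uint8)
        p[0, 0, 0] = 1
        m = voxel_metrics(p, np.zeros((3, 3, 3), np.uint8))
        assert math.isnan(m["dsc"]) and math.isnan(m["avd"])
        assert m["ppv"] == 0.0

    def test_empty_pred_flags_ppv(self):
        g = np.zeros((3, 3, 3), np.uint8)
        g[0, 0, 0] = 1
        m = voxel_metrics(np.zeros((3, 3, 3), np.uint8), g)
        assert math.isnan(m["ppv"])
        assert m["dsc"] == 0.0

    def test_dsc_symmetric_avd_not(self, rng):
        a = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        b = (rng.random((8, 8, 8)) < 0.2).astype(np.uint8)
        assert voxel_metrics(a, b)["dsc"] == pytest.approx(voxel_metrics(b, a)["dsc"])
        assert voxel_metrics(a, b)["avd"] != voxel_metrics(b, a)["avd"]


# ---------------------------------------------------------- lesion detection

class TestLesionDetection:
    def test_hand_enumerated_example(self):
        """GT: WML A, WML B, CL C; prediction hits A and C; one pred is FP."""
        A = {(0, 0, 0), (0, 0, 1)}
        B = {(5, 5, 5), (5, 5, 6)}
        C = {(9, 9, 9)}
        gt = (_components_from_sets([A, B], "WML") + _components_from_sets([C], "CL"))
        preds = _components_from_sets([{(0, 0, 1)}, {(9, 9, 9), (9, 9, 8)}, {(3, 3, 3)}])
        m = lesion_detection(gt, preds)
        assert m["ltpr"] == pytest.approx(2 / 3)
        assert m["ltpr_wm"] == pytest.approx(1 / 2)
        assert m["ltpr_cl"] == pytest.approx(1.0)
        assert m["lfpr"] == pytest.approx(1 / 3)

    def test_perfect_prediction(self):
        s = [{(0, 0, 0), (0, 0, 1)}, {(4, 4, 4)}]
        gt = _components_from_sets(s, "WML")
        m = lesion_detection(gt, _components_from_sets(s))
        assert (m["ltpr"], m["lfpr"]) == (1.0, 0.0)

    def test_empty_prediction_flags_lfpr(self):
        gt = _components_from_sets([{(0, 0, 0)}], "WML")
        m = lesion_detection(gt, [])
        assert m["ltpr"] == 0.0
        assert math.isnan(m["lfpr"])
        assert math.isnan(m["ltpr_cl"])  # no CL in GT either

    def test_bridging_prediction_detects_both_and_is_not_fp(self):
        wml = _components_from_sets([{(0, 0, 0)}], "WML")
        cl = _components_from_sets([{(0, 0, 2)}], "CL")
        bridge = _components_from_sets([{(0, 0, 0), (0, 0, 1), (0, 0, 2)}])
        m = lesion_detection(wml + cl, bridge)
        assert m["ltpr"] == 1.0 and m["lfpr"] == 0.0

    def test_matches_pairwise_overlap_oracle_on_random_masks(self, rng):
        for _ in range(25):
            gt_mask = (rng.random((20, 20, 20)) < 0.05).astype(np.uint8)
            pred_mask = (rng.random((20, 20, 20)) < 0.05).astype(np.uint8)
            gt_sets = flood_fill_components(gt_mask, 18)
            pred_sets = flood_fill_components(pred_mask, 18)
            m = lesion_detection(_components_from_sets(gt_sets, "WML"),
                                 _components_from_sets(pred_sets))
            ltpr, lfpr = pairwise_overlap_detection(gt_sets, pred_sets)
            for got, want in ((m["ltpr"], ltpr), (m["lfpr"], lfpr)):
                assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want)

    def test_ltpr_is_count_weighted_mean_of_type_rates(self, rng):
        for _ in range(10):
            gt_mask = (rng.random((15, 15, 15)) < 0.06).astype(np.uint8)
            pred_mask = (rng.random((15, 15, 15)) < 0.06).astype(np.uint8)
            sets = flood_fill_components(gt_mask, 18)
            if len(sets) < 2:
                continue
            half = len(sets) // 2
            gt = (_components_from_sets(sets[:half], "WML")
                  + _components_from_sets(sets[half:], "CL"))
            m = lesion_detection(gt, _components_from_sets(
                flood_fill_components(pred_mask, 18)))
            n_wm, n_cl = half, len(sets) - half
            expected = (m["ltpr_wm"] * n_wm + m["ltpr_cl"] * n_cl) / (n_wm + n_cl)
            assert m["ltpr"] == pytest.approx(expected)


class TestSizeStratifiedDetection:
    def test_single_bin_equals_overall_ltpr(self, rng):
        gt_mask = (rng.random((15, 15, 15)) < 0.08).astype(np.uint8)
        pred_mask = (rng.random((15, 15, 15)) < 0.08).astype(np.uint8)
        gt = _components_from_sets(flood_fill_components(gt_mask, 18), "WML")
        pred = _components_from_sets(flood_fill_components(pred_mask, 18))
        overall = lesion_detection(gt, pred)["ltpr"]
        table = size_stratified_detection(gt, pred, [(1, None)])
        assert table.loc[0, "detection_rate"] == pytest.approx(overall)
        assert table.loc[0, "n_gt"] == len(gt)

    def test_hand_assigned_bins(self):
        detected = [{(0, 0, z) for z in range(12)}, {(5, y, 0) for y in range(15)}]
        missed = [{(9, 9, z) for z in range(4)}]
        gt = _components_from_sets(detected + missed, "WML")
        pred = _components_from_sets([set.union(*[set(s) for s in detected])])
        table = size_stratified_detection(gt, pred, [(3, 11), (11, None)])
        assert table.loc[0, "detection_rate"] == 0.0   # the size-4 lesion
        assert table.loc[1, "detection_rate"] == 1.0   # sizes 12 and 15
        assert list(table["n_gt"]) == [1, 2]

    def test_half_open_boundary_convention(self):
        ten = _components_from_sets([{(0, 0, z) for z in range(10)}], "WML")
        table = size_stratified_detection(ten, [], [(3, 10), (10, None)])
        assert table.loc[0, "n_gt"] == 0
        assert table.loc[1, "n_gt"] == 1

    def test_non_contiguous_bins_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            size_stratified_detection([], [], [(3, 10), (12, None)])


# ------------------------------------------------------- cohort-level stats

class TestVolumeCorrelation:
    def test_identity_and_linearity(self):
        v = [100.0, 220.0, 310.0, 400.0, 520.0]
        m = volume_correlation(v, v)
        assert m["r"] == pytest.approx(1.0)
        assert m["slope"] == pytest.approx(1.0) and m["intercept"] == pytest.approx(0.0)
        d = volume_correlation(v, [2 * x for x in v])
        assert d["r"] == pytest.approx(1.0) and d["slope"] == pytest.approx(2.0)

    def test_matches_textbook_covariance_formula(self):
        m = [3.0, 8.0, 10.0, 17.0, 24.0]
        a = [5.0, 12.0, 14.0, 13.0, 29.0]
        got = volume_correlation(m, a)["r"]
        mm, aa = np.array(m), np.array(a)
        want = (((mm - mm.mean()) * (aa - aa.mean())).sum()
                / np.sqrt(((mm - mm.mean()) ** 2).sum() * ((aa - aa.mean()) ** 2).sum()))
        assert got == pytest.approx(want, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            volume_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareMethods:
    def test_bonferroni_arithmetic(self, rng):
        a = rng.random(12)
        b = a + rng.random(12) * 0.5 + 0.2  # systematic difference
        res = compare_methods(a, b, n_comparisons=3)
        assert res["p_adjusted"] == pytest.approx(min(1.0, res["p_raw"] * 3))
        res1 = compare_methods(a, b, n_comparisons=1)
        assert res1["p_adjusted"] == pytest.approx(res1["p_raw"])

    def test_identical_samples_flagged_undefined(self):
        a = np.arange(8.0)
        res = compare_methods(a, a.copy())
        assert res["undefined"] and math.isnan(res["p_raw"])

    def test_statistic_matches_signed_rank_oracle(self):
        a = np.array([1.0, 2.0, 3.5, 4.0, 6.0, 7.5, 9.0, 10.0])
        b = np.array([1.2, 1.0, 3.0, 5.5, 5.0, 7.0, 9.5, 8.0])
        d = a - b
        ranks = stats.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        w_minus = ranks[d < 0].sum()
        res = compare_methods(a, b)
        assert res["statistic"] == pytest.approx(min(w_plus, w_minus))


class TestReportAggregation:
    def test_median_iqr_on_five_subject_table(self):
        rows = {f"s{i}": dict(dsc=v, avd=0.1 * i, ppv=0.5, ltpr=1.0, ltpr_wm=1.0,
                              ltpr_cl=float("nan"), lfpr=0.0,
                              manual_volume_ul=100.0, auto_volume_ul=90.0)
                for i, v in enumerate([0.2, 0.4, 0.5, 0.7, 0.9])}
        summary = MetricsReport.from_rows(rows).cohort_summary()
        assert summary.loc["dsc", "median"] == pytest.approx(0.5)
        assert summary.loc["dsc", "iqr"] == pytest.approx(0.7 - 0.4)
        assert summary.loc["ltpr_cl", "n"] == 0  # all-NaN column excluded

    def test_evaluate_case_end_to_end(self, small_truth):
        gt = small_truth.case.gt
        pred = LabelVolume((gt.labels != 0).astype(np.uint8), gt.spacing, gt.affine)
        row = evaluate_case(pred, gt)
        assert row["dsc"] == pytest.approx(1.0)
        assert row["ltpr"] == 1.0 and row["lfpr"] == 0.0
        assert row["manual_volume_ul"] == pytest.approx(row["auto_volume_ul"])


def test_minimum_lesion_physical_volumes():
    """3 voxels = 3 uL at 1 mm isotropic, 3.6 uL at 1 x 1 x 1.2 mm."""
    assert min_lesion_volume_ul((1.0, 1.0, 1.0)) == pytest.approx(3.0)
    assert min_lesion_volume_ul((1.0, 1.0, 1.2)) == pytest.approx(3.6)


def test_clinical_sphere_volume():
    """A 3-mm-diameter sphere holds about 14 mm^3."""
    assert spherical_volume_mm3(3.0) == pytest.approx(14.137, abs=0.001)
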