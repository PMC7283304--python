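"""Threshold grids, overlap scoring, ROC construction and optima."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctperf.perfusion import ParametricMapSet, compute_relative_maps
from ctperf.threshold_eval import (
    TABLE_GRIDS,
    AtsDefaultRule,
    ConfusionCounts,
    InvalidGridError,
    ats_default_prediction,
    binarize,
    confusion,
    dice,
    make_threshold_grid,
    optimal_threshold,
    per_subject_distribution,
    pooled_optimal_threshold,
    roc_curve,
    sweep_counts,
    youden,
)

FULL = np.ones((2, 2, 1), dtype=bool)


class TestThresholdGrid:
    @pytest.mark.parametrize("param,count", [
        ("tmax", 31), ("mtt", 39), ("cbf", 90), ("cbv", 91),
        ("cbv_rel", 70), ("mtt_rel", 60), ("cbf_rel", 60), ("tmax_rel", 80),
    ])
    def test_published_grid_counts(self, param, count):
        grid = TABLE_GRIDS[param]
        # enumeration oracle: count values min, min+inc, ... <= max + tol
        k, vals = 0, []
        while grid.minimum + k * grid.increment <= grid.maximum + 1e-9:
            vals.append(grid.minimum + k * grid.increment)
            k += 1
        assert len(grid) == count == len(vals)
        np.testing.assert_allclose(grid.values, vals, atol=1e-12)

    def test_endpoint_always_included(self):
        grid = make_threshold_grid("tmax", 1.0, 16.0, 0.5)
        assert grid.values[-1] == pytest.approx(16.0)
        grid = make_threshold_grid("mtt", 0.1, 0.7, 0.2)
        np.testing.assert_allclose(grid.values, [0.1, 0.3, 0.5, 0.7])

    def test_simple_two_value_grid(self):
        np.testing.assert_array_equal(
            make_threshold_grid("mtt", 1.0, 2.0, 1.0).values, [1.0, 2.0])

    def test_invalid_grids_rejected(self):
        with pytest.raises(InvalidGridError):
            make_threshold_grid("mtt", 2.0, 1.0, 0.5)
        with pytest.raises(InvalidGridError):
            make_threshold_grid("mtt", 1.0, 2.0, -0.5)
        with pytest.raises(InvalidGridError, match="tmax_rel"):
            make_threshold_grid("tmaxx", 1.0, 2.0, 0.5)


class TestBinarize:
    def test_above_rule(self):
        vol = np.array([[2.0, 7.0], [5.0, 9.0]])[:, :, None]
        out = binarize(vol, 6.0, "above", np.ones_like(vol, dtype=bool))
        np.testing.assert_array_equal(out[:, :, 0], [[0, 1], [0, 1]])

    def test_below_rule(self):
        vol = np.array([[0.3, 0.9]])[:, :, None]
        out = binarize(vol, 0.6, "below", np.ones_like(vol, dtype=bool))
        np.testing.assert_array_equal(out[:, :, 0], [[1, 0]])

    def test_threshold_above_max_empty(self):
        vol = np.random.default_rng(0).random((3, 3, 2))
        assert not binarize(vol, 2.0, "above", np.ones_like(vol, bool)).any()

    def test_masked_voxels_are_zero(self):
        vol = np.full((2, 2, 1), 9.0)
        mask = np.zeros_like(vol, dtype=bool)
        mask[0, 0, 0] = True
        out = binarize(vol, 1.0, "above", mask)
        assert out.sum() == 1 and out[0, 0, 0]

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 16 - 1))
    def test_predicted_count_monotone_in_threshold(self, bits):
        vol = np.arange(16, dtype=float).reshape(4, 4, 1) / 4.0
        mask = (np.array([(bits >> i) & 1 for i in range(16)])
                .reshape(4, 4, 1).astype(bool))
        counts_above = [binarize(vol, t, "above", mask).sum()
                        for t in np.linspace(-1, 5, 13)]
        counts_below = [binarize(vol, t, "below", mask).sum()
                        for t in np.linspace(-1, 5, 13)]
        assert all(b <= a for a, b in zip(counts_above, counts_above[1:]))
        assert all(b >= a for a, b in zip(counts_below, counts_below[1:]))


class TestOverlapScores:
    def test_perfect_prediction(self):
        ref = np.array([[1, 0], [1, 0]], dtype=bool)[:, :, None]
        c = confusion(ref, ref, FULL)
        assert (c.sensitivity, c.specificity) == (1.0, 1.0)
        assert dice(ref, ref, FULL) == 1.0 and youden(c) == 1.0

    def test_complement_prediction(self):
        ref = np.array([[1, 0], [1, 0]], dtype=bool)[:, :, None]
        c = confusion(~ref, ref, FULL)
        assert (c.sensitivity, c.specificity) == (0.0, 0.0)
        assert youden(c) == -1.0

    def test_hand_counted_ten_voxel_toy(self):
        # 6 reference voxels of which 3 predicted, 4 background of which 1
        # predicted: sens 3/6, spec 3/4.
        ref = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0], bool).reshape(10, 1, 1)
        pred = np.array([1, 1, 1, 0, 0, 0, 1, 0, 0, 0], bool).reshape(10, 1, 1)
        c = confusion(pred, ref, np.ones_like(ref))
        assert c.sensitivity == 0.5 and c.specificity == 0.75
        assert youden(c) == pytest.approx(0.25)

    def test_dice_examples(self):
        m = np.ones((10, 1, 1), dtype=bool)
        a = np.zeros((10, 1, 1), bool); a[:4] = True
        b = np.zeros((10, 1, 1), bool); b[1:7] = True   # overlap 3
        assert dice(a, b, m) == pytest.approx(0.6)
        disjoint = np.zeros_like(a); disjoint[8:] = True
        assert dice(a, disjoint, m) == 0.0
        assert np.isnan(dice(np.zeros_like(a), np.zeros_like(a), m))

    def test_youden_arithmetic(self):
        c = ConfusionCounts(tp=8, fn=2, tn=7, fp=3)
        assert youden(c) == pytest.approx(0.5)

    def test_chance_level_prediction_scores_zero(self):
        # prediction independent of reference: sens == 1 - spec
        c = ConfusionCounts(tp=30, fn=70, tn=70, fp=30)
        assert youden(c) == pytest.approx(0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.ones((2, 2, 1), bool), np.ones((3, 2, 1), bool),
                      np.ones((2, 2, 1), bool))


class TestSweepAndRoc:
    def test_sweep_counts_match_per_threshold_binarize(self):
        rng = np.random.default_rng(1)
        vol = rng.random((6, 6, 3)) * 16
        ref = rng.random((6, 6, 3)) > 0.7
        mask = rng.random((6, 6, 3)) > 0.2
        grid = TABLE_GRIDS["tmax"]
        counts = sweep_counts(vol, grid, ref, mask)
        for i, thr in enumerate(grid.values):
            c = confusion(binarize(vol, thr, grid.direction, mask), ref, mask)
            assert (counts["tp"][i], counts["fp"][i],
                    counts["tn"][i], counts["fn"][i]) == (c.tp, c.fp, c.tn, c.fn)

    def test_perfectly_separable_map_gives_auc_one(self):
        ref = np.zeros((4, 4, 2), dtype=bool)
        ref[:2] = True
        vol = np.where(ref, 10.0, 2.0)
        roc = roc_curve(vol, TABLE_GRIDS["tmax"], ref, np.ones_like(ref))
        assert roc.auc == pytest.approx(1.0)

    def test_degenerate_sweep_warns(self):
        ref = np.zeros((2, 2, 1), dtype=bool)
        ref[0, 0, 0] = True
        vol = np.zeros((2, 2, 1))  # nothing ever exceeds the grid
        with pytest.warns(UserWarning, match="degenerate"):
            roc_curve(vol, TABLE_GRIDS["tmax"], ref, np.ones_like(ref))


class TestOptimalThreshold:
    def test_perfect_separation_both_criteria(self):
        ref = np.zeros((4, 4, 2), dtype=bool)
        ref[:2] = True
        vol = np.where(ref, 10.0, 2.0)
        mask = np.ones_like(ref)
        for crit in ("dice", "youden"):
            opt = optimal_threshold(vol, TABLE_GRIDS["tmax"], ref, mask, crit)
            assert opt.score == pytest.approx(1.0)
            assert 2.0 <= opt.threshold < 10.0

    def test_tie_break_most_specific(self):
        # plateau of perfect scores across (2, 10): 'above' picks the
        # largest tied threshold, 'below' direction the smallest.
        ref = np.zeros((4, 4, 2), dtype=bool)
        ref[:2] = True
        mask = np.ones_like(ref)
        vol = np.where(ref, 10.0, 2.0)
        opt = optimal_threshold(vol, TABLE_GRIDS["tmax"], ref, mask, "dice")
        assert opt.threshold == pytest.approx(9.5)
        vol_b = np.where(ref, 2.0, 60.0)
        opt_b = optimal_threshold(vol_b, TABLE_GRIDS["cbf"], ref, mask, "dice")
        assert opt_b.threshold == pytest.approx(3.0)

    def test_grid_argmax_matches_dense_grid_on_unimodal_criterion(self):
        rng = np.random.default_rng(0)
        ref = np.zeros((20, 10, 1), dtype=bool)
        ref[:8] = True
        vol = np.where(ref, 8.0, 3.0) + rng.normal(0, 1.5, ref.shape)
        mask = np.ones_like(ref)
        coarse = optimal_threshold(vol, make_threshold_grid("tmax", 1, 16, 0.5),
                                   ref, mask, "youden")
        fine = optimal_threshold(vol, make_threshold_grid("tmax", 1, 16, 0.01),
                                 ref, mask, "youden")
        assert abs(coarse.threshold - fine.threshold) <= 0.5 + 1e-9

    def test_pooled_vs_single_subject_equivalence(self):
        rng = np.random.default_rng(2)
        vol = rng.random((5, 5, 2)) * 16
        ref = rng.random((5, 5, 2)) > 0.6
        mask = np.ones_like(ref)
        single = optimal_threshold(vol, TABLE_GRIDS["tmax"], ref, mask, "youden")
        pooled = pooled_optimal_threshold([(vol, ref, mask)],
                                          TABLE_GRIDS["tmax"], "youden")
        assert single == pooled

    def test_identical_subjects_zero_spread(self):
        rng = np.random.default_rng(3)
        vol = rng.random((5, 5, 2)) * 16
        ref = rng.random((5, 5, 2)) > 0.6
        mask = np.ones_like(ref)
        opts = per_subject_distribution([(vol, ref, mask)] * 4,
                                        TABLE_GRIDS["tmax"], "dice")
        assert len({o.threshold for o in opts}) == 1

    def test_subject_without_reference_excluded(self):
        vol = np.random.default_rng(0).random((4, 4, 1)) * 16
        mask = np.ones((4, 4, 1), dtype=bool)
        empty_ref = np.zeros_like(mask)
        ref = mask.copy()
        with pytest.warns(UserWarning, match="excluded"):
            opts = per_subject_distribution(
                [(vol, ref, mask), (vol, empty_ref, mask)],
                TABLE_GRIDS["tmax"], "dice")
        assert len(opts) == 1


class TestAtsDefaultRule:
    @staticmethod
    def _map_set(mtt_rel, cbv):
        shape = (2, 1, 1)
        ms = ParametricMapSet(
            algorithm="ats",
            cbf=np.full(shape, 60.0),
            cbv=np.full(shape, cbv),
            mtt=np.full(shape, 4.0),
            time_map=np.zeros(shape),
            valid_mask=np.ones(shape, dtype=bool),
        )
        ms.rel["mtt_rel"] = np.full(shape, mtt_rel)
        ms.rel_valid["mtt_rel"] = np.ones(shape, dtype=bool)
        return ms

    @pytest.mark.parametrize("mtt_rel,cbv,expected", [
        (1.6, 1.5, {"hypoperfused": True, "core": True, "penumbra": False}),
        (1.6, 3.0, {"hypoperfused": True, "core": False, "penumbra": True}),
        (1.2, 1.5, {"hypoperfused": False, "core": False, "penumbra": False}),
    ])
    def test_vendor_rule_classification(self, mtt_rel, cbv, expected):
        ms = self._map_set(mtt_rel, cbv)
        for target, want in expected.items():
            out = ats_default_prediction(ms, AtsDefaultRule(), target)
            assert bool(out[0, 0, 0]) is want

    def test_core_plus_penumbra_equals_hypoperfused(self, noiseless_spec):
        from ctperf.perfusion import DeconvConfig, compute_map_set
        from ctperf.phantom import build_subject, evaluate_aif

        study, _ = build_subject(noiseless_spec, "A", seed=0)
        aif = evaluate_aif(noiseless_spec.aif, noiseless_spec.times)
        ms = compute_relative_maps(compute_map_set(study, aif, DeconvConfig.ats()))
        hypo = ats_default_prediction(ms, target="hypoperfused")
        core = ats_default_prediction(ms, target="core")
        pen = ats_default_prediction(ms, target="penumbra")
        np.testing.assert_array_equal(hypo, core | pen)
        assert not (core & pen).any()

    def test_missing_relative_maps_rejected(self):
        ms = self._map_set(1.6, 1.5)
        ms.rel.clear()
        with pytest.raises(ValueError, match="relative maps"):
            ats_default_prediction(ms)
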