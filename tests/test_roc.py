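"""Observer comparison: pooling, thresholding, ROC, kappa, critical amplitude."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
import hypothesis.extra.numpy as hnp

from pulsemap import (
    auc_empirical,
    cohens_kappa,
    confusion,
    critical_amplitude,
    downscale_mask,
    ideal_threshold,
    rates,
    roc_sweep,
    segment,
)
from pulsemap.roc import THRESHOLDS


class TestDownscaleMask:
    def test_single_pixel_marks_cluster(self):
        mask = np.zeros((10, 10), np.uint8)
        mask[7, 2] = 1
        grid = downscale_mask(mask)
        assert grid[1, 0] == 1 and grid.sum() == 1

    def test_empty_mask_gives_empty_grid(self):
        assert not downscale_mask(np.zeros((15, 15), np.uint8)).any()

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(hnp.arrays(np.uint8, (17, 23), elements=st.integers(0, 1)))
    def test_matches_brute_force_or(self, mask):
        grid = downscale_mask(mask)
        assert grid.shape == (3, 4)
        for r in range(3):
            for c in range(4):
                assert grid[r, c] == int(mask[5*r:5*r+5, 5*c:5*c+5].any())

    def test_shape_mismatch_detected(self):
        with pytest.raises(ValueError, match="grid"):
            downscale_mask(np.zeros((20, 20)), grid_shape=(3, 3))


class TestSegment:
    def test_strictly_greater_than_threshold(self):
        grid = segment(np.array([[5.1, 5.0, 4.9]]), 5)
        np.testing.assert_array_equal(grid, [[1, 0, 0]])

    def test_threshold_above_max_gives_empty(self):
        assert not segment(np.full((3, 3), 39.0), 40).any()


class TestConfusion:
    def test_identical_grids(self):
        g = np.array([[1, 0], [1, 1]])
        c = confusion(g, g, 0)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 0, 0, 1)

    def test_all_predicted_none_true(self):
        c = confusion(np.ones((2, 2)), np.zeros((2, 2)), 0)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 4, 0, 0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(hnp.arrays(np.uint8, (20, 20), elements=st.integers(0, 1)),
           hnp.arrays(np.uint8, (20, 20), elements=st.integers(0, 1)))
    def test_matches_nested_loop_count(self, pred, truth):
        c = confusion(pred, truth, 0)
        tp = fp = fn = tn = 0
        for i in range(20):
            for j in range(20):
                if pred[i, j] and truth[i, j]:
                    tp += 1
                elif pred[i, j]:
                    fp += 1
                elif truth[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        assert c.total == 400


class TestRates:
    def test_rate_formulas(self):
        from pulsemap.roc import ConfusionCounts

        r = rates(ConfusionCounts(0, tp=3, fp=0, fn=1, tn=10))
        assert r["tpr"] == 0.75
        assert r["fpr"] == 0.0 and r["specificity"] == 1.0
        r = rates(ConfusionCounts(0, tp=1, fp=1, fn=1, tn=1))
        assert r["tpr"] == 0.5 and r["fpr"] == 0.5

    def test_zero_denominator_flagged(self):
        from pulsemap.roc import ConfusionCounts

        r = rates(ConfusionCounts(0, tp=0, fp=2, fn=0, tn=2))
        assert r["undefined"] and np.isnan(r["tpr"])


class TestAucEmpirical:
    def test_chance_diagonal(self):
        auc, degenerate = auc_empirical(np.array([]), np.array([]))
        assert auc == 0.5 and degenerate

    def test_perfect_separation(self, separable_run):
        from pulsemap import PulsationMapper

        stack, beats, truth = separable_run
        mapper = PulsationMapper().fit(stack, beats)
        res = roc_sweep(mapper.amplitude_map_, truth.cluster_mask)
        assert res.auc == 1.0

    def test_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        amp = rng.uniform(0, 40, 500)
        labels = rng.random(500) < 0.4
        det = amp[None, :] > THRESHOLDS[:, None]
        tpr = (det & labels).sum(1) / labels.sum()
        fpr = (det & ~labels).sum(1) / (~labels).sum()
        ours, _ = auc_empirical(fpr, tpr)
        # sklearn oracle on the integer-quantised score implied by the sweep
        ref = roc_auc_score(labels, np.ceil(amp))
        assert ours == pytest.approx(ref, abs=0.01)

    def test_label_permutation_null_centres_on_half(self):
        rng = np.random.default_rng(1)
        amp = rng.uniform(0, 40, 1000)
        labels = rng.random(1000) < 0.3
        det = amp[None, :] > THRESHOLDS[:, None]
        aucs = []
        for _ in range(200):
            lab = rng.permutation(labels)
            tpr = (det & lab).sum(1) / lab.sum()
            fpr = (det & ~lab).sum(1) / (~lab).sum()
            aucs.append(auc_empirical(fpr, tpr)[0])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


class TestIdealThreshold:
    def test_argmax_of_product(self):
        tpr = np.array([0.5, 1.0, 0.8])
        fpr = np.array([0.6, 0.5, 0.5])
        assert ideal_threshold(tpr, fpr, thresholds=np.array([0, 1, 2])) == 1

    def test_tie_broken_toward_lowest(self):
        tpr = np.array([0.1, 0.0, 0.8, 0.0, 0.8, 0.0])
        fpr = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        thr = np.arange(2, 8)
        got = ideal_threshold(tpr, fpr, thresholds=thr)
        # brute-force scan oracle
        prods = tpr * (1 - fpr)
        best = thr[np.flatnonzero(prods == prods.max())[0]]
        assert got == best == 4

    def test_separable_gap_consistent_with_scan(self, separable_run):
        from pulsemap import PulsationMapper

        stack, beats, truth = separable_run
        mapper = PulsationMapper().fit(stack, beats)
        res = roc_sweep(mapper.amplitude_map_, truth.cluster_mask)
        prods = res.tpr * (1 - res.fpr)
        assert res.ideal_threshold == THRESHOLDS[np.argmax(prods)]
        r = rates(confusion(segment(mapper.amplitude_map_, res.ideal_threshold),
                            truth.cluster_mask, res.ideal_threshold))
        assert r["sensitivity"] == 1.0 and r["specificity"] == 1.0


class TestCriticalAmplitude:
    def test_single_region_max(self):
        amp = np.array([[3.0, 7.0, 12.0]])
        mask = np.ones((1, 3), np.uint8)
        regions, eye = critical_amplitude(amp, mask)
        assert len(regions) == 1 and regions[0][2] == 12.0 and eye == 12.0

    def test_eye_level_is_min_over_region_maxima(self):
        amp = np.zeros((5, 5))
        amp[0, 0:2] = [5.0, 12.0]
        amp[4, 3:5] = [18.0, 9.0]
        mask = np.zeros((5, 5), np.uint8)
        mask[0, 0:2] = 1
        mask[4, 3:5] = 1
        regions, eye = critical_amplitude(amp, mask)
        assert sorted(r[2] for r in regions) == [12.0, 18.0]
        assert eye == 12.0

    def test_diagonal_clusters_join_8_connected(self):
        mask = np.eye(3, dtype=np.uint8)
        regions, _ = critical_amplitude(np.arange(9.0).reshape(3, 3), mask)
        assert len(regions) == 1

    def test_threshold_at_eye_level_keeps_all_regions(self):
        rng = np.random.default_rng(4)
        amp = rng.uniform(3, 30, (12, 12))  # continuous, non-integer maxima
        mask = np.zeros((12, 12), np.uint8)
        mask[1:4, 1:4] = 1
        mask[8:11, 7:12] = 1
        regions, eye = critical_amplitude(amp, mask)
        from scipy import ndimage

        labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
        for thr in range(0, 41):
            det = segment(amp, thr)
            missed = [rid for rid in range(1, n + 1)
                      if not det[labels == rid].any()]
            if thr <= eye:
                assert not missed
            if thr > eye:
                assert missed

    def test_empty_mask_flagged(self):
        regions, eye = critical_amplitude(np.ones((3, 3)), np.zeros((3, 3)))
        assert regions == [] and np.isnan(eye)


class TestCohensKappa:
    def test_identical_masks(self):
        m = np.array([[1, 0], [0, 1]])
        assert cohens_kappa(m, m) == 1.0

    def test_hand_computed_example(self):
        a = np.concatenate([np.ones(40), np.ones(10), np.zeros(10), np.zeros(40)])
        b = np.concatenate([np.ones(40), np.zeros(10), np.ones(10), np.zeros(40)])
        assert cohens_kappa(a, b) == pytest.approx(0.6)

    def test_independent_masks_near_zero(self):
        rng = np.random.default_rng(6)
        a = rng.random((100, 100)) < 0.4
        b = rng.random((100, 100)) < 0.4
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_both_constant_is_undefined(self):
        assert np.isnan(cohens_kappa(np.ones((3, 3)), np.ones((3, 3))))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(hnp.arrays(np.uint8, 60, elements=st.integers(0, 1)),
           hnp.arrays(np.uint8, 60, elements=st.integers(0, 1)))
    def test_matches_sklearn(self, a, b):
        from sklearn.metrics import cohen_kappa_score

        ours = cohens_kappa(a, b)
        if np.isnan(ours):
            return
        assert ours == pytest.approx(cohen_kappa_score(a, b), abs=1e-10)


class TestMonotonicity:
    def test_tpr_fpr_non_increasing_in_threshold(self, separable_run):
        from pulsemap import PulsationMapper

        stack, beats, truth = separable_run
        mapper = PulsationMapper().fit(stack, beats)
        res = roc_sweep(mapper.amplitude_map_, truth.cluster_mask)
        assert np.all(np.diff(res.tpr) <= 1e-12)
        assert np.all(np.diff(res.fpr) <= 1e-12)
        assert np.all((res.tpr >= 0) & (res.tpr <= 1))
        assert 0 <= res.auc <= 1
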