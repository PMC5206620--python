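"""ROC/AUC machinery, cut-off rules, rank statistics, classifier evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fibroselect import evaluation as ev
from fibroselect import forest as rf

from conftest import make_tiny_cohort


def exhaustive_best_sum(scores, labels):
    """Oracle: max sensitivity+specificity over every possible cut."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = -1.0
    for thr in np.concatenate([[-np.inf], np.sort(np.unique(scores)), [np.inf]]):
        called = scores > thr
        tp = np.sum(called & (labels == 1))
        tn = np.sum(~called & (labels == 0))
        sens = tp / labels.sum()
        spec = tn / (labels == 0).sum()
        best = max(best, sens + spec)
    return best


class TestRocCurve:
    def test_perfect_separation(self):
        curve = ev.roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert curve.auc == 1.0
        assert curve.best_cutoff == 2.5

    def test_reversed_scores_auc_zero_then_auto_flip(self):
        fixed = ev.roc_curve([1, 2, 3, 4], [1, 1, 0, 0], ev.GREATER_IS_POSITIVE)
        assert fixed.auc == 0.0
        auto = ev.roc_curve([1, 2, 3, 4], [1, 1, 0, 0], "auto")
        assert auto.direction == ev.LESS_IS_POSITIVE
        assert auto.auc == 1.0
        assert auto.best_cutoff == 2.5  # positive iff score < 2.5

    def test_chance_level_on_random_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        assert ev.roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_auc_equals_normalized_mann_whitney(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n1, n0 = rng.integers(5, 40, 2)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # force ties
            labels = np.array([1] * n1 + [0] * n0)
            auc = ev.roc_curve(scores, labels).auc
            u = ev.mann_whitney(scores[labels == 1], scores[labels == 0]).statistic
            assert abs(auc - u / (n1 * n0)) < 1e-12

    def test_antisymmetry_without_ties(self):
        rng = np.random.default_rng(1)
        scores = rng.permutation(np.arange(30, dtype=float))
        labels = rng.integers(0, 2, 30)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        a = ev.roc_curve(scores, labels).auc
        b = ev.roc_curve(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            ev.roc_curve([1.0, 2.0], [1, 1])

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        curve = ev.roc_curve(scores, labels)
        ordered = sorted(curve.points, key=lambda p: p[0])
        sens = [p[1] for p in ordered]
        assert all(a >= b for a, b in zip(sens, sens[1:]))


class TestBestCutoff:
    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                labels[:2] = [0, 1]
            curve = ev.roc_curve(scores, labels)
            metrics = ev.classify_threshold(scores, labels, curve.best_cutoff)
            achieved = metrics.sensitivity + metrics.specificity
            assert achieved == pytest.approx(exhaustive_best_sum(scores, labels))

    def test_degenerate_identical_scores(self):
        curve = ev.roc_curve([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        # sens+spec = 1 everywhere; tie rule picks the all-negative point
        assert curve.best_cutoff == math.inf


class TestAucBand:
    @pytest.mark.parametrize(
        "auc,band",
        [(0.55, "uninformative"), (0.6, "poor"), (0.65, "poor"),
         (0.70, "moderate"), (0.75, "moderate"), (0.8, "good"),
         (0.89, "good"), (0.9, "excellent"), (0.95, "excellent")],
    )
    def test_bands(self, auc, band):
        assert ev.auc_band(auc) == band


class TestBinaryMetrics:
    def test_validation_stage_confusion_arithmetic(self):
        # 28 TIF / 21 no-TIF: the class sizes force these counts; tolerance
        # is one unit in the third printed decimal (43/49 = 0.8776 prints
        # as 0.877 under truncation)
        m = ev.binary_metrics(tp=26, fn=2, tn=13, fp=8)
        assert m.sensitivity == pytest.approx(0.929, abs=1e-3)
        assert m.specificity == pytest.approx(0.619, abs=1e-3)
        assert m.accuracy == pytest.approx(0.796, abs=1e-3)
        m2 = ev.binary_metrics(tp=27, fn=1, tn=16, fp=5)
        assert m2.sensitivity == pytest.approx(0.964, abs=1e-3)
        assert m2.specificity == pytest.approx(0.762, abs=1e-3)
        assert m2.accuracy == pytest.approx(0.877, abs=1e-3)

    def test_all_negative_classifier(self):
        m = ev.binary_metrics(tp=0, fn=10, tn=10, fp=0)
        assert (m.sensitivity, m.specificity, m.accuracy) == (0.0, 1.0, 0.5)

    @pytest.mark.parametrize("kw", [dict(tp=0, fn=0, tn=5, fp=0), dict(tp=5, fn=0, tn=0, fp=0)])
    def test_empty_class_rejected(self, kw):
        with pytest.raises(ValueError):
            ev.binary_metrics(**kw)


class TestLockedThreshold:
    def test_identical_cohorts_reproduce_operating_point(self, panel):
        rows = [
            {"VIM": float(v), "tif_grade": g, "tif_pct": 30.0 if g else 2.0}
            for v, g in zip((1, 2, 3, 4, 5, 6), (0, 0, 0, 1, 1, 1))
        ]
        cohort = make_tiny_cohort(panel, rows)
        curve, metrics = ev.locked_threshold_eval(cohort, cohort, "VIM")
        point = [p for p in curve.points if p[0] == curve.best_cutoff][0]
        assert metrics.sensitivity == pytest.approx(point[1])
        assert metrics.specificity == pytest.approx(point[2])

    def test_flipped_validation_labels_swap_error_rates(self, panel):
        rows = [
            {"VIM": float(v), "tif_grade": g, "tif_pct": 30.0 if g else 2.0}
            for v, g in zip((1, 2, 3, 4, 5, 6, 7, 8), (0, 0, 1, 0, 1, 1, 0, 1))
        ]
        test = make_tiny_cohort(panel, rows)
        flipped_rows = [
            {**r, "tif_grade": 0 if r["tif_grade"] else 1,
             "tif_pct": 2.0 if r["tif_grade"] else 30.0}
            for r in rows
        ]
        validation = make_tiny_cohort(panel, flipped_rows)
        curve, straight = ev.locked_threshold_eval(test, test, "VIM")
        _, swapped = ev.locked_threshold_eval(test, validation, "VIM")
        assert swapped.sensitivity == pytest.approx(1.0 - straight.specificity)
        assert swapped.specificity == pytest.approx(1.0 - straight.sensitivity)


class TestCombinedClassifier:
    def test_separating_gene_high_validation_accuracy(self, panel):
        def cohort(n, seed):
            rng = np.random.default_rng(seed)
            rows = []
            for i in range(n):
                label = i % 2
                rows.append(
                    {
                        "tif_grade": 2 if label else 0,
                        "tif_pct": 40.0 if label else 2.0,
                        "VIM": float(2.0 ** (5.0 * label + rng.normal(scale=0.3))),
                    }
                )
            return make_tiny_cohort(panel, rows)

        table = ev.combined_classifier_eval(
            cohort(40, 1), cohort(40, 2), [["VIM"]], rf.ForestParams(seed=3, n_trees=100)
        )
        assert table.loc[0, "accuracy"] >= 0.95

    def test_noise_genes_near_chance(self, synth_pair):
        test, val = synth_pair
        noise = ["ACE", "AGT", "BMP7", "CASP3"]  # no planted effects
        accs = []
        for seed in range(6):
            table = ev.combined_classifier_eval(
                test, val, [noise], rf.ForestParams(seed=seed, n_trees=100)
            )
            accs.append(table.loc[0, "accuracy"])
        majority = max(np.mean(val.labels), 1 - np.mean(val.labels))
        assert abs(np.mean(accs) - majority) < 0.15

    def test_adding_informative_covariate_helps_on_average(self):
        """Across fresh cohort draws, stacking eGFR onto the informative
        gene set does not reduce mean validation accuracy (any apparent
        drop stays within Monte-Carlo noise of the paired differences)."""
        from fibroselect.synthetic import CohortConfig, generate_cohort

        genes = ["TGFB1", "MMP9", "TIMP2", "VIM"]
        diffs = []
        for seed in range(8):
            cfg = CohortConfig(seed=4000 + seed)
            test = generate_cohort(cfg, "test")
            val = generate_cohort(cfg, "validation")
            table = ev.combined_classifier_eval(
                test, val, [genes, [*genes, "egfr"]],
                rf.ForestParams(seed=seed, n_trees=150),
            )
            diffs.append(table.loc[1, "accuracy"] - table.loc[0, "accuracy"])
        diffs = np.asarray(diffs)
        mc_se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert diffs.mean() >= -2 * mc_se


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 4.0, 8.0, 16.0, 32.0, 64.0]
        assert ev.spearman(x, y).r == pytest.approx(1.0)
        assert ev.spearman(x, y[::-1]).r == pytest.approx(-1.0)

    def test_hand_ranked_ties_exact(self):
        # x ranks: 1, 2.5, 2.5, 4, 5, 6 (tie at 2); y ranks: 2, 1, 3, 4, 6, 5
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [0.2, 0.1, 0.3, 0.4, 0.9, 0.5]
        rx = np.array([1, 2.5, 2.5, 4, 5, 6])
        ry = np.array([2, 1, 3, 4, 6, 5])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert abs(ev.spearman(x, y).r - expected) < 1e-12

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        mine = ev.spearman(x, y)
        ref_r, ref_p = sps.spearmanr(x, y)
        assert mine.r == pytest.approx(ref_r, abs=1e-12)
        assert mine.p_value == pytest.approx(ref_p, rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ev.spearman([1.0] * 6, [1, 2, 3, 4, 5, 6])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="n >= 5"):
            ev.spearman([1, 2, 3, 4], [4, 3, 2, 1])


class TestMannWhitney:
    def test_extreme_small_sample_enumeration(self):
        res = ev.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2.0 / 6.0)

    def test_identical_groups_p_one(self):
        res = ev.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(4.5)  # n1*n2/2
        assert res.p_value == 1.0

    def test_u_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 15))
            b = rng.normal(size=rng.integers(2, 15))
            res = ev.mann_whitney(a, b)
            assert 0 <= res.statistic <= len(a) * len(b)

    def test_exact_and_normal_paths_agree(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            exact = ev.mann_whitney(a, b).p_value  # n=12, no ties -> exact
            approx = ev.mann_whitney(np.concatenate([a, [a[0]]]), b)  # tie -> normal
            assert exact == pytest.approx(
                sps.mannwhitneyu(a, b, method="exact").pvalue, abs=1e-12
            )
            del approx  # smoke only: the tie path must not raise

    def test_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=25)
        mine = ev.mann_whitney(a, b).p_value
        ref = sps.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert mine == pytest.approx(ref, abs=1e-9)
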