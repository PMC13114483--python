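"""CV / mean-ratio scoring, ROC/Youden analysis, two-step discrimination."""

import numpy as np
import pytest

from sfdibruise import discriminate as dsc


def pair_counting_auc(scores, labels, orientation="lower"):
    """Brute-force concordance oracle: P(pos better than neg) + 0.5*ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            better = p < q if orientation == "lower" else p > q
            if better:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestCV:
    def test_constant_map_is_zero(self):
        assert dsc.coefficient_of_variation(np.full((5, 5), 2.0)) == 0.0

    def test_population_sd_hand_example(self):
        # {1,1,3,3}: mean 2, population sd 1 -> CV 0.5
        assert dsc.coefficient_of_variation(np.array([1.0, 1.0, 3.0, 3.0])) == 0.5

    def test_scale_invariant(self):
        m = np.random.default_rng(0).uniform(1, 3, (6, 6))
        assert dsc.coefficient_of_variation(4 * m) == pytest.approx(
            dsc.coefficient_of_variation(m)
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dsc.coefficient_of_variation(np.ones((3, 3)), np.zeros((3, 3), bool))


class TestMeanRatio:
    def test_equal_regions_give_unity(self):
        m = np.ones((4, 4))
        bruise = np.zeros((4, 4), bool)
        bruise[:2] = True
        assert dsc.mean_ratio(m, bruise, ~bruise) == 1.0

    def test_bruised_apple_coefficients(self):
        # 1.215 / 1.726 = 0.7039...
        m = np.full((4, 4), 1.726)
        bruise = np.zeros((4, 4), bool)
        bruise[1:3, 1:3] = True
        m[bruise] = 1.215
        assert dsc.mean_ratio(m, bruise, ~bruise) == pytest.approx(0.704, abs=5e-4)

    def test_monotone_in_severity(self):
        from sfdibruise import synth

        ratios = []
        for sev in (0.25, 0.5, 0.75, 1.0):
            spec = synth.FruitSceneSpec("apple", severity=sev, size=64)
            opmap, bruise, sound = synth.make_fruit_map(spec)
            ratios.append(dsc.mean_ratio(opmap.mu_s_prime, bruise, sound))
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_overlapping_masks_rejected(self):
        m = np.ones((3, 3))
        full = np.ones((3, 3), bool)
        with pytest.raises(ValueError):
            dsc.mean_ratio(m, full, full)


class TestROC:
    def test_perfect_separation(self):
        roc = dsc.roc_curve([0.5, 0.6, 0.8, 0.9],
                            [True, True, False, False], orientation="lower")
        assert roc.auc == 1.0

    def test_identical_distributions(self):
        roc = dsc.roc_curve([0.5, 0.7, 0.5, 0.7],
                            [True, True, False, False], orientation="lower")
        assert roc.auc == 0.5

    @pytest.mark.parametrize("orientation", ["lower", "higher"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_auc_equals_pair_counting(self, orientation, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.uniform(0, 1, 20), 2)  # force some ties
        labels = rng.uniform(size=20) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = dsc.roc_curve(scores, labels, orientation)
        assert roc.auc == pytest.approx(
            pair_counting_auc(scores, labels, orientation), abs=1e-12
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = rng.uniform(0, 1, 30)
        labels = rng.uniform(size=30) < 0.4
        labels[0] = True
        labels[1] = False
        roc = dsc.roc_curve(scores, labels, orientation="higher")
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dsc.roc_curve([0.1, 0.2], [True, True])

    def test_curve_monotone(self):
        rng = np.random.default_rng(10)
        scores = rng.uniform(0, 1, 25)
        labels = rng.uniform(size=25) < 0.5
        labels[:2] = [True, False]
        roc = dsc.roc_curve(scores, labels, orientation="lower")
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)


class TestYouden:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(0.96, 0.92, 0.88), (1.00, 0.92, 0.92), (0.96, 0.88, 0.84), (1.0, 1.0, 1.0)],
    )
    def test_index_formula(self, sens, spec, expected):
        assert dsc.youden_index(sens, spec) == pytest.approx(expected, abs=1e-12)

    def test_optimal_threshold_on_separable_data(self):
        roc = dsc.roc_curve([0.5, 0.6, 0.8, 0.9],
                            [True, True, False, False], orientation="lower")
        thr, j = dsc.youden_optimal_threshold(roc)
        assert j == 1.0
        assert thr == 0.6  # largest score still called severe

    def test_youden_consistent_with_confusion_counts(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(0, 1, 40)
        labels = np.r_[scores[:20] < 0.3, np.zeros(20, bool)]
        roc = dsc.roc_curve(scores, labels, orientation="lower")
        thr, j = dsc.youden_optimal_threshold(roc)
        called = scores <= thr
        sens = (called & labels).sum() / labels.sum()
        spec = (~called & ~labels).sum() / (~labels).sum()
        assert j == pytest.approx(sens + spec - 1, abs=1e-12)


class TestClassification:
    def test_cv_boundary_is_non_bruised(self):
        assert not dsc.classify_bruised(0.117, 0.117)
        assert dsc.classify_bruised(0.117 + 1e-9, 0.117)

    def test_severity_boundary_is_mild(self):
        assert dsc.classify_severity(0.7430, 0.7430) == "mild"
        assert dsc.classify_severity(0.70, 0.7430) == "severe"
        assert dsc.classify_severity(0.80, 0.7430) == "mild"

    def test_apple_cv_rule(self):
        # synthetic CV scores spanning the published apple threshold
        thr = 0.117
        sound = [0.05, 0.08, 0.11]
        bruised = [0.13, 0.16, 0.20]
        assert all(not dsc.classify_bruised(cv, thr) for cv in sound)
        assert all(dsc.classify_bruised(cv, thr) for cv in bruised)


class TestSeverityTable:
    def test_rates(self):
        tab = dsc.severity_confusion_table(
            {"mild": 1, "severe": 2}, {"mild": 25, "severe": 25}
        )
        total = tab[tab.grade == "total"].iloc[0]
        assert total.actual == 50
        assert total.faults == 3
        assert total.rate == pytest.approx(0.06)


class TestTwoStepPipeline:
    def _cohort(self):
        rng = np.random.default_rng(7)
        samples = []
        for i in range(10):  # non-bruised, low CV
            samples.append(dsc.SampleScore(f"s{i}", cv=rng.uniform(0.02, 0.06),
                                           true_bruised=False))
        for i in range(10):  # bruised, higher CV; alternate severity
            sev = "mild" if i % 2 else "severe"
            m = rng.uniform(0.8, 0.95) if sev == "mild" else rng.uniform(0.55, 0.72)
            samples.append(dsc.SampleScore(f"b{i}", cv=rng.uniform(0.09, 0.2),
                                           mean_ratio=m, true_bruised=True,
                                           true_severity=sev))
        return samples

    def test_separable_cohort_fully_resolved(self):
        report = dsc.two_step_pipeline(self._cohort())
        assert report.step1_accuracy == 1.0
        total = report.severity_table[report.severity_table.grade == "total"].iloc[0]
        assert total.faults == 0
        assert total.actual == 10

    def test_counts_sum_to_inputs(self):
        report = dsc.two_step_pipeline(self._cohort())
        df = report.to_frame()
        assert len(df) == 20
        tab = report.severity_table
        assert tab[tab.grade != "total"].actual.sum() == \
            tab[tab.grade == "total"].actual.iloc[0]

    def test_single_severity_class_skips_grading(self):
        samples = [
            dsc.SampleScore("a", cv=0.03, true_bruised=False),
            dsc.SampleScore("b", cv=0.15, mean_ratio=0.6, true_bruised=True,
                            true_severity="severe"),
            dsc.SampleScore("c", cv=0.18, mean_ratio=0.65, true_bruised=True,
                            true_severity="severe"),
        ]
        report = dsc.two_step_pipeline(samples)
        assert report.severity_table is None
        assert report.notes
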