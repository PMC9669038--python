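"""Metrics formulas, ROC/AUC, group tests, tumor volume, crosstabs."""

import numpy as np
import pytest
from scipy import stats as sps

from sarcopipe.stats import (
    ConfusionCounts,
    TumorGeometry,
    compare_groups,
    metrics,
    misdiagnosis_crosstab,
    roc_auc,
    round1,
    tumor_volume,
)


def _pairwise_auc(scores, labels):
    """Independent oracle: Mann-Whitney pair counting with half-credit ties."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = scores[y], scores[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_reported_headline_rounding(self):
        """Mean of sensitivity 89.8 and specificity 91.7 is 90.75, reported
        as 90.8 at one decimal."""
        assert round1((89.8 + 91.7) / 2) == 90.8

    def test_symmetric_counts_give_fifty_percent(self):
        m = metrics(ConfusionCounts(tp=5, tn=5, fp=5, fn=5))
        assert (m.accuracy, m.ss_avg, m.sensitivity, m.specificity) == (
            50.0,
            50.0,
            50.0,
            50.0,
        )

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=3, tn=7, fp=0, fn=0))
        assert (m.accuracy, m.ss_avg, m.sensitivity, m.specificity) == (
            100.0,
            100.0,
            100.0,
            100.0,
        )

    @pytest.mark.parametrize("tp,fn,tn,fp", [(8, 2, 6, 4), (1, 9, 9, 1), (5, 5, 3, 7)])
    def test_balanced_cohort_ss_avg_equals_accuracy(self, tp, fn, tn, fp):
        """With equal class sizes SS-Avg coincides with accuracy exactly."""
        assert tp + fn == tn + fp
        m = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        assert m.ss_avg == pytest.approx(m.accuracy)

    def test_ss_avg_is_mean_of_sens_spec(self):
        m = metrics(ConfusionCounts(tp=44, tn=110, fp=10, fn=5))
        assert m.ss_avg == pytest.approx((m.sensitivity + m.specificity) / 2)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="sensitivity"):
            metrics(ConfusionCounts(tp=0, tn=5, fp=5, fn=0))
        with pytest.raises(ValueError, match="specificity"):
            metrics(ConfusionCounts(tp=5, tn=0, fp=0, fn=5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=1, fp=1, fn=1)


class TestRocAuc:
    def test_perfect_separation(self):
        points, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert points[:, 0].min() == 0.0 and points[:, 1].max() == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        scores = rng.random(n)
        labels = rng.random(n) < 0.5
        _, auc = roc_auc(scores, labels)
        n1, n0 = labels.sum(), (~labels).sum()
        sigma = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auc - 0.5) < 3 * sigma

    def test_matches_pairwise_counting_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(_pairwise_auc(scores, labels))

    def test_ties_grouped_matches_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.integers(0, 4, size=12)  # many ties
            labels = rng.random(12) < 0.5
            if labels.all() or not labels.any():
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(_pairwise_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        _, a = roc_auc(scores, labels)
        _, b = roc_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b)

    def test_string_labels_with_positive_label(self):
        _, auc = roc_auc(
            [3, 2, 1],
            ["sarcoma_group", "leiomyoma", "leiomyoma"],
            positive_label="sarcoma_group",
        )
        assert auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], [1, 1])


class TestCompareGroups:
    def test_identical_samples(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_symmetry_up_to_sign(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        ta, pa = compare_groups(a, b)
        tb, pb = compare_groups(b, a)
        assert ta == pytest.approx(-tb)
        assert pa == pytest.approx(pb)

    def test_matches_permutation_oracle(self):
        """Student's t on near-normal samples agrees with a permutation test
        of the mean difference within Monte-Carlo error."""
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(0.9, 1.0, 15)
        _, p_t = compare_groups(a, b, variance_rule="student")

        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        hits = 0
        n_shuffles = 10_000
        for _ in range(n_shuffles):
            perm = rng.permutation(pooled)
            if abs(perm[:15].mean() - perm[15:].mean()) >= observed - 1e-12:
                hits += 1
        p_perm = hits / n_shuffles
        mc_sigma = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_shuffles)
        assert abs(p_t - p_perm) < 0.01 + 4 * mc_sigma

    def test_welch_differs_from_student_under_unequal_variance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.2, 8)
        b = rng.normal(0.4, 3.0, 40)
        _, p_student = compare_groups(a, b, variance_rule="student")
        _, p_welch = compare_groups(a, b, variance_rule="welch")
        assert p_student != pytest.approx(p_welch)
        res = sps.ttest_ind(a, b, equal_var=False)
        assert p_welch == pytest.approx(res.pvalue)

    def test_auto_picks_welch_on_clearly_unequal_variances(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.1, 20)
        b = rng.normal(0, 5.0, 20)
        _, p_auto = compare_groups(a, b, variance_rule="auto")
        _, p_welch = compare_groups(a, b, variance_rule="welch")
        assert p_auto == pytest.approx(p_welch)

    def test_scaling_one_sample_keeps_t_sign(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([5.0, 6.0, 7.0, 8.0])
        t1, _ = compare_groups(a, b)
        spread = (b - b.mean()) * 2 + b.mean()
        t2, _ = compare_groups(a, spread)
        assert np.sign(t1) == np.sign(t2)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups([1.0], [1.0, 2.0])


class TestTumorVolume:
    def test_printed_formula(self):
        vol = tumor_volume(TumorGeometry(2.0, 2.0, 2.0))
        assert vol == pytest.approx(0.75 * np.pi)

    def test_ellipsoid_mode(self):
        vol = tumor_volume(TumorGeometry(2.0, 2.0, 2.0), formula_mode="ellipsoid")
        assert vol == pytest.approx(4.0 / 3.0 * np.pi)

    def test_constant_ratio_between_modes(self):
        g = TumorGeometry(7.3, 4.1, 5.9)
        ratio = tumor_volume(g, "ellipsoid") / tumor_volume(g, "as_printed")
        assert ratio == pytest.approx(16.0 / 9.0)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError):
            TumorGeometry(0.0, 1.0, 1.0)


class TestMisdiagnosisCrosstab:
    def test_all_correct_is_neither(self):
        model = {"c1": ["positive"] * 24}
        readers = {"c1": ["positive"] * 6}
        labels = {"c1": "sarcoma_group"}
        assert misdiagnosis_crosstab(model, readers, labels) == {"c1": "neither"}

    def test_majority_definitions(self):
        # 13/24 ensembles wrong, 2/6 readers wrong -> model_only
        model = {"c1": ["negative"] * 13 + ["positive"] * 11}
        readers = {"c1": ["negative"] * 2 + ["positive"] * 4}
        labels = {"c1": "sarcoma_group"}
        assert misdiagnosis_crosstab(model, readers, labels) == {"c1": "model_only"}

    def test_exact_half_is_not_majority(self):
        model = {"c1": ["negative"] * 12 + ["positive"] * 12}
        readers = {"c1": ["negative"] * 3 + ["positive"] * 3}
        labels = {"c1": "sarcoma_group"}
        assert misdiagnosis_crosstab(model, readers, labels) == {"c1": "neither"}

    def test_random_fixture_matches_recount(self, rng):
        cases = [f"c{i}" for i in range(30)]
        labels = {
            c: ("sarcoma_group" if rng.random() < 0.3 else "leiomyoma")
            for c in cases
        }
        model = {
            c: [bool(rng.random() < 0.5) for _ in range(24)] for c in cases
        }
        readers = {c: [bool(rng.random() < 0.5) for _ in range(6)] for c in cases}
        out = misdiagnosis_crosstab(model, readers, labels)
        for c in cases:
            truth = labels[c] == "sarcoma_group"
            mw = sum(1 for v in model[c] if v != truth) > 12
            rw = sum(1 for v in readers[c] if v != truth) > 3
            expected = (
                "both" if mw and rw else "model_only" if mw
                else "readers_only" if rw else "neither"
            )
            assert out[c] == expected

    def test_unmatched_ids_rejected(self):
        with pytest.raises(ValueError, match="identifiers"):
            misdiagnosis_crosstab({"a": [1]}, {"b": [1]}, {"a": "leiomyoma"})
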