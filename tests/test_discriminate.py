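"""Grouping schemes, SIMCA, OPLS-DA, RMS-X and confusion metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from teanirs.dataset import METAL_COLUMNS, SampleTable, split_sets
from teanirs.discriminate import (
    BLEND_PERCENTAGE,
    NO_CLASS,
    OPLSDA,
    PURE_VS_BLENDS,
    RMSX,
    SIMCA,
    assign_groups,
    confusion_metrics,
)
from teanirs.simulate import GeneratorConfig, generate_library


def _blend_table(rows):
    meta = []
    for i, fr in enumerate(rows):
        row = {"id": f"s{i}", "class": "blend",
               "fraction_black": fr.get("black", 0.0),
               "fraction_green": fr.get("green", 0.0),
               "fraction_red": fr.get("red", 0.0)}
        row.update({c: 1.0 for c in METAL_COLUMNS.values()})
        meta.append(row)
    n = len(rows)
    return SampleTable(pd.DataFrame(meta), np.zeros((n, 4)),
                       np.array([1100.0, 1102.0, 1104.0, 1106.0]))


class TestAssignGroups:
    def test_pure_vs_blends_labels(self):
        table = _blend_table([
            {"black": 1.0},
            {"green": 0.96, "red": 0.04},
            {"red": 0.55, "black": 0.45},
        ])
        labels = assign_groups(table, PURE_VS_BLENDS)
        assert list(labels) == ["black pure", "green blends", "red blends"]

    def test_percentage_bins(self):
        table = _blend_table([
            {"green": 0.96, "red": 0.04},
            {"red": 0.85, "black": 0.15},   # boundary 85 -> upper bin
            {"red": 0.95, "black": 0.05},   # boundary 95 -> 95-85 bin
            {"black": 0.84, "green": 0.16},
            {"black": 0.50, "green": 0.50},
            {"green": 1.0},
        ])
        labels = assign_groups(table, BLEND_PERCENTAGE)
        assert list(labels) == [">95% green", "95-85% red", "95-85% red",
                                "85-75% black", "75-50% black", ">95% green"]

    def test_out_of_design_fraction_rejected(self):
        table = _blend_table([{"black": 0.4, "green": 0.3, "red": 0.3}])
        with pytest.raises(ValueError, match="outside the blend design"):
            assign_groups(table, BLEND_PERCENTAGE)

    def test_every_sample_gets_exactly_one_class(self, default_library):
        for scheme in (PURE_VS_BLENDS, BLEND_PERCENTAGE):
            labels = assign_groups(default_library, scheme)
            assert set(labels) <= set(scheme.classes)
            assert labels.shape == (len(default_library),)


class TestSIMCA:
    def test_near_identical_class_keeps_one_component(self, rng):
        X = np.vstack([np.ones((5, 10)) + 1e-6 * rng.normal(size=(5, 10)),
                       rng.normal(size=(5, 10)) + 5])
        labels = ["a"] * 5 + ["b"] * 5
        res = SIMCA(X, labels, normalize=False).fit()
        assert res.class_models["a"]["n_components"] >= 1

    def test_far_separated_classes_fully_resolved(self, rng):
        a = rng.normal(size=(15, 30))
        b = rng.normal(size=(15, 30)) + 10.0  # 10 SD offset
        X = np.vstack([a, b])
        labels = np.array(["a"] * 15 + ["b"] * 15)
        res = SIMCA(X, labels, normalize=False).fit()
        pred = res.classify(X)
        assert np.all(pred == labels)
        d = res.distances(X)
        assert np.all(d["a"][:15] < d["b"][:15])
        assert np.all(d["b"][15:] < d["a"][15:])

    def test_alien_spectrum_gets_no_class(self, rng):
        a = rng.normal(size=(15, 30)) + 50.0
        b = rng.normal(size=(15, 30)) - 50.0
        labels = ["a"] * 15 + ["b"] * 15
        res = SIMCA(np.vstack([a, b]), labels, normalize=False).fit()
        pred = res.classify(np.zeros((1, 30)))
        assert pred[0] == NO_CLASS

    def test_distances_permutation_equivariant(self, rng):
        X = rng.normal(size=(24, 12))
        labels = np.array(["a", "b", "c"] * 8)
        d1 = SIMCA(X, labels).fit().distances(X)
        # reversing the sample order (with labels) must not change anything
        d2 = SIMCA(X[::-1], labels[::-1]).fit().distances(X[::-1])
        np.testing.assert_allclose(d1.to_numpy()[::-1], d2[d1.columns].to_numpy(),
                                   atol=1e-9)

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(5, 6))
        with pytest.raises(ValueError, match="3 samples"):
            SIMCA(X, ["a", "a", "a", "b", "b"]).fit()


class TestOPLSDA:
    def test_separable_classes_classified_perfectly(self, rng):
        a = rng.normal(size=(20, 15))
        b = rng.normal(size=(20, 15)) + 6.0
        X = np.vstack([a, b])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        res = OPLSDA(X, labels, n_predictive=2, n_orthogonal=1).fit(compute_q2=False)
        assert np.all(res.classify(X) == labels)
        assert 0.0 <= res.r2x <= 1.0 and 0.0 <= res.r2 <= 1.0

    def test_orthogonal_scores_uncorrelated_with_classes(self, rng):
        X = rng.normal(size=(30, 25))
        labels = np.array(["a", "b", "c"] * 10)
        res = OPLSDA(X, labels).fit(compute_q2=False)
        scores = res.orthogonal_scores()
        Y = np.zeros((30, 3))
        for j, c in enumerate(res.classes):
            Y[labels == c, j] = 1.0
        Yc = Y - Y.mean(axis=0)
        corr = scores.T @ Yc
        # t_o = Xc w_o with w_o orthogonal to the X-Y covariance basis
        assert np.max(np.abs(corr)) < 1e-8

    def test_zero_orthogonal_components_reduce_to_plsda(self, rng):
        X = rng.normal(size=(25, 12))
        labels = np.array(["a", "b"] * 12 + ["a"])
        res = OPLSDA(X, labels, n_predictive=2, n_orthogonal=0).fit(compute_q2=False)
        Y = np.zeros((25, 2))
        for j, c in enumerate(res.classes):
            Y[labels == c, j] = 1.0
        pls = PLSRegression(n_components=2, scale=False).fit(X - X.mean(axis=0), Y)
        np.testing.assert_allclose(
            res.predict_scores(X), pls.predict(X - X.mean(axis=0)), atol=1e-8)

    def test_excessive_components_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        labels = ["a", "b", "a", "b", "a", "b"]
        with pytest.raises(ValueError, match="rank"):
            OPLSDA(X, labels, n_predictive=3, n_orthogonal=2)


class TestRMSX:
    def test_class_mean_has_zero_rms(self, rng):
        X = rng.normal(size=(10, 8))
        labels = ["a"] * 5 + ["b"] * 5
        res = RMSX(X, labels).fit()
        rms = res.rms_table(res.class_means["a"][None, :])
        assert rms["a"][0] == pytest.approx(0.0, abs=1e-12)

    def test_rms_invariant_to_consistent_reordering(self, rng):
        X = rng.normal(size=(12, 9))
        labels = ["a", "b"] * 6
        res = RMSX(X, labels).fit()
        perm = rng.permutation(9)
        res_p = RMSX(X[:, perm], labels).fit()
        np.testing.assert_allclose(res.rms_table(X).to_numpy(),
                                   res_p.rms_table(X[:, perm]).to_numpy(),
                                   atol=1e-12)

    def test_two_class_closed_form_distance(self):
        delta = 0.4
        a = np.zeros((3, 6))
        b = np.full((3, 6), delta)
        res = RMSX(np.vstack([a, b]), ["a"] * 3 + ["b"] * 3).fit()
        rms = res.rms_table(np.zeros((1, 6)))
        assert rms["b"][0] == pytest.approx(delta)
        assert rms["a"][0] == pytest.approx(0.0, abs=1e-12)

    def test_equidistant_sample_goes_to_first_class_with_warning(self):
        a = np.zeros((3, 4)); a[:, 0] = [0.1, -0.1, 0.0]
        b = np.ones((3, 4));  b[:, 0] = [1.1, 0.9, 1.0]
        res = RMSX(np.vstack([a, b]), ["a"] * 3 + ["b"] * 3).fit()
        midpoint = np.full((1, 4), 0.5)
        with pytest.warns(UserWarning, match="equidistant"):
            labels, _ = res.classify(midpoint, rule="raw")
        assert labels[0] == "a"

    def test_pure_classes_perfect_on_calibration_split(self, default_split):
        cal, _ = default_split
        y = assign_groups(cal, PURE_VS_BLENDS)
        res = RMSX(cal, y, pretreatment="Detrend (2,4,4,1)").fit()
        pred, _ = res.classify(cal)
        rep = confusion_metrics(y, pred, PURE_VS_BLENDS.classes)
        for c in ("black pure", "red pure", "green pure"):
            assert rep.per_class.loc[c, "pct_correct"] == pytest.approx(100.0)

    def test_accuracy_nonincreasing_in_noise(self):
        """Validation accuracy of the 6-group RMS-X classifier does not
        improve as measurement noise grows (3-level grid, averaged seeds)."""
        levels = (0.001, 0.008, 0.016)
        means = []
        for noise in levels:
            accs = []
            for seed in range(10):
                lib = generate_library(GeneratorConfig(seed=seed, noise_sd=noise))
                cal, val = split_sets(lib, 0.8, seed=seed)
                y_cal = assign_groups(cal, PURE_VS_BLENDS)
                y_val = assign_groups(val, PURE_VS_BLENDS)
                res = RMSX(cal, y_cal, pretreatment="Detrend (2,4,4,1)").fit()
                pred, _ = res.classify(val)
                accs.append(np.mean(pred == y_val))
            means.append(np.mean(accs))
        assert means[0] >= means[1] >= means[2]

    def test_misclassifications_stay_in_neighbouring_purity_bins(self):
        """Blend-percentage errors land in the same or an adjacent purity bin
        (counting the co-constituent tea's bin at the 50/50 boundary) in at
        least 90% of cases."""
        order = {">95%": 3, "95-85%": 2, "85-75%": 1, "75-50%": 0}
        near = total = 0
        for seed in range(5):
            lib = generate_library(GeneratorConfig(seed=seed))
            cal, val = split_sets(lib, 0.8, seed=seed)
            y_cal = assign_groups(cal, BLEND_PERCENTAGE)
            y_val = assign_groups(val, BLEND_PERCENTAGE)
            res = RMSX(cal, y_cal, pretreatment="Detrend (2,4,4,1)").fit()
            pred, _ = res.classify(val)
            for a, b in zip(y_val, pred):
                if a == b:
                    continue
                total += 1
                bin_a, _ = a.split(" ", 1)
                bin_b, _ = b.split(" ", 1)
                if abs(order[bin_a] - order[bin_b]) <= 1:
                    near += 1
        assert total > 0
        assert near / total >= 0.90


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        rep = confusion_metrics(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        assert rep.overall_accuracy == 1.0
        assert (rep.per_class["sensitivity"] == 1.0).all()
        assert (rep.per_class["specificity"] == 1.0).all()

    def test_degenerate_always_a_classifier(self):
        rep = confusion_metrics(["a", "a", "b", "b"], ["a"] * 4, ["a", "b"])
        pc = rep.per_class
        assert pc.loc["a", "sensitivity"] == 1.0
        assert pc.loc["a", "specificity"] == 0.0
        assert pc.loc["b", "sensitivity"] == 0.0
        assert pc.loc["b", "specificity"] == 1.0

    def test_hand_counted_three_class_table(self):
        true = ["a"] * 3 + ["b"] * 3 + ["c"] * 4
        pred = ["a", "a", "b", "b", "b", "b", "a", "c", "c", "c"]
        rep = confusion_metrics(true, pred, ["a", "b", "c"])
        pc = rep.per_class
        assert pc.loc["a", "sensitivity"] == pytest.approx(2 / 3)
        assert pc.loc["b", "sensitivity"] == pytest.approx(1.0)
        assert pc.loc["c", "sensitivity"] == pytest.approx(3 / 4)
        # specificity from complement counts: a receives 1 foreign of 7
        assert pc.loc["a", "specificity"] == pytest.approx(6 / 7)
        assert pc.loc["b", "specificity"] == pytest.approx(6 / 7)
        assert pc.loc["c", "specificity"] == pytest.approx(1.0)
        assert rep.overall_accuracy == pytest.approx(0.8)

    def test_specificity_one_when_no_foreign_assignment(self):
        rep = confusion_metrics(["a", "a", "b"], ["a", "a", "a"], ["a", "b"])
        assert rep.per_class.loc["b", "specificity"] == 1.0

    def test_no_class_counts_as_misclassification(self):
        rep = confusion_metrics(["a", "a"], ["a", NO_CLASS], ["a", "b"])
        assert rep.per_class.loc["a", "sensitivity"] == pytest.approx(0.5)
        assert rep.overall_accuracy == pytest.approx(0.5)

    def test_unknown_true_label_rejected(self):
        with pytest.raises(ValueError, match="outside the class set"):
            confusion_metrics(["z"], ["a"], ["a", "b"])
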