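"""Harmonization, discriminant pipeline, calibration, CV and embedding."""

import numpy as np
import pandas as pd
import pytest

from stpkit import (
    IntrinsicPopulationSpec,
    SubclassClassifier,
    cross_validate,
    embed,
    fit_classifier,
    harmonize_features,
    probability_correlations,
    simulate_intrinsic_features,
)
from stpkit.classifier import protocol_eta_squared


class TestHarmonization:
    def test_protocol_indicator_feature_excluded(self, rng):
        n = 200
        protocol = np.repeat(["connectivity", "patch-seq"], n // 2)
        df = pd.DataFrame(
            {
                "confounded": (protocol == "patch-seq") * 10.0 + rng.normal(0, 0.1, n),
                "clean": rng.normal(size=n),
                "protocol": protocol,
            }
        )
        res = harmonize_features(df)
        assert "confounded" not in res.retained
        assert "clean" in res.retained
        assert res.eta_squared["confounded"] > 0.99

    def test_independent_feature_eta_near_zero(self, rng):
        n = 10_000
        protocol = np.repeat(["connectivity", "patch-seq"], n // 2)
        vals = rng.normal(size=n)
        assert protocol_eta_squared(vals, protocol) < 0.001

    def test_eta_exactly_at_threshold_retained(self):
        # two groups of two values; eta2 computed, then used as the threshold
        df = pd.DataFrame(
            {
                "f": [0.0, 1.0, 0.5, 1.5],
                "protocol": ["connectivity", "connectivity", "patch-seq", "patch-seq"],
            }
        )
        e = protocol_eta_squared(df["f"].to_numpy(), df["protocol"].to_numpy())
        res = harmonize_features(df, threshold=e)  # strict '>' keeps it
        assert "f" in res.retained

    def test_sparse_feature_excluded_with_warning(self, rng):
        df = pd.DataFrame(
            {
                "sparse": [1.0, np.nan, np.nan, 2.0],
                "protocol": ["connectivity", "connectivity", "patch-seq", "patch-seq"],
            }
        )
        with pytest.warns(UserWarning):
            res = harmonize_features(df)
        assert res.retained == []

    def test_single_protocol_rejected(self, rng):
        df = pd.DataFrame({"f": rng.normal(size=5), "protocol": ["connectivity"] * 5})
        with pytest.raises(ValueError):
            harmonize_features(df)


def two_class_table(rng, n=300, separation=6.0, missing=0.0):
    """1-D Mahalanobis separation `separation` on two informative features."""
    spec = IntrinsicPopulationSpec(n_per_class=n // 2, missing_rate=missing)
    sep = np.zeros(len(spec.feature_names))
    sep[:2] = separation / np.sqrt(2)
    spec.class_means = {"PVALB": -sep / 2, "non-PVALB": sep / 2}
    return simulate_intrinsic_features(spec, seed=int(rng.integers(1 << 30)))


class TestClassifierPipeline:
    def test_separated_classes_high_cv_accuracy(self, rng):
        tab = two_class_table(rng, n=400, separation=6.0)
        feats = [c for c in tab.columns if c not in ("protocol", "subclass")]
        rep = cross_validate(tab, feats, seed=1)
        assert rep.accuracy >= 0.99

    def test_identical_classes_chance_accuracy(self, rng):
        tab = two_class_table(rng, n=2000, separation=0.0)
        feats = [c for c in tab.columns if c not in ("protocol", "subclass")]
        rep = cross_validate(tab, feats, seed=2)
        assert rep.accuracy == pytest.approx(0.5, abs=0.05)

    def test_single_missing_value_imputed_from_only_neighbor(self):
        df = pd.DataFrame(
            {
                "a": [0.0, 1.0, 0.0, 1.0, np.nan],
                "b": [0.0, 1.0, 0.1, 1.1, 0.05],
                "subclass": ["PVALB", "non-PVALB", "PVALB", "non-PVALB", "PVALB"],
            }
        )
        clf = SubclassClassifier(["a", "b"], n_neighbors=1).fit(df)
        Xs = clf.scaler_.transform(df[["a", "b"]].to_numpy())
        Xi = clf.imputer_.transform(Xs)
        # nearest neighbour in scaled space is row 2 (b = 0.1)
        assert Xi[4, 0] == pytest.approx(Xs[2, 0])

    def test_zero_iqr_feature_dropped(self, rng):
        tab = two_class_table(rng, n=100)
        tab["constant"] = 1.0
        feats = [c for c in tab.columns if c not in ("protocol", "subclass")]
        with pytest.warns(UserWarning):
            clf = SubclassClassifier(feats).fit(tab)
        assert "constant" not in clf.used_features_


class TestCalibration:
    def test_banded_labels_follow_probability(self):
        clf = SubclassClassifier(["f"])
        clf.used_features_ = ["f"]
        for p, want in [(0.7, "PVALB"), (0.5, "uncertain"), (0.2, "non-PVALB"),
                        (0.4, "uncertain"), (0.6, "uncertain")]:
            lo, hi = clf.uncertain_band
            label = ("uncertain" if lo <= p <= hi
                     else "PVALB" if p > hi else "non-PVALB")
            assert label == want

    def test_calibration_monotone_and_bounded(self, rng):
        tab = two_class_table(rng, n=300, separation=4.0)
        feats = [c for c in tab.columns if c not in ("protocol", "subclass")]
        clf = fit_classifier(tab, feats)
        raw = clf._raw_probability(tab)
        cal = clf.predict_proba(tab)
        assert np.all((cal >= 0) & (cal <= 1))
        order = np.argsort(raw)
        assert np.all(np.diff(cal[order]) >= -1e-12)  # ranking preserved

    def test_training_point_of_separated_class_confident(self, rng):
        tab = two_class_table(rng, n=300, separation=6.0)
        feats = [c for c in tab.columns if c not in ("protocol", "subclass")]
        clf = fit_classifier(tab, feats)
        pv = tab[tab.subclass == "PVALB"]
        probs = clf.predict_proba(pv)
        assert np.median(probs) > 0.9

    def test_sigmoid_alternative_available(self, rng):
        tab = two_class_table(rng, n=200, separation=4.0)
        feats = [c for c in tab.columns if c not in ("protocol", "subclass")]
        clf = fit_classifier(tab, feats, calibration="sigmoid")
        p = clf.predict_proba(tab)
        assert np.all((p >= 0) & (p <= 1))

    def test_json_round_trip_preserves_predictions(self, rng):
        tab = two_class_table(rng, n=200, separation=4.0, missing=0.05)
        feats = [c for c in tab.columns if c not in ("protocol", "subclass")]
        clf = fit_classifier(tab, feats)
        clf2 = SubclassClassifier.from_json(clf.to_json())
        np.testing.assert_allclose(clf2.predict_proba(tab), clf.predict_proba(tab))


class TestCrossValidation:
    def test_report_consistent_with_confusion_matrix(self, feature_table):
        feats = harmonize_features(feature_table).retained
        rep = cross_validate(feature_table, feats, seed=3)
        (tn, fp), (fn, tp) = rep.confusion
        total = tn + fp + fn + tp
        assert total == len(feature_table)
        assert rep.accuracy == pytest.approx((tp + tn) / total)
        assert rep.false_positive_rate == pytest.approx(fp / (fp + tn))
        assert rep.false_negative_rate == pytest.approx(fn / (fn + tp))
        # FPR + specificity = 1 on any confusion matrix
        assert rep.false_positive_rate + tn / (fp + tn) == pytest.approx(1.0)

    def test_label_permutation_null(self, rng):
        tab = two_class_table(rng, n=2000, separation=6.0)
        tab = tab.assign(subclass=rng.permutation(tab["subclass"].to_numpy()))
        feats = [c for c in tab.columns if c not in ("protocol", "subclass")]
        rep = cross_validate(tab, feats, seed=4)
        assert rep.accuracy == pytest.approx(0.5, abs=0.05)

    def test_small_class_reduces_folds(self, rng):
        tab = two_class_table(rng, n=60, separation=6.0)
        tab = pd.concat([tab[tab.subclass == "PVALB"].head(3),
                         tab[tab.subclass == "non-PVALB"]]).reset_index(drop=True)
        feats = [c for c in tab.columns if c not in ("protocol", "subclass")]
        with pytest.warns(UserWarning):
            rep = cross_validate(tab, feats, n_folds=5, seed=5)
        assert rep.n_folds == 3


class TestEmbedding:
    def test_deterministic_and_separating(self, rng):
        tab = two_class_table(rng, n=60, separation=8.0)
        feats = [c for c in tab.columns if c not in ("protocol", "subclass")]
        xy1 = embed(tab, feats, seed=9)
        xy2 = embed(tab, feats, seed=9)
        np.testing.assert_allclose(xy1, xy2)
        lab = tab["subclass"].to_numpy()
        c1, c2 = xy1[lab == "PVALB"].mean(0), xy1[lab == "non-PVALB"].mean(0)
        intra = np.linalg.norm(xy1[lab == "PVALB"] - c1, axis=1).mean()
        assert np.linalg.norm(c1 - c2) > intra

    def test_minimum_size(self, rng):
        tab = two_class_table(rng, n=8)
        feats = [c for c in tab.columns if c not in ("protocol", "subclass")]
        assert embed(tab.head(4), feats, seed=0).shape == (4, 2)
        with pytest.raises(ValueError):
            embed(tab.head(3), feats, seed=0)


class TestProbabilityCorrelations:
    def test_exact_linear_relation(self):
        prob = pd.Series(np.linspace(0.1, 0.9, 10))
        ppr = 2.0 - prob
        amp = 1.0 + 3.0 * prob
        out = probability_correlations(prob, ppr, amp)
        assert out["ppr"].slope == pytest.approx(-1.0)
        assert out["ppr"].r_squared == pytest.approx(1.0)
        assert out["amplitude"].slope == pytest.approx(3.0)

    def test_constant_probability_rejected(self):
        prob = pd.Series(np.full(10, 0.5))
        with pytest.raises(ValueError):
            probability_correlations(prob, prob * 0 + 1.0, prob * 0 + 2.0)

    def test_too_few_pairs_rejected(self):
        prob = pd.Series([0.1, 0.9])
        with pytest.raises(ValueError):
            probability_correlations(prob, prob, prob)
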