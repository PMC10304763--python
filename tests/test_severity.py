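"""Severity encoding, per-DMR linear models, marker screens and classifiers."""

import numpy as np
import pandas as pd
import pytest

from cfmeth.severity import (
    encode_severity,
    fit_dmr_model,
    fit_marker_models,
    fit_severity_models,
    pca_embed,
    select_associated_dmrs,
    single_marker_multinomial,
    train_acs_classifiers,
)


class TestEncode:
    def test_codes(self):
        y = encode_severity(["UA", "NSTEMI", "STEMI"])
        assert list(y) == [1.0, 2.0, 3.0]

    def test_controls_coded_zero_when_included(self):
        y = encode_severity(["control", "STEMI"], include_controls=True)
        assert list(y) == [0.0, 3.0]

    def test_controls_dropped_by_default(self):
        y = encode_severity(["control", "STEMI"])
        assert list(y) == [3.0]

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            encode_severity(["STEMI", "mystery"])


class TestDMRModel:
    def test_exact_linear_response_recovers_slope(self):
        rng = np.random.default_rng(1)
        meth = rng.uniform(0, 100, 20)
        ccf = rng.uniform(5, 30, 20)
        y = 0.05 * meth  # exactly linear in methylation, no ccfDNA effect
        fit = fit_dmr_model(y, meth, ccf)
        assert fit.beta1 == pytest.approx(0.05, abs=1e-10)
        assert fit.beta0 == pytest.approx(0.0, abs=1e-9)
        assert fit.p_F < 1e-12

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(6, 40))
            meth = rng.uniform(0, 100, n)
            ccf = rng.uniform(1, 50, n)
            y = rng.normal(0, 1, n) + 0.01 * meth
            fit = fit_dmr_model(y, meth, ccf)
            assert fit.F_nested == pytest.approx(fit.t_beta1**2, abs=1e-8)
            assert 0 <= fit.p_beta1 <= 1
            assert fit.p_F == pytest.approx(fit.p_beta1, abs=1e-10)

    def test_null_fit_usually_insignificant(self):
        rng = np.random.default_rng(3)
        meth = rng.uniform(0, 100, 30)
        fit = fit_dmr_model(rng.normal(2, 1, 30), meth, rng.uniform(1, 20, 30))
        assert fit.p_beta1 > 0.05

    def test_constant_methylation_flagged(self):
        fit = fit_dmr_model(np.arange(6.0), np.full(6, 50.0), np.arange(6.0))
        assert fit.flagged
        assert fit.p_beta1 == 1.0

    def test_missing_values_dropped_casewise(self):
        y = np.array([1, 2, 3, 1, 2, 3, np.nan])
        meth = np.array([10, 20, 30, 12, 22, 32, 40.0])
        ccf = np.array([5, 6, 7, 5, 6, np.nan, 7.0])
        fit = fit_dmr_model(y, meth, ccf)
        assert fit.n_samples == 5

    def test_agrees_with_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        meth = rng.uniform(0, 100, 25)
        ccf = rng.uniform(1, 40, 25)
        y = 1.0 + 0.02 * meth - 0.01 * ccf + rng.normal(0, 0.4, 25)
        fit = fit_dmr_model(y, meth, ccf)
        ref = sm.OLS(y, sm.add_constant(np.column_stack([meth, ccf]))).fit()
        assert fit.beta1 == pytest.approx(ref.params[1], rel=1e-9)
        assert fit.t_beta1 == pytest.approx(ref.tvalues[1], rel=1e-9)
        assert fit.p_beta1 == pytest.approx(ref.pvalues[1], rel=1e-9)


class TestSelection:
    def test_fraction_reported(self):
        fits = pd.DataFrame({"p_beta1": [0.01, 0.5]})
        kept, fraction = select_associated_dmrs(fits)
        assert len(kept) == 1
        assert fraction == pytest.approx(0.5)

    def test_empty_and_permissive_alpha(self):
        kept, frac = select_associated_dmrs(pd.DataFrame({"p_beta1": []}))
        assert kept.empty
        fits = pd.DataFrame({"p_beta1": [0.3, 0.9]})
        assert len(select_associated_dmrs(fits, alpha=1.0)[0]) == 2


class TestMarkerModels:
    def test_constructed_marker_hits_its_dmr(self):
        rng = np.random.default_rng(5)
        n = 24
        meths = pd.DataFrame(
            rng.uniform(0, 100, (n, 10)), columns=[f"dmr_{i}" for i in range(10)]
        )
        ccf = rng.uniform(1, 30, n)
        markers = pd.DataFrame({"tracker": 2.0 * meths["dmr_7"] + rng.normal(0, 1, n)})
        table = fit_marker_models(markers, meths, ccf)
        hit = table.set_index("dmr_id").loc["dmr_7", "p_beta1"]
        assert hit < 1e-6
        others = table.set_index("dmr_id").drop("dmr_7")["p_beta1"]
        assert (others < 0.05).mean() < 0.3

    def test_sparse_marker_skipped(self):
        meths = pd.DataFrame({"d": np.arange(8.0)})
        markers = pd.DataFrame({"rare": [1.0, 2.0] + [np.nan] * 6})
        with pytest.warns(UserWarning, match="skipped"):
            table = fit_marker_models(markers, meths, np.arange(8.0))
        assert table.empty


class TestMultinomial:
    def test_separable_marker_classifies_perfectly(self):
        marker = np.array([1, 1.2, 1.1, 5, 5.2, 5.1, 9, 9.2, 9.1])
        labels = np.repeat(["UA", "NSTEMI", "STEMI"], 3)
        rate, _ = single_marker_multinomial(marker, labels)
        assert rate == 0.0

    def test_constant_marker_gives_majority_rate(self):
        marker = np.ones(9)
        labels = np.repeat(["UA", "NSTEMI", "STEMI"], 3)
        rate, _ = single_marker_multinomial(marker, labels)
        assert rate == pytest.approx(100 * 6 / 9, abs=0.1)

    def test_missing_values_excluded(self):
        marker = np.array([1, 1, 5, 5, np.nan, np.nan, 9, 9])
        labels = np.array(["a", "a", "b", "b", "a", "b", "c", "c"])
        rate, _ = single_marker_multinomial(marker, labels)
        assert rate == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            single_marker_multinomial(np.arange(4.0), ["a"] * 4)


@pytest.fixture(scope="module")
def onehot_cohort():
    rng = np.random.default_rng(6)
    labels = np.repeat(["UA", "NSTEMI", "STEMI"], 10)
    onehot = pd.get_dummies(pd.Series(labels)).astype(float)
    features = onehot + rng.normal(0, 0.01, onehot.shape)
    features.columns = [f"f{i}" for i in range(3)]
    return features, labels


class TestClassifiers:

    def test_onehot_features_classified_perfectly(self, onehot_cohort):
        features, labels = onehot_cohort
        results = train_acs_classifiers(features, labels, cv_repeats=2, seed=1)
        for model, entry in results.items():
            assert entry["holdout_accuracy"] == 1.0, model

    def test_same_seed_reproducible(self, onehot_cohort):
        features, labels = onehot_cohort
        a = train_acs_classifiers(features, labels, models=("rf",), cv_repeats=1, seed=4)
        b = train_acs_classifiers(features, labels, models=("rf",), cv_repeats=1, seed=4)
        assert a["rf"]["holdout_accuracy"] == b["rf"]["holdout_accuracy"]
        assert a["rf"]["cv_accuracy"] == b["rf"]["cv_accuracy"]

    def test_incomplete_features_rejected(self, onehot_cohort):
        features, labels = onehot_cohort
        broken = features.copy()
        broken.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            train_acs_classifiers(broken, labels)


class TestPCA:
    def test_identical_samples_identical_coordinates(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]] * 2 + [[4.0, 5.0, 6.0]], index=["a", "b", "c"])
        coords, _ = pca_embed(m)
        assert coords.loc["a"].to_numpy() == pytest.approx(coords.loc["b"].to_numpy())

    def test_single_varying_column_drives_pc1(self):
        m = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": 5.0, "z": 7.0})
        coords, evr = pca_embed(m)
        assert evr[0] == pytest.approx(1.0)

    def test_group_shifted_cohort_separates(self):
        rng = np.random.default_rng(8)
        groups = np.repeat([0, 1, 2, 3], 8)
        shift = np.outer(groups, np.ones(20)) * 10.0
        m = pd.DataFrame(shift + rng.normal(0, 1, (32, 20)))
        coords, _ = pca_embed(m)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(coords.to_numpy(), groups) > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            pca_embed(pd.DataFrame([[1.0, 2.0]]))
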