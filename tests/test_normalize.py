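"""Transform round trips, quantile normalization, ComBat, concordance."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from cfmeth.normalize import (
    back_transform,
    combat_adjust,
    concordance_report,
    logit_like_transform,
    normalize_validation_cohort,
    quantile_normalize_to_target,
)


class TestTransform:
    def test_symmetry_and_boundaries(self):
        assert logit_like_transform(50.0) == pytest.approx(0.0)
        assert logit_like_transform(100.0) == pytest.approx(np.log(101.0))
        assert logit_like_transform(0.0) == pytest.approx(-np.log(101.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            logit_like_transform(-0.1)
        with pytest.raises(ValueError):
            logit_like_transform(100.1)

    def test_back_transform_known_points(self):
        assert back_transform(0.0) == pytest.approx(50.0)
        assert back_transform(np.log(101.0)) == pytest.approx(100.0)

    def test_round_trip_identity_on_grid(self):
        x = np.linspace(0, 100, 201)
        assert np.abs(back_transform(logit_like_transform(x)) - x).max() < 1e-9

    def test_forward_is_monotone(self):
        x = np.linspace(0, 100, 500)
        assert (np.diff(logit_like_transform(x)) > 0).all()


class TestQuantileNormalize:
    def test_sample_equal_to_target_is_fixed_point(self):
        target = np.array([1.0, 4.0, 9.0, 16.0])
        samples = pd.DataFrame({"s": [9.0, 1.0, 16.0, 4.0]})
        out = quantile_normalize_to_target(samples, target)
        pd.testing.assert_frame_equal(out, samples)

    def test_rank_replacement_by_hand(self):
        out = quantile_normalize_to_target(pd.DataFrame({"s": [3.0, 1.0, 2.0]}), [10, 20, 30])
        assert list(out["s"]) == [30.0, 10.0, 20.0]

    def test_constant_sample_maps_to_target_median(self):
        out = quantile_normalize_to_target(pd.DataFrame({"s": [5.0, 5.0, 5.0]}), [10, 20, 40])
        assert out["s"].to_numpy() == pytest.approx([20.0, 20.0, 20.0])

    def test_sorted_values_equal_target_exactly(self):
        rng = np.random.default_rng(1)
        target = np.sort(rng.normal(0, 1, 50))
        samples = pd.DataFrame(rng.normal(5, 3, (50, 4)), columns=list("abcd"))
        out = quantile_normalize_to_target(samples, target)
        for col in out:
            assert np.sort(out[col].to_numpy()) == pytest.approx(target)

    def test_unequal_target_length_interpolates(self):
        out = quantile_normalize_to_target(pd.DataFrame({"s": [1.0, 2.0]}), [0.0, 10.0, 20.0])
        assert list(out["s"]) == [0.0, 20.0]

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValueError, match="entirely missing"):
            quantile_normalize_to_target(pd.DataFrame({"s": [np.nan, np.nan]}), [1.0])


def two_batch_data(n_features=200, n_per_batch=10, shift=1.0, seed=0, paired=True,
                   feature_sd=None):
    """Two-batch matrix; ``paired`` makes batch 2 an exact +shift copy of batch 1."""
    rng = np.random.default_rng(seed)
    mu = rng.normal(0, 1, n_features)
    sd = np.ones(n_features) if feature_sd is None else feature_sd
    B1 = mu[:, None] + sd[:, None] * rng.normal(0, 1, (n_features, n_per_batch))
    if paired:
        B2 = B1 + shift
    else:
        B2 = mu[:, None] + sd[:, None] * rng.normal(0, 1, (n_features, n_per_batch)) + shift
    X = np.hstack([B1, B2])
    batches = ["b1"] * n_per_batch + ["b2"] * n_per_batch
    return pd.DataFrame(X), batches


class TestComBat:
    def test_identical_batches_nearly_unchanged(self):
        X, batches = two_batch_data(shift=0.0, seed=3)
        out = combat_adjust(X, batches)
        # only the empirical-Bayes scale shrinkage moves values here
        assert (out - X).abs().to_numpy().max() < 0.5
        assert (out - X).abs().to_numpy().mean() < 0.1

    def test_constant_shift_removed(self):
        X, batches = two_batch_data(shift=2.0, seed=4)
        out = combat_adjust(X, batches)
        gap = out.iloc[:, 10:].mean(axis=1) - out.iloc[:, :10].mean(axis=1)
        assert abs(gap.mean()) < 0.1  # overall batch offset gone
        assert (gap**2).mean() < 0.05 * 4.0  # per-feature gap variance collapsed

    def test_between_batch_variance_reduced(self):
        X, batches = two_batch_data(shift=1.0, seed=5, paired=False)
        def between_var(df):
            return ((df.iloc[:, :10].mean(axis=1) - df.iloc[:, 10:].mean(axis=1)) ** 2).mean()
        assert between_var(combat_adjust(X, batches)) < 0.1 * between_var(X)

    def test_within_batch_order_mostly_preserved(self):
        from scipy.stats import spearmanr

        X, batches = two_batch_data(shift=1.0, seed=6, paired=False)
        out = combat_adjust(X, batches)
        rhos = [
            spearmanr(X.iloc[i, :10], out.iloc[i, :10]).statistic for i in range(50)
        ]
        assert np.mean(rhos) >= 0.9

    def test_single_batch_and_singleton_batch_rejected(self):
        X, _ = two_batch_data()
        with pytest.raises(ValueError, match="two batches"):
            combat_adjust(X, ["b1"] * 20)
        with pytest.raises(ValueError, match="single sample"):
            combat_adjust(X, ["b1"] * 19 + ["b2"])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_matches_reference_sva_combat(self, tmp_path):
        """Independent oracle: the R sva package's ComBat on the same matrix."""
        X, batches = two_batch_data(n_features=60, n_per_batch=5, shift=1.0, seed=7)
        X.to_csv(tmp_path / "x.csv", index=False)
        script = textwrap.dedent(
            """
            suppressMessages(library(sva))
            x <- as.matrix(read.csv(file.path(commandArgs(TRUE)[1], "x.csv")))
            batch <- rep(c("b1", "b2"), each = 5)
            out <- ComBat(dat = x, batch = batch)
            write.csv(out, file.path(commandArgs(TRUE)[1], "ref.csv"), row.names = FALSE)
            """
        )
        (tmp_path / "combat.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "combat.R"), str(tmp_path)],
            check=True, capture_output=True, timeout=300,
        )
        ref = pd.read_csv(tmp_path / "ref.csv").to_numpy()
        ours = combat_adjust(X, batches).to_numpy()
        assert np.abs(ours - ref).max() < 1e-4


class TestPipeline:
    def make_cohorts(self, shift=0.0, seed=0, n_dmrs=40):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"dmr_{i}" for i in range(n_dmrs)])
        disc = pd.DataFrame(
            rng.uniform(5, 95, (n_dmrs, 8)), index=idx,
            columns=[f"d{i}" for i in range(8)],
        )
        t = logit_like_transform(disc.to_numpy())
        val = pd.DataFrame(
            back_transform(t[:, :5] + shift), index=idx, columns=[f"v{i}" for i in range(5)]
        )
        return disc, val

    def test_identical_cohorts_are_near_fixed_point(self):
        disc, _ = self.make_cohorts(seed=2)
        val = disc.iloc[:, :5].copy()
        val.columns = [f"v{i}" for i in range(5)]
        disc_n, val_n = normalize_validation_cohort(disc, val)
        assert (disc_n - disc).abs().to_numpy().mean() < 3.0
        assert np.corrcoef(val_n.to_numpy().ravel(), val.to_numpy().ravel())[0, 1] > 0.98

    def test_batch_shift_removed(self):
        disc, val = self.make_cohorts(shift=1.0, seed=3)
        _, val_raw_gap = None, (
            logit_like_transform(val.to_numpy()).mean()
            - logit_like_transform(disc.to_numpy()).mean()
        )
        disc_n, val_n = normalize_validation_cohort(disc, val)
        gap = (
            logit_like_transform(np.clip(val_n.to_numpy(), 0, 100)).mean()
            - logit_like_transform(np.clip(disc_n.to_numpy(), 0, 100)).mean()
        )
        assert abs(gap) < 0.1 * abs(val_raw_gap)

    def test_per_sample_order_essentially_preserved(self):
        # forward/back transforms and quantile normalization are monotone per
        # sample; the per-feature batch adjustment may swap near-ties only
        from scipy.stats import spearmanr

        disc, val = self.make_cohorts(shift=0.5, seed=4)
        _, val_n = normalize_validation_cohort(disc, val)
        for col in val:
            assert spearmanr(val[col], val_n[col]).statistic > 0.99

    def test_empty_shared_index_rejected(self):
        disc, val = self.make_cohorts()
        val.index = [f"other_{i}" for i in range(len(val))]
        with pytest.raises(ValueError, match="no shared DMRs"):
            normalize_validation_cohort(disc, val)


class TestConcordance:
    def test_identical_diffs_correlate_perfectly(self):
        d = np.array([30.0, -40.0, 25.0, 10.0])
        report = concordance_report(d, d)
        assert report["pearson_r"] == pytest.approx(1.0)
        assert report["n_same_sign"] == 4

    def test_opposite_diffs_anticorrelate(self):
        d = np.array([30.0, -40.0, 25.0, 10.0])
        report = concordance_report(d, -d)
        assert report["pearson_r"] == pytest.approx(-1.0)
        assert report["n_same_sign"] == 0

    def test_toy_counts_by_enumeration(self):
        disc = np.array([30.0, -40.0, 28.0, 26.0, 10.0, -50.0])
        val = np.array([27.0, -35.0, 30.0, -26.0, 12.0, -60.0])
        q = np.array([0.001, 0.001, 0.001, 0.001, 0.5, 0.002])
        report = concordance_report(disc, val, validation_q=q)
        # q<=0.01: idx 0,1,2,3,5; same sign among those: 0,1,2,5; |val|>=25: all four
        assert report["n_significant"] == 5
        assert report["n_significant_same_sign"] == 4
        assert report["n_validated"] == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            concordance_report([1.0, 2.0], [1.0])
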