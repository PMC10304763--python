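"""Reference evaluation scenarios exercising the pipeline end to end.

Each function builds its own synthetic inputs from a seed, runs the package
and returns the measured quantities as a flat dict.  They back both the
acceptance test suite and ``scripts/acceptance.py``; problem sizes are kept
at desk scale (hundreds of mixtures, a few thousand windows, a 29-sample
cohort) so a full evaluation completes in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import SignatureMatrix
from .deconv import BulkProfile, deconvolute
from .dmr import call_dmrs, dm_test_regions, tile_counts
from .mixsim import benchmark_models, simulate_cell_mix
from .normalize import (
    back_transform,
    combat_adjust,
    logit_like_transform,
    quantile_normalize_to_target,
)
from .pipeline import (
    discovery_workflow,
    region_meth_percent,
    stage_seed,
    validation_workflow,
)
from .probemap import collapse_strands
from .severity import fit_dmr_model, train_acs_classifiers
from .synthetic import (
    CohortSpec,
    make_synthetic_atlas,
    manifest_from_atlas,
    simulate_targeted_panel,
    simulate_wgbs_cohort,
)

__all__ = [
    "noiseless_recovery",
    "benchmark_ordering",
    "transform_round_trip",
    "quantile_exactness",
    "batch_removal",
    "dm_test_calibration",
    "planted_dmr_recovery",
    "severity_model_recovery",
    "severity_null_calibration",
    "end_to_end_study",
]


def _random_signature(seed: int, n_probes: int, n_types: int) -> SignatureMatrix:
    rng = np.random.default_rng(seed)
    probes = pd.Index([f"cg{i:06d}" for i in range(n_probes)], name="probe_id")
    beta = pd.DataFrame(
        rng.uniform(0, 1, (n_probes, n_types)),
        index=probes,
        columns=[f"ct{i + 1:02d}" for i in range(n_types)],
    )
    return SignatureMatrix(beta, pd.Series("differential", index=probes))


def noiseless_recovery(
    seed: int, n_mixtures: int = 50, n_probes: int = 300, n_types: int = 10
) -> dict:
    """Exact-mixture recovery of nnls and qp on a full-rank signature."""
    signature = _random_signature(stage_seed(seed, "sig"), n_probes, n_types)
    rng = np.random.default_rng(stage_seed(seed, "mix"))
    S = signature.beta.to_numpy()
    max_err = {"nnls": 0.0, "qp": 0.0}
    for i in range(n_mixtures):
        p = rng.dirichlet(np.ones(n_types))
        bulk = BulkProfile(f"m{i}", pd.Series(np.clip(S @ p, 0, 1), index=signature.probe_ids))
        for model in max_err:
            res = deconvolute(bulk, signature, model)
            max_err[model] = max(max_err[model], float(np.abs(res.proportions.to_numpy() - p).max()))
    return {
        "max_abs_error_nnls": max_err["nnls"],
        "max_abs_error_qp": max_err["qp"],
        "n_mixtures": n_mixtures,
    }


def benchmark_ordering(
    seed: int, n_mixtures: int = 200, noise_sd: float = 0.05,
    n_probes: int = 400, n_types: int = 8,
) -> dict:
    """Four-model RMSE benchmark on noisy mixtures from a synthetic atlas."""
    atlas, _ = make_synthetic_atlas(
        n_cell_types=n_types, n_cpgs=n_probes, n_markers_per_type=10,
        marker_contrast=0.9, seed=stage_seed(seed, "atlas"),
    )
    signature = SignatureMatrix(
        atlas.beta, pd.Series("differential", index=atlas.beta.index)
    )
    mixtures = simulate_cell_mix(
        atlas, n_mixtures, noise_sd=noise_sd, seed=stage_seed(seed, "mixtures")
    )
    result = benchmark_models(mixtures, signature, seed=seed)
    out = {f"rmse_{m}": float(v) for m, v in result.rmse.items()}
    out["best_model"] = result.best_model
    # nnls and qp minimise the same constrained least-squares objective and
    # differ only in where the sum-to-one normalisation is applied; they are
    # treated as equivalent within 1% relative RMSE when ranking models
    out["nnls_is_best"] = bool(
        result.rmse["nnls"] <= result.rmse["svr"]
        and result.rmse["nnls"] <= result.rmse["rlm"]
        and result.rmse["nnls"] <= 1.01 * result.rmse["qp"]
    )
    out["n_mixtures"] = n_mixtures
    return out


def transform_round_trip(n_points: int = 201) -> dict:
    x = np.linspace(0.0, 100.0, n_points)
    err = np.abs(back_transform(logit_like_transform(x)) - x).max()
    return {"max_round_trip_error": float(err), "n_points": n_points}


def quantile_exactness(seed: int, n_values: int = 100, n_samples: int = 6) -> dict:
    rng = np.random.default_rng(stage_seed(seed, "qn"))
    target = np.sort(rng.normal(0, 1, n_values))
    samples = pd.DataFrame(
        rng.normal(3, 2, (n_values, n_samples)),
        columns=[f"s{i}" for i in range(n_samples)],
    )
    out = quantile_normalize_to_target(samples, target)
    dev = max(
        float(np.abs(np.sort(out[c].to_numpy()) - target).max()) for c in out
    )
    return {"max_sorted_deviation": dev, "n_values": n_values}


def batch_removal(
    seed: int, n_features: int = 200, n_per_batch: int = 10, shift: float = 1.0
) -> dict:
    """ComBat on two batches differing by a constant shift on the transformed scale."""
    rng = np.random.default_rng(stage_seed(seed, "batch"))
    mu = rng.normal(0, 1, n_features)
    B1 = mu[:, None] + rng.normal(0, 1, (n_features, n_per_batch))
    X = pd.DataFrame(np.hstack([B1, B1 + shift]))
    batches = ["b1"] * n_per_batch + ["b2"] * n_per_batch
    out = combat_adjust(X, batches)
    gap_pre = X.iloc[:, n_per_batch:].mean(axis=1) - X.iloc[:, :n_per_batch].mean(axis=1)
    gap_post = out.iloc[:, n_per_batch:].mean(axis=1) - out.iloc[:, :n_per_batch].mean(axis=1)
    reduction = 1.0 - float((gap_post**2).mean() / (gap_pre**2).mean())
    return {
        "mean_batch_gap": float(abs(gap_post.mean())),
        "between_batch_variance_reduction": reduction,
        "n_features": n_features,
    }


def dm_test_calibration(
    seed: int, n_windows: int = 2000, n_per_group: int = 10,
    coverage_lambda: float = 10.0, theta: float = 0.5, alpha: float = 0.05,
) -> dict:
    """Type-I error of the window LRT under a binomial null."""
    rng = np.random.default_rng(stage_seed(seed, "null-dm"))
    cov = rng.poisson(coverage_lambda, size=(n_windows, 2 * n_per_group)) + 1
    k = rng.binomial(cov, theta)
    windows = pd.MultiIndex.from_tuples(
        [("chrN", 1 + 500 * i) for i in range(n_windows)], names=["chrom", "start"]
    )
    samples = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    from .dmr import RegionCounts

    regions = RegionCounts(
        meth=pd.DataFrame(k, index=windows, columns=samples),
        coverage=pd.DataFrame(cov, index=windows, columns=samples),
        n_cpgs=pd.DataFrame(3, index=windows, columns=samples),
        window=500,
    )
    tests = dm_test_regions(regions, samples[:n_per_group], samples[n_per_group:])
    frac = float((tests["p_value"] <= alpha).mean())
    return {"type_i_error_at_5pct": frac, "n_windows": n_windows}


def planted_dmr_recovery(
    seed: int, n_cpgs: int = 2550, n_planted: int = 10, effect_pp: float = 40.0
) -> dict:
    """Recovery of planted DMR windows in a full cohort simulation."""
    atlas, _ = make_synthetic_atlas(
        n_cell_types=10, n_cpgs=n_cpgs, n_markers_per_type=10,
        marker_contrast=0.9, seed=stage_seed(seed, "atlas7"),
    )
    spec = CohortSpec(
        n_planted_dmrs=n_planted, effect_size_pp=effect_pp,
        seed=stage_seed(seed, "cohort7"),
    )
    cohort = simulate_wgbs_cohort(spec, atlas)
    collapsed = [collapse_strands(c) for c in cohort.callsets]
    regions = tile_counts(collapsed)
    groups = cohort.sample_sheet["group"]
    controls = list(groups.index[groups == "control"])
    stemi = list(groups.index[groups == "STEMI"])
    tests = dm_test_regions(regions, stemi, controls, comparison="STEMI_vs_control")
    dmrs = call_dmrs(tests)
    truth = cohort.dmr_truth
    planted = set(
        zip(truth.loc[truth["group"] == "STEMI", "chrom"],
            truth.loc[truth["group"] == "STEMI", "start"])
    )
    called = set(dmrs.index)
    return {
        "n_planted": len(planted),
        "n_recovered": len(planted & called),
        "n_false_positive": len(called - planted),
        "n_windows_tested": int(len(regions.windows)),
    }


def severity_model_recovery(
    seed: int, n_replicates: int = 100, n_samples: int = 30,
    beta1: float = 0.05, beta2: float = 0.02,
) -> dict:
    """F = t^2 identity and 95% CI coverage of the methylation coefficient."""
    rng = np.random.default_rng(stage_seed(seed, "sev8"))
    covered = 0
    max_identity_dev = 0.0
    tcrit = stats.t.ppf(0.975, n_samples - 3)
    for _ in range(n_replicates):
        meth = rng.uniform(0, 100, n_samples)
        ccf = rng.uniform(5, 40, n_samples)
        y = 1.0 + beta1 * meth + beta2 * ccf + rng.normal(0, 0.5, n_samples)
        fit = fit_dmr_model(y, meth, ccf)
        max_identity_dev = max(max_identity_dev, abs(fit.F_nested - fit.t_beta1**2))
        se = abs(fit.beta1 / fit.t_beta1)
        if abs(fit.beta1 - beta1) <= tcrit * se:
            covered += 1
    return {
        "max_f_t2_deviation": float(max_identity_dev),
        "ci95_coverage": covered / n_replicates,
        "n_replicates": n_replicates,
    }


def severity_null_calibration(
    seed: int, n_dmrs: int = 1000, n_samples: int = 21, alpha: float = 0.05
) -> dict:
    """Fraction of pure-null severity fits passing p <= alpha."""
    rng = np.random.default_rng(stage_seed(seed, "sev9"))
    y = rng.normal(2.0, 1.0, n_samples)
    ccf = rng.uniform(5, 40, n_samples)
    n_sig = 0
    for _ in range(n_dmrs):
        meth = rng.uniform(0, 100, n_samples)
        fit = fit_dmr_model(y, meth, ccf)
        n_sig += fit.p_beta1 <= alpha
    return {"null_fraction_significant": n_sig / n_dmrs, "n_dmrs": n_dmrs}


def end_to_end_study(seed: int, n_cpgs: int = 5000) -> dict:
    """Discovery plus validation workflows on the default 29-sample cohort."""
    from sklearn.metrics import silhouette_score

    from .atlas import SelectionConfig, make_signature

    atlas, _ = make_synthetic_atlas(
        n_cell_types=10, n_cpgs=n_cpgs, n_markers_per_type=15,
        marker_contrast=0.9, seed=stage_seed(seed, "atlas10"),
    )
    spec = CohortSpec(n_planted_dmrs=10, effect_size_pp=40.0, seed=stage_seed(seed, "cohort10"))
    cohort = simulate_wgbs_cohort(spec, atlas)
    signature = make_signature(atlas, SelectionConfig(k_top=15, k_diff=15))
    manifest = manifest_from_atlas(atlas)
    results = discovery_workflow(
        cohort.callsets, cohort.sample_sheet, signature, manifest, seed=seed
    )
    out: dict = {
        "n_dmrs_total": int(sum(len(t) for t in results["dmrs"].values())),
        "severity_fraction": float(results.get("severity_fraction", float("nan"))),
    }
    coords = results["pca"]
    out["pca_silhouette"] = float(
        silhouette_score(coords[["PC1", "PC2"]].to_numpy(), coords["group"].to_numpy())
    )
    for model, entry in results.get("classifier_metrics", {}).items():
        out[f"holdout_accuracy_{model}"] = entry["holdout_accuracy"]

    # label-permutation control: the same classifier on shuffled labels
    groups = cohort.sample_sheet["group"]
    dmr_meth = results["dmr_methylation"].T.dropna(axis=1)
    dmr_meth.columns = [f"{c}:{s}" for c, s in dmr_meth.columns]
    acs = [s for s in dmr_meth.index if groups.loc[s] != "control"]
    rng = np.random.default_rng(stage_seed(seed, "permute"))
    permuted = rng.permutation(groups.loc[acs].to_numpy())
    perm = train_acs_classifiers(
        dmr_meth.loc[acs], permuted, models=("rf",), cv_repeats=2,
        seed=stage_seed(seed, "perm-clf"),
    )
    acc = perm["rf"]["holdout_accuracy"]
    n_test = perm["rf"]["n_test"]
    chance = pd.Series(permuted).value_counts(normalize=True).max()
    p_chance = stats.binomtest(
        int(round(acc * n_test)), n_test, float(chance), alternative="greater"
    ).pvalue
    out["permuted_holdout_accuracy"] = float(acc)
    out["permuted_vs_chance_pvalue"] = float(p_chance)

    # validation arm: independent small cohort on a targeted panel with bias
    val_spec = CohortSpec(
        group_sizes={"control": 2, "STEMI": 4, "NSTEMI": 3, "UA": 2},
        seed=stage_seed(seed, "valcohort"),
    )
    val_cohort = simulate_wgbs_cohort(val_spec, atlas, planted_dmrs=cohort.dmr_truth)
    panel_calls = simulate_targeted_panel(
        val_cohort, atlas.beta.index, batch_shift=1.0, coverage_lambda=40,
        seed=stage_seed(seed, "panel"),
    )
    val_regions = tile_counts([collapse_strands(c) for c in panel_calls])
    disc_pct = region_meth_percent(results["regions"]).dropna()
    val_pct = region_meth_percent(val_regions).dropna()
    dmr_windows = pd.MultiIndex.from_frame(cohort.dmr_truth[["chrom", "start"]])
    shared = disc_pct.index.intersection(val_pct.index).intersection(dmr_windows)
    val_results = validation_workflow(
        disc_pct.loc[shared], val_pct.loc[shared],
        groups, val_cohort.sample_sheet["group"],
    )
    rs = [rep["pearson_r"] for rep in val_results["concordance"].values()]
    out["validation_pearson_r_min"] = float(min(rs))
    out["validation_pearson_r_mean"] = float(np.mean(rs))
    out["n_samples"] = int(len(cohort.sample_sheet))
    return out
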