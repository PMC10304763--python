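"""Cross-platform normalization of targeted-panel methylation percentages.

Targeted bisulfite/enzymatic panels show systematic location and scale
biases relative to whole-genome discovery data.  The pipeline applied here:

1. pseudo-count log transform  t = ln((x + 1) / ((100 - x) + 1))  mapping
   the [0, 100] percent scale to a finite symmetric scale;
2. quantile normalization of each validation sample to a target
   distribution taken from the discovery cohort;
3. parametric empirical-Bayes location/scale batch adjustment (ComBat)
   with batch = sequencing platform, no covariates;
4. the analytic inverse of the forward transform, back to percent.

Concordance between cohorts is summarised by the Pearson correlation of
per-DMR mean methylation differences and by counts of DMRs that replicate
sign and effect-size cutoffs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "logit_like_transform",
    "back_transform",
    "quantile_normalize_to_target",
    "combat_adjust",
    "normalize_validation_cohort",
    "concordance_report",
]


def logit_like_transform(x):
    """Pseudo-count log transform of methylation percent: ln((x+1)/(101-x)).

    Finite on the whole closed interval [0, 100]; values outside it raise.
    """
    x = np.asarray(x, dtype=float)
    bad = (x < 0) | (x > 100)
    if np.any(bad & np.isfinite(x)):
        raise ValueError("methylation percentages must lie in [0, 100]")
    return np.log((x + 1.0) / (101.0 - x))


def back_transform(t):
    """Analytic inverse of :func:`logit_like_transform`, clipped to [0, 100].

    Solving t = ln((x+1)/(101-x)) for x gives x = (101 e^t - 1)/(1 + e^t).
    """
    t = np.asarray(t, dtype=float)
    et = np.exp(t)
    x = (101.0 * et - 1.0) / (1.0 + et)
    return np.clip(x, 0.0, 100.0)


def quantile_normalize_to_target(samples: pd.DataFrame, target_quantiles) -> pd.DataFrame:
    """Force each sample column onto a reference distribution.

    Per column, values are ranked (average ranks on ties) and replaced by
    linear interpolation into the sorted target vector at the matching
    quantile position, so unequal target lengths are supported.  A column
    of the target's length with distinct values becomes a permutation of
    the target exactly.
    """
    target = np.sort(np.asarray(target_quantiles, dtype=float))
    if target.size == 0:
        raise ValueError("target distribution is empty")
    out = {}
    m = target.size
    for col in samples.columns:
        values = samples[col].to_numpy(dtype=float)
        if np.all(~np.isfinite(values)):
            raise ValueError(f"sample column {col!r} is entirely missing")
        n = values.size
        ranks = stats.rankdata(values, method="average")  # 1..n, ties averaged
        if n == 1:
            positions = np.array([0.5 * (m - 1)])
        else:
            positions = (ranks - 1.0) / (n - 1.0) * (m - 1.0)
        out[col] = np.interp(positions, np.arange(m), target)
    return pd.DataFrame(out, index=samples.index)


def _ensure_batches(batches, n_samples: int) -> np.ndarray:
    batches = np.asarray(batches)
    if batches.size != n_samples:
        raise ValueError("one batch label per sample required")
    labels, counts = np.unique(batches, return_counts=True)
    if labels.size < 2:
        raise ValueError("ComBat needs at least two batches")
    singletons = labels[counts < 2]
    if singletons.size:
        raise ValueError(f"batch with a single sample: {singletons[0]!r}")
    return batches


def combat_adjust(matrix: pd.DataFrame, batches, max_iter: int = 100, tol: float = 1e-4) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Implements the classic ComBat procedure without covariates on a
    feature x sample matrix: (1) feature-wise standardization against the
    sample-size-weighted grand mean and pooled variance; (2) per-batch
    per-feature location (gamma-hat) and scale (delta-hat) estimates;
    (3) empirical-Bayes shrinkage of both toward across-feature priors
    (normal for location, inverse-gamma for scale, moment-matched),
    iterated to convergence; (4) adjustment and rescaling back to the grand
    location/scale.
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("ComBat input must be complete")
    G, N = X.shape
    batches = _ensure_batches(batches, N)
    labels = list(pd.unique(batches))
    idx = {b: np.where(batches == b)[0] for b in labels}
    n_b = {b: len(idx[b]) for b in labels}

    batch_means = np.column_stack([X[:, idx[b]].mean(axis=1) for b in labels])  # G x B
    weights = np.array([n_b[b] / N for b in labels])
    grand_mean = batch_means @ weights
    resid = X - batch_means[:, [labels.index(b) for b in batches]]
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    sd_pooled = np.sqrt(var_pooled)

    Z = (X - grand_mean[:, None]) / sd_pooled[:, None]

    X_adj = np.empty_like(Z)
    for b in labels:
        cols = idx[b]
        Zb = Z[:, cols]
        n = n_b[b]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        delta_hat = np.where(delta_hat <= 0, 1e-12, delta_hat)

        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        # moment-matched inverse-gamma prior on delta
        a_prior = (2.0 * d_var + d_mean**2) / d_var if d_var > 0 else 2.0
        b_prior = (d_mean * d_var + d_mean**3) / d_var if d_var > 0 else d_mean

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            if tau2 > 0:
                gamma_new = (tau2 * n * gamma_hat + delta_star * gamma_bar) / (
                    tau2 * n + delta_star
                )
            else:
                gamma_new = np.full(G, gamma_bar)
            sum2 = ((Zb - gamma_new[:, None]) ** 2).sum(axis=1)
            delta_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
            change = max(
                np.max(np.abs(gamma_new - gamma_star) / np.maximum(np.abs(gamma_star), 1e-12)),
                np.max(np.abs(delta_new - delta_star) / np.maximum(np.abs(delta_star), 1e-12)),
            )
            gamma_star, delta_star = gamma_new, delta_new
            if change < tol:
                break
        X_adj[:, cols] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    X_adj = X_adj * sd_pooled[:, None] + grand_mean[:, None]
    return pd.DataFrame(X_adj, index=matrix.index, columns=matrix.columns)


def normalize_validation_cohort(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    dmr_index=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Make a targeted validation matrix comparable with WGBS discovery data.

    Both matrices are DMR x sample on the percent scale.  The shared DMR
    index (or an explicit one) is used; both are transformed, the
    validation samples quantile-normalized to the pooled discovery values,
    batch-adjusted jointly with batch = cohort, and back-transformed.
    """
    if dmr_index is None:
        dmr_index = discovery.index.intersection(validation.index)
    dmr_index = pd.Index(dmr_index)
    if dmr_index.empty:
        raise ValueError("no shared DMRs between discovery and validation")
    disc = discovery.loc[dmr_index]
    val = validation.loc[dmr_index]
    t_disc = pd.DataFrame(
        logit_like_transform(disc.to_numpy()), index=dmr_index, columns=disc.columns
    )
    t_val = pd.DataFrame(
        logit_like_transform(val.to_numpy()), index=dmr_index, columns=val.columns
    )
    target = np.sort(t_disc.to_numpy().ravel())
    t_val = quantile_normalize_to_target(t_val, target)
    combined = pd.concat([t_disc, t_val], axis=1)
    batches = ["discovery"] * t_disc.shape[1] + ["validation"] * t_val.shape[1]
    adjusted = combat_adjust(combined, batches)
    out_disc = pd.DataFrame(
        back_transform(adjusted.iloc[:, : t_disc.shape[1]].to_numpy()),
        index=dmr_index,
        columns=disc.columns,
    )
    out_val = pd.DataFrame(
        back_transform(adjusted.iloc[:, t_disc.shape[1] :].to_numpy()),
        index=dmr_index,
        columns=val.columns,
    )
    return out_disc, out_val


def concordance_report(
    discovery_diffs,
    validation_diffs,
    validation_q=None,
    q_cutoff: float = 0.01,
    diff_cutoff: float = 25.0,
) -> dict:
    """Compare per-DMR mean differences (condition - control, percent) between cohorts.

    Returns the Pearson correlation of the paired difference vectors and,
    when validation q-values are supplied, counts of DMRs that (a) pass the
    q cutoff, (b) additionally replicate the discovery sign, and
    (c) additionally reach |difference| >= ``diff_cutoff``.
    """
    d = np.asarray(discovery_diffs, dtype=float)
    v = np.asarray(validation_diffs, dtype=float)
    if d.size != v.size:
        raise ValueError("difference vectors must have equal length")
    r, p = stats.pearsonr(d, v)
    report = {"pearson_r": float(r), "pearson_p": float(p), "n_dmrs": int(d.size)}
    same_sign = np.sign(d) == np.sign(v)
    report["n_same_sign"] = int(same_sign.sum())
    if validation_q is not None:
        q = np.asarray(validation_q, dtype=float)
        sig = q <= q_cutoff
        report["n_significant"] = int(sig.sum())
        report["n_significant_same_sign"] = int((sig & same_sign).sum())
        report["n_validated"] = int((sig & same_sign & (np.abs(v) >= diff_cutoff)).sum())
    return report
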