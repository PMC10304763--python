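"""Tiled differential methylation calling.

The genome is partitioned into fixed non-overlapping windows (default
500 bp, anchored at position 1 of each chromosome).  Per window and sample,
methylated and total read counts are summed over the CpGs it contains.
Differential methylation between two groups is tested with a binomial
logistic regression of the per-sample counts on the group indicator; with a
single binary covariate the maximum-likelihood fit has the closed form
"pooled proportion per group", so the likelihood-ratio chi-square statistic
(1 df) is computed exactly without iteration.  Windows are called DMRs when
the multiple-testing-adjusted q-value and the absolute methylation
difference both pass their cutoffs (defaults q <= 0.01 and >= 25
percentage points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .probemap import MethylationCallSet

__all__ = [
    "RegionCounts",
    "DMRRecord",
    "tile_counts",
    "dm_test",
    "dm_test_regions",
    "adjust_qvalues",
    "call_dmrs",
    "compare_dmr_sets",
]


@dataclass
class RegionCounts:
    """Per-window, per-sample methylation counts.

    All three frames share a (chrom, start) MultiIndex (half-open windows of
    ``window`` bp) and one column per sample.
    """

    meth: pd.DataFrame
    coverage: pd.DataFrame
    n_cpgs: pd.DataFrame
    window: int

    @property
    def windows(self) -> pd.MultiIndex:
        return self.meth.index

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    def end(self) -> pd.Series:
        return self.meth.index.get_level_values("start") + self.window


@dataclass
class DMRRecord:
    chrom: str
    start: int
    end: int
    comparison: str
    meth_diff: float
    p_value: float
    q_value: float
    direction: str


def tile_counts(
    callsets: list[MethylationCallSet],
    window: int = 500,
    step: int = 500,
    min_cpgs_per_window: int = 3,
    min_coverage: int = 1,
) -> RegionCounts:
    """Sum CpG counts into fixed windows anchored at position 1 per chromosome.

    Only ``step == window`` (a partition) is supported; windows where any
    sample has fewer than ``min_cpgs_per_window`` covered CpGs are dropped.
    """
    if step != window:
        raise NotImplementedError("only non-overlapping tiling (step == window) is supported")
    if not callsets:
        raise ValueError("no call sets given")
    per_sample = {}
    for cs in callsets:
        calls = cs.calls[cs.calls["coverage"] >= min_coverage]
        start = ((calls["pos"] - 1) // window) * window + 1
        grouped = (
            calls.assign(start=start)
            .groupby(["chrom", "start"])
            .agg(n_meth=("n_meth", "sum"), coverage=("coverage", "sum"), n_cpgs=("pos", "size"))
        )
        per_sample[cs.sample_id] = grouped
    meth = pd.DataFrame({s: g["n_meth"] for s, g in per_sample.items()})
    cov = pd.DataFrame({s: g["coverage"] for s, g in per_sample.items()})
    ncpg = pd.DataFrame({s: g["n_cpgs"] for s, g in per_sample.items()})
    ncpg = ncpg.fillna(0).astype(int)
    keep = (ncpg >= min_cpgs_per_window).all(axis=1)
    meth = meth.loc[keep].fillna(0).astype(int).sort_index()
    cov = cov.loc[keep].fillna(0).astype(int).sort_index()
    ncpg = ncpg.loc[keep].sort_index()
    meth.index = meth.index.set_names(["chrom", "start"])
    cov.index = meth.index
    ncpg.index = meth.index
    return RegionCounts(meth, cov, ncpg, window)


def _binomial_ll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood without the combinatorial constant."""
    return xlogy(k, p) + xlogy(n - k, 1.0 - p)


def dm_test(
    meth_a: np.ndarray,
    cov_a: np.ndarray,
    meth_b: np.ndarray,
    cov_b: np.ndarray,
) -> tuple[float, float]:
    """Group-vs-intercept likelihood-ratio test for one window.

    Returns ``(meth_diff, p_value)`` where meth_diff is the percentage-point
    difference of pooled methylation (group a - group b) and p comes from
    the 1-df chi-square of the logistic-regression likelihood ratio.  Zero
    total coverage in either group yields (0.0, 1.0).
    """
    meth_a = np.asarray(meth_a, dtype=float)
    cov_a = np.asarray(cov_a, dtype=float)
    meth_b = np.asarray(meth_b, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    na, nb = cov_a.sum(), cov_b.sum()
    if na == 0 or nb == 0:
        return 0.0, 1.0
    pa = meth_a.sum() / na
    pb = meth_b.sum() / nb
    p0 = (meth_a.sum() + meth_b.sum()) / (na + nb)
    ll_full = _binomial_ll(meth_a, cov_a, pa).sum() + _binomial_ll(meth_b, cov_b, pb).sum()
    ll_null = _binomial_ll(meth_a, cov_a, p0).sum() + _binomial_ll(meth_b, cov_b, p0).sum()
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    p_value = float(stats.chi2.sf(lrt, df=1))
    return float(100.0 * (pa - pb)), p_value


def dm_test_regions(
    regions: RegionCounts,
    group_a: list[str],
    group_b: list[str],
    comparison: str = "a_vs_b",
) -> pd.DataFrame:
    """Vectorised :func:`dm_test` over every window of ``regions``.

    Returns a frame indexed by (chrom, start) with columns ``end``,
    ``comparison``, ``meth_diff`` and ``p_value``.
    """
    for grp, name in ((group_a, "group_a"), (group_b, "group_b")):
        missing = set(grp) - set(regions.samples)
        if missing:
            raise ValueError(f"{name} samples not in region counts: {sorted(missing)}")
        if not grp:
            raise ValueError(f"{name} is empty")
    ka = regions.meth[group_a].to_numpy(dtype=float)
    na = regions.coverage[group_a].to_numpy(dtype=float)
    kb = regions.meth[group_b].to_numpy(dtype=float)
    nb = regions.coverage[group_b].to_numpy(dtype=float)
    ta, tb = na.sum(axis=1), nb.sum(axis=1)
    ok = (ta > 0) & (tb > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(ta > 0, ka.sum(axis=1) / np.where(ta > 0, ta, 1), 0.0)
        pb = np.where(tb > 0, kb.sum(axis=1) / np.where(tb > 0, tb, 1), 0.0)
        p0 = (ka.sum(axis=1) + kb.sum(axis=1)) / np.where(ta + tb > 0, ta + tb, 1)
        ll_full = _binomial_ll(ka, na, pa[:, None]).sum(axis=1) + _binomial_ll(
            kb, nb, pb[:, None]
        ).sum(axis=1)
        ll_null = _binomial_ll(ka, na, p0[:, None]).sum(axis=1) + _binomial_ll(
            kb, nb, p0[:, None]
        ).sum(axis=1)
    lrt = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
    p_value = stats.chi2.sf(lrt, df=1)
    meth_diff = 100.0 * (pa - pb)
    meth_diff[~ok] = 0.0
    p_value[~ok] = 1.0
    out = pd.DataFrame(
        {
            "end": regions.end(),
            "comparison": comparison,
            "meth_diff": meth_diff,
            "p_value": p_value,
            "zero_coverage": ~ok,
        },
        index=regions.windows,
    )
    return out


def adjust_qvalues(p_values, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment of raw p-values.

    ``bh`` is Benjamini-Hochberg FDR.  ``slim-approx`` additionally scales
    the BH values by a Storey-type null-proportion estimate
    ``pi0 = min(1, #(p > 0.5) / (0.5 n))``, an FDR estimate in the spirit of
    sliding-window q-value methods; it is never larger than BH.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    if method == "bh":
        return q
    if method == "slim-approx":
        pi0 = min(1.0, float((p > 0.5).sum()) / (0.5 * p.size)) if p.size else 1.0
        return np.minimum(q * pi0, 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


def call_dmrs(
    tests: pd.DataFrame,
    q_cutoff: float = 0.01,
    diff_cutoff: float = 25.0,
    method: str = "bh",
) -> pd.DataFrame:
    """Adjust p-values and keep windows with q <= q_cutoff and |diff| >= diff_cutoff.

    ``tests`` is the output of :func:`dm_test_regions`; a ``q_value`` column
    is computed if absent.  Adds ``direction`` ('hyper' when the condition
    group is more methylated than the control, else 'hypo').
    """
    tests = tests.copy()
    if "q_value" not in tests.columns:
        tests["q_value"] = adjust_qvalues(tests["p_value"].to_numpy(), method=method)
    keep = (tests["q_value"] <= q_cutoff) & (tests["meth_diff"].abs() >= diff_cutoff)
    dmrs = tests.loc[keep].copy()
    dmrs["direction"] = np.where(dmrs["meth_diff"] > 0, "hyper", "hypo")
    return dmrs.sort_index()


def compare_dmr_sets(sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-tabulate DMR windows across comparisons.

    ``sets`` maps a comparison label to a DMR frame indexed by
    (chrom, start).  Returns a boolean membership frame (one row per window
    in any set, one column per comparison) plus a ``membership`` column
    naming the exact combination (labels joined by '&').
    """
    if len(sets) < 2:
        raise ValueError("need at least two DMR sets to compare")
    labels = list(sets)
    all_windows = sorted(set().union(*(set(df.index) for df in sets.values())))
    index = pd.MultiIndex.from_tuples(all_windows, names=["chrom", "start"]) if all_windows else pd.MultiIndex.from_tuples([], names=["chrom", "start"])
    table = pd.DataFrame(
        {label: [w in set(sets[label].index) for w in all_windows] for label in labels},
        index=index,
    )
    table["membership"] = [
        "&".join(l for l in labels if row[l]) for _, row in table.iterrows()
    ]
    return table


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED representation: 0-based start, -log10(q) score, '.' strand."""
    q = dmrs["q_value"].to_numpy(dtype=float)
    score = -np.log10(np.clip(q, 1e-300, None))
    return pd.DataFrame(
        {
            "chrom": dmrs.index.get_level_values("chrom"),
            "start": dmrs.index.get_level_values("start") - 1,
            "end": dmrs["end"].to_numpy(),
            "name": [
                f"{c}:{s}-{e}"
                for c, s, e in zip(
                    dmrs.index.get_level_values("chrom"),
                    dmrs.index.get_level_values("start"),
                    dmrs["end"],
                )
            ],
            "score": score,
            "strand": ".",
        }
    )
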