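"""Reference methylation atlas handling and cell-type-specific CpG signature selection.

A methylation atlas is a probe x cell-type matrix of beta values (methylated
read fraction at a CpG, in [0, 1]) measured on purified cell and tissue
types.  Deconvolution of bulk cell-free DNA only works on CpGs that
discriminate between cell types, so the atlas is reduced to a *signature
matrix*: for each cell type the most specifically hyper- and hypomethylated
CpGs, the most differential CpGs versus all other tissues, CpGs neighbouring
the selected ones, and per-pair maximally different CpGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationAtlas",
    "SignatureMatrix",
    "SelectionConfig",
    "merge_atlases",
    "filter_and_pool",
    "select_top_scaled",
    "select_most_differential",
    "add_neighbors",
    "add_pairwise_specific",
    "build_signature",
    "make_signature",
]

#: fixed precedence used when one probe is claimed by several selection routes
PROVENANCE_ORDER = ("hyper_topk", "hypo_topk", "differential", "neighbor", "pairwise")


@dataclass
class MethylationAtlas:
    """Probe x cell-type beta matrix with optional genomic coordinates.

    Parameters
    ----------
    beta
        DataFrame indexed by probe ID with one column per cell type (or
        replicate, e.g. ``"Heart_rep1"``).  Values are beta fractions in
        [0, 1]; NaN is allowed before filtering.
    coords
        Optional DataFrame indexed by probe ID with columns ``chrom``,
        ``pos`` (1-based cytosine position) and ``strand``.
    """

    beta: pd.DataFrame
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.beta.index.is_unique:
            raise ValueError("atlas probe IDs must be unique")
        if self.beta.shape[1] == 0:
            raise ValueError("atlas must contain at least one cell-type column")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.beta.columns)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MethylationAtlas({self.beta.shape[0]} probes x "
            f"{self.beta.shape[1]} cell types)"
        )


@dataclass
class SignatureMatrix:
    """Cell-type-specific CpG submatrix with per-probe selection provenance."""

    beta: pd.DataFrame
    provenance: pd.Series

    def __post_init__(self) -> None:
        if self.beta.isna().any().any():
            raise ValueError("signature matrix must not contain missing values")
        if not self.beta.index.is_unique:
            raise ValueError("signature probes must be unique")
        if not self.provenance.index.equals(self.beta.index):
            raise ValueError("provenance index must match the beta index")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class SelectionConfig:
    """Tuning knobs of signature selection.

    k_top: CpGs kept per direction (hyper / hypo) per cell type.
    k_diff: most-differential CpGs kept per cell type (one vs rest).
    neighbor_window: CpGs within this many bp of a selected CpG are added.
    variance_threshold: rows with population variance below this are dropped.
    k_pair: CpGs added per unordered cell-type pair.
    """

    k_top: int = 100
    k_diff: int = 200
    neighbor_window: int = 50
    variance_threshold: float = 0.001
    k_pair: int = 1

    def __post_init__(self) -> None:
        for name in ("k_top", "k_diff", "neighbor_window", "k_pair"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.variance_threshold <= 0:
            raise ValueError("variance_threshold must be positive")


def merge_atlases(
    base: MethylationAtlas, extension: MethylationAtlas, join: str = "inner"
) -> MethylationAtlas:
    """Merge two atlases on probe ID, concatenating their cell-type columns.

    ``join`` is ``"inner"`` (default; keep shared probes only) or ``"outer"``
    (keep all probes, missing betas become NaN).  Duplicate cell-type labels
    across the two inputs are an error: replicates must carry distinct
    suffixes before merging.
    """
    if join not in ("inner", "outer"):
        raise ValueError(f"join must be 'inner' or 'outer', got {join!r}")
    dup = set(base.beta.columns) & set(extension.beta.columns)
    if dup:
        raise ValueError(f"duplicate cell-type labels across atlases: {sorted(dup)}")
    merged = base.beta.join(extension.beta, how=join).sort_index()
    coords = _merge_coords(base.coords, extension.coords)
    if coords is not None:
        coords = coords.loc[coords.index.intersection(merged.index)]
    return MethylationAtlas(merged, coords)


def _merge_coords(
    a: pd.DataFrame | None, b: pd.DataFrame | None
) -> pd.DataFrame | None:
    if a is None and b is None:
        return None
    parts = [c for c in (a, b) if c is not None]
    merged = pd.concat(parts)
    return merged[~merged.index.duplicated(keep="first")].sort_index()


def filter_and_pool(
    atlas: MethylationAtlas,
    cfg: SelectionConfig | None = None,
    tissue_map: dict[str, str] | None = None,
) -> MethylationAtlas:
    """Drop incomplete / uninformative probes and average replicates per tissue.

    Rows with any missing beta are removed, then rows whose population
    variance across columns falls below ``cfg.variance_threshold``.
    ``tissue_map`` maps each replicate column to its tissue label; replicate
    columns of the same tissue are pooled by arithmetic mean.  Omitting
    ``tissue_map`` treats each column as its own tissue.
    """
    cfg = cfg or SelectionConfig()
    if tissue_map is None:
        tissue_map = {c: c for c in atlas.beta.columns}
    missing_cols = set(atlas.beta.columns) - set(tissue_map)
    if missing_cols:
        raise ValueError(f"tissue_map does not cover columns: {sorted(missing_cols)}")

    n0 = atlas.beta.shape[0]
    complete = atlas.beta.dropna(axis=0, how="any")
    n_missing = n0 - complete.shape[0]
    variances = complete.to_numpy(dtype=float).var(axis=1)  # population variance
    kept = complete.loc[variances >= cfg.variance_threshold]
    n_lowvar = complete.shape[0] - kept.shape[0]
    if kept.empty:
        raise ValueError(
            "no probes survive filtering "
            f"({n_missing} removed for missing values, {n_lowvar} for variance "
            f"< {cfg.variance_threshold})"
        )
    pooled = kept.T.groupby([tissue_map[c] for c in kept.columns]).mean().T
    pooled = pooled.sort_index()
    coords = None
    if atlas.coords is not None:
        coords = atlas.coords.loc[atlas.coords.index.intersection(pooled.index)]
    return MethylationAtlas(pooled, coords)


def _row_scale(beta: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its sum; rows summing to zero are dropped."""
    sums = beta.sum(axis=1)
    keep = sums > 0
    return beta.loc[keep].div(sums[keep], axis=0)


def select_top_scaled(
    atlas: MethylationAtlas,
    k: int,
    used: set[str] | None = None,
) -> dict[tuple[str, str], list[str]]:
    """Select the top-k row-scaled hyper- and hypomethylated CpGs per cell type.

    The atlas is row-scaled (each row divided by its sum) and, per cell type
    in column order, the k probes with the highest scaled value in that
    column are taken.  A shared exclusion list prevents a probe claimed by an
    earlier cell type from being reselected; ties break on probe ID.  The
    hypomethylated pass repeats the procedure on the reversed matrix
    (1 - beta, then row-scaled).

    Returns a mapping ``(direction, cell_type) -> ordered probe list`` where
    direction is ``"hyper"`` or ``"hypo"``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    used = set() if used is None else used
    out: dict[tuple[str, str], list[str]] = {}
    for direction, matrix in (("hyper", atlas.beta), ("hypo", 1.0 - atlas.beta)):
        scaled = _row_scale(matrix)
        for ct in scaled.columns:
            # mergesort is stable; pre-sorting the index makes ties break by ID
            ranked = scaled[ct].loc[sorted(scaled.index)].sort_values(
                ascending=False, kind="mergesort"
            )
            picks: list[str] = []
            for probe in ranked.index:
                if len(picks) == k:
                    break
                if probe in used:
                    continue
                picks.append(probe)
                used.add(probe)
            if len(picks) < k:
                warnings.warn(
                    f"only {len(picks)} of {k} {direction} probes available for "
                    f"cell type {ct!r}",
                    stacklevel=2,
                )
            out[(direction, ct)] = picks
    return out


def _one_vs_rest_f(
    beta: pd.DataFrame, target_cols: list[str], other_cols: list[str]
) -> pd.Series:
    """Two-group one-way ANOVA p-value per probe (replicated atlas columns)."""
    from scipy import stats

    a = beta[target_cols].to_numpy(dtype=float)
    b = beta[other_cols].to_numpy(dtype=float)
    _, p = stats.f_oneway(a, b, axis=1)
    return pd.Series(p, index=beta.index)


def select_most_differential(
    atlas: MethylationAtlas,
    k: int,
    tissue_map: dict[str, str] | None = None,
) -> dict[str, list[str]]:
    """One-vs-rest most-differential CpGs per cell type on the unscaled atlas.

    With ``tissue_map`` providing >= 2 replicate columns on both sides of a
    comparison, probes are ranked by ascending one-way ANOVA p-value.  On a
    pooled atlas (single column per tissue) the rank statistic is
    ``|beta_target - mean(beta_others)| / (sd(beta_others) + 1e-6)`` with the
    population standard deviation.  Ties break on probe ID.
    """
    if atlas.beta.shape[1] < 2:
        raise ValueError("differential selection needs at least two columns")
    beta = atlas.beta.loc[sorted(atlas.beta.index)]
    if tissue_map is None:
        tissues: dict[str, list[str]] = {c: [c] for c in beta.columns}
    else:
        tissues = {}
        for col in beta.columns:
            tissues.setdefault(tissue_map[col], []).append(col)
    k_eff = min(k, beta.shape[0])
    if k_eff < k:
        warnings.warn(f"k={k} exceeds probe count {beta.shape[0]}; selecting all")
    out: dict[str, list[str]] = {}
    for tissue in sorted(tissues):
        target_cols = tissues[tissue]
        other_cols = [c for cols in tissues.values() for c in cols if c not in target_cols]
        replicated = len(target_cols) >= 2 and len(other_cols) >= 2
        if replicated:
            p = _one_vs_rest_f(beta, target_cols, other_cols)
            score = p.fillna(1.0)
            ranked = score.sort_values(ascending=True, kind="mergesort")
        else:
            target = beta[target_cols].mean(axis=1).to_numpy()
            others = beta[other_cols].to_numpy(dtype=float)
            denom = others.std(axis=1) + 1e-6
            z = np.abs(target - others.mean(axis=1)) / denom
            if np.all(z == z[0]):
                warnings.warn(
                    f"no differential signal for tissue {tissue!r}; "
                    "returning deterministic arbitrary probes"
                )
            ranked = pd.Series(-z, index=beta.index).sort_values(kind="mergesort")
        out[tissue] = list(ranked.index[:k_eff])
    return out


def add_neighbors(
    selected: set[str] | list[str],
    atlas: MethylationAtlas,
    window: int = 50,
) -> set[str]:
    """Add atlas probes within ``window`` bp of any selected probe (same chrom)."""
    selected = set(selected)
    if atlas.coords is None:
        warnings.warn("atlas has no coordinates; skipping neighbor expansion")
        return selected
    coords = atlas.coords.loc[atlas.coords.index.intersection(atlas.beta.index)]
    anchors = coords.loc[coords.index.intersection(selected)]
    if anchors.empty:
        return selected
    out = set(selected)
    for chrom, chrom_coords in coords.groupby("chrom", sort=False):
        chrom_anchors = anchors.loc[anchors["chrom"] == chrom, "pos"].to_numpy()
        if chrom_anchors.size == 0:
            continue
        chrom_anchors.sort()
        pos = chrom_coords["pos"].to_numpy()
        # nearest anchor distance via binary search on the sorted anchors
        idx = np.searchsorted(chrom_anchors, pos)
        left = np.abs(pos - chrom_anchors[np.clip(idx - 1, 0, len(chrom_anchors) - 1)])
        right = np.abs(chrom_anchors[np.clip(idx, 0, len(chrom_anchors) - 1)] - pos)
        near = np.minimum(left, right) <= window
        out.update(chrom_coords.index[near])
    return out


def add_pairwise_specific(
    atlas: MethylationAtlas,
    selected: set[str] | list[str],
    k_pair: int = 1,
) -> set[str]:
    """For every unordered cell-type pair add the k_pair CpGs with the largest
    absolute beta difference among probes not yet selected."""
    selected = set(selected)
    beta = atlas.beta.loc[sorted(atlas.beta.index)]
    added: set[str] = set()
    cols = list(beta.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            diff = (beta[a] - beta[b]).abs()
            eligible = diff.drop(labels=selected | added, errors="ignore")
            ranked = eligible.sort_values(ascending=False, kind="mergesort")
            added.update(ranked.index[:k_pair])
    return selected | added


def build_signature(
    atlas: MethylationAtlas,
    selections: dict[str, set[str] | list[str]],
) -> SignatureMatrix:
    """Assemble the signature matrix from tagged selection sets.

    ``selections`` maps a provenance tag (``hyper_topk``, ``hypo_topk``,
    ``differential``, ``neighbor``, ``pairwise``) to the probes that route
    selected.  A probe claimed by several routes gets the first tag in that
    fixed order.  Rows are sorted by probe ID.
    """
    unknown = set(selections) - set(PROVENANCE_ORDER)
    if unknown:
        raise ValueError(f"unknown provenance tags: {sorted(unknown)}")
    provenance: dict[str, str] = {}
    for tag in PROVENANCE_ORDER:
        for probe in selections.get(tag, ()):  # first tag wins
            provenance.setdefault(probe, tag)
    if not provenance:
        raise ValueError("empty selection: no probes to build a signature from")
    missing = set(provenance) - set(atlas.beta.index)
    if missing:
        raise ValueError(
            f"{len(missing)} selected probes absent from atlas, "
            f"e.g. {sorted(missing)[:3]}"
        )
    probes = sorted(provenance)
    beta = atlas.beta.loc[probes]
    return SignatureMatrix(beta, pd.Series([provenance[p] for p in probes], index=beta.index, name="provenance"))


def make_signature(
    atlas: MethylationAtlas,
    cfg: SelectionConfig | None = None,
    tissue_map: dict[str, str] | None = None,
) -> SignatureMatrix:
    """Full selection pipeline: filter/pool, top-scaled hyper/hypo CpGs,
    one-vs-rest differential CpGs, neighbouring CpGs, pairwise-specific CpGs.

    Differential selection runs on the unpooled (replicated) matrix when a
    ``tissue_map`` is given; all other steps use the pooled atlas.
    """
    cfg = cfg or SelectionConfig()
    pooled = filter_and_pool(atlas, cfg, tissue_map)
    top = select_top_scaled(pooled, cfg.k_top)
    hyper = {p for (d, _), probes in top.items() if d == "hyper" for p in probes}
    hypo = {p for (d, _), probes in top.items() if d == "hypo" for p in probes}
    if tissue_map is not None:
        filtered = MethylationAtlas(
            atlas.beta.dropna().loc[lambda df: df.to_numpy().var(axis=1) >= cfg.variance_threshold],
            atlas.coords,
        )
        diff_sel = select_most_differential(filtered, cfg.k_diff, tissue_map)
    else:
        diff_sel = select_most_differential(pooled, cfg.k_diff)
    differential = {p for probes in diff_sel.values() for p in probes}
    core = hyper | hypo | differential
    with_neighbors = add_neighbors(core, pooled, cfg.neighbor_window)
    neighbors = with_neighbors - core
    all_probes = add_pairwise_specific(pooled, with_neighbors, cfg.k_pair)
    pairwise = all_probes - with_neighbors
    return build_signature(
        pooled,
        {
            "hyper_topk": hyper,
            "hypo_topk": hypo,
            "differential": differential,
            "neighbor": neighbors,
            "pairwise": pairwise,
        },
    )
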