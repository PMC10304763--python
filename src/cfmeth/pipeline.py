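"""Workflow orchestration: discovery, validation and benchmark runs.

The discovery workflow follows the analysis order of a cell-free DNA
methylation study: map calls to probes and deconvolute cell-type
proportions, tile the genome and call group-vs-control DMRs, fit per-DMR
severity models with the ccfDNA-level covariate, and train ACS-type
classifiers plus a PCA embedding on the severity-selected DMRs.  The
validation workflow normalises a targeted panel to the discovery scale and
summarises concordance.  All randomness derives from one global seed via
stable per-stage substreams.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import deconv, dmr, severity
from .atlas import MethylationAtlas, SignatureMatrix
from .normalize import concordance_report, normalize_validation_cohort
from .probemap import MethylationCallSet, ProbeManifest, collapse_strands, map_to_probes

logger = logging.getLogger("cfmeth")

__all__ = [
    "stage_seed",
    "region_meth_percent",
    "discovery_workflow",
    "validation_workflow",
    "benchmark_workflow",
    "write_discovery_outputs",
]

ACS_GROUPS = ("UA", "NSTEMI", "STEMI")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the global seed."""
    return (int(seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def region_meth_percent(regions: dmr.RegionCounts) -> pd.DataFrame:
    """Per-window, per-sample methylation percent (coverage-weighted)."""
    cov = regions.coverage.replace(0, np.nan)
    return 100.0 * regions.meth / cov


def discovery_workflow(
    callsets: list[MethylationCallSet],
    sample_sheet: pd.DataFrame,
    signature: SignatureMatrix,
    manifest: ProbeManifest,
    seed: int = 0,
    window: int = 500,
    q_cutoff: float = 0.01,
    diff_cutoff: float = 25.0,
    alpha: float = 0.05,
    min_cpgs_per_window: int = 3,
    deconv_model: str = "nnls",
    classify: bool = True,
) -> dict:
    """Run the discovery arm end to end on in-memory objects.

    Returns a dict with proportions, per-comparison DMR tables, the DMR
    methylation matrix, severity fits, the severity-selected subset, PCA
    coordinates and (optionally) classifier metrics.
    """
    missing = set(s.sample_id for s in callsets) - set(sample_sheet.index)
    if missing:
        raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
    collapsed = [collapse_strands(cs) for cs in callsets]

    logger.info("deconvolution: %d samples", len(collapsed))
    bulks = [map_to_probes(cs, manifest) for cs in collapsed]
    proportions = deconv.deconvolute_cohort(bulks, signature, model=deconv_model)

    logger.info("tiling %d samples into %d bp windows", len(collapsed), window)
    regions = dmr.tile_counts(collapsed, window=window, step=window, min_cpgs_per_window=min_cpgs_per_window)
    logger.info("tiled %d windows", len(regions.windows))
    groups = sample_sheet["group"]
    controls = list(groups.index[groups == "control"])
    if not controls:
        raise ValueError("no control samples in sample sheet")
    dmr_tables = {}
    for group in ACS_GROUPS:
        members = [s for s in groups.index[groups == group] if s in regions.samples]
        if not members:
            continue
        tests = dmr.dm_test_regions(regions, members, controls, comparison=f"{group}_vs_control")
        dmr_tables[group] = dmr.call_dmrs(tests, q_cutoff=q_cutoff, diff_cutoff=diff_cutoff)
        logger.info("%s vs control: %d DMRs", group, len(dmr_tables[group]))

    union_windows = sorted(set().union(*(set(t.index) for t in dmr_tables.values())) if dmr_tables else set())
    meth_pct = region_meth_percent(regions)
    results: dict = {
        "proportions": proportions,
        "regions": regions,
        "dmrs": dmr_tables,
        "dmr_methylation": meth_pct.loc[union_windows] if union_windows else pd.DataFrame(),
    }
    if not union_windows:
        logger.warning("no DMRs called; severity and classification skipped")
        return results

    dmr_meth = results["dmr_methylation"].T.dropna(axis=1)  # samples x DMRs, complete
    dmr_meth.columns = [f"{c}:{s}" for c, s in dmr_meth.columns]
    acs_samples = [s for s in dmr_meth.index if groups.loc[s] != "control"]
    y = severity.encode_severity(groups.loc[acs_samples])
    fits = severity.fit_severity_models(
        y.to_numpy(),
        dmr_meth.loc[acs_samples],
        sample_sheet.loc[acs_samples, "ccfdna_ng_per_ml"].to_numpy(),
    )
    selected, fraction = severity.select_associated_dmrs(fits, alpha=alpha)
    logger.info("severity-associated DMRs: %d/%d (%.1f%%)", len(selected), len(fits), 100 * fraction)
    results["severity_fits"] = fits
    results["severity_selected"] = selected
    results["severity_fraction"] = fraction

    pca_windows = list(selected.index) if len(selected) >= 2 else list(fits.index)
    coords, evr = severity.pca_embed(dmr_meth[pca_windows])
    results["pca"] = coords.join(groups)
    results["pca_explained_variance"] = evr

    if classify and len(acs_samples) >= 9:
        labels = groups.loc[acs_samples].to_numpy()
        metrics = severity.train_acs_classifiers(
            dmr_meth.loc[acs_samples],
            labels,
            seed=stage_seed(seed, "classify"),
        )
        results["classifier_metrics"] = {
            m: {k: v for k, v in entry.items() if isinstance(v, (int, float))}
            for m, entry in metrics.items()
        }
        results["classifiers"] = metrics
    return results


def validation_workflow(
    discovery_meth: pd.DataFrame,
    validation_meth: pd.DataFrame,
    discovery_groups: pd.Series,
    validation_groups: pd.Series,
    validation_tests: pd.DataFrame | None = None,
    q_cutoff: float = 0.01,
    diff_cutoff: float = 25.0,
) -> dict:
    """Normalise a targeted validation matrix and summarise concordance.

    Inputs are DMR x sample percent matrices and per-sample group labels;
    ``validation_tests`` (a frame with q_value per shared DMR) enables the
    replication counts in the concordance report.
    """
    disc_n, val_n = normalize_validation_cohort(discovery_meth, validation_meth)

    def group_diffs(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
        ctrl = matrix.loc[:, [s for s in matrix.columns if groups.loc[s] == "control"]].mean(axis=1)
        out = {}
        for g in ACS_GROUPS:
            members = [s for s in matrix.columns if groups.loc[s] == g]
            if members:
                out[g] = matrix[members].mean(axis=1) - ctrl
        return pd.DataFrame(out)

    disc_diffs = group_diffs(disc_n, discovery_groups)
    val_diffs = group_diffs(val_n, validation_groups)
    reports = {}
    for g in disc_diffs.columns.intersection(val_diffs.columns):
        q = None
        if validation_tests is not None and "q_value" in validation_tests:
            q = validation_tests["q_value"].reindex(disc_n.index).to_numpy()
        reports[g] = concordance_report(
            disc_diffs[g], val_diffs[g], validation_q=q,
            q_cutoff=q_cutoff, diff_cutoff=diff_cutoff,
        )
    combined = pd.concat([disc_n, val_n], axis=1)
    groups_all = pd.concat([discovery_groups, validation_groups])
    coords, evr = severity.pca_embed(combined.T)
    return {
        "normalized_discovery": disc_n,
        "normalized_validation": val_n,
        "discovery_diffs": disc_diffs,
        "validation_diffs": val_diffs,
        "concordance": reports,
        "pca": coords.join(groups_all.rename("group")),
        "pca_explained_variance": evr,
    }


def benchmark_workflow(
    atlas: MethylationAtlas,
    signature: SignatureMatrix,
    n_samples: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Simulate mixtures from the atlas and benchmark all four models."""
    from .mixsim import benchmark_models, simulate_cell_mix

    mixtures = simulate_cell_mix(
        atlas, n_samples, noise_sd=noise_sd, seed=stage_seed(seed, "simulate-mix")
    )
    return benchmark_models(mixtures, signature, seed=seed)


def write_discovery_outputs(results: dict, outdir, params: dict | None = None) -> None:
    """Write the discovery bundle: proportions, DMR TSV/BED, severity fits, metrics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results["proportions"].to_csv(outdir / "proportions.tsv", sep="\t", index=False)
    for group, table in results.get("dmrs", {}).items():
        table.to_csv(outdir / f"dmrs_{group}.tsv", sep="\t")
        dmr.dmrs_to_bed(table).to_csv(
            outdir / f"dmrs_{group}.bed", sep="\t", header=False, index=False
        )
    if "severity_fits" in results:
        results["severity_fits"].to_csv(outdir / "severity_fits.tsv", sep="\t")
    if "pca" in results:
        results["pca"].to_csv(outdir / "pca.tsv", sep="\t")
    metrics = {
        "n_dmrs": {g: int(len(t)) for g, t in results.get("dmrs", {}).items()},
        "severity_fraction": results.get("severity_fraction"),
        "classifiers": results.get("classifier_metrics"),
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))
    if params is not None:
        (outdir / "run_manifest.json").write_text(json.dumps(params, indent=2, default=str))
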