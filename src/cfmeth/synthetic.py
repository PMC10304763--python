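"""Synthetic data generators for the whole pipeline.

Real cell-free DNA cohorts of this kind are controlled-access, so every
stage is exercised on generated data with known ground truth:

* a methylation atlas with planted cell-type-specific hyper- and
  hypomethylated marker CpGs (stand-in for an array-based reference atlas);
* WGBS-like cohorts whose per-sample profiles are known mixtures of the
  atlas cell types, observed through binomial read sampling, with planted
  differentially methylated windows and severity-linear windows, group
  labels mirroring an ACS study (control / UA / NSTEMI / STEMI) and
  elevated circulating-DNA levels in disease;
* targeted validation panels with location/scale distortion on the
  transformed methylation scale, emulating cross-platform bias.

Noise here is binomial read sampling, the natural model for bisulfite
counts; the Gaussian beta-noise used for deconvolution benchmarking lives
in :mod:`cfmeth.mixsim`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import MethylationAtlas
from .normalize import back_transform, logit_like_transform
from .probemap import CALL_COLUMNS, MethylationCallSet, ProbeManifest

__all__ = [
    "CohortSpec",
    "SimulatedCohort",
    "make_synthetic_atlas",
    "manifest_from_atlas",
    "simulate_wgbs_cohort",
    "simulate_targeted_panel",
    "default_group_proportions",
]

ACS_GROUPS = ("UA", "NSTEMI", "STEMI")
SEVERITY = {"control": 0, "UA": 1, "NSTEMI": 2, "STEMI": 3}

#: per-group ccfDNA concentration (ng per ml plasma): mean, sd.  Disease
#: groups are elevated versus controls, spanning the few-to-tens range
#: typical of plasma.
CCFDNA_LEVELS = {
    "control": (8.0, 2.0),
    "UA": (18.0, 5.0),
    "NSTEMI": (22.0, 6.0),
    "STEMI": (26.0, 7.0),
}


@dataclass
class CohortSpec:
    """Study design of a simulated cohort.

    Default group sizes mirror a small four-arm discovery cohort
    (8 controls, 8 STEMI, 7 NSTEMI, 6 UA).  ``effect_size_pp`` is the
    methylation shift (percentage points) planted in each DMR window for
    its target group; ``severity_slope_pp`` shifts methylation linearly
    with the severity code in the severity-linked windows.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 8, "STEMI": 8, "NSTEMI": 7, "UA": 6}
    )
    n_planted_dmrs: int = 10
    effect_size_pp: float = 40.0
    n_severity_windows: int = 0
    severity_slope_pp: float = 0.0
    coverage_lambda: float = 10.0
    window: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 1")
        if not (0 < self.effect_size_pp <= 100):
            raise ValueError("effect_size_pp must be in (0, 100]")


@dataclass
class SimulatedCohort:
    callsets: list[MethylationCallSet]
    sample_sheet: pd.DataFrame
    betas: pd.DataFrame  # true per-sample beta, CpG x sample
    coords: pd.DataFrame
    dmr_truth: pd.DataFrame
    severity_truth: pd.DataFrame
    group_proportions: pd.DataFrame


def make_synthetic_atlas(
    n_cell_types: int = 10,
    n_cpgs: int = 3000,
    n_markers_per_type: int = 25,
    marker_contrast: float = 0.9,
    seed: int = 0,
) -> tuple[MethylationAtlas, pd.DataFrame]:
    """Atlas with planted cell-type-specific marker blocks plus truth table.

    Background betas are Beta(5, 5) (centered on 0.5).  Each cell type gets
    ``n_markers_per_type`` hypermethylated markers (target at
    0.5 + contrast/2, all others at 0.5 - contrast/2) and as many
    hypomethylated markers (reversed); at contrast 1 markers are exactly
    one-hot.  Probes sit every 100 bp on a synthetic chromosome.  Returns
    the atlas and a truth table (probe_id, cell_type, direction).
    """
    need = 2 * n_markers_per_type * n_cell_types
    if need > n_cpgs:
        raise ValueError(
            f"cannot place {need} marker CpGs in an atlas of {n_cpgs} CpGs"
        )
    if not (0 < marker_contrast <= 1):
        raise ValueError("marker_contrast must be in (0, 1]")
    rng = np.random.default_rng(seed)
    probe_ids = [f"cg{i:08d}" for i in range(n_cpgs)]
    cell_types = [f"ct{i + 1:02d}" for i in range(n_cell_types)]
    beta = rng.beta(5.0, 5.0, size=(n_cpgs, n_cell_types))
    marker_rows = rng.choice(n_cpgs, size=need, replace=False)
    hi = 0.5 + marker_contrast / 2.0
    lo = 0.5 - marker_contrast / 2.0
    truth_rows = []
    cursor = 0
    for t, ct in enumerate(cell_types):
        for direction in ("hyper", "hypo"):
            rows = marker_rows[cursor : cursor + n_markers_per_type]
            cursor += n_markers_per_type
            if direction == "hyper":
                beta[rows, :] = lo
                beta[rows, t] = hi
            else:
                beta[rows, :] = hi
                beta[rows, t] = lo
            truth_rows.extend(
                {"probe_id": probe_ids[r], "cell_type": ct, "direction": direction}
                for r in rows
            )
    coords = pd.DataFrame(
        {
            "chrom": "chrS1",
            "pos": 100 * (np.arange(n_cpgs) + 1),
            "strand": "+",
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    atlas = MethylationAtlas(
        pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=cell_types),
        coords,
    )
    truth = pd.DataFrame(truth_rows).sort_values("probe_id").reset_index(drop=True)
    return atlas, truth


def manifest_from_atlas(atlas: MethylationAtlas) -> ProbeManifest:
    """Probe manifest built from the atlas coordinate sidecar."""
    if atlas.coords is None:
        raise ValueError("atlas has no coordinates")
    return ProbeManifest(atlas.coords[["chrom", "pos", "strand"]].copy())


def default_group_proportions(cell_types: list[str]) -> pd.DataFrame:
    """Per-group mixing proportions: a healthy baseline with the first cell
    type (granulocyte-like, the dominant plasma contributor) progressively
    raised with disease severity."""
    n = len(cell_types)
    base = np.full(n, 0.7 / max(n - 1, 1))
    base[0] = 0.3
    base = base / base.sum()
    rows = {}
    for group, sev in SEVERITY.items():
        p = base.copy()
        p[0] += 0.05 * sev
        rows[group] = p / p.sum()
    return pd.DataFrame(rows, index=cell_types).T


def _windows_of(coords: pd.DataFrame, window: int) -> pd.DataFrame:
    start = ((coords["pos"] - 1) // window) * window + 1
    return pd.DataFrame({"chrom": coords["chrom"], "start": start}, index=coords.index)


def simulate_wgbs_cohort(
    spec: CohortSpec,
    atlas: MethylationAtlas,
    group_proportions: pd.DataFrame | None = None,
    planted_dmrs: pd.DataFrame | None = None,
) -> SimulatedCohort:
    """Simulate per-sample CpG counts from known cell-type mixtures.

    Per sample of group g: the true beta vector is ``atlas . p(g)`` with
    the group's planted DMR windows shifted by +-effect_size_pp and the
    severity windows shifted by ``severity_slope_pp * severity``; coverage
    is Poisson(lambda) + 1 per CpG and methylated reads are
    Binomial(coverage, beta).  ccfDNA levels and simple clinical markers
    (troponin-, CK-, LVEF- and CRP-like, trending with severity) are drawn
    per group into the sample sheet.

    ``planted_dmrs`` (a previous cohort's ``dmr_truth``) may be passed to
    reuse the same windows, e.g. for an independent validation cohort.
    """
    if atlas.coords is None:
        raise ValueError("atlas must carry coordinates")
    rng = np.random.default_rng(spec.seed)
    if group_proportions is None:
        group_proportions = default_group_proportions(atlas.cell_types)
    A = atlas.beta.to_numpy(dtype=float)
    coords = atlas.coords.loc[atlas.beta.index]
    win = _windows_of(coords, spec.window)
    window_keys = win.drop_duplicates().itertuples(index=False, name=None)
    all_windows = sorted(set(window_keys))

    if planted_dmrs is None:
        n_needed = spec.n_planted_dmrs * len(ACS_GROUPS) + spec.n_severity_windows
        if n_needed > len(all_windows):
            raise ValueError("not enough windows to plant the requested effects")
        chosen = rng.choice(len(all_windows), size=n_needed, replace=False)
        rows = []
        cursor = 0
        for group in ACS_GROUPS:
            for j in range(spec.n_planted_dmrs):
                chrom, start = all_windows[chosen[cursor]]
                cursor += 1
                sign = 1 if j % 2 == 0 else -1
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": start + spec.window,
                        "group": group,
                        "delta_pp": sign * spec.effect_size_pp,
                    }
                )
        dmr_truth = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "group", "delta_pp"]
        )
        sev_rows = []
        for _ in range(spec.n_severity_windows):
            chrom, start = all_windows[chosen[cursor]]
            cursor += 1
            sev_rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + spec.window,
                    "slope_pp": spec.severity_slope_pp,
                }
            )
        severity_truth = pd.DataFrame(
            sev_rows, columns=["chrom", "start", "end", "slope_pp"]
        )
    else:
        dmr_truth = planted_dmrs.copy()
        severity_truth = pd.DataFrame(columns=["chrom", "start", "end", "slope_pp"])

    window_of_probe = list(zip(win["chrom"], win["start"]))
    probe_rows_by_window: dict[tuple, np.ndarray] = {}
    for i, key in enumerate(window_of_probe):
        probe_rows_by_window.setdefault(key, []).append(i)  # type: ignore[arg-type]
    probe_rows_by_window = {k: np.asarray(v) for k, v in probe_rows_by_window.items()}

    samples, groups = [], []
    for group, size in spec.group_sizes.items():
        if group not in SEVERITY:
            raise ValueError(f"unknown group {group!r}")
        for i in range(size):
            samples.append(f"{group}_{i + 1:02d}")
            groups.append(group)

    callsets = []
    betas = {}
    sheet_rows = []
    pos = coords["pos"].to_numpy()
    chrom = coords["chrom"].to_numpy()
    for sample, group in zip(samples, groups):
        sev = SEVERITY[group]
        p = group_proportions.loc[group].to_numpy(dtype=float)
        beta = np.clip(A @ p, 0.0, 1.0)
        for _, row in dmr_truth[dmr_truth["group"] == group].iterrows():
            rows_idx = probe_rows_by_window.get((row["chrom"], row["start"]))
            if rows_idx is not None:
                beta[rows_idx] = np.clip(beta[rows_idx] + row["delta_pp"] / 100.0, 0.0, 1.0)
        for _, row in severity_truth.iterrows():
            rows_idx = probe_rows_by_window.get((row["chrom"], row["start"]))
            if rows_idx is not None:
                beta[rows_idx] = np.clip(
                    beta[rows_idx] + sev * row["slope_pp"] / 100.0, 0.0, 1.0
                )
        coverage = rng.poisson(spec.coverage_lambda, size=beta.size) + 1
        n_meth = rng.binomial(coverage, beta)
        calls = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "strand": "+",
                "n_meth": n_meth,
                "coverage": coverage,
            }
        )[CALL_COLUMNS]
        callsets.append(MethylationCallSet(sample, calls))
        betas[sample] = beta
        mu, sd = CCFDNA_LEVELS[group]
        sheet_rows.append(
            {
                "sample": sample,
                "group": group,
                "severity": sev,
                "ccfdna_ng_per_ml": max(float(rng.normal(mu, sd)), 0.5),
                "batch": "discovery",
                "troponin_t": max(float(rng.normal(5.0 * sev, 2.0)), 0.0),
                "ck": max(float(rng.normal(100.0 + 40.0 * sev, 30.0)), 10.0),
                "lvef": float(np.clip(rng.normal(70.0 - 5.0 * sev, 4.0), 20.0, 80.0)),
                "crp": max(float(rng.normal(2.0 + 1.5 * sev, 1.0)), 0.1),
            }
        )
    sample_sheet = pd.DataFrame(sheet_rows).set_index("sample")
    betas_df = pd.DataFrame(betas, index=atlas.beta.index)
    return SimulatedCohort(
        callsets=callsets,
        sample_sheet=sample_sheet,
        betas=betas_df,
        coords=coords,
        dmr_truth=dmr_truth,
        severity_truth=severity_truth,
        group_proportions=group_proportions,
    )


def simulate_targeted_panel(
    cohort: SimulatedCohort,
    panel_probes,
    batch_shift: float = 0.0,
    batch_scale: float = 1.0,
    coverage_lambda: float = 30.0,
    seed: int = 0,
) -> list[MethylationCallSet]:
    """Targeted resequencing of a cohort restricted to a CpG panel.

    The underlying per-sample betas are distorted on the transformed
    (pseudo-count log) scale by ``t -> batch_scale * t + batch_shift`` —
    the systematic cross-platform bias the normalization pipeline must
    remove — and reads are resampled independently at the (usually higher)
    panel coverage.
    """
    if batch_scale <= 0:
        raise ValueError("batch_scale must be positive")
    panel_probes = pd.Index(panel_probes)
    panel_probes = panel_probes.intersection(cohort.betas.index)
    if panel_probes.empty:
        raise ValueError("panel does not overlap the cohort CpGs")
    rng = np.random.default_rng(seed)
    coords = cohort.coords.loc[panel_probes]
    out = []
    for sample in cohort.betas.columns:
        beta = cohort.betas.loc[panel_probes, sample].to_numpy(dtype=float)
        t = logit_like_transform(100.0 * beta)
        beta_obs = back_transform(batch_scale * t + batch_shift) / 100.0
        coverage = rng.poisson(coverage_lambda, size=beta_obs.size) + 1
        n_meth = rng.binomial(coverage, beta_obs)
        calls = pd.DataFrame(
            {
                "chrom": coords["chrom"].to_numpy(),
                "pos": coords["pos"].to_numpy(),
                "strand": "+",
                "n_meth": n_meth,
                "coverage": coverage,
            }
        )[CALL_COLUMNS]
        out.append(MethylationCallSet(sample, calls))
    return out
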