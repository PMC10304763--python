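"""Mixture simulation and deconvolution model benchmarking.

Simulates bulk profiles as known convex combinations of atlas columns
(optionally with additive Gaussian noise on the beta scale) and scores the
four deconvolution models by root-mean-square error between predicted and
true proportions.  Binomial read-count noise, which models bisulfite data
more faithfully, lives in :mod:`cfmeth.synthetic` instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import MethylationAtlas, SignatureMatrix
from .deconv import MODELS, BulkProfile, deconvolute

__all__ = ["MixtureSample", "BenchmarkResult", "simulate_cell_mix", "benchmark_models"]


@dataclass
class MixtureSample:
    sample_id: str
    true_proportions: pd.Series
    profile: pd.Series
    noise_sd: float

    def __post_init__(self) -> None:
        p = self.true_proportions.to_numpy(dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("true proportions must be non-negative and sum to 1")


@dataclass
class BenchmarkResult:
    rmse: pd.Series  # per model, ascending
    n_samples: int
    seed: int | None
    n_failed: pd.Series

    @property
    def best_model(self) -> str:
        return str(self.rmse.index[0])


def simulate_cell_mix(
    atlas: MethylationAtlas,
    n_samples: int,
    proportions: np.ndarray | pd.DataFrame | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[MixtureSample]:
    """Simulate bulk mixtures with known cell-type proportions.

    Proportions default to draws from a flat Dirichlet over the atlas cell
    types; an explicit (n_samples x n_cell_types) matrix may be supplied
    instead and must have rows summing to 1 (+-1e-6).  Profiles are
    ``atlas . p`` plus Gaussian(0, noise_sd) noise, clipped to [0, 1].
    """
    if atlas.beta.isna().any().any():
        raise ValueError("atlas must be pooled and free of missing values")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_types = atlas.beta.shape[1]
    if proportions is None:
        P = rng.dirichlet(np.ones(n_types), size=n_samples)
    else:
        P = np.asarray(proportions, dtype=float)
        if P.shape != (n_samples, n_types):
            raise ValueError(f"proportions must be {n_samples} x {n_types}")
        if (P < 0).any() or np.abs(P.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("each proportion row must be non-negative and sum to 1")
    A = atlas.beta.to_numpy(dtype=float)
    samples = []
    width = len(str(max(n_samples, 1)))
    for i in range(n_samples):
        profile = A @ P[i]
        if noise_sd > 0:
            profile = profile + rng.normal(0.0, noise_sd, size=profile.shape)
        profile = np.clip(profile, 0.0, 1.0)
        samples.append(
            MixtureSample(
                sample_id=f"mix_{i:0{width}d}",
                true_proportions=pd.Series(P[i], index=atlas.beta.columns),
                profile=pd.Series(profile, index=atlas.beta.index),
                noise_sd=noise_sd,
            )
        )
    return samples


def benchmark_models(
    mixtures: list[MixtureSample],
    signature: SignatureMatrix,
    models: tuple[str, ...] = MODELS,
    seed: int | None = None,
) -> BenchmarkResult:
    """Deconvolute each mixture with each model and compute per-model RMSE.

    RMSE pools over every (sample, cell type) entry:
    ``sqrt(mean((predicted - true)^2))``.  A solver failure excludes that
    sample from the failing model's RMSE and is counted.
    """
    if not mixtures:
        raise ValueError("no mixtures to benchmark")
    rmse = {}
    failed = {}
    for model in models:
        sq_errors = []
        n_fail = 0
        for mix in mixtures:
            bulk = BulkProfile(mix.sample_id, mix.profile)
            try:
                res = deconvolute(bulk, signature, model)
            except Exception as exc:  # noqa: BLE001 - per-sample robustness
                warnings.warn(f"{model} failed on {mix.sample_id}: {exc}")
                n_fail += 1
                continue
            truth = mix.true_proportions.reindex(res.proportions.index).fillna(0.0)
            sq_errors.append(((res.proportions - truth) ** 2).to_numpy())
        if not sq_errors:
            raise RuntimeError(f"model {model!r} failed on every sample")
        rmse[model] = float(np.sqrt(np.concatenate(sq_errors).mean()))
        failed[model] = n_fail
    rmse_series = pd.Series(rmse, name="rmse").sort_values(kind="mergesort")
    return BenchmarkResult(
        rmse=rmse_series,
        n_samples=len(mixtures),
        seed=seed,
        n_failed=pd.Series(failed, name="n_failed"),
    )
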