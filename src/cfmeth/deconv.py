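"""Cell-type deconvolution of bulk methylation profiles.

Given a signature matrix S (CpGs x cell types) and a bulk beta vector b,
estimate the mixing proportions x with Sx ~ b under one of four regression
models:

``nnls``
    least squares with non-negativity constraint (Lawson-Hanson);
``qp``
    quadratic program min ||Sx - b||^2 subject to x >= 0 and sum(x) = 1;
``svr``
    linear-kernel support vector regression of b on the columns of S;
``rlm``
    robust (Huber M-estimation) linear regression without intercept.

All models except ``qp`` may return coefficients that are negative or do
not sum to one; negatives are truncated at zero and the vector renormalised
so the output is always a probability vector over cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import SignatureMatrix

__all__ = ["BulkProfile", "DeconvolutionResult", "deconvolute", "deconvolute_cohort", "MODELS"]

MODELS = ("nnls", "svr", "qp", "rlm")


@dataclass
class BulkProfile:
    """A probe-indexed bulk beta vector for one sample (NaN = no coverage)."""

    sample_id: str
    beta: pd.Series

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("bulk beta values must lie in [0, 1]")


@dataclass
class DeconvolutionResult:
    sample_id: str
    model: str
    proportions: pd.Series
    n_probes_used: int
    residual_rss: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format row block (sample, cell_type, proportion, model, n_probes_used)."""
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "cell_type": self.proportions.index,
                "proportion": self.proportions.to_numpy(),
                "model": self.model,
                "n_probes_used": self.n_probes_used,
            }
        )


def _solve_nnls(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.optimize import nnls

    coef, _ = nnls(S, b)
    return coef


def _solve_qp(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||Sx-b||^2 s.t. x >= 0, sum x = 1 (SLSQP from the NNLS solution)."""
    from scipy.optimize import minimize

    n = S.shape[1]
    StS = S.T @ S
    Stb = S.T @ b

    def objective(x: np.ndarray) -> float:
        return float(x @ StS @ x - 2.0 * Stb @ x + b @ b)

    def grad(x: np.ndarray) -> np.ndarray:
        return 2.0 * (StS @ x - Stb)

    x0 = _solve_nnls(S, b)
    s = x0.sum()
    x0 = x0 / s if s > 0 else np.full(n, 1.0 / n)
    res = minimize(
        objective,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0, "jac": lambda x: np.ones(n)}],
        options={"ftol": 1e-14, "maxiter": 1000},
    )
    x = np.clip(res.x, 0.0, None)
    return x / x.sum()


def _solve_svr(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    # linear SVR without intercept (proportions have no baseline term);
    # epsilon = 0 so no residual smaller than the beta scale is ignored
    from sklearn.svm import LinearSVR

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LinearSVR(
            epsilon=0.0, C=1.0, fit_intercept=False, max_iter=50000, random_state=0
        )
        model.fit(S, b)
    return model.coef_.ravel()


def _solve_rlm(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.RLM(b, S, M=sm.robust.norms.HuberT()).fit()
    return np.asarray(fit.params)


_SOLVERS = {"nnls": _solve_nnls, "qp": _solve_qp, "svr": _solve_svr, "rlm": _solve_rlm}


def deconvolute(
    bulk: BulkProfile,
    signature: SignatureMatrix,
    model: str = "nnls",
) -> DeconvolutionResult:
    """Estimate cell-type proportions of one bulk profile.

    The bulk vector and signature are intersected on probe ID and probes with
    missing bulk values dropped; at least ``max(10, n_cell_types)`` shared
    probes are required.  The selected model's coefficients are truncated at
    zero and renormalised to sum to one (a no-op for ``qp``, which is
    constrained to the simplex already).
    """
    if model not in _SOLVERS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    shared = signature.beta.index.intersection(bulk.beta.index)
    b_series = bulk.beta.loc[shared].dropna()
    n_used = len(b_series)
    n_types = signature.beta.shape[1]
    minimum = max(10, n_types)
    if n_used < minimum:
        raise ValueError(
            f"only {n_used} shared probes between bulk {bulk.sample_id!r} and "
            f"signature; need at least {minimum}"
        )
    S = signature.beta.loc[b_series.index].to_numpy(dtype=float)
    b = b_series.to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < n_types:
        warnings.warn(
            f"signature is rank-deficient for sample {bulk.sample_id!r}; "
            "solution is solver-dependent"
        )
    coef = _SOLVERS[model](S, b)
    coef = np.clip(coef, 0.0, None)
    total = coef.sum()
    if total <= 0:
        warnings.warn(f"all-zero coefficients for {bulk.sample_id!r}; returning uniform")
        coef = np.full(n_types, 1.0 / n_types)
    else:
        coef = coef / total
    rss = float(np.sum((S @ coef - b) ** 2))
    proportions = pd.Series(coef, index=signature.beta.columns, name=bulk.sample_id)
    return DeconvolutionResult(bulk.sample_id, model, proportions, n_used, rss)


def deconvolute_cohort(
    bulks: list[BulkProfile],
    signature: SignatureMatrix,
    model: str = "nnls",
) -> pd.DataFrame:
    """Deconvolute each sample; per-sample failures are recorded, not fatal.

    Returns a tidy long table (sample, cell_type, proportion, model,
    n_probes_used) in input sample order.  Failed samples appear with NaN
    proportions and the error message in an ``error`` column.
    """
    if not bulks:
        raise ValueError("empty cohort")
    blocks = []
    for bulk in bulks:
        try:
            res = deconvolute(bulk, signature, model)
            frame = res.to_frame()
            frame["error"] = ""
        except ValueError as exc:
            warnings.warn(f"sample {bulk.sample_id!r} failed: {exc}")
            frame = pd.DataFrame(
                {
                    "sample": bulk.sample_id,
                    "cell_type": signature.beta.columns,
                    "proportion": np.nan,
                    "model": model,
                    "n_probes_used": 0,
                    "error": str(exc),
                }
            )
        blocks.append(frame)
    return pd.concat(blocks, ignore_index=True)
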