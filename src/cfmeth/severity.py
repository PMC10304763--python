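"""Severity association of DMR methylation and ACS-type classification.

ACS types are encoded as a numeric severity response (UA = 1, NSTEMI = 2,
STEMI = 3; healthy controls either excluded or coded 0).  For every DMR a
full ordinary-least-squares model

    Y ~ b0 + b1 * DNAmeth + b2 * ccfDNAlevel

is fit and compared against the reduced model Y ~ b0 + b2 * ccfDNAlevel by
a nested ANOVA F-test; because exactly one parameter is dropped, the
F-statistic equals the square of the t-statistic on b1.  The ccfDNA level
covariate controls for the overall amount of circulating DNA, which is
elevated in disease regardless of which tissue released it.

The module also provides single-marker multinomial classification
(misclassification-rate screening of classical biomarkers), multivariate
ACS-type classifiers (random forest, PLS-DA, penalized multinomial
regression) with a stratified 70/30 split and repeated cross-validation,
and a centered PCA embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SEVERITY_CODES",
    "SeverityFit",
    "encode_severity",
    "fit_dmr_model",
    "fit_severity_models",
    "select_associated_dmrs",
    "fit_marker_models",
    "single_marker_multinomial",
    "train_acs_classifiers",
    "pca_embed",
]

SEVERITY_CODES = {"UA": 1, "NSTEMI": 2, "STEMI": 3}
CONTROL_LABEL = "control"


@dataclass
class SeverityFit:
    dmr_id: str
    beta0: float
    beta1: float
    beta2: float
    t_beta1: float
    p_beta1: float
    F_nested: float
    p_F: float
    n_samples: int
    flagged: bool = False

    def as_dict(self) -> dict:
        return {
            "dmr_id": self.dmr_id,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "t_beta1": self.t_beta1,
            "p_beta1": self.p_beta1,
            "F_nested": self.F_nested,
            "p_F": self.p_F,
            "n_samples": self.n_samples,
            "flagged": self.flagged,
        }


def encode_severity(groups, include_controls: bool = False) -> pd.Series:
    """Numeric severity response: UA=1, NSTEMI=2, STEMI=3.

    Controls are coded 0 when ``include_controls`` is set, otherwise dropped
    from the returned vector.  Unknown group labels raise.
    """
    groups = pd.Series(groups)
    valid = set(SEVERITY_CODES) | {CONTROL_LABEL}
    unknown = set(groups.unique()) - valid
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    if not include_controls:
        groups = groups[groups != CONTROL_LABEL]
    codes = {**SEVERITY_CODES, CONTROL_LABEL: 0}
    return groups.map(codes).astype(float)


def fit_dmr_model(
    y,
    meth,
    ccfdna,
    dmr_id: str = "",
) -> SeverityFit:
    """OLS of ``y ~ 1 + meth + ccfdna`` with a nested test on the meth term.

    Missing values are dropped casewise; at least 5 complete cases are
    required.  Constant methylation is flagged (p = 1, zero coefficients on
    meth).  The reduced model drops only the methylation term, so
    ``F_nested == t_beta1 ** 2`` holds identically.
    """
    y = np.asarray(y, dtype=float)
    meth = np.asarray(meth, dtype=float)
    ccfdna = np.asarray(ccfdna, dtype=float)
    ok = np.isfinite(y) & np.isfinite(meth) & np.isfinite(ccfdna)
    y, meth, ccfdna = y[ok], meth[ok], ccfdna[ok]
    n = y.size
    if n < 5:
        raise ValueError(f"need >= 5 complete cases, got {n}")
    if np.ptp(meth) == 0:
        return SeverityFit(dmr_id, float(np.mean(y)), 0.0, 0.0, 0.0, 1.0, 0.0, 1.0, n, flagged=True)
    X_full = np.column_stack([np.ones(n), meth, ccfdna])
    X_red = np.column_stack([np.ones(n), ccfdna])
    beta, rss_full = _ols(X_full, y)
    _, rss_red = _ols(X_red, y)
    df_resid = n - 3
    if df_resid <= 0:
        raise ValueError("not enough degrees of freedom")
    sigma2 = rss_full / df_resid
    xtx_inv = np.linalg.pinv(X_full.T @ X_full)
    se1 = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
    if se1 == 0.0:
        t1, p1 = 0.0, 1.0
    else:
        t1 = float(beta[1] / se1)
        p1 = float(2.0 * stats.t.sf(abs(t1), df_resid))
    if sigma2 == 0.0:
        F = float("inf") if rss_red > rss_full else 0.0
        pF = 0.0 if rss_red > rss_full else 1.0
    else:
        F = float((rss_red - rss_full) / sigma2)
        pF = float(stats.f.sf(F, 1, df_resid))
    return SeverityFit(
        dmr_id,
        float(beta[0]),
        float(beta[1]),
        float(beta[2]),
        t1,
        p1,
        max(F, 0.0),
        pF,
        n,
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_severity_models(
    y,
    dmr_meth: pd.DataFrame,
    ccfdna,
) -> pd.DataFrame:
    """Run :func:`fit_dmr_model` per DMR column and tabulate the fits.

    ``dmr_meth`` is samples x DMRs (methylation percent); rows must align
    with ``y`` and ``ccfdna``.
    """
    rows = []
    for dmr_id in dmr_meth.columns:
        fit = fit_dmr_model(y, dmr_meth[dmr_id], ccfdna, dmr_id=str(dmr_id))
        rows.append(fit.as_dict())
    return pd.DataFrame(rows).set_index("dmr_id")


def select_associated_dmrs(fits: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, float]:
    """Keep fits with p_beta1 <= alpha; returns (subset, fraction retained)."""
    if fits.empty:
        return fits, float("nan")
    keep = fits["p_beta1"] <= alpha
    return fits.loc[keep], float(keep.mean())


def fit_marker_models(
    markers: pd.DataFrame,
    dmr_meth: pd.DataFrame,
    ccfdna,
) -> pd.DataFrame:
    """Per-(marker, DMR) linear fits with the marker as the response.

    Markers with fewer than 5 non-missing samples are skipped with a
    warning.  Returns a long frame with a ``marker`` column and one row per
    (marker, DMR).
    """
    blocks = []
    for marker in markers.columns:
        y = markers[marker]
        if y.notna().sum() < 5:
            warnings.warn(f"marker {marker!r} has < 5 observations; skipped")
            continue
        fits = fit_severity_models(y, dmr_meth, ccfdna)
        fits = fits.assign(marker=marker)
        blocks.append(fits.reset_index())
    if not blocks:
        return pd.DataFrame()
    return pd.concat(blocks, ignore_index=True)


def single_marker_multinomial(marker, labels) -> tuple[float, bool]:
    """In-sample misclassification rate of a one-predictor multinomial model.

    Samples with a missing marker value are excluded.  The model is an
    unpenalised multinomial logistic fit; when it fails to converge
    (complete separation) an L2-penalised fit is used instead and the
    result flagged.  Returns ``(rate_percent, flagged)``.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(marker)
    marker, labels = marker[ok], labels[ok]
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes")
    X = marker.reshape(-1, 1)
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(penalty=None, max_iter=2000)
            model.fit(X, labels)
        except ConvergenceWarning:
            flagged = True
            model = LogisticRegression(penalty="l2", C=1.0, max_iter=2000)
            model.fit(X, labels)
    predicted = model.predict(X)
    rate = 100.0 * float(np.mean(predicted != labels))
    return rate, flagged


def _make_classifier(model: str, seed: int, cv, n_features: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import GridSearchCV

    if model == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if model == "pmr":
        grid = {"C": [0.01, 0.1, 1.0, 10.0]}
        base = LogisticRegression(penalty="l2", max_iter=5000)
        return GridSearchCV(base, grid, cv=cv, scoring="accuracy")
    if model == "pls":
        return _PLSDA(max_components=min(5, n_features), cv=cv)
    raise ValueError(f"unknown model {model!r}; choose from rf, pls, pmr")


class _PLSDA:
    """PLS-DA: PLS regression on one-hot labels, class by argmax.

    The number of components is chosen by cross-validated accuracy.
    """

    def __init__(self, max_components: int = 5, cv=None):
        self.max_components = max_components
        self.cv = cv
        self.n_components_ = None

    def fit(self, X, y):
        from sklearn.base import clone
        from sklearn.model_selection import cross_val_score

        best, best_score = 1, -np.inf
        for nc in range(1, self.max_components + 1):
            trial = _PLSDACore(nc)
            try:
                score = cross_val_score(trial, X, y, cv=self.cv, scoring="accuracy").mean()
            except ValueError:
                continue
            if score > best_score:
                best, best_score = nc, score
        self.n_components_ = best
        self._core = _PLSDACore(best).fit(X, y)
        return self

    def predict(self, X):
        return self._core.predict(X)


from sklearn.base import BaseEstimator, ClassifierMixin


class _PLSDACore(ClassifierMixin, BaseEstimator):
    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        from sklearn.cross_decomposition import PLSRegression

        self.classes_, y_idx = np.unique(y, return_inverse=True)
        Y = np.eye(len(self.classes_))[y_idx]
        nc = min(self.n_components, np.asarray(X).shape[1], np.asarray(X).shape[0] - 1)
        self._pls = PLSRegression(n_components=max(nc, 1), scale=False)
        self._pls.fit(X, Y)
        return self

    def predict(self, X):
        scores = self._pls.predict(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_acs_classifiers(
    features: pd.DataFrame,
    labels,
    models: tuple[str, ...] = ("rf", "pls", "pmr"),
    test_size: float = 0.3,
    cv_folds: int = 10,
    cv_repeats: int = 10,
    seed: int = 0,
    external_features: pd.DataFrame | None = None,
    external_labels=None,
) -> dict[str, dict]:
    """Train ACS-type classifiers on a stratified 70/30 split.

    Features (samples x DMR methylation) must be complete.  Centering and
    scaling parameters are learned on the training split only and applied
    to every evaluation matrix, including an optional external cohort.
    Cross-validation is stratified k-fold repeated ``cv_repeats`` times with
    k capped at the smallest training-class count.

    Returns per model: held-out accuracy, CV accuracy (mean over folds),
    optionally external-cohort accuracy, and the fitted pipeline pieces.
    """
    from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
    from sklearn.preprocessing import StandardScaler

    if features.isna().any().any():
        raise ValueError("features must be complete; impute or drop incomplete DMRs first")
    labels = np.asarray(labels)
    X_train, X_test, y_train, y_test = train_test_split(
        features.to_numpy(dtype=float),
        labels,
        test_size=test_size,
        stratify=labels,
        random_state=seed,
    )
    class_counts = pd.Series(y_train).value_counts()
    if (class_counts < 2).any():
        raise ValueError("every class needs >= 2 training samples")
    k = int(min(cv_folds, class_counts.min()))
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=cv_repeats, random_state=seed)
    scaler = StandardScaler().fit(X_train)
    Xtr, Xte = scaler.transform(X_train), scaler.transform(X_test)
    results: dict[str, dict] = {}
    for model in models:
        clf = _make_classifier(model, seed, cv, features.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xtr, y_train)
            cv_acc = _cv_accuracy(clf, Xtr, y_train, cv)
        holdout = float(np.mean(clf.predict(Xte) == y_test))
        entry = {
            "model": clf,
            "scaler": scaler,
            "holdout_accuracy": holdout,
            "cv_accuracy": cv_acc,
            "n_train": len(y_train),
            "n_test": len(y_test),
        }
        if external_features is not None and external_labels is not None:
            Xext = scaler.transform(external_features.to_numpy(dtype=float))
            entry["external_accuracy"] = float(
                np.mean(clf.predict(Xext) == np.asarray(external_labels))
            )
        results[model] = entry
    return results


def _cv_accuracy(clf, X, y, cv) -> float:
    from sklearn.model_selection import GridSearchCV

    if isinstance(clf, GridSearchCV):
        return float(clf.best_score_)
    if isinstance(clf, _PLSDA):
        from sklearn.model_selection import cross_val_score

        return float(
            cross_val_score(_PLSDACore(clf.n_components_), X, y, cv=cv, scoring="accuracy").mean()
        )
    from sklearn.base import clone
    from sklearn.model_selection import cross_val_score

    return float(cross_val_score(clone(clf), X, y, cv=cv, scoring="accuracy").mean())


def pca_embed(matrix: pd.DataFrame, n_components: int = 2, scale: bool = False):
    """Centered PCA of a samples x DMR matrix.

    Returns ``(coordinates, explained_variance_ratio)`` for the first
    ``n_components`` components.  Scaling to unit variance is off by
    default, matching standard prcomp-style usage on methylation percents.
    """
    from sklearn.decomposition import PCA

    if matrix.isna().any().any():
        raise ValueError("PCA input must be complete")
    if matrix.shape[0] < 2:
        raise ValueError("need at least two samples")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    k = min(n_components, min(X.shape) if X.shape[0] > X.shape[1] else X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=max(k, 1))
    coords = pca.fit_transform(X)
    coords_df = pd.DataFrame(
        coords,
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return coords_df, pca.explained_variance_ratio_
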