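"""Efficacy modelling: features, linear fits, Lasso ensemble, evaluation.

The modelling chain maps a per-sample PPI profile (22 metrics) to a
predicted ex vivo drug-sensitivity score on the [0, 1] AUC scale:

1. metrics are floored and log2-transformed (:func:`transform_metrics`);
2. single metrics are screened by OLS with an upper-tail F-test
   (:func:`fit_single_metric`);
3. a small panel is fitted jointly by OLS (:func:`fit_combined`), or the
   panel itself is discovered by a Lasso train/test ensemble
   (:func:`lasso_ensemble`);
4. per-sample scores (:func:`estimate_score`) are evaluated by ROC
   analysis, mean squared error, a confusion matrix at the 0.61
   responsiveness threshold, and a Mann-Whitney rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.metrics import roc_curve as _sk_roc_curve

from .registry import (
    COUNT_FLOOR,
    INTENSITY_FLOOR,
    INTENSITY_METRICS,
    RESPONSE_THRESHOLD,
    validate_metric_names,
)

__all__ = [
    "EfficacyModel",
    "RegressionResult",
    "EnsembleResult",
    "RocResult",
    "ConfusionResult",
    "transform_metrics",
    "fit_single_metric",
    "fit_combined",
    "lasso_ensemble",
    "estimate_score",
    "roc_analysis",
    "evaluate_mse",
    "confusion",
    "mann_whitney",
]


@dataclass(frozen=True)
class EfficacyModel:
    """A linear score model on log2-transformed metrics.

    ``score = clip(intercept + sum(coef * feature), 0, 1)``; samples with
    ``score >= threshold`` are called responsive (R).
    """

    drug: str
    metric_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    threshold: float = RESPONSE_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.metric_names) != len(self.coefficients):
            raise ValueError("metric_names and coefficients differ in length")
        validate_metric_names(self.metric_names)

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "metrics": list(self.metric_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "threshold": float(self.threshold),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EfficacyModel":
        return cls(
            drug=d["drug"],
            metric_names=tuple(d["metrics"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            intercept=float(d["intercept"]),
            threshold=float(d.get("threshold", RESPONSE_THRESHOLD)),
        )


@dataclass
class RegressionResult:
    """OLS fit summary for a single- or multi-metric model."""

    metrics: tuple[str, ...]
    slopes: np.ndarray          # per log2 unit
    intercept: float
    pearson_r: float            # multiple correlation (signed for 1 metric)
    f_stat: float
    p_value: float              # upper-tail F-test p
    mse: float                  # residual mean squared error
    n: int
    coef_se: np.ndarray = field(default=None)
    coef_ci: np.ndarray = field(default=None)   # (k, 2) 95% intervals
    coef_p: np.ndarray = field(default=None)    # two-sided t-test p
    accepted: bool = True       # overall p < 0.05


@dataclass
class EnsembleResult:
    """Outcome of the Lasso train/test ensemble selection."""

    n_candidates: int
    retained_models: list
    coefficient_matrix: pd.DataFrame    # retained models x metrics
    retention_criteria: dict
    seed: int

    @property
    def n_retained(self) -> int:
        return len(self.retained_models)

    def support_frequency(self, tol: float = 1e-10) -> pd.Series:
        """Fraction of retained models in which each metric is non-zero."""
        if self.n_retained == 0:
            return pd.Series(np.nan, index=self.coefficient_matrix.columns)
        return (self.coefficient_matrix.abs() > tol).mean(axis=0)


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class ConfusionResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity_pct: float  # nan when no observed positives
    specificity_pct: float  # nan when no observed negatives

    @property
    def matrix(self) -> np.ndarray:
        """2x2 array [[TP, FN], [FP, TN]] (rows: observed R, NR)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


# ---------------------------------------------------------------------------
# feature transform
# ---------------------------------------------------------------------------

def transform_metrics(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Floor and log2-transform a profile table.

    Count metrics below 100 spots are fixed to 100; the three
    intensity-type metrics below 1e7 a.u. are fixed to 1e7. Returns
    ``(features, floor_flags)`` with identical shape/index; ``floor_flags``
    is True where the floor was applied.

    Parameters
    ----------
    profiles : DataFrame
        One row per sample, columns drawn from the metric registry.
    """
    validate_metric_names(profiles.columns)
    values = profiles.astype(float)
    if (values.to_numpy() < 0).any():
        bad = values.columns[(values < 0).any(axis=0)].tolist()
        raise ValueError(f"negative metric values in column(s) {bad!r}")
    floors = pd.Series(
        {c: INTENSITY_FLOOR if c in INTENSITY_METRICS else COUNT_FLOOR
         for c in values.columns}
    )
    flags = values.lt(floors, axis=1)
    features = np.log2(values.clip(lower=floors, axis=1))
    return features, flags


# ---------------------------------------------------------------------------
# OLS fits
# ---------------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray):
    """Least-squares fit with intercept; returns coef, intercept, stats.

    The F statistic tests the full model against the intercept-only model
    with (k, n - k - 1) degrees of freedom; its upper-tail probability is
    the reported p-value.
    """
    n, k = X.shape
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_resid = n - k - 1
    if df_resid <= 0:
        raise ValueError(f"not enough samples (n={n}) for {k} metrics")
    if tss <= 0:
        raise ValueError("target has zero variance")
    r2 = 1.0 - rss / tss
    if rss <= 1e-300:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (tss - rss) / k / (rss / df_resid)
        p = float(stats.f.sf(f_stat, k, df_resid))
    sigma2 = rss / df_resid
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, df_resid)
    ci = np.column_stack([beta - tcrit * se, beta + tcrit * se])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    coef_p = 2 * stats.t.sf(np.abs(tvals), df_resid)
    return beta, fitted, rss / n, r2, f_stat, p, se, ci, coef_p


def fit_single_metric(
    feature: "pd.Series | np.ndarray",
    target: "pd.Series | np.ndarray",
    name: str | None = None,
) -> RegressionResult:
    """OLS of the ex vivo AUC on one log2 metric, with upper-tail F-test.

    For a single regressor the F statistic equals the squared t statistic
    of the slope, and ``pearson_r`` is the signed Pearson correlation.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature and target must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("feature has zero variance")
    if name is None:
        name = getattr(feature, "name", None) or "metric"
    beta, fitted, mse, r2, f_stat, p, se, ci, coef_p = _ols(x[:, None], y)
    r = math.copysign(math.sqrt(max(r2, 0.0)), beta[1])
    return RegressionResult(
        metrics=(str(name),),
        slopes=beta[1:],
        intercept=float(beta[0]),
        pearson_r=r,
        f_stat=f_stat,
        p_value=p,
        mse=mse,
        n=len(x),
        coef_se=se[1:],
        coef_ci=ci[1:],
        coef_p=coef_p[1:],
        accepted=p < 0.05,
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name columns involved in a rank deficiency via QR pivoting."""
    from scipy.linalg import qr as _qr

    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    _, r, piv = _qr(arr, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    dependent = sorted(piv[rank:])
    names = ["<intercept>"] + list(X.columns)
    return [names[i] for i in dependent]


def fit_combined(
    features: pd.DataFrame,
    target: "pd.Series | np.ndarray",
    drug: str = "ABT-199",
    threshold: float = RESPONSE_THRESHOLD,
) -> tuple[EfficacyModel, RegressionResult]:
    """Multivariate OLS of the ex vivo AUC on a metric panel.

    Returns the fitted :class:`EfficacyModel` and its fit summary. The
    model is flagged unaccepted (not rejected outright) when the overall
    F-test p-value is >= 0.05.
    """
    y = np.asarray(target, dtype=float)
    X = features.astype(float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 samples (n={n}, k={k})")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy()]))
    if rank < k + 1:
        raise ValueError(
            "rank-deficient design; collinear columns: "
            f"{_collinear_columns(X)!r}"
        )
    beta, fitted, mse, r2, f_stat, p, se, ci, coef_p = _ols(X.to_numpy(), y)
    result = RegressionResult(
        metrics=tuple(X.columns),
        slopes=beta[1:],
        intercept=float(beta[0]),
        pearson_r=math.sqrt(max(r2, 0.0)),
        f_stat=f_stat,
        p_value=p,
        mse=mse,
        n=n,
        coef_se=se[1:],
        coef_ci=ci[1:],
        coef_p=coef_p[1:],
        accepted=p < 0.05,
    )
    model = EfficacyModel(
        drug=drug,
        metric_names=tuple(X.columns),
        coefficients=tuple(float(b) for b in beta[1:]),
        intercept=float(beta[0]),
        threshold=threshold,
    )
    return model, result


# ---------------------------------------------------------------------------
# scoring and evaluation
# ---------------------------------------------------------------------------

def estimate_score(model: EfficacyModel, features: pd.DataFrame) -> pd.Series:
    """Per-sample estimated score, clipped to the [0, 1] AUC scale."""
    missing = [m for m in model.metric_names if m not in features.columns]
    if missing:
        raise ValueError(f"features missing model metric(s): {missing!r}")
    X = features[list(model.metric_names)].to_numpy(dtype=float)
    raw = model.intercept + X @ np.asarray(model.coefficients)
    return pd.Series(np.clip(raw, 0.0, 1.0), index=features.index, name="score")


def roc_analysis(scores, labels) -> RocResult:
    """ROC curve and AUC for responsive-vs-non-responsive prediction.

    The AUC uses the rank (Mann-Whitney) formulation with ties counted
    one half, so it is numerically identical to U / (n1 * n0).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    n1 = int(lab.sum())
    n0 = int((~lab).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(s)
    auc = (ranks[lab].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = _sk_roc_curve(lab.astype(int), s)
    return RocResult(auc=float(auc), fpr=fpr, tpr=tpr, thresholds=thr)


def evaluate_mse(predicted, observed, exclusions=None) -> float:
    """Mean squared error between scores and observed ex vivo AUC.

    ``exclusions`` names samples (index labels) left out as outliers; the
    excluded set is reported via a warning so it is never silent.
    """
    pred = pd.Series(predicted).astype(float)
    obs = pd.Series(observed).astype(float)
    if exclusions:
        exclusions = list(exclusions)
        warnings.warn(f"evaluate_mse excluding samples: {exclusions!r}")
        keep = ~pred.index.isin(exclusions)
        pred, obs = pred[keep], obs[keep]
    if len(pred) == 0:
        raise ValueError("no samples left after exclusions")
    return float(((pred.to_numpy() - obs.to_numpy()) ** 2).mean())


def confusion(predicted, observed) -> ConfusionResult:
    """Confusion matrix for responder (R) vs non-responder (NR) calls.

    Both arguments are boolean arrays (True = R). Sensitivity and
    specificity are percentages; a rate whose observed class is absent is
    reported as NaN rather than raised.
    """
    p = np.asarray(predicted, dtype=bool)
    o = np.asarray(observed, dtype=bool)
    if p.shape != o.shape:
        raise ValueError("predicted and observed differ in length")
    tp = int((p & o).sum())
    fn = int((~p & o).sum())
    fp = int((p & ~o).sum())
    tn = int((~p & ~o).sum())
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return ConfusionResult(tp=tp, fp=fp, tn=tn, fn=fn,
                           sensitivity_pct=sens, specificity_pct=spec)


def mann_whitney(scores_r, scores_nr) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank test between R and NR score groups.

    Uses the exact null distribution when both groups have <= 12
    observations and the data are tie-free, otherwise the tie-corrected
    normal approximation. Returns ``(U, p)`` with U counting pairs where
    an R score exceeds an NR score (ties one half), so
    ``U / (n1 * n2)`` equals the ROC AUC of the same data.
    """
    x = np.asarray(scores_r, dtype=float)
    y = np.asarray(scores_nr, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Lasso train/test ensemble
# ---------------------------------------------------------------------------

def _stratified_split(labels: np.ndarray, test_fraction: float, rng):
    """Index split stratified by the binary responsiveness label."""
    test_idx = []
    for cls in (False, True):
        members = np.flatnonzero(labels == cls)
        if len(members) == 0:
            continue
        n_test = max(1, int(round(test_fraction * len(members))))
        n_test = min(n_test, len(members))
        test_idx.append(rng.choice(members, size=n_test, replace=False))
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(len(labels)), test)
    return train, test


def lasso_ensemble(
    features: pd.DataFrame,
    target,
    n_candidates: int = 10_000,
    test_fraction: float = 0.25,
    alpha_range: tuple[float, float] = (1e-4, 3e-2),
    r_floor: float = 0.7,
    threshold: float = RESPONSE_THRESHOLD,
    drug: str = "ABT-199",
    seed: int | None = None,
) -> EnsembleResult:
    """Panel discovery by an ensemble of Lasso fits on random splits.

    Each candidate draws a stratified train/test split and an L1 penalty
    (log-uniform over ``alpha_range``), fits a Lasso of the ex vivo AUC on
    all metrics, and is retained only when

    1. every test sample's responsiveness (score >= ``threshold``) is
       predicted correctly,
    2. the training-set Pearson R is at least ``r_floor``, and
    3. an OLS refit restricted to the selected (non-zero) support is
       significant overall (F-test p < 0.05).

    An empty retained set is a valid outcome (returned with diagnostics).
    """
    if seed is None:
        raise ValueError("lasso_ensemble requires an explicit seed")
    y = np.asarray(target, dtype=float)
    X = features.astype(float)
    labels = y >= threshold
    if labels.all() or (~labels).all():
        raise ValueError("need both responsive and non-responsive samples")
    rng = np.random.default_rng(seed)
    log_lo, log_hi = np.log(alpha_range[0]), np.log(alpha_range[1])
    Xa = X.to_numpy()

    retained, coef_rows, n_all_correct = [], [], 0
    for _ in range(n_candidates):
        alpha = float(np.exp(rng.uniform(log_lo, log_hi)))
        train, test = _stratified_split(labels, test_fraction, rng)
        las = Lasso(alpha=alpha, max_iter=50_000)
        las.fit(Xa[train], y[train])
        score_test = np.clip(las.predict(Xa[test]), 0.0, 1.0)
        if not ((score_test >= threshold) == labels[test]).all():
            continue
        n_all_correct += 1
        pred_train = las.predict(Xa[train])
        if np.std(pred_train) == 0:
            continue
        r_train = np.corrcoef(pred_train, y[train])[0, 1]
        if not (r_train >= r_floor):
            continue
        support = np.flatnonzero(np.abs(las.coef_) > 1e-10)
        if len(support) == 0 or len(train) <= len(support) + 1:
            continue
        try:
            _, refit = fit_combined(
                X.iloc[train, support], y[train], drug=drug, threshold=threshold
            )
        except ValueError:
            continue
        if not refit.accepted:
            continue
        retained.append(
            EfficacyModel(
                drug=drug,
                metric_names=tuple(X.columns),
                coefficients=tuple(float(c) for c in las.coef_),
                intercept=float(las.intercept_),
                threshold=threshold,
            )
        )
        coef_rows.append(las.coef_.copy())

    coef_matrix = pd.DataFrame(
        np.array(coef_rows).reshape(len(coef_rows), X.shape[1]),
        columns=X.columns,
    )
    return EnsembleResult(
        n_candidates=n_candidates,
        retained_models=retained,
        coefficient_matrix=coef_matrix,
        retention_criteria={
            "test_fraction": test_fraction,
            "alpha_range": alpha_range,
            "r_floor": r_floor,
            "threshold": threshold,
            "n_test_all_correct": n_all_correct,
        },
        seed=seed,
    )
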