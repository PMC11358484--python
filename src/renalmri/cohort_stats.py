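"""Cohort-level statistics for the unilateral-IRI imaging study.

The cohort lives in a tidy long-format table with one row per
(animal, timepoint, side, parameter) value.  This module provides the
study's statistics layer: two-way ANOVA (side x timepoint) with
Bonferroni-corrected left-vs-right contrasts per timepoint, univariate ROC
analysis of each imaging parameter for the healthy-vs-injured kidney
classification, PCA of the retained parameters with ROC on each component
score, Pearson correlation (reported as R^2), and Bland-Altman agreement
between paired GFR measurement methods.

Class definition for the classifier (as in the study design): healthy =
both kidneys at baseline; injured = the right (clamped) kidney at day 1 and
day 15.  Contralateral kidneys at post-surgery timepoints are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "TIMEPOINTS",
    "SIDES",
    "ROCCurve",
    "PCAResult",
    "BlandAltmanResult",
    "AnovaResult",
    "validate_cohort_table",
    "two_way_anova_bonferroni",
    "roc_auc",
    "classifier_samples",
    "univariate_auc",
    "pca_classifier",
    "correlate",
    "bland_altman",
]

TIMEPOINTS = ("baseline", "day1", "day15")
SIDES = ("left", "right")

REQUIRED_COLUMNS = ("animal_id", "timepoint", "side", "parameter", "value")


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must be in [0, 1]")


@dataclass(frozen=True)
class PCAResult:
    """PCA of z-scored parameters via the correlation-matrix eigendecomposition."""

    loadings: pd.DataFrame          # parameters x components, orthonormal columns
    scores: np.ndarray              # samples x components
    variance_fraction: np.ndarray   # per component, sums to 1
    cumulative_variance: np.ndarray
    n_retained: int
    dropped_constant: tuple[str, ...] = ()


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


@dataclass(frozen=True)
class AnovaResult:
    table: pd.DataFrame                    # F and p per factor/interaction
    pairwise: pd.DataFrame                 # per-timepoint left-vs-right contrasts
    n_comparisons: int


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy cohort table schema and vocabularies."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad_tp = set(table["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    bad_side = set(table["side"]) - set(SIDES)
    if bad_side:
        raise ValueError(f"unknown sides: {sorted(bad_side)}")
    dup = table.duplicated(subset=["animal_id", "timepoint", "side", "parameter"])
    if dup.any():
        raise ValueError("duplicate (animal, timepoint, side, parameter) records")
    return table


def two_way_anova_bonferroni(table: pd.DataFrame, parameter: str) -> AnovaResult:
    """Two-factor (side x timepoint) ANOVA with Bonferroni pairwise contrasts.

    Ordinary (not repeated-measures) two-way ANOVA with interaction on the
    per-animal values; then a pooled-variance left-vs-right t-test within
    each timepoint, Bonferroni-corrected across the three timepoints.
    """
    validate_cohort_table(table)
    df = table[table["parameter"] == parameter].copy()
    if df.empty:
        raise ValueError(f"parameter {parameter!r} not in table")
    cells = df.groupby(["timepoint", "side"])["value"].count()
    if (cells < 2).any():
        bad = cells[cells < 2]
        raise ValueError(f"cells with < 2 animals for {parameter!r}:\n{bad}")

    if np.ptp(df["value"].to_numpy()) == 0.0:
        # no variance anywhere: F = 0, p = 1 by convention (0/0 otherwise)
        factors = ["C(side)", "C(timepoint)", "C(side):C(timepoint)"]
        anova_tab = pd.DataFrame(
            {"F": [0.0] * 3, "PR(>F)": [1.0] * 3}, index=factors
        )
    else:
        model = ols("value ~ C(side) * C(timepoint)", data=df).fit()
        anova_tab = sm.stats.anova_lm(model, typ=2)[["F", "PR(>F)"]]

    tps = [t for t in TIMEPOINTS if t in set(df["timepoint"])]
    n_comp = len(tps)
    rows = []
    for tp in tps:
        left = df[(df.timepoint == tp) & (df.side == "left")]["value"].to_numpy()
        right = df[(df.timepoint == tp) & (df.side == "right")]["value"].to_numpy()
        if np.ptp(np.concatenate([left, right])) == 0.0:
            t_stat, p_raw = 0.0, 1.0
        else:
            t_stat, p_raw = sps.ttest_ind(left, right, equal_var=True)
        rows.append({
            "timepoint": tp, "t": float(t_stat), "p_raw": float(p_raw),
            "p_adjusted": min(1.0, float(p_raw) * n_comp),
            "mean_left": float(left.mean()), "mean_right": float(right.mean()),
        })
    return AnovaResult(table=anova_tab, pairwise=pd.DataFrame(rows),
                       n_comparisons=n_comp)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> ROCCurve:
    """ROC curve and AUC (rank/Mann-Whitney estimator with tie correction).

    Orientation is taken as given: a parameter whose scores run the "wrong"
    way yields AUC < 0.5 and is reported as-is, never auto-flipped.
    """
    y = np.asarray(labels)
    x = np.asarray(scores, dtype=float)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    fpr, tpr, thr = roc_curve(y, x)
    auc = float(roc_auc_score(y, x))
    return ROCCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=auc)


def classifier_samples(
    table: pd.DataFrame, parameters: list[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build the healthy/injured sample matrix from the cohort table.

    Healthy: both kidneys at baseline.  Injured: right kidney at day 1 and
    day 15.  Returns a (samples x parameters) frame and a 0/1 label vector
    (1 = injured).  Rows with missing values are dropped listwise.
    """
    validate_cohort_table(table)
    wide = table.pivot_table(
        index=["animal_id", "timepoint", "side"], columns="parameter",
        values="value", aggfunc="first",
    )
    idx = wide.index.to_frame(index=False)
    healthy = idx["timepoint"] == "baseline"
    injured = (idx["side"] == "right") & idx["timepoint"].isin(["day1", "day15"])
    keep = (healthy | injured).to_numpy()
    X = wide.loc[keep, parameters]
    y = injured.to_numpy()[keep].astype(int)
    ok = X.notna().all(axis=1).to_numpy()
    return X.loc[ok], y[ok]


def univariate_auc(X: pd.DataFrame, labels: np.ndarray) -> dict[str, ROCCurve]:
    """Injury-oriented univariate ROC per parameter.

    The renal parameters studied here (volume, F_T, RBF, ADC, D) decline
    with injury, so each parameter enters the ROC negated — one fixed global
    orientation, applied identically to every parameter.  No per-parameter
    auto-flip happens: a parameter that does not separate the classes, or
    separates them the "wrong" way under this orientation, keeps its
    AUC <= 0.5.
    """
    return {p: roc_auc(labels, -X[p].to_numpy()) for p in X.columns}


def pca_classifier(
    X: pd.DataFrame,
    labels: np.ndarray,
    cumulative_variance_target: float = 0.80,
    logistic: bool = False,
) -> dict:
    """PCA of z-scored parameters with per-component ROC analysis.

    Columns are z-scored; components come from the eigendecomposition of the
    correlation matrix (so variance fractions sum to one exactly).  Component
    scores are fed individually to :func:`roc_auc`; components are retained
    up to the cumulative-variance target.  A principal axis has no intrinsic
    sign, so each component is oriented toward the positive class (its score
    correlates positively with the labels) before ROC analysis.  Constant
    columns are dropped with a warning recorded in the result.  ``logistic=True`` additionally fits a
    logistic regression on the retained scores and reports its AUC.
    """
    y = np.asarray(labels)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 parameters for PCA")
    if min(np.sum(y == c) for c in np.unique(y)) < 3:
        raise ValueError("need at least 3 samples per class")
    dropped = tuple(c for c in X.columns if np.ptp(X[c].to_numpy()) == 0.0)
    Xv = X.drop(columns=list(dropped))
    cols = list(Xv.columns)
    M = Xv.to_numpy(dtype=float)
    Z = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # component signs are arbitrary; orient each toward the positive class
    # (fallback: largest-|loading| entry positive when uncorrelated)
    yc = y - y.mean()
    scores_raw = Z @ eigvecs
    for j in range(eigvecs.shape[1]):
        c = float(scores_raw[:, j] @ yc)
        if c < 0 or (c == 0 and eigvecs[np.argmax(np.abs(eigvecs[:, j])), j] < 0):
            eigvecs[:, j] *= -1.0
    var_frac = eigvals / eigvals.sum()
    cumvar = np.cumsum(var_frac)
    n_retained = int(np.searchsorted(cumvar, cumulative_variance_target - 1e-12) + 1)
    scores = Z @ eigvecs
    comp_names = [f"PC{j + 1}" for j in range(len(cols))]
    result = PCAResult(
        loadings=pd.DataFrame(eigvecs, index=cols, columns=comp_names),
        scores=scores,
        variance_fraction=var_frac,
        cumulative_variance=cumvar,
        n_retained=n_retained,
        dropped_constant=dropped,
    )
    rocs = {comp_names[j]: roc_auc(y, scores[:, j]) for j in range(n_retained)}
    out = {"pca": result, "roc": rocs}
    if logistic:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression().fit(scores[:, :n_retained], y)
        prob = clf.predict_proba(scores[:, :n_retained])[:, 1]
        out["logistic_auc"] = float(roc_auc_score(y, prob))
    return out


def correlate(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson correlation reported as R^2 with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "r2": float(r * r), "p": float(p)}


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement of paired methods: d = a - b.

    Bias is mean(d); limits of agreement are bias +/- 1.96 * SD(d) with the
    sample (n-1) standard deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd, sd=sd)
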