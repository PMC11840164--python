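"""Group-level statistics for ALPS cohorts.

Implements the analysis battery applied to the subject table: a
Shapiro-Wilk normality gate routing continuous outcomes to ANCOVA (normal)
or Quade's rank analysis of covariance (non-normal), chi-square tests for
categorical tables, partial correlation with covariate adjustment, ROC/AUC
for group discrimination, and Benjamini-Hochberg multiple-comparison
correction.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparisonResult:
    method: str                      # "ancova" | "quade"
    statistic: float                 # F for the group factor
    p_value: float
    adjusted_means: dict = field(default_factory=dict)
    covariates: tuple = ()
    shapiro_p: float | None = None


@dataclass
class PartialCorrResult:
    r: float
    p_value: float
    df: int
    n: int
    covariates: tuple = ()
    flag: str | None = None


@dataclass
class ROCResult:
    auc: float
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray


# --------------------------------------------------------------------------
# normality gate
# --------------------------------------------------------------------------

def shapiro_gate(values, alpha: float = 0.05) -> tuple[bool, float, str | None]:
    """Shapiro-Wilk normality gate.

    Returns (normal, p_value, flag): normal is True iff the Shapiro-Wilk p
    is >= alpha; a constant vector is non-normal by convention and flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need a 1D vector with n >= 3")
    if np.ptp(v) == 0:
        return False, float("nan"), "constant vector"
    _, p = stats.shapiro(v)
    return bool(p >= alpha), float(p), None


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

def _as_design(covariates, n) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise ValueError("covariate rows do not match outcome length")
    return c


def _binary_groups(group) -> tuple[np.ndarray, list]:
    group = np.asarray(group)
    levels = sorted(set(group.tolist()))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {levels}")
    ind = (group == levels[1]).astype(float)
    if min(ind.sum(), (1 - ind).sum()) < 2:
        raise ValueError("each group needs at least 2 observations")
    return ind, levels


def ancova_group_compare(y, group, covariates=None) -> GroupComparisonResult:
    """ANCOVA for a two-level group factor controlling for covariates.

    Fits y ~ 1 + group + covariates by OLS and tests the group term
    (for a single two-level factor the Type-III F equals the squared t of
    its coefficient).  Adjusted group means are evaluated at the covariate
    means.  Rank-deficient covariates raise, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    ind, levels = _binary_groups(group)
    c = _as_design(covariates, n)
    x = np.column_stack([np.ones(n), ind, c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        for j in range(2, x.shape[1]):
            if np.linalg.matrix_rank(x[:, :j + 1]) < j + 1:
                bad.append(j - 2)
        raise ValueError(f"rank-deficient covariate matrix (columns {bad})")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - x.shape[1]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta[1] / se
    f_stat = float(t ** 2)
    p = float(2 * stats.t.sf(abs(t), dof))
    cbar = c.mean(axis=0) if c.size else np.empty(0)
    base = float(beta[0] + (cbar @ beta[2:] if c.size else 0.0))
    adjusted = {str(levels[0]): base, str(levels[1]): base + float(beta[1])}
    return GroupComparisonResult(method="ancova", statistic=f_stat, p_value=p,
                                 adjusted_means=adjusted,
                                 covariates=tuple(range(c.shape[1])))


def quade_rank_ancova(y, group, covariates=None) -> GroupComparisonResult:
    """Quade's rank analysis of covariance.

    Rank-transforms the outcome and each covariate (midranks for ties),
    regresses the outcome ranks on the covariate ranks with intercept, and
    runs a one-way ANOVA on the residuals across groups.  Invariant to
    strictly monotone transformations of y.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if np.ptp(y) == 0:
        raise ValueError("all outcome values tied; Quade test undefined")
    group = np.asarray(group)
    levels = sorted(set(group.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    c = _as_design(covariates, n)
    ry = stats.rankdata(y)
    rc = np.column_stack([stats.rankdata(c[:, j]) for j in range(c.shape[1])]) \
        if c.shape[1] else np.empty((n, 0))
    x = np.column_stack([np.ones(n), rc])
    beta, *_ = np.linalg.lstsq(x, ry, rcond=None)
    resid = ry - x @ beta
    samples = [resid[group == lv] for lv in levels]
    f_stat, p = stats.f_oneway(*samples)
    return GroupComparisonResult(method="quade", statistic=float(f_stat),
                                 p_value=float(p),
                                 covariates=tuple(range(c.shape[1])))


def gated_group_compare(y, group, covariates=None,
                        alpha: float = 0.05) -> GroupComparisonResult:
    """Route to ANCOVA or Quade by the Shapiro-Wilk gate on the outcome."""
    normal, p_sw, _ = shapiro_gate(y, alpha)
    res = (ancova_group_compare if normal else quade_rank_ancova)(y, group, covariates)
    res.shapiro_p = p_sw
    return res


def chi2_independence(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square of independence on a contingency table.

    Continuity (Yates) correction is off by default; a zero row or column
    marginal raises.  Returns (statistic, p_value).
    """
    t = np.asarray(table)
    if np.any(t < 0) or not np.allclose(t, np.rint(t)):
        raise ValueError("table must hold nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return float(chi2), float(p)


# --------------------------------------------------------------------------
# partial correlation
# --------------------------------------------------------------------------

def partial_correlation(x, y, covariates=None) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (with intercept) by
    OLS; the Pearson correlation of the residuals is the partial r, with a
    t-test on df = n - 2 - n_covariates.  With no covariates this is exactly
    the Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.shape[0]
    c = _as_design(covariates, n)
    k = c.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    df = n - 2 - k
    # residual variance judged relative to the centered variable's scale
    tol = 1e-10
    sx0 = np.linalg.norm(x - x.mean())
    sy0 = np.linalg.norm(y - y.mean())
    if sx <= tol * max(sx0, 1e-300) or sy <= tol * max(sy0, 1e-300):
        return PartialCorrResult(r=float("nan"), p_value=float("nan"), df=df, n=n,
                                 covariates=tuple(range(k)),
                                 flag="zero variance after residualization")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p_value=p, df=df, n=n, covariates=tuple(range(k)))


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC (Mann-Whitney construction; ties count 1/2).

    ``labels`` are binary with 1 the positive class; both classes must be
    present.  Sensitivity = TPR; specificity = 1 - FPR at each threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(labels.tolist()) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return ROCResult(auc=float(roc_auc_score(labels, scores)),
                     thresholds=thresholds, sensitivities=tpr,
                     specificities=1 - fpr)


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Closed-form AUC for two normal score distributions:
    Phi((mu_pos - mu_neg) / sqrt(sd_pos^2 + sd_neg^2))."""
    return float(stats.norm.cdf((mu_pos - mu_neg) / np.hypot(sd_pos, sd_neg)))


# --------------------------------------------------------------------------
# multiple comparisons
# --------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj
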