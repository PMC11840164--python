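"""Preacher-Hayes simple mediation with covariates and bootstrap CI.

The path model is three OLS regressions, all with intercepts and the same
covariate block Z:

    M = i1 + a X + Z g1 + e1          (path a: X -> M)
    Y = i2 + c' X + b M + Z g2 + e2   (paths b and c': M -> Y | X, X -> Y | M)
    Y = i3 + c X + Z g3 + e3          (path c: total effect)

The indirect effect is a*b; on any sample the OLS estimates satisfy
c = c' + a*b exactly.  The confidence interval for a*b comes from a
case-resampling percentile bootstrap of subjects, the simplest member of
the Preacher-Hayes family.  Proportion mediated is 100 * a*b / c, flagged
when |a*b| > |c| or the signs differ (inconsistent mediation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    n_boot: int
    seed: int | None
    proportion_mediated: float
    covariates: tuple = ()
    flags: tuple = ()


def _design(x, cols) -> np.ndarray:
    return np.column_stack([np.ones(x.shape[0]), x, *cols])


def _covariate_block(covariates, n) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise ValueError("covariate rows do not match sample size")
    return c


def _path_coefficients(x, m, y, z) -> tuple[float, float, float, float]:
    """(a, b, c, c_prime) by OLS; on an exactly rank-deficient [x, m, Z]
    design (predictor and mediator perfectly collinear, where the direct
    effect is unidentifiable) the shared variance is attributed to the
    mediator: b from y ~ m + Z and c_prime = c - a*b."""
    dm = _design(x[:, None], [z])
    a = float(np.linalg.lstsq(dm, m, rcond=None)[0][1])
    c = float(np.linalg.lstsq(dm, y, rcond=None)[0][1])
    dy = _design(np.column_stack([x, m]), [z])
    coef, _, rank, _ = np.linalg.lstsq(dy, y, rcond=None)
    if rank < dy.shape[1]:
        dmo = _design(m[:, None], [z])
        b = float(np.linalg.lstsq(dmo, y, rcond=None)[0][1])
        return a, b, c, c - a * b
    return a, float(coef[2]), c, float(coef[1])


def fit_paths(x, m, y, covariates=None,
              cond_warn: float = 1e8) -> tuple[float, float, float, float]:
    """OLS path coefficients (a, b, c, c_prime), all models with intercept.

    Warns with the condition number when the [x, m, covariates] design is
    ill-conditioned (near-collinearity between predictor and mediator).
    """
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if not (m.shape[0] == y.shape[0] == n):
        raise ValueError("x, m, y must have equal length")
    z = _covariate_block(covariates, n)
    if n <= z.shape[1] + 3:
        raise ValueError("need n > n_covariates + 3")
    cond = np.linalg.cond(_design(np.column_stack([x, m]), [z]))
    if cond > cond_warn:
        warnings.warn(f"ill-conditioned mediation design (cond={cond:.3g}); "
                      "predictor and mediator may be collinear", stacklevel=2)
    return _path_coefficients(x, m, y, z)


def bootstrap_indirect(x, m, y, covariates=None, n_boot: int = 5000,
                       level: float = 0.95, seed: int | None = None,
                       max_redraw_frac: float = 0.01) -> tuple[float, float, np.ndarray]:
    """Percentile bootstrap CI for the indirect effect a*b.

    Subjects are case-resampled with replacement; a and b are re-estimated
    per resample.  Resamples with zero variance in x are redrawn (counted,
    capped at ``max_redraw_frac`` of draws).  Deterministic under fixed seed.

    Returns (lower, upper, bootstrap_indirect_samples).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    z = _covariate_block(covariates, n)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    redraws, max_redraws = 0, max(1, int(max_redraw_frac * n_boot))
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, n)
        if np.ptp(x[idx]) == 0:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples "
                                   "(zero variance in predictor)")
            continue
        a, b, _, _ = _path_coefficients(x[idx], m[idx], y[idx], z[idx])
        boots[i] = a * b
        i += 1
    lo = (1 - level) / 2
    lower, upper = np.quantile(boots, [lo, 1 - lo])
    return float(lower), float(upper), boots


def proportion_mediated(indirect: float, c: float) -> tuple[float, str | None]:
    """100 * indirect / c, flagged when mediation is inconsistent.

    Raises on c == 0 (proportion undefined).
    """
    if c == 0:
        raise ValueError("total effect c is zero; proportion mediated undefined")
    flag = None
    if indirect != 0 and (np.sign(indirect) != np.sign(c) or abs(indirect) > abs(c)):
        flag = "inconsistent mediation (proportion unstable)"
    return 100.0 * indirect / c, flag


def mediate(x, m, y, covariates=None, n_boot: int = 5000, level: float = 0.95,
            seed: int | None = None) -> MediationResult:
    """Full simple-mediation analysis: paths, bootstrap CI, proportion mediated."""
    a, b, c, c_prime = fit_paths(x, m, y, covariates)
    indirect = a * b
    lower, upper, _ = bootstrap_indirect(x, m, y, covariates, n_boot, level, seed)
    flags = []
    if c == 0:
        prop = float("nan")
        flags.append("total effect zero; proportion mediated undefined")
    else:
        prop, flag = proportion_mediated(indirect, c)
        if flag:
            flags.append(flag)
    k = 0 if covariates is None else _covariate_block(covariates, len(np.ravel(x))).shape[1]
    return MediationResult(a=a, b=b, c=c, c_prime=c_prime, indirect=indirect,
                           ci_lower=lower, ci_upper=upper, ci_level=level,
                           n_boot=n_boot, seed=seed, proportion_mediated=prop,
                           covariates=tuple(range(k)), flags=tuple(flags))
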