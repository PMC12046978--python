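"""Inferential machinery.

Univariate tests with Cohen's d effect sizes, penalized (ridge) regression
with effective-degrees-of-freedom inference, Benjamini-Hochberg multiplicity
control, and a voxelwise group linear model with cluster extent filtering.

Ridge inference conventions
---------------------------
Predictors are standardized (zero mean, unit sample SD) and the outcome is
centered, so the intercept is handled implicitly and excluded from the
penalty.  With hat matrix ``H = X (X'X + lam I)^-1 X'`` the residual degrees
of freedom are ``edf = n - tr(2H - HH')``; t statistics for the scaled
coefficients are referred to a Student t distribution with ``edf`` degrees of
freedom (which need not be an integer), and per-coefficient effect sizes are
reported as partial R^2 = t^2 / (t^2 + edf).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RidgeFit",
    "VoxelwiseResult",
    "two_sided_p_from_t",
    "one_sample_test",
    "cohens_d_one_sample",
    "d_confidence_interval",
    "welch_two_sample_test",
    "pearson_test",
    "standardize",
    "ridge_fit",
    "effective_df",
    "auto_lambda",
    "partial_r2",
    "bh_fdr",
    "voxelwise_group_glm",
]


# ---------------------------------------------------------------------------
# univariate tests


@dataclass
class TestResult:
    t: float
    df: float
    p: float
    d: float
    ci: tuple[float, float]
    n: int


def two_sided_p_from_t(t: float, df: float) -> float:
    """Two-sided p-value of ``t`` under Student's t with (possibly real) ``df``."""
    if df <= 0:
        raise ValueError(f"df must be > 0, got {df}")
    return float(2.0 * sps.t.sf(abs(t), df))


def cohens_d_one_sample(t: float, n: int) -> float:
    """One-sample Cohen's d from the t statistic: d = t / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(t) / np.sqrt(n)


def d_confidence_interval(d: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for a one-sample d: d +/- z * sqrt(1/n + d^2/(2n))."""
    if n < 2:
        raise ValueError("n must be >= 2")
    z = sps.norm.ppf((1 + level) / 2)
    se = np.sqrt(1.0 / n + d * d / (2.0 * n))
    return (float(d - z * se), float(d + z * se))


def one_sample_test(values, mu: float = 0.0) -> TestResult:
    """One-sample t test of mean(values) == mu, with d = t/sqrt(n)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero sample variance: t statistic undefined")
    t = (x.mean() - mu) / (sd / np.sqrt(n))
    d = cohens_d_one_sample(t, n)
    return TestResult(
        t=float(t),
        df=float(n - 1),
        p=two_sided_p_from_t(t, n - 1),
        d=d,
        ci=d_confidence_interval(d, n),
        n=n,
    )


def welch_two_sample_test(a, b, equal_var: bool = False) -> TestResult:
    """Two-sample t test (Welch by default; pooled with ``equal_var=True``).

    Cohen's d uses the pooled SD regardless of the df mode.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two observations")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("zero variance in both samples")
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = (b.mean() - a.mean()) / se
    pooled_sd = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = (b.mean() - a.mean()) / pooled_sd if pooled_sd > 0 else 0.0
    nh = n1 + n2
    z = sps.norm.ppf(0.975)
    se_d = np.sqrt(1 / n1 + 1 / n2 + d * d / (2 * nh))
    return TestResult(
        t=float(t),
        df=float(df),
        p=two_sided_p_from_t(t, df),
        d=float(d),
        ci=(float(d - z * se_d), float(d + z * se_d)),
        n=nh,
    )


def pearson_test(x, y) -> tuple[float, float, float, float]:
    """Pearson correlation with t-based inference: returns (r, t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return (r, float(np.sign(r) * np.inf), float(df), 0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    return (r, float(t), float(df), two_sided_p_from_t(t, df))


# ---------------------------------------------------------------------------
# ridge regression with effective degrees of freedom


@dataclass
class RidgeFit:
    lam: float
    names: list
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    partial_r2: np.ndarray
    edf: float
    tr_h: float
    tr_hh: float
    r2: float
    sse: float
    n: int
    fitted: np.ndarray
    residuals: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table mirroring (estimate, SE, t, df, p, partial R^2)."""
        return pd.DataFrame(
            {
                "predictor": self.names,
                "estimate_scaled": self.coef,
                "se_scaled": self.se,
                "t": self.t,
                "df": np.full(len(self.names), self.edf),
                "p": self.p,
                "partial_r2": self.partial_r2,
            }
        )


def standardize(X) -> np.ndarray:
    """Column-standardize to zero mean and unit sample SD (ddof=1)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(np.nonzero(sd == 0)[0])
        raise ValueError(f"constant column(s) at index {bad}: cannot standardize")
    return (X - mu) / sd


def _check_standardized(X: np.ndarray) -> None:
    mu = np.abs(X.mean(axis=0)).max()
    sd = np.abs(X.std(axis=0, ddof=1) - 1.0).max()
    if mu > 1e-6 or sd > 1e-6:
        raise ValueError(
            "X must be column-standardized (zero mean, unit sample SD); "
            f"max |mean| = {mu:.3g}, max |sd-1| = {sd:.3g}"
        )


def partial_r2(t: float, df: float) -> float:
    """Share of residual variance for one predictor: t^2 / (t^2 + df)."""
    if np.any(np.asarray(df) <= 0):
        raise ValueError("df must be > 0")
    t = np.asarray(t, dtype=float)
    out = t * t / (t * t + df)
    return float(out) if out.ndim == 0 else out


def effective_df(X, lam: float) -> float:
    """Residual degrees of freedom n - tr(2H - HH') of the ridge hat matrix."""
    X = np.asarray(X, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n = X.shape[0]
    A = X.T @ X + lam * np.eye(X.shape[1])
    H = X @ np.linalg.solve(A, X.T)
    tr_h = np.trace(H)
    tr_hh = float(np.sum(H * H))  # H symmetric: tr(HH') = sum of squares
    return float(n - (2.0 * tr_h - tr_hh))


def ridge_fit(
    X,
    y,
    lam: float | None = None,
    names: list | None = None,
    check_standardized: bool = True,
) -> RidgeFit:
    """Ridge regression with t inference at effective degrees of freedom.

    ``X`` must be column-standardized and ``y`` centered (the intercept is
    absorbed by centering and is not penalized).  With ``lam=None`` the
    penalty is chosen by deterministic GCV minimization (:func:`auto_lambda`).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on n")
    if n < 2:
        raise ValueError("need n > 1")
    if check_standardized:
        _check_standardized(X)
        if abs(y.mean()) > 1e-6 * max(1.0, np.abs(y).max()):
            raise ValueError("y must be centered")
    if lam is None:
        lam = auto_lambda(X, y)
    if lam < 0:
        raise ValueError("lambda must be >= 0")

    A = X.T @ X + lam * np.eye(p)
    A_inv = np.linalg.inv(A)
    coef = A_inv @ (X.T @ y)
    fitted = X @ coef
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())

    H = X @ A_inv @ X.T
    tr_h = float(np.trace(H))
    tr_hh = float(np.sum(H * H))
    edf = float(n - (2.0 * tr_h - tr_hh))

    sigma2 = sse / edf
    cov = sigma2 * (A_inv @ (X.T @ X) @ A_inv)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    pvals = np.array([two_sided_p_from_t(ti, edf) for ti in t])
    pr2 = t * t / (t * t + edf)
    r2 = 1.0 - sse / sst if sst > 0 else np.nan

    if names is None:
        names = [f"x{j}" for j in range(p)]
    return RidgeFit(
        lam=float(lam),
        names=list(names),
        coef=coef,
        se=se,
        t=t,
        p=pvals,
        partial_r2=pr2,
        edf=edf,
        tr_h=tr_h,
        tr_hh=tr_hh,
        r2=float(r2),
        sse=sse,
        n=n,
        fitted=fitted,
        residuals=resid,
    )


def auto_lambda(X, y, n_grid: int = 121, refine: int = 2) -> float:
    """Deterministic ridge penalty by GCV minimization.

    Minimizes ``GCV(lam) = SSE(lam) / (n - tr H(lam))^2`` over ``{0}`` plus a
    log-spaced grid, then refines locally around the incumbent.  Fully
    deterministic for fixed inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.std() == 0:
        raise ValueError("outcome has zero variance: ridge penalty undefined")

    U, s, _ = np.linalg.svd(X, full_matrices=False)
    uy = U.T @ y
    yty = float(y @ y)
    s2 = s * s

    def gcv(lam: float) -> float:
        shrink = s2 / (s2 + lam) if lam > 0 else np.where(s2 > 0, 1.0, 0.0)
        sse = yty - float(((2 * shrink - shrink**2) * uy * uy).sum())
        tr_h = float(shrink.sum())
        denom = n - tr_h
        if denom <= 0:
            return np.inf
        return max(sse, 0.0) / denom**2

    grid = np.concatenate([[0.0], np.logspace(-6, 6, n_grid)])
    scores = np.array([gcv(l) for l in grid])
    best = int(np.argmin(scores))
    best_lam, best_score = grid[best], scores[best]

    for _ in range(refine):
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        if hi <= lo:
            break
        lo = max(lo, 1e-12)
        grid = np.logspace(np.log10(lo), np.log10(max(hi, lo * 10)), 41)
        scores = np.array([gcv(l) for l in grid])
        best = int(np.argmin(scores))
        if scores[best] < best_score:
            best_lam, best_score = grid[best], scores[best]

    return float(best_lam)


# ---------------------------------------------------------------------------
# multiplicity control and voxelwise mapping


def bh_fdr(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejection mask at FDR ``alpha``.

    Rejects the k smallest p-values where k is the largest rank with
    ``p_(k) <= k * alpha / m``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing[-1] + 1  # largest rank satisfying the step-up bound
        reject[order[:k]] = True
    return reject


@dataclass
class VoxelwiseResult:
    t_map: np.ndarray
    p_map: np.ndarray
    sig_mask: np.ndarray
    clusters: pd.DataFrame
    n_tested: int
    n_excluded_zero_variance: int


def voxelwise_group_glm(
    data: np.ndarray,
    group: np.ndarray,
    analysis_mask: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    extent_k: int = 10,
    connectivity: int = 26,
) -> VoxelwiseResult:
    """Voxelwise linear-model group contrast with BH-FDR and extent filtering.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, *grid)
        Stacked subject maps.
    group : ndarray of 0/1, length n_subjects
        Group indicator; the reported t statistic is for this contrast.
    analysis_mask : boolean ndarray
        Voxels entering the test family.
    covariates : optional (n_subjects, q) array of nuisance regressors.
    connectivity : 6, 18 or 26 neighbourhood for cluster labelling.

    Voxels with zero residual variance are excluded from the family and
    counted in ``n_excluded_zero_variance``.
    """
    data = np.asarray(data, dtype=float)
    group = np.asarray(group, dtype=float).ravel()
    mask = np.asarray(analysis_mask, bool)
    n = data.shape[0]
    if group.size != n:
        raise ValueError("group length must match the number of subjects")
    if not mask.any():
        raise ValueError("analysis mask is empty")
    if len(np.unique(group)) < 2 or min(np.sum(group == g) for g in np.unique(group)) < 2:
        raise ValueError("need at least two subjects per group")

    cols = [np.ones(n), group]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    Xd = np.column_stack(cols)
    p = Xd.shape[1]
    if n <= p:
        raise ValueError("more regressors than subjects")

    Y = data[:, mask]  # (n, V)
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    beta = XtX_inv @ (Xd.T @ Y)
    resid = Y - Xd @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    c_var = XtX_inv[1, 1]

    valid = sigma2 > 0
    n_excluded = int((~valid).sum())
    t_vals = np.full(Y.shape[1], np.nan)
    p_vals = np.full(Y.shape[1], np.nan)
    se = np.sqrt(sigma2[valid] * c_var)
    t_vals[valid] = beta[1, valid] / se
    p_vals[valid] = 2.0 * sps.t.sf(np.abs(t_vals[valid]), dof)

    reject = np.zeros(Y.shape[1], dtype=bool)
    if valid.any():
        reject[valid] = bh_fdr(p_vals[valid], alpha=alpha)

    grid_shape = data.shape[1:]
    t_map = np.zeros(grid_shape)
    p_map = np.ones(grid_shape)
    sig = np.zeros(grid_shape, dtype=bool)
    idx = np.nonzero(mask)
    t_map[idx] = np.nan_to_num(t_vals)
    p_map[idx] = np.where(np.isnan(p_vals), 1.0, p_vals)
    sig[idx] = reject

    structure = _connectivity_structure(connectivity)
    labeled, n_comp = ndimage.label(sig, structure=structure)
    rows = []
    keep = np.zeros_like(sig)
    for lab in range(1, n_comp + 1):
        comp = labeled == lab
        size = int(comp.sum())
        if size < extent_k:
            continue
        keep |= comp
        tc = np.where(comp, t_map, 0.0)
        peak_flat = np.argmax(np.abs(tc))
        peak = np.unravel_index(peak_flat, grid_shape)
        rows.append(
            {
                "cluster": len(rows) + 1,
                "size_voxels": size,
                "peak_abs_t": float(np.abs(tc).max()),
                "peak_t": float(tc[peak]),
                "peak_i": int(peak[0]),
                "peak_j": int(peak[1]),
                "peak_k": int(peak[2]),
            }
        )
    clusters = pd.DataFrame(
        rows,
        columns=["cluster", "size_voxels", "peak_abs_t", "peak_t", "peak_i", "peak_j", "peak_k"],
    )
    return VoxelwiseResult(
        t_map=t_map,
        p_map=p_map,
        sig_mask=keep,
        clusters=clusters,
        n_tested=int(valid.sum()),
        n_excluded_zero_variance=n_excluded,
    )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")
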