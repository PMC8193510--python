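"""Covariate-adjusted group inference on MST metrics.

Group differences are tested by permutation with nuisance covariates (age,
gender, head motion) handled by the Freedman-Lane scheme: the outcome is
regressed on the covariates alone, the residuals are permuted and added back to
the covariate fit, and the group statistic is recomputed on each permuted
outcome. The statistic is the difference of group means of the
covariate-residualized outcome; two-sided p = (1 + #{|null| >= |obs|}) /
(1 + n_perm). Multiple metrics are corrected with Benjamini-Hochberg FDR.

Also provides metric intercorrelations, partial correlations, and age/gender
bipartite cohort matching (minimum total |age difference| within each gender
stratum via the Hungarian algorithm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .errors import TreescapeError

GLOBAL_METRICS = ("L", "Lf", "Th", "Dmax", "r", "kappa")


@dataclass
class GroupTestResult:
    metric: str
    observed_stat: float
    p_raw: float
    n_perm: int
    seed: int
    covariates: tuple = ()
    p_fdr: float = float("nan")
    null_stats: np.ndarray | None = None


def _design(covariates, n) -> np.ndarray:
    """Intercept + covariate columns; raises on rank deficiency."""
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        x = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        x = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise TreescapeError("covariate matrix is rank-deficient")
    return x


def covariate_adjusted_permutation_test(
    y, group, covariates=None, n_perm: int = 5000, seed: int = 0,
    scheme: str = "freedman_lane", metric: str = "", return_null: bool = False,
) -> GroupTestResult:
    """Two-sided permutation test of a group difference in ``y`` with nuisance
    covariates removed.

    ``scheme='freedman_lane'`` permutes reduced-model residuals (default);
    ``scheme='raw'`` permutes the group labels directly on the residualized
    outcome. With no covariates both reduce to the plain two-sample
    permutation test.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise TreescapeError(f"exactly two groups required, got {len(labels)}")
    g = (group == labels[1]).astype(float)
    if min((g == 1).sum(), (g == 0).sum()) < 2:
        raise TreescapeError("need >= 2 subjects per group")
    n = len(y)
    x = _design(covariates, n)

    # residualize y on the nuisance design (reduced model)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    resid = y - fitted
    hat = x @ np.linalg.pinv(x)  # projection onto covariate space
    m1, m0 = g == 1, g == 0

    def stat(res):
        return res[m1].mean() - res[m0].mean()

    observed = stat(resid)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    if scheme == "freedman_lane":
        for b in range(n_perm):
            e = resid[rng.permutation(n)]
            e = e - hat @ e  # re-residualize the permuted outcome
            null[b] = stat(e)
    elif scheme == "raw":
        for b in range(n_perm):
            perm = rng.permutation(n)
            null[b] = resid[perm][m1].mean() - resid[perm][m0].mean()
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    p = float((1 + (np.abs(null) >= abs(observed)).sum()) / (1 + n_perm))
    return GroupTestResult(
        metric=metric, observed_stat=float(observed), p_raw=p,
        n_perm=n_perm, seed=seed,
        covariates=tuple(range(x.shape[1] - 1)),
        null_stats=null if return_null else None,
    )


def fdr_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def test_metric_table(
    mt: pd.DataFrame, group_col: str = "group", metrics=GLOBAL_METRICS,
    covariate_cols=("age", "gender", "motion"), n_perm: int = 5000, seed: int = 0,
) -> pd.DataFrame:
    """Run the covariate-adjusted test for each metric column and BH-correct
    across them as one family."""
    cov = _encode_covariates(mt, covariate_cols) if covariate_cols else None
    results = []
    rng = np.random.default_rng(seed)
    for m in metrics:
        y = mt[m].to_numpy(dtype=float)
        keep = np.isfinite(y)
        sub_cov = cov[keep] if cov is not None else None
        r = covariate_adjusted_permutation_test(
            y[keep], mt[group_col].to_numpy()[keep], sub_cov,
            n_perm=n_perm, seed=int(rng.integers(2**31 - 1)), metric=m)
        results.append(r)
    padj = fdr_bh([r.p_raw for r in results])
    rows = []
    for r, q in zip(results, padj):
        r.p_fdr = float(q)
        rows.append({"metric": r.metric, "observed": r.observed_stat,
                     "p_raw": r.p_raw, "p_fdr": r.p_fdr,
                     "n_perm": r.n_perm, "seed": r.seed})
    return pd.DataFrame(rows)


def _encode_covariates(df: pd.DataFrame, cols) -> np.ndarray:
    out = []
    for c in cols:
        col = df[c]
        if col.dtype == object:
            out.append(pd.get_dummies(col, drop_first=True).to_numpy(dtype=float))
        else:
            out.append(col.to_numpy(dtype=float)[:, None])
    return np.column_stack(out)


def metric_intercorrelation(mt: pd.DataFrame, metrics=GLOBAL_METRICS) -> pd.DataFrame:
    """Pearson correlation matrix over the global metrics; constant columns
    are reported as NaN rows/columns."""
    sub = mt.loc[:, list(metrics)].astype(float)
    corr = sub.corr(method="pearson")
    const = sub.std() == 0
    corr.loc[const, :] = np.nan
    corr.loc[:, const] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def partial_correlation(x, y, controls=None):
    """Partial Pearson correlation of x and y given control variables.

    Both x and y are residualized on the controls (with intercept) and the
    residuals correlated; p is two-sided t-based with df = n - #controls - 2.
    With no controls this is the plain Pearson correlation. A y that is an
    exact linear function of the controls yields r ~ 0 (zero residual signal).
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = 0
    if controls is not None:
        c = np.asarray(controls, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        k = c.shape[1]
        design = np.column_stack([np.ones(n), c])
        x = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        y = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = x.std(), y.std()
    if sx < 1e-12 * max(1.0, np.abs(x).max() + 1) or sy < 1e-12:
        return 0.0, 1.0
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    df = n - k - 2
    if df <= 0 or abs(r) == 1.0:
        return r, 0.0 if abs(r) == 1.0 else float("nan")
    t = r * np.sqrt(df / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def match_cohorts(pheno: pd.DataFrame, group_col: str = "group",
                  age_col: str = "age", gender_col: str = "gender",
                  minority: str | None = None) -> pd.DataFrame:
    """1:1 age/gender bipartite matching.

    Within each gender stratum the minority-group subjects are assigned
    majority-group partners minimizing the total |age difference| (Hungarian
    algorithm). Returns the matched subset of the phenotype table.
    """
    groups = pheno[group_col].unique()
    if len(groups) != 2:
        raise TreescapeError("matching requires exactly two groups")
    sizes = pheno[group_col].value_counts()
    minority = minority or sizes.idxmin()
    majority = [g for g in groups if g != minority][0]
    keep_idx = []
    for gender, stratum in pheno.groupby(gender_col):
        minor = stratum[stratum[group_col] == minority]
        major = stratum[stratum[group_col] == majority]
        if len(minor) == 0:
            continue
        if len(major) < len(minor):
            raise TreescapeError(
                f"stratum {gender!r}: majority group smaller than minority "
                f"({len(major)} < {len(minor)})")
        cost = np.abs(minor[age_col].to_numpy()[:, None]
                      - major[age_col].to_numpy()[None, :])
        ri, ci = linear_sum_assignment(cost)
        keep_idx.extend(minor.index[ri])
        keep_idx.extend(major.index[ci])
    return pheno.loc[sorted(keep_idx)]
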