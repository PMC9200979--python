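"""Trial statistics: validation regressions, trait correlations with
significance stars, correlation-matrix PCA, augmented-RCBD adjustment and
broad-sense heritability.

The field design is an augmented randomized complete block design: a few
replicated check varieties appear in every block and estimate block
effects, which are then subtracted from the unreplicated test entries
(Federer's adjustment).  Broad-sense heritability on the adjusted test
values uses the check-replication error mean square as the environmental
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import DesignError, DomainError

STAR_LEVELS = (0.05, 0.01, 0.001)


@dataclass
class ValidationResult:
    """Estimates-vs-truth regression summary (method validation)."""

    r_squared: float
    slope: float
    intercept: float
    mean_abs_pct_error: float
    max_abs_pct_error: float
    n: int


@dataclass
class CorrelationResult:
    r_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    n_matrix: pd.DataFrame
    stars: pd.DataFrame
    df: pd.DataFrame  # n - 2 per pair


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # variable x PC correlations
    pct_variance: np.ndarray
    cumulative_pct: np.ndarray
    significant: pd.DataFrame  # |loading| > 0.45 per the convention used
    n: int


@dataclass
class HeritabilityResult:
    sigma2_G: float
    sigma2_e: float
    H2: float
    n_tests: int
    floored: bool = False


@dataclass
class AdjustedMeans:
    means: pd.Series  # genotype -> adjusted value
    block_effects: pd.Series
    anova: pd.DataFrame
    error_ms: float
    error_df: int


def validation_regression(truth, estimates) -> ValidationResult:
    """OLS of estimates on ground truth plus percentage-error summaries.

    R^2 is the squared Pearson correlation; errors are per-sample absolute
    percentage deviations from truth.
    """
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if t.shape != e.shape or t.ndim != 1 or len(t) < 3:
        raise DomainError("need two equal-length vectors of >= 3 values")
    if (t <= 0).any():
        raise DomainError("truth values must be positive")
    if np.ptp(t) == 0:
        raise DomainError("constant truth: R^2 undefined")
    res = _sps.linregress(t, e)
    pct = np.abs(e - t) / t * 100.0
    return ValidationResult(r_squared=float(res.rvalue ** 2),
                            slope=float(res.slope),
                            intercept=float(res.intercept),
                            mean_abs_pct_error=float(pct.mean()),
                            max_abs_pct_error=float(pct.max()),
                            n=len(t))


def correlation_matrix(table: pd.DataFrame,
                       bonferroni: bool = False) -> CorrelationResult:
    """Pairwise Pearson correlations with two-sided t-test P values.

    Pairwise deletion of missing values; P from t = r sqrt(df / (1 - r^2))
    with df = n - 2.  Stars at P < 0.05 / 0.01 / 0.001.  Constant columns
    yield NaN entries.  P values are raw by default; ``bonferroni``
    multiplies them by the number of distinct pairs.
    """
    num = table.select_dtypes(include=[np.number])
    cols = list(num.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            pair = num[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rv, pv = _sps.pearsonr(x, y)
            if bonferroni:
                pv = min(1.0, pv * (k * (k - 1) / 2))
            r[i, j] = r[j, i] = rv
            p[i, j] = p[j, i] = pv
    stars = np.full((k, k), "", dtype=object)
    for i in range(k):
        for j in range(k):
            if i != j and np.isfinite(p[i, j]):
                stars[i, j] = "*" * sum(p[i, j] < lvl
                                        for lvl in STAR_LEVELS)
    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)  # noqa: E731
    return CorrelationResult(r_matrix=mk(r), p_matrix=mk(p),
                             n_matrix=mk(n), stars=mk(stars),
                             df=mk(np.maximum(n - 2, 0)))


def pca_traits(table: pd.DataFrame, standardize: bool = True,
               sig_threshold: float = 0.45) -> PcaResult:
    """PCA by eigendecomposition of the trait correlation matrix.

    Loadings are variable-PC correlations (eigenvector * sqrt(eigenvalue)
    for standardized data); each component is oriented so its
    largest-magnitude loading is positive.  Eigenvalues of a
    correlation-matrix PCA sum to the number of variables.
    """
    num = table.select_dtypes(include=[np.number])
    if num.isna().any().any():
        raise DomainError("missing values: impute or drop rows first")
    X = num.to_numpy(dtype=float)
    n, k = X.shape
    if n < 3:
        raise DomainError("need at least 3 observations")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = num.columns[sd == 0].tolist()
            raise DomainError(f"constant columns cannot be standardized: "
                              f"{bad}")
        Xc = Xc / sd
        cov = np.corrcoef(X, rowvar=False)
    else:
        cov = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-magnitude entry of each component positive
    for c in range(k):
        ix = np.argmax(np.abs(evecs[:, c]))
        if evecs[ix, c] < 0:
            evecs[:, c] = -evecs[:, c]
    loadings = evecs * np.sqrt(evals)
    pcs = [f"PC{i + 1}" for i in range(k)]
    load_df = pd.DataFrame(loadings, index=num.columns, columns=pcs)
    pct = 100.0 * evals / evals.sum()
    return PcaResult(eigenvalues=evals, loadings=load_df,
                     pct_variance=pct, cumulative_pct=np.cumsum(pct),
                     significant=load_df.abs() > sig_threshold, n=n)


def _check_design(records: pd.DataFrame, trait: str) -> tuple[pd.DataFrame,
                                                              pd.DataFrame]:
    for col in ("genotype", "block", "is_check", trait):
        if col not in records.columns:
            raise DesignError(f"records missing column {col!r}")
    checks = records[records["is_check"].astype(bool)]
    tests = records[~records["is_check"].astype(bool)]
    blocks = sorted(records["block"].unique())
    for g in sorted(checks["genotype"].unique()):
        present = set(checks.loc[checks["genotype"] == g, "block"])
        missing = [b for b in blocks if b not in present]
        if missing:
            raise DesignError(f"check {g!r} missing from block(s) "
                              f"{missing}")
    counts = tests.groupby("genotype").size()
    dup = counts[counts > 1]
    if len(dup):
        raise DesignError(f"test genotypes replicated: {dup.index.tolist()}")
    return checks, tests


def augmented_rcbd_adjust(records: pd.DataFrame,
                          trait: str) -> AdjustedMeans:
    """Federer's augmented-RCBD adjustment and ANOVA.

    Block effects are estimated from the replicated checks (block mean of
    checks minus the grand check mean); each unreplicated test entry is
    adjusted by subtracting its block's effect.  The ANOVA partitions
    blocks (ignoring treatments), treatments (checks, tests, checks vs
    tests) and the check-replication error.
    """
    checks, tests = _check_design(records, trait)
    y_c = checks.pivot_table(index="genotype", columns="block",
                             values=trait)
    grand_check = float(y_c.to_numpy().mean())
    block_eff = y_c.mean(axis=0) - grand_check
    adj_tests = (tests.set_index("genotype")[trait]
                 - tests.set_index("genotype")["block"].map(block_eff))
    check_means = y_c.mean(axis=1)
    means = pd.concat([check_means, adj_tests]).sort_index()

    # ANOVA (checks provide the error term)
    c, b = y_c.shape
    arr = y_c.to_numpy()
    ss_block_checks = c * ((arr.mean(axis=0) - grand_check) ** 2).sum()
    ss_check = b * ((arr.mean(axis=1) - grand_check) ** 2).sum()
    resid = arr - arr.mean(axis=1, keepdims=True) \
        - arr.mean(axis=0, keepdims=True) + grand_check
    ss_error = float((resid ** 2).sum())
    df_error = (c - 1) * (b - 1)
    ms_error = ss_error / df_error if df_error else np.nan

    adj = adj_tests.to_numpy(dtype=float)
    ss_tests = float(((adj - adj.mean()) ** 2).sum())
    ss_cvt = (len(adj) * c * b / max(len(adj) + c * b, 1)
              * (adj.mean() - grand_check) ** 2)
    rows = [
        ("blocks (from checks)", b - 1, ss_block_checks),
        ("checks", c - 1, ss_check),
        ("tests (adjusted)", max(len(adj) - 1, 0), ss_tests),
        ("checks vs tests", 1, ss_cvt),
        ("error (check replication)", df_error, ss_error),
    ]
    anova = pd.DataFrame(rows, columns=["source", "df", "sum_sq"])
    anova["mean_sq"] = anova["sum_sq"] / anova["df"].replace(0, np.nan)
    anova["F"] = anova["mean_sq"] / ms_error
    anova["p"] = _sps.f.sf(anova["F"], anova["df"], df_error)
    anova.loc[anova["source"] == "error (check replication)",
              ["F", "p"]] = np.nan
    return AdjustedMeans(means=means, block_effects=block_eff,
                         anova=anova, error_ms=float(ms_error),
                         error_df=df_error)


def broad_sense_heritability(records: pd.DataFrame,
                             trait: str) -> HeritabilityResult:
    """Broad-sense heritability H2 = sigma2_G / (sigma2_G + sigma2_e).

    sigma2_e is the check-replication error mean square.  The genotypic
    variance among adjusted test values is corrected for the block-effect
    estimation error (each adjusted value carries an extra sigma2_e / c
    from the block mean of the c checks); negative estimates are floored
    at zero.
    """
    adj = augmented_rcbd_adjust(records, trait)
    checks, tests = _check_design(records, trait)
    n_checks = checks["genotype"].nunique()
    test_vals = adj.means[~adj.means.index.isin(
        checks["genotype"].unique())].to_numpy(dtype=float)
    if len(test_vals) < 2:
        raise DesignError("need at least 2 test genotypes")
    s2e = adj.error_ms
    var_adj = float(np.var(test_vals, ddof=1))
    s2g = var_adj - s2e * (1.0 + 1.0 / n_checks)
    floored = s2g < 0
    s2g = max(s2g, 0.0)
    denom = s2g + s2e
    h2 = s2g / denom if denom > 0 else 0.0
    return HeritabilityResult(sigma2_G=s2g, sigma2_e=s2e,
                              H2=float(np.clip(h2, 0.0, 1.0)),
                              n_tests=len(test_vals), floored=floored)


def normality_check(values) -> dict:
    """Normal quantile-quantile pairs plus the Shapiro-Wilk statistic."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise DomainError("need at least 3 values")
    if np.ptp(v) == 0:
        raise DomainError("constant input: normality undefined")
    (osm, osr), (slope, intercept, r) = _sps.probplot(v, dist="norm")
    w, p = _sps.shapiro(v)
    return {"theoretical_quantiles": osm, "sample_quantiles": osr,
            "fit_slope": float(slope), "fit_intercept": float(intercept),
            "shapiro_w": float(w), "shapiro_p": float(p), "n": len(v)}
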