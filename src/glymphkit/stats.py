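"""Statistical layer: HC-referenced z-scores, group comparisons, partial
correlation with FDR, rater agreement (ICC), and percentile-bootstrap
mediation.

Conventions: binary covariates are coded 0/1 (sex: male = 1); the healthy
control (HC) group is the z-score reference; time-based tests (trail
making) are inverted after standardization so that higher z always means
better performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DOMAIN_TESTS",
    "INVERTED_DOMAINS",
    "zscore_cognition",
    "GroupComparison",
    "group_compare",
    "PartialCorrResult",
    "partial_correlation",
    "fdr_adjust",
    "IccResult",
    "icc_absolute_agreement",
    "MediationResult",
    "mediate",
    "count_percent",
]

#: cognitive domain -> raw test column
DOMAIN_TESTS: dict[str, str] = {
    "memory": "avlt",
    "executive": "tmt_b",
    "processing_speed": "tmt_a",
    "visuospatial": "cdt10",
    "language": "bnt",
}

#: domains scored from completion times (higher raw = worse): z is negated
INVERTED_DOMAINS: frozenset[str] = frozenset({"executive", "processing_speed"})


def count_percent(count: int, total: int, decimals: int = 2) -> float:
    """Percentage summary of a count, as printed in demographic tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


# ---------------------------------------------------------------------------
# z-scoring


def zscore_cognition(
    table: pd.DataFrame,
    reference_group: str = "HC",
    domain_tests: dict[str, str] | None = None,
    inverted: frozenset[str] | set[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Standardize raw cognitive scores against the reference (HC) group.

    z = (score - mean_HC) / sd_HC with the sample SD (ddof=1); inverted
    domains are multiplied by -1 after standardization.  Returns one
    ``z_<domain>`` column per domain, index-aligned with ``table``.

    Raises ``ValueError`` if the reference group is too small or has zero
    SD on any test (naming the test).
    """
    domain_tests = dict(DOMAIN_TESTS if domain_tests is None else domain_tests)
    inverted = frozenset(INVERTED_DOMAINS if inverted is None else inverted)
    ref = table[table[group_col] == reference_group]
    if len(ref) < 2:
        raise ValueError(
            f"reference group {reference_group!r} needs at least 2 subjects"
        )
    out = pd.DataFrame(index=table.index)
    for domain, test in domain_tests.items():
        mu = ref[test].mean()
        sd = ref[test].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero reference-group SD for test {test!r}")
        z = (table[test] - mu) / sd
        if domain in inverted:
            z = -z
        out[f"z_{domain}"] = z
    return out


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparison:
    test: str                       # anova | kruskal | chi2
    statistic: float
    p: float
    pairwise_p: dict[tuple[str, str], float] | None = None
    normal: bool | None = None      # Shapiro verdict (continuous only)
    equal_var: bool | None = None   # Levene verdict (continuous only)


def group_compare(
    values, groups, kind: str = "continuous", alpha: float = 0.05
) -> GroupComparison:
    """Omnibus group comparison with the conventional test-selection branch.

    Continuous: ANOVA if every group passes Shapiro-Wilk and Levene's test
    (on medians) finds homogeneous variances, otherwise Kruskal-Wallis;
    pairwise follow-ups (t-test or Mann-Whitney, matching the branch) are
    Bonferroni-corrected (multiplied by the number of pairs, capped at 1).
    Categorical: Pearson chi-square on the contingency table, without
    continuity correction.
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")

    if kind == "categorical":
        tab = pd.crosstab(groups, values)
        if tab.shape[1] < 2:
            raise ValueError(
                "degenerate contingency table: the variable takes a single value"
            )
        chi2, p, _, _ = sps.chi2_contingency(tab.to_numpy(), correction=False)
        return GroupComparison(test="chi2", statistic=float(chi2), p=float(p))

    if kind != "continuous":
        raise ValueError("kind must be 'continuous' or 'categorical'")

    samples = [values[groups == g].astype(float) for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")
    with np.errstate(invalid="ignore", divide="ignore"):
        if any(np.ptp(s) == 0 for s in samples):
            normal = False  # Shapiro is undefined for constant samples
        else:
            normal = all(sps.shapiro(s).pvalue > alpha for s in samples)
        equal_var = bool(sps.levene(*samples, center="median").pvalue > alpha)
        parametric = normal and equal_var

        if parametric:
            stat, p = sps.f_oneway(*samples)
            test = "anova"
        else:
            stat, p = sps.kruskal(*samples)
            test = "kruskal"
    if not np.isfinite(stat):  # identical constant groups
        stat, p = 0.0, 1.0

    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        sa, sb = values[groups == a].astype(float), values[groups == b].astype(float)
        if np.ptp(np.concatenate([sa, sb])) == 0:
            praw = 1.0
        elif parametric:
            praw = sps.ttest_ind(sa, sb).pvalue
        else:
            praw = sps.mannwhitneyu(sa, sb, alternative="two-sided").pvalue
        pairwise[(a, b)] = min(1.0, float(praw) * len(pairs))
    return GroupComparison(
        test=test,
        statistic=float(stat),
        p=float(p),
        pairwise_p=pairwise,
        normal=normal,
        equal_var=bool(equal_var),
    )


# ---------------------------------------------------------------------------
# partial correlation + FDR


@dataclass
class PartialCorrResult:
    x: str
    y: str
    covariates: tuple[str, ...]
    r: float
    dof: int
    p: float
    q: float | None = None  # filled by fdr_adjust at the family level


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, _, _, _ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x, y, covariates=None, names: tuple[str, str] = ("x", "y")
) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given covariates.

    Implemented by residualizing both variables on [1, covariates] and
    correlating the residuals; p from t = r sqrt(df / (1 - r^2)) with
    df = n - 2 - k, two-sided.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        Z = np.empty((n, 0))
        cov_names: tuple[str, ...] = ()
    else:
        if isinstance(covariates, pd.DataFrame):
            cov_names = tuple(covariates.columns)
            Z = covariates.to_numpy(dtype=float)
        else:
            Z = np.asarray(covariates, dtype=float)
            if Z.ndim == 1:
                Z = Z[:, None]
            cov_names = tuple(f"c{i}" for i in range(Z.shape[1]))
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx == 0 or sy == 0:
        raise ValueError("zero residual variance")
    r = float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return PartialCorrResult(
        x=names[0], y=names[1], covariates=cov_names, r=r, dof=dof, p=p
    )


def fdr_adjust(pvalues, families=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, applied within each family.

    ``families`` is an optional label per p-value (e.g. one family of
    ALPS-vs-PVS tests and one of ALPS-vs-cognition tests); ``None`` treats
    all p-values as one family.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.empty_like(p)
    if families is None:
        fam = np.zeros(len(p))
    else:
        fam = np.asarray(families)
        if len(fam) != len(p):
            raise ValueError("families must match pvalues in length")
    for f in pd.unique(fam):
        idx = fam == f
        q[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int


def icc_absolute_agreement(
    ratings: np.ndarray, confidence: float = 0.95
) -> IccResult:
    """Single-measure absolute-agreement ICC from a two-way (mixed) model,
    ICC(A,1), with the standard F-based confidence interval.

    ``ratings`` is subjects x raters with no missing cells.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters array")
    n, k = r.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if not np.all(np.isfinite(r)):
        raise ValueError("missing or non-finite cells are not allowed")

    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ssb = k * np.sum((row_means - grand) ** 2)        # subjects
    ssc = n * np.sum((col_means - grand) ** 2)        # raters
    sst = np.sum((r - grand) ** 2)
    sse = sst - ssb - ssc
    msr = ssb / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0, n_subjects=n, n_raters=k)
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0:  # perfect agreement: degenerate interval
        return IccResult(icc=float(icc), ci_low=1.0, ci_high=1.0, n_subjects=n, n_raters=k)
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return IccResult(
        icc=float(icc),
        ci_low=float(lower),
        ci_high=float(min(upper, 1.0)),
        n_subjects=n,
        n_raters=k,
    )


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    """Regression-path mediation decomposition with a bootstrap CI.

    ``indirect = a * b`` carries the percentile bootstrap interval; the
    exact OLS identity ``c = c_prime + a*b`` holds whenever both models use
    the same covariates.  ``mediation_percent`` (100 * indirect / c) is
    NaN under inconsistent mediation (indirect and total effects of
    opposite sign), where the ratio is uninterpretable.
    """

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    n: int
    mediation_percent: float
    standardized: dict = field(default_factory=dict)
    n_redrawn: int = 0

    @property
    def significant(self) -> bool:
        """Indirect effect significant iff the bootstrap CI excludes zero."""
        return (self.ci_low > 0) or (self.ci_high < 0)


def _ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS via normal equations (designs here are tiny and well-scaled)."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def _paths(x, m, y, Z) -> tuple[float, float, float, float]:
    n = len(x)
    ones = np.ones(n)
    d_a = np.column_stack([ones, x, Z])
    d_b = np.column_stack([ones, x, m, Z])
    a = _ols_beta(d_a, m)[1]
    cb = _ols_beta(d_b, y)
    c_prime, b = cb[1], cb[2]
    c = _ols_beta(d_a, y)[1]
    return float(a), float(b), float(c), float(c_prime)


def mediate(
    table: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: tuple[str, ...] | list[str] = (),
    n_boot: int = 5000,
    ci: float = 95.0,
    seed: int | None = None,
) -> MediationResult:
    """Simple-mediation analysis (X -> M -> Y) with covariates.

    Fits M ~ X + cov (path a), Y ~ X + M + cov (paths c', b) and
    Y ~ X + cov (total effect c) by OLS on complete cases, and bootstraps
    the indirect effect a*b by resampling subjects with replacement and
    refitting both models per replicate.  Rank-deficient replicates are
    redrawn (counted in ``n_redrawn``).
    """
    cols = [x, m, y, *covariates]
    data = table[cols].dropna()
    n = len(data)
    if n < 10 + len(covariates):
        raise ValueError(f"too few complete cases (n={n}) for mediation")
    xv = data[x].to_numpy(dtype=float)
    mv = data[m].to_numpy(dtype=float)
    yv = data[y].to_numpy(dtype=float)
    Z = data[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((n, 0))

    design_full = np.column_stack([np.ones(n), xv, mv, Z])
    if np.linalg.matrix_rank(design_full) < design_full.shape[1]:
        raise ValueError("collinear exposure/mediator/covariates")

    a, b, c, c_prime = _paths(xv, mv, yv, Z)
    indirect = a * b

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    redrawn = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, n)
        try:
            ab, bb, _, _ = _paths(xv[idx], mv[idx], yv[idx], Z[idx])
        except np.linalg.LinAlgError:
            redrawn += 1
            continue
        boot[i] = ab * bb
        i += 1
    tail = (100.0 - ci) / 2.0
    ci_low, ci_high = np.percentile(boot, [tail, 100.0 - tail])

    if c != 0 and np.sign(indirect) == np.sign(c):
        med_pct = 100.0 * indirect / c
    else:
        med_pct = float("nan")

    def _std(v):
        return (v - v.mean()) / v.std(ddof=1)

    sa, sb, sc, scp = _paths(_std(xv), _std(mv), _std(yv), Z)
    return MediationResult(
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=indirect,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=seed,
        n=n,
        mediation_percent=med_pct,
        standardized={"a": sa, "b": sb, "c": sc, "c_prime": scp, "indirect": sa * sb},
        n_redrawn=redrawn,
    )
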