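"""Cohort-level statistics linking the EFR marker, hearing sensitivity and
speech reception thresholds.

Implements the study's statistical battery: a normality-gated correlation
(Pearson when both variables pass Shapiro-Wilk, Spearman otherwise),
Bonferroni family-wise adjustment, the partially overlapping samples t-test
for mixed paired/independent designs, residualisation of SRTs on hearing
thresholds, multiple regression with collinearity and autocorrelation
diagnostics, commonality decomposition of explained variance, and a
continuous two-segment (piecewise linear) growth fit for EFR level series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

__all__ = [
    "CorrelationReport",
    "RegressionReport",
    "CommonalityDecomposition",
    "correlation_auto",
    "bonferroni",
    "pos_ttest",
    "residualize",
    "fit_linear_models",
    "commonality",
    "db_to_microvolt",
    "fit_piecewise_growth",
    "group_summary",
]


@dataclass
class CorrelationReport:
    method: str  # "pearson" or "spearman"
    estimate: float
    p: float
    n: int
    normality_p: tuple

    def __str__(self) -> str:
        sym = "r" if self.method == "pearson" else "rho"
        return f"{sym}({self.n}) = {self.estimate:.2f}, p = {self.p:.3g}"


def correlation_auto(x, y, alpha: float = 0.05) -> CorrelationReport:
    """Normality-gated correlation.

    Pearson's r when both variables pass a Shapiro-Wilk normality test at
    ``alpha``, Spearman's rho otherwise. NaN pairs are dropped pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    px = stats.shapiro(x).pvalue
    py = stats.shapiro(y).pvalue
    if px > alpha and py > alpha:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationReport(method, float(r), float(p), len(x), (px, py))


def bonferroni(p, m: int):
    """Bonferroni family-wise adjustment: ``min(1, p * m)``."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def pos_ttest(paired_pre, paired_post, pre_only=(), post_only=(),
              variance_mode: str = "equal") -> tuple[float, float, float]:
    """Partially overlapping samples t-test (Derrick-style).

    Compares sample 1 (paired pre + pre-only) against sample 2 (paired post
    + post-only), exploiting the correlation ``r`` of the paired subset.

    ``variance_mode='equal'`` uses the pooled-variance statistic with
    df ``(n12-1) + (na+nb+n12-1)/(na+nb+2 n12) * (na+nb)``;
    ``'unequal'`` uses the Welch-type statistic (which reduces exactly to
    the paired t statistic when no independent observations are present).

    Returns ``(t, df, p)`` with a two-sided p-value.
    """
    pre = np.asarray(paired_pre, dtype=float)
    post = np.asarray(paired_post, dtype=float)
    a = np.asarray(pre_only, dtype=float)
    b = np.asarray(post_only, dtype=float)
    if len(pre) != len(post):
        raise ValueError("paired samples must have equal length")
    n12, na, nb = len(pre), len(a), len(b)
    x1 = np.r_[pre, a]
    x2 = np.r_[post, b]
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per side")
    if n12 >= 2 and (np.ptp(pre) > 0 and np.ptp(post) > 0):
        r = float(stats.pearsonr(pre, post)[0])
    else:
        r = 0.0
    s1, s2 = x1.std(ddof=1), x2.std(ddof=1)
    diff = x1.mean() - x2.mean()
    if variance_mode == "equal":
        sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
        denom = sp * np.sqrt(1 / n1 + 1 / n2 - 2 * r * n12 / (n1 * n2))
        df = (n12 - 1) + ((na + nb + n12 - 1) / (na + nb + 2 * n12)) * (na + nb)
    elif variance_mode == "unequal":
        denom = np.sqrt(s1**2 / n1 + s2**2 / n2
                        - 2 * r * s1 * s2 * n12 / (n1 * n2))
        if na + nb == 0:
            df = n12 - 1  # pure paired design
        else:
            v1, v2 = s1**2 / n1, s2**2 / n2
            gamma = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
            df = ((n12 - 1)
                  + ((na + nb + n12 - 1) / (na + nb + 2 * n12))
                  * (gamma - n12 + 1))
    else:
        raise ValueError("variance_mode must be 'equal' or 'unequal'")
    t = diff / denom
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def residualize(y, x) -> np.ndarray:
    """Residuals of the OLS regression ``y ~ 1 + x``.

    The residuals have zero mean and are exactly orthogonal to ``x``; used
    to factor hearing-threshold effects out of speech reception thresholds.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("regressor is constant; residualisation degenerate")
    X = sm.add_constant(x)
    return np.asarray(sm.OLS(y, X).fit().resid)


@dataclass
class RegressionReport:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_df: tuple
    f_pvalue: float
    vif: dict
    durbin_watson: float
    residual_normality_p: float
    model: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [f"Adj. R^2 = {self.adj_r_squared:.3f}, "
                 f"F({self.f_df[0]:.0f}, {self.f_df[1]:.0f}) = "
                 f"{self.f_statistic:.2f}, p = {self.f_pvalue:.3g}"]
        for name in self.params.index:
            lines.append(f"  {name}: beta = {self.params[name]:.4g} "
                         f"(SE {self.bse[name]:.3g}, p = "
                         f"{self.pvalues[name]:.3g})")
        lines.append(f"  VIF: " + ", ".join(f"{k}={v:.2f}"
                                            for k, v in self.vif.items()))
        lines.append(f"  Durbin-Watson = {self.durbin_watson:.2f}, "
                     f"residual Shapiro-Wilk p = "
                     f"{self.residual_normality_p:.3g}")
        return "\n".join(lines)


def fit_linear_models(y, predictors: pd.DataFrame,
                      include_interaction: bool = False) -> RegressionReport:
    """OLS fit of ``y`` on the given predictors with diagnostics.

    Optionally adds the pairwise product interaction of the (exactly two)
    predictors. Reports adjusted R^2, the model F test, per-coefficient
    statistics, variance inflation factors, the Durbin-Watson statistic and
    a Shapiro-Wilk test of residual normality.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(predictors).astype(float).copy()
    if include_interaction:
        if X.shape[1] != 2:
            raise ValueError("interaction requires exactly two predictors")
        c1, c2 = X.columns
        X[f"{c1}:{c2}"] = X[c1] * X[c2]
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.values) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, Xc).fit()
    vif = {col: float(variance_inflation_factor(Xc.values, i))
           for i, col in enumerate(Xc.columns) if col != "const"}
    return RegressionReport(
        params=fit.params, bse=fit.bse, pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_df=(float(fit.df_model), float(fit.df_resid)),
        f_pvalue=float(fit.f_pvalue),
        vif=vif,
        durbin_watson=float(durbin_watson(fit.resid)),
        residual_normality_p=float(stats.shapiro(fit.resid).pvalue),
        model=fit,
    )


@dataclass
class CommonalityDecomposition:
    """Unique and common (shared) components of a regression's R^2.

    ``components`` maps predictor subsets (tuples of names) to their
    commonality coefficient; singleton subsets are unique contributions.
    All components sum to the full-model R^2.
    """

    components: dict
    total_r_squared: float

    @property
    def unique(self) -> dict:
        return {k[0]: v for k, v in self.components.items() if len(k) == 1}

    @property
    def common(self) -> dict:
        return {k: v for k, v in self.components.items() if len(k) > 1}

    def percentages(self) -> dict:
        if self.total_r_squared == 0:
            return {k: np.nan for k in self.components}
        return {k: 100 * v / self.total_r_squared
                for k, v in self.components.items()}


def _subset_r2(y: np.ndarray, X: pd.DataFrame, cols: tuple) -> float:
    if len(cols) == 0:
        return 0.0
    Xc = sm.add_constant(X[list(cols)])
    return float(sm.OLS(y, Xc).fit().rsquared)


def commonality(y, predictors: pd.DataFrame) -> CommonalityDecomposition:
    """All-subsets commonality decomposition of explained variance.

    For each nonempty predictor subset S, the commonality coefficient is
    ``C(S) = -sum_{T subseteq S} (-1)^{|T|} R^2(T u (P - S))`` adjusted so
    singleton coefficients are the familiar unique contributions
    (``U_i = R^2_full - R^2_without_i``) and all coefficients sum to the
    full-model R^2. Supports up to three predictors.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    names = tuple(X.columns)
    p = len(names)
    if p < 2 or p > 3:
        raise ValueError("commonality supports 2 or 3 predictors")
    for c in names:
        if np.ptp(X[c].values) == 0:
            raise ValueError(f"predictor {c!r} is constant")
    r2 = {subset: _subset_r2(y, X, subset)
          for k in range(p + 1) for subset in combinations(names, k)}
    full = r2[names]
    comp: dict = {}
    for k in range(1, p + 1):
        for S in combinations(names, k):
            rest = tuple(n for n in names if n not in S)
            val = 0.0
            for j in range(len(S) + 1):
                for T in combinations(S, j):
                    val -= (-1) ** j * r2[tuple(sorted(
                        set(T) | set(rest), key=names.index))]
            comp[S] = val
    total = sum(comp.values())
    assert abs(total - full) < 1e-8, "commonality components must sum to R^2"
    return CommonalityDecomposition(components=comp, total_r_squared=full)


def db_to_microvolt(db_value):
    """dB re 1 uV to linear uV: ``10 ** (dB / 20)``."""
    return np.power(10.0, np.asarray(db_value, dtype=float) / 20.0)


def fit_piecewise_growth(levels, amplitudes, knee: float | None = None
                         ) -> tuple[float, float, float]:
    """Continuous two-segment linear fit of a level-growth series.

    ``y = a + b_lo * min(x - knee, 0) + b_hi * max(x - knee, 0)``; with
    ``knee=None`` every interior level on the grid is scanned and the knee
    with the smallest residual sum of squares is kept. Returns
    ``(slope_below, slope_above, knee)`` in amplitude units per dB.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]

    def fit_at(k):
        below = np.minimum(x - k, 0.0)
        above = np.maximum(x - k, 0.0)
        X = np.column_stack([np.ones_like(x), below, above])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((X @ beta - y) ** 2))
        return beta, rss

    if knee is not None:
        candidates = [float(knee)]
    else:
        candidates = [float(k) for k in np.unique(x)[1:-1]]
        if not candidates:
            raise ValueError("need interior levels to scan for a free knee")
    best = None
    for k in candidates:
        if np.sum(x < k) < 2 or np.sum(x > k) < 2:
            if knee is not None:
                raise ValueError("need >= 2 points on each side of the knee")
            continue
        beta, rss = fit_at(k)
        if best is None or rss < best[2]:
            best = (beta, k, rss)
    if best is None:
        raise ValueError("no admissible knee with >= 2 points per side")
    beta, k, _ = best
    return float(beta[1]), float(beta[2]), float(k)


def group_summary(cohort: pd.DataFrame, variables=None,
                  group_col: str = "group", equal_var: bool = True
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean/SD table and Bonferroni-adjusted pairwise t-tests.

    Student's independent-samples t-tests (equal variance by default) are
    run for every group pair and variable; the Bonferroni family is the
    total number of tests performed.
    """
    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in (group_col, "id")
                     and np.issubdtype(cohort[c].dtype, np.number)]
    groups = list(dict.fromkeys(cohort[group_col]))
    if len(groups) < 2 or any((cohort[group_col] == g).sum() < 2
                              for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    desc = cohort.groupby(group_col)[variables].agg(["mean", "std"])
    rows = []
    for var in variables:
        for g1, g2 in combinations(groups, 2):
            a = cohort.loc[cohort[group_col] == g1, var].dropna()
            b = cohort.loc[cohort[group_col] == g2, var].dropna()
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            rows.append({"variable": var, "group_1": g1, "group_2": g2,
                         "t": float(t), "p": float(p)})
    tests = pd.DataFrame(rows)
    tests["p_adj"] = bonferroni(tests["p"].values, len(tests))
    return desc, tests
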