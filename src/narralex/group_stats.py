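"""Between-group inference over per-narrative linguistic features.

Implements the statistical battery used to compare narrative groups:
variance-gated two-sample t-tests (Student's pooled test unless Levene's
test flags heteroscedasticity, then Welch's), Cohen's d effect sizes,
Benjamini-Hochberg false-discovery-rate adjustment within declared variable
families, covariance adjustment for narrative length, partial correlation
controlling word count, and Krippendorff's alpha for inter-rater agreement
on the human narrative codings (with a seeded percentile bootstrap over
items for the confidence interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .corpus_io import RaterCodingTable

__all__ = [
    "ComparisonResult", "ReliabilityResult", "AdjustedComparisonResult",
    "PartialCorrelationResult", "DegenerateDataError",
    "levene_test", "two_sample_t", "cohens_d", "bh_adjust",
    "ancova_group_effect", "partial_correlation", "krippendorff_alpha",
    "run_comparison_battery", "comparison_frame", "DEFAULT_FAMILIES",
    "DEFAULT_LEVENE_GATE",
]

DEFAULT_LEVENE_GATE = 0.05

#: default variable families for FDR adjustment: one family per table block
DEFAULT_FAMILIES: dict[str, tuple[str, ...]] = {
    "summary_basic": (
        "authentic", "clout", "analytic",
        "pos_tone", "neg_tone", "social", "total_pronouns",
    ),
    "pronouns": ("pron_I", "pron_we", "pron_you", "pron_she_he", "pron_they"),
}


class DegenerateDataError(ValueError):
    """Inputs with no usable variation for the requested statistic."""


@dataclass(frozen=True)
class ComparisonResult:
    """One between-group test on one variable."""

    variable: str
    group1: str
    group2: str
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    levene_W: float
    levene_p: float
    test_kind: str  # "student" | "welch"
    t: float
    df: float
    p_raw: float
    p_adj: Optional[float] = None
    cohen_d: Optional[float] = None
    family: Optional[str] = None


@dataclass(frozen=True)
class ReliabilityResult:
    """Krippendorff's alpha with a bootstrap percentile CI."""

    alpha: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_items: int
    n_raters: int
    bootstrap_reps: int
    seed: Optional[int]


@dataclass(frozen=True)
class AdjustedComparisonResult:
    """Group effect on an outcome with one covariate partialled out."""

    variable: str
    covariate: str
    group_effect_estimate: float
    group_effect_stat: float
    group_effect_p: float
    covariate_estimate: float
    covariate_stat: float
    covariate_p: float


@dataclass(frozen=True)
class PartialCorrelationResult:
    """Pearson correlation of x and y after regressing out a control."""

    x: str
    y: str
    control: str
    r_partial: float
    p: float
    n: int


def _as_array(x: Sequence[float], name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name}: expected 1-D sample")
    if arr.size < min_n:
        raise ValueError(f"{name}: need at least {min_n} observations, got {arr.size}")
    if np.isnan(arr).any():
        raise ValueError(f"{name}: NaN values not allowed")
    return arr


def levene_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Classic Levene test (absolute deviations from group means).

    Returns (W, p).  Errors if every value in both groups is identical,
    where spread is undefined rather than equal.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if np.ptp(xa) == 0 and np.ptp(ya) == 0:
        raise DegenerateDataError("levene_test: all values identical in both groups")
    with np.errstate(invalid="ignore"):  # 0/0 when both spreads are exactly 0
        W, p = st.levene(xa, ya, center="mean")
    if math.isnan(W):  # both groups have exactly zero spread around their means
        W, p = 0.0, 1.0
    return float(W), float(p)


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardized mean difference (mean1 - mean2) / pooled SD (n-1 weights)."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    n1, n2 = xa.size, ya.size
    pooled_var = (
        (n1 - 1) * xa.var(ddof=1) + (n2 - 1) * ya.var(ddof=1)
    ) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise DegenerateDataError("cohens_d: pooled SD is zero")
    return float((xa.mean() - ya.mean()) / math.sqrt(pooled_var))


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    gate: float = DEFAULT_LEVENE_GATE,
    variable: str = "",
    group1: str = "group1",
    group2: str = "group2",
) -> ComparisonResult:
    """Levene-gated two-sample t-test.

    If Levene's p < *gate* the variances are treated as unequal and Welch's
    test (Satterthwaite df, possibly fractional) is used; otherwise Student's
    pooled test with df = n1 + n2 - 2.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.var(ddof=1) == 0 and ya.var(ddof=1) == 0:
        if xa.mean() == ya.mean():
            raise DegenerateDataError(
                "two_sample_t: zero variance in both groups with equal means"
            )
        levene_W, levene_p = 0.0, 1.0
    else:
        levene_W, levene_p = levene_test(xa, ya)
    equal_var = levene_p >= gate
    res = st.ttest_ind(xa, ya, equal_var=equal_var)
    return ComparisonResult(
        variable=variable,
        group1=group1,
        group2=group2,
        n1=int(xa.size),
        n2=int(ya.size),
        mean1=float(xa.mean()),
        sd1=float(xa.std(ddof=1)),
        mean2=float(ya.mean()),
        sd2=float(ya.std(ddof=1)),
        levene_W=levene_W,
        levene_p=levene_p,
        test_kind="student" if equal_var else "welch",
        t=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
    )


def bh_adjust(p_values: Sequence[float], family: str = "") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, take p_(i) * m / i, then enforce monotonicity from the
    largest rank downward and cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust: expected a 1-D collection")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError(f"bh_adjust[{family}]: p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    return adj


def ancova_group_effect(
    y: Sequence[float],
    groups: Sequence,
    covariate: Sequence[float],
    variable: str = "",
    covariate_name: str = "covariate",
) -> AdjustedComparisonResult:
    """Linear model y ~ group + covariate; reports both effects.

    With a single covariate and two groups the coefficient t-test equals the
    Type-III F-test of the group factor.
    """
    ya = _as_array(y, "y", min_n=4)
    cov = _as_array(covariate, "covariate", min_n=4)
    g = pd.Series(list(groups))
    if len(g) != ya.size or cov.size != ya.size:
        raise ValueError("ancova_group_effect: length mismatch")
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"ancova_group_effect: need exactly 2 groups, got {levels}")
    if np.ptp(cov) == 0:
        raise DegenerateDataError("ancova_group_effect: constant covariate")
    indicator = (g == levels[1]).astype(float).to_numpy()
    X = sm.add_constant(np.column_stack([indicator, cov]))
    fit = sm.OLS(ya, X).fit()
    return AdjustedComparisonResult(
        variable=variable,
        covariate=covariate_name,
        group_effect_estimate=float(fit.params[1]),
        group_effect_stat=float(fit.tvalues[1]),
        group_effect_p=float(fit.pvalues[1]),
        covariate_estimate=float(fit.params[2]),
        covariate_stat=float(fit.tvalues[2]),
        covariate_p=float(fit.pvalues[2]),
    )


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    control: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
    control_name: str = "control",
) -> PartialCorrelationResult:
    """Pearson correlation of the residuals of x and y on the control.

    p-value from the t transform r * sqrt((n-3) / (1-r^2)) on n-3 df.
    """
    xa = _as_array(x, "x", min_n=4)
    ya = _as_array(y, "y", min_n=4)
    ca = _as_array(control, "control", min_n=4)
    n = xa.size
    if ya.size != n or ca.size != n:
        raise ValueError("partial_correlation: length mismatch")
    Z = sm.add_constant(ca)
    rx = xa - Z @ np.linalg.lstsq(Z, xa, rcond=None)[0]
    ry = ya - Z @ np.linalg.lstsq(Z, ya, rcond=None)[0]
    sx, sy = np.sqrt((rx ** 2).sum()), np.sqrt((ry ** 2).sum())
    # residuals that vanish relative to the raw scale mean x or y is an
    # (affine) function of the control: the partial correlation is undefined
    tol = 1e-10
    if sx <= tol * np.linalg.norm(xa - xa.mean()) + 1e-300 or sx == 0:
        raise DegenerateDataError("partial_correlation: zero residual variance in x")
    if sy <= tol * np.linalg.norm(ya - ya.mean()) + 1e-300 or sy == 0:
        raise DegenerateDataError("partial_correlation: zero residual variance in y")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * math.sqrt(df / (1.0 - r * r))
        p = float(2 * st.t.sf(abs(tstat), df))
    return PartialCorrelationResult(
        x=x_name, y=y_name, control=control_name, r_partial=r, p=p, n=n
    )


def _alpha_nominal(codes: np.ndarray) -> float:
    """Krippendorff's alpha (nominal) from an item x rater code matrix."""
    # coincidence matrix over all ordered pairs of pairable values per item
    values = codes[~np.isnan(codes)]
    cats = np.unique(values)
    k = cats.size
    if k == 0:
        raise DegenerateDataError("krippendorff_alpha: no codes")
    cat_index = {c: i for i, c in enumerate(cats)}
    coincidence = np.zeros((k, k))
    for row in codes:
        vals = row[~np.isnan(row)]
        m_u = vals.size
        if m_u < 2:
            continue
        idx = np.array([cat_index[v] for v in vals])
        counts = np.bincount(idx, minlength=k).astype(float)
        pair = np.outer(counts, counts) - np.diag(counts)
        coincidence += pair / (m_u - 1)
    n_total = coincidence.sum()
    if n_total == 0:
        raise DegenerateDataError(
            "krippendorff_alpha: fewer than 2 items with pairable codes"
        )
    if k == 1:
        return 1.0  # a single category observed: perfect agreement by definition
    n_c = coincidence.sum(axis=1)
    d_o = n_total - np.trace(coincidence)
    d_e = (n_total ** 2 - (n_c ** 2).sum()) / (n_total - 1)
    if d_e == 0:
        return 1.0
    return float(1.0 - d_o / d_e)


def krippendorff_alpha(
    codes: RaterCodingTable,
    level: str = "nominal",
    bootstrap_reps: int = 1000,
    seed: Optional[int] = None,
) -> ReliabilityResult:
    """Krippendorff's alpha for nominal codes, with a bootstrap-over-items CI.

    alpha = 1 - Do/De from the coincidence matrix of all pairable values
    within items.  The 95% CI resamples item rows with replacement
    (percentile interval); reps=0 skips the CI.
    """
    if level != "nominal":
        raise NotImplementedError("only nominal-level alpha is implemented")
    matrix = codes.codes
    alpha = _alpha_nominal(matrix)
    ci_low = ci_high = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        n_items = matrix.shape[0]
        stats = []
        for _ in range(bootstrap_reps):
            sample = matrix[rng.integers(0, n_items, n_items)]
            try:
                stats.append(_alpha_nominal(sample))
            except DegenerateDataError:
                continue
        if stats:
            ci_low, ci_high = np.percentile(stats, [2.5, 97.5])
            ci_low = float(min(ci_low, alpha))
            ci_high = float(max(ci_high, alpha))
    return ReliabilityResult(
        alpha=alpha,
        ci_low=ci_low,
        ci_high=ci_high,
        n_items=matrix.shape[0],
        n_raters=matrix.shape[1],
        bootstrap_reps=bootstrap_reps,
        seed=seed,
    )


def run_comparison_battery(
    features: pd.DataFrame,
    grouping: Mapping[str, Sequence[bool]] | tuple[str, str, Sequence],
    families: Optional[Mapping[str, Sequence[str]]] = None,
    gate: float = DEFAULT_LEVENE_GATE,
) -> list[ComparisonResult]:
    """Test every variable in every family between two groups, with BH within family.

    *grouping* is a triple (label1, label2, labels) where *labels* assigns one
    of the two group labels to each row of *features*.  Each family's p-values
    are BH-adjusted separately.
    """
    label1, label2, labels = grouping
    labels = pd.Series(list(labels))
    if len(labels) != len(features):
        raise ValueError("grouping labels must match the feature rows")
    mask1 = (labels == label1).to_numpy()
    mask2 = (labels == label2).to_numpy()
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise DegenerateDataError(
            f"run_comparison_battery: fewer than 2 narratives in a group "
            f"({label1}: {mask1.sum()}, {label2}: {mask2.sum()})"
        )
    fams = families or DEFAULT_FAMILIES
    results: list[ComparisonResult] = []
    for fam_name, variables in fams.items():
        fam_results = []
        for var in variables:
            if var not in features.columns:
                raise KeyError(f"variable {var!r} not in features table")
            x = features.loc[mask1, var].to_numpy(dtype=float)
            y = features.loc[mask2, var].to_numpy(dtype=float)
            try:
                res = two_sample_t(x, y, gate=gate, variable=var,
                                   group1=label1, group2=label2)
            except DegenerateDataError:
                # constant variable, equal in both groups (e.g. a pronoun
                # class no narrative uses): indistinguishable, p = 1
                res = ComparisonResult(
                    variable=var, group1=label1, group2=label2,
                    n1=int(mask1.sum()), n2=int(mask2.sum()),
                    mean1=float(x.mean()), sd1=0.0,
                    mean2=float(y.mean()), sd2=0.0,
                    levene_W=0.0, levene_p=1.0, test_kind="student",
                    t=0.0, df=float(x.size + y.size - 2), p_raw=1.0,
                )
            try:
                d = cohens_d(x, y)
            except DegenerateDataError:
                d = None
            fam_results.append((res, d))
        adj = bh_adjust([r.p_raw for r, _ in fam_results], family=fam_name)
        for (res, d), p_adj in zip(fam_results, adj):
            results.append(
                ComparisonResult(
                    **{**res.__dict__, "p_adj": float(p_adj), "cohen_d": d,
                       "family": fam_name}
                )
            )
    return results


#: fixed column order of the exported comparison table
COMPARISON_COLUMNS = [
    "family", "variable", "group1", "group2", "n1", "n2",
    "mean1", "sd1", "mean2", "sd2", "levene_W", "levene_p",
    "test_kind", "t", "df", "p_raw", "p_adj", "cohen_d",
]


def comparison_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Comparison results as a DataFrame in the documented column order."""
    df = pd.DataFrame([r.__dict__ for r in results])
    return df[COMPARISON_COLUMNS] if len(df) else pd.DataFrame(
        columns=COMPARISON_COLUMNS)
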