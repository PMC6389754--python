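"""Grand-average group statistics on the global alpha-power shift.

ANCOVA models (Type III sums of squares, sum-to-zero factor coding),
planned pooled-t contrasts, assumption checks, effect sizes with
bootstrap confidence intervals, and the standard cohort-table tests
(chi-square, Fisher exact, Mann-Whitney, Kruskal-Wallis).

Post hoc contrasts are plain pooled two-sample t-tests on the log2
shift (df = n_a + n_b - 2), not covariate-adjusted contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignMatrix", "LinearFit", "AnovaResult", "ContrastResult",
    "effects_code", "fit_linear_model", "ancova_oneway", "ancova_factorial",
    "pooled_t", "hedges_g", "levene_test", "slope_homogeneity",
    "normality_check", "chi_square_independence", "fisher_exact",
    "mann_whitney_u", "kruskal_wallis", "shift_seizure_correlation",
]


@dataclass
class AnovaResult:
    effect_name: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_squared: float


@dataclass
class ContrastResult:
    t: float
    df: float
    p: float
    g: float | None = None
    g_ci: tuple[float, float] | None = None
    group_means: tuple[tuple[float, float], tuple[float, float]] | None = None


@dataclass
class LinearFit:
    coef: np.ndarray
    residuals: np.ndarray
    df_resid: int
    rss: float
    columns: tuple[str, ...]


DesignMatrix = pd.DataFrame  # named regressors, one row per subject


def effects_code(values, name: str) -> pd.DataFrame:
    """Sum-to-zero (effects) coding of a factor; levels sorted, last = -1."""
    levels = sorted(pd.unique(np.asarray(values)))
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has a single level")
    arr = np.asarray(values)
    cols = {}
    for lev in levels[:-1]:
        col = np.where(arr == lev, 1.0, 0.0)
        col[arr == levels[-1]] = -1.0
        cols[f"{name}[{lev}]"] = col
    return pd.DataFrame(cols)


def fit_linear_model(y, X: DesignMatrix) -> LinearFit:
    """Ordinary least squares; errors name collinear columns on rank loss."""
    y = np.asarray(y, dtype=float)
    Xm = np.asarray(X, dtype=float)
    names = tuple(X.columns) if hasattr(X, "columns") else tuple(
        f"x{i}" for i in range(Xm.shape[1]))
    if Xm.shape[0] != len(y):
        raise ValueError("row count of X must match length of y")
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # name columns involved in the dependency via pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(Xm, mode="economic", pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {bad}")
    coef, _, _, _ = np.linalg.lstsq(Xm, y, rcond=None)
    resid = y - Xm @ coef
    return LinearFit(coef=coef, residuals=resid,
                     df_resid=len(y) - Xm.shape[1],
                     rss=float(resid @ resid), columns=names)


def _block_f(y, X: DesignMatrix, block: list[str]) -> tuple[float, int, int,
                                                            float, float]:
    """Type III F for a named column block: full vs block-dropped model."""
    full = fit_linear_model(y, X)
    reduced = fit_linear_model(y, X.drop(columns=block))
    q = len(block)
    ss_effect = max(reduced.rss - full.rss, 0.0)
    scale = max(float(np.sum((y - np.mean(y)) ** 2)), 1e-30)
    if full.rss <= 1e-12 * scale:
        # (near-)perfect full fit: 0/0 if the block adds nothing, else inf
        F = 0.0 if ss_effect <= 1e-12 * scale else float("inf")
    else:
        F = (ss_effect / q) / (full.rss / full.df_resid)
    p = float(stats.f.sf(F, q, full.df_resid))
    return float(F), q, full.df_resid, p, float(ss_effect)


def _anova_effect(y, X, block, name) -> AnovaResult:
    y = np.asarray(y, dtype=float)
    F, q, dfd, p, ss = _block_f(y, X, block)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    return AnovaResult(effect_name=name, F=F, df_num=q, df_den=dfd, p=p,
                       eta_squared=ss / ss_total)


def _check_levels(factor, min_count: int = 2) -> None:
    vals, counts = np.unique(np.asarray(factor), return_counts=True)
    if np.any(counts < min_count):
        bad = vals[counts < min_count]
        raise ValueError(f"factor level(s) {list(bad)} have < {min_count} "
                         "subjects")


def ancova_oneway(shift, group, age, gender) -> AnovaResult:
    """One-way ANCOVA for group on log2 shift, age and gender as covariates.

    Type III F with effects coding; df_den = N - 5 for three groups.
    eta^2 = SS_group / SS_total.
    """
    _check_levels(group)
    gender_num = _binary_code(gender, "gender")
    X = pd.DataFrame({"intercept": np.ones(len(shift))})
    X = pd.concat([X, effects_code(group, "group")], axis=1)
    X["age"] = np.asarray(age, dtype=float)
    X["gender"] = gender_num
    block = [c for c in X.columns if c.startswith("group[")]
    return _anova_effect(shift, X, block, "group")


def ancova_factorial(shift, syndrome, control, age, gender,
                     aed_load) -> list[AnovaResult]:
    """2x2 factorial ANCOVA: syndrome, seizure control, their interaction.

    Covariates: age, gender, AED load.  Returns Type III results for
    the two main effects and the interaction from a single full model,
    so all three share one error df (N - 7).
    """
    s = effects_code(syndrome, "syndrome")
    c = effects_code(control, "control")
    if s.shape[1] != 1 or c.shape[1] != 1:
        raise ValueError("factorial ANCOVA expects two 2-level factors")
    cells = pd.crosstab(np.asarray(syndrome), np.asarray(control))
    if cells.shape != (2, 2) or (cells.values == 0).any():
        raise ValueError("all four syndrome x control cells must be non-empty")
    X = pd.DataFrame({"intercept": np.ones(len(shift))})
    X = pd.concat([X, s, c], axis=1)
    X["syndrome:control"] = s.iloc[:, 0] * c.iloc[:, 0]
    X["age"] = np.asarray(age, dtype=float)
    X["gender"] = _binary_code(gender, "gender")
    X["aed_load"] = np.asarray(aed_load, dtype=float)
    return [
        _anova_effect(shift, X, [s.columns[0]], "syndrome"),
        _anova_effect(shift, X, [c.columns[0]], "control"),
        _anova_effect(shift, X, ["syndrome:control"], "syndrome:control"),
    ]


def _binary_code(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "fiu":
        return arr.astype(float)
    levels = sorted(pd.unique(arr))
    if len(levels) != 2:
        raise ValueError(f"{name} must be binary, got levels {levels}")
    return np.where(arr == levels[0], 1.0, -1.0)


def _as_stats(x) -> tuple[float, float, int, np.ndarray | None]:
    """(mean, sd, n, raw-or-None) from a sample or a summary triple."""
    if isinstance(x, tuple) and len(x) == 3 and np.isscalar(x[0]):
        m, s, n = x
        if n < 2 or s < 0:
            raise ValueError("summary statistics require n >= 2 and sd >= 0")
        return float(m), float(s), int(n), None
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("samples must contain >= 2 observations")
    return float(arr.mean()), float(arr.std(ddof=1)), arr.size, arr


def hedges_g_from_stats(m1: float, s1: float, n1: int,
                        m2: float, s2: float, n2: int) -> float:
    """Small-sample-corrected standardized mean difference.

    g = (m1 - m2) / s_pooled * J with J = 1 - 3 / (4 (n1 + n2) - 9).
    """
    sp = np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))
    if sp == 0:
        raise ValueError("zero pooled standard deviation")
    J = 1 - 3 / (4 * (n1 + n2) - 9)
    return float((m1 - m2) / sp * J)


def hedges_g(a, b, n_boot: int = 5000, seed: int = 0
             ) -> tuple[float, tuple[float, float]]:
    """Hedge's g for two raw samples with a percentile-bootstrap 95% CI.

    Bootstrap resamples subjects within each group, n_boot resamples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 observations")
    g = hedges_g_from_stats(a.mean(), a.std(ddof=1), a.size,
                            b.mean(), b.std(ddof=1), b.size)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = a[rng.integers(0, a.size, a.size)]
        rb = b[rng.integers(0, b.size, b.size)]
        sa, sb = ra.std(ddof=1), rb.std(ddof=1)
        if sa == 0 and sb == 0:
            boots[i] = 0.0
            continue
        boots[i] = hedges_g_from_stats(ra.mean(), sa, ra.size,
                                       rb.mean(), sb, rb.size)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return g, (float(lo), float(hi))


def pooled_t(a, b, n_boot: int = 0, seed: int = 0) -> ContrastResult:
    """Classical pooled-variance two-sample t-test (df = n_a + n_b - 2).

    Accepts raw samples or (mean, sd, n) summaries; results are
    identical for a sample and its summary statistics.  Hedge's g is
    attached; a bootstrap CI is computed when raw samples are given and
    n_boot > 0.
    """
    m1, s1, n1, raw_a = _as_stats(a)
    m2, s2, n2, raw_b = _as_stats(b)
    if s1 == 0 and s2 == 0 and m1 != m2:
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                      equal_var=True)
    g = hedges_g_from_stats(m1, s1, n1, m2, s2, n2) \
        if (s1 > 0 or s2 > 0) else 0.0
    ci = None
    if n_boot > 0 and raw_a is not None and raw_b is not None:
        g, ci = hedges_g(raw_a, raw_b, n_boot=n_boot, seed=seed)
    return ContrastResult(t=float(t), df=float(n1 + n2 - 2), p=float(p),
                          g=g, g_ci=ci,
                          group_means=((m1, s1), (m2, s2)))


def levene_test(shift, group) -> tuple[float, float]:
    """Levene's test on absolute deviations from group means."""
    _check_levels(group)
    samples = [np.asarray(shift)[np.asarray(group) == g]
               for g in pd.unique(np.asarray(group))]
    if any(np.ptp(s) == 0 for s in samples):
        raise ValueError("degenerate (constant) group in Levene test")
    W, p = stats.levene(*samples, center="mean")
    return float(W), float(p)


def slope_homogeneity(shift, group, covariate) -> tuple[float, float]:
    """F-test of the group x covariate interaction block.

    Tests the ANCOVA parallel-slopes assumption: the full model adds
    interaction terms between the effects-coded group and the centred
    covariate to the main-effects model.
    """
    _check_levels(group)
    cov = np.asarray(covariate, dtype=float)
    cov = cov - cov.mean()
    codes = effects_code(group, "group")
    X = pd.DataFrame({"intercept": np.ones(len(cov))})
    X = pd.concat([X, codes], axis=1)
    X["cov"] = cov
    inter = []
    for c in codes.columns:
        X[f"{c}:cov"] = codes[c] * cov
        inter.append(f"{c}:cov")
    F, _, _, p, _ = _block_f(np.asarray(shift, dtype=float), X, inter)
    return F, p


def normality_check(residuals) -> tuple[float, float]:
    """Shapiro-Wilk test of model residuals."""
    W, p = stats.shapiro(np.asarray(residuals, dtype=float))
    return float(W), float(p)


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or table.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def mann_whitney_u(a, b) -> tuple[float, float]:
    a, b = np.asarray(a), np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(samples) -> tuple[float, float]:
    samples = [np.asarray(s) for s in samples]
    if any(s.size == 0 for s in samples):
        raise ValueError("empty sample")
    H, p = stats.kruskal(*samples)
    return float(H), float(p)


def shift_seizure_correlation(shift, seizure_count, n_perm: int = 10000,
                              seed: int = 0) -> tuple[float, float]:
    """Spearman rank correlation with a seeded permutation p-value.

    Two-sided p over ``n_perm`` shuffles of the seizure counts; the
    observed labelling counts as one permutation.
    """
    x = np.asarray(shift, dtype=float)
    y = np.asarray(seizure_count, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    # Spearman rho = Pearson on ranks; precompute standardized ranks
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    n = len(x)
    count = 1
    for _ in range(n_perm):
        r = float(zx @ rng.permutation(zy)) / n
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / (n_perm + 1)
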