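"""Group inference layer: t/permutation tests, chi-square with residual
follow-ups, (partial) correlation and two-way factorial ANOVA.

Every stochastic procedure takes an explicit seed.  Bonferroni correction
factors are always passed by the caller as the number of simultaneous
tests in the family; nothing here guesses a family size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "GroupComparison",
    "compare_groups",
    "chi2_residual_test",
    "correlate",
    "two_way_anova",
]


@dataclass
class GroupComparison:
    """Two-sample comparison: pooled t, permutation p and Cohen's d."""

    t: float
    df: int
    p_parametric: float
    p_permutation: float
    cohens_d: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    n_perm: int
    seed: int


def compare_groups(
    a: np.ndarray, b: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> GroupComparison:
    """Pooled-variance two-sample t-test with a permutation confirmation.

    The permutation p is two-sided with the add-one rule
    p = (#{|t_perm| >= |t_obs|} + 1) / (n_perm + 1), shuffling group
    labels.  Cohen's d uses the pooled standard deviation; its sign matches
    the mean difference a - b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two values")
    pooled_var = (
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled_var == 0.0:
        raise ValueError("zero pooled variance; t statistic undefined")
    t_obs, p_par = stats.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        pa, pb = pooled[:na], pooled[na:]
        pv = ((na - 1) * pa.var(ddof=1) + (nb - 1) * pb.var(ddof=1)) / (na + nb - 2)
        if pv == 0.0:
            tp = 0.0
        else:
            tp = (pa.mean() - pb.mean()) / np.sqrt(pv * (1 / na + 1 / nb))
        if abs(tp) >= abs(t_obs):
            count += 1
    p_perm = (count + 1) / (n_perm + 1)

    return GroupComparison(
        t=float(t_obs),
        df=na + nb - 2,
        p_parametric=float(p_par),
        p_permutation=float(p_perm),
        cohens_d=float(d),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=na,
        n_b=nb,
        n_perm=n_perm,
        seed=seed,
    )


def chi2_residual_test(
    table: np.ndarray, alpha: float = 0.05, bonferroni_factor: int | None = None
) -> dict:
    """Pearson chi-square test with post hoc adjusted standardized residuals.

    ``table`` is an r x c contingency table of counts.  The adjusted
    standardized residual of cell (i, j) is
    (O - E) / sqrt(E * (1 - row_share_i) * (1 - col_share_j)), approximately
    standard normal under independence.  Cells are flagged at the
    Bonferroni-corrected two-sided level ``alpha / bonferroni_factor``
    (factor defaults to the number of cells).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("need a 2-D contingency table")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(row, col) / total
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    adj = (table - expected) / np.sqrt(
        expected * np.outer(1 - row / total, 1 - col / total)
    )
    k = bonferroni_factor if bonferroni_factor is not None else table.size
    z_crit = stats.norm.isf(alpha / k / 2)
    return {
        "chi2": chi2,
        "df": df,
        "p": p,
        "residuals": adj,
        "significant": np.abs(adj) > z_crit,
        "alpha": alpha,
        "bonferroni_factor": k,
    }


def correlate(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, int, float]:
    """Pearson or partial correlation with its t-based p value.

    Without covariates: plain Pearson r, df = n - 2.  With covariates
    (n x k array), x and y are residualized on the covariates (with an
    intercept) and the partial correlation is the Pearson r of the
    residuals, df = n - 2 - k.  Returns (r, df, two-sided p).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("constant input to correlation")
    k = 0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
        k = cov.shape[1]
        design = np.column_stack([np.ones(n), cov])
        x = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        y = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            raise ValueError("residual series constant after partialling")
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"not enough observations: df={df}")
    r = float(np.corrcoef(x, y)[0, 1])
    r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_c * np.sqrt(df / (1 - r_c**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, df, p


def two_way_anova(
    values: np.ndarray, factor_a: np.ndarray, factor_b: np.ndarray
) -> dict:
    """Fixed-effects two-way factorial ANOVA with interaction.

    Type II sums of squares (identical to Type I on balanced designs,
    which is the intended use: FC type x group).  Returns F and p for the
    two main effects and the interaction, keyed 'A', 'B', 'A:B'.
    """
    df = pd.DataFrame({"y": values, "a": factor_a, "b": factor_b})
    counts = df.groupby(["a", "b"], observed=True).size()
    n_a = df["a"].nunique()
    n_b = df["b"].nunique()
    if n_a < 2 or n_b < 2:
        raise ValueError("each factor needs at least two levels")
    if len(counts) < n_a * n_b or (counts < 2).any():
        raise ValueError("every cell needs at least two observations")
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    return {
        "A": {"F": float(tab.loc["C(a)", "F"]), "p": float(tab.loc["C(a)", "PR(>F)"]),
              "df": (float(tab.loc["C(a)", "df"]), float(tab.loc["Residual", "df"]))},
        "B": {"F": float(tab.loc["C(b)", "F"]), "p": float(tab.loc["C(b)", "PR(>F)"]),
              "df": (float(tab.loc["C(b)", "df"]), float(tab.loc["Residual", "df"]))},
        "A:B": {
            "F": float(tab.loc["C(a):C(b)", "F"]),
            "p": float(tab.loc["C(a):C(b)", "PR(>F)"]),
            "df": (float(tab.loc["C(a):C(b)", "df"]), float(tab.loc["Residual", "df"])),
        },
    }
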