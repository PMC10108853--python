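"""Cohort statistics: Pearson correlation matrix, strength classes, normality.

Correlation strength follows the conventional bands on |r|: strong for
|r| >= 0.7, moderate for 0.4 <= |r| < 0.7, weak for |r| < 0.4.  Significance
is two-sided at alpha = 0.05 with no multiple-testing correction; a
Holm-adjusted column is emitted alongside, clearly labelled as an extra.
The normality screen is a Kolmogorov-Smirnov test against a normal law with
mean and sd estimated from the sample (the Lilliefors situation), so the
p-value comes from the Lilliefors small-sample approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int
    dof: int
    strength: str


def classify_strength(r: float) -> str:
    """Strength class on |r|: >=0.7 strong, [0.4, 0.7) moderate, <0.4 weak."""
    if not np.isfinite(r) or abs(r) > 1.0:
        raise ValueError("correlation coefficient must lie in [-1, 1]")
    a = abs(r)
    if a >= 0.7:
        return "strong"
    if a >= 0.4:
        return "moderate"
    return "weak"


def pearson_matrix(
    table: pd.DataFrame, pairs: list[tuple[str, str]]
) -> list[CorrelationResult]:
    """Pearson r and two-sided p for each requested variable pair.

    Missing values are dropped pairwise; dof = n - 2.
    """
    results: list[CorrelationResult] = []
    for var_x, var_y in pairs:
        sub = table[[var_x, var_y]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"pair ({var_x}, {var_y}) has fewer than 3 complete rows")
        x = sub[var_x].to_numpy(float)
        y = sub[var_y].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(
                f"pair ({var_x}, {var_y}) has a zero-variance variable; r undefined"
            )
        r, p = sps.pearsonr(x, y)
        results.append(
            CorrelationResult(var_x, var_y, float(r), float(p), n, n - 2,
                              classify_strength(float(r)))
        )
    return results


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabulate correlation results; adds a Holm-adjusted p column (extra)."""
    df = pd.DataFrame(
        [
            {
                "var_x": c.var_x, "var_y": c.var_y, "r": c.r, "p": c.p,
                "n": c.n, "dof": c.dof, "strength": c.strength,
                "significant": c.p < ALPHA,
            }
            for c in results
        ]
    )
    if len(df):
        df["p_holm"] = multipletests(df["p"].to_numpy(), method="holm")[1]
    return df


def normality_screen(values: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov statistic and p against a fitted normal law.

    Mean and sd are estimated from the sample, so the p-value is the
    Lilliefors approximation; it is reported, never used to switch methods
    silently.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("normality screen needs at least 4 observations")
    if np.std(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample standard deviation per numeric column."""
    if len(table) < 2:
        raise ValueError("cohort summary needs at least two participants")
    num = table.select_dtypes(include=[np.number])
    out = []
    for col in num.columns:
        vals = num[col].dropna()
        if vals.empty:
            raise ValueError(f"column {col!r} has no observations")
        out.append({"variable": col, "mean": vals.mean(), "sd": vals.std(ddof=1)})
    return pd.DataFrame(out).set_index("variable")
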