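"""Balanced three-way factorial ANOVA from sums-of-squares first principles.

The survey design crosses season (3) x site (6) x tissue (3) with r
replicate samples per cell; the response is the isolate count of one
replicate.  For a balanced fixed-effects factorial the classical
decomposition by marginal means is exact and Type I/II/III sums of
squares coincide:

    SS_A   = bcr * sum_a (ybar_a.. - ybar)^2
    SS_AB  = cr  * sum_ab (ybar_ab. - ybar_a.. - ybar_.b. + ybar)^2
    SS_ABC = r   * sum_abc (ybar_abc - all lower-order terms)^2
    SS_err = sum (y - ybar_abc)^2

F = MS_effect / MS_error, with the upper-tail F probability computed
through the regularized incomplete beta function.  Unbalanced data are
rejected outright: the decomposition above is only exact for equal cell
sizes, and the survey design is balanced.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "AnovaTable",
    "anova_three_way",
    "f_statistic",
    "p_value",
    "significance_stars",
]


def f_statistic(ms_effect: float, ms_error: float) -> float:
    """Variance ratio F = MS_effect / MS_error."""
    if ms_error <= 0:
        raise ValueError("mean-square error must be positive")
    return ms_effect / ms_error


def p_value(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution.

    Uses the identity P(F' > F) = I_x(df2/2, df1/2) with
    x = df2 / (df2 + df1 * F), where I is the regularized incomplete
    beta function.
    """
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if F < 0:
        raise ValueError("F statistic cannot be negative")
    if np.isinf(F):
        return 0.0
    x = df2 / (df2 + df1 * F)
    return float(special.betainc(df2 / 2, df1 / 2, x))


def significance_stars(p: float) -> str:
    """Display stars mirroring the survey's legend (*** <0.001, ** <0.015)."""
    if p < 0.001:
        return "***"
    if p < 0.015:
        return "**"
    return "ns"


@dataclass
class AnovaTable:
    """Source decomposition (df, SS, MS, F, p) for the three-factor design."""

    frame: pd.DataFrame  # rows: mains, two-ways, three-way, error, total

    def __getitem__(self, source: str) -> pd.Series:
        return self.frame.set_index("source").loc[source]

    @property
    def sources(self) -> list[str]:
        return list(self.frame["source"])

    def display(self) -> pd.DataFrame:
        """Rounded view with a significance column (p truncated at 3 dp)."""
        out = self.frame.copy()
        out["significance"] = [
            significance_stars(p) if np.isfinite(p) else "" for p in out["p"]
        ]
        for col in ("SS", "MS", "F"):
            out[col] = out[col].round(3)
        out["p"] = np.floor(out["p"] * 1000) / 1000
        return out


def _balanced_replicates(df: pd.DataFrame, factors: tuple[str, str, str]) -> int:
    """Replicate count r, or a hard error naming the first deficient cell."""
    sizes = df.groupby(list(factors), observed=True).size()
    levels = [sorted(df[f].unique()) for f in factors]
    expected_cells = list(itertools.product(*levels))
    r = int(sizes.max())
    for cell in expected_cells:
        n = int(sizes.get(cell, 0))
        if n != r:
            key = ", ".join(f"{f}={v}" for f, v in zip(factors, cell))
            raise ValueError(
                f"unbalanced design: cell ({key}) has {n} observations, expected {r}"
            )
    if r == 1:
        raise ValueError("r = 1 leaves no within-cell error term; need >= 2 replicates")
    return r


def anova_three_way(
    data: pd.DataFrame,
    response: str = "response",
    factors: tuple[str, str, str] = ("season", "site", "tissue"),
) -> AnovaTable:
    """Full three-way fixed-effects ANOVA of a balanced factorial.

    ``data`` is a long table with one row per replicate observation,
    carrying the three factor columns and the response column.  Returns
    the complete decomposition including all interactions, the residual
    (error) line and the total line.

    A constant response is a degenerate but legal input: every SS is 0,
    F is reported as 0 and p as 1.
    """
    for col in (*factors, response):
        if col not in data.columns:
            raise ValueError(f"input is missing column {col!r}")
    df = data.loc[:, [*factors, response]].copy()
    y = df[response].astype(float)
    if y.isna().any():
        raise ValueError("response contains missing values")
    r = _balanced_replicates(df, factors)
    N = len(df)
    grand = y.mean()

    # Effect of each factor subset, broadcast to one value per observation:
    # tau_A = m_A - grand; tau_AB = (m_AB - grand) - tau_A - tau_B; and so on
    # by inclusion-exclusion.  Summing tau^2 over observations then carries
    # the correct replication weight (each marginal mean repeats N/levels
    # times), so SS_A = bcr * sum_a (ybar_a - ybar)^2 falls out directly.
    n_levels = {f: df[f].nunique() for f in factors}
    subsets: list[tuple[str, ...]] = []
    for k in (1, 2, 3):
        subsets.extend(itertools.combinations(factors, k))

    tau: dict[tuple[str, ...], np.ndarray] = {}
    ss: dict[tuple[str, ...], float] = {}
    df_eff: dict[tuple[str, ...], int] = {}
    for sub in subsets:
        m = df.groupby(list(sub), observed=True)[response].transform("mean").to_numpy()
        t = m - grand
        for lower in subsets:
            if set(lower) < set(sub):
                t = t - tau[lower]
        tau[sub] = t
        ss[sub] = float(np.sum(t**2))
        df_eff[sub] = int(np.prod([n_levels[f] - 1 for f in sub]))

    cell_mean_col = df.groupby(list(factors), observed=True)[response].transform("mean")
    ss_error = float(np.sum((y - cell_mean_col) ** 2))
    df_error = int(np.prod(list(n_levels.values())) * (r - 1))
    ss_total = float(np.sum((y - grand) ** 2))
    df_total = N - 1

    ms_error = ss_error / df_error
    rows = []
    for sub in subsets:
        label = " x ".join(sub)
        ms = ss[sub] / df_eff[sub]
        if ms_error > 0:
            F = f_statistic(ms, ms_error)
            p = p_value(F, df_eff[sub], df_error)
        else:  # constant response: nothing to test
            F, p = 0.0, 1.0
        rows.append((label, df_eff[sub], ss[sub], ms, F, p))
    rows.append(("error", df_error, ss_error, ms_error, np.nan, np.nan))
    rows.append(("total", df_total, ss_total, np.nan, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["source", "df", "SS", "MS", "F", "p"])
    return AnovaTable(table)
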