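"""Cohort-level descriptive statistics for behavioural measures.

Spending measures in gambling cohorts are heavily right-skewed, so the
descriptives pair parametric summaries (mean, sample SD) with non-parametric
ones (median, inter-quartile range) and a one-sample Kolmogorov–Smirnov
normality statistic per measure.  Relationships between measures are
summarised with Spearman rank-order correlations, and involvement is
contrasted across an empirical split: the top 5% of players by total amount
wagered versus the remaining 95%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .measures import MEASURE_COLUMNS


class ConfigError(ValueError):
    """An option is outside its valid range."""


class DegenerateInputError(ValueError):
    """A statistic is undefined on this input (e.g. constant sample)."""


def ks_normality(sample) -> tuple[float, float]:
    """One-sample K-S statistic against a fitted normal.

    The sample is standardised by its own mean and SD and compared with the
    standard normal CDF: D = sup |ECDF - Phi|, asymptotic p.  Because the
    reference parameters are estimated from the same sample, the p-value is
    biased conservative relative to a Lilliefors-corrected test; the
    statistic's magnitude is the quantity of interest.

    Raises
    ------
    ValueError
        If fewer than 3 observations.
    DegenerateInputError
        If the sample is constant (zero SD).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant sample: normality K-S undefined")
    z = (x - x.mean()) / sd
    res = stats.kstest(z, "norm", method="asymp")
    return float(res.statistic), float(res.pvalue)


#: column order of the per-measure summary block
SUMMARY_COLUMNS = ["mean", "std", "median", "iqr", "ks_norm", "ks_p"]


@dataclass
class CohortSummary:
    """Descriptive statistics for one cohort.

    ``table`` has one row per measure with mean, sample SD (ddof=1), median,
    IQR (75th − 25th percentile, linear interpolation) and the normality K-S
    block; ``n`` is the cohort size.  Degenerate measures (constant, or
    n < 3) carry NaN in the K-S columns.
    """

    table: pd.DataFrame
    n: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="measure")


def describe_measures(
    table: pd.DataFrame, measures: list[str] | None = None
) -> CohortSummary:
    """Summarise each behavioural measure across a cohort of players."""
    if table.empty:
        raise ValueError("cannot describe an empty measures table")
    measures = list(measures) if measures is not None else [
        m for m in MEASURE_COLUMNS if m in table.columns
    ]
    rows = {}
    for m in measures:
        x = table[m].to_numpy(dtype=float)
        q25, q75 = np.percentile(x, [25, 75])  # linear interpolation
        try:
            ks, ks_p = ks_normality(x)
        except (ValueError, DegenerateInputError):
            ks, ks_p = math.nan, math.nan
        rows[m] = {
            "mean": x.mean(),
            "std": x.std(ddof=1) if x.size > 1 else 0.0,
            "median": float(np.median(x)),
            "iqr": float(q75 - q25),
            "ks_norm": ks,
            "ks_p": ks_p,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")[SUMMARY_COLUMNS]
    return CohortSummary(table=out, n=len(table))


@dataclass
class CorrelationMatrix:
    """Spearman rank-order correlations between measures.

    ``rho`` and ``p`` are symmetric M x M frames over ``measures``; the
    diagonal of rho is 1.  Entries involving a constant measure are NaN
    (undefined), never reported as 0.
    """

    measures: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame


def spearman_matrix(
    table: pd.DataFrame, measures: list[str] | None = None
) -> CorrelationMatrix:
    """Spearman correlations between all behavioural measures.

    Ties receive midranks; rho is the Pearson correlation of the ranks and
    p-values use the t-approximation.  Requires at least 3 players.
    """
    measures = list(measures) if measures is not None else [
        m for m in MEASURE_COLUMNS if m in table.columns
    ]
    if len(table) < 3:
        raise ValueError("need at least 3 rows for rank correlations")
    X = table[measures].to_numpy(dtype=float)
    M = len(measures)
    constant = X.std(axis=0) == 0
    rho = np.full((M, M), np.nan)
    p = np.full((M, M), np.nan)
    for i in range(M):
        if constant[i]:
            continue
        rho[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, M):
            if constant[j]:
                continue
            r = stats.spearmanr(X[:, i], X[:, j])
            rho[i, j] = rho[j, i] = r.statistic
            p[i, j] = p[j, i] = r.pvalue
    return CorrelationMatrix(
        measures=measures,
        rho=pd.DataFrame(rho, index=measures, columns=measures),
        p=pd.DataFrame(p, index=measures, columns=measures),
    )


@dataclass
class HeavySplit:
    """The empirical heavy-involvement split of a cohort.

    ``top`` holds the ceil((1-q)·n) most heavily involved players by total
    amount wagered (ties broken by address for determinism), ``rest`` the
    remainder; ``threshold_wagered`` is the smallest total wagered in the
    top cohort.  ``top_summary``/``rest_summary`` are the corresponding
    :class:`CohortSummary` blocks.
    """

    top: pd.DataFrame
    rest: pd.DataFrame
    threshold_wagered: float
    q: float
    top_summary: CohortSummary
    rest_summary: CohortSummary


def heavy_split(table: pd.DataFrame, q: float = 0.95) -> HeavySplit:
    """Split a measures table into heavily involved and remaining players.

    Players are ranked descending by ``total_wagered_eth``; the top
    ceil((1-q)·n) form the heavy cohort.

    Raises
    ------
    ConfigError
        If q is outside (0, 1).
    """
    if not 0.0 < q < 1.0:
        raise ConfigError(f"split quantile must be in (0, 1), got {q}")
    if table.empty:
        raise ValueError("cannot split an empty measures table")
    n = len(table)
    # epsilon guards the ceil against float error, e.g. (1-0.95)*20 -> 1.0000000000000009
    k = math.ceil((1.0 - q) * n - 1e-9)
    ranked = table.sort_values(
        ["total_wagered_eth", "address"], ascending=[False, True]
    ).reset_index(drop=True)
    top = ranked.iloc[:k].reset_index(drop=True)
    rest = ranked.iloc[k:].reset_index(drop=True)
    return HeavySplit(
        top=top,
        rest=rest,
        threshold_wagered=float(top["total_wagered_eth"].min()),
        q=q,
        top_summary=describe_measures(top),
        rest_summary=describe_measures(rest) if len(rest) else CohortSummary(
            table=pd.DataFrame(columns=SUMMARY_COLUMNS), n=0
        ),
    )


def render_summary(summary: CohortSummary, title: str = "Cohort") -> str:
    """Plain-text rendering of a cohort summary for terminal display."""
    header = f"{title} (n = {summary.n:,})"
    body = summary.table.round(3).to_string()
    return f"{header}\n{'-' * len(header)}\n{body}"
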