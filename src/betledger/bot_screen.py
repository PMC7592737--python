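"""Screening application-game groups for non-human (bot) players.

Algorithmic bettors driven by a common script produce near-degenerate
behavioural distributions — hundreds of addresses with essentially identical
bet counts, stakes and schedules — where human populations are heavy-tailed.
A group dominated by such accounts therefore separates from every other group
in distribution.  The screen quantifies this with two-sample
Kolmogorov–Smirnov tests: for each behavioural measure and every pair of
application-game groups, the K-S statistic D (the supremum gap between the
two empirical CDFs) and its asymptotic p-value are collected into a
G x G x M matrix.  A group whose D against almost all other groups is both
large and significant, on any measure, is flagged as likely non-human.

The p-values are deliberately uncorrected — with G(G-1)/2 x M tests their
individual inferential power is limited, and the statistic's magnitude
carries the screening signal — but a multiple-testing correction can be
switched on for the flagging rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .measures import MEASURE_COLUMNS


class ConfigError(ValueError):
    """A threshold or option is outside its valid range."""


def ks2(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum over the pooled sample points of the absolute
    difference between the two empirical CDFs (right-continuous step
    functions).  The p-value is asymptotic, from the Kolmogorov distribution
    evaluated at ``sqrt(n_eff) * D`` with effective size
    ``n_a * n_b / (n_a + n_b)``.

    Raises
    ------
    ValueError
        If either sample is empty.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    a = np.sort(a)
    b = np.sort(b)
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(n_eff) * d))
    return d, min(p, 1.0)


@dataclass
class KSMatrix:
    """Pairwise two-sample K-S results across groups and measures.

    ``D`` and ``p`` are (G, G, M) arrays over ``groups`` x ``groups`` x
    ``measures``; D is symmetric in the group axes with zero diagonal.
    """

    groups: list[str]
    measures: list[str]
    D: np.ndarray
    p: np.ndarray

    def measure_table(self, measure: str) -> pd.DataFrame:
        """The G x G slice of D for one measure, as a labelled square table."""
        m = self.measures.index(measure)
        return pd.DataFrame(self.D[:, :, m], index=self.groups, columns=self.groups)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per (group_a, group_b, measure) pair, a < b."""
        rows = []
        for i, ga in enumerate(self.groups):
            for j, gb in enumerate(self.groups):
                if j <= i:
                    continue
                for k, meas in enumerate(self.measures):
                    rows.append((ga, gb, meas, self.D[i, j, k], self.p[i, j, k]))
        return pd.DataFrame(
            rows, columns=["group_a", "group_b", "measure", "D", "p"]
        )


@dataclass
class FlagReport:
    """Outcome of the non-human screening rule.

    ``evidence`` has one row per (group, measure) with the fraction of other
    groups against which the group's K-S statistic exceeded ``theta`` at
    significance ``alpha``; ``flagged`` lists groups where that fraction
    reached ``phi`` on at least one measure.
    """

    flagged: list[str]
    evidence: pd.DataFrame
    theta: float
    alpha: float
    phi: float
    correction: str | None = None


def pairwise_ks_matrix(
    group_tables: dict[str, pd.DataFrame],
    measures: list[str] | None = None,
) -> KSMatrix:
    """Two-sample K-S tests for every measure between every pair of groups.

    Parameters
    ----------
    group_tables
        Mapping from application-game label to that group's per-player
        measures table.  Group order in the output follows insertion order
        of the mapping.
    measures
        Measure columns to compare; defaults to the eight standard
        behavioural measures.

    Raises
    ------
    ValueError
        With fewer than two groups, or if a named measure is missing from
        any table (schema error naming the measure).
    """
    if len(group_tables) < 2:
        raise ValueError("need at least two groups to compare")
    measures = list(measures) if measures is not None else list(MEASURE_COLUMNS)
    groups = list(group_tables)
    for g, tab in group_tables.items():
        missing = [m for m in measures if m not in tab.columns]
        if missing:
            raise ValueError(
                f"group {g!r} is missing measure column(s): {', '.join(missing)}"
            )
    G, M = len(groups), len(measures)
    D = np.zeros((G, G, M))
    p = np.ones((G, G, M))
    cols = {
        g: {m: tab[m].to_numpy(dtype=float) for m in measures}
        for g, tab in group_tables.items()
    }
    for i in range(G):
        for j in range(i + 1, G):
            for k, m in enumerate(measures):
                d, pv = ks2(cols[groups[i]][m], cols[groups[j]][m])
                D[i, j, k] = D[j, i, k] = d
                p[i, j, k] = p[j, i, k] = pv
    return KSMatrix(groups=groups, measures=measures, D=D, p=p)


def flag_nonhuman(
    m: KSMatrix,
    theta: float = 0.35,
    alpha: float = 0.01,
    phi: float = 0.75,
    correction: str | None = None,
) -> FlagReport:
    """Flag groups whose behaviour separates from almost all others.

    Group *g* is flagged iff for some measure the fraction of other groups
    *h* with ``D[g,h] >= theta`` and ``p[g,h] < alpha`` is at least ``phi``.
    Defaults mirror the conventional reporting thresholds for pairwise K-S
    screens (highlight D > 0.35, significance p < 0.01) with phi = 0.75.

    Parameters
    ----------
    correction
        ``None`` (uncorrected, default), ``"bonferroni"`` or ``"bh"``
        (Benjamini–Hochberg); applied to the p-values only within this
        decision rule, never to the reported matrix.

    Raises
    ------
    ConfigError
        If a threshold is outside [0, 1] or the correction is unknown.
    """
    for name, v in (("theta", theta), ("alpha", alpha), ("phi", phi)):
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name} must be within [0, 1], got {v}")
    pvals = m.p.copy()
    G = len(m.groups)
    n_tests = G * (G - 1) // 2 * len(m.measures)
    if correction == "bonferroni":
        pvals = np.minimum(pvals * n_tests, 1.0)
    elif correction == "bh":
        iu = np.triu_indices(G, k=1)
        flat = m.p[iu].ravel()
        order = np.argsort(flat)
        ranked = flat[order] * n_tests / (np.arange(n_tests) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj_flat = np.empty_like(flat)
        adj_flat[order] = np.minimum(adj, 1.0)
        adj3 = np.ones_like(m.p)
        adj3[iu] = adj_flat.reshape(len(iu[0]), len(m.measures))
        adj3 = np.minimum(adj3, np.swapaxes(adj3, 0, 1))
        pvals = adj3
    elif correction is not None:
        raise ConfigError(f"unknown correction: {correction!r}")

    hits = (m.D >= theta) & (pvals < alpha)
    np.einsum("iik->ik", hits)[...] = False  # self-comparisons never count
    frac = hits.sum(axis=1) / max(G - 1, 1)  # (G, M) fraction of other groups
    evidence = pd.DataFrame(
        {
            "group": np.repeat(m.groups, len(m.measures)),
            "measure": np.tile(m.measures, G),
            "fraction_separated": frac.ravel(),
        }
    )
    flagged = [g for i, g in enumerate(m.groups) if (frac[i] >= phi).any()]
    return FlagReport(
        flagged=flagged,
        evidence=evidence,
        theta=theta,
        alpha=alpha,
        phi=phi,
        correction=correction,
    )
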