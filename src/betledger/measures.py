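"""Per-player behavioural measures of gambling involvement.

The eight classical player-behaviour-tracking summaries, computed per player
from matched bets:

duration
    calendar days from first to last bet inclusive, so a pair of bets at
    22:00 and 09:00 the next morning spans two days even though they are
    under 24 h apart (midnight-boundary rounding);
frequency
    percentage of those days on which at least one bet was placed;
number of bets, bets per betting day, mean bet size (ETH);
total wagered (ETH)
    the involvement measure used for the heavy-bettor split;
net loss (ETH)
    total staked minus total paid out (negative = net win);
percent loss
    net loss as a percentage of total wagered.

Day boundaries are UTC midnights and all temporal measures use bet-placement
times only; payout timestamps never enter.
"""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd

#: measure columns, in the conventional reporting order
MEASURE_COLUMNS = [
    "duration_days",
    "frequency_pct",
    "n_bets",
    "bets_per_day",
    "mean_bet_eth",
    "total_wagered_eth",
    "net_loss_eth",
    "percent_loss",
]


def _utc_dates(bet_times) -> pd.Series:
    ts = pd.to_datetime(pd.Series(list(bet_times)), utc=True)
    if ts.empty:
        raise ValueError("bet_times must be non-empty")
    return ts.dt.normalize()


def duration_days(bet_times: Sequence) -> int:
    """Calendar days spanned from first to last bet, inclusive (UTC dates)."""
    dates = _utc_dates(bet_times)
    return int((dates.max() - dates.min()).days) + 1


def active_days(bet_times: Sequence) -> int:
    """Number of distinct UTC calendar dates with at least one bet."""
    return int(_utc_dates(bet_times).nunique())


def compute_measures(bets: pd.DataFrame) -> pd.Series:
    """Behavioural measures for the matched bets of a single player.

    Parameters
    ----------
    bets
        Matched-bet frame rows of one address (columns ``bet_time``,
        ``stake_eth``, ``payout_eth``).

    Returns
    -------
    pandas.Series indexed by :data:`MEASURE_COLUMNS`.

    Raises
    ------
    ValueError
        If ``bets`` is empty or any stake is non-positive.
    """
    if bets.empty:
        raise ValueError("cannot compute measures from zero bets")
    stakes = bets["stake_eth"].to_numpy(dtype=float)
    if (stakes <= 0).any():
        raise ValueError("all stakes must be strictly positive")
    dates = pd.to_datetime(bets["bet_time"], utc=True).dt.normalize()
    dur = int((dates.max() - dates.min()).days) + 1
    active = int(dates.nunique())
    n = len(bets)
    w = float(stakes.sum())
    p = float(bets["payout_eth"].to_numpy(dtype=float).sum())
    return pd.Series(
        {
            "duration_days": dur,
            "frequency_pct": 100.0 * active / dur,
            "n_bets": n,
            "bets_per_day": n / active,
            "mean_bet_eth": w / n,
            "total_wagered_eth": w,
            "net_loss_eth": w - p,
            "percent_loss": 100.0 * (w - p) / w,
        }
    )


def measures_table(bets: pd.DataFrame, group_by: str = "address") -> pd.DataFrame:
    """Behavioural measures for every player in a matched-bet table.

    Parameters
    ----------
    bets
        Matched-bet frame for any number of players/games.
    group_by
        ``"address"`` — one row per unique address, pooling its bets across
        all games (the combined-cohort view); ``"address-app-game"`` — one
        row per address within each application-game combination (the
        per-group view used for screening).

    Returns
    -------
    One row per group key, sorted by key, with the key columns followed by
    :data:`MEASURE_COLUMNS`.
    """
    if bets.empty:
        raise ValueError("cannot compute measures from an empty bet table")
    if group_by == "address":
        keys = ["address"]
    elif group_by == "address-app-game":
        keys = ["address", "app", "game"]
    else:
        raise ValueError(f"unknown group_by mode: {group_by!r}")

    df = bets.copy()
    if (df["stake_eth"].to_numpy(dtype=float) <= 0).any():
        raise ValueError("all stakes must be strictly positive")
    df["_date"] = pd.to_datetime(df["bet_time"], utc=True).dt.normalize()

    g = df.groupby(keys, sort=True)
    agg = g.agg(
        _first=("_date", "min"),
        _last=("_date", "max"),
        _active=("_date", "nunique"),
        n_bets=("stake_eth", "size"),
        total_wagered_eth=("stake_eth", "sum"),
        _payout=("payout_eth", "sum"),
    )
    dur = (agg["_last"] - agg["_first"]).dt.days + 1
    out = pd.DataFrame(index=agg.index)
    out["duration_days"] = dur.astype(int)
    out["frequency_pct"] = 100.0 * agg["_active"] / dur
    out["n_bets"] = agg["n_bets"].astype(int)
    out["bets_per_day"] = agg["n_bets"] / agg["_active"]
    out["mean_bet_eth"] = agg["total_wagered_eth"] / agg["n_bets"]
    out["total_wagered_eth"] = agg["total_wagered_eth"]
    out["net_loss_eth"] = agg["total_wagered_eth"] - agg["_payout"]
    out["percent_loss"] = 100.0 * out["net_loss_eth"] / out["total_wagered_eth"]
    return out.reset_index()


def to_fiat(table: pd.DataFrame, rate: float) -> pd.DataFrame:
    """Presentation-layer conversion of the ETH-denominated measures.

    Multiplies ``mean_bet_eth``, ``total_wagered_eth`` and ``net_loss_eth`` by
    a single static ETH→fiat ``rate`` and renames them ``*_fiat``.  The
    scale-free measures are untouched; the stored measures table always stays
    in ETH.
    """
    if rate <= 0:
        raise ValueError("fiat rate must be positive")
    out = table.copy()
    for col in ("mean_bet_eth", "total_wagered_eth", "net_loss_eth"):
        out[col.replace("_eth", "_fiat")] = out.pop(col) * rate
    return out
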