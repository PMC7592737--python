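"""Read casino transaction ledgers and pair payouts with stakes.

A decentralised gambling application is a smart contract: every stake is an
on-chain transfer *to* the contract and every winning payout a transfer *from*
it.  The ledger therefore contains two interleaved streams per player address.
This module reads such ledgers from CSV, validates rows, and reconstructs
"matched bets" — each stake paired with the payout it triggered, if any — by
greedy chronological matching within each (address, app, game) stream: an
outgoing transaction is taken to be the payout of the earliest not-yet-paid
stake placed at or before it.  Losing bets receive no payout transaction and
end up with payout 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical transaction-frame columns
TX_COLUMNS = ["tx_hash", "address", "app", "game", "timestamp", "direction", "value"]

#: stable on-disk layout for matched-bet files
BET_COLUMNS = [
    "address",
    "app",
    "game",
    "bet_time",
    "stake_eth",
    "payout_eth",
    "bet_hash",
    "payout_hash",
]

#: default mapping from ledger CSV headers to canonical names
DEFAULT_SCHEMA = {c: c for c in TX_COLUMNS}


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class IntegrityError(ValueError):
    """Input data violates a structural invariant (duplicate hash, bad order)."""


@dataclass
class RejectReport:
    """Row-level problems found while reading a ledger.

    Rejected rows are counted and retained (with a reason) rather than
    silently dropped.
    """

    n_rows_read: int = 0
    n_accepted: int = 0
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


@dataclass
class MatchReport:
    """Accounting for one matching pass.

    ``n_bets_matched + n_bets_unmatched`` equals the number of stake rows;
    orphan payouts are outgoing transfers with no eligible prior stake.
    """

    n_bets_matched: int = 0
    n_bets_unmatched: int = 0
    n_orphan_payouts: int = 0

    def __add__(self, other: "MatchReport") -> "MatchReport":
        return MatchReport(
            self.n_bets_matched + other.n_bets_matched,
            self.n_bets_unmatched + other.n_bets_unmatched,
            self.n_orphan_payouts + other.n_orphan_payouts,
        )


def read_transactions(
    path, schema: dict | None = None
) -> tuple[pd.DataFrame, RejectReport]:
    """Read a transaction ledger CSV into the canonical transaction frame.

    Parameters
    ----------
    path
        CSV file with a header row, one row per on-chain transfer.
    schema
        Mapping from canonical column names (``tx_hash``, ``address``, ``app``,
        ``game``, ``timestamp``, ``direction``, ``value``) to the file's
        header names.  Defaults to the identity mapping.

    Returns
    -------
    (frame, report)
        ``frame`` is sorted by (address, timestamp, tx_hash) with addresses
        lower-cased and timestamps tz-aware UTC.  Malformed rows (unparseable
        timestamp or value, negative value, unknown direction, zero-value
        stakes) are collected into ``report.rejects`` with a ``reject_reason``
        column, never silently dropped.

    Raises
    ------
    SchemaError
        If a mapped column is absent, naming the missing column.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path, dtype=str)
    missing = [schema[c] for c in TX_COLUMNS if schema[c] not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = raw.rename(columns={v: k for k, v in schema.items()})[TX_COLUMNS].copy()

    reasons = pd.Series("", index=df.index, dtype=object)

    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="mixed")
    reasons[ts.isna()] = "unparseable timestamp"
    value = pd.to_numeric(df["value"], errors="coerce")
    bad_value = value.isna() & (reasons == "")
    reasons[bad_value] = "unparseable value"
    neg = (value < 0) & (reasons == "")
    reasons[neg] = "negative value"
    direction = df["direction"].str.strip().str.lower()
    bad_dir = ~direction.isin(["to_app", "from_app"]) & (reasons == "")
    reasons[bad_dir] = "unknown direction"
    # zero-value transfers to the contract cannot be bets: drop and log
    zero_stake = (value == 0) & (direction == "to_app") & (reasons == "")
    reasons[zero_stake] = "zero-value stake"

    ok = reasons == ""
    rejects = raw.loc[~ok].copy()
    rejects["reject_reason"] = reasons[~ok]
    if len(rejects):
        logger.warning("rejected %d of %d ledger rows", len(rejects), len(raw))

    out = df.loc[ok].copy()
    out["timestamp"] = ts[ok]
    out["value"] = value[ok].astype(float)
    out["direction"] = direction[ok]
    out["address"] = out["address"].str.lower()
    if out["tx_hash"].duplicated().any():
        dup = out.loc[out["tx_hash"].duplicated(), "tx_hash"].iloc[0]
        raise IntegrityError(f"duplicate tx_hash in ledger: {dup}")
    out = out.sort_values(["address", "timestamp", "tx_hash"]).reset_index(drop=True)
    return out, RejectReport(
        n_rows_read=len(raw), n_accepted=len(out), rejects=rejects
    )


def _match_stream(
    stakes: pd.DataFrame, payouts: pd.DataFrame, window_s: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Greedy earliest-first matching for one time-sorted stream.

    Each payout, in chronological order, is assigned to the earliest unmatched
    stake placed at or before it (plus an optional lookahead ``window_s``
    allowing a payout recorded marginally ahead of its stake).  The assignment
    is the FIFO solution, computed by a vectorised scan: after payout *j*, the
    number matched is ``m_j = min(j + 1, min_{i<=j}(c_i + j - i))`` where
    ``c_i`` counts stakes eligible for payout *i*.
    """
    s_times = stakes["timestamp"].to_numpy(dtype="datetime64[ns]")
    q_times = payouts["timestamp"].to_numpy(dtype="datetime64[ns]")
    if len(q_times) == 0:
        return np.array([], dtype=int), np.array([], dtype=int), 0
    eligible = q_times + np.timedelta64(int(round(window_s * 1e9)), "ns")
    c = np.searchsorted(s_times, eligible, side="right")
    j = np.arange(len(q_times))
    m = np.minimum(j + 1, np.minimum.accumulate(c - j) + j)
    prev = np.concatenate(([0], m[:-1]))
    matched = m > prev
    payout_idx = np.flatnonzero(matched)  # positions into payout stream
    stake_idx = m[matched] - 1  # positions into stake stream
    n_orphans = int((~matched).sum())
    return stake_idx, payout_idx, n_orphans


def match_bets(
    records: pd.DataFrame, window_s: float = 0.0
) -> tuple[pd.DataFrame, MatchReport]:
    """Pair payouts with stakes for a single (address, app, game) stream.

    Parameters
    ----------
    records
        Canonical transaction frame holding exactly one (address, app, game)
        combination, sorted by timestamp.
    window_s
        Lookahead in seconds: a payout may be matched to a stake recorded up
        to ``window_s`` after it, to tolerate marginal reordering on the
        chain.  Default 0 (strict chronological rule).

    Returns
    -------
    (bets, report)
        ``bets`` is a matched-bet frame (:data:`BET_COLUMNS`), one row per
        stake in chronological order; unmatched stakes are losing bets with
        ``payout_eth`` 0 and no ``payout_hash``.

    Raises
    ------
    IntegrityError
        If the stream mixes keys or is not time-sorted.
    """
    if records.empty:
        return _empty_bets(), MatchReport()
    for key in ("address", "app", "game"):
        if records[key].nunique() > 1:
            raise IntegrityError(f"match_bets got mixed values in {key!r}")
    ts = records["timestamp"]
    if not ts.is_monotonic_increasing:
        raise IntegrityError("records must be sorted by timestamp")

    stakes = records[records["direction"] == "to_app"].reset_index(drop=True)
    payouts = records[records["direction"] == "from_app"].reset_index(drop=True)
    stake_idx, payout_idx, n_orphans = _match_stream(stakes, payouts, window_s)

    payout_val = np.zeros(len(stakes))
    payout_hash = np.full(len(stakes), None, dtype=object)
    payout_val[stake_idx] = payouts["value"].to_numpy()[payout_idx]
    payout_hash[stake_idx] = payouts["tx_hash"].to_numpy()[payout_idx]

    bets = pd.DataFrame(
        {
            "address": stakes["address"],
            "app": stakes["app"],
            "game": stakes["game"],
            "bet_time": stakes["timestamp"],
            "stake_eth": stakes["value"],
            "payout_eth": payout_val,
            "bet_hash": stakes["tx_hash"],
            "payout_hash": payout_hash,
        }
    )
    report = MatchReport(
        n_bets_matched=len(stake_idx),
        n_bets_unmatched=len(stakes) - len(stake_idx),
        n_orphan_payouts=n_orphans,
    )
    return bets, report


def match_all(
    transactions: pd.DataFrame, window_s: float = 0.0
) -> tuple[pd.DataFrame, MatchReport]:
    """Match every (address, app, game) stream in a ledger.

    Returns the concatenated matched-bet frame, sorted by
    (address, app, game, bet_time), and the aggregate :class:`MatchReport`.
    """
    if transactions.empty:
        return _empty_bets(), MatchReport()
    df = transactions.sort_values(
        ["address", "app", "game", "timestamp", "tx_hash"]
    ).reset_index(drop=True)
    key = (
        df["address"].astype(str)
        + "\x00"
        + df["app"].astype(str)
        + "\x00"
        + df["game"].astype(str)
    )
    codes = pd.factorize(key)[0]
    times = df["timestamp"].to_numpy("datetime64[ns]")
    is_stake = (df["direction"] == "to_app").to_numpy()
    values = df["value"].to_numpy(dtype=float)
    hashes = df["tx_hash"].to_numpy(dtype=object)

    stake_pos = np.flatnonzero(is_stake)
    stake_rank = np.cumsum(is_stake) - 1  # output row of each stake, in order
    payout_val = np.zeros(len(stake_pos))
    payout_hash = np.full(len(stake_pos), None, dtype=object)

    starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
    ends = np.r_[starts[1:], len(df)]
    window = np.timedelta64(int(round(window_s * 1e9)), "ns")
    n_matched = n_orphans = 0
    for s0, s1 in zip(starts, ends):
        sm = is_stake[s0:s1]
        st = times[s0:s1][sm]
        q_rows = np.flatnonzero(~sm) + s0
        if len(q_rows) == 0:
            continue
        qt = times[q_rows]
        # FIFO scan (see _match_stream): m_j unmatched stakes consumed so far
        c = np.searchsorted(st, qt + window, side="right")
        j = np.arange(len(qt))
        m = np.minimum(j + 1, np.minimum.accumulate(c - j) + j)
        prev = np.concatenate(([0], m[:-1]))
        matched = m > prev
        s_rows = (np.flatnonzero(sm) + s0)[m[matched] - 1]
        out_rows = stake_rank[s_rows]
        payout_val[out_rows] = values[q_rows[matched]]
        payout_hash[out_rows] = hashes[q_rows[matched]]
        n_matched += int(matched.sum())
        n_orphans += int((~matched).sum())

    bets = pd.DataFrame(
        {
            "address": df["address"].to_numpy()[stake_pos],
            "app": df["app"].to_numpy()[stake_pos],
            "game": df["game"].to_numpy()[stake_pos],
            "bet_time": df["timestamp"].to_numpy()[stake_pos],
            "stake_eth": values[stake_pos],
            "payout_eth": payout_val,
            "bet_hash": hashes[stake_pos],
            "payout_hash": payout_hash,
        }
    )
    bets["bet_time"] = pd.to_datetime(bets["bet_time"], utc=True)
    report = MatchReport(
        n_bets_matched=n_matched,
        n_bets_unmatched=len(stake_pos) - n_matched,
        n_orphan_payouts=n_orphans,
    )
    if report.n_orphan_payouts:
        logger.warning("%d orphan payouts had no eligible prior stake",
                       report.n_orphan_payouts)
    return bets, report


def _empty_bets() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in BET_COLUMNS})
    df["bet_time"] = pd.Series(dtype="datetime64[ns, UTC]")
    df["stake_eth"] = pd.Series(dtype=float)
    df["payout_eth"] = pd.Series(dtype=float)
    return df


def write_matched_bets(bets: pd.DataFrame, path) -> None:
    """Write a matched-bet frame to CSV in the stable deposited layout.

    Columns and order are :data:`BET_COLUMNS`; ``bet_time`` is ISO-8601 UTC;
    losing bets have an empty ``payout_hash`` cell.
    """
    out = bets[BET_COLUMNS].copy()
    out["bet_time"] = pd.to_datetime(out["bet_time"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def read_matched_bets(path) -> pd.DataFrame:
    """Read a matched-bet CSV written by :func:`write_matched_bets`.

    A missing ``payout_hash`` cell forces ``payout_eth`` to 0 (losing bet).

    Raises
    ------
    SchemaError
        If a required column is absent.
    IntegrityError
        If ``bet_hash`` values are not unique.
    """
    raw = pd.read_csv(path, dtype={"bet_hash": str, "payout_hash": str})
    missing = [c for c in BET_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = raw[BET_COLUMNS].copy()
    if df["bet_hash"].duplicated().any():
        dup = df.loc[df["bet_hash"].duplicated(), "bet_hash"].iloc[0]
        raise IntegrityError(f"duplicate bet_hash: {dup}")
    df["bet_time"] = pd.to_datetime(df["bet_time"], utc=True)
    df["stake_eth"] = df["stake_eth"].astype(float)
    df["payout_eth"] = df["payout_eth"].astype(float)
    no_payout = df["payout_hash"].isna() | (df["payout_hash"] == "")
    df.loc[no_payout, "payout_eth"] = 0.0
    df.loc[no_payout, "payout_hash"] = None
    df["address"] = df["address"].str.lower()
    return df
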