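import numpy as np
import pandas as pd
import pytest


def make_ledger(rows):
    """Build a canonical transaction frame from (hash, addr, app, game, ts, dir, value)."""
    df = pd.DataFrame(
        rows,
        columns=["tx_hash", "address", "app", "game", "timestamp", "direction", "value"],
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df["value"] = df["value"].astype(float)
    return df


def make_bets(rows):
    """Build a matched-bet frame from (addr, app, game, time, stake, payout)."""
    df = pd.DataFrame(
        rows,
        columns=["address", "app", "game", "bet_time", "stake_eth", "payout_eth"],
    )
    df["bet_time"] = pd.to_datetime(df["bet_time"], utc=True)
    df["bet_hash"] = [f"b{i}" for i in range(len(df))]
    df["payout_hash"] = [f"p{i}" if v > 0 else None for i, v in enumerate(df["payout_eth"])]
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_stream():
    """One player, one stake immediately followed by its payout."""
    return make_ledger(
        [
            ("h1", "0xa", "app", "dice", "2019-01-01T10:00:00Z", "to_app", 1.0),
            ("h2", "0xa", "app", "dice", "2019-01-01T10:00:30Z", "from_app", 1.9),
        ]
    )
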