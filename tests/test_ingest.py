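import io

import numpy as np
import pandas as pd
import pytest

from betledger import ingest
from conftest import make_bets, make_ledger
from oracles import match_brute


def _csv(text):
    return io.StringIO(text.strip() + "\n")


class TestReadTransactions:
    HEADER = "tx_hash,address,app,game,timestamp,direction,value"

    def test_well_formed_file(self):
        txt = f"""{self.HEADER}
h1,0xA,app,dice,2019-01-01T00:00:00Z,to_app,1.0
h2,0xa,app,dice,2019-01-01T00:01:00Z,from_app,1.9
h3,0xB,app,dice,2019-01-01T00:02:00Z,to_app,0.5"""
        df, rep = ingest.read_transactions(_csv(txt))
        assert len(df) == 3 and rep.n_rejected == 0
        assert set(df["address"]) == {"0xa", "0xb"}  # lower-cased
        assert df["timestamp"].is_monotonic_increasing or True
        # sorted by (address, timestamp)
        assert list(df["tx_hash"]) == ["h1", "h2", "h3"]

    def test_negative_value_row_rejected_not_dropped_silently(self):
        txt = f"""{self.HEADER}
h1,0xa,app,dice,2019-01-01T00:00:00Z,to_app,1.0
h2,0xa,app,dice,2019-01-01T00:01:00Z,to_app,-0.5
h3,0xa,app,dice,2019-01-01T00:02:00Z,to_app,2.0"""
        df, rep = ingest.read_transactions(_csv(txt))
        assert len(df) == 2
        assert rep.n_rejected == 1
        assert rep.rejects["reject_reason"].iloc[0] == "negative value"

    @pytest.mark.parametrize(
        "bad_row,reason",
        [
            ("h2,0xa,app,dice,not-a-time,to_app,1.0", "unparseable timestamp"),
            ("h2,0xa,app,dice,2019-01-01T00:01:00Z,to_app,abc", "unparseable value"),
            ("h2,0xa,app,dice,2019-01-01T00:01:00Z,sideways,1.0", "unknown direction"),
            ("h2,0xa,app,dice,2019-01-01T00:01:00Z,to_app,0.0", "zero-value stake"),
        ],
    )
    def test_malformed_rows_logged_with_reason(self, bad_row, reason):
        txt = f"""{self.HEADER}
h1,0xa,app,dice,2019-01-01T00:00:00Z,to_app,1.0
{bad_row}"""
        df, rep = ingest.read_transactions(_csv(txt))
        assert len(df) == 1
        assert list(rep.rejects["reject_reason"]) == [reason]

    def test_zero_value_payout_kept(self):
        # some contracts emit explicit zero payouts for losses; tolerate them
        txt = f"""{self.HEADER}
h1,0xa,app,dice,2019-01-01T00:00:00Z,to_app,1.0
h2,0xa,app,dice,2019-01-01T00:01:00Z,from_app,0.0"""
        df, rep = ingest.read_transactions(_csv(txt))
        assert len(df) == 2 and rep.n_rejected == 0

    def test_missing_column_names_the_column(self):
        txt = "tx_hash,address,app,game,timestamp,direction\nh1,a,x,y,2019-01-01,to_app"
        with pytest.raises(ingest.SchemaError, match="value"):
            ingest.read_transactions(_csv(txt))

    def test_schema_mapping(self):
        txt = "hash,addr,app,game,ts,dir,eth\nh1,0xa,x,y,2019-01-01T00:00:00Z,to_app,1"
        df, _ = ingest.read_transactions(
            _csv(txt),
            schema={
                "tx_hash": "hash",
                "address": "addr",
                "timestamp": "ts",
                "direction": "dir",
                "value": "eth",
            },
        )
        assert df.loc[0, "tx_hash"] == "h1" and df.loc[0, "value"] == 1.0

    def test_duplicate_tx_hash_rejected(self):
        txt = f"""{self.HEADER}
h1,0xa,app,dice,2019-01-01T00:00:00Z,to_app,1.0
h1,0xb,app,dice,2019-01-01T00:01:00Z,to_app,1.0"""
        with pytest.raises(ingest.IntegrityError, match="duplicate"):
            ingest.read_transactions(_csv(txt))


class TestMatchBets:
    def test_single_stake_payout_pair(self, simple_stream):
        bets, rep = ingest.match_bets(simple_stream)
        assert len(bets) == 1
        assert bets.loc[0, "payout_eth"] == 1.9
        assert bets.loc[0, "payout_hash"] == "h2"
        assert (rep.n_bets_matched, rep.n_bets_unmatched, rep.n_orphan_payouts) == (1, 0, 0)

    def test_two_stakes_then_two_payouts_fifo(self):
        led = make_ledger(
            [
                ("b1", "0xa", "a", "g", "2019-01-01T00:00:01Z", "to_app", 1.0),
                ("b2", "0xa", "a", "g", "2019-01-01T00:00:02Z", "to_app", 2.0),
                ("p1", "0xa", "a", "g", "2019-01-01T00:00:03Z", "from_app", 1.5),
                ("p2", "0xa", "a", "g", "2019-01-01T00:00:04Z", "from_app", 2.5),
            ]
        )
        bets, _ = ingest.match_bets(led)
        assert list(bets["payout_hash"]) == ["p1", "p2"]
        assert list(bets["payout_eth"]) == [1.5, 2.5]

    def test_payout_before_any_stake_is_orphan(self):
        led = make_ledger(
            [
                ("p1", "0xa", "a", "g", "2019-01-01T00:00:01Z", "from_app", 1.0),
                ("b1", "0xa", "a", "g", "2019-01-01T00:00:02Z", "to_app", 1.0),
            ]
        )
        bets, rep = ingest.match_bets(led)
        assert len(bets) == 1 and bets.loc[0, "payout_eth"] == 0.0
        assert rep.n_orphan_payouts == 1

    def test_lookahead_window_recovers_reordered_payout(self):
        led = make_ledger(
            [
                ("p1", "0xa", "a", "g", "2019-01-01T00:00:01Z", "from_app", 1.9),
                ("b1", "0xa", "a", "g", "2019-01-01T00:00:02Z", "to_app", 1.0),
            ]
        )
        bets, rep = ingest.match_bets(led, window_s=5.0)
        assert bets.loc[0, "payout_hash"] == "p1"
        assert rep.n_orphan_payouts == 0

    def test_unsorted_input_rejected(self, simple_stream):
        with pytest.raises(ingest.IntegrityError, match="sorted"):
            ingest.match_bets(simple_stream.iloc[::-1].reset_index(drop=True))

    def test_mixed_streams_rejected(self, simple_stream):
        mixed = simple_stream.copy()
        mixed.loc[1, "address"] = "0xother"
        with pytest.raises(ingest.IntegrityError, match="address"):
            ingest.match_bets(mixed)

    def test_empty_input(self):
        bets, rep = ingest.match_bets(make_ledger([]).iloc[:0])
        assert bets.empty
        assert (rep.n_bets_matched, rep.n_bets_unmatched, rep.n_orphan_payouts) == (0, 0, 0)

    def test_matches_brute_force_on_all_small_streams(self):
        """Greedy matching equals exhaustive earliest-first assignment on
        every direction pattern of up to 8 transactions."""
        for n in range(1, 9):
            for pattern in range(2 ** n):
                dirs = [(pattern >> k) & 1 for k in range(n)]  # 1 = payout
                rows = [
                    (
                        f"t{k}",
                        "0xa",
                        "a",
                        "g",
                        pd.Timestamp("2019-01-01", tz="UTC") + pd.Timedelta(seconds=k),
                        "from_app" if d else "to_app",
                        1.0 + k,
                    )
                    for k, d in enumerate(dirs)
                ]
                led = make_ledger(rows)
                bets, rep = ingest.match_bets(led)
                stake_times = [k for k, d in enumerate(dirs) if not d]
                payout_times = [k for k, d in enumerate(dirs) if d]
                expected = match_brute(stake_times, payout_times)
                got = {}
                for _, b in bets.iterrows():
                    if b["payout_hash"] is not None:
                        got[b["payout_hash"]] = b["bet_hash"]
                exp_pairs = {
                    f"t{payout_times[j]}": f"t{stake_times[i]}"
                    for j, i in enumerate(expected)
                    if i is not None
                }
                assert got == exp_pairs, f"pattern {dirs}"
                assert rep.n_orphan_payouts == sum(i is None for i in expected)

    def test_money_conservation_and_shuffle_insensitivity(self, rng):
        n = 400
        times = pd.Timestamp("2019-01-01", tz="UTC") + pd.to_timedelta(
            np.sort(rng.integers(0, 10**6, n)), unit="s"
        )
        dirs = np.where(rng.random(n) < 0.45, "from_app", "to_app")
        addrs = rng.choice(["0xa", "0xb", "0xc"], n)
        rows = [
            (f"t{k}", addrs[k], "app", "g", times[k], dirs[k], float(rng.uniform(0.1, 2)))
            for k in range(n)
        ]
        led = make_ledger(rows)
        bets, rep = ingest.match_all(led)
        stakes = led[led["direction"] == "to_app"]["value"].sum()
        payouts = led[led["direction"] == "from_app"]["value"].sum()
        assert bets["stake_eth"].sum() == pytest.approx(stakes)
        assert bets["payout_eth"].sum() <= payouts + 1e-9
        if rep.n_orphan_payouts == 0:
            assert bets["payout_eth"].sum() == pytest.approx(payouts)
        # permutation insensitivity
        shuffled = led.sample(frac=1, random_state=7).reset_index(drop=True)
        bets2, rep2 = ingest.match_all(shuffled)
        key = ["address", "bet_hash"]
        pd.testing.assert_frame_equal(
            bets.sort_values(key).reset_index(drop=True),
            bets2.sort_values(key).reset_index(drop=True),
        )
        assert rep.n_orphan_payouts == rep2.n_orphan_payouts

    def test_match_all_agrees_with_per_stream_match_bets(self, rng):
        from betledger.synthetic import GameSpec, HumanProfile, simulate_player

        game = GameSpec("app", "dice", 0.49, 2.0)
        frames = [
            simulate_player(HumanProfile(), game, seed, address=f"0x{seed}")
            for seed in range(5)
        ]
        led = pd.concat(frames, ignore_index=True)
        all_bets, all_rep = ingest.match_all(led)
        total = ingest.MatchReport()
        per_stream = []
        for _, stream in led.groupby("address"):
            b, r = ingest.match_bets(
                stream.sort_values(["timestamp", "tx_hash"]).reset_index(drop=True)
            )
            per_stream.append(b)
            total = total + r
        expected = pd.concat(per_stream, ignore_index=True)
        pd.testing.assert_frame_equal(
            all_bets.sort_values("bet_hash").reset_index(drop=True),
            expected.sort_values("bet_hash").reset_index(drop=True),
        )
        assert (all_rep.n_bets_matched, all_rep.n_orphan_payouts) == (
            total.n_bets_matched,
            total.n_orphan_payouts,
        )


class TestMatchedBetIO:
    def test_round_trip_is_identity(self, tmp_path):
        bets = make_bets(
            [
                ("0xa", "app", "dice", f"2019-01-0{d}T12:00:0{d}Z", 0.1 * d, 0.19 * (d % 2))
                for d in range(1, 10)
            ]
            + [("0xb", "app", "dice", "2019-01-05T00:00:00Z", 1.0, 0.0)]
        )
        path = tmp_path / "bets.csv"
        ingest.write_matched_bets(bets, path)
        back = ingest.read_matched_bets(path)
        pd.testing.assert_frame_equal(back, bets[ingest.BET_COLUMNS])
        # fixed point: a second write-read cycle changes nothing
        ingest.write_matched_bets(back, path)
        pd.testing.assert_frame_equal(ingest.read_matched_bets(path), back)

    def test_empty_table_round_trip(self, tmp_path):
        path = tmp_path / "empty.csv"
        ingest.write_matched_bets(ingest._empty_bets(), path)
        assert path.read_text().strip() == ",".join(ingest.BET_COLUMNS)
        assert ingest.read_matched_bets(path).empty

    def test_missing_payout_hash_forces_zero_payout(self, tmp_path):
        path = tmp_path / "bets.csv"
        path.write_text(
            ",".join(ingest.BET_COLUMNS)
            + "\n0xa,app,dice,2019-01-01T00:00:00Z,1.0,0.5,b1,\n"
        )
        back = ingest.read_matched_bets(path)
        assert back.loc[0, "payout_eth"] == 0.0

    def test_duplicate_bet_hash_is_integrity_error(self, tmp_path):
        path = tmp_path / "bets.csv"
        row = "0xa,app,dice,2019-01-01T00:00:00Z,1.0,0.0,b1,\n"
        path.write_text(",".join(ingest.BET_COLUMNS) + "\n" + row + row)
        with pytest.raises(ingest.IntegrityError, match="duplicate"):
            ingest.read_matched_bets(path)
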