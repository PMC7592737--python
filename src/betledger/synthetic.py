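"""Synthetic transaction ledgers with the structure the analysis assumes.

Emulates the statistical shape of real decentralised-casino ledgers so every
pipeline stage can be exercised without any download:

* several application-game groups, each a fixed-odds game with win
  probability ``p`` and payout multiplier ``m`` (house edge ``e = 1 - p*m``);
* heavy-tailed human populations — log-normal stakes and bet counts, careers
  with most mass at a single day and a long engaged tail, bets clustered
  into within-day sessions;
* optionally a bot-dominated group: algorithmic bettors with near-constant
  stakes, near-constant bet counts, and regular inter-bet intervals over a
  long fixed span — the minimal mechanism producing a second, degenerate
  peak in the behavioural-measure distributions.

Every bet emits a stake transfer to the application; with probability ``p``
a payout transfer of ``stake * m`` follows after a fixed small confirmation
lag (next block, seconds).  All randomness flows from a single master seed
through ``numpy.random.SeedSequence`` spawns, so a config reproduces its
ledger byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .ingest import TX_COLUMNS

SECONDS_PER_DAY = 86_400
PAYOUT_DELAY_S = 15  # next-block confirmation lag


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class GameSpec:
    """A fixed-odds casino game offered by an application contract.

    A unit stake returns ``payout_multiplier`` with probability ``win_prob``
    and nothing otherwise, so the expected return is ``p*m = 1 - e`` with
    house edge ``e``.
    """

    app: str
    game: str
    win_prob: float
    payout_multiplier: float

    @property
    def house_edge(self) -> float:
        return 1.0 - self.win_prob * self.payout_multiplier

    def validate(self, allow_player_favourable: bool = False) -> None:
        if not 0.0 <= self.win_prob <= 1.0:
            raise ConfigError(f"win_prob must be in [0, 1], got {self.win_prob}")
        if self.payout_multiplier <= 0:
            raise ConfigError("payout_multiplier must be positive")
        e = self.house_edge
        if e < 0.0 and not allow_player_favourable:
            raise ConfigError(
                f"house edge {e:.4f} is negative (player-favourable); "
                "require allow_player_favourable=True to simulate"
            )

    @property
    def label(self) -> str:
        return f"{self.app}/{self.game}"


def expected_percent_loss(game: GameSpec) -> float:
    """Long-run percent loss for a player of ``game``: 100 * house edge.

    Over many bets the realised loss fraction converges to the house take
    per unit staked, which is why heavily involved bettors' percent loss
    concentrates tightly near this value while casual players' is dominated
    by the binomial noise of a handful of outcomes.
    """
    game.validate(allow_player_favourable=True)
    return 100.0 * game.house_edge


@dataclass(frozen=True)
class HumanProfile:
    """Heavy-tailed human bettor population.

    Bet counts are log-normal (median ``exp(n_bets_mu)``).  Stakes are
    hierarchical log-normal: each player draws a typical stake (population
    median ``exp(stake_mu)``, log-SD ``stake_sigma_between`` across players)
    and individual bets vary around it with log-SD ``stake_sigma_within`` —
    most of the spread in spending sits between players, not within one
    player's bets.  Careers mix a point mass at a single day with a
    log-normal engaged tail; within a career, bets fall on uniformly chosen
    days and cluster into one to three within-day sessions.  Defaults
    describe a casual population: median career of one day, ~11 bets,
    ~0.1 ETH typical stakes.
    """

    kind: str = "human"
    n_bets_mu: float = 2.398  # log 11
    n_bets_sigma: float = 1.1
    n_bets_cap: int = 10_000
    stake_mu: float = -2.303  # log 0.1 ETH, population median typical stake
    stake_sigma_between: float = 1.2  # player-to-player spread of typical stake
    stake_sigma_within: float = 0.25  # bet-to-bet spread around a player's typical stake
    p_one_day: float = 0.55
    career_mu: float = 1.946  # log 7 days, for the engaged tail
    career_sigma: float = 1.0
    max_sessions_per_day: int = 3
    session_length_s: int = 7_200


@dataclass(frozen=True)
class BotProfile:
    """Algorithmic bettor: near-degenerate behaviour.

    Constant stake (up to a relative jitter), near-constant large bet count,
    and regular inter-bet intervals spread over a long fixed span.
    """

    kind: str = "bot"
    n_bets_mean: int = 400
    n_bets_sd: float = 5.0
    stake_eth: float = 0.02
    stake_jitter: float = 1e-4
    span_days: int = 120
    interval_jitter_s: float = 2.0


@dataclass(frozen=True)
class GroupSpec:
    """One application-game group of a simulated population."""

    game: GameSpec
    n_human: int = 200
    n_bot: int = 0
    human_profile: HumanProfile = field(default_factory=HumanProfile)
    bot_profile: BotProfile = field(default_factory=BotProfile)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of a synthetic population.

    ``seed`` is mandatory and fixes the entire output stream; ``start`` is
    the UTC date of the observation window's first day.
    """

    groups: tuple[GroupSpec, ...]
    seed: int
    start: str = "2019-01-01"
    window_days: int = 365

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("config needs at least one group")
        labels = [g.game.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate (app, game) labels in config")
        for g in self.groups:
            g.game.validate()
            if g.n_human + g.n_bot < 1:
                raise ConfigError(f"group {g.game.label} has no players")
        if self.window_days < 1:
            raise ConfigError("window_days must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        groups = tuple(
            GroupSpec(
                game=GameSpec(**g["game"]),
                n_human=g.get("n_human", 0),
                n_bot=g.get("n_bot", 0),
                human_profile=HumanProfile(**g.get("human_profile") or {}),
                bot_profile=BotProfile(**g.get("bot_profile") or {}),
            )
            for g in raw["groups"]
        )
        return cls(
            groups=groups,
            seed=int(raw["seed"]),
            start=str(raw.get("start", "2019-01-01")),
            window_days=int(raw.get("window_days", 365)),
        )


def default_config(seed: int, with_bots: bool = True) -> SimConfig:
    """The standard synthetic study population.

    Five human application-game groups of 200 players each (house edges
    1-3%, the realistic range for on-chain dice contracts) and, when
    ``with_bots``, a sixth group of 200 players dominated by bots (180 bots,
    20 humans).
    """
    human = HumanProfile()

    def grp(app, game, p, e, n_human=200, n_bot=0):
        return GroupSpec(
            game=GameSpec(app, game, p, (1.0 - e) / p),
            n_human=n_human,
            n_bot=n_bot,
            human_profile=human,
        )

    groups = [
        grp("rollhouse", "coin_flip", 0.49, 0.02),
        grp("rollhouse", "single_dice", 0.45, 0.02),
        grp("rollhouse", "double_dice", 0.40, 0.03),
        grp("luckyblock", "hi_lo", 0.48, 0.03),
        grp("luckyblock", "roulette", 0.474, 0.03),
    ]
    if with_bots:
        groups.append(
            grp("spinchain", "coin_flip", 0.49, 0.01, n_human=20, n_bot=180)
        )
    return SimConfig(groups=tuple(groups), seed=seed)


def _human_bet_times(profile: HumanProfile, rng, window_days: int, n_bets: int):
    if rng.random() < profile.p_one_day:
        career = 1
    else:
        career = 1 + int(round(rng.lognormal(profile.career_mu,
                                             profile.career_sigma)))
    career = min(career, window_days)
    start_day = int(rng.integers(0, max(window_days - career, 0) + 1))
    days = rng.integers(0, career, size=n_bets)
    if career > 1:  # pin the career ends so duration reflects the career
        days[0] = 0
        if n_bets > 1:
            days[-1] = career - 1
    n_sessions = int(rng.integers(1, profile.max_sessions_per_day + 1))
    session_starts = rng.integers(
        0, SECONDS_PER_DAY - profile.session_length_s, size=n_sessions
    )
    chosen = session_starts[rng.integers(0, n_sessions, size=n_bets)]
    tod = chosen + rng.integers(0, profile.session_length_s, size=n_bets)
    t = (start_day + days) * SECONDS_PER_DAY + tod
    return np.sort(t)


def _bot_bet_times(profile: BotProfile, rng, window_days: int, n_bets: int):
    span_s = min(profile.span_days, window_days) * SECONDS_PER_DAY
    start_day = int(rng.integers(0, max(window_days - profile.span_days, 0) + 1))
    interval = span_s / n_bets
    jitter = rng.normal(0.0, profile.interval_jitter_s, size=n_bets)
    t = start_day * SECONDS_PER_DAY + np.arange(n_bets) * interval + jitter
    return np.sort(np.clip(t, 0, None)).astype(np.int64)


def _player_bets(
    profile: HumanProfile | BotProfile,
    game: GameSpec,
    rng: np.random.Generator,
    window_days: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample one player's bets: (times in s from window start, stakes, wins)."""
    if isinstance(profile, BotProfile) or profile.kind == "bot":
        n_bets = max(1, int(round(rng.normal(profile.n_bets_mean, profile.n_bets_sd))))
        t = _bot_bet_times(profile, rng, window_days, n_bets)
        stakes = profile.stake_eth * (
            1.0 + rng.uniform(-profile.stake_jitter, profile.stake_jitter, n_bets)
        )
    else:
        n_bets = min(
            profile.n_bets_cap,
            max(1, int(round(rng.lognormal(profile.n_bets_mu, profile.n_bets_sigma)))),
        )
        t = _human_bet_times(profile, rng, window_days, n_bets)
        # hierarchical stakes: each player bets around their own typical size
        player_mu = rng.normal(profile.stake_mu, profile.stake_sigma_between)
        stakes = rng.lognormal(player_mu, profile.stake_sigma_within, n_bets)
    wins = rng.random(n_bets) < game.win_prob
    return t, stakes, wins


def _records_frame(
    addresses: np.ndarray,
    apps: np.ndarray,
    games: np.ndarray,
    hashes: np.ndarray,
    epochs: np.ndarray,
    directions: np.ndarray,
    values: np.ndarray,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "tx_hash": hashes,
            "address": addresses,
            "app": apps,
            "game": games,
            "timestamp": pd.to_datetime(epochs, unit="s", utc=True),
            "direction": directions,
            "value": values,
        }
    )
    return df.sort_values(["address", "timestamp", "tx_hash"]).reset_index(
        drop=True
    )[TX_COLUMNS]


def simulate_player(
    profile: HumanProfile | BotProfile,
    game: GameSpec,
    seed,
    address: str = "0xplayer",
    start: str = "2019-01-01",
    window_days: int = 365,
) -> pd.DataFrame:
    """Simulate one player's transaction stream for one game.

    Returns a canonical transaction frame: one ``to_app`` record per bet and,
    for winning bets, a ``from_app`` record of ``stake * m`` placed
    ``PAYOUT_DELAY_S`` seconds after the bet.  ``seed`` may be an integer or
    a ``numpy.random.Generator``.
    """
    game.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t, stakes, wins = _player_bets(profile, game, rng, window_days)
    base = pd.Timestamp(start, tz="UTC").value // 10**9
    bet_epoch = base + t
    n = len(t)
    idx = np.arange(n)
    return _records_frame(
        addresses=np.full(n + wins.sum(), address, dtype=object),
        apps=np.full(n + wins.sum(), game.app, dtype=object),
        games=np.full(n + wins.sum(), game.game, dtype=object),
        hashes=np.concatenate(
            [
                np.char.add(f"{address}-b", idx.astype(str)),
                np.char.add(f"{address}-p", idx[wins].astype(str)),
            ]
        ),
        epochs=np.concatenate([bet_epoch, bet_epoch[wins] + PAYOUT_DELAY_S]),
        directions=np.concatenate(
            [np.full(n, "to_app"), np.full(int(wins.sum()), "from_app")]
        ),
        values=np.concatenate([stakes, stakes[wins] * game.payout_multiplier]),
    )


def simulate_population(config: SimConfig) -> pd.DataFrame:
    """Simulate a full multi-group population into one transaction ledger.

    Deterministic given the config (including its master seed): per-player
    generators are spawned from ``SeedSequence(config.seed)`` in a fixed
    order.  Output is sorted by (address, timestamp, tx_hash), the canonical
    ledger order.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    group_seeds = root.spawn(len(config.groups))
    addr_l, app_l, game_l, hash_l, epoch_l, dir_l, val_l = ([] for _ in range(7))
    for gi, (grp_spec, gseed) in enumerate(zip(config.groups, group_seeds)):
        base = pd.Timestamp(config.start, tz="UTC").value // 10**9
        n_players = grp_spec.n_human + grp_spec.n_bot
        player_seeds = gseed.spawn(n_players)
        for pi in range(n_players):
            is_bot = pi >= grp_spec.n_human
            profile = grp_spec.bot_profile if is_bot else grp_spec.human_profile
            address = f"0x{gi:02d}{'b' if is_bot else 'h'}{pi:05d}"
            rng = np.random.default_rng(player_seeds[pi])
            t, stakes, wins = _player_bets(
                profile, grp_spec.game, rng, config.window_days
            )
            n = len(t)
            idx = np.arange(n)
            n_wins = int(wins.sum())
            addr_l.append(np.full(n + n_wins, address, dtype=object))
            app_l.append(np.full(n + n_wins, grp_spec.game.app, dtype=object))
            game_l.append(np.full(n + n_wins, grp_spec.game.game, dtype=object))
            hash_l.append(
                np.concatenate(
                    [
                        np.char.add(f"{address}-b", idx.astype(str)),
                        np.char.add(f"{address}-p", idx[wins].astype(str)),
                    ]
                )
            )
            epoch_l.append(
                np.concatenate([base + t, base + t[wins] + PAYOUT_DELAY_S])
            )
            dir_l.append(
                np.concatenate([np.full(n, "to_app"), np.full(n_wins, "from_app")])
            )
            val_l.append(
                np.concatenate(
                    [stakes, stakes[wins] * grp_spec.game.payout_multiplier]
                )
            )
    return _records_frame(
        addresses=np.concatenate(addr_l),
        apps=np.concatenate(app_l),
        games=np.concatenate(game_l),
        hashes=np.concatenate(hash_l),
        epochs=np.concatenate(epoch_l),
        directions=np.concatenate(dir_l),
        values=np.concatenate(val_l),
    )


def write_ledger(ledger: pd.DataFrame, path) -> None:
    """Write a transaction ledger CSV in the layout :mod:`betledger.ingest` reads."""
    out = ledger[TX_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)
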