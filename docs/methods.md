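# Methods

betledger analyses betting ledgers from decentralised gambling applications —
casino-style smart contracts where every stake is an on-chain transfer to the
contract and every winning payout a transfer back.  This note records the
models and procedures the package implements, the choices made where the
design was open, and what the synthetic validation does and does not show.

## Bet/payout matching

A ledger holds, per player address, two interleaved streams of transfers:
stakes (`to_app`) and payouts (`from_app`).  Within each (address,
application, game) stream, matching is greedy and chronological: each payout,
taken in time order, is assigned to the earliest not-yet-paid stake placed at
or before it.  This is the FIFO assignment; it is computed by a vectorised
scan (`m_j = min(j+1, min_{i<=j}(c_i + j - i))`, with `c_i` the number of
stakes eligible for payout *i*), and the test suite verifies it against an
exhaustive earliest-first enumeration on every direction pattern of up to 8
transactions.

Conventions, chosen where the on-chain reality is ambiguous:

* **Losses produce no payout transaction.**  Dice-style contracts pay only
  winners, so an unmatched stake is a losing bet with payout 0.  Aggregate
  measures (net loss, percent loss) need only the stake and payout sums, so
  they are insensitive to occasional pairing errors in dense streams.
* **Zero-value stakes are dropped** (they cannot be bets, and percent-loss
  denominators require stake > 0) and logged in the rejects report, never
  silently.  Explicit zero-value *payouts* — some contracts do emit them for
  losses — are tolerated and match normally.
* **No reordering tolerance by default.**  An optional lookahead window
  (seconds) lets a payout match a stake recorded marginally after it, for
  chains where confirmation order can invert; the default of 0 keeps the
  strict rule reproducible.
* **Timestamps are UTC** (block timestamps are UTC by convention) and
  addresses are compared case-insensitively and stored lower-cased.

## Behavioural measures

Eight per-player summaries, the standard player-behaviour-tracking set:

| measure | definition |
|---|---|
| duration (days) | calendar days from first to last bet, inclusive |
| frequency (%) | 100 × active days / duration |
| number of bets | count of stakes |
| bets per day | bets / active days |
| mean bet (ETH) | total wagered / number of bets |
| total wagered (ETH) | sum of stakes, the involvement measure |
| net loss (ETH) | total wagered − total paid out (negative = net win) |
| percent loss | 100 × net loss / total wagered |

Day boundaries are UTC midnights, so a pair of bets at 22:00 and 09:00 the
next morning has duration 2 even though they are under 24 h apart.  An
"active day" is a UTC calendar date with at least one bet.  All temporal
measures use bet-placement times only; payout timestamps never enter.  Fiat
conversion is a presentation-layer multiplication by one static configured
rate; the stored tables are always in ETH.

## Non-human (bot) screening

Algorithmic bettors driven by a shared script produce near-degenerate
behavioural distributions where human populations are heavy-tailed, so a
bot-dominated application-game group separates *in distribution* from every
other group.  The screen computes, for every pair of groups and every
measure, the two-sample Kolmogorov–Smirnov statistic

D = sup_x |F̂_a(x) − F̂_b(x)|

over the pooled sample points (right-continuous ECDFs, ties handled by
evaluating at every pooled value), with the asymptotic p-value
`P(K ≥ √(n_eff) · D)` from the Kolmogorov distribution at effective size
`n_eff = n_a n_b/(n_a+n_b)`.  The matrix is G × G × M (groups × groups ×
measures); p-values are reported uncorrected, since with G(G−1)/2 × M tests
their individual inferential power is limited and the statistic's magnitude
carries the screening signal.

The flagging rule quantifies "stands out against almost all others": group
*g* is flagged iff on some measure the fraction of other groups *h* with
D[g,h] ≥ θ and p[g,h] < α reaches φ.  Defaults θ = 0.35, α = 0.01, φ = 0.75
follow the conventional highlight/significance thresholds for such tables;
φ = 0.75 operationalises "almost all".  A Bonferroni or Benjamini–Hochberg
switch is available for the flag rule only — the reported matrix is always
uncorrected.  Flagged groups are removed wholesale (at the transaction
level) before any cohort analytics; the screen does not attempt to identify
individual bot addresses.

## Cohort statistics

Spending measures are heavily right-skewed, so parametric summaries (mean,
sample SD with n−1) are paired with non-parametric ones (median, IQR as the
75th − 25th percentile with linear interpolation) and a per-measure
one-sample K-S normality statistic: the sample is standardised by its own
mean and SD and compared with Φ.  Because the reference parameters are
estimated from the same sample, the p-value is biased conservative relative
to a Lilliefors-corrected test; the statistic's magnitude is the quantity of
interest and this uncorrected form is what comparable cohort tables report.
Constant or n < 3 measures carry NaN in the K-S columns rather than a
fabricated value.

Relationships between measures use Spearman rank-order correlations
(midranks for ties, t-approximation p-values); entries involving a constant
measure are reported missing, never 0.  Heavy involvement uses the empirical
95:5 split: players ranked descending by total wagered (ties broken by
address for determinism), the top ⌈(1−q)·n⌉ forming the heavy cohort — 518
of 10,357 at the default q = 0.95.  An epsilon guards the ceiling against
binary-float artefacts ((1−0.95)·20 evaluates to 1.0000000000000009).

## Synthetic populations

The generator emulates the structure the analysis assumes, so every stage is
testable without any download.  Its defaults are the package's reference
study conditions and are deliberately modest in scale — large enough for the
screening statistics to be decisive, small enough that full multi-seed
studies run in minutes on one CPU.

**Games.**  Fixed-odds contracts: win probability p, payout multiplier m,
house edge e = 1 − p·m.  A winning bet returns stake·m after a fixed 15 s
next-block lag; losing bets produce no payout record.  Default groups use
p ∈ [0.40, 0.49] and e ∈ [1%, 3%], the realistic range for on-chain dice
games.  `expected_percent_loss` returns 100·e, the value long-run percent
loss converges to.

**Humans.**  Per player: bet count log-normal (median 11, log-SD 1.1, capped
at 10⁴); careers mix a 55% point mass at one day with a log-normal tail
(median 8 days), matching the casual-majority/engaged-tail shape of real
cohorts; within a career, bets fall on uniform days clustered into 1–3
two-hour sessions.  Stakes are **hierarchical log-normal**: each player draws
a typical stake (population median 0.1 ETH, between-player log-SD 1.2) and
individual bets vary around it with within-player log-SD 0.25.  The
hierarchy matters: bettors tend to re-bet similar amounts, so the heavy tail
of spending sits *between* players, and the cohort median of per-player mean
bet then recovers the typical-stake median (the structural bias factor is
exp(0.25²/2) ≈ 1.03).  A single shared log-normal cannot do this — the
per-player mean converges to exp(μ+σ²/2), double the median at σ = 1.2.

**Bots.**  Near-constant stake (0.02 ETH ± 10⁻⁴ relative), near-constant
large bet count (400 ± 5), regular inter-bet intervals over a fixed 120-day
span — the minimal mechanism producing a second, degenerate peak in the
measure distributions.

**Default population.**  Five human groups of 200 players plus one
bot-dominated group (180 bots + 20 humans).  Under these conditions the
screen flags exactly the bot group in ≥ 95% of seeds and flags nothing when
no bot group is present.  All randomness derives from one master seed via
`numpy.random.SeedSequence` spawns; a config reproduces its ledger byte for
byte.

**What the generator does not emulate:** contract jackpot mechanics, gas
fees, exchange-rate dynamics, within-session dependence (chasing losses),
address reuse across applications, and adversarial bots tuned to mimic human
distributions.  Passing tests therefore show the pipeline is correct and the
screen works against script-like bots; they do not show the screen would
detect a deliberately humanised bot population.

## Numerical and validation choices

* Problem sizes for the multi-seed studies (100 power seeds + 50 null seeds
  at ~1,200 players each; 15 players × 10⁴ bets for house-edge recovery;
  n = 5,000 for the seed-robust stake-recovery check) keep full runs in the
  low minutes on a single CPU.
* The two-sample K-S p differs from scipy's asymptotic variant only by
  scipy's finite-n argument correction; statistics agree exactly.
* Verification is dual-route throughout: fast implementations vs naive
  brute-force oracles (exhaustive ECDF sup; exhaustive earliest-first
  matching on all ≤ 8-transaction patterns; midrank-formula Spearman), plus
  money-conservation identities (Σ player net loss = house gross win).
* The n = 500 stake-recovery band (10%) is about one sampling SD of the
  cohort median under the default between-player spread, so it is checked
  under a fixed seed; the seed-robust version of the same calibration is
  checked at n = 5,000 (~2% SE).

## Known limitations

The measures deliberately stop at the classical set: no session detection,
inter-bet intervals, trajectory or variability measures, and no loss-chasing
analysis (those require trusted bet-level pairing, which greedy matching
cannot guarantee in dense interleaved streams).  The screen reports, but
never auto-removes, a second borderline group.  Calldata decoding (bet
targets, odds selections) and live chain harvesting are out of scope; the
package consumes ledgers that have already been exported to CSV.
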