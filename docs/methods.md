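# Methods

## Model

The blossom game is a singleton congestion game with player-specific
payoffs played repeatedly over seasons.  Each of `n` players holds a
fixed preference `m_i = 1 + U`, `U ~ Uniform[0, 2]`, and each season
chooses one day of a `D`-day season or stays home.  A visitor's payoff
is its share of the day's recreational value, `m_i K(d) / n(d)`,
provided that share reaches the capacity threshold `z`; below the
threshold the trip fails outright and costs the disappointment `−c`.
Staying home pays exactly 0.  The externality is purely pecuniary:
crowding erodes utility but never the resource itself.  Travel costs,
weekday/weekend structure and within-season (real-time) information are
deliberately outside the model.

Behaviour is satisficing with stochastic exploration:

1. positive last season → repeat the same choice (even if a better
   option is visible);
2. zero or negative → stay home with probability `1 − p`, otherwise
   explore.  Under **local** knowledge exploration redraws a day with
   probabilities `K(d)/ΣK` (home excluded from the draw).  Under
   **global** knowledge the explorer anticipates every day's utility by
   adding itself to the previous season's disclosed attendance,
   `m_i K(d) / (n(d)+1)`, picks a maximising day if the maximum is
   positive (exact ties uniform at random) and otherwise stays home.

Learning multiplies `p` by `L` after each strictly *negative* season
only.  A run of home seasons therefore costs no decay — the rule that
keeps exploration alive among home-stayers — and every player's `p`
always equals `p_init · L^(#negative seasons)` exactly (this identity is
asserted in the test suite, not merely documented).

Home-stayers re-enter the decision rule every season: utility 0 falls
under "zero or negative".  In global mode the `1 − p / p` split is
applied *before* the best-response computation for home players too,
mirroring the local rule's two-stage structure.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `n_players` | population size | 2000 | reference scale; desk-sized |
| `n_days` `D` | season length (days) | 19 | |
| `K(d)` | flower abundance | `min{d, D+1−d}` | symmetric, interior peak `K(10)=10`, `ΣK=100` |
| `z` | capacity threshold (utility units) | 0.1 | single global value for all players |
| `pref_low/high` | preference bounds | 1, 3 | `m ≥ 1` by construction |
| `disappointment_cost` `c` | failed-visit cost magnitude | 1 | failure utility is `−c` |
| `p_init` | initial exploration probability | 0.5 | |
| `learning_L` | decay multiplier per negative season | 0.5 | `1` = no learning |
| `n_seasons` | horizon | 100 | |
| `turnover_fraction` | per-season replacement rate | 0 | entrants are memory-free |

The cost parameter is stored as a non-negative magnitude `c` with
failure utility `−c`; the sign convention is fixed by the requirement
that a failed visit be strictly worse than staying home.

Bat variant (`BatConfig`): 11 slots, 5 equally sized types, 100 days,
`p_init = 0.5`, `L = 0.5`, uniform initial and exploration slot draws
(slots carry no bloom-like salience).  The per-slot capacity `z` (in
bats) defaults to **60**: with 11 slots that accommodates 500 bats in
pure-type slots (660 ≥ 500) while 2000 bats exceed total capacity, so
both the clean-partitioning and the crowding-out regimes appear.  The
affinity term in the payoff `(z/n)·(n_same/n)` uses the within-slot
*fraction* of own-type company; the algebraically possible count
reading is exposed as `type_term="count"` but is not the default, since
only the fraction reading makes the positivity condition coincide with
"arrivals exceed the waterhole capacity".

## Simulation mechanics and numerics

Within a season: (1) turnover, (2) decisions, (3) payoffs, (4) learning
— all synchronous, so season `t+1` depends only on season `t` outcomes.
Attendance counts include the deciding player itself (a lone visitor
has `n(d) = 1`), and the success comparison is `≥ z` (the exact
boundary succeeds).  Empty days carry NaN mean utility — an explicit
missing marker, never 0.  The changer count includes every kind of
switch (day↔day, day↔home); season 1 is 0 by convention.

Randomness is one master `SeedSequence` spawning three named streams —
`choices`, `turnover`, `ties` — so enabling turnover or tie-breaking
never perturbs the choice stream; equal seeds give bit-identical runs,
including byte-identical CSV output.  Global-mode tie-breaking draws a
uniform score per (player, day) and takes the argmax over the tied set,
which is exactly uniform over ties.

Anticipated attendance in global mode is literally `n(d) + 1` for every
day, with no self-subtraction even on the player's own previous day;
the alternative is available as `anticipate_self_subtract=True` (we
observed no qualitative difference between the two on any headline
diagnostic).

`diagnose` summarises a run over a trailing window (default 20
seasons): *strong convergence* is literally zero changes in the window;
*weak trend* is late-window mean changer fraction divided by the
first-window mean (0/0 reported as 0).

## Equilibrium toolkit

`is_nash` uses strict improvement: a deviation must strictly raise the
deviator's utility (a visitor evaluates home and every other day at
`n(d′)+1`; a home player every day likewise).  `construct_optimal_ne`
fills days greedily in descending preference order (ties shuffled),
placing each player on its own-utility-maximising day among those where
its addition leaves every occupant — itself included — at or above
threshold; the fill criterion is a pluggable policy (`best_day`,
`peak_first`).  `enumerate_equilibria` brute-forces all
`(D+1)^n` assignments below a 10^6 cap and is the independent oracle.

The welfare-optimality of the preference-ordered construction is an
*audited claim*, not an assumption: on the shipped six-player,
three-day fixture the construction yields a Nash equilibrium of welfare
6.4 while exhaustive enumeration finds an equilibrium of welfare 6.6,
so the greedy class is not always welfare-maximal.  The audit reports
both numbers instead of suppressing the gap.  The classic sub-optimal
winner-takes-all pattern is also exhibited concretely (`suboptimal`
fixture: four modest players fill a day exactly to threshold and a
keener player cannot profitably join).

## What the generator emulates — and what passing tests do not show

All inputs are synthetic by design: the game is a typification, not a
calibrated model of any one site.  The default configuration *is* the
study condition set (population 2000, triangular 19-day bloom,
`z = 0.1`, `p = 0.5`, `L = 0.5`, 100 seasons; bats: 500/2000, 11 slots,
5 types, 100 days).  Real visitation data would add features the
generator deliberately lacks — weekday structure, weather shocks,
correlated preferences, travel costs, partial information, behavioural
noise beyond the single exploration probability — so passing tests
demonstrate the internal dynamics of the model class, not predictive
accuracy for any empirical system.

## Emergent-behaviour caveats

Two documented operational expectations are *not* met by the literal
rules, and we report rather than patch them:

- **Full information without learning oscillates through one day at a
  time.**  The anticipated utility `m K(d)/(n(d)+1)` is `m` times an
  agent-independent profile, so every explorer in a season shares the
  same argmax day: the dissatisfied herd floods exactly one day, fails
  there, and floods the next argmax.  Consequently only the flooded and
  the vacated days (2 of 19) flip congestion state between consecutive
  late seasons, even though the oscillation itself is vigorous (late
  changer fraction ≈ 0.4, late mean visitor utility < 0).
- **Full information with learning converges weakly, not strongly, on
  the 100-season horizon.**  Because zero-utility seasons never decay
  `p`, home-stayers whose explorations return home retain `p = p_init`
  indefinitely, and occasional anticipated-positive joins trigger small
  displacement cascades.  At N = 2000 the late change rate is ≈ 1 % per
  season rather than literally zero; the run is visually stable (the
  visiting set and its positive utilities are essentially frozen) but
  an absorbing state is not reached within 100 seasons.  The
  corresponding acceptance assertions are left failing by design; the
  mechanism, not the assertion, is the scientific content.

## Known limitations

- Pure pecuniary externality only; no resource degradation or recovery.
- No mixed-strategy equilibria or equilibrium-selection theory; the
  enumeration oracle is exponential and capped at tiny instances.
- Turnover entrants are always memory-free; socialised entrants (who
  inherit knowledge of history) are not modelled.
- The bat variant models a single waterhole and ignores within-slot
  interval spacing and empirical species mixes.
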