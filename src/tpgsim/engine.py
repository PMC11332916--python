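"""Season loop: synchronous updates, turnover, convergence diagnostics.

Within a season the order of operations is (1) turnover, (2) decisions,
(3) payoffs, (4) learning.  All players decide synchronously from
season-``t`` information only, so equal seeds give bit-identical runs.

Randomness is organised as one master seed spawning three independent
named streams -- ``choices`` (preference draws, initial and exploration
day draws, exploration gates), ``turnover`` (replacement sampling and
entrant state) and ``ties`` (best-response tie-breaks) -- so that e.g.
enabling turnover does not perturb the choice stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .blossom_core import (
    HOME,
    BloomProfile,
    ConfigError,
    GameConfig,
    Player,
    SeasonRecord,
    default_bloom,
    season_payoffs,
)
from .strategies import (
    global_update_many,
    initial_choices,
    learning_update,
    local_update_many,
)

__all__ = [
    "STREAM_NAMES",
    "spawn_streams",
    "RunResult",
    "ConvergenceReport",
    "run_game",
    "apply_turnover",
    "diagnose",
]

STREAM_NAMES = ("choices", "turnover", "ties")


def spawn_streams(seed: int) -> Dict[str, np.random.Generator]:
    """Independent named generators spawned from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
    return {name: np.random.default_rng(child) for name, child in zip(STREAM_NAMES, children)}


@dataclass
class RunResult:
    """Full trace of one blossom-game run.

    ``utilities[t-1, i]`` and ``choices[t-1, i]`` are player ``i``'s
    utility and choice in season ``t`` (under turnover, column ``i``
    tracks the population slot, not a biography).  ``changer_series``
    starts at 0 by convention.
    """

    config: GameConfig
    bloom: BloomProfile
    records: List[SeasonRecord]
    final_players: List[Player]
    changer_series: np.ndarray
    utilities: np.ndarray
    choices: np.ndarray

    @property
    def changer_fraction(self) -> np.ndarray:
        return self.changer_series / self.config.n_players

    def negative_season_counts(self) -> np.ndarray:
        """Per-slot count of strictly negative-utility seasons."""
        return (self.utilities < 0).sum(axis=0)

    def mean_visitor_utility(self) -> np.ndarray:
        """Per-season mean utility over visitors (NaN when nobody visits)."""
        out = np.full(len(self.records), np.nan)
        for t, rec in enumerate(self.records):
            if rec.n_visitors:
                # home players contribute exactly 0 to total welfare
                out[t] = rec.total_welfare / rec.n_visitors
        return out


@dataclass
class ConvergenceReport:
    """Diagnostics over a trailing window of seasons.

    ``strong_converged`` means literally zero choice changes over the
    final window (an absorbing visitor set).  ``weak_trend`` is the mean
    changer fraction over the final window divided by the mean over the
    first window: values well below 1 indicate the decaying change rate
    of weak convergence; 0/0 is reported as 0.
    """

    strong_converged: bool
    weak_trend: float
    mean_utility_late: float
    visitor_pref_mean: float
    home_pref_mean: float
    window: int

    def to_dict(self) -> dict:
        return {
            "strong_converged": bool(self.strong_converged),
            "weak_trend": float(self.weak_trend),
            "mean_utility_late": float(self.mean_utility_late),
            "visitor_pref_mean": float(self.visitor_pref_mean),
            "home_pref_mean": float(self.home_pref_mean),
            "window": int(self.window),
        }


def _draw_entrants(n: int, cfg: GameConfig, bloom: BloomProfile, rng: np.random.Generator):
    """Fresh agents: new preference, p reset to p_init, bloom-weighted day."""
    m = rng.uniform(cfg.pref_low, cfg.pref_high, n)
    p = np.full(n, cfg.p_init)
    choice = initial_choices(bloom, rng, n)
    return m, p, choice


def apply_turnover(
    players: Sequence[Player],
    fraction: float,
    cfg: GameConfig,
    rng: np.random.Generator,
    bloom: Optional[BloomProfile] = None,
) -> List[Player]:
    """Replace ``ceil(fraction * N)`` uniformly chosen players by fresh,
    memory-free entrants; everyone else keeps their state intact."""
    if not 0 <= fraction < 1:
        raise ConfigError(f"turnover fraction must be in [0, 1), got {fraction!r}")
    if bloom is None:
        bloom = default_bloom(cfg.n_days)
    out = list(players)
    n_rep = math.ceil(fraction * len(out))
    if n_rep == 0:
        return out
    idx = rng.choice(len(out), size=n_rep, replace=False)
    m, p, choice = _draw_entrants(n_rep, cfg, bloom, rng)
    for j, i in enumerate(idx):
        out[i] = Player(id=out[i].id, m=float(m[j]), p=float(p[j]), choice=int(choice[j]), last_utility=0.0)
    return out


def run_game(cfg: GameConfig, bloom: Optional[BloomProfile] = None) -> RunResult:
    """Simulate ``cfg.n_seasons`` seasons of the blossom game.

    Season 1 gives every player a bloom-weighted initial day.  Each
    later season applies turnover (if configured), then the information
    mode's decision rule to continuing players, then payoffs, then the
    learning decay of ``p``.
    """
    cfg.validate()
    if bloom is None:
        bloom = default_bloom(cfg.n_days)
    if bloom.n_days != cfg.n_days:
        raise ConfigError(f"bloom has {bloom.n_days} days but config expects {cfg.n_days}")

    streams = spawn_streams(cfg.seed)
    rng_c, rng_t, rng_tie = streams["choices"], streams["turnover"], streams["ties"]

    n, n_seasons = cfg.n_players, cfg.n_seasons
    m = rng_c.uniform(cfg.pref_low, cfg.pref_high, n)
    p = np.full(n, cfg.p_init)
    choice = initial_choices(bloom, rng_c, n)
    last_util = np.zeros(n)
    last_attendance: Optional[np.ndarray] = None

    records: List[SeasonRecord] = []
    changer_series = np.zeros(n_seasons, dtype=int)
    utilities = np.empty((n_seasons, n))
    choices_hist = np.empty((n_seasons, n), dtype=int)

    n_rep = math.ceil(cfg.turnover_fraction * n)
    for t in range(1, n_seasons + 1):
        if t > 1:
            cont = np.ones(n, dtype=bool)
            if n_rep:
                idx = rng_t.choice(n, size=n_rep, replace=False)
                m[idx], p[idx], choice[idx] = _draw_entrants(n_rep, cfg, bloom, rng_t)
                last_util[idx] = 0.0
                cont[idx] = False
            if cfg.info_mode == "local":
                choice[cont] = local_update_many(
                    last_util[cont], choice[cont], p[cont], bloom, rng_c
                )
            else:
                choice[cont] = global_update_many(
                    last_util[cont],
                    choice[cont],
                    p[cont],
                    m[cont],
                    last_attendance,
                    bloom,
                    cfg.z,
                    cfg.disappointment_cost,
                    rng_c,
                    rng_tie,
                    self_subtract=cfg.anticipate_self_subtract,
                )
        prev = choices_hist[t - 2] if t > 1 else None
        util, record = season_payoffs(
            choice, m, bloom, cfg, season=t, previous_choices=prev
        )
        utilities[t - 1] = util
        choices_hist[t - 1] = choice
        records.append(record)
        changer_series[t - 1] = record.changers
        p = learning_update(p, util, cfg.learning_L)
        last_util = util
        last_attendance = record.attendance

    final_players = [
        Player(id=i, m=float(m[i]), p=float(p[i]), choice=int(choice[i]), last_utility=float(last_util[i]))
        for i in range(n)
    ]
    return RunResult(
        config=cfg,
        bloom=bloom,
        records=records,
        final_players=final_players,
        changer_series=changer_series,
        utilities=utilities,
        choices=choices_hist,
    )


def diagnose(result: RunResult, window: int = 20) -> ConvergenceReport:
    """Convergence diagnostics over the trailing ``window`` seasons."""
    n_seasons = len(result.records)
    if not 0 < window < n_seasons:
        raise ValueError(f"window must be in 1..{n_seasons - 1}, got {window}")
    frac = result.changer_fraction
    late, early = frac[-window:], frac[:window]
    strong = bool((result.changer_series[-window:] == 0).all())
    if early.mean() > 0:
        weak_trend = float(late.mean() / early.mean())
    else:
        weak_trend = 0.0 if late.mean() == 0 else float("inf")

    mvu = result.mean_visitor_utility()[-window:]
    mean_utility_late = float(np.nanmean(mvu)) if not np.all(np.isnan(mvu)) else float("nan")

    final_choice = result.choices[-1]
    m = np.array([pl.m for pl in result.final_players])
    visitors = final_choice != HOME
    visitor_pref = float(m[visitors].mean()) if visitors.any() else float("nan")
    home_pref = float(m[~visitors].mean()) if (~visitors).any() else float("nan")
    return ConvergenceReport(
        strong_converged=strong,
        weak_trend=weak_trend,
        mean_utility_late=mean_utility_late,
        visitor_pref_mean=visitor_pref,
        home_pref_mean=home_pref,
        window=window,
    )
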