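"""Waterhole variant: typed bats with same-type affinity.

Bats choose a nightly time slot (minutes-after-sunset bins) at a single
waterhole, or stay at the roost (utility 0).  The waterhole supports at
most ``z`` bats per slot; a bat in a slot with ``n(d)`` attendees of
which ``n_same`` share its type receives ``(z / n(d)) * (n_same / n(d))``
when that quantity is at least 1, and otherwise wastes energy ``-c``.
The same-type factor is the within-slot *fraction* of the bat's own
type, so mixed slots are strictly worse for the minority -- the
homophily pressure that drives the emergent one-type-per-slot
partitioning.  (A literal count reading of the affinity term is exposed
via ``type_term="count"``.)

Information is local and learning is multiplicative, exactly as in the
blossom game; exploration redraws a slot uniformly (slots carry no
bloom-like salience).  Water is refilled between days, so payoffs are
independent across days given choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .blossom_core import ConfigError, SeasonRecord
from .engine import spawn_streams
from .strategies import learning_update

__all__ = [
    "ROOST",
    "BatConfig",
    "Bat",
    "BatRunResult",
    "bat_utility",
    "run_bat_game",
    "slot_dominance",
]

#: Distinguished "stay at the roost" choice.  Slots are ``1..n_slots``.
ROOST = 0

TYPE_TERMS = ("fraction", "count")


@dataclass
class BatConfig:
    """Parameters of the waterhole game.

    ``z`` is the waterhole capacity in bats per slot.  The default 60
    is chosen so that the 11 slots can hold 500 bats in pure-type slots
    (11 * 60 = 660) while 2000 bats exceed total capacity, producing
    both the partitioning and the crowding-out regimes.
    """

    n_bats: int = 500
    n_slots: int = 11
    n_types: int = 5
    type_proportions: Optional[Sequence[float]] = None
    z: float = 60.0
    c: float = 1.0
    p_init: float = 0.5
    L: float = 0.5
    n_days: int = 100
    seed: int = 0
    type_term: str = "fraction"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_bats", "n_slots", "n_types", "n_days"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.n_types > self.n_bats:
            raise ConfigError("n_types cannot exceed n_bats")
        if not self.z > 0:
            raise ConfigError(f"z must be positive, got {self.z!r}")
        if self.c < 0:
            raise ConfigError(f"c must be non-negative, got {self.c!r}")
        if not 0 < self.p_init <= 1:
            raise ConfigError(f"p_init must be in (0, 1], got {self.p_init!r}")
        if not 0 < self.L <= 1:
            raise ConfigError(f"L must be in (0, 1], got {self.L!r}")
        if self.type_term not in TYPE_TERMS:
            raise ConfigError(f"type_term must be one of {TYPE_TERMS}, got {self.type_term!r}")
        if self.type_proportions is not None:
            props = np.asarray(self.type_proportions, dtype=float)
            if props.size != self.n_types:
                raise ConfigError("type_proportions must have one entry per type")
            if (props < 0).any() or not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
                raise ConfigError("type_proportions must be non-negative and sum to 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")


@dataclass
class Bat:
    """One bat: type label (1-based), exploration probability, current
    slot choice (ROOST = 0) and last utility."""

    id: int
    type: int
    p: float
    choice: int = ROOST
    last_utility: float = 0.0


@dataclass
class BatRunResult:
    """Trace of one waterhole run.

    ``type_tallies[t-1, s-1, k-1]`` counts type-``k`` bats in slot ``s``
    on day ``t``.
    """

    config: BatConfig
    records: List[SeasonRecord]
    final_bats: List[Bat]
    changer_series: np.ndarray
    utilities: np.ndarray
    choices: np.ndarray
    type_tallies: np.ndarray

    @property
    def changer_fraction(self) -> np.ndarray:
        return self.changer_series / self.config.n_bats

    def roost_series(self) -> np.ndarray:
        return np.array([rec.home_count for rec in self.records])


def type_counts(cfg: BatConfig) -> np.ndarray:
    """Integer head-counts per type (largest-remainder apportionment of
    the configured proportions; default uniform)."""
    props = (
        np.full(cfg.n_types, 1.0 / cfg.n_types)
        if cfg.type_proportions is None
        else np.asarray(cfg.type_proportions, dtype=float)
    )
    raw = props * cfg.n_bats
    counts = np.floor(raw).astype(int)
    short = cfg.n_bats - counts.sum()
    if short:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def bat_utility(n_d: int, n_same: int, z: float, c: float, type_term: str = "fraction") -> float:
    """Utility of a bat in a slot with ``n_d`` attendees, ``n_same`` of
    its own type (itself included).

    The value ``(z/n_d) * (n_same/n_d)`` (fraction reading) must reach 1
    for the visit to pay off; otherwise the bat wastes energy ``-c``.
    Staying at the roost yields 0.
    """
    if n_d < 1:
        raise ValueError("n_d must be >= 1: the bat counts itself")
    if not 1 <= n_same <= n_d:
        raise ValueError(f"n_same must be in 1..n_d, got n_same={n_same}, n_d={n_d}")
    if type_term == "fraction":
        val = (z / n_d) * (n_same / n_d)
    elif type_term == "count":
        val = (z / n_d) * n_same
    else:
        raise ValueError(f"type_term must be one of {TYPE_TERMS}, got {type_term!r}")
    return float(val) if val >= 1 else -float(c)


def _day_payoffs(choice: np.ndarray, types: np.ndarray, cfg: BatConfig):
    """Vectorised one-day payoffs.  Returns (utilities, attendance,
    roost_count, slot-by-type tally)."""
    att_full = np.bincount(choice, minlength=cfg.n_slots + 1)
    tally = np.zeros((cfg.n_slots, cfg.n_types), dtype=int)
    visiting = choice != ROOST
    np.add.at(tally, (choice[visiting] - 1, types[visiting] - 1), 1)

    util = np.zeros(choice.size)
    if visiting.any():
        n_d = att_full[choice[visiting]].astype(float)
        n_same = tally[choice[visiting] - 1, types[visiting] - 1].astype(float)
        if cfg.type_term == "fraction":
            val = (cfg.z / n_d) * (n_same / n_d)
        else:
            val = (cfg.z / n_d) * n_same
        util[visiting] = np.where(val >= 1, val, -cfg.c)
    return util, att_full[1:].copy(), int(att_full[ROOST]), tally


def run_bat_game(cfg: BatConfig) -> BatRunResult:
    """Simulate ``cfg.n_days`` days of the waterhole game.

    Day 1 assigns every bat a uniform random slot (never ROOST).  On
    later days a bat with positive utility repeats its slot; otherwise
    it roosts with probability ``1 - p`` and redraws a uniform slot with
    probability ``p``.  ``p`` decays by ``L`` after strictly negative
    days only.
    """
    cfg.validate()
    rng = spawn_streams(cfg.seed)["choices"]

    n = cfg.n_bats
    types = np.repeat(np.arange(1, cfg.n_types + 1), type_counts(cfg))
    p = np.full(n, cfg.p_init)
    choice = rng.integers(1, cfg.n_slots + 1, size=n)
    last_util = np.zeros(n)

    records: List[SeasonRecord] = []
    changer_series = np.zeros(cfg.n_days, dtype=int)
    utilities = np.empty((cfg.n_days, n))
    choices_hist = np.empty((cfg.n_days, n), dtype=int)
    tallies = np.zeros((cfg.n_days, cfg.n_slots, cfg.n_types), dtype=int)

    for t in range(1, cfg.n_days + 1):
        if t > 1:
            unsat = last_util <= 0
            k = int(unsat.sum())
            if k:
                explores = rng.random(k) < p[unsat]
                new = np.full(k, ROOST, dtype=int)
                n_exp = int(explores.sum())
                if n_exp:
                    new[explores] = rng.integers(1, cfg.n_slots + 1, size=n_exp)
                choice = choice.copy()
                choice[unsat] = new

        util, attendance, roost_count, tally = _day_payoffs(choice, types, cfg)
        sums = np.zeros(cfg.n_slots + 1)
        np.add.at(sums, choice, util)
        mean_by_slot = np.full(cfg.n_slots, np.nan)
        occ = attendance > 0
        mean_by_slot[occ] = sums[1:][occ] / attendance[occ]
        changers = 0 if t == 1 else int(np.count_nonzero(choice != choices_hist[t - 2]))
        records.append(
            SeasonRecord(
                season=t,
                attendance=attendance,
                home_count=roost_count,
                mean_utility_by_day=mean_by_slot,
                changers=changers,
                total_welfare=float(util.sum()),
            )
        )
        utilities[t - 1] = util
        choices_hist[t - 1] = choice
        tallies[t - 1] = tally
        changer_series[t - 1] = changers
        p = learning_update(p, util, cfg.L)
        last_util = util

    final_bats = [
        Bat(id=i, type=int(types[i]), p=float(p[i]), choice=int(choice[i]), last_utility=float(last_util[i]))
        for i in range(n)
    ]
    return BatRunResult(
        config=cfg,
        records=records,
        final_bats=final_bats,
        changer_series=changer_series,
        utilities=utilities,
        choices=choices_hist,
        type_tallies=tallies,
    )


def slot_dominance(tally: Union[np.ndarray, pd.DataFrame]) -> pd.DataFrame:
    """Per-slot type-dominance shares from a slot-by-type tally.

    Returns a DataFrame indexed by 1-based slot with columns
    ``attendance``, ``dominant_share`` (largest single-type share) and
    ``top2_share``; empty slots carry NaN shares.
    """
    arr = np.asarray(tally, dtype=float)
    if arr.ndim != 2:
        raise ValueError("tally must be a 2-d slots-by-types array")
    total = arr.sum(axis=1)
    sorted_desc = -np.sort(-arr, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dom = np.where(total > 0, sorted_desc[:, 0] / total, np.nan)
        if arr.shape[1] >= 2:
            top2 = np.where(total > 0, (sorted_desc[:, 0] + sorted_desc[:, 1]) / total, np.nan)
        else:
            top2 = dom
    return pd.DataFrame(
        {
            "attendance": total.astype(int),
            "dominant_share": dom,
            "top2_share": top2,
        },
        index=pd.RangeIndex(1, arr.shape[0] + 1, name="slot"),
    )
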