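"""Domain types and single-season payoff rules for the blossom game.

The blossom game is a temporal partitioning congestion game (TPG): ``n``
players each choose one day of a short flowering season -- or stay home
-- and everyone who picked the same day shares that day's recreational
value.  A visitor with nature preference ``m`` on day ``d`` attended by
``n(d)`` people receives the share ``m * K(d) / n(d)``, where ``K(d)``
is the flower abundance on day ``d``.  When the share falls below the
capacity threshold ``z`` the visit fails and the visitor instead pays a
disappointment cost ``c`` (utility ``-c``).  Staying home is always
worth exactly zero, which is what makes congestion a genuine dilemma: a
failed trip is strictly worse than not going at all.

The threshold is agent-specific through ``m``: on the same crowded day a
player who values nature highly may still clear ``z`` while a lukewarm
player fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "HOME",
    "ConfigError",
    "GameConfig",
    "BloomProfile",
    "Player",
    "SeasonRecord",
    "default_bloom",
    "day_utility",
    "home_utility",
    "season_payoffs",
]

#: Distinguished "stay at home" choice.  Days are numbered ``1..n_days``.
HOME = 0

INFO_MODES = ("local", "global")


class ConfigError(ValueError):
    """Raised when a configuration violates a model constraint."""


@dataclass
class GameConfig:
    """All run parameters for one blossom-game simulation.

    Defaults are the reference study conditions: 2000 players over a
    19-day season, capacity threshold ``z = 0.1``, preferences drawn
    uniformly from ``[1, 3]``, disappointment cost 1, initial
    exploration probability 0.5, learning multiplier 0.5, 100 seasons.

    Parameters
    ----------
    n_players : int
        Population size ``n``.
    n_days : int
        Length of the blossom season.
    z : float
        Capacity threshold: a visit succeeds iff ``m*K(d)/n(d) >= z``.
    pref_low, pref_high : float
        Bounds of the uniform preference draw; ``pref_low >= 1``.
    disappointment_cost : float
        Non-negative magnitude ``c``; a failed visit yields ``-c``.
    p_init : float
        Initial exploration probability ``p`` in ``(0, 1]``.
    learning_L : float
        Multiplier applied to ``p`` after each strictly negative season;
        ``L = 1`` disables learning.
    info_mode : {"local", "global"}
        Whether players see only their own day's crowding ("local") or
        the full previous-season attendance vector ("global").
    n_seasons : int
        Number of seasons to simulate.
    turnover_fraction : float
        Fraction of the population replaced by memory-free entrants at
        the start of every season after the first.
    seed : int
        Master seed for all random streams.
    anticipate_self_subtract : bool
        In global mode, whether a player removes itself from its own
        previous day's attendance before anticipating utilities.  The
        default (False) is the literal "add itself to the last known
        attendance" rule.
    """

    n_players: int = 2000
    n_days: int = 19
    z: float = 0.1
    pref_low: float = 1.0
    pref_high: float = 3.0
    disappointment_cost: float = 1.0
    p_init: float = 0.5
    learning_L: float = 0.5
    info_mode: str = "local"
    n_seasons: int = 100
    turnover_fraction: float = 0.0
    seed: int = 0
    anticipate_self_subtract: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_players, (int, np.integer)) or self.n_players < 1:
            raise ConfigError(f"n_players must be a positive integer, got {self.n_players!r}")
        if not isinstance(self.n_days, (int, np.integer)) or self.n_days < 1:
            raise ConfigError(f"n_days must be a positive integer, got {self.n_days!r}")
        if not self.z > 0:
            raise ConfigError(f"z must be positive, got {self.z!r}")
        if self.pref_low < 1:
            raise ConfigError(f"pref_low must be >= 1 (preferences satisfy m >= 1), got {self.pref_low!r}")
        if self.pref_high < self.pref_low:
            raise ConfigError("pref_high must be >= pref_low")
        if self.disappointment_cost < 0:
            raise ConfigError(f"disappointment_cost must be non-negative, got {self.disappointment_cost!r}")
        if not 0 < self.p_init <= 1:
            raise ConfigError(f"p_init must be in (0, 1], got {self.p_init!r}")
        if not 0 < self.learning_L <= 1:
            raise ConfigError(f"learning_L must be in (0, 1], got {self.learning_L!r}")
        if self.info_mode not in INFO_MODES:
            raise ConfigError(f"info_mode must be one of {INFO_MODES}, got {self.info_mode!r}")
        if not isinstance(self.n_seasons, (int, np.integer)) or self.n_seasons < 1:
            raise ConfigError(f"n_seasons must be a positive integer, got {self.n_seasons!r}")
        if not 0 <= self.turnover_fraction < 1:
            raise ConfigError(f"turnover_fraction must be in [0, 1), got {self.turnover_fraction!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")


@dataclass
class BloomProfile:
    """Per-day flower abundance ``K(d)`` over the blossom season.

    ``k[d-1]`` is the abundance on day ``d``; all entries are positive.
    """

    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        if self.k.ndim != 1 or self.k.size < 1:
            raise ConfigError("bloom profile must be a non-empty 1-d vector")
        if not np.all(self.k > 0):
            raise ConfigError("bloom profile entries must all be positive")

    @property
    def n_days(self) -> int:
        return int(self.k.size)

    @property
    def weights(self) -> np.ndarray:
        """Normalised profile ``K(d) / sum(K)`` used for weighted day draws."""
        return self.k / self.k.sum()

    def value(self, day: int) -> float:
        """Abundance ``K(day)`` for a 1-based day index."""
        if not 1 <= day <= self.n_days:
            raise ValueError(f"day must be in 1..{self.n_days}, got {day}")
        return float(self.k[day - 1])


def default_bloom(n_days: int) -> BloomProfile:
    """Symmetric triangular profile ``K(i) = min(i, n_days + 1 - i)``.

    For the reference 19-day season this peaks at ``K(10) = 10`` on the
    mid-season day and sums to 100.
    """
    if not isinstance(n_days, (int, np.integer)) or n_days < 1:
        raise ConfigError(f"n_days must be a positive integer, got {n_days!r}")
    i = np.arange(1, n_days + 1)
    return BloomProfile(np.minimum(i, n_days + 1 - i).astype(float))


@dataclass
class Player:
    """One agent: preference ``m``, exploration probability ``p``, and
    the choice / utility from the most recent season."""

    id: int
    m: float
    p: float
    choice: int = HOME
    last_utility: float = 0.0


@dataclass
class SeasonRecord:
    """Aggregate outcome of one season.

    ``attendance[d-1]`` is the visitor count on day ``d``;
    ``mean_utility_by_day`` holds NaN for empty days (mean utility is
    undefined there, never zero).  Conservation:
    ``sum(attendance) + home_count == n_players``.
    """

    season: int
    attendance: np.ndarray
    home_count: int
    mean_utility_by_day: np.ndarray
    changers: int
    total_welfare: float

    @property
    def n_visitors(self) -> int:
        return int(self.attendance.sum())

    def check_conservation(self, n_players: int) -> bool:
        return self.n_visitors + self.home_count == n_players


def day_utility(m: float, k_d: float, n_d: int, z: float, c: float) -> float:
    """Utility of a visitor with preference ``m`` on a day of abundance
    ``k_d`` attended by ``n_d`` players (the visitor included).

    Returns ``m*k_d/n_d`` when that share clears the threshold ``z``,
    otherwise ``-c``.  ``n_d = 0`` is a contract violation: a chosen day
    always has at least one attendee.
    """
    if n_d < 1:
        raise ValueError("n_d must be >= 1: a chosen day counts the deciding player itself")
    if k_d <= 0:
        raise ValueError(f"k_d must be positive, got {k_d!r}")
    share = m * k_d / n_d
    return float(share) if share >= z else -float(c)


def home_utility() -> float:
    """Staying home always yields exactly zero."""
    return 0.0


def _pref_array(players: Union[Sequence[Player], np.ndarray]) -> np.ndarray:
    """Preference vector from a Player list, an array, or anything with ``.m``."""
    if isinstance(players, np.ndarray):
        return np.asarray(players, dtype=float)
    m = getattr(players, "m", None)
    if m is not None:
        return np.asarray(m, dtype=float)
    return np.array([pl.m for pl in players], dtype=float)


def season_payoffs(
    choices: Sequence[int],
    players: Union[Sequence[Player], np.ndarray],
    bloom: BloomProfile,
    cfg: GameConfig,
    *,
    season: int = 1,
    previous_choices: Optional[Sequence[int]] = None,
):
    """Compute every player's utility for one season of choices.

    Parameters
    ----------
    choices : array of int
        Per-player choice, ``HOME`` (0) or a day in ``1..n_days``.
    players : list of Player or preference array
        Only the preferences ``m`` are consulted.
    season : int
        Season index stored on the record.
    previous_choices : array of int, optional
        Previous season's choices; when given, the record's ``changers``
        counts players whose choice differs (day<->day and HOME<->day
        alike).

    Returns
    -------
    (utilities, record) : (ndarray, SeasonRecord)
    """
    choices = np.asarray(choices, dtype=int)
    m = _pref_array(players)
    if choices.shape != m.shape:
        raise ValueError(f"got {choices.size} choices for {m.size} players")
    if choices.size and (choices.min() < HOME or choices.max() > bloom.n_days):
        bad = choices[(choices < HOME) | (choices > bloom.n_days)][0]
        raise ValueError(f"choice {bad} outside HOME(0)..{bloom.n_days}")

    att_full = np.bincount(choices, minlength=bloom.n_days + 1)
    home_count = int(att_full[HOME])
    attendance = att_full[1:].copy()

    utilities = np.zeros(choices.size, dtype=float)
    visiting = choices != HOME
    if visiting.any():
        vdays = choices[visiting]
        share = m[visiting] * bloom.k[vdays - 1] / att_full[vdays]
        utilities[visiting] = np.where(share >= cfg.z, share, -cfg.disappointment_cost)

    # per-day mean utility; empty days keep an explicit NaN marker
    sums = np.zeros(bloom.n_days + 1, dtype=float)
    np.add.at(sums, choices, utilities)
    mean_by_day = np.full(bloom.n_days, np.nan)
    occupied = attendance > 0
    mean_by_day[occupied] = sums[1:][occupied] / attendance[occupied]

    if previous_choices is None:
        changers = 0
    else:
        previous_choices = np.asarray(previous_choices, dtype=int)
        changers = int(np.count_nonzero(choices != previous_choices))

    record = SeasonRecord(
        season=season,
        attendance=attendance,
        home_count=home_count,
        mean_utility_by_day=mean_by_day,
        changers=changers,
        total_welfare=float(utilities.sum()),
    )
    return utilities, record
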