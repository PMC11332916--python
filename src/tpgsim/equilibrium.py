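"""Static Nash-equilibrium analysis of the blossom game.

The blossom game is a singleton congestion game with player-specific
payoffs.  This module verifies pure-strategy Nash equilibria (NE),
constructs the greedy preference-ordered NE, exhaustively enumerates
all NEs on tiny instances (the independent oracle), and audits whether
the constructed NE attains maximal welfare among the enumerated ones.

Deviations are strict: a player breaks an equilibrium only if some
unilateral move *strictly* improves its utility.  A visitor evaluates
staying home (0) and every other day at attendance ``n(d') + 1``; a
home player evaluates every day the same way.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .blossom_core import (
    HOME,
    BloomProfile,
    GameConfig,
    Player,
    _pref_array,
    day_utility,
)

__all__ = [
    "Assignment",
    "NashWitness",
    "EnumerationCapError",
    "assignment_utilities",
    "is_nash",
    "construct_optimal_ne",
    "enumerate_equilibria",
    "optimality_audit",
]


class EnumerationCapError(ValueError):
    """Raised when an instance is too large for exhaustive enumeration."""


@dataclass
class Assignment:
    """A static players -> (day | HOME) map."""

    choices: np.ndarray

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=int)

    def attendance(self, n_days: int) -> np.ndarray:
        return np.bincount(self.choices, minlength=n_days + 1)[1:]

    @property
    def n_players(self) -> int:
        return int(self.choices.size)


@dataclass
class NashWitness:
    """A profitable unilateral deviation disproving equilibrium."""

    player: int
    current_choice: int
    target_choice: int
    current_utility: float
    target_utility: float


def assignment_utilities(
    a: Assignment,
    players: Union[Sequence[Player], np.ndarray],
    bloom: BloomProfile,
    cfg: GameConfig,
) -> np.ndarray:
    """Per-player utilities under a static assignment."""
    m = _pref_array(players)
    att_full = np.bincount(a.choices, minlength=bloom.n_days + 1)
    util = np.zeros(m.size)
    visiting = a.choices != HOME
    if visiting.any():
        vdays = a.choices[visiting]
        share = m[visiting] * bloom.k[vdays - 1] / att_full[vdays]
        util[visiting] = np.where(share >= cfg.z, share, -cfg.disappointment_cost)
    return util


def is_nash(
    a: Assignment,
    players: Union[Sequence[Player], np.ndarray],
    bloom: BloomProfile,
    cfg: GameConfig,
) -> Tuple[bool, Optional[NashWitness]]:
    """Check whether no player strictly gains from a unilateral move.

    Returns ``(True, None)`` or ``(False, witness)`` with a concrete
    deviating player and target.
    """
    m = _pref_array(players)
    util = assignment_utilities(a, players, bloom, cfg)
    att = a.attendance(bloom.n_days)
    for i in range(m.size):
        cur = util[i]
        # staying home is a deviation for visitors
        if a.choices[i] != HOME and 0.0 > cur:
            return False, NashWitness(i, int(a.choices[i]), HOME, float(cur), 0.0)
        for d in range(1, bloom.n_days + 1):
            if d == a.choices[i]:
                continue
            dev = day_utility(m[i], bloom.k[d - 1], int(att[d - 1]) + 1, cfg.z, cfg.disappointment_cost)
            if dev > cur:
                return False, NashWitness(i, int(a.choices[i]), d, float(cur), float(dev))
    return True, None


def _best_day_policy(feasible: np.ndarray, own_util: np.ndarray, bloom: BloomProfile) -> int:
    """Default fill policy: the feasible day maximising own utility."""
    cand = np.flatnonzero(feasible)
    return int(cand[np.argmax(own_util[cand])]) + 1


def _peak_first_policy(feasible: np.ndarray, own_util: np.ndarray, bloom: BloomProfile) -> int:
    """Alternative fill policy: the feasible day with most flowers."""
    cand = np.flatnonzero(feasible)
    return int(cand[np.argmax(bloom.k[cand])]) + 1


FILL_POLICIES: dict = {"best_day": _best_day_policy, "peak_first": _peak_first_policy}


def construct_optimal_ne(
    players: Union[Sequence[Player], np.ndarray],
    bloom: BloomProfile,
    cfg: GameConfig,
    rng: Optional[np.random.Generator] = None,
    fill_policy: Union[str, Callable] = "best_day",
) -> Assignment:
    """Greedy preference-ordered equilibrium construction.

    Players are processed in descending preference ``m`` (ties
    shuffled); each is placed on the fill policy's choice among days
    where its addition leaves every current occupant -- and itself --
    at or above threshold.  A player with no feasible day stays HOME.
    """
    m = _pref_array(players)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    policy = FILL_POLICIES[fill_policy] if isinstance(fill_policy, str) else fill_policy

    # descending m with randomised ties: shuffle first, stable sort second
    perm = rng.permutation(m.size)
    order = perm[np.argsort(-m[perm], kind="stable")]

    choices = np.full(m.size, HOME, dtype=int)
    att = np.zeros(bloom.n_days, dtype=int)
    min_m = np.full(bloom.n_days, np.inf)  # weakest occupant per day
    for i in order:
        new_n = att + 1
        own = m[i] * bloom.k / new_n
        weakest = np.minimum(min_m, m[i])
        feasible = (own >= cfg.z) & (weakest * bloom.k / new_n >= cfg.z)
        if feasible.any():
            day = policy(feasible, own, bloom)
            choices[i] = day
            att[day - 1] += 1
            min_m[day - 1] = min(min_m[day - 1], m[i])
    return Assignment(choices)


def enumerate_equilibria(
    players: Union[Sequence[Player], np.ndarray],
    bloom: BloomProfile,
    cfg: GameConfig,
    cap: int = 10**6,
) -> List[Tuple[Assignment, float]]:
    """Exhaustively test every assignment; the brute-force NE oracle.

    Returns all pure-strategy NEs with their total welfare.  Instances
    with more than ``cap`` assignments are rejected outright.
    """
    m = _pref_array(players)
    n_opts = bloom.n_days + 1
    total = n_opts ** m.size
    if total > cap:
        raise EnumerationCapError(
            f"{n_opts}^{m.size} = {total} assignments exceed the enumeration cap {cap}"
        )
    out: List[Tuple[Assignment, float]] = []
    for combo in itertools.product(range(n_opts), repeat=m.size):
        a = Assignment(np.array(combo, dtype=int))
        ok, _ = is_nash(a, m, bloom, cfg)
        if ok:
            welfare = float(assignment_utilities(a, m, bloom, cfg).sum())
            out.append((a, welfare))
    return out


def optimality_audit(
    players: Union[Sequence[Player], np.ndarray],
    bloom: BloomProfile,
    cfg: GameConfig,
    cap: int = 10**6,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Empirical audit of the greedy construction on one instance.

    Reports whether the constructed assignment is an NE, its welfare,
    the maximal welfare among all enumerated NEs, and whether the two
    agree -- i.e. whether the preference-ordered fill really is welfare
    optimal on this instance.  Discrepancies are reported, not hidden.
    """
    m = _pref_array(players)
    constructed = construct_optimal_ne(m, bloom, cfg, rng=rng)
    ok, witness = is_nash(constructed, m, bloom, cfg)
    welfare = float(assignment_utilities(constructed, m, bloom, cfg).sum())
    all_ne = enumerate_equilibria(m, bloom, cfg, cap=cap)
    max_welfare = max(w for _, w in all_ne) if all_ne else float("nan")
    return {
        "constructed_is_nash": bool(ok),
        "witness": witness,
        "constructed_welfare": welfare,
        "n_equilibria": len(all_ne),
        "max_welfare": max_welfare,
        "attains_max_welfare": bool(all_ne and ok and np.isclose(welfare, max_welfare)),
        "constructed": constructed,
        "equilibria": all_ne,
    }
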