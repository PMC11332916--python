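"""Decision rules: initial choice, local/global season updates, learning.

Both information conditions share the same skeleton (satisficing plus a
two-stage exploration rule):

* a player whose last utility was strictly positive repeats its choice;
* otherwise it stays home with probability ``1 - p`` and explores with
  probability ``p``.  Note that home-stayers (utility exactly zero)
  re-apply this rule every season -- that is what keeps exploration
  alive.

The conditions differ only in what "explore" means.  With local
knowledge the player redraws a day with bloom-dependent weights (home
excluded from the draw).  With global knowledge it anticipates every
day's utility by adding itself to the last observed attendance and best
responds, falling back to home if every day looks negative; exact ties
are broken uniformly at random.

Learning multiplies ``p`` by ``L`` after each strictly *negative*
season.  Zero-utility (home) seasons never decay ``p``, so a long home
spell costs only the one multiplication that preceded it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .blossom_core import HOME, BloomProfile

__all__ = [
    "DecisionContext",
    "initial_choice",
    "initial_choices",
    "local_update",
    "local_update_many",
    "global_update",
    "global_update_many",
    "anticipated_utilities",
    "learning_update",
]


@dataclass
class DecisionContext:
    """State visible to one player when deciding next season's choice.

    ``last_attendance`` is present only in global mode (the previous
    season's per-day visitor counts disclosed by the planner).
    """

    last_utility: float
    last_choice: int
    p: float
    bloom: BloomProfile
    rng: np.random.Generator
    last_attendance: Optional[np.ndarray] = None


def initial_choices(bloom: BloomProfile, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` first-season days with probability ``K(d)/sum(K)``.

    The initial draw never returns HOME.
    """
    return rng.choice(bloom.n_days, size=n, p=bloom.weights) + 1


def initial_choice(bloom: BloomProfile, rng: np.random.Generator) -> int:
    """Single bloom-weighted first-season day (never HOME)."""
    return int(initial_choices(bloom, rng, 1)[0])


def learning_update(
    p: Union[float, np.ndarray], last_utility: Union[float, np.ndarray], L: float
) -> Union[float, np.ndarray]:
    """Multiply ``p`` by ``L`` iff the last utility was strictly negative."""
    scalar = np.isscalar(p)
    p_arr = np.asarray(p, dtype=float)
    out = np.where(np.asarray(last_utility, dtype=float) < 0, p_arr * L, p_arr)
    return float(out) if scalar else out


def local_update_many(
    last_utility: np.ndarray,
    last_choice: np.ndarray,
    p: np.ndarray,
    bloom: BloomProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised local-knowledge rule for a block of players."""
    out = np.asarray(last_choice, dtype=int).copy()
    unsat = np.asarray(last_utility, dtype=float) <= 0
    k = int(unsat.sum())
    if k == 0:
        return out
    explores = rng.random(k) < np.asarray(p, dtype=float)[unsat]
    new = np.full(k, HOME, dtype=int)
    n_exp = int(explores.sum())
    if n_exp:
        new[explores] = initial_choices(bloom, rng, n_exp)
    out[unsat] = new
    return out


def local_update(ctx: DecisionContext) -> int:
    """Local-knowledge rule for a single player (see module docstring)."""
    out = local_update_many(
        np.array([ctx.last_utility]),
        np.array([ctx.last_choice]),
        np.array([ctx.p]),
        ctx.bloom,
        ctx.rng,
    )
    return int(out[0])


def anticipated_utilities(
    m: float,
    last_attendance: np.ndarray,
    bloom: BloomProfile,
    z: float,
    c: float,
) -> np.ndarray:
    """Per-day utility a player of preference ``m`` anticipates by adding
    itself to the last observed attendance (``n(d) + 1``)."""
    share = m * bloom.k / (np.asarray(last_attendance, dtype=float) + 1.0)
    return np.where(share >= z, share, -c)


def global_update_many(
    last_utility: np.ndarray,
    last_choice: np.ndarray,
    p: np.ndarray,
    m: np.ndarray,
    last_attendance: np.ndarray,
    bloom: BloomProfile,
    z: float,
    c: float,
    rng: np.random.Generator,
    tie_rng: Optional[np.random.Generator] = None,
    self_subtract: bool = False,
) -> np.ndarray:
    """Vectorised global-knowledge (best-response) rule for a block of players.

    ``tie_rng`` is a separate stream used only to break exact ties among
    maximising days; it defaults to ``rng``.
    """
    if tie_rng is None:
        tie_rng = rng
    out = np.asarray(last_choice, dtype=int).copy()
    unsat = np.asarray(last_utility, dtype=float) <= 0
    idx = np.flatnonzero(unsat)
    if idx.size == 0:
        return out
    explores = rng.random(idx.size) < np.asarray(p, dtype=float)[idx]
    out[idx[~explores]] = HOME
    exp_idx = idx[explores]
    if exp_idx.size == 0:
        return out

    att = np.broadcast_to(
        np.asarray(last_attendance, dtype=float), (exp_idx.size, bloom.n_days)
    )
    if self_subtract:
        att = att.copy()
        prev = np.asarray(last_choice, dtype=int)[exp_idx]
        was_day = prev != HOME
        att[np.flatnonzero(was_day), prev[was_day] - 1] -= 1
    share = np.asarray(m, dtype=float)[exp_idx, None] * bloom.k[None, :] / (att + 1.0)
    u_eff = np.where(share >= z, share, -c)
    row_max = u_eff.max(axis=1)
    # uniform tie-break: random scores restricted to the argmax set
    scores = np.where(u_eff == row_max[:, None], tie_rng.random(u_eff.shape), -1.0)
    best_day = np.argmax(scores, axis=1) + 1
    out[exp_idx] = np.where(row_max > 0, best_day, HOME)
    return out


def global_update(ctx: DecisionContext, m: float, z: float, c: float) -> int:
    """Global-knowledge rule for a single player."""
    if ctx.last_attendance is None:
        raise ValueError("global_update requires last_attendance (first season uses initial_choice)")
    out = global_update_many(
        np.array([ctx.last_utility]),
        np.array([ctx.last_choice]),
        np.array([ctx.p]),
        np.array([m]),
        ctx.last_attendance,
        ctx.bloom,
        z,
        c,
        ctx.rng,
    )
    return int(out[0])
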