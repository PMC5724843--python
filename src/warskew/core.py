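"""Domain types and skew-based payoff/strength distributions.

A group of ``N`` males is ranked 1 (top) to ``N``.  Resources and fighting
ability are distributed down the hierarchy by a priority-of-access rule: the
skew parameter ``beta`` (for payoff) or ``sigma`` (for fighting ability) is
the fraction of resources left by all higher-ranked males that the focal male
usurps.  The resulting shares form a geometric series

    x_i = X * beta * (1 - beta)**(i - 1) / (1 - (1 - beta)**N)

normalised so that the shares sum to the group total ``X``.  ``beta = 0`` is
the perfect-scramble limit (equal shares, handled as an explicit branch since
the formula is 0/0 there); ``beta -> 1`` is absolute despotism and is excluded
from the domain because it drives lower-rank payoffs to exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "GroupConfig",
    "Individual",
    "Population",
    "payoff_shares",
    "strength_shares",
    "build_population",
]


@dataclass(frozen=True)
class GroupConfig:
    """Parameters of one group: size, totals, and skew.

    Attributes
    ----------
    n_males : int
        Number of ranked males, ``N >= 1``.
    total_resource : float
        Total divisible resource ``X > 0`` held jointly by the group.
    total_strength : float
        Total fighting ability ``S > 0`` (simple sum over males).
    beta : float
        Payoff skew in ``[0, 1)``; 0 = egalitarian scramble, high = despotic.
    sigma : float
        Fighting-ability skew in ``[0, 1)``.  Payoff and fighting ability are
        expected to co-vary with rank, so scenarios typically set
        ``sigma = beta``; it is kept independent so the assumption can be
        relaxed.
    """

    n_males: int
    total_resource: float
    total_strength: float
    beta: float
    sigma: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n_males, (int, np.integer)) and self.n_males >= 1):
            raise ValueError(f"n_males must be a positive integer, got {self.n_males!r}")
        if not (np.isfinite(self.total_resource) and self.total_resource > 0):
            raise ValueError(f"total_resource must be finite and > 0, got {self.total_resource!r}")
        if not (np.isfinite(self.total_strength) and self.total_strength > 0):
            raise ValueError(f"total_strength must be finite and > 0, got {self.total_strength!r}")
        _check_skew(self.beta, "beta")
        _check_skew(self.sigma, "sigma")


@dataclass(frozen=True)
class Individual:
    """One ranked male: group identity, rank, strength, and pre-war payoff."""

    group_id: int
    rank: int  # 1-based, 1 = top
    strength: float
    payoff_pre: float


@dataclass(frozen=True)
class Population:
    """A fully materialised group: its config plus per-rank arrays.

    ``strengths[i]`` and ``payoffs[i]`` belong to the male of rank ``i + 1``.
    Arrays are the working representation (all downstream computation is
    vectorised); :attr:`members` exposes the same data as a list of
    :class:`Individual` for inspection.
    """

    config: GroupConfig
    group_id: int
    strengths: NDArray[np.float64] = field(repr=False)
    payoffs: NDArray[np.float64] = field(repr=False)

    @property
    def members(self) -> list[Individual]:
        return [
            Individual(self.group_id, i + 1, float(s), float(x))
            for i, (s, x) in enumerate(zip(self.strengths, self.payoffs))
        ]

    def __len__(self) -> int:
        return self.config.n_males


def _check_skew(value: float, name: str) -> None:
    if not (np.isfinite(value) and 0.0 <= value < 1.0):
        raise ValueError(f"{name} must lie in [0, 1), got {value!r}")


def _shares(total: float, skew: float, n: int) -> NDArray[np.float64]:
    if not (np.isfinite(total) and total > 0):
        raise ValueError(f"total must be finite and > 0, got {total!r}")
    _check_skew(skew, "skew")
    n = int(n)
    if n < 1:
        raise ValueError(f"n_males must be >= 1, got {n}")
    if skew == 0.0:
        return np.full(n, total / n)
    # (1-skew)**i and 1-(1-skew)**n via log1p/expm1: keeps N=1 exact and the
    # scramble limit (skew -> 0) accurate where the direct form loses digits
    log_keep = np.log1p(-skew)
    ranks = np.arange(n, dtype=np.float64)
    weights = skew * np.exp(ranks * log_keep)
    # normalise before scaling by total so extreme magnitudes cannot underflow
    return total * (weights / -np.expm1(n * log_keep))


def payoff_shares(total_resource: float, beta: float, n_males: int) -> NDArray[np.float64]:
    """Per-rank payoffs under priority of access.

    Rank ``i`` (1-based) receives
    ``X * beta * (1 - beta)**(i - 1) / (1 - (1 - beta)**N)``; ``beta = 0``
    yields the equal split ``X / N``.  Shares sum to ``total_resource`` and,
    for ``beta > 0``, decrease strictly with rank with the exact ratio
    ``x_{i+1} / x_i = 1 - beta``.
    """
    return _shares(total_resource, beta, n_males)


def strength_shares(total_strength: float, sigma: float, n_males: int) -> NDArray[np.float64]:
    """Per-rank fighting abilities; same rule as :func:`payoff_shares` with
    ``(S, sigma)`` in place of ``(X, beta)``."""
    return _shares(total_strength, sigma, n_males)


def build_population(config: GroupConfig, group_id: int) -> Population:
    """Materialise a group's ranked males from its config."""
    if group_id not in (1, 2):
        raise ValueError(f"group_id must be 1 or 2, got {group_id!r}")
    return Population(
        config=config,
        group_id=group_id,
        strengths=strength_shares(config.total_strength, config.sigma, config.n_males),
        payoffs=payoff_shares(config.total_resource, config.beta, config.n_males),
    )
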