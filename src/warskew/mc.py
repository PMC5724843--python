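"""Stochastic realizations of the participation decisions.

The deterministic coalition strengths are expectations of Bernoulli-weighted
sums: each male joins a side with his sigmoid probability.  This module draws
actual realizations so that ensemble statistics over many equivalent groups
can be compared with the deterministic values.

Per realization a male joins at most one side.  The model specifies only the
marginal participation probabilities (attack: p_a, defense: p_d, with
p_a + p_d <= 1 by construction since the switcher offset always lowers the
cross-side probability); the per-realization joint law is fixed here by
drawing the attack decision first and evaluating defense for non-attackers
with the renormalized probability p_d / (1 - p_a), which reproduces both
marginals exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .core import GroupConfig, build_population
from .merge import enumerate_merge
from .participation import ParticipationParams, join_probability, proportional_change

__all__ = [
    "RealizationResult",
    "EnsembleSummary",
    "sample_realization",
    "ensemble_summary",
    "realization_moments",
]


@dataclass(frozen=True)
class RealizationResult:
    """One realized war: who joined which side, and the realized strengths.

    ``joined_attack`` / ``joined_defense`` list ``(group_id, rank)`` pairs;
    the FA values are sums of the actual joiners' strengths.
    """

    seed: int
    joined_attack: tuple[tuple[int, int], ...]
    joined_defense: tuple[tuple[int, int], ...]
    fa_attack: float
    fa_defense: float
    delta: float


@dataclass(frozen=True)
class EnsembleSummary:
    n: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    frac_delta_positive: float = 0.0


def _side_probabilities(
    dx: NDArray[np.float64], params: ParticipationParams, group_id: int
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Marginal (attack, defense) probabilities for one group's males."""
    if group_id == 1:
        p_attack = np.asarray(join_probability(params, params.theta_own, dx))
        if params.switching_enabled:
            p_defense = 1.0 - np.asarray(
                join_probability(params, params.theta_switch_defense, dx)
            )
        else:
            p_defense = np.zeros_like(p_attack)
    else:
        p_defense = 1.0 - np.asarray(join_probability(params, params.theta_own, dx))
        if params.switching_enabled:
            p_attack = np.asarray(
                join_probability(params, params.theta_switch_attack, dx)
            )
        else:
            p_attack = np.zeros_like(p_defense)
    return p_attack, p_defense


def sample_realization(
    cfg1: GroupConfig,
    cfg2: GroupConfig,
    n_kill: int,
    params: ParticipationParams | None = None,
    seed: int = 0,
) -> RealizationResult:
    """Draw one realization of every male's participation decision.

    Reproducible: identical (scenario, seed) pairs give identical results.
    """
    if params is None:
        params = ParticipationParams()
    rng = np.random.default_rng(seed)
    pop1 = build_population(cfg1, 1)
    pop2 = build_population(cfg2, 2)
    outcome = enumerate_merge(pop1, pop2, n_kill)

    joined_attack: list[tuple[int, int]] = []
    joined_defense: list[tuple[int, int]] = []
    fa = {"attack": 0.0, "defense": 0.0}
    for pop, post in ((pop1, outcome.payoff_g1), (pop2, outcome.payoff_g2)):
        dx = np.asarray(proportional_change(post - params.war_cost * (post > 0), pop.payoffs))
        p_attack, p_defense = _side_probabilities(dx, params, pop.group_id)
        u_attack = rng.random(len(pop))
        u_defense = rng.random(len(pop))
        attacks = u_attack < p_attack
        # conditional defense prob given not attacking keeps both marginals exact
        with np.errstate(divide="ignore", invalid="ignore"):
            p_def_cond = np.where(p_attack < 1.0, p_defense / (1.0 - p_attack), 0.0)
        defends = ~attacks & (u_defense < p_def_cond)
        for r in np.flatnonzero(attacks):
            joined_attack.append((pop.group_id, int(r) + 1))
        for r in np.flatnonzero(defends):
            joined_defense.append((pop.group_id, int(r) + 1))
        fa["attack"] += float(pop.strengths[attacks].sum())
        fa["defense"] += float(pop.strengths[defends].sum())

    return RealizationResult(
        seed=seed,
        joined_attack=tuple(joined_attack),
        joined_defense=tuple(joined_defense),
        fa_attack=fa["attack"],
        fa_defense=fa["defense"],
        delta=fa["attack"] - fa["defense"],
    )


def realization_moments(
    cfg1: GroupConfig,
    cfg2: GroupConfig,
    n_kill: int,
    params: ParticipationParams | None = None,
) -> dict[str, dict[str, float]]:
    """Exact mean and variance of one realization's FA_a, FA_d, and Δ.

    Each male contributes ``s * (A - D)`` to Δ, where A and D are the
    attack/defense indicators with ``A + D <= 1``; hence
    ``Var(A - D) = p_a + p_d - (p_a - p_d)**2``.  The means coincide with the
    deterministic coalition sums, which is the unbiasedness contract the
    realizations are tested against.
    """
    if params is None:
        params = ParticipationParams()
    pop1 = build_population(cfg1, 1)
    pop2 = build_population(cfg2, 2)
    outcome = enumerate_merge(pop1, pop2, n_kill)
    mean = {"fa_attack": 0.0, "fa_defense": 0.0, "delta": 0.0}
    var = {"fa_attack": 0.0, "fa_defense": 0.0, "delta": 0.0}
    for pop, post in ((pop1, outcome.payoff_g1), (pop2, outcome.payoff_g2)):
        dx = np.asarray(proportional_change(post - params.war_cost * (post > 0), pop.payoffs))
        p_a, p_d = _side_probabilities(dx, params, pop.group_id)
        s, s2 = pop.strengths, pop.strengths ** 2
        mean["fa_attack"] += float(np.dot(s, p_a))
        mean["fa_defense"] += float(np.dot(s, p_d))
        var["fa_attack"] += float(np.dot(s2, p_a * (1.0 - p_a)))
        var["fa_defense"] += float(np.dot(s2, p_d * (1.0 - p_d)))
        var["delta"] += float(np.dot(s2, p_a + p_d - (p_a - p_d) ** 2))
    mean["delta"] = mean["fa_attack"] - mean["fa_defense"]
    return {"mean": mean, "var": var}


def ensemble_summary(results: list[RealizationResult]) -> EnsembleSummary:
    """Sample mean, sd, and standard error of FA_a, FA_d, Δ over realizations."""
    if not results:
        raise ValueError("cannot summarise an empty ensemble")
    n = len(results)
    arrays = {
        "fa_attack": np.array([r.fa_attack for r in results]),
        "fa_defense": np.array([r.fa_defense for r in results]),
        "delta": np.array([r.delta for r in results]),
    }
    mean = {k: float(v.mean()) for k, v in arrays.items()}
    sd = {k: float(v.std(ddof=1)) if n > 1 else 0.0 for k, v in arrays.items()}
    se = {k: s / np.sqrt(n) for k, s in sd.items()}
    return EnsembleSummary(
        n=n,
        mean=mean,
        sd=sd,
        se=se,
        frac_delta_positive=float((arrays["delta"] > 0).mean()),
    )
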