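"""Participation decisions and the war viability index.

Each male compares his expected post-war payoff with his pre-war payoff and
joins a coalition with a probability that is sigmoid in the proportional
change Δx = (x' - x)/x:

    p(k, θ, Δx) = 1 / (1 + exp(-k (Δx - θ)))

``k`` measures risk-taking (steeper sigmoid = closer to a step decision);
``θ`` is a payoff offset applied to males who defect to the other side
("switchers"), representing the extra cost of leaving one's own group.

The attacking coalition's fighting ability is

    FA_a = Σ_i s_1i p(k, 0, Δx_i)  +  Σ_j s_2j p(k, θ_sw, Δx_j)

and the defending coalition's

    FA_d = Σ_i s_1i (1 - p(k, -θ_sw, Δx_i))  +  Σ_j s_2j (1 - p(k, 0, Δx_j))

with the cross terms (group-2 males attacking, group-1 males defending)
zeroed when switching is disabled.  The viability index Δ = FA_a - FA_d is
the model's decision criterion: war is feasible when Δ > 0, and more so the
larger Δ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray
from scipy.special import expit

from .core import GroupConfig, Population, build_population
from .merge import MergeOutcome, enumerate_merge

__all__ = [
    "ParticipationParams",
    "ViabilityResult",
    "proportional_change",
    "join_probability",
    "coalition_strengths",
    "viability_index",
]


@dataclass(frozen=True)
class ParticipationParams:
    """Sigmoid steepness, switching offsets, and the switching toggle.

    ``theta_switch_attack`` applies to group-2 defectors joining the attack;
    ``theta_switch_defense`` to group-1 males joining the defense (entering
    through ``1 - p(k, theta, Δx)``, hence the negative default).  ``war_cost``
    is a flat per-capita payoff cost hook; it defaults to 0 (the zero-cost
    limiting case, an upper bound on war likelihood) and is subtracted from
    every survivor's post-war payoff before Δx is computed.
    """

    k: float = 10.0
    theta_own: float = 0.0
    theta_switch_attack: float = 0.6
    theta_switch_defense: float = -0.6
    switching_enabled: bool = True
    war_cost: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be finite and > 0, got {self.k!r}")
        for name in ("theta_own", "theta_switch_attack", "theta_switch_defense", "war_cost"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def without_switching(self) -> "ParticipationParams":
        return replace(self, switching_enabled=False)


@dataclass(frozen=True)
class ViabilityResult:
    """Coalition fighting abilities and the index Δ = FA_a - FA_d.

    ``components`` decomposes each coalition into its own-group and switcher
    contributions: keys ``attack_own`` (group 1 attacking), ``attack_switch``
    (group-2 defectors), ``defense_own`` (group 2 defending),
    ``defense_switch`` (group-1 defectors).
    """

    fa_attack: float
    fa_defense: float
    delta: float
    components: dict[str, float] = field(default_factory=dict)


def proportional_change(
    payoff_post: float | NDArray[np.float64], payoff_pre: float | NDArray[np.float64]
) -> float | NDArray[np.float64]:
    """Δx = (x' - x)/x; exactly -1 for killed males (x' = 0)."""
    pre = np.asarray(payoff_pre, dtype=np.float64)
    if np.any(pre <= 0):
        raise ValueError("payoff_pre must be strictly positive")
    out = (np.asarray(payoff_post, dtype=np.float64) - pre) / pre
    return out if out.ndim else float(out)


def join_probability(
    params: ParticipationParams, theta: float, dx: float | NDArray[np.float64]
) -> float | NDArray[np.float64]:
    """Sigmoid joining probability ``1 / (1 + exp(-k (dx - theta)))``."""
    out = expit(params.k * (np.asarray(dx, dtype=np.float64) - theta))
    return out if out.ndim else float(out)


def coalition_strengths(
    pop1: Population,
    pop2: Population,
    outcome: MergeOutcome,
    params: ParticipationParams,
) -> ViabilityResult:
    """Evaluate both coalitions' fighting abilities for a given merge outcome.

    Every male weighs his strength by his sigmoid participation probability;
    the sums are the expected coalition strengths over independent decisions.
    Killed defenders (Δx = -1) defend the status quo with probability
    ``1 - p(k, 0, -1) ≈ 1``.
    """
    if len(outcome.payoff_g1) != len(pop1) or len(outcome.payoff_g2) != len(pop2):
        raise ValueError("merge outcome does not match the supplied populations")

    post1 = outcome.payoff_g1 - params.war_cost * (outcome.payoff_g1 > 0)
    post2 = outcome.payoff_g2 - params.war_cost * (outcome.payoff_g2 > 0)
    dx1 = proportional_change(post1, pop1.payoffs)
    dx2 = proportional_change(post2, pop2.payoffs)

    attack_own = float(np.dot(pop1.strengths, join_probability(params, params.theta_own, dx1)))
    defense_own = float(
        np.dot(pop2.strengths, 1.0 - join_probability(params, params.theta_own, dx2))
    )
    if params.switching_enabled:
        attack_switch = float(
            np.dot(pop2.strengths, join_probability(params, params.theta_switch_attack, dx2))
        )
        defense_switch = float(
            np.dot(pop1.strengths, 1.0 - join_probability(params, params.theta_switch_defense, dx1))
        )
    else:
        attack_switch = 0.0
        defense_switch = 0.0

    fa_attack = attack_own + attack_switch
    fa_defense = defense_own + defense_switch
    return ViabilityResult(
        fa_attack=fa_attack,
        fa_defense=fa_defense,
        delta=fa_attack - fa_defense,
        components={
            "attack_own": attack_own,
            "attack_switch": attack_switch,
            "defense_own": defense_own,
            "defense_switch": defense_switch,
        },
    )


def viability_index(
    cfg1: GroupConfig,
    cfg2: GroupConfig,
    n_kill: int,
    params: ParticipationParams | None = None,
) -> ViabilityResult:
    """Δ for group 1 attacking group 2 and eliminating the top ``n_kill``.

    Composes population construction, the sort-based merge, and the coalition
    sums; fully deterministic.
    """
    if params is None:
        params = ParticipationParams()
    pop1 = build_population(cfg1, 1)
    pop2 = build_population(cfg2, 2)
    outcome = enumerate_merge(pop1, pop2, n_kill)
    return coalition_strengths(pop1, pop2, outcome, params)
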