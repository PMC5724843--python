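"""Post-war group fusion.

After a successful attack by group 1, the top ``n_kill`` (N_k) ranked males
of group 2 are eliminated and the survivors of both groups fuse into a single
group of ``N_1 + N_2 - N_k`` males.  Survivors are re-ranked by fighting
ability (a group-2 male with exactly the same fighting ability as a group-1
male is inserted below him), and the pooled resource ``X_1 + X_2`` is
redistributed down the new hierarchy under the winner's skew ``beta_1``.

Two engines are provided:

* :func:`enumerate_merge` — explicit sort-based merge, exact by construction.
  This is the authoritative engine used by everything downstream.
* :func:`analytic_new_rank` — the closed-form continuous rank maps obtained by
  solving ``s_1i = s_2j`` for the rank-equivalence between the two
  hierarchies.  Valid for ``sigma > 0`` in both groups; ranks are continuous
  and must be rounded (floor for group 1, ceiling for group 2, implementing
  the ties-below rule).  Provided as a validated fast path and cross-checked
  against enumeration in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .core import GroupConfig, Individual, Population, payoff_shares

__all__ = [
    "MergeOutcome",
    "AnalyticMapCoefficients",
    "enumerate_merge",
    "analytic_coefficients",
    "analytic_new_rank",
    "post_war_payoff",
]


@dataclass(frozen=True)
class MergeOutcome:
    """Result of fusing the two groups after ``n_killed`` eliminations.

    ``new_rank_g1[i]`` is the merged-group rank of the group-1 male of
    original rank ``i + 1``; ``new_rank_g2[j]`` likewise for group 2, with 0
    marking a killed male.  ``payoff_g1`` / ``payoff_g2`` hold post-war
    payoffs on the original rank axis (exactly 0 for the killed).
    """

    n_killed: int
    n_merged: int
    total_resource_merged: float
    beta_merged: float
    new_rank_g1: NDArray[np.int64] = field(repr=False)
    new_rank_g2: NDArray[np.int64] = field(repr=False)
    payoff_g1: NDArray[np.float64] = field(repr=False)
    payoff_g2: NDArray[np.float64] = field(repr=False)

    @property
    def killed(self) -> list[tuple[int, int]]:
        """Eliminated males as ``(group_id, original_rank)`` pairs."""
        return [(2, j + 1) for j in range(self.n_killed)]

    def new_rank(self, individual: Individual) -> int:
        """Merged-group rank of a surviving individual (error if killed)."""
        ranks = self.new_rank_g1 if individual.group_id == 1 else self.new_rank_g2
        r = int(ranks[individual.rank - 1])
        if r == 0:
            raise ValueError(f"individual {individual} was killed and has no merged rank")
        return r


@dataclass(frozen=True)
class AnalyticMapCoefficients:
    """Constants of the closed-form rank maps between the two hierarchies.

    ``M = S_1/S_2``, ``mu = sigma_1/sigma_2``, and ``B`` is the ratio of the
    geometric-series normalisers
    ``(1 - (1-sigma_1)**N_1) / (1 - (1-sigma_2)**N_2)``.  ``nk1`` is the
    real-valued threshold rank N_k^(1): group-1 males ranked at or above it
    keep their original rank because no group-2 survivor outranks them.
    """

    M: float
    mu: float
    B: float
    nk1: float


def enumerate_merge(pop1: Population, pop2: Population, n_kill: int) -> MergeOutcome:
    """Merge the two populations after killing the top ``n_kill`` of group 2.

    Survivors are sorted by strength descending; ties are broken with group 1
    above group 2, and within a group by original rank (only possible at
    ``sigma = 0``).  Post-war payoffs come from
    ``payoff_shares(X_1 + X_2, beta_1, N_1 + N_2 - n_kill)`` at each
    survivor's new rank; killed males receive exactly 0.
    """
    n1, n2 = len(pop1), len(pop2)
    n_kill = int(n_kill)
    if not (0 <= n_kill <= n2):
        raise ValueError(f"n_kill must lie in [0, {n2}], got {n_kill}")

    surv2 = np.arange(n_kill, n2)  # 0-based original ranks of group-2 survivors
    strengths = np.concatenate([pop1.strengths, pop2.strengths[surv2]])
    group = np.concatenate([np.ones(n1, dtype=np.int64), np.full(len(surv2), 2, dtype=np.int64)])
    orig_rank = np.concatenate([np.arange(1, n1 + 1), surv2 + 1])

    # lexsort: last key is primary -> strength desc, then group 1 first, then rank.
    order = np.lexsort((orig_rank, group, -strengths))
    n_merged = n1 + len(surv2)
    new_rank = np.empty(n_merged, dtype=np.int64)
    new_rank[order] = np.arange(1, n_merged + 1)

    x_total = pop1.config.total_resource + pop2.config.total_resource
    beta1 = pop1.config.beta
    shares = payoff_shares(x_total, beta1, n_merged)

    new_rank_g1 = new_rank[:n1]
    payoff_g1 = shares[new_rank_g1 - 1]
    new_rank_g2 = np.zeros(n2, dtype=np.int64)
    new_rank_g2[surv2] = new_rank[n1:]
    payoff_g2 = np.zeros(n2)
    payoff_g2[surv2] = shares[new_rank[n1:] - 1]

    return MergeOutcome(
        n_killed=n_kill,
        n_merged=n_merged,
        total_resource_merged=x_total,
        beta_merged=beta1,
        new_rank_g1=new_rank_g1,
        new_rank_g2=new_rank_g2,
        payoff_g1=payoff_g1,
        payoff_g2=payoff_g2,
    )


def analytic_coefficients(
    cfg1: GroupConfig, cfg2: GroupConfig, n_kill: int
) -> AnalyticMapCoefficients:
    """Closed-form rank-map constants; requires ``sigma > 0`` in both groups.

    The cross-hierarchy maps follow from equating fighting abilities,
    ``s_1i = s_2j``, which in logs gives

        (j - 1) ln(1 - sigma_2) = (i - 1) ln(1 - sigma_1) + ln(M mu / B).

    Note the normaliser ratio enters as ``ln(M mu / B)``: dividing the two
    share formulas puts group 1's normaliser in the denominator of the
    left-hand side, so ``B`` divides rather than multiplies.  The threshold
    ``nk1`` is the group-1-equivalent rank of the first group-2 survivor
    (original rank ``n_kill + 1``).
    """
    if cfg1.sigma <= 0.0 or cfg2.sigma <= 0.0:
        raise ValueError("analytic rank maps require sigma > 0 in both groups; "
                         "use enumerate_merge for sigma = 0")
    if not (0 <= n_kill <= cfg2.n_males):
        raise ValueError(f"n_kill must lie in [0, {cfg2.n_males}], got {n_kill}")
    M = cfg1.total_strength / cfg2.total_strength
    mu = cfg1.sigma / cfg2.sigma
    B = (1.0 - (1.0 - cfg1.sigma) ** cfg1.n_males) / (1.0 - (1.0 - cfg2.sigma) ** cfg2.n_males)
    l1 = math.log(1.0 - cfg1.sigma)
    l2 = math.log(1.0 - cfg2.sigma)
    c = math.log(M * mu / B)
    nk1 = n_kill * l2 / l1 - c / l1 + 1.0
    return AnalyticMapCoefficients(M=M, mu=mu, B=B, nk1=nk1)


def _g2_equivalent_rank(i: float, coeffs: AnalyticMapCoefficients,
                        cfg1: GroupConfig, cfg2: GroupConfig) -> float:
    """Continuous group-2 rank j with the same fighting ability as group-1 rank i."""
    l1 = math.log(1.0 - cfg1.sigma)
    l2 = math.log(1.0 - cfg2.sigma)
    c = math.log(coeffs.M * coeffs.mu / coeffs.B)
    return (i - 1.0) * l1 / l2 + c / l2 + 1.0


def _g1_equivalent_rank(j: float, coeffs: AnalyticMapCoefficients,
                        cfg1: GroupConfig, cfg2: GroupConfig) -> float:
    """Continuous group-1 rank i with the same fighting ability as group-2 rank j."""
    l1 = math.log(1.0 - cfg1.sigma)
    l2 = math.log(1.0 - cfg2.sigma)
    c = math.log(coeffs.M * coeffs.mu / coeffs.B)
    return (j - 1.0) * l2 / l1 - c / l1 + 1.0


def analytic_new_rank(
    individual: Individual,
    coeffs: AnalyticMapCoefficients,
    cfg1: GroupConfig,
    cfg2: GroupConfig,
    n_kill: int,
) -> float:
    """Continuous merged-group rank of a surviving individual.

    For a group-1 male of rank ``i``: if ``i <= nk1`` no group-2 survivor
    outranks him and his rank is unchanged; otherwise the group-2 survivors
    stronger than him — those with equivalent rank below ``j(i)`` and above
    ``n_kill`` — are inserted above, giving ``i + (j(i) - 1 - n_kill)``.
    For a group-2 survivor of rank ``j``: the ``j - 1 - n_kill`` stronger
    group-2 survivors plus the group-1 males at least as strong (ranks up to
    ``i(j)``, ties above) precede him, giving ``i(j) + j - n_kill``.

    Rounding to integer ranks is the caller's concern: floor for group 1,
    ceiling for group 2 (ties-below convention); agreement with
    :func:`enumerate_merge` is within +/-1.
    """
    if individual.group_id == 1:
        i = individual.rank
        if i <= coeffs.nk1:
            return float(i)
        j_eq = _g2_equivalent_rank(i, coeffs, cfg1, cfg2)
        # number of group-2 survivors stronger than him, capped by how many exist
        above = min(max(j_eq - 1.0 - n_kill, 0.0), float(cfg2.n_males - n_kill))
        return i + above
    j = individual.rank
    if j <= n_kill:
        raise ValueError(f"group-2 rank {j} is killed (n_kill={n_kill}); no merged rank")
    i_eq = _g1_equivalent_rank(j, coeffs, cfg1, cfg2)
    above = min(max(i_eq, 0.0), float(cfg1.n_males))
    return above + j - n_kill


def post_war_payoff(individual: Individual, outcome: MergeOutcome) -> float:
    """Post-war payoff of an original individual: 0 if killed, otherwise the
    merged-group share at his new rank."""
    if individual.group_id == 1:
        arr = outcome.payoff_g1
    elif individual.group_id == 2:
        arr = outcome.payoff_g2
    else:
        raise ValueError(f"unknown group_id {individual.group_id!r}")
    if not (1 <= individual.rank <= len(arr)):
        raise ValueError(f"rank {individual.rank} outside group {individual.group_id}")
    return float(arr[individual.rank - 1])
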