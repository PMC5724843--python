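"""Deterministic parameter sweeps over skew and elimination count.

The central questions of the model — when is war viable, and how many
defenders should the victors eliminate — are answered by exhaustively
evaluating the viability index Δ over grids of (β_1, β_2, N_k) and reading
off the argmax over N_k per skew combination.  Named scenario presets
configure the standard study conditions: equal groups, skew asymmetry, a
strong-but-small attacker, and a double-strength defender with switching
on/off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GroupConfig, build_population
from .merge import enumerate_merge
from .participation import ParticipationParams, coalition_strengths

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "optimal_kill_count",
    "scenario_preset",
    "PRESET_NAMES",
    "DEFAULT_BETA_GRID",
]

#: Realistic skew range for small-scale societies; values above 0.25 are rare.
DEFAULT_BETA_GRID: tuple[float, ...] = tuple(np.round(np.arange(1, 26) * 0.01, 2))

PRESET_NAMES = (
    "equal_groups",
    "skew_asymmetry",
    "strong_small_attacker",
    "strong_defender_switching",
)


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for a viability sweep.

    ``couple_sigma`` sets σ_j := β_j at every grid point (skews in payoff and
    fighting ability co-vary); ``couple_beta`` restricts the sweep to the
    β_1 = β_2 diagonal (the grids must then be identical).  One record is
    produced per (β_1, β_2, N_k, switching-variant) combination.
    """

    cfg1: GroupConfig
    cfg2: GroupConfig
    params: ParticipationParams = field(default_factory=ParticipationParams)
    beta1_grid: tuple[float, ...] = DEFAULT_BETA_GRID
    beta2_grid: tuple[float, ...] = DEFAULT_BETA_GRID
    nk_grid: tuple[int, ...] | None = None  # default: every integer 0..N_2
    couple_sigma: bool = True
    couple_beta: bool = False
    switching_variants: tuple[bool, ...] = (True,)

    def __post_init__(self) -> None:
        for name, grid in (("beta1_grid", self.beta1_grid), ("beta2_grid", self.beta2_grid)):
            if len(grid) == 0:
                raise ValueError(f"{name} must be nonempty")
            if any(not (0.0 <= b < 1.0) for b in grid):
                raise ValueError(f"{name} values must lie in [0, 1)")
        if self.couple_beta and tuple(self.beta1_grid) != tuple(self.beta2_grid):
            raise ValueError("couple_beta requires identical beta1_grid and beta2_grid")
        nk = self.resolved_nk_grid()
        if len(nk) == 0:
            raise ValueError("nk_grid must be nonempty")
        if any(not (0 <= n <= self.cfg2.n_males) for n in nk):
            raise ValueError(f"nk_grid values must lie in [0, {self.cfg2.n_males}]")
        if len(self.switching_variants) == 0:
            raise ValueError("at least one switching variant is required")

    def resolved_nk_grid(self) -> tuple[int, ...]:
        if self.nk_grid is None:
            return tuple(range(self.cfg2.n_males + 1))
        return tuple(int(n) for n in self.nk_grid)

    def cells(self) -> list[tuple[float, float]]:
        if self.couple_beta:
            return [(b, b) for b in self.beta1_grid]
        return [(b1, b2) for b1 in self.beta1_grid for b2 in self.beta2_grid]


@dataclass(frozen=True)
class SweepResult:
    """Long-format sweep records plus the optimal-elimination table.

    ``records`` has one row per (beta1, beta2, n_kill, switching);
    ``optimal_nk`` one row per (beta1, beta2, switching) holding the N_k that
    maximises Δ (smallest N_k on ties) and the Δ achieved there.
    """

    spec: SweepSpec
    records: pd.DataFrame
    optimal_nk: pd.DataFrame


def optimal_kill_count(
    nk_values: Sequence[int], deltas: Sequence[float]
) -> tuple[int, float]:
    """Argmax of Δ over the N_k grid, ties broken to the smallest N_k."""
    nk_arr = np.asarray(nk_values)
    d_arr = np.asarray(deltas, dtype=np.float64)
    if nk_arr.size == 0:
        raise ValueError("empty N_k grid")
    best = d_arr.max()
    idx = np.flatnonzero(d_arr == best)
    j = idx[np.argmin(nk_arr[idx])]
    return int(nk_arr[j]), float(d_arr[j])


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Exhaustively evaluate the viability index over the grid.

    For each (β_1, β_2) cell the populations are built once and each N_k is
    merged and scored; the switching-off variant reuses the same coalition
    decomposition with the cross (switcher) terms zeroed, which is exactly
    what disabling switching means.
    """
    nk_grid = spec.resolved_nk_grid()
    params_on = replace(spec.params, switching_enabled=True)
    rows: list[tuple] = []
    for b1, b2 in spec.cells():
        cfg1 = replace(spec.cfg1, beta=b1, sigma=b1 if spec.couple_sigma else spec.cfg1.sigma)
        cfg2 = replace(spec.cfg2, beta=b2, sigma=b2 if spec.couple_sigma else spec.cfg2.sigma)
        pop1 = build_population(cfg1, 1)
        pop2 = build_population(cfg2, 2)
        for nk in nk_grid:
            outcome = enumerate_merge(pop1, pop2, nk)
            res = coalition_strengths(pop1, pop2, outcome, params_on)
            c = res.components
            for switching in spec.switching_variants:
                if switching:
                    fa_a, fa_d = res.fa_attack, res.fa_defense
                else:
                    fa_a, fa_d = c["attack_own"], c["defense_own"]
                rows.append((b1, b2, nk, switching, fa_a, fa_d, fa_a - fa_d))

    records = pd.DataFrame(
        rows,
        columns=["beta1", "beta2", "n_kill", "switching",
                 "fa_attack", "fa_defense", "delta"],
    )
    opt_rows = []
    for (b1, b2, sw), grp in records.groupby(["beta1", "beta2", "switching"], sort=True):
        nk_star, d_star = optimal_kill_count(grp["n_kill"].to_numpy(), grp["delta"].to_numpy())
        opt_rows.append((b1, b2, sw, nk_star, d_star))
    optimal = pd.DataFrame(
        opt_rows, columns=["beta1", "beta2", "switching", "optimal_nk", "delta_max"]
    )
    return SweepResult(spec=spec, records=records, optimal_nk=optimal)


def _nk_range(n2: int, stride: int) -> tuple[int, ...]:
    grid = list(range(0, n2 + 1, max(1, int(stride))))
    if grid[-1] != n2:
        grid.append(n2)
    return tuple(grid)


def scenario_preset(
    name: str,
    nk_stride: int = 1,
    params: ParticipationParams | None = None,
) -> SweepSpec:
    """Standard study conditions.

    ``equal_groups``
        Both groups identical (N = 100, X = 100, S = 100), β equal in the two
        groups, swept jointly against N_k — the baseline viability surface.
    ``skew_asymmetry``
        Same identical groups but β_1 and β_2 varied independently — which
        skew combinations allow victory, and at what optimal N_k.
    ``strong_small_attacker``
        Group 1 has twice the total fighting ability but half the men
        (S_1 = 200, N_1 = 100; S_2 = 100, N_2 = 200).
    ``strong_defender_switching``
        The defending group is twice as strong (S_2 = 2 S_1, equal sizes),
        evaluated with switching both allowed and forbidden.

    ``nk_stride`` coarsens the N_k grid for speed (endpoints always kept).
    """
    if params is None:
        params = ParticipationParams()
    base = GroupConfig(n_males=100, total_resource=100.0, total_strength=100.0,
                       beta=0.1, sigma=0.1)
    if name == "equal_groups":
        return SweepSpec(cfg1=base, cfg2=base, params=params, couple_beta=True,
                         nk_grid=_nk_range(100, nk_stride))
    if name == "skew_asymmetry":
        return SweepSpec(cfg1=base, cfg2=base, params=params,
                         nk_grid=_nk_range(100, nk_stride))
    if name == "strong_small_attacker":
        cfg1 = replace(base, total_strength=200.0)
        cfg2 = replace(base, n_males=200)
        return SweepSpec(cfg1=cfg1, cfg2=cfg2, params=params,
                         nk_grid=_nk_range(200, nk_stride))
    if name == "strong_defender_switching":
        cfg2 = replace(base, total_strength=200.0)
        return SweepSpec(cfg1=base, cfg2=cfg2, params=params,
                         nk_grid=_nk_range(100, nk_stride),
                         switching_variants=(True, False))
    raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
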