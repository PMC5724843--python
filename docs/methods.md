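# Methods

## The model

Two groups of males, group 1 (the attacker) and group 2 (the defender),
compete over a shareable resource.  Group *j* has *N_j* males, total resource
*X_j*, and total fighting ability *S_j*.  Within each group every male holds a
distinct dominance rank *i* (1 = top), and both his payoff and his fighting
ability follow a priority-of-access rule: rank *i* takes the fraction β (for
payoff; σ for fighting ability) of whatever the ranks above him left over,

    x_ji = X_j · β_j (1 − β_j)^(i−1) / (1 − (1 − β_j)^N_j),
    s_ji = S_j · σ_j (1 − σ_j)^(i−1) / (1 − (1 − σ_j)^N_j).

β = 0 is perfect scramble (equal shares; an explicit code branch, since the
formula is 0/0 there) and β → 1 absolute despotism.  β = 1 is excluded from
the domain: it gives all lower ranks exactly zero payoff, which makes the
proportional payoff change undefined.  Empirically realistic values for
small-scale societies are roughly 0.05–0.2, rarely above 0.25, which is why
the default sweep grid spans 0.01–0.25.

**War outcome.**  If group 1 wins, it eliminates the top *N_k* (0 ≤ N_k ≤ N_2)
ranked males of group 2.  The survivors of both groups fuse into a single
group of N_1 + N_2 − N_k males, re-ranked by fighting ability, and the pooled
resource X_1 + X_2 is redistributed down the new hierarchy under the winner's
skew β_1.  There are no attacker casualties and no accidental killing.

**Participation.**  Every male compares his expected post-war payoff x′ with
his pre-war payoff x and joins a coalition with probability sigmoid in
Δx = (x′ − x)/x:

    p(k, θ, Δx) = 1 / (1 + e^(−k(Δx − θ))).

The attacking coalition's strength is
FA_a = Σᵢ s_1i p(k, 0, Δxᵢ) + Σⱼ s_2j p(k, θ_sw, Δxⱼ) and the defending
coalition's FA_d = Σᵢ s_1i (1 − p(k, −θ_sw, Δxᵢ)) + Σⱼ s_2j (1 − p(k, 0, Δxⱼ)).
The cross terms are the "switchers" (defectors); disabling switching zeroes
them.  Males marked for elimination have Δx = −1 exactly and defend the
status quo with probability ≈ 1.  The decision criterion is the viability
index Δ = FA_a − FA_d: war is feasible when Δ > 0, and more attractive the
larger Δ.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| β_j | payoff skew, dimensionless ∈ [0, 1) | sweep grid 0.01–0.25 step 0.01 | realistic range for small-scale societies |
| σ_j | strength skew ∈ [0, 1) | σ_j = β_j | payoff and fighting ability co-vary with rank; decoupling supported |
| k | sigmoid steepness, per unit Δx | 10 | a near-threshold decision at the scale of ±10% payoff changes; qualitative results are checked at k ∈ {5, 20} too |
| θ_sw | switcher offset, units of Δx | ±0.6 | the extra cost (economic ties, retribution risk) of defecting; results are qualitatively insensitive to it |
| N_k grid | defenders eliminated | every integer 0..N_2 | coarsenable by stride; endpoints always kept |
| X_j, S_j | totals in the presets | 100 (S_1 = 200 or S_2 = 200 in the asymmetric presets) | Δ is invariant to joint resource rescaling and exactly linear in joint strength rescaling, so these choices only set the scale |
| war cost | flat per-capita payoff cost | 0 | the zero-cost limiting case; an upper bound on war likelihood.  A hook (`war_cost`) subtracts a flat amount from every survivor's post-war payoff before Δx |

## Merging: enumeration vs analytic maps

The authoritative merge engine is an explicit sort: survivors ordered by
strength descending, ties broken group 1 above group 2 (a defender with equal
fighting ability is inserted below his attacker counterpart) and within a
group by original rank (only possible at σ = 0).  This is exact by
construction for every parameter combination, including σ = 0 and arbitrary
size/strength asymmetries.

The closed-form rank maps are provided as a validated fast path.  Equating
s_1i = s_2j gives, with M = S_1/S_2, μ = σ_1/σ_2 and
B = (1 − (1−σ_1)^N_1)/(1 − (1−σ_2)^N_2),

    (j − 1) ln(1 − σ_2) = (i − 1) ln(1 − σ_1) + ln(M μ / B),

i.e. the normaliser ratio B enters by division.  Two numerical conventions
make the continuous maps agree with enumeration within ±1 rank everywhere
tested: (i) the count of stronger opponents is clamped to [0, N_other], since
the continuous equivalent rank extrapolates past the end of the other
hierarchy for asymmetric groups; (ii) rounding is floor for group-1 ranks and
ceiling for group-2 ranks, implementing the ties-below rule.  The maps
require σ > 0 in both groups; at σ = 0 use enumeration.

## Stochastic realizations

The deterministic FA sums are expectations of Bernoulli-weighted sums.  The
realization sampler draws each male's decision so that a male never fights on
both sides in one draw: the attack decision is drawn first with the marginal
attack probability p_a, and non-attackers defend with probability
p_d/(1 − p_a).  Both marginals are reproduced exactly; consistency
(p_a + p_d ≤ 1) is guaranteed because the switcher offset always lowers the
cross-side probability relative to the own-side one.  Only the marginals are
specified by the model; the joint law per realization is this package's
contract, chosen for expectation-matching.  `realization_moments` returns the
exact mean and variance of one realization's FA_a, FA_d and Δ (per male,
Var(A − D) = p_a + p_d − (p_a − p_d)², A and D being the mutually exclusive
side indicators); tests compare 2000-draw ensemble means against the
deterministic values at 3 exact standard errors.

## Numerical choices

- Shares are computed via `log1p`/`expm1` and normalised before scaling by
  the total, so N = 1 returns X to the last bit even for tiny β, the
  scramble limit is smooth, and extreme totals cannot underflow the
  normalisation.
- For very steep hierarchies (e.g. β = 0.9, N = 1000) the geometric tail
  leaves float64 range and the lowest ranks' shares underflow to exactly 0;
  sums and all rank-order logic remain correct, and tests of the ratio law
  restrict themselves to normally-representable shares.
- Argmax over the N_k grid breaks ties toward the smallest N_k (the least
  killing among equally good options).
- Sigmoids use `scipy.special.expit` (numerically stable at saturation).

## What the sweeps show (and problem sizes used)

The four presets evaluate Δ exhaustively on the β grid × N_k grid
(N_1 = N_2 = 100 except the strong-small-attacker preset, N_2 = 200).  The
full grids run in seconds; the test-suite and acceptance-script runs use an
N_k stride of 2, which does not move any of the qualitative features.  Key
reproducible features:

- **Equal groups:** Δ is negative or ≈ 0 almost everywhere; the maximum sits
  in the egalitarian/mass-elimination region (β ≈ 0.01–0.05, N_k ≈ 50–65 of
  100) and clearly exceeds the surface's center.  Under these equations the
  despotic/eliminate-the-elite corner is strongly negative for equal groups,
  because the killed elite (Δx = −1) defends with probability ≈ 1 and at
  high σ holds most of the group's strength.
- **Skew asymmetry:** a low-skew group easily defeats an otherwise-equal
  high-skew group while eliminating only the elite (optimal N_k ≈ 4); the
  reverse matchup is barely viable and requires near-total elimination.
- **Strong small attacker:** with twice the strength in half the men, Δ* > 0
  at every skew combination; egalitarian defenders are eliminated nearly
  wholesale (mean optimal N_k ≈ 184 of 200), despotic ones lose ~55 on
  average.
- **Double-strength defender:** allowing defection raises Δ* where the
  defender is despotic and enlarges the winnable region (≈ 327 of 625 cells
  vs 0 without switching); with σ tied to β, the defectors' summed strength
  is small, so switching alone does not make the egalitarian-attacker cell
  positive here.

## Scope and limitations

- No evolutionary dynamics, no repeated wars, no coercion or conscription,
  no explicit victory-probability or casualty model: the index Δ is the
  model's endpoint.
- The generator of random test scenarios samples parameter ranges
  (β ∈ [0.01, 0.25], N ∈ [2, 300]); it emulates parameter diversity, not any
  empirical population, so passing tests demonstrate internal consistency of
  the model, not fit to ethnographic data.
- The merged group's skew is fixed at β_1; post-merge re-estimation of σ is
  out of scope.
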