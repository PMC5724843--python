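# warskew

A coalitionary model of all-out warfare between two stratified small-scale
societies, for behavioral ecologists and evolutionary anthropologists who
want to explore when intergroup war is individually rational and how many of
the defeated should be eliminated.

## The model

Each group *j* ∈ {1, 2} has *N_j* ranked males, total resource *X_j* and
total fighting ability *S_j*, both distributed down the dominance hierarchy
by a priority-of-access (reproductive-skew) rule with skew parameters β_j
(payoff) and σ_j (strength):

    x_ji = X_j β_j (1−β_j)^(i−1) / (1−(1−β_j)^N_j)

If group 1 attacks and wins, the top *N_k* defenders are eliminated, the
survivors merge into one hierarchy re-ranked by fighting ability, and
X_1 + X_2 is redistributed under the winner's skew β_1.  Every male joins a
coalition with probability sigmoid in his expected proportional payoff change
Δx = (x′−x)/x, p(k, θ, Δx) = 1/(1+e^(−k(Δx−θ))), with an offset θ for males
who defect to the other side.  The decision criterion is the **viability
index** Δ = FA_a − FA_d, the difference between the attacking and defending
coalitions' summed (probability-weighted) fighting abilities: war is feasible
when Δ > 0.

The package provides the closed-form skew distributions, an exact sort-based
merge engine plus the validated analytic rank maps, the deterministic
viability index, seeded Monte-Carlo realizations of the participation
decisions, and parameter-sweep tooling with scenario presets.

## Worked example

A minimal asymmetric duel — one male per group, the attacker twice as strong,
the lone defender targeted for elimination:

```python
from warskew import GroupConfig, viability_index

cfg1 = GroupConfig(n_males=1, total_resource=10, total_strength=2, beta=0.3, sigma=0.3)
cfg2 = GroupConfig(n_males=1, total_resource=10, total_strength=1, beta=0.3, sigma=0.3)
res = viability_index(cfg1, cfg2, n_kill=1)
print(f"{res.fa_attack:.4f} {res.fa_defense:.4f} {res.delta:.4f}")
```

prints

```
1.9999 1.0000 1.0000
```

The attacker's payoff would double (Δx = +1), so he attacks with probability
≈ 1 and contributes his full strength 2; the defender faces Δx = −1 and
defends with probability ≈ 1, contributing 1.  Δ ≈ 1 > 0: the attack is
viable.

The same scenario from the shell, plus a full preset sweep:

```sh
warskew viability --n1 1 --n2 1 --x1 10 --x2 10 --s1 2 --s2 1 \
                  --beta1 0.3 --beta2 0.3 --nk 1
warskew sweep --preset skew_asymmetry --nk-stride 2 --out out/ --plot
```

The sweep writes `sweep_records.csv` (one row per β_1 × β_2 × N_k × switching
combination with FA_a, FA_d, Δ), `sweep_optimal_nk.csv` (per skew cell, the
N_k maximising Δ and the Δ achieved), a JSON sidecar of the spec, and a
heatmap with the Δ = 0 contour.  On the `skew_asymmetry` preset the optimal-Δ
table shows, e.g., that a low-skew group (β_1 = 0.05) facing a despotic one
(β_2 = 0.25) attacks viably (Δ* ≈ 36.5) by eliminating only the top 4
defenders, while the reverse matchup is barely viable (Δ* ≈ 0.05) and
requires eliminating 98 of 100.

Presets: `equal_groups`, `skew_asymmetry`, `strong_small_attacker`,
`strong_defender_switching`.  See `docs/methods.md` for the model details,
parameter meanings, and numerical conventions.

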