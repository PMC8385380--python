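# Methods

## Model and assumptions

All dynamics assume an effectively infinite population (only proportions
evolve), discrete non-overlapping generations, pure viability selection —
no mutation, migration or drift — and deterministic updates given the
per-generation fitness landscape. Fitness values are accepted anywhere in
`[0, ∞)`: every update uses only fitness ratios, and time-varying examples
naturally use values such as `e^{1/2} > 1`. A genotype is an abstract
tuple of 0-based allele indices, one per locus; genotypes are enumerated
row-major over loci, and every serialisation (JSON fitness arrays,
trajectory TSV columns) follows that single convention.

State spaces:

* `Δ(Γ)` — distributions over genotypes (`GenotypeDistribution`);
* `Θ = Δ_1 × … × Δ_m` — per-locus allele frequencies (`AllelicProfile`);
* the allele simplex for single-locus diploids, and gamete frequencies
  plus a symmetric pair-fitness matrix for the two-locus diploid.

`ρ : Δ(Γ) → Θ` marginalises; `ρ⁻¹` lifts a profile to its product
(linkage-equilibrium) distribution. `linkage_deviation` is the max-norm
distance of a distribution from its own lift — zero exactly at linkage
equilibrium.

## Step operators

* **Asexual**: `d⁺_g = d_g w_g / w̄`. Fixed points are exactly the point
  masses plus distributions supported on fitness plateaus.
* **Haploid sexual**: `q⁺_ij = q_ij w_ij / w̄`, with `w_ij` the marginal
  fitness of allele `j` at locus `i` under the linkage-equilibrium lift of
  `q`. Implementation note: the numerator `q_ij w_ij` is accumulated
  directly as `Σ_{g ∋ a_ij} d_g w_g`, so alleles at zero frequency stay at
  zero rather than hitting a 0/0.
* **λ-type reproduction** ("select then block-factorize"): apply selection
  `d·w/w̄`, then replace the distribution by the product of its block
  marginals over the partition λ of loci. The coarsest partition
  reproduces the asexual step everywhere; the finest reproduces
  `ρ⁻¹∘τ∘ρ` on linkage-equilibrium states, which is the regime the linkage
  convergence results address (off linkage equilibrium the two differ,
  because the product lift and the actual distribution assign different
  marginal fitnesses). A recombination tuple `{r_λ}` takes the convex
  combination `Σ_λ r_λ T_λ(d)`.
* **Diploid single locus**: `p⁺_i = p_i W_i / W̄` with `W_i = (Wp)_i`,
  `W̄ = pᵀWp`, `W` symmetric (symmetry is enforced by averaging on
  construction — no position effects).
* **Diploid two loci**: random union of gametes; with probability `r` the
  offspring gamete swaps locus-2 alleles between its two parental gametes:
  `x⁺_{(i,j)} W̄ = (1−r) x_{(i,j)} W_{(i,j)} + r Σ_{k,l} x_{(i,l)} x_{(k,j)}
  W_{(i,l),(k,j)}`. The per-gamete linkage-disequilibrium term is reported
  as the residual `D_g = x_g W_g/W̄ − x⁺_g`, identically zero at `r = 0`.
  General `m > 2` diploid linkage is out of scope.
* **MWU**: polynomial `d⁺_i ∝ d_i(1+ηℓ_i)` (parameter-free limit
  `d⁺_i ∝ d_i ℓ_i`, which is the replicator itself) and exponential/Hedge
  `d⁺_i ∝ d_i e^{ηℓ_i}` (max-subtracted, hence shift-invariant and
  overflow-safe). Step-size violations (`1+ηℓ ≤ 0` on the support;
  non-positive payoffs in parameter-free mode) raise rather than clip.
* **Baum–Eagon**: `q⁺_ij = q_ij (∂U/∂q_ij) / Σ_s q_is (∂U/∂q_is)` for a
  polynomial `U` with nonnegative coefficients, represented as an explicit
  term list (`SimplexPolynomial`) with analytic gradients. The multilinear
  mean-fitness polynomial reproduces the haploid step; the quadratic
  `pᵀWp` reproduces the diploid single-locus step; linear `U` reproduces
  the asexual step. These identities are tested as oracle equivalences.

## Potential games

`game_from_landscape` builds the loci game; `find_potential` constructs an
exact potential for an arbitrary finite game by integrating unilateral
payoff differences along coordinate paths from the all-zeros profile and
then verifying every unilateral edge (tolerance 1e-9 on payoff
differences; failure returns `None` — that is the signal, not an error).
Nash enumeration uses weak inequalities: profiles with payoff-equal
deviations still count, so degenerate landscapes return plateaus.
Best-reply ties break to the lowest action index, making the documented
2×2 miscoordination cycle deterministic. `epsilon_nash_gap` is the largest
unilateral expected-payoff improvement available to any player.

## Numerical choices

* Simplex conservation: every operator renormalises its output; tests
  assert mass 1 within 1e-12. Tolerances: 1e-9 for potential defects,
  1e-12 for monotonicity (`≥ −1e-12` per step), 1e-14 default fixed-point
  stopping inside `run_trajectory` (configurable; `stop_tol=0` disables).
* Convergence classification keeps two separate tolerances: fixed-point
  (1e-9, "has the state stopped moving") and vertex/ε-Nash (1e-6, "is the
  stationary state monomorphic"). Distances are max-norm on the natural
  coordinates.
* `mwu_profile_orbit` iterates simultaneous MWU on *log*-weights. In plain
  weight space a temporarily losing action can underflow to exact zero
  near a saddle, absorbing the orbit at a non-Nash vertex — a pure float
  artifact, since the exact dynamic preserves full support. The log-space
  orbit is the same map and can leave saddles; its stop rule refuses to
  stop at a vertex whose carried action is not payoff-maximal. In the
  parameter-free mode a zero payoff is allowed there (the action's
  log-weight becomes −∞), matching the exact dynamic's limit.
* Diploid equilibria are found by support enumeration: solve the linear
  marginal-fitness-equalisation system on each support, keep simplex
  solutions, and classify stability by probing `W̄` with ~200 seeded
  random perturbations of size 1e-8. Practical for modest allele counts
  (≲ 10).
* Long-run runs renormalise every step; no log-space state is kept for
  the replicator trajectories themselves (horizons used here, ≤ 1e5
  steps, do not need it).

## Environments and one-step-ahead statistics

`EnvironmentProcess` realises a landscape per generation (fixed, cycled
schedule, i.i.d., finite Markov chain, or callback), bit-reproducibly from
its seed. The average one-step-ahead expected log fitness
`ρ̂_t^g = (1/t) Σ_{s≤t} E[ln w_g(ψ_{s+1}) | ψ_s]` is computed in closed
form for fixed, i.i.d. (constant `Σ_ω μ(ω) ln w_g(ω)`) and Markov modes
(conditioning on the current chain state, by the Markov property). For
arbitrary schedules no conditional law exists, so an empirical plug-in
estimator (realised next-step log fitness, running-averaged) is provided
and labelled as such. Asymptotic superiority is decided by a tail-window
surrogate for liminf/limsup: genotype `g` wins if its tail-window minimum
strictly exceeds every rival's tail-window maximum (default window: last
20% of the horizon) — finite-horizon software cannot evaluate true
limits. For ergodic environments "optimal" means maximal stationary
expected *log* fitness, the criterion consistent with multiplicative
growth; with unequal fitness variances this differs from maximal expected
fitness, and the log criterion is the one the convergence results support.

## Diagnostics

Regret is computed in log-growth mode by default: the population's
per-step payoff is `ln w̄^t` and the benchmark is the genotype vertex with
the highest cumulative log fitness. Best-in-hindsight candidates are
vertices only — the linear argmax is attained at a vertex. The per-locus
virtual-convergence gap scores each locus against its best allele in
hindsight under the internal environment (the realised frequencies of the
other loci); the allele payoff is computed directly as the fitness-tensor
contraction against the other loci, which is defined even for extinct
alleles. The joint genotype-level gap is reported but not asserted to
vanish under varying environments; the per-locus guarantee is the one the
theory provides. Basins of attraction are sampled with per-simplex
Dirichlet(1,…,1) starts; non-converged samples are labelled `"none"`,
never dropped. Exponential rates are least-squares slopes of log distance
to the limit over the trajectory tail (−∞ flags exact convergence, NaN
flags no contracting movement).

## What the generators emulate — and what they do not

The built-in fixtures are the worked inputs of the underlying theory: the
two 3×3 two-locus matrices (unique pure Nash each, at `(0,2)` and
`(2,0)`), the 2/1/0 coordination game, the antiphase periodic environment
with fitnesses `e^{1/2}`/`e^{1/3}` and period 200, and the
heterozygote-advantage diploid matrix. `random_landscape` draws strictly
positive, pairwise-distinct (generic) fitnesses — uniform on (0,1] or
log-normal — so that Nash equilibria are isolated and convergence
statements hold without tie qualifications. None of this emulates finite
populations: there is no sampling noise, no mutation, no linkage map
beyond the partition structure. Passing tests certify the deterministic
infinite-population recursions and their game-theoretic structure, not
the behaviour of finite populations under drift.

## Problem sizes used

Test and acceptance runs use desk-scale instances chosen to leave wide
safety margins on every asserted tolerance: landscapes up to 3 loci × 4
alleles, horizons of 10⁴ steps for fixed-fitness convergence (the
fixtures fix to machine precision within ~500 steps), 10⁵ steps × 20
seeds for Markov parameter recovery, and 40–300 Dirichlet restarts for
basin maps.

## Known limitations

* `m > 2` diploid linkage disequilibrium is not implemented (only the
  two-locus gamete recursion).
* No mixed-Nash enumeration for general games; mixed equilibria are found
  only for the single-locus diploid model via support enumeration.
* Tail-window surrogates for liminf/limsup can mislabel superiority for
  environments whose mixing time exceeds the window.
* Monotonicity under theory-covered dynamics is asserted with tolerance
  −1e-12; exact-tie steps on degenerate landscapes are logged at WARNING
  inside the runner's diagnostics rather than treated as violations.
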