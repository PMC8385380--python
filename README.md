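# repdyn

Discrete-time replicator dynamics, potential games and convergence
diagnostics for multi-locus selection models.

## What this is for

Population geneticists and evolutionary game theorists use the same
discrete update under different names: reweight a probability vector by
relative fitness,

```
d⁺_g = d_g · w_g / w̄,          w̄ = Σ_g d_g w_g .
```

`repdyn` implements the family of selection dynamics built from this map —
asexual (clonal), haploid sexual with arbitrary genetic linkage, and
single- and two-locus diploid — together with the two pieces of machinery
that explain their long-run behaviour:

* **Potential games.** A fixed fitness landscape over `m` loci defines an
  identical-interests game: each locus is a player, its alleles are
  actions, and every player receives the common payoff `w_g` at the profile
  spelling genotype `g`. Population mean fitness `w̄` is the multilinear
  potential of this game, so pure Nash equilibria are exactly the
  single-allele-swap local maxima of the landscape. The haploid dynamic is
  each locus independently running parameter-free multiplicative-weights
  updating (MWU) on this game, and the Baum–Eagon inequality — the
  gradient-reweighted simplex map `q⁺_ij ∝ q_ij ∂U/∂q_ij` never decreases
  a nonnegative-coefficient polynomial `U` — makes `w̄` a Lyapunov
  function. Hence monotone mean-fitness increase and monomorphic
  convergence to pure Nash genotypes under fixed fitness.
* **Regret and virtual convergence.** Under arbitrarily varying fitness
  the state need not converge, but the replicator is an MWU-type no-regret
  algorithm: its cumulative log growth trails the best fixed genotype in
  hindsight by at most `−ln(min_g d⁰_g)` (exactly, via the telescoping
  identity `Π_t w̄^t = Σ_g d⁰_g Π_t w_g^t`). The realised average growth
  rate therefore matches the optimal-in-hindsight genotype even when the
  composition oscillates forever — "virtual convergence".

The library provides the step operators, a trajectory runner over
environment processes (fixed, scheduled/periodic, i.i.d., Markov),
pure-Nash enumeration and exact-potential construction for finite games,
and diagnostics: convergence classification (monomorphic / polymorphic /
none), Lyapunov monotonicity checks, regret records, per-locus
virtual-convergence gaps, empirical basins of attraction and local
exponential rates.

## Worked example

The built-in `table3_rainy` fixture is a two-locus, three-allele fitness
matrix whose largest cell, 0.80, sits at allele pair `(0, 2)`:

```python
import repdyn as rd

rainy = rd.make_fixture("table3_rainy")
print(rd.enumerate_pure_nash(rd.game_from_landscape(rainy)))
# {(0, 2)}

env  = rd.EnvironmentProcess.fixed(rainy)
traj = rd.run_trajectory("haploid", rd.AllelicProfile.uniform(rainy.space),
                         env, 10_000, record_every=1000)
rep = rd.classify_convergence(traj)
print(rep.status, round(rep.limiting_mean_fitness, 6))
# monomorphic 0.8
```

The haploid population, started from uniform allele frequencies at both
loci, fixes on the unique pure Nash equilibrium `(0, 2)` and its mean
fitness climbs monotonically to that genotype's fitness 0.80. The
`examples/` directory holds five short narrative scripts of this kind:
fixed-fitness convergence, MWU versus cycling best replies on a 2×2
coordination game, periodic environments with vanishing regret, genetic
linkage and basin shifts, and diploid balanced polymorphism with
mean-fitness reversals.

A thin CLI mirrors the main entry points:

```
repdyn nash --fixture table3_rainy
repdyn simulate --fixture table3_rainy --dynamic haploid --steps 10000 --out run/
repdyn basins --fixture table3_rainy --samples 200 --out basins.tsv
```

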