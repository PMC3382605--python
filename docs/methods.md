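# Methods

## Model

A population of `N` individuals is subdivided into `D` demes of
carrying capacity `N0 = N / D`, placed on the nodes of an undirected
migration network.  Each individual carries a pure strategy (cooperate
or defect) and a real-valued fitness.  One generation applies, in
order: the game stage, migration, selection.  The census (generation
counter, cooperator frequency ρ, total size, occupied demes) is taken
after selection, at the end of the life cycle.

**Game stage.**  Within each deme a uniform random perfect matching is
drawn (uniform shuffle, adjacent pairing); each pair plays one round of
the prisoner's dilemma with payoffs `T > R > P > S`, `2R > T + S`.  The
round payoff `G` enters the accumulated fitness through the convex
recurrence

    f' = (1 - w) f + w G,        w in (0, 1], default w = 1/2.

Under a constant payoff the iterates converge geometrically to that
payoff, so fitness is bounded by `[min(S, 0), T]`; with `w = 1/2` and
`f0 = 0` the n-th iterate is exactly `G (1 - 2^-n)`.  The recurrence is
the simplest generation-accumulated ("learning") fitness with these two
properties — dependence on the previous fitness and the current payoff,
and boundedness with maximum equal to the top payoff — and the weight
`w` is exposed in the configuration.  In an odd-sized deme the unpaired
individual sits out with fitness unchanged (setting `leftover_decay`
makes it take payoff 0 instead).

**Migration.**  Each individual independently moves with probability
`m` to a uniformly chosen neighbour of its current deme.  Strategy and
fitness travel unchanged; individuals in isolated demes stay; empty
demes are legal destinations (recolonisation).  Deme sizes float freely
here and are restored only by selection.

**Selection** is strictly local.  First, every individual with fitness
strictly below the elimination threshold `E` is removed (`f = E`
survives; "below" is read literally as strict).  Then, per deme: at
size `N0` nothing happens; above `N0` a minimum-fitness individual is
removed repeatedly (ties broken uniformly at random — the sort-based
description is silent on ties); below `N0` but non-empty, the deme
expands back to `N0` by fitness-proportional (roulette-wheel) draws
with replacement from the pre-expansion survivors, each daughter
inheriting the parent's strategy with fitness 0.  Empty demes stay
empty.  Daughters cannot parent within the same expansion; since they
carry fitness 0 they would have zero weight anyway, but the rule keeps
the procedure well defined if the newborn-fitness default is changed.
Negative survivor fitness (only reachable if a user configures `S < 0`
with `E < 0`) is clamped to weight 0; if every weight is 0 the parent
is drawn uniformly (logged as a degenerate event).

**Outcome classification.**  ρ = 1 (with survivors) and total
extinction are absorbing and end a replicate.  An all-defector state is
*not* short-circuited: elimination plays out emergently, because under
modified payoffs with `P ≥ E` pure defection could persist.  A mixed
population is declared stationary — outcome "coexistence", with final ρ
the mean over the last window — when the means of ρ over the last two
disjoint windows differ by at most `stationarity_tol`.  A replicate
that exhausts `max_generations` unresolved is excluded from probability
denominators and counted separately (warned when above 1% of runs).

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| T, R, P, S | 1.5, 1.0, 0.1, 0.0 | payoff units; satisfy both dilemma inequalities, and an all-defector deme's limiting fitness P lies below E so pure defection self-destructs |
| E | 0.4 | elimination threshold, payoff units; validated E < R |
| w | 0.5 | fitness memory weight |
| m | 0.1 | per-individual migration probability per generation |
| N, D | 400, 20 | population and deme count (N0 = 20) |
| z | 4 | mean degree for random and scale-free networks |
| init_coop_frac | 0.5 | i.i.d. founder cooperation probability |
| init_fitness | 0.0 | founders and newborns start with empty payoff history |
| max_generations | 5000 | replicate horizon |
| stationarity_window, tol | 200, 0.01 | coexistence detection |

These desk-scale values are the package's study conditions; every one
is configurable via `ModelParams`, the YAML/JSON config, or CLI flags.

## Networks

* **Erdős–Rényi** `G(D, p)` with `p = z/(D-1)`: Poisson-like degree
  distribution, finite variance.  Isolated nodes are kept (no
  connectivity filter); `resample_isolated` resamples until minimum
  degree 1 if wanted.
* **Island model**: the complete graph `K_D`; degree `D - 1`
  everywhere, zero degree variance.
* **Scale-free**: Barabási–Albert preferential attachment with
  attachment count `round(z/2)`, so mean degree ≈ `z` and topologies
  are compared at matched mean connectivity; the degree distribution is
  heavy-tailed (largest variance of the three).
* **User**: whitespace edge list, one `u v` pair per line, 0-based ids;
  self-loops rejected; load∘export is the identity on edge sets.

The network is generated once per replicate and held fixed (quenched).
Graph construction is delegated to networkx.

## Randomness contract

One numpy PCG64 generator per replicate, seeded with `base_seed + r`
for replicate `r`; network generation, founding, and all three stages
draw from this single stream in a fixed order.  Per generation, demes
are processed in id order:

1. game: one `permutation(n)` per deme with `n ≥ 2`;
2. migration: one `random(n)` per non-empty deme, then one
   `integers(0, k, size=n_movers)` when there are movers and `k ≥ 1`
   neighbours (sorted ascending); arrivals append in processing order;
3. selection: one `integers(n_ties)` per tied cull removal; one
   `random(births)` per expansion (or `integers(n, size=births)` under
   the all-zero-weight fallback), parent = first index whose cumulative
   weight exceeds `u · total`.

This contract makes `(params, seed)` fully determine a trajectory and
is what the naive reference engine in `tests/reference_engine.py`
shares; trajectory-level equality between two implementations is only
meaningful relative to such a contract.

## What the simulations show — and do not show

The generator *is* the model: there is no external data, and the
synthetic dynamics embody the stated assumptions (panmictic interaction
inside demes, exactly one round per individual per generation, no
strategy imitation or mutation, undirected unweighted migration,
quenched networks).  Passing tests therefore validate the
implementation of this model, not the model's fit to any empirical
population.  Real systems violate several assumptions at once —
overlapping generations, payoff-dependent migration, within-deme
structure — and none of those are probed here.

Observed behaviour at the default payoffs, verified by the test suite
at desk scale: no coexistence at `m = 0`; certain extinction of
all-defector populations; fixation probability rising with `m` from
near-isolation and coexistence dominating at high `m`; conditional
cooperation level falling across the coexistence range; more demes (at
fixed `N`) widening the pure-cooperation window and raising fixation at
small `m`; heterogeneous (scale-free) networks sustaining a higher
cooperation level than the island model while the fixation
probabilities stay indistinguishable; a higher elimination threshold
delaying both onsets; and a critical deme number `D_c` between 2 and 80
at minimal migration.  One caveat the package documents deliberately:
at these payoffs the fixation probability is *not* monotone all the way
up in `m` — it dips where coexistence replaces pure fixation (runs that
end extinct from a mixed state), so "rises with migration" holds on the
approach to the coexistence regime, not uniformly.

## Problem sizes and numerical choices

Ensembles in the tests and the acceptance script use 30–100 replicates
per grid point at `N = 400–500`, chosen as the smallest sizes at which
the qualitative contrasts above are statistically decisive (the
topology gap, for instance, is ≈ 0.19 with a standard error well under
0.02 at 80 runs per arm).  Regime classification uses
`eps_onset = 0.01` and `eps_pure = 0.02`; resolving an onset
probability of `eps_onset` nominally needs ≈ `3/eps_onset` replicates,
and with fewer the classifier warns rather than refuses, since
100-run ensembles are the package's standard working scale.  `D_c` is
defined operationally at the smallest *simulated* migration rate of a
scan, not at a true `m → 0` limit, and near the onset boundary its
estimate at 100 runs can flip on single rare fixation events — the
model's own finite-size stochasticity, reported as computed.

Statistical checks are single pre-registered one-sided tests per
directional claim (no multiple-comparison correction); binomial
standard errors are `sqrt(p(1-p)/n)`.  Culling removes one individual
per iteration (`O(n²)` worst case) — deme sizes are small enough that
this is irrelevant.  Floating-point equality between the optimized and
reference engines relies on identical operation order; the roulette
span is taken from the sequential cumulative sum for exactly this
reason.

## Known limitations

* The stationarity detector compares two window means every generation
  once `2 × window` records exist; a slow drift below `tol` per window
  can be declared stationary early.  Tighten `stationarity_tol` or
  widen the window for long-memory settings.
* `p_coop` estimates near 0 or 1 have asymmetric binomial error; the
  reported symmetric SE is a convenience, not an exact interval.
* The scale-free generator fixes attachment count `round(z/2)`, so only
  even-ish mean degrees are matched exactly across topologies.
* No checkpointing: a replicate is an atomic unit of work.
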