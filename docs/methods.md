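# Methods

## Model and assumptions

The simulator implements a transactional (reproductive-skew) model of
inequality on an explicit landscape.  Each of `P` polities holds one
dominant and a pool of subordinates; productivity is homogeneous and group
sizes are fixed, so the only state is the extraction share `z_i ∈ [0, 1]`.
Subordinates treat migration as a threat point: they would move to the best
neighbouring polity iff the stay payoff `(1 − z_i)` falls strictly below the
discounted outside option `(1 − c_m) · max_{j∈P_i}(1 − z_j)`.  Indifference
keeps them home, so a rational dominant sets exactly the indifference value

    z_i ← 1 − (1 − c_m) · max_{j∈P_i}(1 − z_j).

Migration is never executed; the population composition never changes.

Scheduling is asynchronous and memoryless: each update event picks one
polity uniformly at random (with replacement), applies the rule above, and
then, with probability `μ_r`, perturbs the fresh value by a uniform draw on
`[−ε, +ε]`, clamped to `[0, 1]` (a share cannot leave the unit interval).
The shock strikes only the polity that just updated; a variant in which
shocks can strike any polity was considered and not adopted, as the
per-update reading keeps the shock rate tied to the update rate and one
parameter fewer.  One *time step* is `P` update events, so each polity
updates once per step on average — some twice, some not at all.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| `c_m` | proportional migration cost | 0.05 | share of payoff |
| `mu_r` | shock probability per update | 0.01 | probability |
| `epsilon` | shock half-width | 0.25 | inequality units |
| `z0_low, z0_high` | initial inequality range | 0.05, 0.10 | inequality units |
| `n_time_steps` | horizon | 3000 | time steps |
| `last_k` | equilibrium averaging window | 500 | time steps |
| `n_replicates` | ensemble size | 100 | runs |

Defaults describe a near-egalitarian starting point with a modest migration
cost and rare, sizeable shocks.  Replicate `r` runs with seed
`base_seed + r`; sweep cell `c` shifts the base seed by `100003·c` so cell
streams do not collide.  All seeds are reduced modulo 2^31.

Horizons: the default 3000 steps (with `last_k = 500`) are a desk-scale
choice; at the default parameters the dynamics equilibrate well within
~1500 steps (absorption without shocks completes in a few hundred), and
longer horizons — e.g. 30 000 steps — are one config key away
(`dynamics.n_time_steps`).

## Networks

- `complete` — the open plain, every pair connected.
- `grid` — square lattice with unit spacing; edge iff Euclidean distance
  ≤ `d_max` (squared-distance comparison, so `d_max = 1` yields rook
  neighbourhoods and `d_max = √2` adds diagonals exactly).  The comparator
  is inclusive by default because a strict reading at `d_max = 1` would
  disconnect adjacent squares; a flag restores strictness.  `periodic`
  wraps distances on the torus.
- `islands` / `valleys` — polities assigned uniformly at random to
  `n_cliques` cliques (10 / 3 by default), rejecting assignments with an
  empty clique.  When `n_cliques = n_polities` the conditional law is a
  uniform permutation and is sampled directly.  Island cliques are complete;
  valley cliques are stepping-stone paths in ascending polity-index order
  (any fixed order is statistically equivalent under random assignment).
  Linked clique pairs — a chain by default, with ring and complete
  alternatives — are bridged by a single edge between uniformly chosen
  members.  The chain default keeps the bridge count minimal, matching the
  single-link valleys description.  This generator fixes link counts
  exactly, unlike a stochastic block model which fixes probabilities.
- `custom` — plain-text edge list with a `# n_polities=N` header.

Isolated polities are an error by default; an `autarky` flag instead sets
`z = 1` (no outside option ⇒ full extraction), the natural limit for a
disconnected polity.

## Numerical choices

- Draw order per update event is fixed — polity choice, shock Bernoulli,
  shock magnitude (consumed only when the Bernoulli fires) — so a run is a
  bit-reproducible pure function of `(network, params)`; the batch runner
  and the single-step `update_one` consume the stream identically.
- The update rule cannot leave `[0, 1]`; only shocks are clamped.
- Ties in the migration condition favour staying (strict inequality), the
  standard skew-model convention that lets the dominant post exactly the
  indifference value.
- Floating point: a value copied at `c_m = 0` is `1 − (1 − m)`, within one
  double rounding (≤ 2⁻⁵²) of `m`; the indifference identity after an
  update holds to the same absolute precision.  Tests assert bit-exactness
  only where the arithmetic is literally shared.
- Trajectory index `t` holds the state after `t` complete time steps;
  index 0 is the initial draw.

## What the generator emulates — and what it does not

Runs are synthetic throughout: uniform initial inequality, homogeneous
productivity, constant group sizes, a single global migration cost, and
i.i.d. symmetric shocks.  Passing tests therefore demonstrate the internal
logic of the circumscription mechanism — cost-controlled rates, shock-driven
suppression, landscape effects — not calibration to any empirical record.
Real landscapes add heterogeneous productivity, demography, conquest and
levelling coalitions, all outside this model's scope.

## Design choices where the design was open

- **Zero-cost limit.**  With `c_m = 0` the update copies the minimum
  inequality among *neighbours* (a polity is not its own neighbour).  If
  the unique holder of the global minimum happens to update before any
  neighbour has copied its value, that minimum is overwritten (probability
  ≈ 1/P on a complete graph).  The dynamics still reach consensus at a
  (copy of a) low initial draw; tests condition the "exact minimum" check
  on a schedule-derived survival predicate computed by an independent
  oracle.
- **Equilibrium statistic** is the mean of the population-mean `z` over the
  final `last_k` time steps, averaged over replicates; dispersion is the
  replicate standard deviation (no inferential tests).
- **"Reached the maximum"** is operationalized as `min_i z_i ≥ 0.99`.
- **Random families are redrawn each replicate**, so island/valley
  ensembles average over the generative model, not one realization; a flag
  freezes a single draw instead.
- **Fig-style sweeps** derive grid shape from `n_polities` when it is a
  perfect square (3×3, 7×7, …), so landscape size can be swept with one key.

## Configuration

Every experiment is a YAML file with strict schema validation (unknown keys
are rejected by name); CLI flags mirror config keys 1:1.  For example, the
connectivity × landscape-size sweep:

```yaml
seed: 1
network:
  family: grid
dynamics:
  c_m: 0.05
  mu_r: 0.01
  epsilon: 0.25
  n_time_steps: 3000
experiment:
  n_replicates: 100
  last_k: 500
  sweep:
    n_polities: [9, 25, 49]
    d_max: [1.0, 1.5, 3.0, 100.0]
output:
  directory: results/landscape_sweep
```

run with `circumskew sweep --config sweep.yaml`.  Output directories always
contain a config echo, the seed and the package version in
`metadata.json`, plus SHA-256 checksums of every file in `manifest.json`,
so any result can be regenerated bit-identically.

## Limitations

Single-threaded, in-memory; full recording stores a `(T+1) × P` matrix, so
very long fully recorded runs are memory-bound.  The update loop is pure
Python/numpy (~1 s per 10⁵ update events); very large ensembles (hundreds
of replicates × tens of thousands of steps) are feasible but take hours,
which is why the desk-scale defaults above are the shipped configuration.
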