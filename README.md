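# circumskew

Agent-based simulations of how geographic circumscription — barriers to
migration such as mountains, seas or sheer distance — shapes the evolution
of inequality among connected polities.

The package is aimed at researchers in cultural evolution, archaeology and
evolutionary ecology who want to explore transactional (reproductive-skew)
models of despotism on explicit landscapes: how fast inequality rises, where
it equilibrates, and how the answer depends on the cost of moving, the
number of polities and the shape of the migration network.

## The model

A landscape holds `P` polities on an undirected network; a link means
subordinates of one polity could move to the other.  Each polity `i` has a
dominant who extracts a share `z_i ∈ [0, 1]` of the subordinates' surplus
(`z = 0` egalitarian, `z = 1` full extraction).  Subordinates never actually
move — migration is a credible threat.  They would leave iff

    (1 − z_i) < (1 − c_m) · max_{j ∈ P_i} (1 − z_j),

where `c_m` is the proportional cost of migration and `P_i` the set of
neighbours.  The dominant therefore concedes exactly enough to keep them
indifferent: when polity `i` updates,

    z_i ← 1 − (1 − c_m) · max_{j ∈ P_i} (1 − z_j).

With probability `μ_r` per update, the new value is perturbed by a shock
drawn uniformly from `[−ε, +ε]` (clamped to `[0, 1]`), capturing dominants'
errors and fluctuations of power.  Updates are asynchronous: one uniformly
random polity updates at a time, and one *time step* is `P` such updates.
Initial inequality is drawn from `U[0.05, 0.10]`.

Three headline behaviours emerge:

- **Any positive migration cost absorbs at full extraction.**  Each update
  sets inequality slightly above the most attractive neighbour's, so without
  shocks `z → 1` everywhere; `c_m` controls the *rate*, not the endpoint.
  With `c_m = 0` inequality instead contracts to the lowest initial draw.
- **Symmetric shocks asymmetrically lower equilibrium inequality**: one
  more-equal neighbour forces a dominant down, while an increase propagates
  only if *all* neighbours increase.
- **Smaller and less connected landscapes are more unequal.**  Equilibrium
  inequality decreases with the number of polities and with connectivity,
  and the named scenarios order as plain < islands < valleys.

Network families: `complete` (open plain), `grid` (square lattice, edge iff
Euclidean distance ≤ `d_max`), `islands` (random complete cliques bridged by
single links), `valleys` (random stepping-stone cliques bridged by single
links), `custom` (edge-list file).

## Worked example

```python
import circumskew as cs

params = cs.SimParams(c_m=0.05, mu_r=0.01, epsilon=0.25, n_time_steps=1500, seed=3)
results = cs.scenario_compare(["plain", "islands", "valleys"], params,
                              n_replicates=15, n_polities=50, last_k=500)
for name, summary in results.items():
    print(f"{name:8s} equilibrium mean z = {summary.equilibrium_mean:.3f} "
          f"(+/- {summary.equilibrium_se:.3f} s.e.)")
```

prints

```
plain    equilibrium mean z = 0.154 (+/- 0.005 s.e.)
islands  equilibrium mean z = 0.610 (+/- 0.010 s.e.)
valleys  equilibrium mean z = 0.802 (+/- 0.005 s.e.)
```

i.e. with a 5% migration cost and moderate instability (`ε = 0.25`,
`μ_r = 0.01`), an open plain of 50 polities settles at low inequality
(dominants extract ~15% of surplus, averaged over the last 500 time steps
and 15 replicates), while the same polities split into 10 islands sustain
~61%, and 3 narrow valleys ~80%.

The same experiment from the shell:

```sh
circumskew scenario --scenarios plain,islands,valleys --replicates 15 \
    --seed 3 --n-polities 50 --n-time-steps 1500 --last-k 500 --out-dir results/
```

which writes per-scenario trajectory CSVs, a `scenario_summary.json`, a
`metadata.json` (full config echo + seed + version) and a `manifest.json`
with SHA-256 checksums.  `circumskew run`, `circumskew sweep` and
`circumskew network` cover single ensembles, parameter grids and network
generation; every experiment is equally expressible as a YAML config file
(see `docs/methods.md`).

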