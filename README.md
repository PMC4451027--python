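# divlabsim

Adaptive dynamics and individual-based simulation of trade-off-driven social
division of labour.

Groups of `N` individuals drawn from a well-mixed population solve a
collective task split into two costly subtasks, A and B. Each individual
carries two heritable traits: the probability `q` of choosing subtask A and
the cost `c_A` it assigns to that task, with the complementary cost bound to
the power-law trade-off `c_A**alpha + c_B**alpha == k**alpha`. The group
benefit `beta(i)` depends on the realised task composition and is shared
either equally among all members (model I) or per task subgroup, so the
scarcer task earns more (model II).

The package provides:

- **`tradeoff_costs`** — the cost constraint, average-cost minimisation per
  `q`, and the cost-side selection-gradient term `H(q)`.
- **`group_game`** — benefit functions (Gaussian or tabulated), sharing
  rules, the binomial composition distribution, expected role payoffs, and
  invasion fitness.
- **`adaptive_dynamics`** — benefit-side gradient term `G(q)`, selection
  gradients, singular points (roots of `G + H` plus the pure boundary
  states), pure-state invasibility, and the Jacobian/Hessian
  convergence/branching classification with the closed-form criterion
  `delta_w(1/2) * 2**(1/alpha) * (alpha-1)/4 > k`.
- **`ibm_simulator`** — a numba-accelerated stochastic individual-based model
  (group games, tournament reproduction, two-trait mutation with the cost
  trait mutating uniformly in `u = c_A**alpha`), trajectory recording and an
  operational branching detector.
- **`experiments`** — batch drivers: the `(k, alpha)` branching-frequency
  sweep, the initial-condition basin grid, and asymmetric-benefit runs.
- **`cli_io` / `cli`** — YAML/JSON configuration, CSV/JSON outputs with
  checksummed manifests, and the `divlabsim` command-line tool.

## Command line

All subcommands read one config file and write tables plus a `manifest.json`
(config echo, seeds, file checksums) into `--out`:

```sh
divlabsim analyze  --config conf.yaml --out out/analysis
divlabsim simulate --config conf.yaml --out out/run --seed 3
divlabsim sweep    --config conf.yaml --out out/sweep
divlabsim grid     --config conf.yaml --out out/grid --scale desk
```

A minimal config is just the game definition; everything else is defaulted
to the reference parameterisation (Gaussian benefit 30/5/3.5, population
1000, 1000 groups/generation, 100 bouts, mutation 0.1 with half-width 0.005):

```yaml
model: I        # or II
N: 7
k: 0.25
alpha: 0.15
scale: desk     # desk-scale IBM defaults (pop 300, 2e4 generations, eps 0.02)
sweep:
  k_values: [0.25, 0.5]
  alpha_values: [0.15, 0.5, 1.5]
  replicates: 10
```

`--scale paper|desk` switches between the full-scale and scaled-down IBM
parameter sets; `--force` allows overwriting an existing output directory.
Errors are reported as one-line JSON records on stderr with a nonzero exit.

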