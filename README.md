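# leafopt

Optimal seasonal scheduling of a fully volatile protective compound
(e.g. isoprene) in tree leaves, solved as a one-state optimal-control
problem with the maximum principle.

A cohort of leaves flushes at `t = 0` and is shed at `t = T`. Leaf area
`L(t)` is lost at rate `u + h(t)/(1 + b(t) s(t))`, where `h(t)` is a
seasonal hazard (heat stress / herbivory), `b(t)` the per-unit
effectiveness of the compound, and `s(t)` the per-area production rate,
bounded by `s_max`. The plant maximizes the season total of net
assimilation `∫ (p(t) − s(t)) L(t) dt`.

The package provides:

- **`leafopt.model`** — rate-function families (constants and
  exponentially modulated cosines), the state dynamics, objective
  integrand, and Hamiltonian.
- **`leafopt.solver`** — the piecewise control law (zero / interior
  square-root branch / saturation), backward costate integration from
  `λ(T) = 0` with feedback control at every integrator stage, forward
  state integration, and objective evaluation. Fixed-step RK4 by default;
  an adaptive path via `scipy.integrate.solve_ivp` is available.
- **`leafopt.analysis`** — the closed-form switching time for constant
  rates, the root-found switching condition for seasonal rates,
  integrated hazard `H_total`, phase classification with bisection-refined
  boundaries, production/stress peak-shift diagnostics, elasticities of
  initial production, and a costate identity check (`λ(t)` equals the
  future net production per unit leaf area).
- **`leafopt.oracle`** — independent brute-force validation: exhaustive /
  coordinate-ascent direct search over piecewise-constant schedules, and a
  dominance suite (seeded random schedules + local perturbations) with a
  swapped-threshold mutation probe.
- **`leafopt.scenarios` / `leafopt.io` / `leafopt.cli`** — built-in
  scenario registry (`fig2`, `fig3`, `fig4`, `fig5a`, `fig5b`), YAML
  configuration parsing with strict schema validation, TSV/JSON export,
  and the command-line surface.

## CLI

```sh
leafopt solve --config cfg.yaml --out-dir out/    # solve a config file
leafopt scenario fig2 --out-dir out/              # built-in reproduction
leafopt scenario fig4 --sweep-b1 1,2,4            # hazard-shape sweep
leafopt sweep --b1 1,2,4                          # H_total / t_s / peak shift
leafopt elasticity --params p,h,b,u,T             # elasticities of s(0)
leafopt validate --scenario fig2 --seed 1         # brute-force oracle suite
```

Summaries are printed as JSON on stdout; resolved parameters are logged
to stderr. `--out-dir` additionally writes the trajectory table
(`*_trajectory.tsv`), a JSON summary, and a round-trippable YAML config.

An example configuration:

```yaml
rates:
  p: {family: constant, level: 1.0}
  h: {family: exp_cosine, a1: 0.0, b1: 1.0, sign: -1}
  b: {family: constant, level: 2.0}
  u: 0.0001
season: {T: 1.0, L0: 1.0, s_max: 0.155, n_steps: 20000}
```

If `s_max` is omitted, a non-binding bound (10× the unconstrained
seasonal production peak) is chosen and a warning is logged.

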