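# neqfe

Non-equilibrium alchemical free energy estimation: a library and CLI for
turning dH/dλ traces from driven alchemical transitions into absolute
binding free energies, with convergence diagnostics and benchmark
statistics.

What's inside:

- **work_io** — XVG-dialect dH/dλ parsing, trapezoidal work integration
  over a λ schedule, work-set assembly and sampling-time truncation.
  Works are stored "as performed in their own direction": for a reversible
  process W_forward = ΔG and W_reverse = −ΔG.
- **estimators** — Jarzynski (uni-directional) and maximum-likelihood
  BAR (bi-directional) ΔG estimators, bootstrap standard errors, and
  chained multi-window estimators (BAR / exponential averaging).
- **diagnostics** — a work-distribution overlap convergence measure in
  [−1, 1] (≈0 for well-converged bi-directional estimates, →1 for
  disjoint work distributions) and per-direction work summaries.
- **restraints_cycle** — the analytical standard-state correction for a
  6-DOF (Boresch-style) pose restraint, pooling of independent repeats
  into one estimate, and thermodynamic-cycle assembly
  (ΔG_bind = −ΔG_solv + ΔG_prot + ΔG_restr).
- **benchmark_stats** — AUE/RMSE/Pearson/Spearman/Kendall-τ-b versus a
  reference, combined parametric + non-parametric bootstrap errors for
  those metrics, bias-vs-sampling-time traces, and pairwise
  method-comparison matrices.
- **toysim** — synthetic ground-truth engines: a Crooks-consistent
  Gaussian work generator at known ΔG, and a one-particle overdamped
  Langevin simulator driven through a λ-dependent potential (harmonic or
  double-well) with analytically known ΔF.

Energies are kJ/mol internally (k_B = 0.0083144621 kJ/mol/K); kcal/mol
only at the reporting layer. The toy engines use reduced units (kT = 1).

## CLI

```sh
# integrate dH/dλ traces into a works CSV
neqfe integrate --forward fwd/*.xvg --reverse rev/*.xvg \
    --switch-time 500ps -T 298.15 -o works.csv

# ΔG with bootstrap uncertainty
neqfe estimate --works works.csv --method bar -T 298.15 \
    --boot 1000 --seed 42 --units kcal

# overlap/convergence report as JSON
neqfe analyze --works works.csv -T 298.15 --seed 1

# analytical restraint correction (angles in degrees, K in kcal/mol units)
neqfe restraint --r0 5.0 --thetaA 90 --thetaB 90 \
    --kr 10 --kth 10 10 --kphi 10 10 10 -T 298.15

# assemble a thermodynamic cycle from leg estimates (name:dg:se:sign)
neqfe cycle --leg solv:10.0:0.2:-1 --leg prot:14.5:0.3:1 --leg restr:-6.8:0:1

# benchmark statistics and bias traces from CSV tables
neqfe metrics table.csv --ref-col dg_exp --boot 1000 --seed 7
neqfe bias table_timecols.csv

# synthetic campaign with known ΔF (emits the works.csv schema)
neqfe toysim --kA 1 --kB 4 --snapshots 200 --switch-steps 2000 \
    --seed 11 -o works.csv
```

Every command prints a JSON summary (including the resolved seed) and uses
exit codes 0 (success), 1 (domain error), 2 (usage error).

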