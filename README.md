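# growthcurve

Per-timepoint statistical testing of two-arm tumor growth curves with lag
conditioning, plus the conventional comparators and Monte-Carlo power
machinery.

The central procedure (the *homologous test*) compares the two arms' mean
volumes at a time point `j` while conditioning each arm on its own sample mean
at time `j − 1`. The point estimate of the group difference is algebraically
identical to the plain difference of time-`j` means, but its standard error is
driven by the conditional variance `Var(Y_j) · (1 − ρ²)` — with strongly
autocorrelated growth curves this is far smaller than the marginal variance the
two-sample t test must use. Inference runs through a single four-coefficient
regression (intercept, group, lagged volume, group × lagged volume) with the
contrast `z = (0, 1, ȳ₁,prev − ȳ₀,prev, ȳ₁,prev)` referred to a t distribution
on `n − 4` df.

Note the semantics: the test addresses the *conditional* null (equal
conditional means at the observed lagged group means), which differs from the
marginal mean-equality null by a term driven by the chance difference of the
arms' lagged means. The Monte-Carlo engines expose a `calibrate` switch that
pins this term to zero in the data generation, which is the configuration under
which the published operating characteristics hold.

## Modules

- `growthcurve.homologous_core` — dataset container, per-arm lag summaries and
  conditional regressions, the combined four-coefficient regression, the
  contrast and its t-based inference (`homologous_test`).
- `growthcurve.comparators` — pooled-variance two-sample t test, closed-form
  noncentral-t power for both tests, and a random-intercept linear mixed model
  (group difference at the final time point, Satterthwaite df by default)
  backed by a fast profiled-REML solver.
- `growthcurve.simulation` — vectorised Monte-Carlo engines: the
  regression-model power study (`simulate_study1`) and the six-timepoint
  compound-symmetry panel study comparing homologous / t / LMM
  (`simulate_study2`), with scenario builders.
- `growthcurve.growthcurve_io` — wide/long CSV reading and writing, the
  per-timepoint report (means, both SE flavours, lag correlations, both
  p-values), and a deterministic synthetic-study generator.

## CLI

```sh
# synthetic two-arm study (4 animals/arm, 9 days), wide CSV
growthcurve fixture --out study.csv --seed 7

# homologous test at the 9th time point
growthcurve test --input study.csv --j 9 --sides two

# full per-timepoint report (TSV; add --json-out for full precision)
growthcurve report --input study.csv --json-out report.json

# closed-form power
growthcurve power --test t --n 16 --delta 1 --sd 1

# Monte-Carlo studies
growthcurve simulate-study1 --sigma 0.4 --reps 10000 --seed 1
growthcurve simulate-study2 --scenario null --reps 10000 --seed 1
```

Input CSV dialects: wide `animal_id,group,<t1>,<t2>,...` (canonical) or long
`animal_id,group,time,volume` via `--dialect long`. Group labels other than
0/1 require `--control <label>` to name the reference arm; `--log` analyses
natural-log volumes.

## Worked-example data

The published worked example's raw measurements are only available in that
study's supplementary file. If a copy is placed at
`data/supplementary_tumor_volumes.csv` (wide dialect, control arm labelled
`IL-1Ra`), the test suite checks the printed day-24 conditional SE end to end;
otherwise the example surface is exercised with the synthetic generator.
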