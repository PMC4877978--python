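# finebin

Non-parametric ungrouping of coarsely binned count data.

Health and demographic statistics are routinely published as coarse
histograms — age-specific death or disease-onset counts in 5-year
classes, often ending in an open-ended "85+" group. `finebin` estimates
the underlying single-year distribution from such tables, for
epidemiologists and demographers who need detailed age patterns (to
compare across sources with different boundaries, study the oldest ages,
or feed downstream models) but only have grouped counts.

## Methods

Five non-parametric methods, all guaranteeing non-negative estimates:

- **pclm** — penalized composite link model. Observed counts
  `y_i ~ Poisson(μ_i)` with `μ = Cγ`, where `γ_j = exp(β_j)` is the
  latent single-year expected count and `C` sums unit bins into the
  observed intervals. `β` maximizes the penalized likelihood
  `L* = L − (λ/2)‖D₂β‖²` via modified IRWLS; the smoothing weight λ
  minimizes `AIC = deviance + 2·ED`, with ED the trace of the hat
  matrix.
- **hyman** — cubic spline through the cumulative counts with the Hyman
  monotonicity filter on its knot derivatives; single-year counts by
  unit differencing `f(x) = F(x+1) − F(x)`.
- **pchip** — monotone piecewise cubic Hermite interpolation of the
  cumulative counts (Fritsch–Carlson limiting), differenced the same way.
- **ickde** — iterated conditional-expectation kernel density estimator:
  the kernel term of each grouped observation is replaced by its
  expectation under the current within-interval density, iterating from
  the histogram.
- **bootkde** — smoothed-bootstrap kernel density estimator: pseudo
  observations drawn uniformly within their intervals, Gaussian KDE per
  replicate, averaged over replicates; bandwidth by estimated-ISE
  minimization.

A simulation harness samples a Weibull(shape 8, scale 82) age-at-death
target, groups it (5-year classes with or without a wide 85+ group),
runs all methods, and scores each against the truth by integrated
absolute error `Σ|f̂−f|`, integrated squared error `Σ(f̂−f)²`, and
Kullback–Leibler distance `Σ f·log(f/f̂)` on the single-year grid.

## Worked example

```python
import finebin as fb

edges = list(range(0, 90, 5)) + [115]          # 5-year classes, 85+ closed at 115
counts = [6, 2, 3, 5, 6, 9, 13, 19, 27, 38, 52, 67, 81, 89, 85, 68, 44, 21]
gc = fb.append_closing_interval(fb.GroupedCounts(edges, counts), 130)

est = fb.pclm_ungroup(gc)                      # AIC-tuned PCLM
print(est.settings)                            # lambda*, ED, AIC
print(est.gamma[85:90])                        # expected deaths at 85..89
```

Running `python examples/ungroup_table.py` on this table prints

```
total deaths: 635 in 19 intervals
pclm: lambda*=3.24e+03, effective dimension=7.16, AIC=19.07
...
sum over 85+: pclm=26.43, hyman=21.00, observed=21
grand total:  pclm=635.00, hyman=635.00, observed=635
```

i.e. the AIC-selected fit uses about 7 effective parameters; the spline
reproduces every interval count exactly while PCLM conserves the grand
total and trades a little local fidelity for smoothness. And
`python examples/compare_methods.py` scores one simulated n=1000
replicate under the open-ended scheme:

```
method        IAE        ISE       KL
pclm       0.0846   0.000144   0.0079
hyman      0.1561   0.000607   0.0679
pchip      0.2614   0.001914   0.1307
ickde      0.1635   0.000538   0.0380
bootkde    0.3502   0.002954   0.1700
```

— the composite link model redistributes the wide 85+ interval best;
the other methods either twist near the wide interval (splines) or
smear its mass uniformly (kernels).

Other entry points: `examples/run_simulation.py` (scaled-down scenario
comparison), and a thin CLI —

```sh
finebin fit --input grouped.csv --method pclm --close-at 115 --out fine.csv
finebin simulate --scenario 4 --reps 50 --seed 1 --out results/
```

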