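# polymax

Maximal point-polyserial correlation between a continuous random variable
and a k-category ordinal variable, plus everything that hangs off that
question:

- **Attainable correlation bounds** (Fréchet–Hoeffding): the interval of
  Pearson correlations reachable for two fixed margins, by closed form
  (lognormal pairs) or quantile quadrature.
- **Maximal point-polyserial correlation** for a given discretization,
  through closed-form partial moments of seven families (normal, uniform,
  exponential, Pareto, logistic, power, lognormal).
- **CIS optimization**: the probability vector on consecutive integer
  scores 1..k maximizing the correlation (SQP on the simplex, plus the
  exact two-variable shift/scale reformulation), with the
  equal-threshold-spacing optimality diagnostic.
- **OPT optimization**: free support values — Lloyd's algorithm, i.e. the
  k principal points / optimal quantizer.
- **Equal-probability closed forms and their k→∞ limits** per family.
- **Copula experiment**: point-polyserial vs. polyserial correlation
  ratios when the pair is linked by a Gauss, Frank, Clayton, or Gumbel
  copula calibrated through Spearman's rho.
- **k-point discrete approximations** compared side by side:
  moment-standardized max-correlation CIS, principal points, and
  Golub–Welsch moment matching (first 2k−1 moments).
- **Synthetic fixtures**: seeded bivariate continuous/ordinal samples
  (comonotone, countermonotone, or copula-linked) for Monte-Carlo
  cross-validation, and the sorted-sample empirical maximal correlation.

## Library quick tour

```python
import polymax as pm

normal = pm.make_distribution("normal")

# equal-probability closed form and its large-k limit
pm.equalprob_maxcorr(normal, 5)        # 0.9423...
pm.limit_equalprob(normal)             # sqrt(3/pi) = 0.977205...

# best probability vector on scores 1..10 for a Pareto(4) variable
res = pm.maximize_cis(pm.make_distribution("pareto", 4.0), 10)
res.rho, res.disc.probs                # 0.9439, strongly decreasing probs

# principal points of the unit exponential (free-support optimum)
opt = pm.maximize_opt(pm.make_distribution("exponential", 1.0), 7)
opt.disc.values, opt.disc.probs

# attainable Pearson correlation interval for two lognormals
pm.attainable_bounds(
    pm.make_distribution("lognormal", 0, 1),
    pm.make_distribution("lognormal", 0, 2),
)                                       # (-0.090, 0.666)

# copula-linked ratio curve (data behind the ratio plots)
pm.ratio_curve("frank", k=2).to_records()
```

## CLI

Installed as `polymax`:

```sh
polymax optimize --family "pareto:alpha=4" --k 10 --mode cis
polymax optimize --family exponential:rate=1 --k 7 --mode opt
polymax limits --family logistic --k 1000
polymax copula-ratio --family gauss --k 2 --out curve.csv
polymax approx-table --family normal --k 7
polymax fixtures --family normal --k 6 --dependence comonotone \
    --n 100000 --seed 7 --out pair.csv
polymax empirical pair.csv
polymax bounds "lognormal:mu=0,sigma=1" "lognormal:mu=0,sigma=2"
```

Families are spelled `family:name=value,...`; bare names use standard
parameters (standard normal, uniform(0,1), standard logistic, unit-rate
exponential).

## Notes

- Only standardized family forms are exposed: Pearson correlation is
  invariant under positive affine transformations, so location-scale
  variants would not change any result.
- The printed limit formulas are implemented with the radical placement
  that reproduces the published decimals and are unit-tested against
  large-k evaluation of the exact finite-k expressions.
- Moment matching is capped at k = 12; beyond that double precision in the
  Jacobi-matrix eigenproblem is no longer trustworthy even with the
  extended-precision Chebyshev recurrence step.
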