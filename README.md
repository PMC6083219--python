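# skewtlst

Simulation, maximum-likelihood estimation and Monte Carlo evaluation of
**skew-t mixture latent state-trait (LST) models** for longitudinal data.

Within each latent class, two indicators observed over *j* occasions
decompose into a common trait, an indicator-specific trait residual, one
occasion-specific factor per occasion, and measurement error.  The trait
follows a restricted multivariate skew-t (rMST) distribution; under the
shared t-mixing construction the whole observed vector is rMST, which gives
the two-class mixture a closed-form likelihood.

## Modules

| module | what it does |
|---|---|
| `skewtlst.rmst_core` | rMST density, sampler and moment formulas, with the t / skew-normal / normal special cases |
| `skewtlst.lst_spec` | model specification, identification and invariance constraints, free-parameter packing, model-implied observed-variable distribution |
| `skewtlst.synthetic_data` | design-grid enumeration (4 sample sizes × 5 occasion counts × 2 skewness levels) and reproducible replication datasets |
| `skewtlst.estimator` | direct quasi-Newton ML of the two-class mixture, observed-information standard errors, warning diagnostics |
| `skewtlst.postprocess` | label-switching detection/correction and replication inclusion rules |
| `skewtlst.evaluation` | per-condition, per-parameter relative parameter bias, SE bias, MSE, 95% coverage, threshold classification |
| `skewtlst.cli_io` | YAML configs, results bundles, CLI orchestration |

## CLI

```bash
skewtlst fixtures --skew 2.8 --out fixture.yaml     # default truth values
skewtlst simulate --conditions "N=250,j=3,skew=2.8" --reps 5 --out data/
skewtlst run-all  --conditions "N=500,j=4,skew=6"   --reps 50 --seed 1 --out results/
skewtlst evaluate results/estimates.csv --truth-yaml fixture.yaml --occasions 4
```

`run-all` writes `estimates.csv`, `status.csv`, `eval_table.csv`,
`summaries.json` and a `manifest.json` recording every seed, so a bundle is
fully reproducible from its manifest.  Replications are independent and
seeded individually; `--workers` parallelizes without changing results.

## Python API sketch

```python
from skewtlst import lst_spec, synthetic_data, estimator

truth = lst_spec.default_fixture(delta_T=2.8)            # package fixture values
cond = synthetic_data.SimCondition(N=500, n_occasions=4, delta_T=2.8, base_seed=1)
ds = synthetic_data.simulate_dataset(cond, rep_index=0, truth=truth)
fit = estimator.fit_mixture(ds.data, cond.spec(), start=truth)
print(fit.loglik, fit.estimates, fit.standard_errors)
```

Note: the shipped default fixture parameters are illustrative values chosen
to satisfy the design's ordering constraints; they are not estimates from
any dataset.

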