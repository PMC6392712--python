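# physmig

Residual-method estimation of inter-prefectural physician migration.

Regional inequality in physician supply persists even in countries whose
total physician stock is growing, and no registry records where physicians
move after licensure. `physmig` implements a demographic-accounting estimator
of net physician migration between prefectures, built from two public
quantities only: the practicing-physician stock per prefecture (observed at
biennial surveys) and the annual count of newly licensed physicians
attributed to the prefecture of their medical school. It targets health-
services researchers studying workforce distribution, and ships a synthetic
panel generator with exact ground truth so the whole chain is testable
without restricted survey data.

## The method

Over a study window `[b, f]`, with `L_i` the cumulative newly licensed count
in prefecture *i* and `S_i(t)` its practicing stock:

1. **National attrition (residual).** Deaths and retirements are not
   reported, so the national total is the accounting residual
   `A = Σ_i L_i − Σ_i (S_i(f) − S_i(b))`.
2. **Proportional allocation.** `A` is split across prefectures in
   proportion to each prefecture's mean observed stock over the window:
   `Â_i = A · m_i / Σ_j m_j`. The identifying assumption is a uniform
   per-physician attrition rate.
3. **Net migration.** The *adjusted* newly licensed count
   `L_i − Â_i` is the stock increase prefecture *i* would have seen with no
   migration; subtracting the actual increase gives the net migrant count
   `M_i = (L_i − Â_i) − (S_i(f) − S_i(b))`, positive for net outflow,
   negative for net inflow. The **migration ratio** `M_i / L_i` can exceed
   100% in magnitude for strong inflow. By construction `Σ_i M_i = 0`,
   the method's key internal check.

Prefectures are then sorted by migration ratio into four groups (high/low
outflow, low/high inflow; 47 prefectures split 11/12/12/12 with the short
block at the high-outflow extreme), and the signed ratio is regressed on
eight socio-demographic covariates (practicing physicians per 100,000
population, annual newly licensed per 100,000, physician mean age, female
physician ratio, inhabitable-land population density, unemployment ratio,
aged-population ratio, average income) by per-covariate simple OLS and one
joint OLS.

## Worked example

```bash
cat > pipeline.yaml <<'YAML'
simulation: {}        # calibrated defaults: 47 prefectures, 1994-2014
seed: 1
out_dir: out
YAML
physmig run --config pipeline.yaml
cat out/summary.txt
```

prints (abridged):

```
window: 1994-2014 (20 years), 47 prefectures, strict=True, seed=1

national totals (residual accounting):
  new licensed: 152265.0 (7613.2/yr)
  estimated deceased/retired: 69357.0 (3467.9/yr)
  increase: 82908.0 (4145.4/yr)

maximum outflow ratio: 98.1% (P15)
maximum inflow ratio: 86.8% (P47)
flow difference: 184.9%
zero-sum check: sum of net migrants = -4.002e-11

joint regression (n=47, alpha=0.05): significant after adjustment: new_licensed_ppr
```

Reading it: the Step-1 residual attributes 69,357 of the 152,265 licensed
physicians to deaths/retirements; the most extreme prefectures lose 98% or
gain 87% of their own licensing output to migration (flow difference 184.9%);
net migrants sum to zero up to float rounding; and after adjustment only the
newly licensed-physician rate per 100,000 population predicts the migration
ratio — high-licensing prefectures export physicians — exactly the structure
the generator plants. Stage-by-stage equivalents: `physmig simulate`,
`estimate`, `classify`, `regress` (see `physmig --help`). Real data can be
supplied as CSVs with columns `prefecture,year,stock,new_licensed` and
`prefecture,<eight covariates>` via `panel_path`/`covariates_path` in the
pipeline config.

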