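# plymod

Static microsimulation of the indirect costs of ischemic heart disease (IHD)
through lost productive life years (PLYs) among older workers (45–64 years),
projected to 2015/2020/2025/2030.

A *lost PLY* is a person who is out of the labour force in a given year
because of their own ill-health or disability and whose main chronic
condition is in the IHD group (heart disease, angina, myocardial
infarction). The model values those lost years from three perspectives:

* **individuals** — lost weekly income, aggregated to annual national lost
  income;
* **government** — extra welfare payments and lost income-tax revenue;
* **society** — lost GDP via a proportional-labour decomposition.

The original analysis runs on restricted survey and tax/transfer microdata
(a national disability survey base file and a static incomes model as the
economic donor pool). `plymod` re-implements the full pipeline as a tested,
reusable library and replaces the restricted inputs with a synthetic-data
module whose group shares, income medians and welfare/tax structure are
anchored to the published 2015 weighted table — so every stage runs, and is
validated, without any external data.

## Pipeline

1. **Synthetic data** (`plymod.population`) — a base survey file of 45–64
   year olds (demographics, six-state labour-force status, "own ill-health"
   NILF reason, main-condition codelist, survey weights) and a disease-blind
   economic donor pool carrying the ten matching variables plus weekly
   income, welfare and tax in 2013 dollars.
2. **Synthetic matching** (`plymod.imputation`) — hot-deck imputation of the
   three economic variables onto every person from a donor sharing the ten
   matching variables (sex, age group, labour-force status, DSP receipt,
   age-pension receipt, education, income quintile, hours band, income-unit
   type, home ownership), dropping variables from the end of that priority
   order when a cell is empty.
3. **Static ageing** (`plymod.ageing`) — GREGWT-style chi-square calibration
   of weights to age×sex population totals and full/part-time employment
   benchmarks; proportional chronic-disease prevalence trends (frozen after
   2023); uprating of income/tax at 1 %/yr real and welfare at zero real
   growth from the 2013 economic base.
4. **Cohorts** (`plymod.cohorts`) — lost-PLY identification and the
   five-group classification (employed FT/PT with/without IHD, NILF due to
   IHD) with weighted mean/SD/median summaries.
5. **Counterfactual Monte Carlo** (`plymod.counterfactual`) — for each
   lost-PLY case, a counterfactual drawn at random with replacement from a
   no-IHD donor pool matched on sex, age group and education; 1000
   replicates; percentile 95 % CIs.
6. **Cost aggregation** (`plymod.costs`) — weekly differences × weighted
   lost-PLY count × 52 weeks → AU$ millions/year; lost GDP =
   GDP × lost workers / reference workforce.
7. **Reporting** (`plymod.reporting`) — recomputation of every published
   derived ratio/percent-change from its printed inputs, and cost-series
   figures with CI bands.

## Worked example

```python
import plymod as pm

cfg = pm.ScenarioConfig(n_records=25_104, n_donors=25_000, n_sims=1000)
res = pm.run_scenario(cfg, seed=1)

t1 = res.table1
row = t1[(t1.year == 2015) & (t1.group == "nilf_ihd")].iloc[0]
print(f"lost PLYs 2015: {row.weighted_count:.0f} persons "
      f"({100 * row.share:.2f}% of the population), "
      f"median weekly income ${row.weekly_income_median:.2f}")
print(res.national_costs.round(2).head(1).to_string(index=False))
```

prints

```
lost PLYs 2015: 2670 persons (0.11% of the population), median weekly income $369.47
 year  n_lost_ply  lost_income  lost_income_lower  lost_income_upper  extra_welfare  ...  lost_gdp  potential_gdp_gain_pct
 2015     2670.13       123.55              70.35             190.30          33.14  ...    312.84                    0.02
```

Reading this: on the synthetic file, about 0.11 % of 45–64 year olds are out
of the labour force due to IHD in 2015 — the published population share.
Their median weekly income sits far below the full-time median, and the
whole-labour-force counterfactual comparison values the loss at AU$123.5M of
income per year (95 % CI 70.4–190.3), AU$33.1M of extra welfare and
AU$34.2M of lost tax, on the synthetic file's population scale (the
synthetic file represents ~2.5M people versus ~5.9M nationally, so national
dollar levels are proportionally smaller). The same run projects 2020–2030
by recalibrating weights to each year's benchmarks.

The same pipeline is available from a shell:

```bash
plymod run --seed 1 --year all --out results/
plymod repro --out report.csv
```

`plymod run` writes `table1.csv` (group summaries), `table2.csv`
(counterfactual differences), `national_costs.csv`, `gdp.csv`, figures, and
`run.log`; `plymod repro` writes the derived-statistics reproduction report.

## Layout

```
src/plymod/
  population.py      synthetic base survey + donor pool generators
  imputation.py      ten-variable hot-deck matching with fallback
  ageing.py          GREGWT calibration, disease trends, uprating
  cohorts.py         lost-PLY identification, groups, weighted summaries
  counterfactual.py  matched Monte Carlo + percentile CIs
  costs.py           national costs, lost GDP, derived-ratio helpers
  reporting.py       derived-statistic reproduction, figures
  pipeline.py        end-to-end scenario runner
  published.py       published reference values (generator anchors + fixture)
  data/gdp_inputs.csv  projected GDP and reference workforce by year
```

See `docs/methods.md` for the model description, parameter defaults, and
the limits of what the synthetic-data validation shows.
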