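# Methods

## Model overview

`plymod` is a *static* microsimulation: it never simulates life-course
events. A base-year person file is made to represent a future year by
changing weights (calibration, disease trends) and indexing dollar amounts
(uprating), and outcomes are then computed on the reweighted file. Mortality,
migration and labour-force transitions are outside the model by
construction; the projections answer "what would the cross-section look like
in year Y" rather than "what happens to these people".

The quantity of interest is the number of people aged 45–64 who are out of
the labour force because of their own ill-health with an ischemic heart
disease (IHD) main condition — lost productive life years (PLYs) on a
prevalence basis — and the weekly income, welfare and tax gaps between them
and matched counterfactuals who are in the labour force without IHD. Gaps
are valued with the human capital approach: the full earnings stream forgone
while out of the labour force.

## Synthetic data

The real base file is a restricted national disability survey; the real
economic donor pool is a restricted static incomes model. The generator
reproduces the statistical structure those stages rely on:

* **Group shares.** Each record is assigned to one of six analysis groups
  (employed FT/PT with/without IHD, NILF-due-to-IHD, other) with
  probabilities equal to the published 2015 weighted shares (53.08 %,
  1.06 %, 20.09 %, 0.40 %, 0.11 %, remainder). The residual group mixes
  unemployment (30 %), NILF for non-health reasons (49 %), NILF due to
  ill-health with a non-IHD condition (18 %) and a small not-applicable
  slice (3 %).
* **Income laws.** Employed weekly incomes are log-normal, anchored so the
  median equals the published 2015 group median (FT 1305.46, PT 600.78,
  2013 AU$/week) and the log-sigma reproduces the published mean/median
  ratio (sigma ≈ 0.61 FT, 0.57 PT). Log-normality is the standard
  right-skew assumption for income microdata, and medians are the only
  printed location statistics to anchor on.
* **Welfare-led NILF economics.** Out-of-labour-force donors receive a
  disability-pension-style payment, normal with median 321.87 and SD 117.62,
  clipped at zero; their total income is welfare divided by 0.7740
  (= 321.87/415.83), so welfare is ~77 % of income and the income median is
  415.83 — the published structure of the lost-PLY group. Their tax is
  exactly zero.
* **Tax scale.** A stylised two-bracket weekly scale (19 % above ≈521.8,
  ≈33.5 % above 700) chosen so the FT and PT median incomes map exactly
  onto the published median taxes (236.70 and 15.00). Tax is a deterministic
  function of income; that is enough structure for everything downstream.
* **Weights.** Uniform on [50, 150] persons per record — positive,
  moderate-variance, so weighted statistics are genuinely exercised rather
  than degenerate at equal weights.
* **Scale.** The default file has 25,104 records, the size of the pooled
  survey the analysis concatenates; the weighted file then represents
  ~2.5M people, about 42 % of the real 45–64 population, so synthetic
  dollar aggregates are proportionally smaller than the published national
  levels. All level comparisons in the tests are therefore against the
  generator's own targets; published *levels* are never asserted from
  synthetic runs.

What the generator does **not** emulate: household structure beyond the
income-unit type, correlation between education/quintile and income within
groups, disclosure-accurate survey design effects, multi-condition
comorbidity, and the with-IHD employed groups' slightly lower incomes (the
donor pool is disease-blind, as the real economic model is). Passing tests
show the pipeline's statistical machinery is correct under the published
marginal structure, not that the synthetic file is a substitute for the
restricted microdata.

## Synthetic matching (hot-deck imputation)

The ten matching variables are ordered by their importance for income:
sex, age group, labour-force status, DSP receipt, age-pension receipt,
education, income quintile, hours band, income-unit type, home ownership.
A person takes the income/welfare/tax of a donor drawn uniformly at random
from the exact ten-variable cell; if the cell is empty, variables are
dropped one at a time from the *end* of the order until a donor exists
(`fallback_depth` = number dropped), never below (sex, age group). Hours
are matched as bands (0, 1–34, 35+): exact-hours cells would be empty at
any realistic pool size. Donors are sampled with replacement across
recipients, and donor cells are sorted by donor id so results are invariant
to donor file order. Records unmatched even at (sex, age group) are dropped
and counted — with the default generator this does not occur.

## Calibration (GREGWT-style)

Weight calibration minimises the chi-square distance
`sum_i (w_i - d_i)^2 / d_i` subject to `X'w = t`, whose solution is the
linear form `w_i = d_i (1 + x_i'lambda)` with `lambda` solved from
`(X' diag(d) X) lambda = t - X'd`. Weights pushed outside ratio bounds
(default 0.1–10 times the input weight) are truncated and frozen, and the
system is re-solved on the free records against the residual targets until
no new truncations occur — the iterative restricted loop of GREGWT-family
calibration. Margins are the age-group × sex population totals plus
full-time and part-time employment *counts* (rate × population) per cell:
the two benchmark families the projection uses. Convergence is max relative
margin error ≤ 1e-6 (default); non-convergence returns diagnostics rather
than raising, while a structurally infeasible margin (positive target, no
contributing records) raises immediately naming the cell. The linear solve
uses `lstsq`, so collinear margins degrade gracefully.

Default benchmarks scale the base file's own cell totals by the published
45–64 population series (5.945M → 7.130M over 2015–2030) and drift the
cell employment rates with the published aggregate full-time (54.1 % →
55.8 %) and part-time (20.5 % → 22.1 %) shares — an emulation of the
external population/labour-force projections on the synthetic file's scale.

## Disease trends

Within each sex × age-group stratum, the weight of records whose main
condition maps to a trended disease (IHD group, stroke, cancer, type 2
diabetes, COPD) is scaled by `m^(min(year, 2023) - 2009)`, where `m` is the
disease's annual prevalence multiplier and 2023 is the stabilisation year
after which prevalence is frozen. Untrended records are rescaled so the
stratum total is conserved to machine precision. Default multipliers follow
the directions of the national burden-of-disease trends the analysis cites
— IHD 0.99/yr both sexes, cancer 1.0, stroke 0.995, type 2 diabetes 1.02,
COPD 1.0 (men) / 1.01 (women); the magnitudes are scenario defaults, not
published values. A multiplier implying stratum prevalence above one
raises.

## Uprating

Income and tax are multiplied by `1.01^(year - 2013)` (1 %/yr real growth);
welfare by `1.0` (zero real growth — indexation to CPI only). Uprating
touches only dollar columns and calibration only the weight column, so the
two commute exactly; the composition order used is trends → calibration →
uprating.

## Counterfactual Monte Carlo

Cases are the NILF-due-to-IHD records; donor pools are employed-FT-no-IHD,
employed-PT-no-IHD, or the whole labour force without IHD (full-time,
part-time and unemployed job seekers) — the last is what national costs are
defined against. Matching is on (sex, age group, education), with the same
drop-last-variable fallback (education first). Within a cell, donors are
drawn with replacement with probability proportional to their survey weight
(a config switch allows uniform draws; weight-proportional is the default
because it preserves the pool's population representativeness). Each of the
1000 replicates draws one full counterfactual set — shared across the three
outcomes — and records the case-weighted mean difference per outcome.
Replicate k uses a sub-seed spawned deterministically from the master seed
(`numpy` SeedSequence), so runs are reproducible and replicate order is
irrelevant. The point estimate is the mean of the replicate draws; the 95 %
CI is the nearest-rank percentile interval (order statistics 25 and 975 of
1000). Negative differences mean cases receive less than counterfactuals.

### What the validation studies show

The recovery study builds case and donor frames with incomes normal around
415.83 (SD 86.41) and 415.83 + 950 (SD 500) respectively — a designed
case-vs-full-time gap of $950/week, the published 2015 point estimate used
as the design value — with exact truncation-corrected truths. The point
estimate must land within 3 analytic Monte-Carlo SEs of truth (the SE
accounts for case sampling, the finite donor pool's shared cell means, and
residual assignment noise). The coverage study repeats the synthesis 200
times (400 cases, 500 donors) and checks the percentile CI covers the
design truth at the nominal 95 % rate within a 3-SD binomial band. The
percentile interval quantifies Monte-Carlo (assignment + finite-pool)
uncertainty; its coverage of the design truth is nominal when those sources
dominate case-sampling noise, which the chosen sizes ensure — with a much
larger donor pool the interval is conservative for the design truth. It
does not, and is not claimed to, capture survey sampling variance of the
case file.

## Cost aggregation

Annual national cost = |weekly difference| × weighted lost-PLY count × 52
weeks / 1e6, in AU$ millions (2013 dollars); CI endpoints pass through the
same monotone map and are reordered when the map is decreasing. The
52-week annualisation is config-overridable; it is the convention
consistent with the published weekly/annual pairs. Lost GDP uses a
proportional-labour decomposition, GDP × lost workers / reference
workforce. The packaged `data/gdp_inputs.csv` carries the published
projected-GDP rows; the reference workforce column is *derived* by
back-solving the published GDP, lost-GDP and lost-worker values
(≈12.66M employed persons in 2015 rising to ≈15.47M in 2030 — a plausible
national workforce), since the underlying projection series is not printed.
With those inputs the formula returns the published lost-GDP values for the
published lost-worker counts, which is the intended self-consistency.

## Derived-statistic reproduction

Every ratio, share and percent change the analysis prints is recomputed
from its printed inputs and compared after half-up rounding to two decimals
(rounding is applied only at comparison time, never inside computation).
Four printed values do not survive recomputation and are carried as flagged
display-only entries: the 19.95 % population growth (recomputes to 19.94),
the "about 58.12 %" tax-revenue growth (58.11), and two discussion-section
growth figures (43.91 % welfare, 63.94 % income-difference) that recompute
to 34.91 % and 33.62 % from the printed inputs. They are reported, never
asserted.

## Numerical and design choices

* Weighted median: lower-median convention (smallest value whose cumulative
  weight reaches half the total) — deterministic and order-independent.
* Weighted SD: population convention `sqrt(sum w (x - mean)^2 / sum w)`; a
  single record has SD 0.
* Nearest-rank quantiles use a 1e-9 slack before the ceiling so exact
  binary-representable ranks (0.025 × 1000) do not round up spuriously.
* Stage seeds (generation, imputation, Monte Carlo) are drawn from a single
  master seed through one generator, so one integer reproduces a whole run;
  all derived seeds stay below 2^31.
* Empty analysis groups are reported with zero count and NaN moments rather
  than dropped, so the partition property is visible in every summary.
* Problem sizes: the default scenario uses the pooled-survey record count
  (25,104 records, 25,000 donors, 1000 replicates) and runs in seconds;
  validation studies use 1000-record calibration files and 400–500-case
  recovery studies, sizes at which every asserted tolerance has comfortable
  statistical margin.

## Known limitations

* No mortality, migration, or labour-force transition dynamics (static
  model by design).
* Only the main chronic condition is consulted; comorbidity is ignored.
* The synthetic donor pool is disease-blind, so imputed incomes for the
  with-IHD employed groups inherit the no-IHD distributions.
* National dollar outputs from synthetic runs are on the synthetic file's
  population scale and are not comparable to published levels; derived
  ratios and validation properties are the comparable surface.
* The whole-labour-force counterfactual includes unemployed job seekers
  whose imputed incomes are welfare-led, so national lost-income estimates
  are smaller than FT-only comparisons — as in the published design.
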