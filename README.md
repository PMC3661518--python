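# pmslt

A proportional multi-state life table cost-effectiveness model for
population-level bariatric (gastric banding) surgery, implemented as a tested,
reusable Python pipeline:

1. **synthetic_data** — generates internally consistent model inputs
   (age-sex population counts, Gompertz all-cause mortality, disability
   rates, nine obesity-related diseases with incidence/case-fatality
   tables, lognormal BMI distributions with a secular trend, relative
   risks per BMI unit, unit costs) from a single seed.
2. **risk_model** — lognormal BMI exposure, five-category partition
   (cutpoints 25/30/35/40), category relative risks, exposure shifting
   and the potential impact fraction (PIF) that rescales disease
   incidence.
3. **disease_model** — per-disease illness-death life tables turning
   (pre/post-PIF) incidence into prevalence, disease mortality and
   disability by age.
4. **lifetable** — the master proportional life table: all-other-cause
   decomposition, post-intervention recomposition, survivorship,
   (disability-adjusted) life years, DALYs averted.
5. **intervention** — eligibility (BMI > 40 or BMI > 35), the
   piecewise-linear weight-loss trajectory (0 → 27.4 kg at 2 y → 32 kg at
   3 y, optional 15-year attenuation), post-surgical mortality and
   long-term complication risks.
6. **economics** — costs, cost offsets (prevalent case-years for chronic
   disease, incident cases for cancers), discounting, net cost, ICER with
   dominance, the sensitivity/costing grid, budget impact.
7. **uncertainty** — Monte Carlo uncertainty analysis (normal /
   beta-from-count / gamma-from-mean-SE / relative-risk samplers,
   3000-iteration default, rank-based ICER intervals with "dominant"
   labels, cost-effectiveness probabilities).
8. **interface** — configuration (YAML + CLI), orchestration, file I/O.

## CLI

```bash
pmslt synth --seed 1 --out data/                # write input CSVs
pmslt run --scenario bmi40 --seed 1 --out out/  # one deterministic run
pmslt grid --seed 1 --out grid.csv              # full sensitivity grid
pmslt psa --iterations 3000 --seed 1 --out psa/ # Monte Carlo analysis
pmslt budget-impact --eligible 140673 --govt-expenditure 35729000000
pmslt pif-table --seed 1 --out pif.csv
```

Every run can alternatively read inputs from `--input-dir` (the CSVs that
`pmslt synth` writes) instead of regenerating them from the seed.

## Layout

```
src/pmslt/        one module per pipeline stage (listed above) + cli
tests/            pytest suite; test_acceptance.py holds the acceptance criteria
scripts/          acceptance.py report generator
```
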