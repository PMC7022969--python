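# herdledger

Event-record analytics for dairy herds that use an on-farm management
information system (MIS). Given long-format herd event logs — calvings,
confirmed conceptions, daily milk weighings, clinical mastitis and
lameness cases, cullings — the package answers two questions a herd
advisor or veterinary epidemiologist cares about:

1. **Does more consistent record keeping go together with better herd
   performance over the first years of MIS use?** Herds are classified
   by *adoption level* (LOW = reproductive records only, MEDIUM = plus
   productive records, HIGH = plus health records, each requiring at
   least five consecutive recorded years), six herd-year performance
   traits are derived, and their trends across follow-up years are
   estimated with a linear mixed model.
2. **Is the MIS worth its money?** A partial budget compares the extra
   costs of running the system (hardware/software amortization, data
   collection and entry labor) with the income from the trait
   improvements, including deterministic (±10 %) and Monte-Carlo
   sensitivity analysis and the break-even herd size.

A synthetic herd-event generator with the same statistical structure
(published trait baselines, between-herd heterogeneity, within-herd
AR(1) serial correlation, adoption-dependent record availability) makes
the whole pipeline testable without access to any proprietary herd
database.

## The model

Each trait `Y` (age at first calving AFC, days open DO, daily milk yield
DMY, productive life PL, mastitis incidence MAST, lameness incidence
LAM; the two incidences are log-transformed) is analyzed at the
herd-year level:

```
Y_hj = β₀ + β₁·ER + β₂·PB + β₃·HS + β₄·CP + β₅·AL + β₆·FY + β₇·AL×FY
       + b_h + e_hj
```

with categorical fixed effects for agroecological zone (ER), predominant
breed (PB), herd-size class (HS), five-year calendar period (CP),
adoption level (AL), follow-up year (FY, 1–10) and the AL×FY
interaction; a random herd intercept `b_h ~ N(0, σ²_between)`; and a
within-herd AR(1) process `e_hj` with marginal variance σ²_within and
correlation ρ^|Δyear|. Estimation is by REML with the scale profiled
out. Marginal (least-squares) means per AL×FY cell average the linear
predictor with equal weights over the nuisance factors; for the
log-transformed incidences they are back-transformed to geometric means.

The partial budget uses `GM = ΔI − ΔC` and `MRR = 100·GM/ΔC`, where ΔI
accrues each trait's annual change × economic value × cows once per year
of the horizon, and ΔC combines straight-line amortization of hardware
and software with labor lines that scale linearly with herd size.

## Worked example

```python
from herdledger import (BudgetInputs, evaluate, break_even_herd_size,
                        scenario_table)

result = evaluate(BudgetInputs())   # 100 cows, 5 years, base trait changes
print(round(result.delta_cost, 1))            # 4215.8
print(round(result.delta_income, 1))          # 11109.5
print(round(result.gross_margin, 1))          # 6893.7
print(round(result.marginal_return_rate, 1))  # 163.5
print(break_even_herd_size(BudgetInputs()))   # 17
```

A 100-cow herd keeping records for five years spends ≈ $4216 more
(computer, license, 22.8 extra labor days/year) and gains ≈ $11,110 from
a 0.31 kg/year rise in daily milk yield and 1.02 fewer days open per
year — a gross margin of ≈ $6894 and a 163 % return on the extra money
spent. Below 17 cows the fixed investments are no longer covered.

The statistical side, end to end on synthetic data:

```python
import dataclasses
from herdledger import default_config, simulate_events, classify_adoption, \
    select_followup, derive_traits
from herdledger.pipeline import fit_trait

cfg = dataclasses.replace(default_config(), n_herds_per_level=(30, 30, 30))
events, meta, truth = simulate_events(cfg)
profiles = classify_adoption(events)
levels = {h: p.level for h, p in profiles.items() if p.level != "EXCLUDED"}
table = derive_traits(events, select_followup(profiles), levels=levels)
res = fit_trait(table, meta, levels, "DMY")
print(res.summary())                 # variance components, Wald tests
print(res.marginal_means().head())   # adoption-level x year trajectories
```

Or from the shell:

```bash
herdledger simulate --seed 1 --out-dir run/
herdledger classify --events run/events.csv --out run/profiles.csv
herdledger derive --events run/events.csv --out run/traits.csv
herdledger budget
herdledger sensitivity --mode mc --n 10000 --seed 42 --out corr.csv
herdledger reproduce-tables
```

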