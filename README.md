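# telecea

Trial-based cost-effectiveness analysis of remote video-consultation
services, built as a reusable, tested pipeline:

* **Service costing** — annuitized equipment investments (equivalent annual
  cost at a configurable discount rate and lifetime), recurring annual costs,
  and volume-driven per-consultation costs, all tagged by payer
  (health sector / patient / production loss) and equipment alternative
  (`telemedicine_A` standard videoconferencing units, `telemedicine_B`
  desktop conferencing, plus the `standard` in-person arm).
* **Travel and production-loss valuation** — per-mode fare schedule
  (per-km + per-trip, companion uplift, extra-transport surcharge, flat
  patient-paid user fee), and wage-valued work absence (part-time at 50%;
  patients on sick leave or outside employment excluded).
* **Outcomes** — EQ-5D-3L utility scoring with a pluggable tariff (the UK
  time-trade-off value set ships as the default), complete-case handling,
  QALYs gained = utility change x duration (1 year).
* **CEA engine** — per-consultation costs under societal or health-sector
  perspectives, dominance classification and ICERs, exact integer break-even
  consultation volumes, break-even curves, and one-way sensitivity scenarios
  (cheaper equipment, relocated hospital distance, health-sector
  perspective).
* **Synthetic trial generator** — seed-deterministic patient and consultation
  tables matching the motivating trial's marginals (arm sizes 190/199,
  1-6 consultations per patient, arm-specific travel modes and journey
  lengths, employment, EQ-5D responses at baseline and 12 months).
* **Statistics** — two-sample t tests (pooled or Welch), Pearson chi-square,
  and GEE with exchangeable working correlation and robust variance for
  clustered binary outcomes.

## CLI

```sh
telecea cost                      # annual service costs per alternative
telecea cea                       # cost-and-effectiveness synthesis at 300/yr
telecea breakeven                 # break-even volumes, all scenarios
telecea scenario skype_for_business
telecea simulate --seed 1 --out-dir data/   # synthetic trial CSVs
telecea report --out-dir output --seed 1    # full report bundle (JSON/CSV)
```

All commands default to the bundled fixtures (`src/telecea/data/`): the
service cost components, trial unit costs, fare schedule and tariff. Pass
`--cost-config` / `--unit-costs` to re-parameterize, or give
`telecea report --config run.yaml` a run-config YAML referencing your own
trial CSVs (`patients_csv`, `consultations_csv`) to re-price travel and
re-score QALYs from patient-level data.

Monetary config may be declared in NOK (`currency: NOK`); conversion to EUR
happens once at load (9.60 NOK/EUR).

## Layout

```
src/telecea/
  costing.py     annuitization, cost aggregation, fares, production losses
  outcomes.py    EQ-5D-3L states, tariffs, QALYs
  cea.py         perspectives, break-even solver, scenarios, curves
  synthetic.py   seeded trial generator and parameter-recovery report
  stats.py       t / chi-square / GEE comparisons, descriptive tables
  trial.py       patient-table scoring helpers
  io.py          YAML/CSV loaders with schema validation
  report.py      full-analysis orchestration
  cli.py         click-based command line
  data/          bundled fixtures (cost components, unit costs, fares, tariff)
```
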