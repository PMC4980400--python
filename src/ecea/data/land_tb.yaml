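# The country-"Land" tuberculosis scenario: universal public finance of TB
# treatment across five income quintiles of 2 million persons each.
strata:
  - {label: Q1, income: 300.0, incidence_per_100k: 400}
  - {label: Q2, income: 470.0, incidence_per_100k: 300}
  - {label: Q3, income: 640.0, incidence_per_100k: 200}
  - {label: Q4, income: 810.0, incidence_per_100k: 100}
  - {label: Q5, income: 980.0, incidence_per_100k: 0}
stratum_defaults:
  population: 2000000
  case_fatality: 0.20
  care_seeking: 0.40     # 40% of cases pay for treatment entirely out of pocket
  c_dm: 100.0            # $ per treated case, direct medical
policy:
  name: UPF TB treatment
  cov_baseline: 0.50
  cov_policy: 0.60       # +10 percentage points of treatment coverage
  effectiveness: 0.80
  unit_cost: 100.0       # $ per covered case, implementer perspective
  crowd_out: 1.0         # public finance fully displaces out-of-pocket payment
  cov_costing: 0.50      # the implementer prices coverage of 50% of cases
frp:
  metric: poverty
  threshold: 0.4
  poverty_line: 600.0
  risk_aversion: 3.0
  poverty_affected_fraction: 0.8   # documented reading reproducing 3,200 cases
currency_label: USD
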