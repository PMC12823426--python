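"""The survival estimators on tiny hand-checkable inputs.

Three patients suffice to see the product-limit recursion: a censoring at
day 5 leaves 2 at risk, the event at day 10 halves survival, the event at
day 15 takes it to zero.  With a competing death, the Aalen–Johansen
cumulative incidence weights each cause-specific event by the all-cause
survival just before it — here CIF(3) = (2/3) * (1/2) = 1/3, not the 1/2
a naive Kaplan–Meier on the cause would report.
"""

import pandas as pd

import ttebench as tb

km = tb.kaplan_meier(pd.DataFrame({
    "time": [5, 10, 15], "status": ["censored", "event", "event"]}))
print("Kaplan–Meier risk:  risk(10) =", km.risk_at(10), " risk(15) =", km.risk_at(15))

aj = tb.aalen_johansen(pd.DataFrame({
    "time": [1, 2, 3], "status": ["competing_death", "event", "censored"]}))
print("Aalen–Johansen cumulative incidence at day 3:", round(aj.risk_at(3), 4))

# Cox hazard ratio for an arm indicator, Efron ties
records = pd.DataFrame({
    "patient_id": range(8),
    "arm": ["exposure"] * 4 + ["comparator"] * 4,
    "time": [10, 40, 200, 364, 8, 25, 120, 300],
    "status": ["event", "event", "censored", "censored",
               "event", "event", "event", "censored"],
})
est = tb.cox_hr(records)
print(f"Cox HR exposure vs comparator: {est.hr:.3f} "
      f"(95% CI {est.ci_low:.3f}–{est.ci_high:.3f}), events {est.n_events}")
print("An HR below 1 means the exposure arm accrued events at a lower rate.")
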