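# Institutional five-fraction normal-tissue directives (doses in GyE).
# The liver rule is a sparing constraint: at least 700 cc of liver must
# receive < 15 GyE. The kidney V12 rule is applied to each kidney.
name: institutional-5fx
n_fractions: 5
constraints:
  - {structure: stomach, metric: max_dose, limit: 30.0, units: Gy, comparator: "<"}
  - {structure: bowel, metric: max_dose, limit: 30.0, units: Gy, comparator: "<"}
  - {structure: liver, metric: spare_volume, threshold_dose_gy: 15.0, limit: 700.0, units: cc, comparator: ">="}
  - {structure: kidney_ipsi, metric: V_at_dose, threshold_dose_gy: 12.0, limit: 33.0, units: "%", comparator: "<"}
  - {structure: kidney_contra, metric: V_at_dose, threshold_dose_gy: 12.0, limit: 33.0, units: "%", comparator: "<"}
  - {structure: spinal_canal, metric: max_dose, limit: 25.0, units: Gy, comparator: "<"}
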