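# Five-fraction iso-BED equivalents of published_constraints_28fx.yaml
# (alpha/beta = 3.0 Gy, nearest-0.05 Gy rounding). Doses in Gy (GyE for
# RBE-weighted proton plans). This is the golden counterpart used to
# verify the LQ conversion end to end.
name: derived-5fx
n_fractions: 5
constraints:
  - {structure: stomach, metric: V_at_dose, threshold_dose_gy: 25.55, limit: 100.0, units: "%", comparator: "<="}
  - {structure: stomach, metric: V_at_dose, threshold_dose_gy: 27.90, limit: 50.0, units: "%", comparator: "<="}
  - {structure: stomach, metric: max_dose, limit: 30.65, units: Gy, comparator: "<"}
  - {structure: duodenum, metric: V_at_dose, threshold_dose_gy: 25.55, limit: 100.0, units: "%", comparator: "<="}
  - {structure: duodenum, metric: V_at_dose, threshold_dose_gy: 27.90, limit: 50.0, units: "%", comparator: "<="}
  - {structure: duodenum, metric: max_dose, limit: 30.65, units: Gy, comparator: "<"}
  - {structure: bowel, metric: V_at_dose, threshold_dose_gy: 10.45, limit: 830.0, units: cc, comparator: "<"}
  - {structure: bowel, metric: V_at_dose, threshold_dose_gy: 25.55, limit: 195.0, units: cc, comparator: "<="}
  - {structure: liver, metric: mean_dose, limit: 16.30, units: Gy, comparator: "<"}
  - {structure: kidneys_bilateral, metric: mean_dose, limit: 10.45, units: Gy, comparator: "<", condition: both_remain}
  - {structure: kidneys_bilateral, metric: V_at_dose, threshold_dose_gy: 12.10, limit: 50.0, units: "%", comparator: "<", condition: both_remain}
  - {structure: kidneys_bilateral, metric: V_at_dose, threshold_dose_gy: 12.10, limit: 15.0, units: "%", comparator: "<", condition: one_resected}
  - {structure: femoral_head_ipsi, metric: V_at_dose, threshold_dose_gy: 23.20, limit: 64.0, units: "%", comparator: "<"}
  - {structure: femoral_head_ipsi, metric: max_dose, limit: 27.90, units: Gy, comparator: "<"}
  - {structure: femoral_head_ipsi, metric: mean_dose, limit: 21.75, units: Gy, comparator: "<"}
  - {structure: femoral_head_contra, metric: V_at_dose, threshold_dose_gy: 23.20, limit: 64.0, units: "%", comparator: "<"}
  - {structure: femoral_head_contra, metric: max_dose, limit: 27.90, units: Gy, comparator: "<"}
  - {structure: femoral_head_contra, metric: mean_dose, limit: 21.75, units: Gy, comparator: "<"}
  - {structure: spinal_canal, metric: max_dose, limit: 27.90, units: Gy, comparator: "<"}
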