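# Published conventionally-fractionated (28 fx) normal-tissue constraints
# from consensus retroperitoneal-sarcoma planning guidance. Doses in Gy.
# Femoral-head and kidney rows are expanded per evaluable structure.
name: published-28fx
n_fractions: 28
constraints:
  - {structure: stomach, metric: V_at_dose, threshold_dose_gy: 45.0, limit: 100.0, units: "%", comparator: "<="}
  - {structure: stomach, metric: V_at_dose, threshold_dose_gy: 50.0, limit: 50.0, units: "%", comparator: "<="}
  - {structure: stomach, metric: max_dose, limit: 56.0, units: Gy, comparator: "<"}
  - {structure: duodenum, metric: V_at_dose, threshold_dose_gy: 45.0, limit: 100.0, units: "%", comparator: "<="}
  - {structure: duodenum, metric: V_at_dose, threshold_dose_gy: 50.0, limit: 50.0, units: "%", comparator: "<="}
  - {structure: duodenum, metric: max_dose, limit: 56.0, units: Gy, comparator: "<"}
  - {structure: bowel, metric: V_at_dose, threshold_dose_gy: 15.0, limit: 830.0, units: cc, comparator: "<"}
  - {structure: bowel, metric: V_at_dose, threshold_dose_gy: 45.0, limit: 195.0, units: cc, comparator: "<="}
  - {structure: liver, metric: mean_dose, limit: 26.0, units: Gy, comparator: "<"}
  - {structure: kidneys_bilateral, metric: mean_dose, limit: 15.0, units: Gy, comparator: "<", condition: both_remain}
  - {structure: kidneys_bilateral, metric: V_at_dose, threshold_dose_gy: 18.0, limit: 50.0, units: "%", comparator: "<", condition: both_remain}
  - {structure: kidneys_bilateral, metric: V_at_dose, threshold_dose_gy: 18.0, limit: 15.0, units: "%", comparator: "<", condition: one_resected}
  - {structure: femoral_head_ipsi, metric: V_at_dose, threshold_dose_gy: 40.0, limit: 64.0, units: "%", comparator: "<"}
  - {structure: femoral_head_ipsi, metric: max_dose, limit: 50.0, units: Gy, comparator: "<"}
  - {structure: femoral_head_ipsi, metric: mean_dose, limit: 37.0, units: Gy, comparator: "<"}
  - {structure: femoral_head_contra, metric: V_at_dose, threshold_dose_gy: 40.0, limit: 64.0, units: "%", comparator: "<"}
  - {structure: femoral_head_contra, metric: max_dose, limit: 50.0, units: Gy, comparator: "<"}
  - {structure: femoral_head_contra, metric: mean_dose, limit: 37.0, units: Gy, comparator: "<"}
  - {structure: spinal_canal, metric: max_dose, limit: 50.0, units: Gy, comparator: "<"}
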