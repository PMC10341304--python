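# Target dose and coverage goals for the 25/30 GyE-in-5-fraction
# prescription: percentage of the target volume that must receive 100% of
# the prescribed dose, at the planning goal and at the hard constraint,
# plus the global maximum point dose as a percentage of the prescription.
goals:
  - {target: gtv, prescription_gye: 25.0, goal_pct: 100.0, hard_pct: 98.0, max_point_pct: 108.0}
  - {target: ctv, prescription_gye: 25.0, goal_pct: 98.0, hard_pct: 95.0, max_point_pct: 108.0}
  - {target: ctv_boost, prescription_gye: 30.0, goal_pct: 95.0, hard_pct: 90.0, max_point_pct: 108.0}
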