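never: 0.0
couple_times_per_year: 0.0054757015742642025
1-3_per_month: 0.0657030223390276
once_per_week: 0.14285714285714285
2-3_per_week: 0.35714285714285715
4-6_per_week: 0.7142857142857143
once_per_day: 1.0
2-3_per_day: 2.5
4+_per_day: 4.0
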