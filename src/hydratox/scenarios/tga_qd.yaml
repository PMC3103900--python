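# Thioglycolic-acid-capped CdTe quantum dots: the more toxic surface chemistry.
# Hazard anchored to the published reference points (300 nM -> LT50 36 hr;
# dose exponent solved so the implied 72-hr LC50 is 153.24 nM).
label: TGA-QDs
lt50_ref_hr: 36.0
dose_ref_nM: 300.0
dose_exponent: 1.0319
lifetime_shape: 6.0
doses_nM: [50, 100, 200, 300, 500, 750, 1000, 1500, 2000]
times_hr: [24, 48, 72]
n_per_group: 20
emergence_rate: 2.5
elongation_rate: 0.8
delay_factor: 1.9
n_polyps: 4
regen_days: 14
k_treated: 0.15
k_control: 0.25
n0: 4
growth_days: 14
n_replicates: 3
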