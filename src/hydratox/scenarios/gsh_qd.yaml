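# Glutathione-capped CdTe quantum dots: the milder surface chemistry.
# Hazard anchored to the published reference points (500 nM -> LT50 63 hr;
# dose exponent solved so the implied 72-hr LC50 is 434.29 nM).
label: GSH-QDs
lt50_ref_hr: 63.0
dose_ref_nM: 500.0
dose_exponent: 0.9478
lifetime_shape: 6.0
doses_nM: [50, 100, 200, 300, 500, 750, 1000, 1500, 2000]
times_hr: [24, 48, 72]
n_per_group: 20
emergence_rate: 2.5
elongation_rate: 0.8
delay_factor: 1.0
n_polyps: 4
regen_days: 14
k_treated: 0.24
k_control: 0.25
n0: 4
growth_days: 14
n_replicates: 3
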