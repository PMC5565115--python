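species_code,total_length_m,head_width_m,swim_speed_mean_ms,swim_speed_travel_ms,swim_speed_ars_ms,pbr
blue,20.9,2.96,1.0,1.8,0.5,2.3
humpback,13.5,3.21,1.1,1.6,0.6,11
fin,18.48,2.65,1.3,2.5,0.8,16
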