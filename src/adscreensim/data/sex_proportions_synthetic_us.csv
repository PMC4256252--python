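# Synthetic base-age -> proportion-female table (US-census-style approximation).
base_age,prop_female
55,0.520
60,0.530
65,0.540
70,0.550
75,0.570
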