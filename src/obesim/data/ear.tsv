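sex	age_years	kcal
male	3.0	1171.0
female	3.0	1076.0
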