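sex	age_years	L	M	S
male	2.0	-1.60	16.20	0.080
male	3.0	-1.45	15.90	0.082
male	4.0	-1.30	15.70	0.084
male	5.0	-1.15	15.60	0.087
male	6.0	-1.00	15.55	0.090
male	7.0	-0.85	15.70	0.094
male	8.0	-0.70	15.95	0.098
female	2.0	-1.50	16.00	0.084
female	3.0	-1.35	15.70	0.086
female	4.0	-1.20	15.50	0.089
female	5.0	-1.05	15.45	0.092
female	6.0	-0.90	15.50	0.096
female	7.0	-0.75	15.70	0.100
female	8.0	-0.60	16.00	0.104
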