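step	group	count	percent
enrolled_with_scan	all	180	
scanned_W1	all	172	
scanned_W2	all	172	
excluded_implausible_dates	all	0	
excluded_outliers_W1	W1	0	
retained_W1	W1	172	
excluded_outliers_W2	W2	0	
retained_W2	W2	172	
with_birthweight	all	157	87.2
classifiable_lt_42wk	all	152	96.8
sga	all	41	27.0
aga	all	111	73.0
sga_site	A	22	44.0
sga_site	B	15	28.3
sga_site	C	4	8.2
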