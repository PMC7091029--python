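estimator	window	stratum	n	bias	ci_low	ci_high	loa_low	loa_high	approximation
chavez_tcd	W1	ALL	171	-1.4	-2.5	-0.4	-15.1	12.3	13.7
chavez_tcd	W1	AGA	104	-1.2	-2.5	0.1	-14.5	12.1	13.3
chavez_tcd	W1	SGA	40	-1.5	-3.5	0.6	-14.3	11.4	12.9
chavez_tcd	W2	ALL	171	-0.5	-1.4	0.3	-11.4	10.3	10.9
chavez_tcd	W2	AGA	108	-0.5	-1.5	0.5	-11.4	10.4	10.9
chavez_tcd	W2	SGA	37	-1.2	-2.8	0.4	-11.1	8.7	9.9
hadlock_bpd	W1	ALL	171	-3.6	-4.7	-2.5	-18.2	11.0	14.6
hadlock_bpd	W1	AGA	104	-2.4	-3.7	-1.1	-15.7	10.9	13.3
hadlock_bpd	W1	SGA	40	-5.7	-8.2	-3.2	-21.5	10.0	15.7
hadlock_bpd	W2	ALL	171	-4.3	-5.8	-2.8	-23.8	15.2	19.5
hadlock_bpd	W2	AGA	108	-2.3	-4.0	-0.7	-19.7	15.1	17.4
hadlock_bpd	W2	SGA	37	-8.5	-11.9	-5.1	-29.2	12.1	20.6
intergrowth_hc	W1	ALL	170	-3.8	-4.8	-2.7	-17.5	9.9	13.7
intergrowth_hc	W1	AGA	103	-2.5	-3.6	-1.3	-14.2	9.3	11.8
intergrowth_hc	W1	SGA	40	-6.9	-9.4	-4.5	-22.4	8.5	15.4
intergrowth_hc	W2	ALL	172	-5.5	-7.1	-3.9	-26.6	15.6	21.1
intergrowth_hc	W2	AGA	109	-2.8	-4.6	-1.0	-21.6	16.0	18.8
intergrowth_hc	W2	SGA	37	-12.1	-15.3	-8.9	-31.7	7.5	19.6
hadlock_fl	W1	ALL	172	-3.3	-4.3	-2.3	-16.7	10.1	13.4
hadlock_fl	W1	AGA	105	-1.9	-3.1	-0.7	-13.9	10.1	12.0
hadlock_fl	W1	SGA	40	-7.3	-9.3	-5.2	-20.2	5.7	12.9
hadlock_fl	W2	ALL	172	-4.0	-5.4	-2.7	-21.7	13.6	17.7
hadlock_fl	W2	AGA	109	-1.9	-3.5	-0.3	-18.5	14.7	16.6
hadlock_fl	W2	SGA	37	-9.3	-12.1	-6.5	-26.4	7.7	17.0
hadlock_ac	W1	ALL	171	-2.7	-3.7	-1.7	-15.9	10.6	13.3
hadlock_ac	W1	AGA	104	-2.2	-3.4	-0.9	-14.9	10.6	12.7
hadlock_ac	W1	SGA	40	-5.0	-7.2	-2.9	-18.8	8.8	13.8
hadlock_ac	W2	ALL	171	-4.0	-5.3	-2.6	-21.3	13.4	17.3
hadlock_ac	W2	AGA	108	-3.0	-4.6	-1.4	-19.6	13.6	16.6
hadlock_ac	W2	SGA	37	-7.9	-10.9	-4.9	-26.0	10.2	18.1
hadlock_combo	W1	ALL	170	-2.6	-3.8	-1.5	-17.7	12.5	15.1
hadlock_combo	W1	AGA	103	-1.5	-2.9	-0.1	-15.6	12.6	14.1
hadlock_combo	W1	SGA	40	-5.9	-8.5	-3.4	-22.4	10.5	16.4
hadlock_combo	W2	ALL	170	-2.9	-4.0	-1.9	-16.6	10.8	13.7
hadlock_combo	W2	AGA	107	-1.5	-2.7	-0.4	-13.8	10.7	12.2
hadlock_combo	W2	SGA	37	-6.5	-9.1	-4.0	-22.0	9.0	15.5
intergrowth_combo	W1	ALL	170	-2.8	-4.1	-1.6	-19.1	13.4	16.2
intergrowth_combo	W1	AGA	103	-1.2	-2.7	0.2	-15.8	13.3	14.5
intergrowth_combo	W1	SGA	40	-7.2	-10.0	-4.5	-24.6	10.2	17.4
intergrowth_combo	W2	ALL	172	-3.3	-4.5	-2.2	-18.5	11.8	15.1
intergrowth_combo	W2	AGA	109	-1.4	-2.6	-0.2	-14.3	11.5	12.9
intergrowth_combo	W2	SGA	37	-8.1	-10.7	-5.6	-23.8	7.5	15.7
amanhi_model1	W1	ALL	169	1.0	0.2	1.8	-9.4	11.4	10.4
amanhi_model1	W1	AGA	102	1.6	0.6	2.5	-8.1	11.2	9.6
amanhi_model1	W1	SGA	40	-0.6	-2.2	1.0	-10.8	9.7	10.2
amanhi_model1	W2	ALL	169	-1.0	-1.7	-0.3	-10.2	8.2	9.2
amanhi_model1	W2	AGA	106	-0.5	-1.4	0.4	-9.8	8.7	9.2
amanhi_model1	W2	SGA	37	-2.8	-4.1	-1.5	-10.9	5.3	8.1
amanhi_model2	W1	ALL	171	1.0	0.2	1.8	-9.8	11.8	10.8
amanhi_model2	W1	AGA	104	1.7	0.7	2.7	-8.2	11.6	9.9
amanhi_model2	W1	SGA	40	-0.6	-2.4	1.1	-11.7	10.4	11.0
amanhi_model2	W2	ALL	171	-1.0	-1.7	-0.3	-10.2	8.2	9.2
amanhi_model2	W2	AGA	108	-0.5	-1.4	0.4	-9.9	9.0	9.4
amanhi_model2	W2	SGA	37	-2.7	-4.0	-1.5	-10.6	5.1	7.8
amanhi_model3	W1	ALL	170	1.1	0.2	2.0	-10.4	12.6	11.5
amanhi_model3	W1	AGA	103	1.6	0.6	2.7	-9.1	12.3	10.7
amanhi_model3	W1	SGA	40	0.4	-1.4	2.1	-10.8	11.6	11.2
amanhi_model3	W2	ALL	170	-1.1	-1.8	-0.3	-10.9	8.7	9.8
amanhi_model3	W2	AGA	107	-0.7	-1.6	0.3	-10.2	8.9	9.6
amanhi_model3	W2	SGA	37	-2.4	-3.8	-1.0	-10.8	6.0	8.4
amanhi_model4	W1	ALL	170	1.1	0.2	1.9	-9.8	12.0	10.9
amanhi_model4	W1	AGA	103	1.3	0.3	2.4	-9.0	11.7	10.3
amanhi_model4	W1	SGA	40	0.2	-1.4	1.8	-9.9	10.3	10.1
amanhi_model4	W2	ALL	170	-1.1	-1.8	-0.3	-10.7	8.6	9.6
amanhi_model4	W2	AGA	107	-0.8	-1.8	0.1	-10.4	8.7	9.5
amanhi_model4	W2	SGA	37	-2.4	-3.8	-1.1	-10.8	6.0	8.4
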