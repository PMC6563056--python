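system	pair	exp_A	md_avg_A	md_err_A	md_violation_A	leus_avg_A	leus_err_A	leus_violation_A
1	d(HT,H)	2.9	3.4	0.02	0.5	3.4	0.2	0.5
1	d(HA,HT)	2.3	2.3	0.01	0	2.3	0.06	0
1	d(HA,H)	2.9	2.6	0.02	0	2.7	0.2	0
1	d(HT,HB1)	2.5	3.5	0.01	1.0	3.2	0.2	0.7
1	d(HT,HB2)	2.6	3.2	0.06	0.6	3.1	0.2	0.5
1	d(H1,HA)	3.9	3.8	0.01	0	3.7	0.6	0
2	d(HT,H)	2.8	3.8	0.03	1.0	4.0	0.6	1.2
2	d(HA,HT)	2.4	2.2	0.3	0	2.2	0.6	0
2	d(HA,H)	2.9	2.8	0.01	0	2.7	0.03	0
2	d(HT,HB)	2.8	3.2	0.01	0.4	2.8	0.1	0
2	d(H,HB)	3.5	3.0	0.2	0	3.4	0.4	0
2	d(H,HN2)	3.3	4.0	0.06	0.6	3.4	0.3	0.1
3	d(HT,H)	2.9	3.4	0.03	0.5	3.6	0.2	0.7
3	d(HA,HT)	2.2	2.3	0.01	0.1	2.3	0.00	0.1
3	d(HA,H)	2.6	2.6	0.04	0	2.7	0.1	0.1
3	d(HT,HB1)	2.6	3.4	0.01	0.8	3.4	0.2	0.8
3	d(HT,HB2)	2.8	3.3	0.04	0.5	3.4	0.3	0.6
4	d(HT,H)	3.0	3.4	0.02	0.4	3.1	0.1	0.1
4	d(HA,HT)	2.3	2.3	0.01	0	2.3	0.06	0
4	d(HA,H)	2.8	2.7	0.01	0.1	2.7	0.1	0.1
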