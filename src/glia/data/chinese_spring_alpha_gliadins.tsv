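gene_id	genome	mw	pi	q_count_I	q_count_II	DQ2.5-glia-a1a	DQ2.5-glia-a1b	DQ2.5-glia-a2	DQ2.5-glia-a3	DQ8-glia-a1	has_33mer	has_cstt
alpha-A1	A	31440	6.37	14	9	0	0	0	0	1	0	1
alpha-A2	A	34470	6.5	29	14	0	0	0	0	1	0	1
alpha-A4	A	30506	7.12	14	7	1	0	0	1	0	0	0
alpha-A5	A	33479	6.62	36	8	1	0	0	1	0	0	0
alpha-A6	A	30621	7.79	16	6	1	0	0	1	0	0	0
alpha-A8	A	31050	7.08	17	7	1	0	0	1	0	0	0
alpha-A9	A	32181	6.53	23	12	1	0	0	0	0	0	0
alpha-A10	A	29996	6.18	11	7	1	0	0	1	0	0	0
alpha-B3	B	36206	7.76	22	45	0	0	0	0	1	0	1
alpha-B7	B	33968	7.12	18	23	0	0	0	0	0	0	1
alpha-B8	B	34781	8.28	23	25	0	0	0	0	0	0	1
alpha-B9	B	33977	7.16	18	22	0	0	0	0	0	0	1
alpha-B11	B	31535	7.07	17	16	0	0	0	0	0	0	1
alpha-B14	B	31413	7.02	17	16	0	0	0	0	0	0	1
alpha-B15	B	32054	6.42	15	23	0	0	0	0	0	0	1
alpha-B16	B	32039	6.42	19	18	0	0	0	0	0	0	1
alpha-B17	B	31714	7.12	19	16	0	0	0	0	0	0	1
alpha-B18	B	31828	7.12	15	13	0	0	0	0	0	0	1
alpha-B25	B	33817	7.78	12	36	0	0	0	0	1	0	1
alpha-D1	D	30699	6.53	13	12	0	0	0	0	1	0	1
alpha-D4	D	31542	6.79	16	10	1	0	1	0	1	0	0
alpha-D5	D	33412	7.75	20	12	1	2	3	1	1	1	0
alpha-D6	D	31706	6.53	13	14	1	1	2	0	1	0	0
alpha-D8	D	31706	6.53	14	11	1	1	2	1	1	0	0
alpha-D12	D	30175	6.44	11	6	0	0	0	0	0	0	1
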